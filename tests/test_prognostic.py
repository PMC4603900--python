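import itertools
import math

import numpy as np
import pytest

from snpindex.data_model import Genotype, PanelSpec, SNPSpec, default_panel
from snpindex.association import ModelFit, SNPAssociation, GenotypeCounts
from snpindex.prognostic import (build_score_map, choose_cutoff, classify,
                                 combined_analysis, compute_index,
                                 select_genetic_model)
from snpindex.synthetic import GeneratorConfig, generate_cohort


def _assoc(snp_id, p_dom, p_rec, p_add, coef=0.5):
    def fit(p):
        return ModelFit(hr=math.exp(coef), ci95=(1.0, 2.0), p=p,
                        coef=coef, se=0.2, converged=p is not None)
    return SNPAssociation(
        snp_id, "os", GenotypeCounts(50, 30, 20), 0.35, 0.9,
        (0.7, 0.65, 0.5), (10, 8, 9), None, None,
        {"dominant": fit(p_dom), "recessive": fit(p_rec), "additive": fit(p_add)})


class TestSelectGeneticModel:
    def test_smallest_os_p_wins(self):
        # dominant 0.02 / recessive 0.007 / additive 0.004 -> additive
        assert select_genetic_model(_assoc("rs2287845", 0.02, 0.007, 0.004)) \
            == "additive"

    def test_tie_breaks_toward_additive(self):
        # dominant and additive tied at 0.004 -> additive by preference
        assert select_genetic_model(_assoc("rs3756585", 0.004, 0.02, 0.004)) \
            == "additive"

    def test_single_converged_model_selected(self):
        a = _assoc("rs1", 0.5, 0.5, 0.5)
        a.model_fits["dominant"] = ModelFit.not_estimable("x")
        a.model_fits["additive"] = ModelFit.not_estimable("x")
        assert select_genetic_model(a) == "recessive"

    def test_no_converged_model_errors(self):
        a = _assoc("rs1", None, None, None)
        for k in a.model_fits:
            a.model_fits[k] = ModelFit.not_estimable("x")
        with pytest.raises(ValueError, match="no collapsed model"):
            select_genetic_model(a)

    def test_explicit_model_overrides(self):
        spec = SNPSpec("rs1", "G", "A", "G", genetic_model="recessive",
                       risk_direction="variant_is_risk")
        assert select_genetic_model(_assoc("rs1", 0.001, 0.9, 0.5), spec) \
            == "recessive"


@pytest.fixture(scope="module")
def score_map(panel):
    assocs = {s.snp_id: _assoc(s.snp_id, 0.5, 0.5, 0.5) for s in panel.snps}
    return build_score_map(panel, assocs)


class TestBuildScoreMap:
    def test_recessive_scoring(self, score_map):
        # CD3EAP recessive, variant A is risk: GG/GA low, AA high
        assert score_map.scores["rs967591"] == {"GG": 1, "GA": 1, "AA": 3}

    def test_additive_scoring(self, score_map):
        # C3 additive, variant C is risk
        assert score_map.scores["rs2287845"] == {"TT": 1, "TC": 2, "CC": 3}

    def test_dominant_scoring(self, score_map):
        assert score_map.scores["rs3803300"] == {"AA": 1, "AG": 3, "GG": 3}

    def test_protective_variant_flips(self):
        spec = SNPSpec("rs9", "G9", "A", "G")
        panel = PanelSpec((spec,))
        assoc = _assoc("rs9", 0.01, 0.5, 0.5, coef=-0.4)  # protective variant
        sm = build_score_map(panel, {"rs9": assoc})
        assert sm.models["rs9"] == "dominant"
        assert sm.risk_directions["rs9"] == "wild_is_risk"
        assert sm.scores["rs9"]["AA"] == 3  # wild-hom is the risk carrier
        assert sm.scores["rs9"]["GG"] == 1

    def test_zero_coefficient_orientation_undecidable(self):
        spec = SNPSpec("rs9", "G9", "A", "G")
        assoc = _assoc("rs9", 0.01, 0.5, 0.5, coef=0.0)
        with pytest.raises(ValueError, match="orientation"):
            build_score_map(PanelSpec((spec,)), {"rs9": assoc})


def _subject_with(panel, calls):
    from snpindex.data_model import Subject
    genos = {s.snp_id: Genotype.from_string(s.snp_id, c, s)
             for s, c in zip(panel.snps, calls)}
    return Subject("X", "<=64", "male", "ever", 10.0, "SCC", "I", 0,
                   10.0, 0, 10.0, 0, genos)


class TestComputeIndex:
    def test_exhaustive_enumeration_bounds(self, panel, score_map):
        """All 3^8 genotype vectors: min 8, max 24, all integers in [8,24]."""
        all_indices = []
        label_sets = [s.genotype_labels() for s in panel.snps]
        for combo in itertools.product(*label_sets):
            total = sum(score_map.scores[s.snp_id][lab]
                        for s, lab in zip(panel.snps, combo))
            all_indices.append(total)
        assert len(all_indices) == 3 ** 8
        assert min(all_indices) == 8
        assert max(all_indices) == 24
        assert all(8 <= v <= 24 for v in all_indices)

    def test_all_low_and_all_high(self, panel, score_map):
        low = _subject_with(panel, [s.genotype_labels()[0] for s in panel.snps])
        high = _subject_with(panel, [s.genotype_labels()[2] for s in panel.snps])
        assert compute_index(low, score_map) == 8
        assert compute_index(high, score_map) == 24

    def test_missing_genotype_undefined(self, panel, score_map):
        subj = _subject_with(panel, [s.genotype_labels()[0] for s in panel.snps])
        subj.genotypes["rs967591"] = Genotype("rs967591", None)
        assert compute_index(subj, score_map) is None

    def test_monotone_in_genotype_score(self, panel, score_map):
        """Raising any one SNP to a higher-scoring genotype never lowers
        the index."""
        rng = np.random.default_rng(41)
        labels = [s.genotype_labels() for s in panel.snps]
        for _ in range(50):
            combo = [labs[rng.integers(3)] for labs in labels]
            base = compute_index(_subject_with(panel, combo), score_map)
            i = rng.integers(8)
            snp = panel.snps[i]
            scores = score_map.scores[snp.snp_id]
            for lab in labels[i]:
                if scores[lab] >= scores[combo[i]]:
                    bumped = list(combo)
                    bumped[i] = lab
                    assert compute_index(_subject_with(panel, bumped),
                                         score_map) >= base


class TestChooseCutoff:
    def test_published_fraction_example(self):
        # 394/1000 at >=15 and 250/1000 at >=16: cutoff 15 is closer to 1/3
        indices = [14] * 606 + [15] * 144 + [16] * 250
        assert choose_cutoff(indices) == 15

    def test_degenerate_all_equal(self):
        # all indices v: empty high group beats everyone-high
        assert choose_cutoff([12] * 40) == 13

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(43)
        indices = rng.integers(8, 21, size=500)
        best = min(range(8, 23),
                   key=lambda c: (abs((indices >= c).mean() - 1 / 3), c))
        assert choose_cutoff(indices) == best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_cutoff([])


@pytest.fixture(scope="module")
def cohort_and_map(default_cohort):
    cohort, _ = default_cohort
    assocs = {s.snp_id: _assoc(s.snp_id, 0.5, 0.5, 0.5)
              for s in cohort.panel.snps}
    return cohort, build_score_map(cohort.panel, assocs)


class TestCombinedAnalysis:
    def test_group_sizes_and_exclusions(self, cohort_and_map):
        cohort, sm = cohort_and_map
        rep = combined_analysis(cohort, sm, endpoint="os")
        assert rep.low.n + rep.high.n + rep.n_excluded_missing == cohort.n
        assert rep.n_excluded_missing > 0  # default missing rate ~1%/SNP
        assert rep.low.pct + rep.high.pct == pytest.approx(100.0)

    def test_risk_effect_direction(self, cohort_and_map):
        """Generated SNP effects are harmful, so high-risk HR > 1."""
        cohort, sm = cohort_and_map
        rep = combined_analysis(cohort, sm, endpoint="os")
        assert rep.high_vs_low["hr"] > 1.0
        assert rep.high.five_year_rate < rep.low.five_year_rate
        assert 0 < rep.logrank.p_value <= 1

    def test_classification_consistency(self, cohort_and_map):
        cohort, sm = cohort_and_map
        res = classify(cohort, sm)
        idx = res.index[res.defined]
        frac = (idx >= res.cutoff).mean()
        # within one subject's mass of the brute-force optimum
        best = min((abs((idx >= c).mean() - 1 / 3)
                    for c in range(int(idx.min()), int(idx.max()) + 2)))
        assert abs(frac - 1 / 3) <= best + 1.0 / idx.size + 1e-12

    def test_fixed_cutoff_respected(self, cohort_and_map):
        cohort, sm = cohort_and_map
        rep = combined_analysis(cohort, sm, cutoff=15, endpoint="dfs")
        assert rep.cutoff == 15
        res = classify(cohort, sm, cutoff=15)
        assert ((res.index[res.defined] >= 15) ==
                (res.risk_group[res.defined] == "high")).all()

    def test_degenerate_single_group_rejected(self, cohort_and_map):
        cohort, sm = cohort_and_map
        with pytest.raises(ValueError, match="degenerate"):
            combined_analysis(cohort, sm, cutoff=0, endpoint="os")
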