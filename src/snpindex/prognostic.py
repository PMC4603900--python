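"""The SNP prognostic index: model selection, genotype scoring, tertile
cutoff, risk-group classification and the combined survival comparison.

Each panel SNP gets a genetic model (explicit in the panel, or selected
as the collapsed model with the smallest OS Wald p) and a genotype
score: under the additive model the three genotypes score 1/2/3 by
risk-allele count; under dominant or recessive the low-risk grouping
scores 1 and the high-risk grouping 3.  The per-subject index is the
sum over the panel, so an eight-SNP panel yields integer indices in
[8, 24].  An integer cutoff places approximately the top tertile of
defined indices in the high-risk group; the two groups are then
compared by Kaplan-Meier/log-rank and a covariate-adjusted Cox model.
Subjects missing any panel genotype have an undefined index and are
excluded from the combined analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import Cohort, FIVE_YEARS, PanelSpec, SNPSpec, Subject, covariate_design
from .survival import (CoxFit, KMCurve, LogRankResult, cox_fit, km_estimate,
                       logrank_test, survival_at)
from .association import SNPAssociation, genotype_code

MODEL_PREFERENCE = ("additive", "recessive", "dominant")  # tie-break order
DEFAULT_TARGET_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class ScoreMap:
    """Per-SNP mapping from canonical genotype string to score 1/2/3."""

    scores: Mapping[str, Mapping[str, int]]  # snp_id -> {"GG": 1, ...}
    models: Mapping[str, str]                # snp_id -> chosen model
    risk_directions: Mapping[str, str]

    def score(self, snp_id: str, genotype_string: str) -> int:
        return self.scores[snp_id][genotype_string]


@dataclass
class IndexResult:
    subject_ids: list[str]
    index: np.ndarray            # float; NaN where undefined
    cutoff: int
    risk_group: np.ndarray       # "high"/"low"/"" (undefined)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.index)


@dataclass
class GroupSummary:
    n: int
    pct: float
    n_events: int
    event_pct: float
    five_year_rate: float
    km: KMCurve


@dataclass
class RiskGroupReport:
    """The combined risk-group analysis for one endpoint."""

    endpoint: str
    cutoff: int
    low: GroupSummary
    high: GroupSummary
    logrank: LogRankResult
    cox: CoxFit
    high_vs_low: dict            # hr / ci95 / p / coef / se
    n_excluded_missing: int


def select_genetic_model(assoc: SNPAssociation,
                         spec: Optional[SNPSpec] = None) -> str:
    """Choose the collapsed genetic model for one SNP.

    An explicit model on the SNP spec wins.  Otherwise the converged
    collapsed fit (dominant/recessive/additive) with the smallest OS
    Wald p is chosen; exact ties break by preference
    additive > recessive > dominant.
    """
    if spec is not None and spec.genetic_model is not None:
        return spec.genetic_model
    candidates = [(m, f) for m, f in assoc.model_fits.items()
                  if f is not None and f.converged and f.p is not None]
    if not candidates:
        raise ValueError(f"{assoc.snp_id}: no collapsed model converged")
    best_p = min(f.p for _, f in candidates)
    tied = {m for m, f in candidates if f.p == best_p}
    for m in MODEL_PREFERENCE:
        if m in tied:
            return m
    raise AssertionError("unreachable")


def build_score_map(panel: PanelSpec,
                    associations: Optional[Mapping[str, SNPAssociation]] = None,
                    ) -> ScoreMap:
    """Assign genotype scores for every panel SNP.

    The model comes from the panel spec or :func:`select_genetic_model`;
    the risk orientation comes from the spec or, failing that, the sign
    of the chosen model's coefficient (positive coefficient on the
    variant coding means the variant allele is the risk allele).
    Higher risk always maps to a higher score.
    """
    scores: dict[str, dict[str, int]] = {}
    models: dict[str, str] = {}
    directions: dict[str, str] = {}
    for spec in panel.snps:
        if spec.genetic_model is not None and spec.risk_direction is not None:
            assoc = None
            model = spec.genetic_model
        else:
            if associations is None:
                raise ValueError(
                    f"{spec.snp_id}: no explicit model/orientation and no "
                    "associations supplied to select from")
            assoc = associations[spec.snp_id]
            model = select_genetic_model(assoc, spec)
        direction = spec.risk_direction
        if direction is None:
            fit = assoc.model_fits[model]
            if fit is None or fit.coef is None or fit.coef == 0.0:
                raise ValueError(
                    f"{spec.snp_id}: risk orientation undecidable "
                    "(no usable coefficient sign)")
            direction = "variant_is_risk" if fit.coef > 0 else "wild_is_risk"
        oriented = SNPSpec(spec.snp_id, spec.gene, spec.wild_allele,
                           spec.variant_allele, model, direction)
        per_geno: dict[str, int] = {}
        for label, nv in zip(spec.genotype_labels(), (0, 1, 2)):
            n_risk = nv if direction == "variant_is_risk" else 2 - nv
            if model == "additive":
                per_geno[label] = 1 + n_risk            # 1 / 2 / 3
            elif model == "dominant":
                per_geno[label] = 3 if n_risk >= 1 else 1
            else:                                        # recessive
                per_geno[label] = 3 if n_risk == 2 else 1
        scores[spec.snp_id] = per_geno
        models[spec.snp_id] = model
        directions[spec.snp_id] = direction
    return ScoreMap(scores, models, directions)


def compute_index(subject: Subject, score_map: ScoreMap) -> Optional[int]:
    """Sum of per-SNP genotype scores; None if any panel genotype is
    missing (the subject is excluded from the combined analysis)."""
    total = 0
    for snp_id, per_geno in score_map.scores.items():
        g = subject.genotypes.get(snp_id)
        if g is None or g.is_missing:
            return None
        total += per_geno[g.to_string()]
    return total


def choose_cutoff(indices: Sequence[int],
                  target_fraction: float = DEFAULT_TARGET_FRACTION) -> int:
    """Integer cutoff c minimizing |fraction(index >= c) − target|.

    Scans every achievable threshold (ties broken toward the smaller
    cutoff), so the high-risk group is the best integer approximation
    to the target upper tail — the "approximate tertile" rule with the
    default target of 1/3.
    """
    idx = np.asarray(list(indices), dtype=float)
    idx = idx[~np.isnan(idx)]
    if idx.size == 0:
        raise ValueError("no defined indices")
    lo, hi = int(idx.min()), int(idx.max())
    best_c, best_err = None, np.inf
    for c in range(lo, hi + 2):       # hi+1 gives an empty high group
        frac = float((idx >= c).mean())
        err = abs(frac - target_fraction)
        if err < best_err - 1e-12:
            best_c, best_err = c, err
    return int(best_c)


def enumerate_indices(panel: PanelSpec, score_map: ScoreMap) -> np.ndarray:
    """Index values of every genotype combination (3^k vectors)."""
    import itertools
    label_sets = [s.genotype_labels() for s in panel.snps]
    return np.array([
        sum(score_map.scores[s.snp_id][lab]
            for s, lab in zip(panel.snps, combo))
        for combo in itertools.product(*label_sets)])


def compute_indices(cohort: Cohort, score_map: ScoreMap) -> tuple[list[str], np.ndarray]:
    ids, vals = [], []
    for s in cohort.subjects:
        ids.append(s.subject_id)
        v = compute_index(s, score_map)
        vals.append(np.nan if v is None else float(v))
    return ids, np.array(vals)


def classify(cohort: Cohort, score_map: ScoreMap,
             cutoff: Optional[int] = None,
             target_fraction: float = DEFAULT_TARGET_FRACTION) -> IndexResult:
    """Compute indices, choose (or accept) the cutoff, and classify."""
    ids, idx = compute_indices(cohort, score_map)
    if cutoff is None:
        cutoff = choose_cutoff(idx[~np.isnan(idx)], target_fraction)
    group = np.where(np.isnan(idx), "",
                     np.where(idx >= cutoff, "high", "low"))
    return IndexResult(ids, idx, int(cutoff), group)


def combined_analysis(cohort: Cohort, score_map: ScoreMap,
                      cutoff: Optional[int] = None, endpoint: str = "os",
                      covariate_set: Optional[Sequence[str]] = None) -> RiskGroupReport:
    """Risk-group survival comparison: counts, KM 5-year rates, log-rank
    p, and the covariate-adjusted Cox hazard ratio for high vs low.

    Subjects with undefined index are excluded; both groups must be
    nonempty with at least one event between them.
    """
    covariate_set = tuple(covariate_set if covariate_set is not None
                          else cohort.panel.covariate_set)
    result = classify(cohort, score_map, cutoff)
    keep = result.defined
    n_excluded = int((~keep).sum())

    frame = cohort.to_frame().loc[keep].reset_index(drop=True)
    group = result.risk_group[keep]
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise ValueError(
            f"degenerate classification at cutoff {result.cutoff}: one risk "
            "group is empty")
    times = frame[f"{endpoint}_time"].to_numpy(dtype=float)
    events = frame[f"{endpoint}_event"].to_numpy(dtype=int)

    summaries = {}
    n_def = len(frame)
    for name in ("low", "high"):
        m = group == name
        km = km_estimate(times[m], events[m])
        ne = int(events[m].sum())
        summaries[name] = GroupSummary(
            n=int(m.sum()), pct=100.0 * m.sum() / n_def,
            n_events=ne, event_pct=100.0 * ne / m.sum(),
            five_year_rate=survival_at(km, FIVE_YEARS), km=km)

    lr = logrank_test(times, events, group)
    design = covariate_design(frame, covariate_set)
    design.insert(0, "high_risk", (group == "high").astype(float))
    fit = cox_fit(times, events, design)
    return RiskGroupReport(endpoint, result.cutoff, summaries["low"],
                           summaries["high"], lr, fit, fit["high_risk"],
                           n_excluded)
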