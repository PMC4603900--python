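"""Per-SNP descriptive genetics and adjusted survival association.

For each panel SNP: genotype counts and column percentages, minor
allele frequency, a 1-df Hardy-Weinberg chi-square, Kaplan-Meier
5-year rates per genotype, and covariate-adjusted Cox hazard ratios at
genotype level (het and variant-hom vs wild-hom) and under the three
collapsed genetic models (dominant, recessive, additive).

Missing genotypes are handled per SNP: each SNP's fits use that SNP's
complete cases, so per-SNP totals may differ across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (Cohort, FIVE_YEARS, Genotype, SNPSpec,
                         covariate_design)
from .survival import CoxFit, NonIdentifiableError, cox_fit, km_estimate, survival_at

MISSING_CODE = -1


@dataclass(frozen=True)
class GenotypeCounts:
    n_wild_hom: int
    n_het: int
    n_var_hom: int
    n_missing: int = 0

    @property
    def n_typed(self) -> int:
        return self.n_wild_hom + self.n_het + self.n_var_hom

    @property
    def total(self) -> int:
        return self.n_typed + self.n_missing

    def percentages(self) -> tuple[float, float, float]:
        """Column percentages of genotyped subjects."""
        t = self.n_typed
        if t == 0:
            return (float("nan"),) * 3
        return tuple(100.0 * c / t for c in
                     (self.n_wild_hom, self.n_het, self.n_var_hom))


@dataclass
class ModelFit:
    """One collapsed-model (or one genotype-contrast) Cox result."""

    hr: Optional[float]
    ci95: Optional[tuple[float, float]]
    p: Optional[float]
    coef: Optional[float]
    se: Optional[float]
    converged: bool
    note: str = ""

    @classmethod
    def from_cox(cls, fit: CoxFit, label: str) -> "ModelFit":
        d = fit[label]
        return cls(d["hr"], d["ci95"], d["p"], d["coef"], d["se"], fit.converged)

    @classmethod
    def not_estimable(cls, note: str) -> "ModelFit":
        return cls(None, None, None, None, None, False, note)


@dataclass
class SNPAssociation:
    """Everything the per-SNP table row needs, for one endpoint."""

    snp_id: str
    endpoint: str
    counts: GenotypeCounts
    maf: float
    hwe_p: float
    five_year_rate: tuple[float, float, float]  # per genotype, KM at 60 months
    n_events_by_genotype: tuple[int, int, int]
    het_fit: Optional[ModelFit]
    var_hom_fit: Optional[ModelFit]
    model_fits: dict  # {"dominant"|"recessive"|"additive": ModelFit}


def genotype_code(g: Genotype, model: str, spec: SNPSpec) -> int:
    """Numeric genetic-model code for one genotype.

    additive: risk-allele count 0/1/2; dominant: any risk allele;
    recessive: risk-allele homozygote.  Orientation follows
    ``spec.risk_direction`` (codes flip when the wild allele is the
    risk allele).  Missing calls return :data:`MISSING_CODE`.
    """
    nv = g.n_variant(spec)
    if nv is None:
        return MISSING_CODE
    n_risk = nv if spec.risk_direction != "wild_is_risk" else 2 - nv
    if model == "additive":
        return n_risk
    if model == "dominant":
        return int(n_risk >= 1)
    if model == "recessive":
        return int(n_risk == 2)
    raise ValueError(f"unknown model {model!r}")


def allele_stats(counts: GenotypeCounts) -> tuple[float, float]:
    """Minor allele frequency (folded to <= 0.5) and 1-df HWE chi-square p.

    Expected genotype counts come from the estimated allele frequency;
    a monomorphic SNP has maf 0 and p 1 by convention.
    """
    n = counts.n_typed
    if n <= 0:
        raise ValueError("no genotyped subjects")
    q = (counts.n_het + 2 * counts.n_var_hom) / (2 * n)
    maf = min(q, 1 - q)
    if q in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    observed = np.array([counts.n_wild_hom, counts.n_het, counts.n_var_hom], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return maf, float(stats.chi2.sf(chi2, df=1))


def count_genotypes(cohort: Cohort, snp_id: str) -> GenotypeCounts:
    spec = cohort.panel.get(snp_id)
    tallies = [0, 0, 0]
    missing = 0
    for s in cohort.subjects:
        nv = s.genotypes[snp_id].n_variant(spec)
        if nv is None:
            missing += 1
        else:
            tallies[nv] += 1
    return GenotypeCounts(*tallies, missing)


def genotype_by_factor_test(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a genotype-by-
    factor contingency table; returns (statistic, df, p)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def _fit_snp_term(times, events, term: np.ndarray, term_label: str,
                  adjust: pd.DataFrame) -> ModelFit:
    """Adjusted Cox fit for one SNP coding; degenerate strata are
    reported as non-estimable instead of raising."""
    if np.unique(term).size <= 1:
        return ModelFit.not_estimable("coding constant in complete cases")
    # zero events in a level of a binary coding -> monotone likelihood
    if np.unique(term).size == 2:
        for level in np.unique(term):
            if events[term == level].sum() == 0:
                return ModelFit.not_estimable(
                    f"no events at coding level {level:g}")
    design = adjust.copy()
    design.insert(0, term_label, term)
    try:
        fit = cox_fit(times, events, design)
    except NonIdentifiableError as err:
        return ModelFit.not_estimable(str(err))
    return ModelFit.from_cox(fit, term_label)


def per_snp_analysis(cohort: Cohort, snp_id: str, endpoint: str = "os",
                     covariate_set: Optional[Sequence[str]] = None) -> SNPAssociation:
    """Full single-SNP association analysis for one endpoint.

    Subjects missing this SNP's genotype are excluded from this SNP's
    fits only.  ``covariate_set`` defaults to the panel's configured
    adjustment set.
    """
    spec = cohort.panel.get(snp_id)
    covariate_set = tuple(covariate_set if covariate_set is not None
                          else cohort.panel.covariate_set)
    counts = count_genotypes(cohort, snp_id)
    maf, hwe_p = allele_stats(counts)

    frame = cohort.to_frame()
    nv = np.array([s.genotypes[snp_id].n_variant(spec) if not
                   s.genotypes[snp_id].is_missing else MISSING_CODE
                   for s in cohort.subjects])
    keep = nv != MISSING_CODE
    sub = frame.loc[keep].reset_index(drop=True)
    nv = nv[keep]
    times = sub[f"{endpoint}_time"].to_numpy(dtype=float)
    events = sub[f"{endpoint}_event"].to_numpy(dtype=int)
    adjust = covariate_design(sub, covariate_set)

    rates = []
    ev_counts = []
    for level in (0, 1, 2):
        m = nv == level
        ev_counts.append(int(events[m].sum()))
        if m.sum() == 0:
            rates.append(float("nan"))
        else:
            rates.append(survival_at(km_estimate(times[m], events[m]), FIVE_YEARS))

    # genotype-level: het and variant-hom indicators vs wild-hom reference
    het = (nv == 1).astype(float)
    hom = (nv == 2).astype(float)
    if np.unique(nv).size >= 2:
        geno_design = adjust.copy()
        drop_het = het.sum() == 0 or events[nv == 1].sum() == 0
        drop_hom = hom.sum() == 0 or events[nv == 2].sum() == 0
        cols = []
        if not drop_het:
            cols.append(("het", het))
        if not drop_hom:
            cols.append(("var_hom", hom))
        for i, (name, col) in enumerate(cols):
            geno_design.insert(i, name, col)
        het_fit = var_hom_fit = None
        if cols:
            try:
                fit = cox_fit(times, events, geno_design)
                if not drop_het:
                    het_fit = ModelFit.from_cox(fit, "het")
                if not drop_hom:
                    var_hom_fit = ModelFit.from_cox(fit, "var_hom")
            except NonIdentifiableError as err:
                het_fit = var_hom_fit = ModelFit.not_estimable(str(err))
        if het_fit is None:
            het_fit = ModelFit.not_estimable("no het stratum events")
        if var_hom_fit is None:
            var_hom_fit = ModelFit.not_estimable("no variant-hom stratum events")
    else:
        het_fit = var_hom_fit = ModelFit.not_estimable("monomorphic in complete cases")

    model_fits = {}
    for model in ("dominant", "recessive", "additive"):
        n_risk = nv if spec.risk_direction != "wild_is_risk" else 2 - nv
        if model == "additive":
            term = n_risk.astype(float)
        elif model == "dominant":
            term = (n_risk >= 1).astype(float)
        else:
            term = (n_risk == 2).astype(float)
        model_fits[model] = _fit_snp_term(times, events, term, model, adjust)

    return SNPAssociation(snp_id, endpoint, counts, maf, hwe_p,
                          tuple(rates), tuple(ev_counts),
                          het_fit, var_hom_fit, model_fits)
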