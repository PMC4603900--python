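"""Delimited-text report writers mirroring the published table layouts.

Rounding happens only here: counts carry percentages to one decimal,
hazard ratios and confidence bounds print to two decimals, and
p-values below 0.001 switch to scientific notation ("8.0x10-9").
Internal results keep full precision.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .association import SNPAssociation, ModelFit
from .prognostic import IndexResult, RiskGroupReport
from .survival import KMCurve


def fmt_count_pct(count: int, pct: float) -> str:
    return f"{count}({pct:.1f})"


def fmt_hr_ci(fit: ModelFit | None) -> str:
    if fit is None or fit.hr is None:
        return "NE"  # not estimable
    return f"{fit.hr:.2f} ({fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})"


def fmt_rate(rate: float) -> str:
    return "NA" if math.isnan(rate) else f"{100 * rate:.0f}"


def fmt_p(p: float | None) -> str:
    """Two decimals >= 0.01, three in [0.001, 0.01), scientific below:
    0.52 / 0.007 / 8.0x10-9."""
    if p is None or math.isnan(p):
        return "NE"
    if p >= 0.01:
        return f"{p:.2f}"
    if p >= 0.001:
        return f"{p:.3f}"
    if p <= 0.0:
        return "0"
    e = math.floor(math.log10(p))
    m = p / 10 ** e
    if round(m, 1) >= 10:
        m /= 10
        e += 1
    return f"{m:.1f}x10{e}"


def per_snp_table(associations: Mapping[str, SNPAssociation],
                  panel) -> pd.DataFrame:
    """One row per genotype and per collapsed model, per SNP, for one
    endpoint (the published per-SNP layout)."""
    rows = []
    for spec in panel.snps:
        a = associations[spec.snp_id]
        labels = spec.genotype_labels()
        pcts = a.counts.percentages()
        ns = (a.counts.n_wild_hom, a.counts.n_het, a.counts.n_var_hom)
        geno_fits = (None, a.het_fit, a.var_hom_fit)
        for i, lab in enumerate(labels):
            ev_pct = 100.0 * a.n_events_by_genotype[i] / ns[i] if ns[i] else float("nan")
            rows.append({
                "snp": f"{spec.gene} {spec.snp_id}", "row": lab,
                "n_cases": fmt_count_pct(ns[i], pcts[i]),
                "n_events": fmt_count_pct(a.n_events_by_genotype[i], ev_pct)
                            if ns[i] else "0",
                "rate_5y": fmt_rate(a.five_year_rate[i]),
                "hr_ci": "1.00 (ref)" if i == 0 else fmt_hr_ci(geno_fits[i]),
                "p": "" if i == 0 else fmt_p(geno_fits[i].p if geno_fits[i] else None),
            })
        for model in ("dominant", "recessive", "additive"):
            f = a.model_fits[model]
            rows.append({"snp": f"{spec.gene} {spec.snp_id}",
                         "row": model.capitalize(), "n_cases": "", "n_events": "",
                         "rate_5y": "", "hr_ci": fmt_hr_ci(f),
                         "p": fmt_p(f.p if f else None)})
        rows.append({"snp": f"{spec.gene} {spec.snp_id}", "row": "MAF/HWE",
                     "n_cases": f"{a.maf:.3f}", "n_events": "",
                     "rate_5y": "", "hr_ci": "", "p": fmt_p(a.hwe_p)})
    return pd.DataFrame(rows)


def risk_group_table(reports: Mapping[str, RiskGroupReport]) -> pd.DataFrame:
    """The combined risk-group layout, one endpoint per column block."""
    any_rep = next(iter(reports.values()))
    rows = []
    for name in ("low", "high"):
        row = {"risk_group": f"{name.capitalize()} risk "
               f"({'<' if name == 'low' else '>='}{any_rep.cutoff})"}
        for ep, rep in reports.items():
            g = getattr(rep, name)
            row[f"{ep}_n_cases"] = fmt_count_pct(g.n, g.pct)
            row[f"{ep}_n_events"] = fmt_count_pct(g.n_events, g.event_pct)
            row[f"{ep}_rate_5y"] = fmt_rate(g.five_year_rate)
            row[f"{ep}_logrank_p"] = fmt_p(rep.logrank.p_value) if name == "low" else ""
            if name == "low":
                row[f"{ep}_hr_ci"], row[f"{ep}_p"] = "1.00", ""
            else:
                hvl = rep.high_vs_low
                row[f"{ep}_hr_ci"] = (f"{hvl['hr']:.2f} "
                                      f"({hvl['ci95'][0]:.2f}-{hvl['ci95'][1]:.2f})")
                row[f"{ep}_p"] = fmt_p(hvl["p"])
        rows.append(row)
    return pd.DataFrame(rows)


def km_curve_frame(km: KMCurve) -> pd.DataFrame:
    return pd.DataFrame({"time": km.event_times, "survival": km.survival,
                         "at_risk": km.at_risk})


def write_report_tables(out_dir,
                        per_snp: Mapping[str, Mapping[str, SNPAssociation]] | None = None,
                        risk_reports: Mapping[str, RiskGroupReport] | None = None,
                        index_result: IndexResult | None = None,
                        univariate: pd.DataFrame | None = None,
                        panel=None) -> list[Path]:
    """Write every available report as a TSV under ``out_dir``; returns
    the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    if univariate is not None:
        emit(univariate, "univariate.tsv")
    if per_snp is not None:
        for ep, assoc in per_snp.items():
            emit(per_snp_table(assoc, panel), f"per_snp_{ep}.tsv")
    if risk_reports is not None:
        emit(risk_group_table(risk_reports), "risk_groups.tsv")
        for ep, rep in risk_reports.items():
            emit(km_curve_frame(rep.low.km), f"km_{ep}_low.csv")
            emit(km_curve_frame(rep.high.km), f"km_{ep}_high.csv")
    if index_result is not None:
        emit(pd.DataFrame({"subject_id": index_result.subject_ids,
                           "prognostic_index": index_result.index,
                           "risk_group": index_result.risk_group}),
             "prognostic_index.tsv")
    return written
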