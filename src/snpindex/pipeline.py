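"""End-to-end orchestration: univariate clinical analysis, per-SNP
association, index construction, combined risk-group comparison, and a
reproducibility manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (Cohort, COVARIATE_PRESETS, FIVE_YEARS, PanelSpec,
                         read_cohort, read_panel)
from .survival import km_estimate, logrank_test, survival_at
from .association import per_snp_analysis
from .prognostic import (RiskGroupReport, ScoreMap, build_score_map, classify,
                         combined_analysis)
from .report import fmt_count_pct, fmt_p, fmt_rate, write_report_tables

log = logging.getLogger("snpindex")

ENDPOINTS = ("os", "dfs")

#: Univariate factors: column, display name, level order (None = derived).
UNIVARIATE_FACTORS = (
    ("age_group", "Age", ("<=64", ">64")),
    ("sex", "Sex", ("male", "female")),
    ("smoking", "Smoking status", ("never", "ever")),
    ("histology", "Histological type", ("SCC", "AC", "LCC")),
    ("stage", "Pathologic stage", ("I", "II-IIIA")),
)


@dataclass
class RunConfig:
    cohort_path: Optional[str] = None
    panel_path: Optional[str] = None
    out_dir: str = "snpindex_out"
    endpoints: tuple[str, ...] = ENDPOINTS
    adjust: str = "table2"            # covariate preset name
    cutoff: Optional[int] = None      # None = approximate-tertile rule
    seed: int = 42
    log_level: str = "INFO"


def univariate_analysis(cohort: Cohort) -> pd.DataFrame:
    """Per clinical factor and endpoint: n, events(%), KM 5-year rate,
    and the log-rank p across levels (the univariate clinical table)."""
    frame = cohort.to_frame()
    rows = []

    def block(label, level_names, masks):
        row_common = []
        for ep in ENDPOINTS:
            t = frame[f"{ep}_time"].to_numpy(dtype=float)
            e = frame[f"{ep}_event"].to_numpy(dtype=int)
            groups = np.full(len(frame), -1)
            for gi, m in enumerate(masks):
                groups[m] = gi
            keep = groups >= 0
            lr = logrank_test(t[keep], e[keep], groups[keep]) if len(masks) > 1 else None
            for gi, (lev, m) in enumerate(zip(level_names, masks)):
                n, ne = int(m.sum()), int(e[m].sum())
                km = km_estimate(t[m], e[m]) if n else None
                entry = {
                    f"{ep}_n_events": fmt_count_pct(ne, 100 * ne / n) if n else "0",
                    f"{ep}_rate_5y": fmt_rate(survival_at(km, FIVE_YEARS)) if n else "NA",
                    f"{ep}_logrank_p": fmt_p(lr.p_value) if (lr and gi == 0) else "",
                }
                if ep == ENDPOINTS[0]:
                    row_common.append({"factor": label, "level": lev, "n": n, **entry})
                else:
                    row_common[gi].update(entry)
        rows.extend(row_common)

    all_mask = np.ones(len(frame), dtype=bool)
    block("Overall", ("",), [all_mask])
    for col, label, levels in UNIVARIATE_FACTORS:
        masks = [frame[col].eq(lev).to_numpy() for lev in levels]
        block(label, levels, masks)
    # pack-years split among ever-smokers, mirroring the published table
    ever = frame["smoking"].eq("ever") & frame["pack_years"].notna()
    if ever.any():
        lt = (ever & (frame["pack_years"] < 40)).to_numpy()
        ge = (ever & (frame["pack_years"] >= 40)).to_numpy()
        if lt.any() and ge.any():
            block("Pack-years", ("<40", ">=40"), [lt, ge])
    return pd.DataFrame(rows)


def run_pipeline(cohort: Cohort, config: RunConfig,
                 ) -> dict:
    """Execute every stage on an in-memory cohort; write tables and a
    manifest under ``config.out_dir``; return the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    covariate_set = COVARIATE_PRESETS[config.adjust]
    panel = cohort.panel

    log.info("stage univariate: %d subjects", cohort.n)
    uni = univariate_analysis(cohort)

    per_snp = {}
    for ep in config.endpoints:
        per_snp[ep] = {sid: per_snp_analysis(cohort, sid, ep, covariate_set)
                       for sid in panel.snp_ids}
        log.info("stage per-snp (%s): %d SNPs, per-SNP n %s", ep,
                 len(panel.snp_ids),
                 [a.counts.n_typed for a in per_snp[ep].values()])

    os_assoc = per_snp.get("os") or {
        sid: per_snp_analysis(cohort, sid, "os", covariate_set)
        for sid in panel.snp_ids}
    score_map = build_score_map(panel, os_assoc)

    idx = classify(cohort, score_map, config.cutoff)
    n_def = int(idx.defined.sum())
    log.info("stage index: cutoff %d, %d/%d subjects with defined index",
             idx.cutoff, n_def, cohort.n)

    risk_reports: dict[str, RiskGroupReport] = {}
    for ep in config.endpoints:
        risk_reports[ep] = combined_analysis(cohort, score_map, idx.cutoff,
                                             ep, covariate_set)
        log.info("stage combined (%s): low %d / high %d, %d excluded", ep,
                 risk_reports[ep].low.n, risk_reports[ep].high.n,
                 risk_reports[ep].n_excluded_missing)

    written = write_report_tables(out, per_snp=per_snp, risk_reports=risk_reports,
                                  index_result=idx, univariate=uni, panel=panel)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": cohort.n,
        "n_index_defined": n_def,
        "adjust": config.adjust,
        "covariate_set": list(covariate_set),
        "endpoints": list(config.endpoints),
        "cutoff": idx.cutoff,
        "cutoff_mode": "fixed" if config.cutoff is not None else "auto-tertile",
        "selected_models": dict(score_map.models),
        "risk_directions": dict(score_map.risk_directions),
        "score_map": {sid: dict(m) for sid, m in score_map.scores.items()},
        "inputs": {"cohort": config.cohort_path, "panel": config.panel_path},
        "tables": [p.name for p in written],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"univariate": uni, "per_snp": per_snp, "score_map": score_map,
            "index": idx, "risk_reports": risk_reports, "manifest": manifest}


def run_from_files(config: RunConfig) -> dict:
    if config.cohort_path is None or config.panel_path is None:
        raise ValueError("cohort_path and panel_path are required")
    panel = read_panel(config.panel_path)
    cohort = read_cohort(config.cohort_path, panel)
    return run_pipeline(cohort, config)
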