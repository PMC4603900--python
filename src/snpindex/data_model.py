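"""Domain types for survival cohorts genotyped on a SNP panel.

A cohort is a table of surgically treated patients with clinical
covariates, two right-censored endpoints — overall survival (OS, surgery
to death) and disease-free survival (DFS, surgery to recurrence or
death) — and one biallelic germline genotype per panel SNP.  The panel
assigns each SNP its two alleles, optionally a genetic model
(additive / dominant / recessive) and a risk orientation.

Times are in months throughout; "5-year" means 60 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

GENETIC_MODELS = ("additive", "dominant", "recessive")
RISK_DIRECTIONS = ("variant_is_risk", "wild_is_risk")

AGE_LEVELS = ("<=64", ">64")
SEX_LEVELS = ("female", "male")
SMOKING_LEVELS = ("never", "ever")
HISTOLOGY_LEVELS = ("SCC", "AC", "LCC")
STAGE_LEVELS = ("I", "II-IIIA")

#: Clinical covariates available for Cox adjustment, in canonical order.
COVARIATES = ("age", "sex", "smoking", "histology", "stage", "adjuvant_chemo")

#: Adjustment presets: the five-covariate set used for the per-SNP and
#: combined tables, and the variant that additionally adjusts for
#: adjuvant chemotherapy.
COVARIATE_PRESETS = {
    "table2": ("age", "sex", "smoking", "histology", "stage"),
    "methods": ("age", "sex", "smoking", "histology", "stage", "adjuvant_chemo"),
}

MISSING_TOKEN = "NA"

FIVE_YEARS = 60.0  # months


class CohortValidationError(ValueError):
    """A cohort table failed validation; message carries row/column context."""


@dataclass(frozen=True)
class SNPSpec:
    """One biallelic SNP: identifiers, alleles and (optional) model.

    ``wild_allele`` and ``variant_allele`` are single bases.  When a
    genetic model is assigned, ``risk_direction`` says which allele
    increases hazard under that model's collapsing.
    """

    snp_id: str
    gene: str
    wild_allele: str
    variant_allele: str
    genetic_model: Optional[str] = None
    risk_direction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wild_allele == self.variant_allele:
            raise ValueError(f"{self.snp_id}: wild and variant allele must differ")
        if self.genetic_model is not None:
            if self.genetic_model not in GENETIC_MODELS:
                raise ValueError(f"{self.snp_id}: unknown model {self.genetic_model!r}")
            if self.risk_direction is None:
                raise ValueError(f"{self.snp_id}: model set but risk_direction unset")
        if self.risk_direction is not None and self.risk_direction not in RISK_DIRECTIONS:
            raise ValueError(f"{self.snp_id}: unknown risk_direction {self.risk_direction!r}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.wild_allele, self.variant_allele)

    def genotype_labels(self) -> tuple[str, str, str]:
        """Canonical genotype strings: wild-hom, het, variant-hom."""
        w, v = self.wild_allele, self.variant_allele
        return (w + w, w + v, v + v)


@dataclass(frozen=True)
class Genotype:
    """An unordered allele pair at one SNP, or a missing call.

    The heterozygote is stored canonically with the wild allele first,
    so ``"GA"`` and ``"AG"`` denote the same call.
    """

    snp_id: str
    call: Optional[tuple[str, str]]  # canonical order, or None if missing

    @classmethod
    def from_string(cls, snp_id: str, cell: str, spec: SNPSpec,
                    missing_token: str = MISSING_TOKEN) -> "Genotype":
        if cell == missing_token or cell == "":
            return cls(snp_id, None)
        if len(cell) != 2:
            raise CohortValidationError(
                f"SNP {snp_id}: genotype cell {cell!r} is not a two-letter call")
        for a in cell:
            if a not in spec.alleles:
                raise CohortValidationError(
                    f"SNP {snp_id}: allele {a!r} not in declared alleles "
                    f"{spec.wild_allele}>{spec.variant_allele}")
        # canonical order: wild allele(s) first
        n_var = sum(a == spec.variant_allele for a in cell)
        w, v = spec.wild_allele, spec.variant_allele
        call = (w, w) if n_var == 0 else (w, v) if n_var == 1 else (v, v)
        return cls(snp_id, call)

    @property
    def is_missing(self) -> bool:
        return self.call is None

    def n_variant(self, spec: SNPSpec) -> Optional[int]:
        """Variant-allele count 0/1/2, or None if missing."""
        if self.call is None:
            return None
        return sum(a == spec.variant_allele for a in self.call)

    def to_string(self, missing_token: str = MISSING_TOKEN) -> str:
        return missing_token if self.call is None else "".join(self.call)


@dataclass(frozen=True)
class PanelSpec:
    """Ordered SNP panel plus the covariate set used for adjustment."""

    snps: tuple[SNPSpec, ...]
    covariate_set: tuple[str, ...] = COVARIATE_PRESETS["table2"]

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        for c in self.covariate_set:
            if c not in COVARIATES:
                raise ValueError(f"unknown covariate {c!r}")

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.snps)

    def get(self, snp_id: str) -> SNPSpec:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def with_models(self, models: Mapping[str, str],
                    directions: Mapping[str, str]) -> "PanelSpec":
        """Return a copy with genetic models / risk orientations filled in."""
        new = tuple(
            replace(s, genetic_model=models.get(s.snp_id, s.genetic_model),
                    risk_direction=directions.get(s.snp_id, s.risk_direction))
            for s in self.snps)
        return PanelSpec(new, self.covariate_set)


@dataclass
class Subject:
    """One patient: covariates, OS/DFS endpoint pairs and genotypes."""

    subject_id: str
    age_group: str          # "<=64" / ">64"
    sex: str                # "female" / "male"
    smoking: str            # "never" / "ever"
    pack_years: Optional[float]
    histology: str          # "SCC" / "AC" / "LCC"
    stage: str              # "I" / "II-IIIA"
    adjuvant_chemo: Optional[int]   # 0/1 or None
    os_time: float          # months > 0
    os_event: int           # 1 = death
    dfs_time: float         # months > 0
    dfs_event: int          # 1 = recurrence or death
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def validate(self) -> None:
        ctx = f"subject {self.subject_id}"
        if self.age_group not in AGE_LEVELS:
            raise CohortValidationError(f"{ctx}: bad age_group {self.age_group!r}")
        if self.sex not in SEX_LEVELS:
            raise CohortValidationError(f"{ctx}: bad sex {self.sex!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise CohortValidationError(f"{ctx}: bad smoking {self.smoking!r}")
        if self.histology not in HISTOLOGY_LEVELS:
            raise CohortValidationError(f"{ctx}: bad histology {self.histology!r}")
        if self.stage not in STAGE_LEVELS:
            raise CohortValidationError(f"{ctx}: bad stage {self.stage!r}")
        if not (self.os_time > 0 and self.dfs_time > 0):
            raise CohortValidationError(f"{ctx}: times must be strictly positive")
        if self.dfs_time > self.os_time:
            raise CohortValidationError(f"{ctx}: dfs_time exceeds os_time")
        if self.os_event not in (0, 1) or self.dfs_event not in (0, 1):
            raise CohortValidationError(f"{ctx}: event flags must be 0/1")
        if self.os_event == 1 and self.dfs_event != 1:
            raise CohortValidationError(f"{ctx}: death implies a DFS event")
        if self.pack_years is not None and self.pack_years < 0:
            raise CohortValidationError(f"{ctx}: negative pack_years")


@dataclass
class Cohort:
    """A validated list of subjects genotyped on a panel."""

    subjects: list[Subject]
    panel: PanelSpec

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate subject_id")
        panel_ids = set(self.panel.snp_ids)
        for s in self.subjects:
            extra = set(s.genotypes) - panel_ids
            if extra:
                raise CohortValidationError(
                    f"subject {s.subject_id}: genotype for SNP(s) {sorted(extra)} "
                    "not in panel")
            s.validate()

    @property
    def n(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per subject, genotype calls as strings."""
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "age_group": s.age_group,
                "sex": s.sex,
                "smoking": s.smoking,
                "pack_years": np.nan if s.pack_years is None else s.pack_years,
                "histology": s.histology,
                "stage": s.stage,
                "adjuvant_chemo": np.nan if s.adjuvant_chemo is None else s.adjuvant_chemo,
                "os_time": s.os_time,
                "os_event": s.os_event,
                "dfs_time": s.dfs_time,
                "dfs_event": s.dfs_event,
            }
            for sid in self.panel.snp_ids:
                g = s.genotypes.get(sid, Genotype(sid, None))
                row[sid] = g.to_string()
            rows.append(row)
        return pd.DataFrame(rows)

    def endpoint(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) arrays for endpoint 'os' or 'dfs'."""
        if which not in ("os", "dfs"):
            raise ValueError("endpoint must be 'os' or 'dfs'")
        t = np.array([getattr(s, f"{which}_time") for s in self.subjects], dtype=float)
        e = np.array([getattr(s, f"{which}_event") for s in self.subjects], dtype=int)
        return t, e


def covariate_design(cohort_or_frame, covariate_set: Sequence[str]) -> pd.DataFrame:
    """Reference-coded indicator matrix for the requested covariates.

    Reference levels are fixed: age <=64, female, never-smoker, SCC
    histology, stage I, no adjuvant chemotherapy.
    """
    df = (cohort_or_frame.to_frame() if isinstance(cohort_or_frame, Cohort)
          else cohort_or_frame)
    cols: dict[str, np.ndarray] = {}
    for c in covariate_set:
        if c == "age":
            cols["age_gt64"] = (df["age_group"] == ">64").astype(float).to_numpy()
        elif c == "sex":
            cols["male"] = (df["sex"] == "male").astype(float).to_numpy()
        elif c == "smoking":
            cols["ever_smoker"] = (df["smoking"] == "ever").astype(float).to_numpy()
        elif c == "histology":
            cols["hist_AC"] = (df["histology"] == "AC").astype(float).to_numpy()
            cols["hist_LCC"] = (df["histology"] == "LCC").astype(float).to_numpy()
        elif c == "stage":
            cols["stage_II_IIIA"] = (df["stage"] == "II-IIIA").astype(float).to_numpy()
        elif c == "adjuvant_chemo":
            vals = df["adjuvant_chemo"].astype(float)
            if vals.isna().any():
                raise CohortValidationError(
                    "adjuvant_chemo requested for adjustment but missing for "
                    f"{int(vals.isna().sum())} subject(s)")
            cols["adjuvant_chemo"] = vals.to_numpy()
        else:
            raise ValueError(f"unknown covariate {c!r}")
    return pd.DataFrame(cols, index=df.index)


# ---------------------------------------------------------------------------
# Readers / writers

COHORT_COLUMNS = ("subject_id", "age_group", "sex", "smoking", "pack_years",
                  "histology", "stage", "adjuvant_chemo",
                  "os_time", "os_event", "dfs_time", "dfs_event")


def read_cohort(path, panel: PanelSpec, sep: str = "\t",
                missing_token: str = MISSING_TOKEN) -> Cohort:
    """Read a delimited cohort table; validate and canonicalize genotypes.

    The file must have a header with the clinical columns followed by one
    genotype column per panel SNP (two-letter calls or the missing token).
    Row count is preserved: every data row yields exactly one subject.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    missing_cols += [sid for sid in panel.snp_ids if sid not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"{path}: missing column(s) {missing_cols}")

    def _num(row_i, col, cell, kind):
        try:
            return float(cell) if kind is float else int(cell)
        except ValueError:
            raise CohortValidationError(
                f"{path} row {row_i}: column {col!r} has non-numeric {cell!r}") from None

    subjects = []
    for i, row in df.iterrows():
        genos = {}
        for spec in panel.snps:
            try:
                genos[spec.snp_id] = Genotype.from_string(
                    spec.snp_id, row[spec.snp_id], spec, missing_token)
            except CohortValidationError as err:
                raise CohortValidationError(f"{path} row {i}: {err}") from None
        subj = Subject(
            subject_id=row["subject_id"],
            age_group=row["age_group"],
            sex=row["sex"],
            smoking=row["smoking"],
            pack_years=(None if row["pack_years"] in (missing_token, "")
                        else _num(i, "pack_years", row["pack_years"], float)),
            histology=row["histology"],
            stage=row["stage"],
            adjuvant_chemo=(None if row["adjuvant_chemo"] in (missing_token, "")
                            else _num(i, "adjuvant_chemo", row["adjuvant_chemo"], int)),
            os_time=_num(i, "os_time", row["os_time"], float),
            os_event=_num(i, "os_event", row["os_event"], int),
            dfs_time=_num(i, "dfs_time", row["dfs_time"], float),
            dfs_event=_num(i, "dfs_event", row["dfs_event"], int),
            genotypes=genos,
        )
        try:
            subj.validate()
        except CohortValidationError as err:
            raise CohortValidationError(f"{path} row {i}: {err}") from None
        subjects.append(subj)
    return Cohort(subjects, panel)


def write_cohort(cohort: Cohort, path, sep: str = "\t",
                 missing_token: str = MISSING_TOKEN) -> None:
    """Write the cohort as a delimited table (inverse of :func:`read_cohort`)."""
    df = cohort.to_frame()
    df["pack_years"] = df["pack_years"].map(
        lambda v: missing_token if pd.isna(v) else repr(float(v)))
    df["adjuvant_chemo"] = df["adjuvant_chemo"].map(
        lambda v: missing_token if pd.isna(v) else str(int(v)))
    for col in ("os_time", "dfs_time"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, sep=sep, index=False)


def read_panel(path) -> PanelSpec:
    """Load a panel config (YAML): SNP blocks plus the covariate set."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return panel_from_dict(raw)


def panel_from_dict(raw: Mapping) -> PanelSpec:
    snps = []
    for block in raw["snps"]:
        wild, variant = str(block["alleles"]).split(">")
        snps.append(SNPSpec(
            snp_id=str(block["id"]),
            gene=str(block.get("gene", "")),
            wild_allele=wild.strip(),
            variant_allele=variant.strip(),
            genetic_model=block.get("model"),
            risk_direction=block.get("risk_direction"),
        ))
    cov = tuple(raw.get("covariate_set", COVARIATE_PRESETS["table2"]))
    return PanelSpec(tuple(snps), cov)


def write_panel(panel: PanelSpec, path) -> None:
    raw = {
        "covariate_set": list(panel.covariate_set),
        "snps": [
            {"id": s.snp_id, "gene": s.gene,
             "alleles": f"{s.wild_allele}>{s.variant_allele}",
             **({"model": s.genetic_model} if s.genetic_model else {}),
             **({"risk_direction": s.risk_direction} if s.risk_direction else {})}
            for s in panel.snps
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_panel() -> PanelSpec:
    """The packaged eight-SNP panel with its published model assignments.

    Three SNPs carry the additive model and five a dominant or recessive
    model; the variant allele is the risk allele for all eight.
    """
    rows = [
        ("rs967591", "CD3EAP", "G", "A", "recessive"),
        ("rs1047266", "TNFRSF10B", "C", "T", "recessive"),
        ("rs3803300", "AKT1", "A", "G", "dominant"),
        ("rs2287845", "C3", "T", "C", "additive"),
        ("rs1256428", "HOMER2", "A", "G", "additive"),
        ("rs3756585", "GNB2L1", "T", "G", "additive"),
        ("rs11259927", "ADAMTSL3", "C", "T", "recessive"),
        ("rs3181259", "CD3D", "T", "C", "recessive"),
    ]
    snps = tuple(
        SNPSpec(snp_id, gene, w, v, genetic_model=model,
                risk_direction="variant_is_risk")
        for snp_id, gene, w, v, model in rows)
    return PanelSpec(snps, COVARIATE_PRESETS["table2"])
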