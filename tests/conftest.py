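import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from snpindex import default_panel, generate_cohort
from snpindex.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """One packaged default cohort (n=814, fixed seed)."""
    cohort, effects = generate_cohort(GeneratorConfig(seed=42))
    return cohort, effects


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast pipeline-level tests."""
    cohort, _ = generate_cohort(GeneratorConfig(n=300, seed=7))
    return cohort


@pytest.fixture()
def cohort_file(tmp_path, panel):
    """Hand-written 5-row cohort file with one missing genotype."""
    snp_cells = {
        "rs967591": ["GG", "GA", "AA", "AG", "GG"],   # AG: non-canonical het
        "rs1047266": ["CC", "CT", "TT", "CC", "NA"],  # one missing call
        "rs3803300": ["AA", "AG", "GG", "AA", "AG"],
        "rs2287845": ["TT", "TC", "CC", "TT", "TC"],
        "rs1256428": ["AA", "AG", "GG", "AA", "AG"],
        "rs3756585": ["TT", "TG", "GG", "TT", "TG"],
        "rs11259927": ["CC", "CT", "TT", "CC", "CT"],
        "rs3181259": ["TT", "TC", "CC", "TT", "TC"],
    }
    clinical = [
        ("P1", "<=64", "male", "ever", "35.0", "SCC", "I", "0", "60.0", "0", "60.0", "0"),
        ("P2", ">64", "female", "never", "NA", "AC", "II-IIIA", "1", "24.0", "1", "18.0", "1"),
        ("P3", "<=64", "male", "ever", "50.5", "LCC", "I", "0", "72.0", "0", "40.0", "1"),
        ("P4", ">64", "male", "never", "NA", "AC", "I", "0", "12.0", "1", "12.0", "1"),
        ("P5", "<=64", "female", "ever", "20.0", "SCC", "II-IIIA", "1", "48.0", "0", "48.0", "0"),
    ]
    header = ["subject_id", "age_group", "sex", "smoking", "pack_years",
              "histology", "stage", "adjuvant_chemo", "os_time", "os_event",
              "dfs_time", "dfs_event"] + list(snp_cells)
    lines = ["\t".join(header)]
    for i, row in enumerate(clinical):
        lines.append("\t".join(list(row) + [snp_cells[s][i] for s in snp_cells]))
    path = tmp_path / "cohort.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
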