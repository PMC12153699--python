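from pathlib import Path

import pytest

from faersig.pipeline import run_pipeline
from faersig.synthetic_faers import SimConfig, default_quarters, fixture_smqs, generate

DEMO_HEADER = ("primaryid$caseid$caseversion$fda_dt$event_dt$age$age_cod$sex"
               "$wt$wt_cod$occp_cod$reporter_country$occr_country$lit_ref"
               "$rept_cod")


def write_quarter(directory: Path, quarter: str, demo, drug=(), indi=(),
                  outc=(), reac=(), ther=()) -> Path:
    """Write hand-crafted dollar-delimited table files for one quarter."""
    yy, q = quarter[2:4], quarter[5]
    headers = {
        "DEMO": DEMO_HEADER,
        "DRUG": "primaryid$drug_seq$role_cod$drugname$prod_ai",
        "INDI": "primaryid$indi_drug_seq$indi_pt",
        "OUTC": "primaryid$outc_cod",
        "REAC": "primaryid$pt",
        "THER": "primaryid$dsg_drug_seq$start_dt$end_dt",
    }
    rows = {"DEMO": demo, "DRUG": drug, "INDI": indi, "OUTC": outc,
            "REAC": reac, "THER": ther}
    directory.mkdir(parents=True, exist_ok=True)
    for name, header in headers.items():
        lines = [header] + ["$".join(map(str, r)) for r in rows[name]]
        (directory / f"{name}{yy}Q{q}.txt").write_text("\n".join(lines) + "\n",
                                                       encoding="latin-1")
    return directory


def demo_row(primaryid, caseid, caseversion="1", fda_dt="20190215",
             event_dt="20190110", age="60", age_cod="YR", sex="M", wt="80",
             wt_cod="KG", occp_cod="MD", country="US", lit_ref="",
             rept_cod="DIR"):
    return (primaryid, caseid, caseversion, fda_dt, event_dt, age, age_cod,
            sex, wt, wt_cod, occp_cod, country, country, lit_ref, rept_cod)


@pytest.fixture
def smqs():
    return fixture_smqs()


@pytest.fixture
def tiny_quarter(tmp_path):
    """Three reports, four drug rows: one D+T melanoma case with atrial
    fibrillation, one vemurafenib case, one background aspirin report."""
    demo = [demo_row("101", "C101"),
            demo_row("102", "C102", sex="F", age="55"),
            demo_row("103", "C103", age="70")]
    drug = [("101", "1", "PS", "TAFINLAR", "DABRAFENIB"),
            ("101", "2", "SS", "MEKINIST", "TRAMETINIB"),
            ("102", "1", "PS", "ZELBORAF", "VEMURAFENIB"),
            ("103", "1", "PS", "ASPIRIN", "ASPIRIN")]
    indi = [("101", "1", "Malignant melanoma"),
            ("102", "1", "Malignant melanoma")]
    outc = [("101", "HO"), ("101", "DE"), ("102", "OT")]
    reac = [("101", "Atrial fibrillation"), ("101", "Nausea"),
            ("102", "Pyrexia"), ("103", "Headache")]
    ther = [("101", "1", "20190101", ""), ("102", "1", "20181201", "")]
    return write_quarter(tmp_path / "q1", "2019q1", demo, drug, indi, outc,
                         reac, ther)


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """One moderately sized synthetic study shared across tests: 50,000
    distinct reports, a planted D+T–atrial fibrillation signal with odds
    multiplier 4, duplicates and exclusion material injected, pipeline run
    once end to end."""
    config = SimConfig(
        n_reports=50_000, seed=11, quarters=default_quarters(2018, 2019),
        group_shares={"D+T": 0.10, "V": 0.03, "V+C": 0.02},
        planted_signals=[("D+T", "Atrial fibrillation", 4.0)],
        duplicate_id_fraction=0.10, duplicate_similarity_fraction=0.03,
        nonmelanoma_indication_rate=0.02, literature_rate=0.01,
        investigational_rate=0.01, no_ae_rate=0.01)
    data_dir = tmp_path_factory.mktemp("faers_sim")
    ledger = generate(config, data_dir)
    result = run_pipeline(data_dir, config.quarters, fixture_smqs())
    return config, ledger, result
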