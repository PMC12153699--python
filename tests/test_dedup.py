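import pandas as pd
import pytest

from faersig.dedup import (apply_exclusions, build_similarity_keys,
                           dedup_by_ids, dedup_by_similarity)
from faersig.faers_io import build_combined, read_quarter
from faersig.synthetic_faers import SimConfig, generate

from conftest import demo_row

DEMO_COLS = ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
             "age", "age_cod", "sex", "wt", "wt_cod", "occp_cod",
             "reporter_country", "occr_country", "lit_ref", "rept_cod"]


def demo_frame(rows):
    return pd.DataFrame([demo_row(*a, **k) for a, k in rows],
                        columns=DEMO_COLS)


class TestDedupByIds:
    def test_most_recent_version_kept(self):
        demo = demo_frame([(("1001", "C1"), {"caseversion": "1"}),
                           (("10012", "C1"), {"caseversion": "2"})])
        out = dedup_by_ids(demo)
        assert list(out["primaryid"]) == ["10012"]

    def test_single_report_unchanged(self):
        demo = demo_frame([(("1001", "C1"), {})])
        assert dedup_by_ids(demo).equals(demo)

    def test_tie_break_ladder(self):
        # equal versions: later fda_dt wins; equal dates: larger primaryid
        demo = demo_frame([
            (("31", "C1"), {"caseversion": "1", "fda_dt": "20190101"}),
            (("32", "C1"), {"caseversion": "1", "fda_dt": "20190301"}),
            (("41", "C2"), {"caseversion": "", "fda_dt": ""}),
            (("42", "C2"), {"caseversion": "", "fda_dt": ""}),
        ])
        out = dedup_by_ids(demo)
        assert set(out["primaryid"]) == {"32", "42"}

    def test_idempotent(self):
        demo = demo_frame([(("1", "C1"), {"caseversion": "1"}),
                           (("2", "C1"), {"caseversion": "2"}),
                           (("3", "C2"), {})])
        once = dedup_by_ids(demo)
        assert dedup_by_ids(once).equals(once)

    def test_output_subset_of_input(self):
        demo = demo_frame([(("1", "C1"), {}), (("2", "C1"), {}),
                           (("3", "C3"), {})])
        out = dedup_by_ids(demo)
        assert set(out["primaryid"]) <= set(demo["primaryid"])


def _clone_tables(demo):
    """Suspect drug + reaction rows shared by every report (so similarity
    keys depend only on the DEMO fields)."""
    ids = demo["primaryid"]
    drug = pd.DataFrame({"primaryid": ids, "drug_seq": "1",
                         "role_cod": "PS", "drugname": "TAFINLAR",
                         "prod_ai": "DABRAFENIB", "indi_pt": "",
                         "start_dt": "", "end_dt": ""})
    reac = pd.DataFrame({"primaryid": ids, "pt": "Atrial fibrillation"})
    return drug, reac


class TestDedupBySimilarity:
    def test_exact_clones_collapse(self):
        demo = demo_frame([(("1", "C1"), {}), (("2", "C2"), {})])
        drug, reac = _clone_tables(demo)
        out = dedup_by_similarity(demo, combined_drug=drug, combined_reac=reac)
        assert len(out) == 1
        assert out.iloc[0]["primaryid"] == "2"  # larger primaryid = most recent

    def test_missing_field_never_merges(self):
        demo = demo_frame([(("1", "C1"), {}), (("2", "C2"), {"age": ""})])
        drug, reac = _clone_tables(demo)
        out = dedup_by_similarity(demo, combined_drug=drug, combined_reac=reac)
        assert len(out) == 2

    def test_differing_reactions_kept(self):
        demo = demo_frame([(("1", "C1"), {}), (("2", "C2"), {})])
        drug, reac = _clone_tables(demo)
        reac.loc[reac["primaryid"] == "2", "pt"] = "Nausea"
        out = dedup_by_similarity(demo, combined_drug=drug, combined_reac=reac)
        assert len(out) == 2

    def test_idempotent(self):
        demo = demo_frame([(("1", "C1"), {}), (("2", "C2"), {}),
                           (("3", "C3"), {"sex": "F"})])
        drug, reac = _clone_tables(demo)
        keys = build_similarity_keys(demo, drug, reac)
        once = dedup_by_similarity(demo, keys=keys)
        keys2 = build_similarity_keys(once, drug, reac)
        assert dedup_by_similarity(once, keys=keys2).equals(once)


class TestApplyExclusions:
    def make_universe(self):
        demo = demo_frame([
            (("1", "C1"), {}),                                   # clean
            (("2", "C2"), {"lit_ref": "Smith 2020", "rept_cod": "EXP"}),
            (("3", "C3"), {}),                                   # invest drug
            (("4", "C4"), {}),                                   # no AE only
            (("5", "C5"), {}),                                   # clean
        ])
        drug = pd.DataFrame(
            [("1", "1", "PS", "TAFINLAR", "DABRAFENIB"),
             ("2", "1", "PS", "TAFINLAR", "DABRAFENIB"),
             ("3", "1", "PS", "INVESTIGATIONAL PRODUCT", ""),
             ("4", "1", "PS", "ASPIRIN", "ASPIRIN"),
             ("5", "1", "PS", "ASPIRIN", "ASPIRIN")],
            columns=["primaryid", "drug_seq", "role_cod", "drugname",
                     "prod_ai"])
        reac = pd.DataFrame(
            [("1", "Nausea"), ("2", "Rash"), ("3", "Rash"),
             ("4", "No adverse event"),
             ("5", "No adverse event"), ("5", "Atrial fibrillation")],
            columns=["primaryid", "pt"])
        return demo, drug, reac

    def test_three_filters(self):
        demo, drug, reac = self.make_universe()
        res = apply_exclusions(demo, drug, reac)
        assert set(res.demo["primaryid"]) == {"1", "5"}
        assert res.log["excluded_literature"] == 1
        assert res.log["excluded_investigational"] == 1
        assert res.log["excluded_no_adverse_event"] == 1
        # the no-AE PT itself is dropped from surviving reports
        assert list(res.reac.loc[res.reac["primaryid"] == "5", "pt"]) == \
            ["Atrial fibrillation"]

    def test_literature_requires_study_report_type(self):
        demo, drug, reac = self.make_universe()
        demo.loc[demo["primaryid"] == "2", "rept_cod"] = "DIR"
        res = apply_exclusions(demo, drug, reac)
        assert "2" in set(res.demo["primaryid"])

    def test_fixture_counts(self):
        # 10 reports, 3 matching a filter -> 7 survive
        demo, drug, reac = self.make_universe()
        extra = demo_frame([((str(10 + i), f"C{10 + i}"), {})
                            for i in range(5)])
        demo = pd.concat([demo, extra], ignore_index=True)
        drug2 = pd.concat([drug, pd.DataFrame(
            [(str(10 + i), "1", "PS", "ASPIRIN", "ASPIRIN")
             for i in range(5)], columns=drug.columns)], ignore_index=True)
        reac2 = pd.concat([reac, pd.DataFrame(
            [(str(10 + i), "Nausea") for i in range(5)],
            columns=reac.columns)], ignore_index=True)
        res = apply_exclusions(demo, drug2, reac2)
        assert len(res.demo) == 7


def test_two_step_dedup_recovers_ledger(tmp_path):
    """Injected id- and similarity-duplicates all removed; the clean count
    equals the generator's distinct-case ledger."""
    config = SimConfig(n_reports=2000, seed=5, quarters=["2021q1"],
                       group_shares={"D+T": 0.1},
                       duplicate_id_fraction=0.10,
                       duplicate_similarity_fraction=0.05)
    ledger = generate(config, tmp_path)
    tables = build_combined([read_quarter(tmp_path, "2021q1")])
    demo = tables.combined_demo
    assert len(demo) == 2000 + len(ledger.duplicates)
    demo = dedup_by_ids(demo)
    demo = dedup_by_similarity(demo, combined_drug=tables.combined_drug,
                               combined_reac=tables.combined_reac)
    assert len(demo) == ledger.distinct_case_count == 2000
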