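"""End-to-end analysis pipeline: extracts in, signal tables out.

Fixed step order (the dedup order is part of the method): read quarters →
combine tables → deduplicate by identifiers → deduplicate by similarity →
exclusion filters → exposure classification → melanoma indication filter →
SMQ tagging → descriptive summaries and TTO → disproportionality scan.
The ``flowchart`` dict mirrors a report-selection flowchart: the surviving
report count after every step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import cohort, dedup, descriptives, faers_io, signals

log = logging.getLogger("faersig.pipeline")


@dataclass
class PipelineResult:
    universe: pd.DataFrame        # clean deduplicated DEMO with 'group' column
    cases: pd.DataFrame           # of-interest reports with group/is_cae
    cae_hits: pd.DataFrame        # (primaryid, smq, pt) hits on cases
    table1: pd.DataFrame
    tto_records: pd.DataFrame
    tto_summary: pd.DataFrame
    signal_table: pd.DataFrame
    flowchart: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)


def run_pipeline(data_dir: str | Path,
                 quarters: Sequence[str],
                 smqs: Sequence[cohort.SMQDefinition],
                 dictionary: Mapping[str, str] | None = None,
                 melanoma_pts: Iterable[str] | None = None,
                 ime_list: Iterable[str] = (),
                 dme_list: Iterable[str] = (),
                 label_map: Mapping[str, Iterable[str]] | None = None,
                 quartile_method: str = "tukey",
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the whole analysis on FAERS-style quarterly extracts."""
    extracts = [faers_io.read_quarter(data_dir, q) for q in quarters]
    combined = faers_io.build_combined(extracts)
    demo = combined.combined_demo
    flowchart = {"raw_reports": len(demo)}
    run_log = dict(combined.log)

    # two-step dedup, identifiers first, then similarity (fixed order)
    demo = dedup.dedup_by_ids(demo)
    flowchart["after_id_dedup"] = len(demo)
    keys = dedup.build_similarity_keys(demo, combined.combined_drug,
                                       combined.combined_reac, dictionary)
    demo = dedup.dedup_by_similarity(demo, keys=keys)
    flowchart["after_similarity_dedup"] = len(demo)

    drug = combined.combined_drug.loc[
        combined.combined_drug["primaryid"].isin(set(demo["primaryid"]))]
    reac = combined.combined_reac.loc[
        combined.combined_reac["primaryid"].isin(set(demo["primaryid"]))]
    excl = dedup.apply_exclusions(demo, drug.reset_index(drop=True),
                                  reac.reset_index(drop=True))
    demo, drug, reac = excl.demo, excl.drug, excl.reac
    run_log.update(excl.log)
    flowchart["clean_universe"] = len(demo)

    # cohorts
    drug = cohort.add_ingredient_column(drug, dictionary)
    groups = cohort.assign_groups(drug)
    flowchart["of_interest"] = len(groups)
    groups, indi_log = cohort.filter_indication(groups, drug,
                                                melanoma_pts=melanoma_pts)
    run_log.update(indi_log)
    flowchart["after_indication_filter"] = len(groups)

    universe = demo.copy()
    universe["group"] = universe["primaryid"].map(groups)
    cases = universe.loc[universe["group"].notna()].copy()
    hits = cohort.tag_cases(reac.loc[reac["primaryid"].isin(
        set(cases["primaryid"]))], smqs)
    cae_ids = set(hits["primaryid"])
    cases["is_cae"] = cases["primaryid"].isin(cae_ids)
    flowchart["cae_cases"] = int(cases["is_cae"].sum())

    table1 = descriptives.summarize(cases, quartile_method=quartile_method)
    tto_rec, tto_sum, tto_log = descriptives.compute_tto(
        cases.loc[cases["is_cae"]], drug, quartile_method=quartile_method)
    run_log.update(tto_log)

    signal_table = signals.compute_signals(universe, reac, smqs)
    signal_table = signals.annotate(signal_table, ime_list=ime_list,
                                    dme_list=dme_list, label_map=label_map)
    signal_table = signals.detect_sdrs(signal_table)

    result = PipelineResult(universe=universe, cases=cases, cae_hits=hits,
                            table1=table1, tto_records=tto_rec,
                            tto_summary=tto_sum, signal_table=signal_table,
                            flowchart=flowchart, log=run_log)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table1.to_csv(out / "table1_all.tsv", sep="\t", index=False)
    by_drug = result.table1.loc[~result.table1["cohort"].isin(
        ("combination", "monotherapy"))]
    by_drug.to_csv(out / "table1_by_drug.tsv", sep="\t", index=False)
    result.tto_summary.to_csv(out / "tto_summary.tsv", sep="\t", index=False)
    table = result.signal_table.copy()
    for col in ("ror", "ci_low", "ci_high"):
        table[col] = table[col].round(2)
    table.to_csv(out / "signals.tsv", sep="\t", index=False)
    (out / "run_log.json").write_text(
        json.dumps({"flowchart": result.flowchart, "log": result.log},
                   indent=2, default=int),
        encoding="utf-8")
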