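"""Two-step deduplication and exclusion filters for the report universe.

Spontaneous-reporting databases accumulate the same case several times:
manufacturers resubmit updated versions of a report (same ``caseid``, higher
``caseversion``), and the same clinical event may be reported independently
under different case identifiers.  Both inflate disproportionality
statistics, so the clean universe is built in a fixed two-step order:

1. :func:`dedup_by_ids` — one row per ``caseid``, keeping the most recent
   version;
2. :func:`dedup_by_similarity` — reports that agree exactly on six key
   fields (reaction PT multiset, onset date, sex, age, reporting country,
   suspect drug set) are collapsed to the most recent one.  A report with
   any of the six fields missing is never merged.

"Most recent" is made deterministic by a total order: highest
``caseversion``, then latest ``fda_dt``, then lexicographically largest
``primaryid``.

:func:`apply_exclusions` then removes (i) premarketing reports backed by a
literature reference, (ii) reports naming an investigational / blinded /
unspecified product, and (iii) reports whose only reaction is the
"No adverse event" PT (the PT itself is dropped everywhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .cohort import INGREDIENTS_OF_INTEREST, clean_drug_name, normalize_drug, normalize_pt
from .faers_io import date_sort_key

log = logging.getLogger("faersig.dedup")

#: case-insensitive substrings marking investigational/blinded products
DEFAULT_INVESTIGATIONAL_PATTERNS = (
    "investigational", "blinded", "unspecified ingredient", "biosimilar",
)

#: DEMO rept_cod values treated as study/literature premarketing sources
DEFAULT_STUDY_REPORT_CODES = ("EXP", "PER")

DEFAULT_NO_AE_PTS = ("no adverse event",)


def _recency_rank(frame: pd.DataFrame) -> pd.DataFrame:
    """Columns used by the tie-break ladder, ascending = older."""
    out = pd.DataFrame(index=frame.index)
    out["_cv"] = pd.to_numeric(frame["caseversion"], errors="coerce").fillna(-1.0)
    out["_fda"] = frame["fda_dt"].map(date_sort_key)
    out["_pid"] = frame["primaryid"].astype(str)
    return out


def _keep_most_recent(frame: pd.DataFrame, group_key: pd.Series) -> pd.DataFrame:
    """Keep one row per group, the maximal one under the recency ladder."""
    ranked = pd.concat([frame, _recency_rank(frame)], axis=1)
    ranked["_grp"] = group_key.values
    ranked = ranked.sort_values(["_cv", "_fda", "_pid"], kind="mergesort")
    kept = ranked.drop_duplicates("_grp", keep="last")
    kept = kept.drop(columns=["_cv", "_fda", "_pid", "_grp"])
    return kept.sort_values("primaryid", kind="mergesort").reset_index(drop=True)


def dedup_by_ids(reports: pd.DataFrame) -> pd.DataFrame:
    """Collapse report versions: one row per ``caseid``, most recent kept.

    Groups where every row misses both ``caseversion`` and ``fda_dt`` fall
    through to the primaryid tie-break (logged).
    """
    if reports.empty:
        return reports.copy()
    blind = (pd.to_numeric(reports["caseversion"], errors="coerce").isna()
             & (reports["fda_dt"].map(date_sort_key) == ""))
    if blind.any():
        log.info("dedup_by_ids: %d rows lack all recency fields; "
                 "primaryid tie-break used", int(blind.sum()))
    return _keep_most_recent(reports, reports["caseid"])


# ---------------------------------------------------------------------------
# similarity step
# ---------------------------------------------------------------------------

def build_similarity_keys(reports: pd.DataFrame,
                          combined_drug: pd.DataFrame,
                          combined_reac: pd.DataFrame,
                          dictionary: Mapping[str, str] | None = None
                          ) -> pd.Series:
    """Per-report similarity key: (PT multiset, onset date, sex, age,
    reporting country, suspect drug set), or ``None`` if any field missing.

    The suspect drug set is the set of normalized ingredients with role
    PS/SS (unrecognized names fall back to their cleaned verbatim so a key
    is still defined).  Matching is exact equality; missing never equals
    missing.
    """
    ids = reports["primaryid"]

    reac = combined_reac.loc[combined_reac["primaryid"].isin(set(ids))].copy()
    reac["pt_norm"] = reac["pt"].map(normalize_pt)
    reac = reac.loc[reac["pt_norm"] != ""]
    pt_key = (reac.sort_values("pt_norm", kind="mergesort")
              .groupby("primaryid")["pt_norm"].agg(tuple))

    drug = combined_drug.loc[
        combined_drug["primaryid"].isin(set(ids))
        & combined_drug["role_cod"].str.upper().isin(("PS", "SS"))].copy()
    names = drug["prod_ai"].where(drug["prod_ai"] != "", drug["drugname"])
    lookup = {v: (normalize_drug(v, dictionary) or clean_drug_name(v))
              for v in names.unique()}
    drug["suspect"] = names.map(lookup)
    drug = drug.loc[drug["suspect"] != ""]
    suspect_key = (drug.drop_duplicates(["primaryid", "suspect"])
                   .sort_values("suspect", kind="mergesort")
                   .groupby("primaryid")["suspect"].agg(tuple))

    frame = reports.set_index("primaryid", drop=False)
    parts = pd.DataFrame({
        "pts": ids.map(pt_key).values,
        "onset": frame["event_dt"].values,
        "sex": frame["sex"].values,
        "age": (frame["age"].astype(str) + "|" + frame["age_cod"].astype(str)).values,
        "country": frame["reporter_country"].values,
        "suspects": ids.map(suspect_key).values,
    }, index=reports.index)

    missing = (parts["pts"].isna() | parts["suspects"].isna()
               | (parts["onset"] == "") | (parts["sex"] == "")
               | (parts["country"] == "")
               | frame["age"].eq("").values)
    keys = pd.Series(list(zip(parts["pts"], parts["onset"], parts["sex"],
                              parts["age"], parts["country"], parts["suspects"])),
                     index=reports.index, dtype=object)
    keys[missing.values] = None
    return keys


def dedup_by_similarity(reports: pd.DataFrame,
                        keys: pd.Series | None = None,
                        combined_drug: pd.DataFrame | None = None,
                        combined_reac: pd.DataFrame | None = None,
                        dictionary: Mapping[str, str] | None = None
                        ) -> pd.DataFrame:
    """Collapse cross-case clones: among reports with identical, fully
    populated similarity keys keep the most recent.

    ``keys`` may be precomputed with :func:`build_similarity_keys`;
    otherwise the combined tables must be supplied.
    """
    if reports.empty:
        return reports.copy()
    if keys is None:
        if combined_drug is None or combined_reac is None:
            raise ValueError("need either precomputed keys or combined tables")
        keys = build_similarity_keys(reports, combined_drug, combined_reac,
                                     dictionary)
    keys = keys.reset_index(drop=True)
    frame = reports.reset_index(drop=True)
    mergeable = keys.notna()
    kept_mergeable = _keep_most_recent(frame.loc[mergeable],
                                       keys[mergeable]) if mergeable.any() \
        else frame.iloc[0:0]
    out = pd.concat([frame.loc[~mergeable], kept_mergeable], ignore_index=True)
    removed = len(frame) - len(out)
    if removed:
        log.info("dedup_by_similarity removed %d clone reports", removed)
    return out.sort_values("primaryid", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

@dataclass
class ExclusionResult:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    log: dict = field(default_factory=dict)


def apply_exclusions(demo: pd.DataFrame,
                     combined_drug: pd.DataFrame,
                     combined_reac: pd.DataFrame,
                     investigational_patterns: Iterable[str] = DEFAULT_INVESTIGATIONAL_PATTERNS,
                     no_ae_pts: Iterable[str] = DEFAULT_NO_AE_PTS,
                     study_report_codes: Iterable[str] = DEFAULT_STUDY_REPORT_CODES,
                     ) -> ExclusionResult:
    """Apply the three universe-level exclusion filters.

    (i) literature-supported premarketing reports (non-empty literature
    reference and a study/literature report type); (ii) reports naming any
    investigational/blinded/unspecified product; (iii) reports whose
    reactions are only "no adverse event" PTs — that PT is dropped from all
    reports first.  Each removal count is logged separately.
    """
    ids = demo["primaryid"]

    # (i) premarketing literature reports
    lit = demo["lit_ref"].fillna("") != ""
    if "rept_cod" in demo.columns:
        codes = {c.upper() for c in study_report_codes}
        lit &= demo["rept_cod"].str.upper().isin(codes)

    # (ii) investigational products
    patterns = [p.lower() for p in investigational_patterns]
    names = (combined_drug["drugname"].fillna("") + " "
             + combined_drug["prod_ai"].fillna("")).str.lower()
    invest_rows = names.apply(lambda s: any(p in s for p in patterns))
    invest_ids = set(combined_drug.loc[invest_rows, "primaryid"])
    invest = ids.isin(invest_ids)

    # (iii) "no adverse event" reactions
    banned = {normalize_pt(p) for p in no_ae_pts}
    reac = combined_reac.copy()
    reac_norm = reac["pt"].map(normalize_pt)
    reac = reac.loc[~reac_norm.isin(banned)].reset_index(drop=True)
    had_reac = ids.isin(set(combined_reac["primaryid"]))
    has_reac = ids.isin(set(reac["primaryid"]))
    no_ae_only = had_reac & ~has_reac

    excluded = lit | invest | no_ae_only
    run_log = {
        "excluded_literature": int(lit.sum()),
        "excluded_investigational": int(invest.sum()),
        "excluded_no_adverse_event": int(no_ae_only.sum()),
        "excluded_total": int(excluded.sum()),
    }
    log.info("exclusions: literature=%(excluded_literature)d "
             "investigational=%(excluded_investigational)d "
             "no_adverse_event=%(excluded_no_adverse_event)d", run_log)

    kept = demo.loc[~excluded].reset_index(drop=True)
    kept_ids = set(kept["primaryid"])
    return ExclusionResult(
        demo=kept,
        drug=combined_drug.loc[combined_drug["primaryid"].isin(kept_ids)]
        .reset_index(drop=True),
        reac=reac.loc[reac["primaryid"].isin(kept_ids)].reset_index(drop=True),
        log=run_log,
    )
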