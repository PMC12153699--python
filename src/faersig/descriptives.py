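"""Demographic/clinical summary tables and time-to-onset statistics.

Continuous variables are summarized as median (Q1–Q3), categorical ones as
counts and percentages, per therapy group and for the pooled combination /
monotherapy cohorts, separately for all adverse events and for the
cardiovascular subset.

Time-to-onset (TTO) is the number of days between the primary-suspect
drug's earliest therapy start date and the report's event date; reports
where either date is missing or not resolvable to day precision are dropped
from the TTO computation (never imputed) and counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (COMBINATION_GROUPS, INGREDIENTS_OF_INTEREST,
                     MONOTHERAPY_GROUPS, add_ingredient_column)
from .faers_io import parse_partial_date

log = logging.getLogger("faersig.descriptives")

# ---------------------------------------------------------------------------
# age handling
# ---------------------------------------------------------------------------

#: conversion factors from FAERS age unit codes to years
AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_GROUPS = ("Neonate", "Child", "Adolescent", "Adult", "Elderly",
              "Not available")


@dataclass(frozen=True)
class AgeYears:
    value: float
    source_unit: str


def age_to_years(raw, unit_code: str) -> AgeYears | None:
    """Convert a FAERS age to years.

    A missing unit with a value ≤ 120 is taken as years (the dominant FAERS
    convention); otherwise the age is treated as missing.  Negative values
    are missing (logged).
    """
    try:
        x = float(raw)
    except (TypeError, ValueError):
        return None
    if np.isnan(x):
        return None
    if x < 0:
        log.debug("negative age %r treated as missing", raw)
        return None
    unit = str(unit_code).strip().upper()
    if unit in AGE_FACTORS:
        return AgeYears(x * AGE_FACTORS[unit], unit)
    if unit == "":
        return AgeYears(x, "YR") if x <= 120 else None
    return None


def assign_age_group(age: AgeYears | float | None) -> str:
    """Pediatric/adult age bands: Neonate <28 days, Child <12 y,
    Adolescent 12–17, Adult 18–64, Elderly ≥65."""
    if age is None:
        return "Not available"
    years = age.value if isinstance(age, AgeYears) else float(age)
    if np.isnan(years):
        return "Not available"
    if years < 28.0 / 365.25:
        return "Neonate"
    if years < 12:
        return "Child"
    if years < 18:
        return "Adolescent"
    if years < 65:
        return "Adult"
    return "Elderly"


# ---------------------------------------------------------------------------
# quartiles
# ---------------------------------------------------------------------------

def quartiles(values, method: str = "tukey") -> tuple[float, float, float]:
    """(Q1, median, Q3) of a 1-d sample.

    ``tukey`` (default) uses median-of-halves hinges, including the sample
    median in both halves for odd n; ``linear`` uses the interpolated
    quantile convention.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    if x.size == 0:
        return (np.nan, np.nan, np.nan)
    med = float(np.median(x))
    if method == "linear":
        return (float(np.quantile(x, 0.25)), med, float(np.quantile(x, 0.75)))
    if method != "tukey":
        raise ValueError(f"unknown quartile method {method!r}")
    n = x.size
    half = (n + 1) // 2  # odd n: median belongs to both halves
    return (float(np.median(x[:half])), med, float(np.median(x[n - half:])))


# ---------------------------------------------------------------------------
# reporter regions
# ---------------------------------------------------------------------------

COUNTRY_REGIONS: Mapping[str, str] = {
    **dict.fromkeys(("US", "CA", "MX"), "North America"),
    **dict.fromkeys(("DE", "FR", "IT", "GB", "ES", "NL", "BE", "CH", "AT",
                     "SE", "NO", "DK", "FI", "PL", "PT", "IE", "GR", "CZ",
                     "HU", "RO", "RU", "UA", "SK", "HR", "BG"), "Europe"),
    **dict.fromkeys(("JP", "CN", "KR", "IN", "TH", "TW", "SG", "IL", "SA",
                     "TR", "PH", "MY", "ID", "VN", "HK"), "Asia"),
    **dict.fromkeys(("AU", "NZ"), "Oceania"),
    **dict.fromkeys(("BR", "AR", "CL", "CO", "PE", "VE", "EC", "UY"),
                    "South America"),
    **dict.fromkeys(("GT", "CR", "PA", "CU", "DO", "HN", "SV", "NI", "JM"),
                    "Central America"),
    **dict.fromkeys(("ZA", "NG", "EG", "KE", "MA", "TN", "DZ", "GH"),
                    "Africa"),
}

#: FAERS occupation codes -> reporter types
REPORTER_TYPES = {
    "CN": "Consumer", "MD": "Physician", "PH": "Pharmacist",
    "HP": "Health-professional", "OT": "Other health-professional",
    "LW": "Other health-professional",
}

#: FAERS outcome codes -> outcome labels
OUTCOME_LABELS = {
    "DE": "Death", "DS": "Disability", "LT": "Life-threatening",
    "HO": "Hospitalization", "OT": "Other serious (IME)",
    "CA": "Congenital anomaly", "RI": "Required intervention",
}


def reporter_region(country: str) -> str:
    c = str(country).strip().upper()
    return COUNTRY_REGIONS.get(c, "Not available") if c else "Not available"


# ---------------------------------------------------------------------------
# demographic/clinical summary
# ---------------------------------------------------------------------------

def _prepare(cases: pd.DataFrame) -> pd.DataFrame:
    frame = cases.copy()
    ages = [age_to_years(a, u) for a, u in zip(frame["age"], frame["age_cod"])]
    frame["age_years"] = [a.value if a else np.nan for a in ages]
    frame["age_group"] = [assign_age_group(a) for a in ages]
    frame["sex_label"] = frame["sex"].str.upper().map(
        {"F": "Female", "M": "Male"}).fillna("Not available")
    frame["reporter"] = frame["occp_cod"].str.upper().map(
        REPORTER_TYPES).fillna("Not available")
    frame["region"] = frame["reporter_country"].map(reporter_region)
    frame["year"] = frame["fda_dt"].astype(str).str[:4]
    frame["wt_kg"] = pd.to_numeric(frame["wt"], errors="coerce")
    return frame


def _block(frame: pd.DataFrame, cohort: str, population: str,
           quartile_method: str) -> list[dict]:
    rows = []
    n = len(frame)

    def add(section, category, count=None, pct=None, value=None):
        rows.append({"cohort": cohort, "population": population,
                     "section": section, "category": category,
                     "n": count, "pct": pct, "value": value})

    add("N", "reports", count=n)
    ages = frame["age_years"].dropna()
    q1, med, q3 = quartiles(ages, quartile_method) if len(ages) else (np.nan,) * 3
    add("age_years", "median", value=med)
    add("age_years", "q1", value=q1)
    add("age_years", "q3", value=q3)
    wts = frame["wt_kg"].dropna()
    wq1, wmed, wq3 = quartiles(wts, quartile_method) if len(wts) else (np.nan,) * 3
    add("weight_kg", "median", value=wmed)
    add("weight_kg", "q1", value=wq1)
    add("weight_kg", "q3", value=wq3)

    def categorical(section, series, categories=None):
        counts = series.value_counts()
        cats = categories if categories is not None else sorted(counts.index)
        for cat in cats:
            c = int(counts.get(cat, 0))
            add(section, cat, count=c, pct=(100.0 * c / n) if n else 0.0)

    categorical("age_group", frame["age_group"], AGE_GROUPS)
    categorical("sex", frame["sex_label"],
                ("Female", "Male", "Not available"))
    categorical("reporter", frame["reporter"])
    categorical("region", frame["region"])
    categorical("year", frame["year"])
    # outcomes: a report can carry several codes, so counts may exceed N
    outc = frame["outcomes"].explode().dropna()
    counts = outc.map(lambda c: OUTCOME_LABELS.get(c, c)).value_counts()
    none = int((frame["outcomes"].apply(len) == 0).sum())
    for cat in sorted(counts.index):
        c = int(counts[cat])
        add("outcome", cat, count=c, pct=(100.0 * c / n) if n else 0.0)
    add("outcome", "Not available", count=none,
        pct=(100.0 * none / n) if n else 0.0)
    return rows


def summarize(cases: pd.DataFrame,
              quartile_method: str = "tukey") -> pd.DataFrame:
    """Tidy demographic/clinical summary table.

    ``cases`` needs columns ``group`` (therapy code), ``is_cae`` (bool) and
    the DEMO fields ``age, age_cod, sex, wt, occp_cod, reporter_country,
    fda_dt, outcomes``.  Blocks are emitted for the pooled ``combination``
    and ``monotherapy`` cohorts and for every individual group present, each
    for the ``all`` and ``cae`` populations.  Empty cohorts produce an N=0
    block.
    """
    frame = _prepare(cases)
    cohorts: list[tuple[str, pd.DataFrame]] = [
        ("combination", frame.loc[frame["group"].isin(COMBINATION_GROUPS)]),
        ("monotherapy", frame.loc[frame["group"].isin(MONOTHERAPY_GROUPS)]),
    ]
    cohorts += [(g, frame.loc[frame["group"] == g])
                for g in list(COMBINATION_GROUPS) + list(MONOTHERAPY_GROUPS)
                if (frame["group"] == g).any()]
    rows: list[dict] = []
    for name, sub in cohorts:
        rows += _block(sub, name, "all", quartile_method)
        rows += _block(sub.loc[sub["is_cae"]], name, "cae", quartile_method)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time to onset
# ---------------------------------------------------------------------------

def compute_tto(cases: pd.DataFrame,
                combined_drug: pd.DataFrame,
                quartile_method: str = "tukey"
                ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Days from earliest primary-suspect therapy start to event date.

    ``cases`` needs ``primaryid, group, event_dt``.  Only PS rows of
    ingredients of interest contribute start dates; both dates must resolve
    to day precision.  Incomplete-date and negative records are dropped and
    counted.  Returns (records, per-group five-number summary, log).
    """
    drug = combined_drug
    if "ingredient" not in drug.columns:
        drug = add_ingredient_column(drug)
    ps = drug.loc[(drug["role_cod"].str.upper() == "PS")
                  & drug["ingredient"].isin(INGREDIENTS_OF_INTEREST)
                  & drug["primaryid"].isin(set(cases["primaryid"]))]

    starts: dict[str, object] = {}
    for pid, raw in zip(ps["primaryid"], ps["start_dt"]):
        d, prec = parse_partial_date(raw)
        if prec != "day":
            continue
        if pid not in starts or d < starts[pid]:
            starts[pid] = d

    records = []
    n_incomplete = n_negative = 0
    for pid, group, ev in zip(cases["primaryid"], cases["group"],
                              cases["event_dt"]):
        event, prec = parse_partial_date(ev)
        start = starts.get(pid)
        if prec != "day" or start is None:
            n_incomplete += 1
            continue
        days = (event - start).days
        if days < 0:
            n_negative += 1
            continue
        records.append({"primaryid": pid, "group": group, "days": days})
    rec = pd.DataFrame(records, columns=["primaryid", "group", "days"])

    rows = []
    for group, sub in rec.groupby("group"):
        q1, med, q3 = quartiles(sub["days"], quartile_method)
        rows.append({"group": group, "n": len(sub),
                     "min": float(sub["days"].min()), "q1": q1,
                     "median": med, "q3": q3,
                     "max": float(sub["days"].max())})
    summary = pd.DataFrame(rows, columns=["group", "n", "min", "q1",
                                          "median", "q3", "max"])
    run_log = {"tto_incomplete_dates": n_incomplete,
               "tto_negative": n_negative, "tto_records": len(rec)}
    log.info("TTO: %(tto_records)d records, %(tto_incomplete_dates)d dropped "
             "for incomplete dates, %(tto_negative)d negative", run_log)
    return rec, summary, run_log
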