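"""Reading FAERS-style quarterly ASCII extracts and building combined tables.

The FDA distributes FAERS as quarterly archives of six dollar-delimited text
tables (DEMO, DRUG, INDI, OUTC, REAC, THER), all keyed by ``primaryid``.  This
module parses one quarter into a :class:`QuarterExtract` and concatenates /
joins any number of quarters into the three combined tables the downstream
analysis runs on:

* ``combined_demo`` — one row per DEMO row, with OUTC outcome codes collapsed
  to a per-report set;
* ``combined_drug`` — DRUG rows joined with INDI (indications) and THER
  (therapy dates) on ``(primaryid, drug sequence)``;
* ``combined_reac`` — REAC rows restricted to reports present in DEMO.

Dialect: ``$``-delimited, first line is the header, no quoting.  Input is
decoded as Latin-1 (FAERS archives are not uniformly valid UTF-8, and Latin-1
is a lossless byte map).  All values are kept as strings; the empty string
means missing.  Malformed rows (wrong field count) are padded or truncated,
counted and logged — never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

log = logging.getLogger("faersig.io")

#: The six FAERS table names, lower-case, in canonical order.
TABLES = ("demo", "drug", "indi", "outc", "reac", "ther")

QUARTER_RE = re.compile(r"^20\d{2}q[1-4]$")

#: Header drift across quarters: known synonyms mapped to canonical names.
#: Unknown columns are carried through untouched.
COLUMN_ALIASES = {
    "gndr_cod": "sex",          # DEMO sex column before 2014Q2
    "case": "caseid",
    "case_id": "caseid",
    "lit_ref_cod": "lit_ref",
}

#: Columns guaranteed to exist (added empty if a quarter lacks them).
REQUIRED_COLUMNS = {
    "demo": ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
             "age", "age_cod", "sex", "wt", "wt_cod", "occp_cod",
             "reporter_country", "occr_country", "lit_ref", "rept_cod"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
    "outc": ["primaryid", "outc_cod"],
    "reac": ["primaryid", "pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
}

#: Stable column order for persisted combined tables.
COMBINED_DEMO_COLUMNS = REQUIRED_COLUMNS["demo"] + ["outcomes"]
COMBINED_DRUG_COLUMNS = ["primaryid", "drug_seq", "role_cod", "drugname",
                         "prod_ai", "indi_pt", "start_dt", "end_dt"]
COMBINED_REAC_COLUMNS = ["primaryid", "pt"]


# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------

def parse_partial_date(value: str) -> tuple[date | None, str | None]:
    """Parse a FAERS partial date (YYYY / YYYYMM / YYYYMMDD).

    Returns ``(date, precision)`` with precision one of ``'year'``,
    ``'month'``, ``'day'`` (or ``(None, None)`` when missing/unparseable).
    Year- and month-precision values are anchored to the first day of the
    period, but callers needing day arithmetic must check the precision.
    """
    s = str(value).strip()
    if not s or not s.isdigit():
        return None, None
    try:
        if len(s) == 4:
            return date(int(s), 1, 1), "year"
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 1), "month"
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8])), "day"
    except ValueError:
        return None, None
    return None, None


def date_sort_key(value: str) -> str:
    """Right-pad a partial date to 8 digits so lexicographic order is
    chronological ('' sorts before everything)."""
    s = str(value).strip()
    return s.ljust(8, "0") if s.isdigit() else ""


# ---------------------------------------------------------------------------
# single-quarter reading
# ---------------------------------------------------------------------------

@dataclass
class QuarterExtract:
    """One parsed FAERS quarter: six string-typed tables plus parse metadata."""

    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    #: per-table count of malformed (padded/truncated) rows
    parse_warnings: dict = field(default_factory=dict)
    #: per-table count of rows whose primaryid has no DEMO parent
    orphans: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _canon_column(name: str) -> str:
    c = name.strip().lower()
    return COLUMN_ALIASES.get(c, c)


def _read_dollar_file(path: Path) -> tuple[pd.DataFrame, int]:
    """Parse one $-delimited table. Returns (frame, n_malformed_rows)."""
    with open(path, encoding="latin-1", newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        columns = [_canon_column(c) for c in header.split("$")]
        ncol = len(columns)
        rows: list[list[str]] = []
        bad = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != ncol:
                bad += 1
                log.warning("%s line %d: %d fields where %d expected",
                            path.name, lineno, len(fields), ncol)
                fields = (fields + [""] * ncol)[:ncol]
            rows.append([f.strip() for f in fields])
    if rows:
        frame = pd.DataFrame(rows, columns=columns, dtype=str)
    else:
        frame = pd.DataFrame({c: pd.Series(dtype=str) for c in columns})
    return frame, bad


def read_quarter(directory_path: str | Path, quarter_label: str) -> QuarterExtract:
    """Read the six FAERS table files of one quarter from ``directory_path``.

    Files are located case-insensitively as ``<TABLE><yy>Q<n>.txt`` (e.g.
    ``DEMO14Q1.txt`` for quarter ``2014q1``).  A missing table file is fatal;
    malformed rows are repaired and counted in ``parse_warnings``.
    """
    if not QUARTER_RE.match(quarter_label):
        raise ValueError(f"quarter label {quarter_label!r} does not match YYYYqN")
    directory = Path(directory_path)
    available = {p.name.lower(): p for p in directory.iterdir() if p.is_file()}
    yy, q = quarter_label[2:4], quarter_label[5]

    tables: dict[str, pd.DataFrame] = {}
    warnings: dict[str, int] = {}
    for name in TABLES:
        fname = f"{name}{yy}q{q}.txt"
        if fname not in available:
            raise FileNotFoundError(
                f"missing FAERS table file {fname!r} for quarter "
                f"{quarter_label} in {directory}")
        frame, bad = _read_dollar_file(available[fname])
        for col in REQUIRED_COLUMNS[name]:
            if col not in frame.columns:
                frame[col] = ""
        tables[name] = frame
        warnings[name] = bad

    demo_ids = set(tables["demo"]["primaryid"])
    orphans = {
        name: int((~tables[name]["primaryid"].isin(demo_ids)).sum())
        for name in TABLES if name != "demo"
    }
    for name, n in orphans.items():
        if n:
            log.info("%s %s: %d orphan rows (no DEMO parent)",
                     quarter_label, name, n)
    return QuarterExtract(quarter_label=quarter_label, parse_warnings=warnings,
                          orphans=orphans, **tables)


# ---------------------------------------------------------------------------
# combined tables
# ---------------------------------------------------------------------------

@dataclass
class CombinedTables:
    """The three analysis tables assembled from one or more quarters."""

    combined_demo: pd.DataFrame   # one row per DEMO row; 'outcomes' frozenset
    combined_drug: pd.DataFrame   # DRUG + INDI + THER on (primaryid, drug_seq)
    combined_reac: pd.DataFrame   # REAC rows with a DEMO parent
    log: dict = field(default_factory=dict)


def build_combined(quarters: list[QuarterExtract]) -> CombinedTables:
    """Concatenate quarters and join the six tables into three.

    Quarters are sorted by label before concatenation so the result does not
    depend on input order.  Orphan rows (no DEMO parent anywhere in the
    concatenated universe) are excluded from the combined tables and counted
    in the log.  Duplicate ``(primaryid, drug_seq)`` pairs are kept (and, when
    a drug carries several indications, the drug row is repeated per
    indication, as in a plain relational join).
    """
    if not quarters:
        raise ValueError("build_combined requires at least one quarter")
    ordered = sorted(quarters, key=lambda q: q.quarter_label)

    def concat(name: str) -> pd.DataFrame:
        return pd.concat([q.table(name) for q in ordered], ignore_index=True)

    demo = concat("demo")
    drug, indi, outc, reac, ther = (concat(n) for n in
                                    ("drug", "indi", "outc", "reac", "ther"))

    demo_ids = set(demo["primaryid"])
    run_log: dict = {"n_quarters": len(ordered), "orphans_excluded": {}}
    frames = {"drug": drug, "indi": indi, "outc": outc,
              "reac": reac, "ther": ther}
    for name, frame in frames.items():
        mask = frame["primaryid"].isin(demo_ids)
        run_log["orphans_excluded"][name] = int((~mask).sum())
        frames[name] = frame.loc[mask].reset_index(drop=True)
    drug, indi, outc, reac, ther = (frames[n] for n in
                                    ("drug", "indi", "outc", "reac", "ther"))

    # DEMO + OUTC: outcome codes collapsed to a per-report frozenset
    outc_sets = (outc.loc[outc["outc_cod"] != ""]
                 .groupby("primaryid")["outc_cod"]
                 .agg(lambda s: frozenset(s)))
    combined_demo = demo.copy()
    combined_demo["outcomes"] = (combined_demo["primaryid"].map(outc_sets)
                                 .apply(lambda v: v if isinstance(v, frozenset)
                                        else frozenset()))

    # DRUG + INDI + THER, matched strictly on the drug's own sequence number
    dup_seq = int(drug.duplicated(["primaryid", "drug_seq"]).sum())
    if dup_seq:
        log.info("combined_drug: %d duplicate (primaryid, drug_seq) rows kept",
                 dup_seq)
    run_log["duplicate_drug_seq"] = dup_seq
    indi_j = indi.rename(columns={"indi_drug_seq": "drug_seq"})
    ther_j = ther.rename(columns={"dsg_drug_seq": "drug_seq"})
    combined_drug = (drug
                     .merge(indi_j[["primaryid", "drug_seq", "indi_pt"]],
                            on=["primaryid", "drug_seq"], how="left")
                     .merge(ther_j[["primaryid", "drug_seq", "start_dt", "end_dt"]],
                            on=["primaryid", "drug_seq"], how="left"))
    for col in ("indi_pt", "start_dt", "end_dt"):
        combined_drug[col] = combined_drug[col].fillna("")

    combined_reac = reac.reset_index(drop=True)
    run_log["n_reports"] = len(combined_demo)
    return CombinedTables(combined_demo=combined_demo,
                          combined_drug=combined_drug,
                          combined_reac=combined_reac,
                          log=run_log)


def write_combined(tables: CombinedTables, out_dir: str | Path) -> None:
    """Persist the combined tables as TSV with a stable column order.

    The ``outcomes`` set is serialized as a comma-joined sorted string.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo = tables.combined_demo.copy()
    demo["outcomes"] = demo["outcomes"].apply(lambda s: ",".join(sorted(s)))
    specs = [(demo, COMBINED_DEMO_COLUMNS, "combined_demo.tsv"),
             (tables.combined_drug, COMBINED_DRUG_COLUMNS, "combined_drug.tsv"),
             (tables.combined_reac, COMBINED_REAC_COLUMNS, "combined_reac.tsv")]
    for frame, order, fname in specs:
        extra = sorted(c for c in frame.columns if c not in order)
        frame.to_csv(out / fname, sep="\t", index=False,
                     columns=[c for c in order if c in frame.columns] + extra)
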