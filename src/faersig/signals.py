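"""Case/non-case disproportionality: ROR, SDR rule, annotation, audit.

For every (therapy group, PT) pair a 2x2 contingency table is formed over
the cleaned report universe::

                        PT present    PT absent
    group reports           a             b
    all other reports       c             d

The reporting odds ratio is ROR = (a·d)/(b·c) with the log-normal (Woolf)
95% confidence interval  exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).
A signal of disproportionate reporting (SDR) requires the CI lower bound to
exceed 1 with at least three reports of the pair.  Tables containing a zero
cell receive the Haldane–Anscombe +0.5 correction on every cell and are
flagged.

:func:`invert_ror` is the audit tool: given a published (n, group total,
universe N, ROR) quadruple it reconstructs the full table by solving for
the comparator cell, so published confidence intervals can be recomputed
and verified without access to the underlying database.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import ALL_GROUPS, SMQDefinition, normalize_pt, tag_cases

log = logging.getLogger("faersig.signals")

#: two-sided 97.5% normal quantile used for the 95% CI
DEFAULT_Z = 1.959964

SIGNALS_COLUMNS = ["group", "smq", "pt", "a", "b", "c", "d", "ror",
                   "ci_low", "ci_high", "corrected", "is_sdr", "is_ime",
                   "is_dme", "expected"]


class AuditError(ValueError):
    """Raised when a printed result cannot be reconstructed consistently."""


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one (group, PT) pair."""

    a: int  # group reports with the PT
    b: int  # group reports without the PT
    c: int  # other reports with the PT
    d: int  # all remaining reports

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def group_total(self) -> int:
        return self.a + self.b

    @property
    def pt_total(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool = False


@dataclass
class SignalResult:
    group: str
    pt: str
    smq: str
    n: int                  # = a, reports of the pair
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool = False
    is_sdr: bool = False
    is_ime: bool = False
    is_dme: bool = False
    expected: bool = False


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_table(group: str, pt: str, universe: pd.DataFrame,
                reactions: pd.DataFrame) -> ContingencyTable:
    """Count the 2x2 table for one (group, PT) pair.

    ``universe`` is the cleaned report table with a ``group`` column (empty
    string or NaN for comparator reports); ``reactions`` are the cleaned
    REAC rows.  Counting is at report level: a report mentioning the PT
    twice counts once.
    """
    pt_norm = normalize_pt(pt)
    with_pt = set(reactions.loc[reactions["pt"].map(normalize_pt) == pt_norm,
                                "primaryid"])
    in_group = universe["group"].eq(group).fillna(False) \
        if "group" in universe.columns else pd.Series(False, index=universe.index)
    has_pt = universe["primaryid"].isin(with_pt)
    a = int((in_group & has_pt).sum())
    b = int((in_group & ~has_pt).sum())
    c = int((~in_group & has_pt).sum())
    d = int((~in_group & ~has_pt).sum())
    if c == 0:
        log.debug("PT %r occurs only within group %s; CI will be corrected",
                  pt, group)
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# ROR and confidence interval
# ---------------------------------------------------------------------------

def ror_ci(t: ContingencyTable, z: float = DEFAULT_Z) -> RorResult:
    """ROR with log-normal 95% CI; Haldane–Anscombe +0.5 when any cell is 0."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(ror=ror,
                     ci_low=math.exp(math.log(ror) - z * se),
                     ci_high=math.exp(math.log(ror) + z * se),
                     corrected=corrected)


def invert_ror(a: int, group_total: int, universe_n: int,
               ror_printed: float) -> ContingencyTable:
    """Reconstruct the 2x2 table behind a printed (n, ROR) pair.

    With b = group_total − a fixed and c + d = universe_n − group_total,
    the ROR equation a·d = r·b·c is linear in c:
    c = a·(universe_n − group_total) / (r·b + a).  c is rounded to the
    nearest integer and the table is accepted only if its recomputed ROR is
    within 1% of the printed value.
    """
    if not (a >= 1 and group_total > a and universe_n > group_total
            and ror_printed > 0):
        raise ValueError("invert_ror preconditions violated")
    b = group_total - a
    m = universe_n - group_total
    c = int(round(a * m / (ror_printed * b + a)))
    if c < 1 or c > m:
        raise AuditError(
            f"no positive comparator cell solves ROR={ror_printed} "
            f"(a={a}, group_total={group_total}, N={universe_n})")
    table = ContingencyTable(a=a, b=b, c=c, d=m - c)
    recomputed = (table.a * table.d) / (table.b * table.c)
    if abs(recomputed / ror_printed - 1) > 0.01:
        raise AuditError(
            f"reconstructed ROR {recomputed:.4f} deviates >1% from printed "
            f"{ror_printed}")
    return table


# ---------------------------------------------------------------------------
# SDR rule and annotation
# ---------------------------------------------------------------------------

def detect_sdrs(results: pd.DataFrame | Sequence[SignalResult],
                min_n: int = 3) -> pd.DataFrame | list[SignalResult]:
    """Set the SDR flag: CI lower bound > 1 and at least ``min_n`` reports.

    Corrected (zero-cell) results follow the same rule; a pair with a = 0
    can never satisfy it.
    """
    if isinstance(results, pd.DataFrame):
        out = results.copy()
        n = out["a"] if "a" in out.columns else out["n"]
        out["is_sdr"] = (out["ci_low"] > 1.0) & (n >= min_n)
        return out
    return [replace(r, is_sdr=(r.ci_low > 1.0 and r.n >= min_n))
            for r in results]


def annotate(results: pd.DataFrame,
             ime_list: Iterable[str] = (),
             dme_list: Iterable[str] = (),
             label_map: Mapping[str, Iterable[str]] | None = None
             ) -> pd.DataFrame:
    """Flag IME/DME membership and label expectedness per (group, PT).

    ``label_map`` maps a group code to the PT set present in that product's
    label ("expected"); PTs absent from the map are unexpected.  Matching is
    case-insensitive.  IME membership is what reports call "clinically
    relevant".
    """
    ime = {normalize_pt(p) for p in ime_list}
    dme = {normalize_pt(p) for p in dme_list}
    labels = {g: {normalize_pt(p) for p in pts}
              for g, pts in (label_map or {}).items()}
    out = results.copy()
    pts = out["pt"].map(normalize_pt)
    out["is_ime"] = pts.isin(ime)
    out["is_dme"] = pts.isin(dme)
    out["expected"] = [p in labels.get(g, frozenset())
                       for g, p in zip(out["group"], pts)]
    return out


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def compute_signals(universe: pd.DataFrame,
                    reactions: pd.DataFrame,
                    smqs: Sequence[SMQDefinition],
                    groups: Sequence[str] = ALL_GROUPS,
                    z: float = DEFAULT_Z,
                    min_n: int = 3) -> pd.DataFrame:
    """PT-level disproportionality scan within the SMQ scope.

    ``universe`` must carry ``primaryid`` and ``group`` (comparator reports
    empty/NaN).  One row per (group, SMQ, PT) with a ≥ 1; a PT in two SMQs
    appears once per SMQ with identical statistics.  The frame's ``attrs``
    carry ``n_tests`` (hypotheses scanned) so users can adjust for
    multiplicity post hoc.
    """
    hits = tag_cases(reactions, smqs)
    n_universe = len(universe)
    group_sizes = universe["group"].value_counts()
    pt_reports = hits.drop_duplicates(["primaryid", "pt_norm"])
    pt_totals = pt_reports.groupby("pt_norm")["primaryid"].nunique()
    merged = hits.merge(universe[["primaryid", "group"]], on="primaryid",
                        how="left")
    in_group = merged.loc[merged["group"].isin(groups)]
    pair_counts = (in_group.groupby(["group", "smq", "pt_norm"])
                   ["primaryid"].nunique())
    display_pt = (hits.groupby("pt_norm")["pt"]
                  .agg(lambda s: s.value_counts().index[0]))

    rows = []
    for (group, smq, pt_norm), a in sorted(pair_counts.items()):
        g_total = int(group_sizes.get(group, 0))
        total_pt = int(pt_totals[pt_norm])
        t = ContingencyTable(a=int(a), b=g_total - int(a),
                             c=total_pt - int(a),
                             d=n_universe - g_total - (total_pt - int(a)))
        r = ror_ci(t, z=z)
        rows.append({"group": group, "smq": smq, "pt": display_pt[pt_norm],
                     "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "corrected": r.corrected})
    frame = pd.DataFrame(rows, columns=[c for c in SIGNALS_COLUMNS
                                        if c not in ("is_sdr", "is_ime",
                                                     "is_dme", "expected")])
    frame = detect_sdrs(frame, min_n=min_n)
    frame["is_ime"] = False
    frame["is_dme"] = False
    frame["expected"] = False
    frame.attrs["n_tests"] = len(frame)
    return frame[SIGNALS_COLUMNS]


def audit_printed(rows: Iterable[Mapping], universe_n: int,
                  group_totals: Mapping[str, int],
                  z: float = DEFAULT_Z) -> pd.DataFrame:
    """Reconstruct printed (n, ROR, CI) triplets and recompute their CIs.

    ``rows`` are mappings with keys ``group, pt, n, ror, ci_low, ci_high``.
    A row passes when each recomputed bound is within 0.02 of the printed
    one on the log scale (the wobble left by rounding the printed ROR and
    the solved integer cell).
    """
    out = []
    for row in rows:
        entry = dict(row)
        try:
            t = invert_ror(int(row["n"]), int(group_totals[row["group"]]),
                           int(universe_n), float(row["ror"]))
            r = ror_ci(t, z=z)
            entry.update({"c_solved": t.c, "ror_recomputed": r.ror,
                          "ci_low_recomputed": r.ci_low,
                          "ci_high_recomputed": r.ci_high,
                          "passed": (abs(math.log(r.ci_low / float(row["ci_low"]))) <= 0.02
                                     and abs(math.log(r.ci_high / float(row["ci_high"]))) <= 0.02)})
        except (AuditError, ValueError) as exc:
            entry.update({"c_solved": None, "ror_recomputed": None,
                          "ci_low_recomputed": None,
                          "ci_high_recomputed": None,
                          "passed": False, "error": str(exc)})
        out.append(entry)
    return pd.DataFrame(out)
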