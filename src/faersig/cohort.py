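"""Exposure cohorts and cardiovascular case tagging.

The analysis concerns six targeted-therapy ingredients used in BRAF
V600-mutant melanoma — the BRAF inhibitors dabrafenib (D), vemurafenib (V)
and encorafenib (E) and the MEK inhibitors trametinib (T), cobimetinib (C)
and binimetinib (B) — as monotherapy or as one of the three approved
combinations D+T, V+C and E+B.

A report enters a therapy group from its FAERS drug role codes: the primary
suspect (PS) must be one of the six ingredients; if the approved partner is
the secondary suspect (SS) the report is a combination case, if no other
ingredient of interest appears as PS/SS it is a monotherapy case, and
anything else (non-approved pairings, of-interest drugs only as
concomitants) is assigned to no group.  Reports whose suspect drugs of
interest carry a stated non-melanoma indication are excluded.

Cardiovascular adverse-event (cAE) cases are reports with at least one
reaction Preferred Term (PT) inside the narrow PT set of one of seven
cardiovascular Standardized MedDRA Queries (SMQs).  MedDRA is licensed, so
SMQ contents ship as user-editable configuration; only the seven SMQ names
are built in.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger("faersig.cohort")

# ---------------------------------------------------------------------------
# drugs of interest
# ---------------------------------------------------------------------------

#: single-letter code per ingredient of interest
MONO_CODES = {
    "dabrafenib": "D", "trametinib": "T",
    "vemurafenib": "V", "cobimetinib": "C",
    "encorafenib": "E", "binimetinib": "B",
}
INGREDIENTS_OF_INTEREST = frozenset(MONO_CODES)

#: approved BRAF/MEK partner of each ingredient (symmetric)
PARTNERS = {
    "dabrafenib": "trametinib", "trametinib": "dabrafenib",
    "vemurafenib": "cobimetinib", "cobimetinib": "vemurafenib",
    "encorafenib": "binimetinib", "binimetinib": "encorafenib",
}
COMBO_CODES = {
    frozenset({"dabrafenib", "trametinib"}): "D+T",
    frozenset({"vemurafenib", "cobimetinib"}): "V+C",
    frozenset({"encorafenib", "binimetinib"}): "E+B",
}
COMBINATION_GROUPS = ("D+T", "V+C", "E+B")
MONOTHERAPY_GROUPS = ("D", "T", "V", "C", "E", "B")
ALL_GROUPS = COMBINATION_GROUPS + MONOTHERAPY_GROUPS

#: brand/generic variants of the six drugs (extend via user dictionaries)
DEFAULT_DRUG_DICTIONARY = {
    "DABRAFENIB": "dabrafenib", "TAFINLAR": "dabrafenib",
    "TRAMETINIB": "trametinib", "MEKINIST": "trametinib",
    "VEMURAFENIB": "vemurafenib", "ZELBORAF": "vemurafenib",
    "COBIMETINIB": "cobimetinib", "COTELLIC": "cobimetinib",
    "ENCORAFENIB": "encorafenib", "BRAFTOVI": "encorafenib",
    "BINIMETINIB": "binimetinib", "MEKTOVI": "binimetinib",
}

#: trailing salt/formulation tokens stripped during lookup
SALT_TOKENS = frozenset({
    "MESYLATE", "MESILATE", "HYDROCHLORIDE", "HCL", "SULFATE", "SULPHATE",
    "HEMISULFATE", "SODIUM", "POTASSIUM", "CALCIUM", "ACETATE", "TARTRATE",
    "CITRATE", "MALEATE", "FUMARATE", "PHOSPHATE", "BESYLATE", "DIMETHYL",
    "SULFOXIDE", "ANHYDROUS", "MONOHYDRATE", "DIHYDRATE",
})

_PUNCT_RE = re.compile(r"[^A-Z0-9 ]+")


@dataclass(frozen=True)
class TherapyGroup:
    """One of the nine exposure groups."""

    code: str

    def __post_init__(self):
        if self.code not in ALL_GROUPS:
            raise ValueError(f"unknown therapy group code {self.code!r}")

    @property
    def kind(self) -> str:
        return "combination" if "+" in self.code else "monotherapy"


@dataclass(frozen=True)
class DrugRecord:
    """One drug mention on a report."""

    primaryid: str
    role_cod: str            # PS / SS / C / I
    ingredient: str | None   # normalized, None = not recognized
    drug_seq: str = ""
    indi_pt: str = ""
    start_dt: str = ""


def clean_drug_name(verbatim: str) -> str:
    """Upper-case, strip punctuation, collapse whitespace."""
    s = _PUNCT_RE.sub(" ", str(verbatim).upper())
    return " ".join(s.split())


def normalize_drug(verbatim: str,
                   dictionary: Mapping[str, str] | None = None) -> str | None:
    """Map a free-text FAERS drug name to a normalized ingredient.

    Lookup is case/punctuation-insensitive; trailing salt tokens are stripped
    one by one until a dictionary hit.  Unmatched names return ``None``.
    """
    table = DEFAULT_DRUG_DICTIONARY if dictionary is None else dictionary
    tokens = clean_drug_name(verbatim).split()
    while tokens:
        hit = table.get(" ".join(tokens))
        if hit is not None:
            return hit
        if tokens[-1] in SALT_TOKENS:
            tokens = tokens[:-1]
        else:
            return None
    return None


def add_ingredient_column(combined_drug: pd.DataFrame,
                          dictionary: Mapping[str, str] | None = None
                          ) -> pd.DataFrame:
    """Return a copy of ``combined_drug`` with a normalized ``ingredient``
    column (prod_ai preferred, drugname as fallback; '' when unrecognized)."""
    frame = combined_drug.copy()
    names = frame["prod_ai"].where(frame["prod_ai"] != "", frame["drugname"])
    # normalize each distinct verbatim once
    lookup = {v: normalize_drug(v, dictionary) or "" for v in names.unique()}
    frame["ingredient"] = names.map(lookup)
    return frame


# ---------------------------------------------------------------------------
# exposure classification
# ---------------------------------------------------------------------------

def classify_exposure(drugs: Iterable[DrugRecord | tuple]) -> str | None:
    """Assign one report's drug list to a therapy group code (or ``None``).

    Accepts :class:`DrugRecord` objects or plain ``(ingredient, role_cod)``
    pairs.  Rules: the PS drug must be one of the six ingredients; an approved
    partner as SS makes the combination group; no other ingredient of
    interest as PS/SS makes the monotherapy group; everything else (including
    several conflicting of-interest PS drugs) maps to no group.
    """
    ps: set[str] = set()
    ss: set[str] = set()
    for rec in drugs:
        if isinstance(rec, DrugRecord):
            ing, role = rec.ingredient, rec.role_cod
        else:
            ing, role = rec
        if ing not in INGREDIENTS_OF_INTEREST:
            continue
        role = str(role).upper()
        if role == "PS":
            ps.add(ing)
        elif role == "SS":
            ss.add(ing)
    if len(ps) != 1:
        if len(ps) > 1:
            log.debug("conflicting of-interest PS drugs %s -> no group", ps)
        return None
    (primary,) = ps
    others = (ps | ss) - {primary}
    if not others:
        return MONO_CODES[primary]
    if others == {PARTNERS[primary]}:
        return COMBO_CODES[frozenset({primary, PARTNERS[primary]})]
    return None


def assign_groups(combined_drug: pd.DataFrame,
                  dictionary: Mapping[str, str] | None = None) -> pd.Series:
    """Vectorized exposure classification over a combined DRUG table.

    Returns a Series mapping primaryid -> group code for every report that
    classifies into one of the nine groups.
    """
    frame = combined_drug
    if "ingredient" not in frame.columns:
        frame = add_ingredient_column(frame, dictionary)
    roles = frame["role_cod"].str.upper()
    mask = roles.isin(("PS", "SS")) & frame["ingredient"].isin(
        INGREDIENTS_OF_INTEREST)
    sub = frame.loc[mask, ["primaryid", "ingredient"]].copy()
    sub["role"] = roles[mask]
    if sub.empty:
        return pd.Series(dtype=object, name="group")
    assigned = (sub.groupby("primaryid")[["ingredient", "role"]]
                .apply(lambda g: classify_exposure(
                    zip(g["ingredient"], g["role"]))))
    assigned = assigned.dropna()
    assigned.name = "group"
    return assigned


def filter_indication(groups: pd.Series,
                      combined_drug: pd.DataFrame,
                      melanoma_pts: Iterable[str] | None = None,
                      dictionary: Mapping[str, str] | None = None
                      ) -> tuple[pd.Series, dict]:
    """Drop reports whose of-interest suspect drugs carry a non-melanoma
    indication.

    ``melanoma_pts`` is the allowed indication PT set; by default any PT
    containing the token "melanoma" qualifies.  Missing indications are
    retained (exclusion requires a *stated* non-melanoma condition).
    """
    if melanoma_pts is None:
        is_melanoma: Callable[[str], bool] = lambda pt: "melanoma" in pt.lower()
    else:
        allowed = {normalize_pt(p) for p in melanoma_pts}
        is_melanoma = lambda pt: normalize_pt(pt) in allowed

    frame = combined_drug
    if "ingredient" not in frame.columns:
        frame = add_ingredient_column(frame, dictionary)
    roles = frame["role_cod"].str.upper()
    mask = (frame["primaryid"].isin(groups.index)
            & roles.isin(("PS", "SS"))
            & frame["ingredient"].isin(INGREDIENTS_OF_INTEREST)
            & (frame["indi_pt"] != ""))
    stated = frame.loc[mask, ["primaryid", "indi_pt"]]
    bad = stated.loc[~stated["indi_pt"].map(is_melanoma), "primaryid"].unique()
    kept = groups.drop(index=bad, errors="ignore")
    run_log = {"excluded_non_melanoma": len(groups) - len(kept)}
    if run_log["excluded_non_melanoma"]:
        log.info("indication filter removed %d reports",
                 run_log["excluded_non_melanoma"])
    return kept, run_log


# ---------------------------------------------------------------------------
# SMQ tagging
# ---------------------------------------------------------------------------

#: the seven cardiovascular SMQs analysed by default
DEFAULT_SMQ_NAMES = (
    "Bradyarrhythmias (incl conduction defects and disorders of sinus node function)",
    "Cardiac failure",
    "Cardiomyopathy",
    "Embolic and thrombotic events",
    "Ischaemic heart disease",
    "Noninfectious myocarditis/pericarditis",
    "Tachyarrhythmias (incl supraventricular and ventricular tachyarrhythmias)",
)


def normalize_pt(pt: str) -> str:
    """Case-insensitive, whitespace-normalized PT comparison form."""
    return " ".join(str(pt).split()).lower()


@dataclass(frozen=True)
class SMQDefinition:
    """A named narrow-scope PT set defining one cardiovascular event class."""

    name: str
    narrow_pts: frozenset = field(default_factory=frozenset)
    version_label: str = ""

    def __post_init__(self):
        if not self.narrow_pts:
            raise ValueError(f"SMQ {self.name!r} has an empty narrow PT set")
        object.__setattr__(self, "narrow_pts",
                           frozenset(normalize_pt(p) for p in self.narrow_pts))

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.narrow_pts


def tag_cae(reactions: Iterable[str],
            smqs: Sequence[SMQDefinition]) -> list[tuple[str, str]]:
    """Return every (SMQ name, PT) hit for one report's reaction PTs.

    A PT belonging to two SMQs yields two hits.  Event-level outputs count
    hits; case-level outputs count distinct reports (a report is a cAE case
    iff this list is non-empty).
    """
    hits = []
    for pt in reactions:
        for smq in smqs:
            if pt in smq:
                hits.append((smq.name, pt))
    return hits


def tag_cases(combined_reac: pd.DataFrame,
              smqs: Sequence[SMQDefinition]) -> pd.DataFrame:
    """Vectorized SMQ tagging: one row per (primaryid, smq, pt) hit.

    Duplicate mentions of the same PT on one report count once.
    """
    pt_to_smqs: dict[str, list[str]] = {}
    for smq in smqs:
        for pt in smq.narrow_pts:
            pt_to_smqs.setdefault(pt, []).append(smq.name)
    reac = combined_reac[["primaryid", "pt"]].copy()
    reac["pt_norm"] = reac["pt"].map(normalize_pt)
    reac = reac.drop_duplicates(["primaryid", "pt_norm"])
    reac = reac.loc[reac["pt_norm"].isin(pt_to_smqs)]
    if reac.empty:
        return pd.DataFrame(columns=["primaryid", "smq", "pt", "pt_norm"])
    rows = reac.assign(smq=reac["pt_norm"].map(pt_to_smqs)).explode("smq")
    return rows[["primaryid", "smq", "pt", "pt_norm"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration loaders
# ---------------------------------------------------------------------------

def load_pt_list(path: str | Path) -> frozenset:
    """Load a flat PT list (one PT per line, '#' comments) as a normalized
    frozenset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"term list not found: {path}")
    pts = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            pts.append(normalize_pt(line))
    return frozenset(pts)


def load_smqs(path: str | Path) -> list[SMQDefinition]:
    """Load SMQ definitions from YAML.

    Layout::

        version_label: "MedDRA 26.1"
        smqs:
          - name: Cardiac failure
            narrow_pts: [Cardiac failure, Cardiogenic shock, ...]
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SMQ configuration not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    version = str(doc.get("version_label", ""))
    return [SMQDefinition(name=entry["name"],
                          narrow_pts=frozenset(entry["narrow_pts"]),
                          version_label=version)
            for entry in doc["smqs"]]
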