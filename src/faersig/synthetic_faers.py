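"""Synthetic FAERS quarterly extracts with known ground truth.

The generator writes the same dollar-delimited quarterly ASCII layout the
reader consumes, together with a :class:`Ledger` recording per-report truth
(therapy group, reaction set, duplicate lineage, true time-to-onset), so
every pipeline stage can be validated end to end without downloading the
real database.

Model: each report independently draws a therapy group (or the background),
a drug list (suspect drugs per group plus background concomitants), and a
reaction set where each Preferred Term is an independent Bernoulli draw.
Planted (group, PT) signals multiply the background *odds* of the PT inside
the group, so the expected reporting odds ratio of a planted pair equals
the configured multiplier regardless of universe size.  Duplicates are
exact clones of base reports (id-duplicates keep the caseid with a bumped
version; similarity-duplicates get fresh identifiers but identical
similarity-key fields) because the pipeline's similarity rule is exact
matching.  Partial dates and missing fields are injected at configured
rates.  All randomness flows from one seeded generator, and output files
are byte-identical for a fixed configuration.

The fixture vocabularies in this module (SMQ PT sets, drug catalogs,
indication terms) are synthetic stand-ins for the licensed MedDRA
dictionary and real FAERS content.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MONO_CODES, SMQDefinition, normalize_pt
from .faers_io import REQUIRED_COLUMNS

# ---------------------------------------------------------------------------
# fixture vocabularies (synthetic stand-ins for licensed MedDRA / real FAERS)
# ---------------------------------------------------------------------------

#: narrow PT sets per cardiovascular SMQ (synthetic fixture vocabulary)
FIXTURE_SMQ_PTS: dict[str, tuple[str, ...]] = {
    "Bradyarrhythmias (incl conduction defects and disorders of sinus node function)":
        ("Atrioventricular block complete", "Brugada syndrome",
         "Electrocardiogram QT prolonged", "Sinus bradycardia"),
    "Cardiac failure":
        ("Cardiac failure", "Cardiogenic shock", "Left ventricular failure",
         "Pulmonary oedema"),
    "Cardiomyopathy":
        ("Cardiomyopathy", "Cardiotoxicity", "Ejection fraction decreased",
         "Dilated cardiomyopathy"),
    "Embolic and thrombotic events":
        ("Disseminated intravascular coagulation", "Pulmonary embolism",
         "Deep vein thrombosis", "Cerebral ischaemia", "Splenic infarction"),
    "Ischaemic heart disease":
        ("Myocardial infarction", "Coronary artery stenosis",
         "Angina pectoris", "Acute coronary syndrome"),
    "Noninfectious myocarditis/pericarditis":
        ("Myocarditis", "Pericarditis"),
    "Tachyarrhythmias (incl supraventricular and ventricular tachyarrhythmias)":
        ("Atrial fibrillation", "Ventricular arrhythmia", "Sinus tachycardia",
         "Tachyarrhythmia"),
}

BACKGROUND_PTS: tuple[tuple[str, float], ...] = (
    ("Nausea", 0.08), ("Fatigue", 0.07), ("Drug ineffective", 0.06),
    ("Headache", 0.05), ("Diarrhoea", 0.05), ("Pyrexia", 0.04),
    ("Rash", 0.04), ("Vomiting", 0.03), ("Arthralgia", 0.03),
    ("Dizziness", 0.03), ("Pruritus", 0.02), ("Anaemia", 0.02),
    ("Cough", 0.02), ("Insomnia", 0.02), ("Malaise", 0.02),
)

#: background (non-interest) drugs: ingredient, brands, concomitant rate
BACKGROUND_DRUGS: tuple[tuple[str, tuple[str, ...], float], ...] = (
    ("aspirin", ("ASPIRIN",), 0.06),
    ("atorvastatin", ("LIPITOR", "ATORVASTATIN"), 0.05),
    ("metformin", ("GLUCOPHAGE", "METFORMIN"), 0.05),
    ("lisinopril", ("ZESTRIL", "LISINOPRIL"), 0.04),
    ("omeprazole", ("PRILOSEC", "OMEPRAZOLE"), 0.04),
    ("levothyroxine", ("SYNTHROID",), 0.03),
    ("pembrolizumab", ("KEYTRUDA",), 0.03),
    ("nivolumab", ("OPDIVO",), 0.03),
    ("ibuprofen", ("ADVIL", "IBUPROFEN"), 0.03),
    ("amlodipine", ("NORVASC",), 0.03),
    ("prednisone", ("PREDNISONE",), 0.03),
    ("paracetamol", ("TYLENOL", "PARACETAMOL"), 0.03),
)

MELANOMA_INDICATIONS = ("Malignant melanoma", "Melanoma", "Metastatic melanoma")
NON_MELANOMA_INDICATIONS = ("Colorectal cancer", "Non-small cell lung cancer",
                            "Thyroid cancer")
BACKGROUND_INDICATIONS = ("Hypertension", "Diabetes mellitus", "Pain",
                          "Depression", "Rheumatoid arthritis",
                          "Product used for unknown indication")

COUNTRIES = ("US", "DE", "FR", "IT", "JP", "GB", "AU", "CN", "BR", "CA",
             "ES", "NL")

COMBO_DRUGS = {"D+T": ("dabrafenib", "trametinib"),
               "V+C": ("vemurafenib", "cobimetinib"),
               "E+B": ("encorafenib", "binimetinib")}

BRAND_BY_INGREDIENT = {
    "dabrafenib": ("TAFINLAR", "DABRAFENIB", "Dabrafenib Mesylate"),
    "trametinib": ("MEKINIST", "TRAMETINIB", "Trametinib Dimethyl Sulfoxide"),
    "vemurafenib": ("ZELBORAF", "VEMURAFENIB"),
    "cobimetinib": ("COTELLIC", "COBIMETINIB"),
    "encorafenib": ("BRAFTOVI", "ENCORAFENIB"),
    "binimetinib": ("MEKTOVI", "BINIMETINIB"),
}

#: paper-shape group shares of the of-interest cohort (fractions of 18,370)
PAPER_GROUP_COUNTS = {
    "D+T": 8895, "E+B": 3097, "V": 2174, "V+C": 2111, "D": 852,
    "T": 695, "C": 263, "B": 161, "E": 122,
}
PAPER_OF_INTEREST_TOTAL = 18_370
PAPER_UNIVERSE_N = 14_077_067
PAPER_CAE_FRACTION = 0.087

DEFAULT_MISSING_RATES = {
    "age": 0.10, "sex": 0.05, "wt": 0.30, "country": 0.05, "occp": 0.05,
    "event_dt": 0.15, "event_dt_partial": 0.10,
    "start_dt": 0.20, "start_dt_partial": 0.10,
}


def fixture_smqs(version_label: str = "synthetic-fixture-1.0") -> list[SMQDefinition]:
    """The synthetic SMQ definitions matching the generator's vocabulary."""
    return [SMQDefinition(name=name, narrow_pts=frozenset(pts),
                          version_label=version_label)
            for name, pts in FIXTURE_SMQ_PTS.items()]


def default_quarters(first_year: int = 2014, last_year: int = 2023) -> list[str]:
    return [f"{y}q{q}" for y in range(first_year, last_year + 1)
            for q in (1, 2, 3, 4)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one synthetic universe (seed mandatory)."""

    n_reports: int
    seed: int
    quarters: list[str] = field(default_factory=default_quarters)
    #: of-interest group -> share of the universe
    group_shares: dict[str, float] = field(default_factory=dict)
    drug_catalog: tuple = BACKGROUND_DRUGS
    #: (pt, background rate, smq name or None)
    pt_catalog: list[tuple[str, float, str | None]] = field(default_factory=list)
    #: (group, pt, target odds multiplier)
    planted_signals: list[tuple[str, str, float]] = field(default_factory=list)
    duplicate_id_fraction: float = 0.0
    duplicate_similarity_fraction: float = 0.0
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    nonmelanoma_indication_rate: float = 0.0
    literature_rate: float = 0.0
    investigational_rate: float = 0.0
    no_ae_rate: float = 0.0
    tto_median_days: float = 30.0
    tto_sigma: float = 1.0

    def __post_init__(self):
        if not self.pt_catalog:
            self.pt_catalog = default_pt_catalog()
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        rates = ([self.duplicate_id_fraction, self.duplicate_similarity_fraction,
                  self.nonmelanoma_indication_rate, self.literature_rate,
                  self.investigational_rate, self.no_ae_rate]
                 + list(self.missing_rates.values())
                 + [r for _, r, _ in self.pt_catalog]
                 + list(self.group_shares.values()))
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if sum(self.group_shares.values()) > 1.0 + 1e-9:
            raise ValueError("group shares exceed 1")
        bad = set(self.group_shares) - set(PAPER_GROUP_COUNTS)
        if bad:
            raise ValueError(f"unknown therapy groups in shares: {bad}")
        rate_by_pt = {p: r for p, r, _ in self.pt_catalog}
        for group, pt, mult in self.planted_signals:
            if group not in PAPER_GROUP_COUNTS:
                raise ValueError(f"planted signal for unknown group {group!r}")
            if pt not in rate_by_pt:
                raise ValueError(f"planted signal for unknown PT {pt!r}")
            if planted_probability(rate_by_pt[pt], mult) >= 0.99:
                raise ValueError(
                    f"infeasible planted signal ({group}, {pt}, x{mult}): "
                    "joint probability reaches 1")


def default_pt_catalog(cv_rate: float = 0.002) -> list[tuple[str, float, str | None]]:
    """Background PT catalog: common non-CV terms plus every fixture SMQ PT
    at a uniform background reporting rate."""
    catalog: list[tuple[str, float, str | None]] = [
        (pt, rate, None) for pt, rate in BACKGROUND_PTS]
    for smq, pts in FIXTURE_SMQ_PTS.items():
        for pt in pts:
            catalog.append((pt, cv_rate, smq))
    return catalog


def planted_probability(background_rate: float, multiplier: float) -> float:
    """In-group PT probability whose odds are ``multiplier`` x background."""
    odds = multiplier * background_rate / (1.0 - background_rate)
    return odds / (1.0 + odds)


def emulate_paper_shape(scale: float, seed: int = 0,
                        quarters: list[str] | None = None) -> SimConfig:
    """Configuration mirroring the published cohort structure.

    The universe holds ``scale`` x 14,077,067 reports of which the
    of-interest groups take their published shares of ``scale`` x 18,370
    reports (D+T 48.4%, E+B 16.9%, V 11.8%, V+C 11.5%, D 4.6%, T 3.8%,
    C 1.4%, B 0.8%, E 0.7%).  A uniform odds multiplier is planted on every
    (group, cardiovascular PT) pair, solved so the expected in-group
    fraction of reports with at least one cardiovascular PT is 8.7%.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    n = max(1, round(scale * PAPER_UNIVERSE_N))
    shares = {g: c / PAPER_UNIVERSE_N for g, c in PAPER_GROUP_COUNTS.items()}
    catalog = default_pt_catalog()
    cv = [(pt, rate) for pt, rate, smq in catalog if smq is not None]

    def cae_fraction(mult: float) -> float:
        return 1.0 - math.prod(1.0 - planted_probability(r, mult)
                               for _, r in cv)

    lo, hi = 1.0, 64.0
    for _ in range(80):  # bisection: cae_fraction is increasing in mult
        mid = 0.5 * (lo + hi)
        if cae_fraction(mid) < PAPER_CAE_FRACTION:
            lo = mid
        else:
            hi = mid
    mult = 0.5 * (lo + hi)
    planted = [(g, pt, mult) for g in PAPER_GROUP_COUNTS for pt, _ in cv]
    return SimConfig(
        n_reports=n, seed=seed,
        quarters=quarters if quarters is not None else default_quarters(),
        group_shares=shares, planted_signals=planted,
        duplicate_id_fraction=0.10, duplicate_similarity_fraction=0.03,
        nonmelanoma_indication_rate=0.02, literature_rate=0.005,
        investigational_rate=0.005, no_ae_rate=0.005)


# ---------------------------------------------------------------------------
# ledger
# ---------------------------------------------------------------------------

@dataclass
class Ledger:
    """Ground truth for one generated universe.

    ``reports`` holds one row per *distinct* case (duplicates excluded):
    primaryid, caseid, group (None for background), excluded_reason
    (''/'literature'/'investigational'/'no_ae'), excluded_by_indication,
    reactions (tuple of PTs), is_cae, tto_days (None when either date is
    not day-complete).  ``duplicates`` maps clone primaryid -> base
    primaryid.
    """

    reports: pd.DataFrame
    duplicates: dict[str, str] = field(default_factory=dict)
    config_seed: int = 0

    @property
    def distinct_case_count(self) -> int:
        return len(self.reports)

    def clean(self) -> pd.DataFrame:
        """Reports surviving the exclusion filters (the analysis universe)."""
        return self.reports.loc[self.reports["excluded_reason"] == ""]

    def group_counts(self) -> dict[str, int]:
        """Retained of-interest reports per group (indication filter applied)."""
        clean = self.clean()
        cohort = clean.loc[clean["group"].notna()
                           & ~clean["excluded_by_indication"]]
        return cohort["group"].value_counts().to_dict()

    def cae_case_count(self) -> int:
        clean = self.clean()
        cohort = clean.loc[clean["group"].notna()
                           & ~clean["excluded_by_indication"]]
        return int(cohort["is_cae"].sum())

    def contingency(self, group: str, pt: str) -> tuple[int, int, int, int]:
        """Realized a/b/c/d cells over the clean universe for (group, pt)."""
        clean = self.clean()
        in_group = (clean["group"] == group) & ~clean["excluded_by_indication"]
        pt_norm = normalize_pt(pt)
        has_pt = clean["reactions"].apply(
            lambda pts: any(normalize_pt(p) == pt_norm for p in pts))
        a = int((in_group & has_pt).sum())
        b = int((in_group & ~has_pt).sum())
        c = int((~in_group & has_pt).sum())
        d = int((~in_group & ~has_pt).sum())
        return a, b, c, d

    def to_json(self, path: str | Path) -> None:
        doc = {
            "config_seed": self.config_seed,
            "duplicates": self.duplicates,
            "reports": [
                {**row, "reactions": list(row["reactions"]),
                 "tto_days": (None if row["tto_days"] is None
                              or (isinstance(row["tto_days"], float)
                                  and math.isnan(row["tto_days"]))
                              else int(row["tto_days"]))}
                for row in self.reports.to_dict("records")],
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "Ledger":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        reports = pd.DataFrame(doc["reports"])
        reports["reactions"] = reports["reactions"].apply(tuple)
        return cls(reports=reports, duplicates=doc["duplicates"],
                   config_seed=doc["config_seed"])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _quarter_bounds(label: str) -> tuple[date, date]:
    year, q = int(label[:4]), int(label[5])
    start = date(year, 3 * (q - 1) + 1, 1)
    end = date(year + 1, 1, 1) if q == 4 else date(year, 3 * q + 1, 1)
    return start, end - timedelta(days=1)


def _fmt(d: date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _date_field(d: date, i: int, missing, partial) -> str:
    """Format one date with its missing/partial mask (alternating rows keep
    month vs year precision when partial)."""
    if missing[i]:
        return ""
    s = _fmt(d)
    if partial[i]:
        return s[:6] if i % 2 == 0 else s[:4]
    return s


def generate(config: SimConfig, out_dir: str | Path) -> Ledger:
    """Write quarterly extract files under ``out_dir`` and return the ledger.

    Deterministic: the same configuration (seed included) produces
    byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    group_codes = sorted(config.group_shares)
    probs = np.array([config.group_shares[g] for g in group_codes])
    choices = group_codes + [None]
    group = np.array(rng.choice(len(choices), size=n,
                                p=list(probs) + [1.0 - probs.sum()]),
                     dtype=int)
    group_lab = np.array([choices[i] for i in group], dtype=object)

    # identifiers: base reports are version 1
    case_num = 10_000_001 + np.arange(n)
    caseid = np.char.mod("%d", case_num)
    primaryid = np.char.add(caseid, "1")

    # dates: fda_dt inside a uniformly chosen quarter
    q_idx = rng.integers(0, len(config.quarters), size=n)
    bounds = [_quarter_bounds(q) for q in config.quarters]
    fda = np.empty(n, dtype=object)
    for i, (qs, qe) in enumerate(bounds):
        mask = q_idx == i
        offs = rng.integers(0, (qe - qs).days + 1, size=int(mask.sum()))
        fda[mask] = [qs + timedelta(days=int(o)) for o in offs]
    event_delay = rng.integers(3, 90, size=n)
    event_date = np.array([f - timedelta(days=int(d))
                           for f, d in zip(fda, event_delay)], dtype=object)
    tto = np.maximum(0, np.round(np.exp(
        np.log(config.tto_median_days)
        + config.tto_sigma * rng.standard_normal(n)))).astype(int)
    start_date = np.array([e - timedelta(days=int(t))
                           for e, t in zip(event_date, tto)], dtype=object)

    mr = config.missing_rates
    event_missing = rng.random(n) < mr.get("event_dt", 0.0)
    event_partial = rng.random(n) < mr.get("event_dt_partial", 0.0)
    start_missing = rng.random(n) < mr.get("start_dt", 0.0)
    start_partial = rng.random(n) < mr.get("start_dt_partial", 0.0)
    event_str = np.array([_date_field(d, i, event_missing, event_partial)
                          for i, d in enumerate(event_date)], dtype=object)
    start_str = np.array([_date_field(d, i, start_missing, start_partial)
                          for i, d in enumerate(start_date)], dtype=object)
    fda_str = np.array([_fmt(d) for d in fda])

    # demographics
    age_years = np.clip(rng.normal(62, 13, size=n), 18, 95)
    age_unit = rng.choice(["YR", "DEC", "MON"], size=n, p=[0.9, 0.05, 0.05])
    age_val = np.where(age_unit == "YR", np.round(age_years),
                       np.where(age_unit == "DEC", np.round(age_years / 10, 1),
                                np.round(age_years * 12)))
    age_out = np.char.mod("%g", age_val).astype(object)
    unit_out = age_unit.astype(object)
    age_missing = rng.random(n) < mr.get("age", 0.0)
    age_out[age_missing] = ""
    unit_out[age_missing] = ""
    sex = rng.choice(["F", "M"], size=n, p=[0.45, 0.55]).astype(object)
    sex[rng.random(n) < mr.get("sex", 0.0)] = ""
    wt = np.char.mod("%.1f", np.clip(rng.normal(77, 15, size=n), 40, 160)
                     ).astype(object)
    wt_cod = np.full(n, "KG", dtype=object)
    wt_missing = rng.random(n) < mr.get("wt", 0.0)
    wt[wt_missing] = ""
    wt_cod[wt_missing] = ""
    occp = rng.choice(["MD", "CN", "PH", "OT", "HP"], size=n,
                      p=[0.35, 0.30, 0.08, 0.17, 0.10]).astype(object)
    occp[rng.random(n) < mr.get("occp", 0.0)] = ""
    country = rng.choice(COUNTRIES, size=n).astype(object)
    country[rng.random(n) < mr.get("country", 0.0)] = ""

    literature = rng.random(n) < config.literature_rate
    lit_ref = np.where(literature, "Doe J et al. Case series. J Oncol.", "")
    rept_cod = rng.choice(["EXP", "PER", "DIR"], size=n,
                          p=[0.55, 0.30, 0.15]).astype(object)
    rept_cod[literature] = "EXP"
    investigational = rng.random(n) < config.investigational_rate
    no_ae_only = rng.random(n) < config.no_ae_rate

    # reactions: per-PT Bernoulli; planted pairs multiply in-group odds
    pts = [p for p, _, _ in config.pt_catalog]
    base_rates = np.array([r for _, r, _ in config.pt_catalog])
    smq_of = {p: s for p, _, s in config.pt_catalog}
    prob = np.tile(base_rates, (n, 1))
    pt_index = {p: j for j, p in enumerate(pts)}
    for g, pt, mult in config.planted_signals:
        mask = group_lab == g
        prob[mask, pt_index[pt]] = planted_probability(
            base_rates[pt_index[pt]], mult)
    hit = rng.random((n, len(pts))) < prob
    # never leave a report without a reaction
    empty = ~hit.any(axis=1)
    hit[empty, pt_index["Drug ineffective"]] = True
    reactions = [tuple(p for j, p in enumerate(pts) if hit[i, j])
                 for i in range(n)]
    reactions = [("No adverse event",) if no_ae_only[i] else reactions[i]
                 for i in range(n)]
    is_cae = np.array([any(smq_of.get(p) for p in r) and not no_ae_only[i]
                       for i, r in enumerate(reactions)])

    # make base-report similarity keys unique by construction: deterministic
    # event-date bumps ensure a chance agreement between two *distinct*
    # reports can never contradict the ledger's distinct-case ground truth
    mono_of = {v: k for k, v in MONO_CODES.items()}

    def _suspects(i: int) -> tuple:
        g = group_lab[i]
        if g is None:
            s = [config.drug_catalog[bg_idx[i]][0]]
        elif "+" in g:
            s = list(COMBO_DRUGS[g])
        else:
            s = [mono_of[g]]
        if investigational[i]:
            s.append("INVESTIGATIONAL PRODUCT")
        return tuple(sorted(s))

    def _simkey(i: int) -> tuple:
        return (tuple(sorted(reactions[i])), event_str[i], sex[i],
                f"{age_out[i]}|{unit_out[i]}", country[i], _suspects(i))

    # drug lists
    of_interest = group_lab != None  # noqa: E711  (object-array comparison)
    bg_idx = rng.integers(0, len(config.drug_catalog), size=n)
    seen_keys: set = set()
    for i in range(n):
        if (event_missing[i] or sex[i] == "" or country[i] == ""
                or age_out[i] == ""):
            continue
        key = _simkey(i)
        while key in seen_keys:
            event_date[i] = event_date[i] + timedelta(days=1)
            start_date[i] = event_date[i] - timedelta(days=int(tto[i]))
            event_str[i] = _date_field(event_date[i], i, event_missing,
                                       event_partial)
            start_str[i] = _date_field(start_date[i], i, start_missing,
                                       start_partial)
            key = _simkey(i)
        seen_keys.add(key)
    conc = (rng.random((n, len(config.drug_catalog)))
            < np.array([r for _, _, r in config.drug_catalog]))
    brand_pick = rng.integers(0, 4, size=n)
    nonmel = rng.random(n) < config.nonmelanoma_indication_rate
    nonmel &= of_interest
    indi_missing = rng.random(n) < 0.2
    mel_pick = rng.integers(0, len(MELANOMA_INDICATIONS), size=n)
    nonmel_pick = rng.integers(0, len(NON_MELANOMA_INDICATIONS), size=n)
    bg_indi = rng.integers(0, len(BACKGROUND_INDICATIONS), size=n)
    bg_indi_present = rng.random(n) < 0.5

    drug_rows, indi_rows, ther_rows = [], [], []
    for i in range(n):
        pid = primaryid[i]
        seq = 1
        g = group_lab[i]
        if g is not None:
            if "+" in g:
                braf, mek = {"D+T": ("dabrafenib", "trametinib"),
                             "V+C": ("vemurafenib", "cobimetinib"),
                             "E+B": ("encorafenib", "binimetinib")}[g]
                suspects = [(braf, "PS"), (mek, "SS")]
            else:
                ing = {v: k for k, v in MONO_CODES.items()}[g]
                suspects = [(ing, "PS")]
            for ing, role in suspects:
                brands = BRAND_BY_INGREDIENT[ing]
                name = brands[brand_pick[i] % len(brands)]
                drug_rows.append((pid, str(seq), role, name, ing.upper()))
                if role == "PS":
                    if not indi_missing[i]:
                        pt = (NON_MELANOMA_INDICATIONS[nonmel_pick[i]]
                              if nonmel[i]
                              else MELANOMA_INDICATIONS[mel_pick[i]])
                        indi_rows.append((pid, str(seq), pt))
                    ther_rows.append((pid, str(seq), start_str[i], ""))
                seq += 1
        else:
            ing, brands, _ = config.drug_catalog[bg_idx[i]]
            name = brands[brand_pick[i] % len(brands)]
            drug_rows.append((pid, str(seq), "PS", name, ing.upper()))
            if bg_indi_present[i]:
                indi_rows.append((pid, str(seq),
                                  BACKGROUND_INDICATIONS[bg_indi[i]]))
            ther_rows.append((pid, str(seq), start_str[i], ""))
            seq += 1
        if investigational[i]:
            drug_rows.append((pid, str(seq), "SS",
                              "INVESTIGATIONAL PRODUCT", ""))
            seq += 1
        for j, (ing, brands, _) in enumerate(config.drug_catalog):
            if conc[i, j] and not (g is None and j == bg_idx[i]):
                drug_rows.append((pid, str(seq), "C", brands[0], ing.upper()))
                seq += 1

    outc_codes = ("HO", "DE", "OT", "LT", "DS")
    outc_p = (0.30, 0.10, 0.35, 0.03, 0.01)
    outc_hit = rng.random((n, len(outc_codes))) < np.array(outc_p)
    outc_rows = [(primaryid[i], code)
                 for i in range(n)
                 for j, code in enumerate(outc_codes) if outc_hit[i, j]]
    reac_rows = [(primaryid[i], p) for i in range(n) for p in reactions[i]]

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid,
        "caseversion": "1", "fda_dt": fda_str, "event_dt": event_str,
        "age": age_out, "age_cod": unit_out, "sex": sex,
        "wt": wt, "wt_cod": wt_cod, "occp_cod": occp,
        "reporter_country": country, "occr_country": country,
        "lit_ref": lit_ref, "rept_cod": rept_cod,
    })
    drug = pd.DataFrame(drug_rows, columns=REQUIRED_COLUMNS["drug"])
    indi = pd.DataFrame(indi_rows, columns=REQUIRED_COLUMNS["indi"])
    outc = pd.DataFrame(outc_rows, columns=REQUIRED_COLUMNS["outc"])
    reac = pd.DataFrame(reac_rows, columns=REQUIRED_COLUMNS["reac"])
    ther = pd.DataFrame(ther_rows, columns=REQUIRED_COLUMNS["ther"])

    # --- duplicates -------------------------------------------------------
    duplicates: dict[str, str] = {}
    extra = {"demo": [], "drug": [], "indi": [], "outc": [], "reac": [],
             "ther": []}
    n_id = int(round(config.duplicate_id_fraction * n))
    id_bases = rng.choice(n, size=min(n_id, n), replace=False) if n_id else []
    # similarity clones require a fully populated similarity key
    complete = (~event_missing & (sex != "") & (country != "")
                & ~age_missing)
    pool = np.flatnonzero(complete)
    n_sim = int(round(config.duplicate_similarity_fraction * n))
    sim_bases = (rng.choice(pool, size=min(n_sim, len(pool)), replace=False)
                 if n_sim and len(pool) else [])

    def clone(i: int, new_pid: str, new_caseid: str, version: str) -> None:
        row = demo.iloc[i].copy()
        row["primaryid"], row["caseid"] = new_pid, new_caseid
        row["caseversion"] = version
        extra["demo"].append(row)
        for name, frame in (("drug", drug), ("indi", indi), ("outc", outc),
                            ("reac", reac), ("ther", ther)):
            sub = frame.loc[frame["primaryid"] == primaryid[i]].copy()
            sub["primaryid"] = new_pid
            extra[name].append(sub)
        duplicates[new_pid] = primaryid[i]

    for i in id_bases:
        clone(int(i), caseid[int(i)] + "2", caseid[int(i)], "2")
    for k, i in enumerate(sim_bases):
        new_case = str(50_000_001 + k)
        clone(int(i), new_case + "1", new_case, "1")

    if extra["demo"]:
        demo = pd.concat([demo, pd.DataFrame(extra["demo"])],
                         ignore_index=True)
        for name, frame in (("drug", drug), ("indi", indi), ("outc", outc),
                            ("reac", reac), ("ther", ther)):
            merged = pd.concat([frame] + extra[name], ignore_index=True)
            if name == "drug":
                drug = merged
            elif name == "indi":
                indi = merged
            elif name == "outc":
                outc = merged
            elif name == "reac":
                reac = merged
            else:
                ther = merged

    # --- write quarterly files -------------------------------------------
    quarter_of = {}
    for label in config.quarters:
        qs, qe = _quarter_bounds(label)
        quarter_of[label] = (_fmt(qs), _fmt(qe))
    demo_q = pd.Series("", index=demo.index, dtype=object)
    for label, (lo, hi) in quarter_of.items():
        demo_q[(demo["fda_dt"] >= lo) & (demo["fda_dt"] <= hi)] = label
    pid_quarter = dict(zip(demo["primaryid"], demo_q))

    for label in config.quarters:
        yy, qn = label[2:4], label[5]
        ids = {p for p, q in pid_quarter.items() if q == label}
        for name, frame in (("demo", demo), ("drug", drug), ("indi", indi),
                            ("outc", outc), ("reac", reac), ("ther", ther)):
            sub = frame.loc[frame["primaryid"].isin(ids),
                            REQUIRED_COLUMNS[name]]
            sub = sub.sort_values(list(sub.columns), kind="mergesort")
            path = out / f"{name.upper()}{yy}Q{qn}.txt"
            lines = ["$".join(REQUIRED_COLUMNS[name])]
            lines += ["$".join(map(str, row)) for row in
                      sub.itertuples(index=False, name=None)]
            path.write_text("\n".join(lines) + "\n", encoding="latin-1")

    # --- ledger -----------------------------------------------------------
    excluded_reason = np.where(literature, "literature",
                               np.where(investigational, "investigational",
                                        np.where(no_ae_only, "no_ae", "")))
    tto_known = [int(t) if (not event_missing[i] and not event_partial[i]
                            and not start_missing[i] and not start_partial[i]
                            and group_lab[i] is not None)
                 else None
                 for i, t in enumerate(tto)]
    ledger_frame = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid,
        "group": group_lab, "excluded_reason": excluded_reason,
        # a missing indication never excludes, so only written ones count
        "excluded_by_indication": nonmel & ~indi_missing,
        "reactions": reactions, "is_cae": is_cae, "tto_days": tto_known,
    })
    return Ledger(reports=ledger_frame, duplicates=duplicates,
                  config_seed=config.seed)
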