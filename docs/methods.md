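# Methods

## Setting and data model

`faersig` implements a spontaneous-reporting-system safety analysis of the
kind run on the FDA Adverse Event Reporting System (FAERS): quarterly
dollar-delimited ASCII extracts (DEMO, DRUG, INDI, OUTC, REAC, THER) are
merged into three combined tables, cleaned, and scanned for signals of
disproportionate reporting (SDRs) of cardiovascular adverse events (cAEs)
among reports of the six BRAF/MEK-inhibitor ingredients used in melanoma —
dabrafenib (D), trametinib (T), vemurafenib (V), cobimetinib (C),
encorafenib (E), binimetinib (B) — as monotherapy or as one of the approved
combinations D+T, V+C, E+B.

All table values are handled as strings with the empty string meaning
missing; input is decoded as Latin-1 (a lossless byte map — FAERS archives
are not uniformly valid UTF-8). Header drift across quarters is absorbed by
a small alias table (e.g. `gndr_cod` → `sex`); unknown columns are carried
through. Rows with the wrong field count are padded/truncated and counted,
never silently dropped. Orphan rows (no DEMO parent) stay in the raw tables
but are excluded from combined outputs and counted in the run log.

## Deduplication

One case can appear many times (resubmitted versions, independent
reporters), which inflates disproportionality statistics. Cleaning is a
fixed two-step order:

1. **By identifiers** — one row per `caseid`, keeping the most recent
   version. "Most recent" is a total order: highest `caseversion`, then
   latest `fda_dt` (partial dates compared after right-padding to 8
   digits), then lexicographically largest `primaryid`. The ladder makes
   the result deterministic; the choice of the final tie-break is
   arbitrary but fixed.
2. **By similarity** — reports agreeing *exactly* on six fields (reaction
   PT multiset, onset date, sex, age with unit, reporting country, and the
   set of normalized PS/SS suspect drugs) collapse to the most recent one
   under the same ladder. A report with any of the six fields missing is
   never merged: fuzzy or partial matching would be irreproducible, and
   missing ≠ missing.

Both steps are idempotent and only ever remove rows; tests assert the
pipeline applies them in the fixed order.

Three exclusion filters then remove (i) premarketing reports supported by a
literature reference (non-empty `lit_ref` and, when the column exists, a
study/literature `rept_cod`, default {EXP, PER}), (ii) reports naming any
investigational/blinded/unspecified/biosimilar product (case-insensitive
substring patterns, configurable), and (iii) reports whose only reaction is
the "No adverse event" PT — that PT is first dropped from every report.
Counts are logged per filter.

## Cohorts and case definition

Free-text drug names are normalized through a brand/generic dictionary with
case/punctuation folding and iterative trailing-salt stripping
("Dabrafenib Mesylate" → dabrafenib). Exposure classification uses FAERS
role codes: the primary suspect (PS) must be one of the six ingredients;
the approved partner as secondary suspect (SS) gives the combination group;
no other of-interest PS/SS drug gives the monotherapy group; everything
else — non-approved pairings such as D+B, of-interest drugs appearing only
as concomitants, conflicting PS drugs — is assigned to no group. This makes
group assignment a partition: at most one group per report.

Reports whose of-interest suspect drugs carry a *stated* non-melanoma
indication are excluded; missing indications are retained, because
exclusion on absence of information would discard most of the cohort for a
rule that targets stated off-indication use. The melanoma term set is
configurable; the default accepts any indication PT containing "melanoma".
The filter looks at all of-interest suspect drugs (PS and SS), not the PS
drug alone.

A report is a cAE case when at least one reaction PT belongs to the narrow
PT set of one of seven cardiovascular SMQs (bradyarrhythmias, cardiac
failure, cardiomyopathy, embolic and thrombotic events, ischaemic heart
disease, noninfectious myocarditis/pericarditis, tachyarrhythmias).
MedDRA is licensed, so SMQ contents (and the IME/DME and per-drug label
term lists) ship as user-editable flat text/YAML configuration with a
version label; only the seven SMQ names are built in, and the test suite
uses a small synthetic fixture vocabulary. A PT in two SMQs counts as two
*events* but the report remains one *case*; event-level outputs count PT
hits per SMQ, case-level outputs count distinct reports.

## Descriptive statistics

Ages arrive in mixed units and convert by fixed factors (DEC x10, YR x1,
MON /12, WK /52.1775, DY /365.25, HR /8766); a missing unit with value
<= 120 is taken as years, anything else is missing. Age bands are
Neonate < 28 days, Child < 12 y, Adolescent 12–17, Adult 18–64, Elderly
>= 65 (ICH-style; the "Elderly" cut at 65 matches the convention of
geriatric reporting).

Continuous summaries are median (Q1–Q3). Quartiles default to Tukey
median-of-halves hinges (the median joins both halves for odd n), with a
`linear` interpolated-quantile option; the two conventions never differ by
more than one inter-observation gap (property-tested). Categorical blocks
report counts and percentages of the block N; outcome counts may exceed N
because one report can carry several outcome codes.

Time-to-onset (TTO) is event date minus the earliest therapy start date of
the PS drug, in days. Both dates must resolve to full day precision;
partial dates are never imputed, because imputation would manufacture TTO
signal. Records with incomplete dates or negative differences are dropped
and counted. Per-group five-number summaries are exported for box plots.

## Disproportionality

For each (group, PT) pair within the SMQ scope, a report-level 2x2 table is
built over the **full cleaned universe** (not the melanoma cohort): cases
are reports of the group with the PT, non-cases all other reports. The
reporting odds ratio is ROR = (a·d)/(b·c) with the log-normal (Woolf) 95%
CI exp(ln ROR ± z·sqrt(1/a+1/b+1/c+1/d)), z = 1.959964 (configurable; the
full-precision quantile rather than 1.96 so one fixed value governs
determinism). A zero cell triggers the Haldane–Anscombe +0.5 correction on
all cells and flags the result. An SDR requires CI lower bound > 1 and at
least 3 reports of the pair; corrected results follow the same rule, and
a = 0 can never qualify. Analysis stays at PT level within the SMQ scope
and applies no multiplicity adjustment (the scan's hypothesis count is
carried in the output's `n_tests` attribute so users can adjust post hoc).

### Auditing published results

`invert_ror` reconstructs the 2x2 table behind a published (n, ROR) pair
given the group total and universe size: with b = G − a fixed and
c + d = N − G, the ROR equation is linear in c, c = a(N − G)/(r·b + a).
The solved c is rounded to an integer and accepted only if the recomputed
ROR is within 1% of print. Recomputing the CI from the reconstructed cells
reproduces published bounds to within 0.02 on the log scale — the wobble
left by print rounding of the ROR and integer rounding of c — and usually
to the printed 2 decimals exactly. This is how the package verifies
published disproportionality tables without the 14-million-report
download.

## Synthetic universe

The generator emulates the features of FAERS the pipeline must survive:
multi-quarter files with a shared schema, id- and similarity-duplicates,
partial dates (YYYY/YYYYMM/YYYYMMDD), mixed age units, PS/SS/C role codes,
indication and therapy-date records, exclusion-filter material, and planted
drug–event associations. Reports are independent; each PT is an
independent Bernoulli draw, and a planted (group, PT) signal multiplies the
background *odds* of the PT inside the group so the expected ROR equals
the configured multiplier independently of universe size. Duplicates are
exact clones (the similarity rule is exact matching, so noisy clones would
test a different method). Base-report similarity keys are made unique by
construction (deterministic event-date bumps), so the ledger's
distinct-case count is exactly recoverable for any duplicate fraction.

Default study conditions, chosen once: background cardiovascular PT rate
0.002 per report over a fixture vocabulary of 27 PTs in 7 SMQs; common
non-CV background PTs at 0.02–0.08; TTO lognormal with median 30 days and
log-sd 1; missing-data rates of 10% (age), 5% (sex, country), 15%/10%
(missing/partial event date), 20%/10% (therapy start). `emulate_paper_shape`
scales the published cohort structure: a universe of scale x 14,077,067
reports, of-interest groups at their published shares of scale x 18,370
(D+T 48.4%, E+B 16.9%, V 11.8%, V+C 11.5%, D 4.6%, T 3.8%, C 1.4%,
B 0.8%, E 0.7%), and a uniform planted odds multiplier solved by bisection
so the expected in-group cAE fraction is 8.7%, with 10% id-duplicates and
3% similarity clones.

What the generator does **not** emulate: confounding by indication or
channeling, notoriety/stimulated-reporting dynamics, correlated
drug–event structure beyond the planted pairs, within-case longitudinal
structure, or free-text coding noise beyond brand/salt variants. Passing
tests therefore demonstrate correctness of the mechanics (parsing, joins,
dedup, counting, estimation) and calibration of the statistics under
independence — not robustness to the epidemiological biases of real
spontaneous-reporting data.

## Problem sizes and numerical choices

The test suite exercises one shared synthetic study of 50,000 distinct
reports (10% id-duplicates, 3% similarity clones, a planted D+T–atrial
fibrillation signal with odds multiplier 4), chosen so that expected
contingency cells are large enough for a ±3-SE log-scale recovery band
while the whole suite stays lightweight; CI coverage is checked over
10,000 simulated tables with all expected cells >= 5. Ties in the dedup
ladder, zero cells, empty groups and empty quarters all have defined
behaviour (see the module docstrings). Reported ROR/CI values are written
at uniform 2-decimal precision.

## Known limitations

- Similarity dedup requires exact field agreement; truly identical
  duplicates differing by a typo survive (by design, documented above).
- The literature-report filter depends on the presence of a `rept_cod`
  column; without it, a non-empty literature reference alone triggers
  exclusion.
- Expectedness annotation is a configured per-drug PT list, not label
  parsing; IME/DME lists are user-supplied.
- The region summary uses a built-in country→continent table covering the
  common reporter countries; anything else maps to "Not available".
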