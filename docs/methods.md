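# Methods

## Scope and data model

`pvsignal` analyses spontaneous adverse-event reports in the public FAERS
quarterly ASCII dialect: dollar-delimited tables DEMO (demographics and
receipt dates), DRUG (drug entries with role codes), REAC (MedDRA
preferred terms), OUTC (regulatory outcome codes) and THER (therapy
dates). RPSR and INDI files exist in real releases but feed no
computation here and are not read. Dates are kept as partial dates (year,
year+month, or full); out-of-range components are rejected at parse time
and counted, never clamped or repaired. A row whose field count exceeds
the header (an embedded delimiter inside free text) is rejected rather
than guessed at, because any repair is unverifiable.

## Case processing

**Deduplication.** A case (CASEID) may appear as several report versions
(PRIMARYID) across quarters. Per case, the version with the latest FDA_DT
is kept; ties keep the higher PRIMARYID (numeric comparison when all ids
are numeric, zero-padded string comparison otherwise, with a warning).
Deduplication runs across all loaded quarters jointly — per-quarter
deduplication would leave cross-quarter duplicates in place.

**Seriousness.** FAERS has no single "serious" flag; a report is serious
iff it carries at least one OUTC code. The outcome table is non-exclusive
(a report may be both hospitalized and fatal), so its rows deliberately
do not sum to the report count.

**Age.** Ages normalize to years via DEC×10, YR×1, MON/12, WK/52.14,
DY/365.25, HR/8766 (calendar-accurate divisors; any consistent convention
differs only in the fourth decimal). Negative or implausible (>120 y)
results become missing with a warning; a value with no unit is taken as
years. Age strata are half-open: [0,18), [18,45), [45,65), [65,∞).

**Screening.** A case belongs to the target set when at least one drug
entry matches the active-ingredient keyword (case-insensitive substring
on PROD_AI, falling back to DRUGNAME when PROD_AI is blank — a drug named
only by brand should not escape the screen) **and** that entry has the
required role (default PS, primary suspect). All remaining deduplicated
cases form the comparator background; the split is an exact partition.

## Dictionary mapping

MedDRA content is licensed, so the PT→SOC dictionary is a user-supplied
TSV (columns `pt`, `soc`, optional `synonym`). Lookup is case- and
whitespace-insensitive; synonyms resolve to their canonical PT. Each PT
maps to exactly one primary SOC, keeping SOC-level counts a disjoint
partition. Terms the dictionary cannot resolve stay in PT-level
statistics under their raw name (flagged unmapped) and are excluded from
SOC-level tables only; dropping them entirely would silently change
PT-level counts.

## Disproportionality

The counting unit is the report × PT pair after within-report collapse of
repeated PTs. For each PT occurring in the target set: a = target reports
containing the PT, b = remaining target pairs, c and d analogously in the
background. ROR = ad/bc with the Wald interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)); 1.96 is fixed by convention, not
recomputed. No continuity correction: zero-cell tables yield an undefined
ROR and can never be signals (the ≥3-report rule makes a=0 irrelevant
anyway). Signal ⇔ lower bound > 1 and n ≥ `min_count` (default 3). No
multiplicity adjustment is applied — the criterion is the field's raw
per-PT rule — and the number of tests is recorded in the flow log. SOC
"signal counts" are counts of PT-level signals grouped by SOC, not
SOC-level RORs.

**Subgroups.** Default comparator is *within-stratum*: both target and
background are restricted to the stratum before tables are built, so each
stratum is a self-contained analysis frame; a `global` comparator is
available as a configuration flag. Cases missing a dimension's label are
excluded from that dimension only. Country strata default to the top-k
countries by target-report count. No cross-level consistency is enforced:
a PT can be a signal overall and in no stratum (or vice versa) under
Simpson-style imbalance.

**Ranking.** Top-k tables rank positive signals by ROR or by report
count; ties break by the other key descending, then PT name. The
new-signal view keeps signals whose PT is absent from the label list and
which carry at least `new_signal_min_n` (default 10) reports; below-threshold
new signals remain in the full output.

## Time to onset

Onset is the calendar-day difference from the earliest full
therapy-start date among the case's target-drug entries to the event
date; either date partial or missing, or a negative difference
(data-entry error), yields "unknown". Bins are closed: [0,30], [31,60],
[61,90], [91,120], [121,150], [151,180], [181,360], [361,∞). Bin
percentages use the known-onset count as denominator; quartiles use
linear interpolation; SD is the n−1 sample form.

## Rounding

Printed percentages are exact rational divisions rounded half-up to two
decimals (banker's rounding would disagree with published tables on
ties). Output tables carry both the 2-decimal presentation columns and
full-precision columns.

## Synthetic data generator

The generator emulates the structure that matters statistically, with
defaults chosen to mirror a newly approved drug's reporting profile:

| parameter | default | rationale |
|---|---|---|
| `n_reports` | 20 000 | desk-scale; gives ≈1 000 target reports |
| `target_drug_fraction` | 0.05 | a new drug is a small share of the database |
| `pt_catalogue` | 27 PTs, Σp ≈ 1.56 | ≈1.8 events/report after conditioning |
| `planted_signals` | Nephrolithiasis, θ = ln 8 | one strong association |
| `duplicate_rate` | 0.10 | follow-up versions are common |
| `missing_age_rate` | 0.52 | half of spontaneous reports lack age |
| `missing_sex_rate` | 0.177 | |
| `partial_date_rate` | 0.75 | ≈¾ of reports cannot support onset |
| `onset_lognormal` | (ln 64, 2.45) | median ≈2 months, heavy tail past a year |
| `outcome_rate` | 0.4427 | serious fraction |
| ages | Gamma(1.55, 14.9), years | mean ≈23, SD ≈19, child-heavy skew |

Each catalogue PT enters a report independently with its baseline
probability; for planted PTs in target-drug reports the probability is
multiplied by e^θ. Reports are conditioned on carrying ≥1 event by
redrawing; the conditioning factor cancels within each drug arm, so with
a single planted PT the population pair-level ROR equals e^θ *exactly*.
`expected_ror` evaluates the exact closed form
ROR = p′(S−p) / (p(S′−p′)) (p, p′ the comparator/target probabilities,
S, S′ the catalogue sums): with several PTs planted simultaneously each
inflates the others' comparator column, so their pair-level RORs sit
slightly below e^θ — an intrinsic property of ratio-based
disproportionality, not an artefact. The default config therefore plants
a single PT.

Duplicate case versions copy the original under an incremented PRIMARYID
with FDA_DT either advanced 1–90 days or kept equal (half/half),
exercising both branches of the deduplication rule; the manifest records
the intended keeper per case, the exact expected contingency tables, true
RORs, and per-quarter row counts, so loaders and the deduplicator can be
checked against ground truth. Identical config and seed give
byte-identical files.

What the generator does **not** emulate: the real marginal distribution
of 20 000+ PTs, indication-channelled confounding, reporter-dependent
term choice, free-text drug-name noise beyond a brand/ingredient split,
and secular reporting trends. Passing tests therefore demonstrate the
pipeline's correctness and calibration under independence assumptions,
not robustness to confounding by indication — a known limitation of ROR
methods generally.

## Validation strategy and problem sizes

The acceptance suite checks, at sizes chosen to keep the whole suite
under a minute of CPU: exact reproduction of a published study's printed
percentage tables from their integer counts (1 588 reports, 3 470 AE
pairs, 401 onsets); ROR/CI equality with a 50-digit-precision oracle on
1 000 random tables (tolerance 1e−12); 95% CI coverage within ±2% over
2 500 simulated tables with known odds ratios and margins ≥ 100; a
flagged-PT fraction ≤5% pooled over ten 20 000-report null datasets (one
dataset offers only 27 PT-tests, so pooling turns the fraction into a
measurement rather than a 0/27-granularity coin flip); median ln ROR
recovery within ±0.15 of θ = ln 8 over five 20 000-report replicates
(expected a ≈ 190 per replicate); exact agreement of deduplication with a
brute-force group-max oracle on 500 versioned cases and of onset binning
with a linear interval scan on days 0–10 000; and byte-identical outputs
across repeated pipeline runs. All analysis-side code is deterministic
and seed-free; every random draw in the toolchain lives in the generator
and is controlled by the config seed.

## Degenerate inputs and tie-breaks

Empty target set, empty keyword, a quarter without DEMO, conflicting
dictionary rows and a synonym pointing at an unknown PT are refusals
(explicit errors), not silent empties. Undefined RORs are values, not
exceptions. Deterministic orderings everywhere ties could appear: dedup
output by CASEID, scan output by PT name, rankings by the documented tie
rule, SOC tables by count then name.
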