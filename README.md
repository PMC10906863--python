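# pvsignal

Disproportionality signal detection for spontaneous adverse-event report
databases in the FAERS quarterly ASCII dialect.

Post-marketing drug safety surveillance asks a simple question of a very
messy database: among millions of spontaneous reports, is a particular
adverse event reported *disproportionately often* with a particular drug?
`pvsignal` implements the full analysis chain a pharmacovigilance study
runs to answer it — quarterly file ingestion, case deduplication,
target-drug screening, dictionary normalization of event terms, reporting
odds ratios with the classical signal criterion, stratified subgroup
scans, time-to-onset analysis and demographic summaries — together with a
synthetic-data generator that plants associations of known strength, so
every stage is testable without downloading a multi-million-report
database. It is written for pharmacoepidemiologists and biostatisticians
who want a transparent, fully deterministic desk-scale pipeline.

## The statistic

For each preferred term (PT), reports are cross-classified into the 2×2
table of report × PT pairs

|             | target AE | other AEs |
|-------------|-----------|-----------|
| target drug | a         | b         |
| other drugs | c         | d         |

and the reporting odds ratio with its 95% Wald interval is

```
ROR = (a/b) / (c/d) = ad / bc
95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )
```

A PT is a **positive signal** when the lower CI bound exceeds 1 and at
least three reports support it. No continuity correction is applied: any
zero cell leaves the ROR undefined and the PT cannot be a signal. A
signal is flagged **new** when its PT is absent from the drug's label
list. Subgroup scans (sex, age strata, reporting country) restrict both
the target and the comparator sets to the stratum before building tables.

The ROR is a reporting imbalance measure, not a risk estimate: it
inherits all the biases of spontaneous reporting (notoriety effects,
indication channelling, unknown denominators) and is a
hypothesis-generating flag only.

## Worked example

Simulate twelve quarters of reports with one planted association
(Nephrolithiasis at a true ROR of 8 for the target drug), run the
pipeline, and render the report:

```
$ pvsignal simulate --seed 11 --n-reports 5000 --out demo/data
wrote 31933 rows across 12 quarters to demo/data

$ pvsignal run --input demo/data --out demo/results --keyword risdiplam
232 target cases, 27 PTs scanned, 2 positive signals; outputs in demo/results

$ pvsignal report --run-dir demo/results
wrote demo/results/report.md
```

The new-signals section of `report.md` then reads:

| pt | soc | n | ror | ci_low | ci_high |
|---|---|---|---|---|---|
| Nephrolithiasis | Renal and urinary disorders | 36 | 6.85 | 4.65 | 10.08 |
| Weight decreased | Investigations | 19 | 1.68 | 1.04 | 2.70 |

Reading: among the 232 reports naming the target drug as primary suspect,
36 list nephrolithiasis, 6.85 times the reporting odds of the comparator
reports (95% CI 4.65–10.08) — the planted association, recovered. The
second row (true ROR 1, lower bound 1.04) is a chance finding: the
criterion is applied per PT without multiplicity adjustment, so a few
false positives per scan are expected and that is the method, not a bug.
`demo/results/` also holds the complete per-PT table (`signals.tsv`),
stratified scans, SOC summaries, demographics, onset bins, the
deduplication audit and a machine-readable stage-flow log.

The same pipeline runs unchanged on real FAERS quarterly ASCII files
(`DEMO2023Q1.txt`, …) given a PT→SOC dictionary TSV exported from a
licensed MedDRA installation.

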