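# hlstrat

Cure-fraction survival modelling and immunohistochemistry (IHC) marker
stratification for Hodgkin lymphoma (HL) cohorts.

Classical HL is mostly curable: after first-line therapy the survival curve
of a patient subgroup typically falls for a few years and then settles on a
plateau — the fraction of patients who are effectively cured.  This package
implements the full analysis chain for asking whether a tumour-cell marker
(here SATB1 and p16 scored on Hodgkin/Reed–Sternberg cells) splits a cohort
into subgroups with different cure fractions and different event kinetics:

* **IHC scoring** — staining intensity (SI, 0–3) × percent-positive points
  (PP, 1–3) → immunoreactive score (IRS, 0–9) with the IRS > 1 positivity
  cut for SATB1; a four-tier percent-positive score with the ≥10 % cut for
  p16.
* **Kaplan–Meier estimation** of overall survival (OS) and
  progression-free survival (PFS) with right censoring (via lifelines).
* **Decay-to-plateau model** — S(t) = P + (S₀ − P)·e^(−kt), where P is the
  survival plateau (cure fraction), k the event rate constant among
  non-cured patients, and ln 2 / k the half-life; fitted by bounded least
  squares to the KM curve or by censored-data maximum likelihood to the
  records.
* **Model selection** — a null model (one curve for everyone) against a
  stratified model (one curve per marker-defined group), reported as
  ΔAIC = AIC_null − AIC_stratified, the evidence ratio ER = exp(|ΔAIC|/2)
  with its direction, and the extra-sum-of-squares F test; includes
  small-group merging (e.g. SATB1+/p16+ and SATB1−/p16+ collapse into a
  single p16+ group) and a shared-dynamics test for any two subgroups.
* **Synthetic cohorts** — a generator that inverts the plateau model
  (cure indicator ~ Bernoulli(P), exponential event times, uniform-accrual
  censoring), produces raw IHC readings consistent with every marker call,
  and plants gene-set signatures into expression matrices.
* **Enrichment** — single-sample GSEA (rank-weighted ECDF-difference walk)
  plus reduced major axis (RMA) regression of signature scores against a
  transcript: slope = sign(r)·sd(y)/sd(x).

See `docs/methods.md` for the statistical details and design decisions.

## Worked example

Simulate a study-sized cohort (86 patients, joint SATB1/p16 split
12/8/4/62, cure-fraction survival per combined marker group, censoring over
a 1–197 month window) and compare the null and stratified models for OS:

```bash
hlstrat simulate --seed 7 --out demo
hlstrat compare --cohort demo/cohort.csv --endpoint OS --markers satb1,p16 --min-group-size 10
```

which prints (after the JSON payload):

```
SATB1+/p16-: half-life 4.9 ± 4.0 mo, plateau 80.3 ± 12.9%
SATB1-/p16-: half-life 108.6 ± 81.8 mo, plateau 30.4 ± 34.1%
p16+: half-life 1.6 ± 0.8 mo, plateau 65.5 ± 14.1%
dAIC = 15.61, ER > 100, F = 205.9, p = 3.142e-42
```

Reading this: the two small p16+ cells were merged into one group of 12;
each group's fitted cure model is shown as half-life ± SE and plateau ± SE.
The positive ΔAIC (from the censored-data likelihood) says the stratified
model is far more plausible than a single shared curve — an evidence ratio
above 100.  The generating truth behind this cohort had plateaus
0.907 / 0.75 / 0.60; the SATB1−/p16− plateau is recovered with a very wide
standard error because its half-life (84 months) is long relative to the
follow-up window, so its plateau is extrapolated rather than observed —
the same caveat applies to real cohorts of this shape.  The F test and its
p-value are descriptive diagnostics computed from the least-squares
staircase fits (see the methods note for why they are anti-conservative).

The full pipeline (scoring → KM → single-marker and combined comparisons →
plateau-vs-no-plateau tests → figures) runs as:

```bash
hlstrat run --simulate paper_like --seed 7 --out report_dir
```

and writes `results.json`, CSV tables, SVG figures and a log, all
reproducible byte-for-byte from the seed.

Library use mirrors the CLI:

```python
from hlstrat import (paper_like_spec, simulate_cohort, assign_groups,
                     compare_stratification, km_estimate, fit_plateau)

cohort = simulate_cohort(paper_like_spec(), seed=7)
grouping = assign_groups(cohort.records, ["satb1", "p16"], min_group_size=10)
cmp = compare_stratification(cohort.records, "OS", grouping)
print(cmp.delta_aic, cmp.evidence_ratio.render())
```

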