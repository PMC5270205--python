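# Methods

## The rule

The LDL window is a hard two-axis partition of a fasting lipid panel.
One axis estimates LDL particle number: apoB, one molecule per
VLDL/IDL/LDL particle, with ≥ 90 % of plasma apoB riding on LDL; or
non-HDL-C as its widely available surrogate. The other axis estimates
LDL particle size inversely through triglycerides, the strongest
conventional correlate of LDL diameter. Cutoffs are inclusive on the
elevated side:

| group         | particle axis        | TG axis      |
|---------------|----------------------|--------------|
| normal        | apoB < 110 mg/dL     | TG < 150     |
| hyper-TG      | apoB < 110           | TG ≥ 150     |
| hyper-apoB    | apoB ≥ 110           | TG < 150     |
| hyper-TG/-apoB| apoB ≥ 110           | TG ≥ 150     |

The alternative window is the same classifier consulting non-HDL-C at
170 mg/dL — one rule, two markers, selected by `WindowConfig.mode`.
The apoB cutoff itself is derived, not assumed: OLS of non-HDL-C on
apoB in the reference healthy population
(non-HDL-C = 1.404·apoB + 9.48, R² = 0.94), inverted at the consensus
high non-HDL-C threshold of 170 mg/dL (→ apoB ≈ 114 mg/dL; the
original analysis quoted 113) and floored to a multiple of 10. Both
the inverted value and the floor are exposed; they agree on 110.

The rule is defined on fasting TG. Fasting state is not modelled or
enforced; users applying it to non-fasting panels are on their own.

## Derived measures and validation

Derivations are exact subtractions/ratios carried at full precision:
non-HDL-C = total-C − HDL-C, lbLDL-C = LDL-C − sdLDL-C,
sdLDL-C/LDL-C in percent, LDL-C/apoB, pattern B as LDL size < 25.5 nm
(strict: 25.5 nm itself is pattern A), HbA1c NGSP = 1.02 × JDS + 0.25.
Rounding to one decimal happens only at report rendering, half-up to
match the publication style.

Validation is total and rejecting: positive concentrations,
HDL-C < total-C, sdLDL-C ≤ LDL-C, LDL-C ≤ non-HDL-C, LDL size inside a
[23, 29] nm plausibility band. A violating panel raises a structured
error naming the field, the rule and the offending subject ids —
inconsistent assay values must surface, not be clamped. Missing
optional fields (LDL size, HbA1c) yield absent derived values, never
errors; window classification does not need size.

Published per-group ratio rows (sdLDL-C/LDL-C, LDL-C/apoB) are means of
per-subject ratios here; the source tables do not say whether they were
that or ratios of means (for quartile 1, 13.9 vs 13.3), so no equality
between the two conventions is asserted anywhere.

## Quartile scheme

Quartile boundaries are the 25th/50th/75th percentiles of a *reference*
cohort's sdLDL-C under linear interpolation between order statistics
(the numpy default; no alternative convention is offered). Assignment
is half-open upward: Q1 v < q25 … Q4 v ≥ q75. The published boundaries
were printed at 0.1 mg/dL resolution with gaps (Q2 ends 21.9, Q3 starts
22.0; Q4 is "> 31.7"), so the shipped reference scheme places effective
boundaries at the half-resolution points (15.4, 21.95, 31.75), making
every printed edge case land exactly as the source tables bracket it.
Reference boundaries are always derived from the healthy standard and
applied unchanged to patient cohorts, so "Q4" means the same thing in
every table.

## Statistics

One-way ANOVA is computed from explicit between/within sums of squares
(cross-checked against `scipy.stats.f_oneway` in the tests). The
"Bonferroni–Dunn" post-hoc is implemented as pooled-within-variance
pairwise t tests on the full within degrees of freedom, p multiplied by
the number of pairs and capped at 1 — the standard reading of Dunn's
procedure. Software using Tukey HSD or per-pair variances will differ;
raw p values are retained next to the adjusted ones. OLS and Pearson
correlations come from scipy. The size-surrogate comparison correlates
raw TG by default; a `log_tg` flag is available because the original
r = −0.52 could have been computed either way (undocumented in the
source).

## The synthetic-cohort generator

Subject-level data for the three study cohorts were never deposited.
The generator therefore emulates their *published summary structure*,
making every pipeline stage testable offline:

1. five standard-normal latents (apoB, log TG, HDL-C, LDL-C/apoB
   ratio, LDL size) drawn from a latent correlation matrix (checked
   positive definite at model construction);
2. TG is log-normal, moment-matched to the published mean/SD — the
   printed SD ≈ 0.7 × mean implies strong right skew, and the
   log-normal with matched moments lands the healthy sdLDL-C quartile
   boundaries within a few percent of the published 15.4/22.0/31.7;
3. non-HDL-C = 1.404·apoB + intercept + ε with Var(ε) set so the
   population R² equals the configured value (published 0.94 for the
   healthy preset; patient presets moment-match their published
   non-HDL-C mean/SD under the same slope);
4. total-C = non-HDL-C + HDL-C, so the accounting hierarchy holds by
   construction;
5. LDL-C = apoB × ratio; rows where LDL-C would exceed non-HDL-C
   redraw the ratio latent from its conditional distribution truncated
   to the feasible interval (exact inverse-CDF sampling — plain
   accept-reject stalls on rows with near-zero acceptance mass);
   infeasible rows fall through to a bounded full-row redraw;
6. sdLDL-C = LDL-C × logistic(b0 + b_apob·z_apob + b_tg·z_logtg +
   noise), guaranteeing 0 < sdLDL-C < LDL-C.

The latent TG–size correlation is back-computed from the target *raw*
Pearson r(TG, size) = −0.52 via corr(e^{σZ}, Y) = ρσ/√(e^{σ²}−1).
Cross-correlations not identified by any published number
(apoB–logTG 0.30, HDL–logTG −0.40, and the smaller entries in
`CohortModel`) are realism defaults, **not** study-derived; they are
ordinary model fields for sensitivity analysis. Two preset constants
compensate the LDL-C ≤ non-HDL-C truncation, which trims the upper
ratio tail: a small solved shift on the configured ratio mean
(+0.016 … +0.025) and a latent ratio–size correlation of 0.48 so the
realised correlation lands near the published +0.44.

### Calibration

The sdLDL coupling has no published counterpart, so it is calibrated:
`calibrate_intercept` bisects b0 against the cohort's published mean
sdLDL-C (common random numbers, n = 50k default), and
`calibrate_sdldl_coupling` scans slope candidates — recalibrating b0 at
each — until the simulated hyper-TG/-apoB group reaches a target Q4
share (default ≥ 0.85). The shipped presets are frozen outputs of this
procedure at n = 150k, chosen to satisfy simultaneously: every
published cohort mean within 2 % and SD within 10 %, the fraction
row's mean/SD, Q4 enrichment with margin, and the published ordering of
group mean sdLDL-C (normal < hyper-TG < hyper-apoB < hyper-TG/-apoB).
Demographics (sex, age, diabetes flags, HbA1c for the diabetes preset)
follow the published proportions but do not feed the lipid model.

### What the generator does not emulate

Real lipid panels have heavier tails than a Gaussian copula (extreme
hypertriglyceridemia, familial hyperlipidemias), assay noise and
digit-preference rounding, treatment effects, and postprandial
dynamics — none are modelled. The simulated window-group shares
therefore drift from the published ones (e.g. healthy hyper-TG ≈ 10 %
simulated vs 6.0 % published: the moment-matched log-normal puts
slightly more mass above 150 mg/dL than the real TG distribution did).
Passing recovery tests shows the pipeline is correct *given* the
published summary structure, not that the generator reproduces the
original subjects; the printed-count reconstructions are the anchors
that do not depend on the generator at all.

## Numerical conventions

* percentiles: linear interpolation between closest order statistics;
* report rounding: decimal half-up at 1 dp, applied only at render;
* boundary conventions: "≥" on every hyper side of the window, strict
  "<" for pattern B, half-open-upward quartiles;
* determinism: every stochastic routine takes a single integer seed;
  identical (model, n, seed) reproduce byte-identical cohorts;
* degenerate inputs: zero SDs are legal (noise-free limits are used in
  consistency tests); constant collections are rejected where a
  quantity is undefined (quartiles of a constant, regression on
  constant x, zero-slope inversion).

## Problem sizes

Recovery tests and the acceptance script use n = 100 000 synthetic
subjects (sampling error ≪ the 2 % mean tolerance: SE of the sdLDL-C
mean ≈ 0.04 mg/dL); the analysis drivers use the study-sized cohorts
(1665/201/528), where a few percent of scatter is expected and visible.
The ANOVA null-calibration check uses 1000 simulated four-group
datasets.

## Known limitations

* Reported group tables cannot be reproduced subject-for-subject —
  only the printed counts and summary statistics constrain them; at
  exact cutoff boundaries the original tally convention is asserted
  from the stated "≥" wording, not from data.
* The printed healthy non-HDL-C mean (133.4) disagrees by 0.1 with the
  printed subtraction 195.5 − 62.0 (inputs rounded before printing);
  the reconstruction reports what the arithmetic gives.
* The inverted cutoff (114.3) differs from the originally quoted 113;
  possibly a reverse regression or different rounding. Both values are
  exposed and floor to the same 110 mg/dL.
* No Friedewald LDL-C estimation, no mmol/L conversion, no risk score:
  the window is, deliberately, a hard partition of measured values.
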