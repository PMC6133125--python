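# Methods

## Setting

In an olfactometric stack-emission proficiency test an organizer doses a
known mass concentration c_ik [µg/m³] of an odorant k into a simulated
stack, and each participating laboratory i samples the gas and measures
its odor concentration x_ik [ou_E/m³] by dynamic olfactometry with a
human panel (EN 13725). Because panels, olfactometers and sampling all
contribute multiplicative error, every statistic in this package is
computed on the log10 scale; linear concentrations are derived on output
only. All concentrations refer to olfactometric normal conditions
(1013.25 mbar, 293.15 K) and are never converted.

The odor threshold c0_k — the mass concentration corresponding to
1 ou_E/m³ — links the two concentration scales: a measurement's implied
threshold estimate is log10(c_ik / x_ik), and the assigned (reference)
odor concentration of a dosing is X_ik = c_ik / c0_k.

## Robust consensus thresholds

Per component, the consensus threshold is the robust mean of all implied
log10 thresholds, pooled over every test in which the component was
dosed, using the ISO 13528 iterative winsorization (Algorithm A):

* initialize m\* = median, s\* = 1.483 × median |v − m\*|;
* iterate: clamp values to m\* ± 1.5 s\*; m\* ← mean, s\* ← 1.134 × SD
  (sample SD, n − 1) of the clamped values;
* stop when both m\* and s\* change by < 1e−4 in relative terms, or
  after 100 iterations.

The 1e−4 relative tolerance tightens the usual "third significant
figure" stopping rule so results are bit-reproducible in tests. If the
initial MAD is zero while values differ (more than half the sample tied
at the median), iteration starts from the classical SD instead; a fully
degenerate sample returns (median, 0) without iterating. At least three
values are required.

The standard uncertainty of the consensus is u = 1.25 · s\*/√n. Two
choices of n are implemented: the number of pooled individual
measurements (default — matching the convention of treating each single
result as one proficiency result, n = 456 over a whole default
campaign), and the number of participating laboratories. When
between-lab bias dominates the spread, replicates within a lab are not
independent results and the lab count is the statistically valid
effective sample size; the package therefore uses the participant basis
wherever a calibrated (nominal 95 %) coverage statement is needed, such
as the Monte-Carlo coverage checks in the test suite. The k = 2
interval [10^(m\*−2u), 10^(m\*+2u)] is geometrically symmetric; since
the linear-scale interval is skewed upward, the relative standard
uncertainty is taken from the upper limit, u(c0) = (c0_high/c0 − 1)/2.
An alternative log-scale convention, u(c0) = 10^u − 1, is available
behind a flag in the scoring layer; the two differ only in how a log
half-width is expressed as a percentage.

## Scoring

z_ik = (1/σ_k) · log10(x_ik / X_ik). Assigned values use the fixed
EN 13725 threshold c0 = 123 µg/m³ for n-butanol — even where a consensus
estimate differs — and the consensus c0 for all other components; this
is configurable per component. A fixed conventional threshold carries no
uncertainty, so only the dosing uncertainty u(c_k) (default 1.01 %
relative) enters the assigned-value uncertainty
u_k = √(u(c_k)² + u(c0,k)²).

The criterion for proficiency assessment is σ_k = 0.10 log10 units
unless the ISO 13528 fitness-for-purpose condition
σ_k ≥ (1/0.3)·log10(1 + u_k) fails, in which case σ_k is raised to that
bound ("adapted"). σ_k is never rounded internally; display rounding to
two decimals happens only in reports. A component verdict is the mean
of the |z| over the (three) replicates, passing on mean |z| < 3 —
strictly: a mean of exactly 3 fails. With σ_k = 0.10 the |z| < 3 band
corresponds to recoveries strictly inside 10^(±0.3) = 50.1–199.5 %,
commonly glossed as "50–200 %". Overall pass requires every component
to pass.

Cross-component predictivity (does performance on the n-butanol
reference predict performance on other odorants?) is quantified as the
Pearson correlation of per-participant mean |z| scores, paired within
tests; at least three complete pairs are required.

## Recoveries and variance components

Recovery = x_ik / X_ik per measurement. Grouped summaries report the
mean assigned and measured concentrations, the relative SD
100 × SD/mean of the measured values (sample SD), and quartiles of the
log10 recoveries using the linear-interpolation (type-7) quantile
definition — a deliberate, documented choice since several definitions
are in circulation. The within-margin fraction is the share of
recoveries in [0.5, 2.0].

The reproducibility analysis is a one-way ANOVA of the log10 implied
thresholds with laboratory = (test, participant) as the grouping
factor, pooled across all tests per component (the implied threshold is
threshold-convention-free, so no c0 enters):

* s_w² = pooled within-lab mean square (repeatability including
  sampling);
* s_L² = max(0, (MS_between − s_w²)/n̄) with the unbalanced-design
  correction n̄ = (N − Σn_i²/N)/(p − 1); negative estimates truncate to
  zero (standard ISO 5725-2 convention);
* s_R² = s_w² + s_L².

Laboratories contributing a single replicate are excluded (no
within-lab information); at least two laboratories with two replicates
are required. Derived quantities: expanded uncertainty U₀.₉₅ = 2·s_R on
the log10 scale, 10 × that in dB odor level, the percent interval
100·10^(∓2 s_R) (bounds are exact reciprocals, low·high = 10⁴ %²), and
the k = 2 reproducibility factor 10^(2√2·s_R) bounding the ratio of two
independent single measurements (the difference of two iid log10
results has SD √2·s_R; k = 2 covers ≈ 95.45 %). The EN 13725
repeatability cap s_r ≤ 0.1721 log10 units corresponds to a 0.3442
(3.44 dB) expanded limit, a ≈ 45–220 % band and a factor-3 bound —
the yardstick observed reproducibilities are compared against.

Report rounding: dB to two decimals, percent bounds to the nearest
integer, EN-limit band quoted at two significant figures (the
convention under which 10^0.3442 = 2.209 prints as 220 %). Published
tables of this kind occasionally truncate upper bounds instead;
comparisons in the tests therefore allow ±1 on the two cells where the
conventions disagree.

## Synthetic campaigns

The generator emulates the data-generating process the analysis
assumes, on the measurement level:

* per (test, participant), a lab bias b_p = z_p · s_L(k) with one
  standard-normal z_p shared across the components of a test — the
  simplest structure consistent with per-participant clustering of
  recoveries; an option redraws z per component instead (the dosing and
  noise streams are unchanged between the two modes);
* per measurement, dosing drift c_ik = nominal × (1 + d) with d uniform
  in ±2 % (dosing is instrument-controlled and bounded, hence uniform
  rather than normal), and log10 x_ik = log10(c_ik/c0_k) + b_p + e_ik
  with e_ik normal with SD s_w(k); replicates are independent beyond
  s_w.

Randomness derives from one root seed with a child stream per
(test, participant), so extending a configuration never changes
earlier draws. The default campaign has six tests with 9/7/5/4/6/7
participants (38 in total), four components each with three replicates
(456 single results); n-butanol is dosed in all six tests, THT in all
six, ETX and PIG in four, AAC and RLI in two. Default noise magnitudes
are s_w ≈ 0.06–0.09 and s_L ≈ 0.20–0.35 log10 units per component, and
default dosing levels put assigned values in the few-hundred to
few-thousand ou_E/m³ range, matching the magnitudes reported for such
campaigns. The generator truth for the n-butanol threshold is
106.1 µg/m³ — deliberately different from the 123 µg/m³ used for
scoring, reproducing the tension between a conventional and an
empirical threshold.

What the generator does **not** emulate: individual panelists, dilution
series and YES/NO response curves; heavy-tailed or skewed lab effects;
drifts over campaign years; correlations between components beyond the
shared lab bias. Consequences: passing tests demonstrate that the
estimators recover the parameters of this lognormal two-variance-
component world, not that real panels behave this way. In particular,
cohort pass rates and within-margin fractions under Gaussian bias are
noticeably higher than real campaigns report — real recovery
distributions have heavier tails than a normal law with the same s_L.

## Verification strategy and problem sizes

The statistical machinery is verified against independent oracles: a
literal step-by-step transcription of the winsorization iteration, and
a two-loop brute-force ANOVA, exercised over an enumerated grid of
small designs (2–5 labs × 2–4 replicates, plus unbalanced cases) at
1e−10. Monte-Carlo checks use 200 seeded runs: parameter recovery with
40 labs × 3 replicates (s_w = 0.07, s_L = 0.20) within three MC
standard errors, and ≥ 90 % empirical coverage of the k = 2 consensus
interval (participant basis) at nominal 95 %. These sizes keep the full
suite and the acceptance script in the seconds-to-a-minute range on a
single CPU while leaving the MC error well below the tested margins.

## Known limitations

* Algorithm A's uncertainty formula assumes independent results;
  the measurement-basis u is reported but is anti-conservative under
  strong lab clustering (see above).
* The ANOVA treats each (test, participant) pair as a distinct
  laboratory; the same physical laboratory appearing in several tests
  is not tracked (participants are anonymized per test), so s_L
  absorbs any lab-by-test interaction.
* No mixed-effects or kernel threshold estimation; no conversion to
  triangle-bag-method scales; no plotting — the package emits the
  tables figures would be drawn from.
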