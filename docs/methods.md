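# Methods

## Scope and data model

The package analyses three kinds of measurements from an SCFA screening
campaign: colony-size time courses on solid media (arbitrary pixel-intensity
units from plate scans; image acquisition and segmentation are upstream and
out of scope), Nile-red lipid plate readings (background fluorescence,
stained fluorescence, OD595), and shake-flask fermentation time courses
(per-acid g/L and OD600). All tabular interfaces are plain pandas
DataFrames / delimited text with fixed column names; plate coordinates are
row letters and 1-based column numbers.

## Growth phenotyping

Each colony series (strictly increasing times, ≥ 3 points) is smoothed with
a centered rolling median before any derived quantity. The baseline s0 is
the median of the first three smoothed points; *fitness* is the smoothed
endpoint (an endpoint-size definition, not the maximum). The slope profile
is the least-squares slope of every sliding window spanning
`slope_window_h` hours; *t_max* starts from the earliest maximizing window
center and is refined by fitting a quadratic to the slope profile within
`refine_h` hours of that peak and taking the vertex (clipped to the fitted
span; skipped if the fit is not concave). *lag* is the first time the
smoothed signal exceeds s0 + f · (s_max − s0), f = 0.05 by default. A well
is called a grower iff fitness ≥ θ_rel · s0 and fitness ≥ θ_abs
(θ_rel = 1.5, θ_abs = 0 by default; the thresholds are config, since
endpoint-only screens may want an absolute floor instead).

Defaults and why: with 15-min sampling, a 5-point median and a 2 h slope
window leave the slope profile so noisy that the argmax wanders hours
across the broad slope maximum of a logistic-like curve (multiplicative
noise at CV 0.05 is ~50–100 a.u. near the inflection, while the slope
profile drops only ~1 a.u./h within ±2 h of its peak). The shipped defaults
— 9-point median smoothing, 4 h slope window, quadratic-vertex refinement
over ±8 h — recover the planted inflection time with a median error of
~0.3 h at CV 0.05 and ≤ 0.03 h noiselessly, while leaving noiseless lag
and fitness estimates unchanged. The raw window-center estimate is
available with `refine_h=None`, and the sliding-window slopes themselves
are oracle-tested against per-window polynomial fits.

For non-growers, lag and t_max are reported as NaN — they are undefined
for a flat signal and are never fabricated. Replicate aggregation uses
medians; lag/t_max medians are taken over growing replicates only, with
both the total and growing replicate counts recorded. Intersection counts
("grew on ≥ 1 medium", "on all media", and every exclusive combination)
are computed from a complete strain × medium boolean table; percentages
are reported against the full panel with configurable rounding, matching
table-style reporting.

Scaling invariance: multiplying a series by c > 0 scales fitness and
max-slope by c and leaves lag, t_max and the growth call (with θ_abs
scaled) unchanged; this is property-tested.

## Normalization and statistics

* Relative fitness = 100 · fitness_SCFA / fitness_glucose (%); a missing or
  non-positive glucose fitness yields an explicit NaN, never an exception.
* Fold change = value / reference − 1.
* RFU = max(0, F_stained − F_background) / OD595; negative
  background-corrected fluorescence is clamped to zero (a small-signal
  measurement artifact), OD595 ≤ 0 is an error.
* MaxAbs scaling divides each variable by its maximum absolute value
  (sklearn's MaxAbsScaler); all-zero variables are left as zeros with a
  warning. The transform is idempotent and scale-invariant.
* The gate runs Shapiro–Wilk per group (skipped with a recorded reason for
  n < 3 or constant samples) and Levene across groups at α = 0.05; any
  rejection flags the nonparametric path, which is how screening data are
  then treated.
* Mann–Whitney U is two-sided, reporting U for the first group. The exact
  permutation null is used when n1·n2 ≤ 400 and the pooled sample is
  tie-free; otherwise the normal approximation with tie and continuity
  corrections. Identical groups contain ties by construction and therefore
  take the corrected-approximation path, which returns p = 1 exactly.
* Benjamini–Hochberg adjustment is the standard step-up (statsmodels),
  oracle-tested against the literal formula; families default to one per
  (variable, medium) across candidate strains and are recorded in the
  output, since the published tables do not state the family.
* Lipid content across groups: one-way ANOVA F and Kruskal–Wallis H; fully
  degenerate (all-equal) input returns F = H = 0, p = 1 rather than raising.
  Two-sided testing and α = 0.05 are used throughout; both are config.

## Weighted ranking

For every variable column (fitness and t_max per SCFA medium, one lipid
column) strains are ranked so the best value gets rank n and the worst
rank 1; fitness and lipid rank descending, t_max ascending. Ties receive
average ranks; a strain missing a variable (it never grew on that medium)
is pinned to the worst rank and counted in `n_missing` — with panels in
which some strains grow on only one or two media, some such rule is
unavoidable. Each growth rank is multiplied by k_growth = 1.2 and the
lipid rank by k_lipid = 1.6, scores are summed, and strains are re-ranked
(n = best) with a deterministic tie-break by strain id, making the result
invariant to input order.

Weight semantics are genuinely ambiguous: with three media there are six
growth columns, so literal multiplication gives lipid
1.6/(6·1.2 + 1.6) ≈ 18% of the total weight, not the stated 60%. Both
interpretations are provided — `literal` (the default, applying the k
multipliers per column) and `grouped` (growth columns jointly 40%, lipid
60%, split evenly within each group) — and neither is asserted to be the
published arithmetic. Selection takes the top-N final ranks (default 11),
best first.

## Fermentation

Media: given total SCFA (g/L) and an A:P:B ratio, carbon mode (default,
matching the stated carbon-basis ratios) solves m_i ∝ ratio_i / c_i with
Σ m_i = total, where c_i is each acid's carbon mass fraction
(2·12.011/60.052, 3·12.011/74.079, 4·12.011/88.106); mass mode sets
m_i ∝ ratio_i directly. Nitrogen dosing returns
(carbon / target_C:N) / 0.212, the nitrogen mass fraction of ammonium
sulphate, counting SCFA carbon only.

Accounting: per-acid consumption = 100 · (initial − final)/initial,
clamped to [0, 100] (overshoot from measurement noise clamps to 0 with a
warning); values below 10% can be rendered "<10" to mirror table
convention and are parsed back as 0 by default (configurable midpoint 5).
The total is the carbon-ratio-weighted mean Σ (ratio_i/Σratio) · pct_i with
half-up integer rounding for reporting — this rule reproduces the
published total cells tested in the suite; occasional ±1–3 discrepancies
in other rows are consistent with pre-rounded per-acid inputs and are not
forced. Y_L/S = (lipid%/100) · biomass / SCFA consumed; an
inverse-consistency helper recovers the biomass implied by a printed
(lipid, consumed, yield) triplet. The mean consumption rate is consumed
mass over elapsed time; the summariser always uses the first and last
samples — when to stop a run is the experimentalist's decision.

## Synthetic data

Colonies follow an offset logistic
s(t) = s0 + (K − s0)/(1 + exp(−r (t − t_mid))) — the simplest model whose
inflection gives an unambiguous true t_max; non-viable strain × medium
wells stay flat at the baseline. True lag is derived from the same closed
form (threshold crossing), keeping truth self-consistent with the
estimator's definition. Noise is multiplicative Gaussian (CV 0.05 default)
plus an additive floor (1 a.u.), truncated at zero; no replicate-variance
estimates were available to calibrate these CVs, so they are explicit,
arbitrary defaults. Acquisition defaults mirror the study conditions:
0.25 h sampling for 96 h, ≥ 3 replicates, 96/384/1536 plate densities, a
glucose control plus three SCFA compositions, and a reference strain on
every plate. One master seed drives everything; per-plate streams are
derived from (seed, plate index), so outputs are byte-identical across
runs and plates are statistically independent.

Lipid readings are stained = background + g · lipid · OD595 · (1 + ε) with
gain g = 10⁴, so recovered RFU is linear in the planted lipid fraction.
Fermentations use sequential piecewise-linear uptake: each acid is consumed
at its rate times `suppression^(number of higher-preference acids still
present)` (suppression 0.15), giving acetic-first depletion and the
characteristic staggered curves; OD600 rises as biomass yield × consumed
substrate / 0.45 g CDW per OD unit. The generator's default measurement
noise is zero so that concentrations decline exactly monotonically;
a multiplicative noise option exists for robustness exercises.

What the generators do **not** emulate: spatial plate effects, pinning
artifacts, pseudohyphal/filamentous growth, pH drift, toxicity-dependent
death kinetics or SCFA inhibition beyond binary viability — so passing
tests demonstrate correctness of the analysis chain under the stated
model, not robustness to those real-data phenomena.

## Pipeline

Stages (simulate, phenotype, lipids, stats, rank, ferment) form a DAG over
files in one output directory; a stage whose inputs are missing raises an
error naming the stage to run first, and each stage writes a JSON
provenance sidecar (stage, config hash excluding the output path, seed,
package version, row counts). Deterministic stages are byte-identical
under identical config and seed. The demo configuration simulates a
24-strain panel; problem sizes in the test suite (20-strain call-accuracy
checks, 200-colony recovery runs, 24-strain × 20-seed end-to-end
selection) were chosen as the smallest panels at which the tested
properties are statistically unambiguous.

## Known limitations

* The logistic generator cannot probe estimator bias under asymmetric
  (e.g. Gompertz-like) growth; the growth model is a configurable hook.
* The exact Mann–Whitney path requires tie-free data; heavily tied small
  samples fall back to the corrected approximation, whose small-sample p
  is approximate.
* Lag is threshold-based and therefore depends on the smoothing and f; it
  is comparable within a screen, not an absolute physiological quantity.
* Carbon-weighted totals assume the printed per-acid percentages are
  unrounded; reproducing every published cell exactly is not guaranteed.
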