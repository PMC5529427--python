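# Methods

`clptel` models a biotelemetry-enhanced cecal ligation and puncture (CLP)
study of murine sepsis: continuously monitored heart rate and core
temperature trigger enrollment of each mouse at its own moment of acute
physiologic deterioration, instead of treating every animal at one fixed
clock time after surgery. The package covers four stages — synthetic
telemetry generation, deterioration detection, capture-window variability
analysis, and a cost-equivalency decision model — plus CSV I/O and a CLI
that chains them.

## Deterioration criterion (detector)

A mouse meets criteria at the first sample time *t* at which **both** hold
simultaneously:

1. HR(t) ≤ (1 − f_HR) · max_{s≤t} HR(s), with f_HR = 0.10;
2. T(t) ≤ M(t) − f_T · (M(t) − 25 °C), where M(t) = max_{s≤t} T(s) and
   f_T = 0.10.

Design choices the criterion's verbal definition leaves open:

- **"Peak value" = running maximum.** The model triages live animals, so
  detection must be causal. A retrospective variant using the whole-trace
  maximum is available (`peak_mode="global"`) for sensitivity analyses;
  on monotone rise–fall traces the two coincide.
- **Conjunction at a single timestamp.** Both criteria must hold at the
  same sample. On the simulator's piecewise-linear traces this makes the
  detection time the *later* of the two channel crossings.
- **No smoothing, no debounce by default.** The first qualifying sample
  wins. An optional trailing moving average (`smooth_window`, in samples)
  suppresses single-sample artifacts at the price of a small delay.
- Samples beyond the 1440-min horizon never count as detections
  (24-h exclusion rule); a trace whose peak temperature never exceeds the
  25 °C floor makes the temperature criterion undefined and raises an
  error rather than silently censoring.

## Synthetic telemetry

No raw per-mouse telemetry was ever deposited, so the simulator *is* the
data source for every downstream stage. Each trace is a deliberately
simple ramp–plateau–decline shape:

- linear rise over the first 120 min from a post-anaesthesia baseline
  (HR at 85% of peak, temperature 1 °C below peak) to the plateau peak —
  HR peak uniform on 650–750 bpm, temperature peak uniform on
  37.0–38.5 °C;
- plateau until a latent deterioration onset;
- linear decline at 2 bpm/min (HR) and 0.04 °C/min (temperature),
  flattening at moribund floors (30 bpm, 23 °C);
- additive Gaussian noise (SD 15 bpm, 0.15 °C), 1-min sampling.

The shape is invented — the study reports no waveform — and chosen
because its threshold crossings have closed forms: with HR peak *P* and
slope *m*, the HR criterion is crossed exactly 0.1·P/m minutes after
onset (35 min at defaults), the temperature criterion 0.1·(T_peak −
25)/m_T minutes after onset (~31 min at defaults), and the detector must
land within one sampling interval of the later of the two. This is the
oracle used throughout the detector tests. Note the *detected* time
therefore trails the latent onset by that crossing delay; with noise the
running peak is additionally inflated by a few SD, stretching the delay
by roughly another 15–20 min.

Latent onsets are log-normal with median exp(μ) = 465 min and log-scale
σ = 0.16, truncated to [240, 1440] min by rejection. σ = 0.16 reproduces
the reported IQR only approximately (model quartiles ≈ 417–517 min vs
422–536 reported); the study states summary quantiles, not a
distributional family, and no single log-normal matches its slightly
right-skewed IQR exactly. Each mouse is independently a non-deteriorator
with probability 0.07 (8.05 expected of 115), simulated as plateau-only —
the physiology of mice that never meet criteria is not described, and
treating them as never declining is the conservative reading. Activity is
a token Poisson channel (bursty before onset, quiet after); it feeds no
analysis.

Determinism: every per-mouse draw comes from a generator keyed on
`(seed, index)`, so a trace is bit-reproducible in isolation and cohorts
are reproducible under any iteration order. `draw_latent` exposes the
latent state (censoring flag, onset, peaks) without trace construction
and consumes the identical stream.

**What the simulator does not emulate:** circadian modulation, ECG
morphology, heteroscedastic or autocorrelated sensor noise, partial
single-criterion decline, device dropout. Tests passing on these traces
demonstrate correctness of the *analysis machinery* under the study's
summary statistics, not fidelity of any physiologic model.

## Reconstructed cohort (`fixture_cohort_table1`)

The published per-hour frequency column (whole percents of 107 analyzable
mice) pins down integer window counts: 2, 13, 26, 30, 11, 5, 4, 2, 3, 3,
1, 1, 1 at hours 5–17 plus 1 and 2 at hours 22–23 — 105 mice. The column
itself sums to 99%, so 2 mice are unplaceable from the printed table;
they are placed in the final half-hour before the 24-h horizon, the only
region not covered by the hourly windows. Within each window
[60h−30, 60h+30) the k times are evenly spaced at lo + i·(width)/(k+1),
i = 1..k — a fixed, documented rule that also keeps the earliest
reconstructed time (290 min) above the reported minimum of 287 min. Eight
further mice are censored (8/115 = 7%). The reconstruction reproduces the
percent column exactly at hours 4–23; its median (475.2 min) is near but
not equal to the reported 465 min, because raw times are not recoverable
from whole-percent rounding — documented, never asserted.

## Capture-window analysis

Windows are half-open, [60h − tol, 60h + tol) with tol = 30 min, making
the hourly windows a partition: every uncensored time is captured by
exactly one hour and paired-window discordant counts reduce to the window
counts themselves. All proportions use the uncensored denominator
(n = 107) and are carried at full precision; reporting rounds half-up to
whole percent (proportions) or 2 decimals (p-values, fold changes). The
cumulative column is recomputed from raw times (fraction with
t < 60h + tol) rather than copied, because the published cumulative
column is not the running sum of its own window column.

Statistics:

- **Exact McNemar** for paired windows: p = min(1, 2·P(X ≤ min(b,c))),
  X ~ Binomial(b+c, ½); b = c = 0 returns 1 by convention. A
  continuity-corrected χ² variant is available. The exact form equals
  brute-force enumeration of all 2^(b+c) discordant-pair splits
  (property-tested to b+c ≤ 16, plus a statsmodels cross-check).
- **Binomial CIs** via statsmodels (Wald default; Wilson and
  Clopper–Pearson selectable). The 8-h lower bound rounds to 20% under
  all three; the upper bound rounds to 37–38%, none reproducing the
  published 36%, so only the lower bound is asserted.
- **2×k Fisher exact test** (k ≤ 4) by complete enumeration of tables
  with fixed margins under the multivariate hypergeometric null
  (Freeman–Halton construction); enumeration beyond a configurable
  budget raises a capability error instead of approximating. Checked
  against scipy (2×2) and R `fisher.test` (2×3, 2×4).
- **Seasonal machinery**: per-season median/IQR, Kruskal–Wallis across
  seasons, per-season capture proportions with the 2×k exact test, and
  Spearman correlation of ambient temperature against time-to-criteria.
  The seasonal raw data are not recoverable from the publication, so
  these operations are validated on synthetic null and shifted cohorts
  (a +120-min shift at n = 30/season is detected in >80% of 500
  replicates), not against printed seasonal values.

Sample-size planning: fold increase = 1/p̂ (2 decimals), required
enrolment = ⌈q/p̂⌉. At p̂ = 0.28 and q = 120 this gives 3.57-fold and
429 mice.

## Cost-equivalency model

Equipment follows a stepped schedule: system ($24,336.50) + four devices
($11,610) up front, one battery set ($2,405) after each full block of 120
monitored experiments, i.e. ⌈Q/120⌉ − 1 battery sets for Q quality mice.
The fixed-time-point arm enrols Q/p mice. Crucially, the *fractional*
Q/p stays in the cost algebra (integer ceilings appear only in reported
animal counts); this reproduces the published $235.27 incremental cost
and $116.49 / $62.14 / $44.03 equivalency costs exactly, which
integer-only algebra does not. p defaults to the published 0.28 rather
than 30/107 (configurable; the pipeline substitutes the measured p̂ of
the analyzed cohort).

The equivalency solver inverts c = setup(Q)/(Q/p − Q) per battery tier:
candidate Q_k = (system + devices + k·battery)/(c·(1/p − 1)) is accepted
when self-consistent with tier k, then rounded to the nearest mouse; the
standard count is round(Q/p). This reproduces the published rows at
c = $50 (Q = 317) and $250 (56 / 200 / 144). The remaining published
rows (c = 25, 37.5, 75, 100, 150, 200) deviate from this — and from every
tier/rounding rule tried — by 1–30 mice, and the published standard count
at $50 (1130 vs model 1132) and $91.54 cost-per-mouse-spared (model
$91.49) are likewise not exactly recoverable; these are computed and
reported but never asserted. Where exact values are unattainable the test
suite instead pins structure: solve↔evaluate round trip (±1 mouse),
setup-cost steps of exactly one battery set at multiples of 120, strict
monotone decrease of the equivalency cost within a tier, and exact
linearity of the incremental-difference curve with slope Q − Q/p.

## Numerical conventions and limitations

- Rounding for reporting is half-up (the convention consistent with the
  published 3.57 and 0.01); computation never rounds internally.
- Window boundaries are half-open left-closed; a time exactly on a
  boundary belongs to the later hour.
- Ties for the best window break to the earliest hour.
- The acceptance script (`scripts/acceptance.py`) recomputes every
  reported quantity at run time: the cost model closed-form, the
  reconstructed-cohort variability numbers, and a 10⁴-draw seeded check
  that the generator's onset median is recovered. Simulation sizes
  (10⁴ latent draws; 2000-replicate censoring expectation in the tests)
  were chosen so Monte-Carlo error is well under the asserted tolerances.
- Known limitations: conclusions about real telemetry transfer only to
  the extent the ramp–plateau–decline caricature does; the seasonal
  analysis is machinery-only; the cost model is deterministic (no labor,
  discounting, or stochastic failure of devices).
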