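# Methods

`sprintnirs` analyzes near-infrared spectroscopy (NIRS) recordings of
muscle (vastus lateralis) and cerebral (prefrontal cortex) oxygenation
collected during repeated-sprint cycling tests to exhaustion: 10-s all-out
sprints alternating with 20-s active recoveries (1:2 work:rest) until task
failure, defined as cadence falling below 70 rpm. This note documents the
models, algorithms and numerical choices, and what the synthetic-data tests
do and do not establish about real recordings.

## Signal model and synthetic sessions

The generator produces sessions with the statistical structure the analysis
assumes, plus ground truth for recovery tests. Its core is a deoxygenation
excursion process for each NIRS site: during sprint *k* the HHb level rises
mono-exponentially from its current value toward (current level + Δₖ) with
time constant τ_deoxy (default 2.5 s); during recovery it decays back
toward the session baseline with τ_reoxy (default 8 s). Because the rise
asymptote is anchored at the level *at sprint onset*, the within-window
max − min of the noiseless trace is exactly

    Δₖ · (1 − exp(−T_sprint / τ_deoxy)),

which is the closed-form oracle used throughout the tests. Residual
deoxygenation carries over between sprints (exp(−20/8) ≈ 8% of the
end-of-sprint level), so the baseline creeps upward across the session, as
real muscle HHb does under incomplete reoxygenation.

Per-sprint asymptotic amplitudes follow

    Δₖ = [amp·scale(condition) + b_subject] · (1 + trend · k/N),

with a per-subject Gaussian intercept b (SD `subject_sd`, default 1.5 µM,
shared across that subject's sessions — the random-effect structure the
mixed model assumes) and a multiplicative within-set trend (default −0.2
per set fraction, i.e. the final sprint's amplitude is 80% of the first).
O2Hb mirrors the HHb excursion with opposite sign, scaled by the channel
amplitude ratio; TSI is a constant tissue baseline (70% muscle, 68%
cerebral) minus the scaled excursion. On top of the clean waveform the
generator adds: white measurement noise (default SD 1 µM, 10% of the
muscle HHb amplitude), a pedal-stroke sinusoid at cadence/60 Hz (85 rpm →
1.417 Hz, default 2 µM) present only during sprint phases, and a slow
linear drift (default 0.2 µM/min).

Defaults encode the study conditions: 11 subjects × 3 hypoxia levels
(FIO2 0.209 / 0.165 / 0.133 for 400 m / 2000 m / 3800 m); sprint counts
drawn from rounded normals with means 30 / 20 / 15 and SD 8, re-drawn
below a floor of 5 (the set-duration grid needs ≥5 sprints; observed
sessions in this protocol span roughly 7–47); sprint power decaying
geometrically from 750 W at 3% per sprint (yielding percent-decrement
scores near 25%, typical for this protocol); SpO2 declining logistically
to condition-dependent floors (94 / 87 / 77%); VO2 and heart rate rising
mono-exponentially toward condition-dependent plateaus; breath-by-breath
VO2 on an irregular (~1 s, ±15% jitter) clock. Native rates differ by
stream: 10 Hz muscle NIRS, 50 Hz cerebral NIRS, 5 Hz SpO2 and heart rate.

What the generator does **not** emulate: motion-artifact spikes, optode
repositioning and adipose-tissue-thickness differences between subjects,
heteroscedastic noise, non-exponential kinetics (e.g. biphasic
reoxygenation), or correlated noise between channels. Passing recovery
tests therefore demonstrate correctness of the algorithms under the stated
model, not robustness to every artifact class seen in field recordings.

## Preprocessing

Fixed order: resample → filter → derive. All NIRS channels are linearly
interpolated onto a uniform 10 Hz grid (no extrapolation beyond the
recorded range), then low-pass filtered with a 4th-order Butterworth
(cutoff 0.2 Hz) applied forward–backward, giving the squared magnitude
response and zero net phase. Edges are reflect-padded with 3·(order+1)
samples so a constant passes bit-exactly; this padding convention is part
of the contract so results reproduce across implementations. TSI is
filtered identically to the concentration channels. The derived channels
are the standard NIRS definitions Hbdiff = O2Hb − HHb and
tHb = O2Hb + HHb, computed after filtering (the filter is linear, so the
order does not matter; a test verifies commutativity). SpO2 is exempt from
resampling and filtering — its only downstream use is the raw-stream
minimum.

One consequence worth knowing: the 0.2 Hz filter attenuates the realized
within-sprint max−min by roughly 10% for τ_deoxy = 2.5 s. This is
systematic and condition-neutral, so condition contrasts are unaffected,
but closed-form oracle comparisons are made against unfiltered channels
(`preprocess.raw_channelset`).

## Sprint detection

Deoxyhemoglobin is the reference signal: each sprint produces a steep HHb
rise. Detection proceeds in stages:

1. **Coarse candidates** — upward crossings of the filtered-HHb first
   derivative through a threshold of 3 × MAD of the derivative (a robust
   scale, insensitive to slow drift), separated by a refractory gap of
   25 s (just under one 30-s work:rest cycle).
2. **Gap filling** — the ergometer enforces a strict cycle period, so an
   inter-onset gap of ~2+ cycles implies a missed low-amplitude sprint;
   candidates are inserted on the cycle grid.
3. **Matched-filter refinement** — the zero-phase filter spreads the HHb
   rise symmetrically around the true onset, biasing raw crossing times
   ~0.4 s early. Each candidate is shifted (±3 s) to maximize correlation
   between the local derivative and the derivative of a canonical
   sprint/recovery cycle passed through the same filter. The template uses
   nominal time constants (2.5 s / 8 s); accuracy degrades gracefully
   under mismatch because the correlation peak is broad.
4. **Score validation** — candidates scoring below 0.25× the session
   median matched-filter score are pruned (spurious lead-in crossings),
   and one extra cycle is probed before the first and after the last onset
   (accepted at ≥0.5× median), catching first/last sprints in
   low-amplitude sessions.

Each segment spans [onset, onset + 10 s]. If fewer than 3 crossings are
found, an optional fallback aligns a protocol-periodic template by
cross-correlation. Cerebral channels reuse the muscle-derived segments:
one session clock, one event set.

Measured recovery (generator truth as oracle): with noise at 10% of the
sprint amplitude, 50/50 sessions yield exact sprint counts and >99% of
onsets fall within ±0.5 s; at the harder 0.6-amplitude condition used in
the power study, 990/990 sessions were exact.

## Per-sprint deltas and performance metrics

For each segment and channel, Δ = max − min over the sprint window
(inclusive endpoints; ties go to the earliest sample; an optional `lag_s`
extends the search window into recovery for channels with delayed
extrema). Deltas are non-negative, translation-invariant and scale
equivariant by construction.

Performance metrics per session: per-sprint mean power (arithmetic mean of
samples in each window); the percent-decrement fatigue index
S_dec = [1 − ΣSᵢ/(S_best·n)]·100 with S_best the best scored sprint; total
work as the trapezoidal integral of power over sprint windows (kJ); task
failure as the first sprint whose cadence drops below 70 rpm; the highest
30-s average of (irregular, breath-by-breath) VO2 via a time-weighted
sliding window anchored at every sample — the discrete anchor scan differs
from continuous optimization by less than sensor resolution; the SpO2
minimum on the raw 5 Hz stream; and a pacing flag checking that sprints
1–2 reached ≥95% of the warm-up best (carried as session metadata).
"Mean power" is the mean of per-sprint means (not the pooled sample mean);
the two differ only through unequal window sample counts.

## Set-duration normalization

Participants complete different numbers of sprints per condition, so
per-sprint deltas are mapped onto 20/40/60/80/100% of the set duration.
The convention: on the 1-based sprint index, grid point k (of 5) targets
position x = k·N/5; integer x takes that sprint's delta, fractional x
interpolates linearly between the flanking sprints. This guarantees the
100% point is exactly the final sprint. Sessions with N < 5 are rejected
rather than extrapolated. The mapping is linear in the delta vector and
reproduces raw deltas exactly whenever N is a multiple of 5.

## Mixed-model inference

The modeling table is one row per subject × condition × grid point ×
channel. For each response channel a linear mixed model is fitted with
categorical fixed effects (condition; set duration as a 5-level factor,
matching the discrete-point contrasts reported for this design; optionally
their interaction) and a per-subject random intercept — no random slopes.
All fits use maximum likelihood; each effect's p-value is a
likelihood-ratio test of the model with the effect against the model
without it, referenced to χ² with df equal to the parameter difference.
Boundary/singular fits are flagged on the result object, never silently
dropped.

Pairwise contrasts are differences of least-squares means (averaging
uniformly over the other factor's levels). Degrees of freedom use the
containment method: n_obs − p_fixed − (n_subjects − 1). Family-wise (Tukey)
adjustment is single-step max-|T|: the contrast statistics are jointly
multivariate t with a rank-deficient correlation matrix (a full pairwise
set has rank L−1), so the family distribution is evaluated by Monte Carlo
through the underlying normal (40 000 draws, fixed internal seed —
adjusted p-values are reproducible bit-for-bit and have MC error ≈ 0.003).
Adjusted p-values are clipped to never fall below the unadjusted ones.

Monte-Carlo calibration through the complete pipeline (11 subjects × 3
conditions per cohort): under a true null (equal amplitudes), the
condition-effect LRT rejects at α = 0.05 at close to the nominal rate and
the null p-values are near-uniform; with a 40% amplitude reduction at the
most hypoxic condition, power exceeds 0.8. The test suite runs this at
500 null / 200 alternative cohorts; `scripts/acceptance.py` recomputes it
at the same sizes (≈5 min on one CPU).

## Numerical and design choices

- Filter edge handling: reflect padding, 3·(order+1) samples (`scipy`
  `filtfilt`, `padtype="even"`); series shorter than the pad are rejected.
- Resampling grids start at the first input timestamp; sub-microsecond
  grid jitter is enforced.
- The ergometer holds the sprint load through the closing sample of a
  sprint window, so inclusive-window power means equal the per-sprint
  closed form; the NIRS excursion is continuous at the boundary.
- Sprint-count draws: rounded normal, re-drawn below the floor (default 5)
  with a warning below 3; a mean below 1 is rejected as ill-posed, and 100
  consecutive failed draws raise.
- Random streams are keyed by (seed, subject, condition-label CRC), so a
  subject's intercept is identical in every condition and any session can
  be regenerated in isolation, bit-identically.
- Tie-breaking for equal extrema: earliest sample (irrelevant to Δ, fixed
  for reproducibility).
- Open choice, resolved: whether the max/min search extends into recovery
  is exposed as `lag_s` (default 0 — sprint phase only) rather than
  guessed; whether interaction terms are included is a flag, with the
  interaction LRT reported when set.

## Known limitations

- The segmentation template assumes the protocol's work:rest period;
  free-form exercise would need the crossing detector alone.
- Containment df is an approximation; with 11 subjects it is close to,
  but not identical to, Satterthwaite or Kenward-Roger values.
- The χ² reference for variance-adjacent LRTs is mildly conservative near
  boundary variance estimates.
- Filtered deltas are attenuated ~10% relative to the underlying
  physiological excursion (condition-neutral; see Preprocessing).
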