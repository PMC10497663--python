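# Methods

`duosync` analyses interpersonal movement coordination in a two-person
musical ensemble (a voice-plus-piano "Lied" duo) from two inputs: score
beat onsets and 3-D motion-capture marker trajectories.  This note
documents the model and procedure, the tunables and their defaults, what
the synthetic generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Pipeline

1. **Tempo.** Beat onsets (score beats at the 1/8-note level) may have
   gaps where the score has a rest or the performer missed a note.
   Interior gaps are filled by linear interpolation between the nearest
   performed onsets; edge gaps are linearly extrapolated from the two
   nearest performed onsets, and all filled beats are flagged so they can
   be audited.  The performance tempo is the mean inter-beat interval
   (IBI); the SD uses the sample (n−1) denominator.  Phrase-level
   durations are `mean IBI × beats-per-bar × bars` for levels of 1/2, 1,
   2, 3 and 4 bars.

2. **Kinematics.** Marker positions (mm, uniformly sampled) are smoothed
   and differentiated in one pass with a Savitzky–Golay filter
   (polynomial order 3, window 25 samples).  Boundary samples are
   evaluated from the same polynomial fitted over the edge window rather
   than truncated, so velocity stays aligned with beat timestamps; the
   derivative is exact for polynomial trajectories up to the filter
   order.  The analysis signal is the scalar speed `√(vx²+vy²+vz²)` of
   each performer's front-head marker — invariant to the performer's
   orientation in the capture volume.  Quantity of motion (QoM) is the
   path length travelled per whole second (mm), summed over the 14
   head/upper-body markers of both performers; the singer's hip markers
   are excluded and rejected if present.  Path length realises
   "displacement per unit time" and is sampling-rate independent; a
   `mean_speed` mode (numerically identical at integer sampling rates) is
   available by configuration.

3. **Cross-wavelet transform.** Each speed series is mean-centered
   (optionally variance-normalized via `standardize`; off by default,
   so absolute power levels depend on movement amplitude) and
   transformed with a complex Morlet wavelet (ω₀ = 6) on a geometric
   period grid with `dj = 1/20` sub-octaves, spanning a piece-specific
   broadband (1–26 s for the slow 12/8 piece, 0.2–6.2 s for the fast 2/8
   piece).  The transform is computed in the frequency domain with
   unit-energy scale normalisation; the series is zero-padded to a power
   of two at least twice its length, which makes the circular FFT
   convolution agree with a direct linear convolution to numerical
   precision at all retained scales.  The cone of influence (period
   bound per timestamp under the e-folding criterion) is stored but, by
   default, not used to mask averages; a flag enables exclusion.  The
   cross-spectrum is `Wxy = Wx · conj(Wy)` with the pianist fixed as the
   first channel.  Coordination power is `|Wxy|` (modulus, not squared;
   squared available by configuration); the phase difference is
   `arg(Wxy) ∈ (−π, π]`.

4. **Band aggregation and leadership.** Each phrase level gets a narrow
   period band `duration × 2^±0.25` (a configurable half-width of 0.25
   octaves), clipped so adjacent bands meet at most at the geometric
   midpoint of neighbouring durations (guaranteeing non-overlap) and
   clipped to the broadband.  Within a band × time selection, power is
   averaged arithmetically; phase is aggregated as the argument of the
   mean unit phasor (circular mean), because an arithmetic mean of
   angles is meaningless near the ±π wrap.  The modulus of that mean
   phasor (resultant length ∈ [0, 1]) is reported as a reliability
   diagnostic.  The band phase is converted to milliseconds using the
   level's duration as the period: `ms = φ/(2π) × duration × 1000`.
   Positive phase ⇒ the pianist's oscillation is earlier in the cycle
   (pianist leads) in the in-phase regime; the quadrant scheme assigns
   pianist-lead on (0, π/2) ∪ (−π, −π/2), singer-lead on [π/2, π] and
   [−π/2, 0) (shared endpoints resolved to the upper interval), 0 to
   "in sync", and calls the motion in-phase for |φ| < π/2, out-of-phase
   otherwise.  The dominant phrase level is the band with maximal mean
   power (ties go to the shorter period and are flagged).  Power peaks
   on the time-averaged power-by-period curve are strict local maxima
   (plateaus indexed at their left edge, power ties ranked toward the
   longer period); the top three per session are classified into the
   session's own bands or "outside".

5. **Statistics.** The model battery mirrors the analysis design:
   `power ~ phrase_level/take` and `phase ~ phrase_level/take` with a
   random intercept per duo (REML); `phase ~ pianist_EPT + singer_EPT`;
   `power ~ EPT_group`; `QoM ~ pianist_EPT + singer_EPT + piece/take`.
   R-style nesting `A/B` expands to `A + A:B`.  Baselines are the
   four-bar level, take 0, and the slow piece.  If the random-intercept
   variance falls below 1e−3 of the residual variance or the mixed fit
   is singular, the model is automatically refit by OLS and flagged.
   Marginal/conditional R² follow the Nakagawa variance decomposition.
   Tukey post-hoc contrasts use the Tukey–Kramer statistic with the
   studentized-range distribution (so identical groups yield an adjusted
   p of exactly 1 rather than a table-clipped value).  The battery of 24
   empathy models uses a Bonferroni-corrected threshold `0.05/24 =
   0.002083`.

## Synthetic data generator

The generator exists so every downstream stage is testable with known
ground truth.  A duo session consists of:

- a beat track whose i-th IBI is `base × (1 + drift · sin(2πi/n))`, with
  a seeded random subset of interior onsets blanked (first and last beats
  always remain: performances start and end with played notes);
- front-head markers whose *speed* is a constant baseline plus planted
  zero-mean sinusoids at phrase-level periods, integrated to positions
  along a fixed axis, with white Gaussian velocity noise on every axis.
  Components are planted in speed rather than as zero-mean sinusoidal
  velocities because the pipeline analyses the Euclidean norm of
  velocity: the norm would rectify a zero-mean oscillation to half its
  period, moving the spectral ground truth away from the planted level.
  The singer's copy of each component is delayed by a signed lag
  (positive lag = pianist earlier = positive cross-wavelet phase);
- remaining markers carrying noise plus a low-amplitude slow drift
  common to all markers;
- a cohort-level planted association: each duo's singer-lead lag is
  `lead_slope × (singer EPT − EPT midrange)`, with EPT scores drawn
  uniformly on the configured range, so the ground-truth lag–EPT
  relation is exactly linear.

Defaults mirror the study design the package targets: 24 duos, EPT range
13–28, 240 Hz capture, pieces of 39 bars at 12 beats/bar with mean IBI
0.38 s (broadband 1–26 s) and 156 bars at 2 beats/bar with mean IBI
0.49 s (broadband 0.2–6.2 s).  The planted dominant level defaults to
two bars with speed amplitude 10 mm/s against 2 mm/s noise (SNR 5), and
`lead_slope` defaults to 0.01 s per EPT unit (±75 ms of singer lead over
the EPT range) — values chosen once as realistic magnitudes for head-sway
coordination in small ensembles.

What the generator does **not** emulate: biomechanically realistic
motion, tempo-following coupling dynamics between the performers,
non-Gaussian or autocorrelated measurement noise, marker occlusion and
gaps, and expressive timing beyond smooth drift.  Passing tests
therefore demonstrate that the pipeline recovers planted spectral
structure, lags and cohort-level effects under white noise — not that
real recordings satisfy those assumptions.

## Numerical choices and degenerate inputs

- Band half-width 0.25 octaves is an invention (only a graphical width
  is available to match); it is configurable, and the non-overlap clip
  guarantees the band invariants for any width.
- Broadband endpoints are configuration constants taken as given rather
  than re-derived from IBI ranges, since no closed-form margin rule
  reproduces them.
- Phase exactly at ±π/2 is labelled out-of-phase and logged; a circular
  mean that lands exactly at −π is folded to +π.
- Readers reject rather than repair: non-monotonic or irregular
  (relative jitter > 1e−6) sampling, beat-index gaps, decreasing onsets,
  overlapping sections, hip markers in a QoM input all raise errors that
  name the offending row/section/component.
- Sub-Nyquist requested periods, series shorter than the SG window, and
  empty time masks are rejected.

## Problem sizes in tests and verification scripts

The test-suite cohorts use scaled-down scores (16–40 bars) at 12–20 Hz
with one marker per performer; these sizes keep every planted period ≥ 3
cycles and the shortest band ≥ 4× oversampled, which is all the recovery
properties require.  The dominant-level/peak-recovery check uses 20 duos
at SNR 5; the leadership-slope check uses 24 duos; the null
false-positive check uses 200 replicate cohorts.  Full-scale defaults
(240 Hz, full-length pieces, 14 markers) run through the same code path
via `duosync run`.

## Known limitations

- Wavelet coherence (smoothed normalised cross-spectrum) and
  simulation-based significance contours are out of scope; power is
  un-normalised, so only relative power comparisons are meaningful.
- Leadership is a band-mean phase summary; it is not a causal or
  Granger-style directionality measure, and rolling within-take
  leadership dynamics beyond section masks are not provided.
- Whether grand means of phase in the target analysis were circular or
  arithmetic is unknown; the circular mean is the package's choice, with
  an arithmetic comparison possible through the stored per-cell phases.
- SD of phase across duos is reported over per-duo means; alternative
  pooling (over timestamps) is not implemented.
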