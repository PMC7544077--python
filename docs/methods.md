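# Methods

## Problem and model

Repetitive clinical movement tasks (foot stomping, forearm
pronation–supination) produce quasi-periodic trajectories whose *rhythm
regularity* carries the clinical signal: disease disrupts cycle-to-cycle
period, amplitude, and continuity (pauses). `rhythmclust` treats each
recording as a 1-D sampled sequence and asks whether an unsupervised
two-way clustering of periodicity fingerprints separates recordings with
low vs high ordinal severity ratings.

The fingerprint is the **averaged short-time autocorrelation**: slide a
window of width *W* frames with shift *s*; within each window remove the
mean and compute the biased sample autocorrelation
`r(k) = Σ_t (x_t−x̄)(x_{t+k}−x̄) / Σ_t (x_t−x̄)²` for lags `0..W−1`;
average each lag across windows. A regular mover concentrates the averaged
ACF in a sharp peak near the movement period; jitter and pauses smear it.
The companion spectral fingerprint averages the magnitude DFT of each
demeaned window over bins `1..⌊W/2⌋`.

## Estimator choices

* **ACF**: biased normalization (divide by the full within-window sum of
  squares), per-window mean removal, `r(0)=1`, full lag range `0..W−1`.
  The biased form is the default of standard statistical environments and
  keeps every fingerprint exactly length *W*; truncating lags at
  `10·log10(W)` would break cross-recording comparability. An unbiased
  variant is easy to add but not exposed: all downstream contracts assume
  the biased scale.
* **FFT**: rectangular window (no taper), demeaned, DC excluded (after
  demeaning it carries no rhythm information), magnitudes unnormalized —
  the 1/W constant cancels inside any fixed-W distance comparison.
  Whether the source analyses demeaned windows before the FFT is not
  knowable from their descriptions; demeaning is standard practice and is
  applied here, so spectra may differ marginally from other
  implementations in the DC-adjacent bins.
* **Degenerate (constant) windows** yield NaN ACF columns rather than
  errors — real recordings contain motionless spans — and are skipped in
  row averaging; a row with no valid window averages to NaN with a
  warning.
* **Trailing samples** that do not fill a window are dropped, never
  padded: padding injects artificial periodicity.
* **Period read-out** (`dominant_period_lag`): the averaged ACF of any
  smooth signal has a lag-0 shoulder that exceeds the period peak — the
  biased estimator further attenuates the peak by the overlap fraction
  `1−p/W` — so a plain argmax lands on lag 2. The standard
  pitch-detection rule is used instead: advance to the first local
  minimum at or beyond lag 2, then take the argmax of the remaining lags.
  On noiseless synthetic fixtures this recovers the true period exactly
  (rotation chain) or within one frame (tapping, whose averaged peak can
  shift by one lag through window-phase averaging).

## Distances and clustering

Five dissimilarities (all defined for unequal lengths), an explicit
Lance–Williams agglomeration, and a k=2 dendrogram cut:

* **DTW**: absolute-difference local cost, steps (i−1,j), (i,j−1),
  (i−1,j−1), unconstrained, unnormalized. Normalization is moot because
  distances only feed a relative clustering. The step pattern is the
  classic symmetric one.
* **Euclidean**: plain L2 cannot compare unequal lengths; the pair is
  truncated to the shorter length (order-preserving, logged). This only
  affects the raw/diff representations — the four averaged fingerprints
  always have equal length. Linear resampling was considered and
  rejected: it silently rescales the time axis, which is the very signal
  of interest.
* **ACF distance**: L2 between whole-vector biased ACFs, lags 1..50
  (capped at the shorter length − 1) — 50 is the common default of the
  time-series dissimilarity literature.
* **AR (Piccolo) distance**: AIC-selected autoregressive fits up to order
  10 (orders beyond 10 are unstable at 57–329-frame lengths; the cap
  shrinks to n/2−1 for very short inputs), zero-padded L2 between
  coefficient vectors.
* **LPC cepstral distance**: cepstra of the fitted all-pole filters by
  the standard recursion, L2 over 25 coefficients. Which of the two
  model-based distances best matches any given legacy analysis labelled
  "ARIMA/ARMA method" is ambiguous; both are provided under explicit
  names.
* **Linkages**: `complete`, and the two Ward variants distinguished as in
  R's `hclust` — `ward_d` applies the Ward update to dissimilarities as
  given; `ward_d2` applies it to squared dissimilarities and reports
  square-root heights. Ties in the minimum break toward the smallest pair
  index, making merges a pure function of the matrix. The cut removes the
  final merge; label 1 goes to the cluster holding the lexicographically
  smallest sequence id.

## Evaluation

Cluster labels are arbitrary, so the AUC of clinical score against
membership is reported raw and oriented (`max(a, 1−a)`); grids summarize
the oriented value. This mirrors automatic direction selection in common
ROC tooling and is mildly optimistic near AUC 0.5 — the synthetic null
experiment quantifies exactly how much (null-cohort oriented AUCs stay
within ~0.5–0.65 at n=40). Ties use the Mann–Whitney ½ convention.
DeLong variance comes from placement values; comparing two
representations means two *different* binary responses over the same
recordings, which the classical paired test does not cover, so the paired
covariance is used only when the two partitions coincide and the
independent-variance form otherwise. The four default representation
pairs are BH-adjusted together at FDR 0.05. Sequences lacking a score are
retained by IO and dropped (with a logged count) at evaluation.

## Accelerometer chain

Per-axis 0–1 normalization → Euclidean magnitude of the three normalized
axes (the "synthetic acceleration"; the norm is the standard magnitude
synthesis) → 0–1 normalization → centered 20-frame sliding-median
subtraction (centered, symmetric boundary shrink, avoiding the phase lag
of a trailing window) → double integration (cumulative sums, unit step,
zero initial conditions; trapezoidal available). The chain detrends
linearly after each integration **by default**: the median centering
leaves a small residual baseline whose double integral grows
quadratically and otherwise dwarfs the oscillation (every analysis window
degenerates into a ramp and the averaged ACF into a structureless decay).
`double_integrate` itself defaults to no detrend so the raw operation
matches its textbook definition; `accel_to_trajectory(..., detrend=False)`
restores the literal chain. Resulting pseudo-trajectories are analyzed
with `WindowSpec(100, 10)`.

## Synthetic generator

`gen_tapping` concatenates one stroke per movement cycle (half-sine by
default — differentiable, so the difference sequence is well-behaved;
sine and sawtooth variants probe shape robustness) with per-cycle
multiplicative period jitter `N(0, σ_p)` and amplitude jitter, motionless
pauses inserted after a cycle with probability `pause_prob`
(`pause_len`=15 frames ≈ half a cycle), and additive Gaussian noise
(fraction of amplitude). `gen_accel3` drives three sinusoids from one
jittered phase track at phase offsets (0, π/2, π) — deliberately not the
symmetric 120° trio, whose normalized sum of squares is constant and
would make the magnitude sequence degenerate — plus per-axis offsets,
gains and noise.

`gen_cohort` draws per-member cycle counts uniformly from [2, 10] so
lengths at the 30-frame default period span roughly 57–330 frames
(matching the spread typical of short clinical task recordings), assigns
scores {0,1} to regular members and {2,3} to irregular ones (multiplying
jitter and pause parameters by `irregular_boost`), and derives member
seeds deterministically from the cohort seed. The pinned "headline"
fixture is 20+20 members, base `σ_p`=0.03, `pause_prob`=0.05, boost 6,
seed 20201008.

What the generator does **not** emulate: tremor superimposed on the
task, amplitude decrement trends within a recording, pose-estimation
dropouts/outliers, sensor drift and gravity components, or rater noise in
the scores (scores are monotone in the generating irregularity by
construction). Passing tests therefore demonstrate that the pipeline
recovers rhythm-irregularity structure it is designed for, not that it
is robust to every artifact of real recordings.

## Problem sizes

Default test and reproduction runs use 40-recording cohorts (the full
90-condition grid on 40 recordings takes a few seconds; DTW dominates and
is numba-compiled), 2000 replicates for the DeLong null calibration at
n=100, and 8-cycle rotation fixtures for period recovery — sizes chosen
to exercise every code path at comfortably interactive cost.

## Known limitations

* Averaging the short-time matrices discards *when* rhythm changes occur;
  two recordings with the same mix of fast/slow spans are
  indistinguishable.
* The oriented AUC inflates chance-level performance at small n (see the
  null experiment); interpret grid maxima across 90 conditions with
  multiplicity in mind — only the four pre-declared pairs are formally
  tested.
* Severely reduced movement amplitude with preserved rhythm is invisible
  to an amplitude-invariant fingerprint by design.
* Hierarchical clustering is O(n³) here; fine for cohorts of hundreds,
  not for continuous monitoring streams.
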