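# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the conventions adopted where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Task and timing conventions

A trial is fixation (jittered uniform 1.9–2.1 s) → encoding (2.0 s) →
delay (jittered uniform 3.9–4.1 s) → action/recall (2.0 s); trials of the
'different' condition append a 2.0 s identity question.  Trials run in
counterbalanced blocks of 10 per condition (ABBA block order, the leading
condition drawn from the seed), 80 trials per condition at full size.
All internal times are float64 seconds from session start; sample indices
are derived with `round(t * rate)` at the point of use and never stored,
which keeps the pipeline grid-agnostic (512 Hz signal, 64 Hz envelope,
40 Hz GC grids).

Epochs span −0.5 to +7.8 s around encoding onset and are assembled by
concatenating per-period segments cut at their own anchors: baseline
(last 0.5 s of fixation), encoding (2.0 s), delay1 and delay2 (1.9 s
each, starting 0.2 s after delay onset so the jittered head is dropped;
any residual jitter tail before recall is discarded), recall (2.0 s).
Per-epoch length is therefore constant regardless of jitter.  Segment
boundaries are real discontinuities; anything computing derivatives
(e.g. the spike detector) works within segments.  Connectivity stages
use their own windows: PLV baseline is the last 1.9 s of fixation and
PLV recall the first 0.5 s of the action phase (before typical response
times); GC uses 1.9 s windows everywhere, trims encoding to its first
1.9 s, and excludes recall as too short for stable spectra.

Durations that are non-integer in samples (1.9 s at 512 Hz = 972.8)
round to the nearest sample; the ±1-sample boundary slack is far below
any analyzed frequency.

## Band power

Per 1 Hz band `[k, k+1)` Hz (k = 2…119; theta aggregates k = 2…6, alpha
k = 8…12 — the inclusive printed endpoints "2–7"/"8–13" make the last bin
ambiguous, so the half-open convention is documented and configurable):
zero-phase 3rd-order Butterworth band-pass, Hilbert magnitude, decimation
to 64 Hz through `scipy.signal.resample_poly` (anti-aliased FIR; plain
"downsampling" without anti-aliasing would alias envelope fluctuations),
division by the band's session mean, ×100.  Whitening makes the session
mean exactly 100 per band and channel, flattening the 1/f decay.

Active-channel detection compares, per post-stimulus time point, the
envelope across trials against each trial's baseline mean with a paired
Wilcoxon signed-rank test (normal approximation; all-zero differences
return p = 1, i.e. no evidence, rather than an error).  Each point's p is
replaced by the maximum within a centred 6-sample window truncated at the
epoch edges (window alignment was unspecified; centred is the symmetric
choice), then Benjamini–Hochberg FDR is applied jointly across time
points and channels (pooling across regions; pooling scope was
unspecified).  Because max-p smoothing only raises p-values and BH is
monotone, the smoothed significant set is a subset of the unsmoothed one.
Note BH controls the false-discovery rate, not FWER: in sessions with
strong true effects a small fraction of null channels can be declared
active by design; the ≤ 5 % (+ smoothing slack, ≤ 7.5 % empirically)
false-positive bound applies under the global null.

## Phase-locking value

Trial spectra: 2 DPSS tapers with time–bandwidth NW = 1.5 ("two tapers"
does not pin the family; a 2-taper DPSS family is the standard reading,
K = 2NW − 1), windows zero-padded to the next whole second so the FFT
grid contains every integer frequency 2–20 Hz exactly.  Tapers are pooled
as additional observations inside the trial mean (coefficient-level
pooling); per-taper PLV averaging is an alternative the API permits.
Coefficients with zero magnitude are excluded with count adjustment.

The permutation null swaps each trial's baseline and task segments with
probability ½ (within-trial pairing preserved, so frequency-dependent
smoothness biases cancel), recomputing ΔPLV 200 times; one draw of 200
swap vectors is shared across frequencies per (pair, period).  Point
threshold: per-frequency 95th percentile of the null.  Cluster statistic:
mass (sum of ΔPLV over a contiguous suprathreshold run), tested against
the permutation distribution of the maximal cluster mass at P < 0.05
(the cluster statistic was unspecified; mass is the common default).
The test is one-sided for PLV increases.  Unequal window lengths
(0.5 s recall vs 1.9 s baseline) are compared as-is; the null inherits
the same asymmetry.

Sig.P.Ratio: pairs significant in any task period are pooled across
patients per region pair; each 1 Hz bin's count is tested one-sided
against the median ratio across bins (the chance level) with an exact
binomial test, BH-corrected across the 19 bins; selected ranges are
maximal runs of significant bins.  Pairs are restricted to
within-hemisphere IPL–VTC and IPL–HIP combinations.

## Spectral Granger causality

Signals (bipolar, artifact-clean trials common to both channels; only
PLV-significant pairs are processed) are decimated to 40 Hz, windows
transformed with two orthonormal sine tapers (the "two Hann tapers"
phrase is ambiguous — two identical Hann tapers add no degrees of
freedom — so the 2-taper orthogonal sine family is used) and zero-padded
to 20 s, giving the 0.05 Hz grid; analysis is limited to 1–20 Hz.

Wilson's spectral-matrix factorization runs on the two-sided extension of
the CSD, initialised with the upper Cholesky factor of the zero-lag
covariance; the plus-operator keeps non-negative lags with the lag-0 term
halved and upper-triangularised (the standard normalisation).
Convergence: relative change of the factor < 1e-8, max 100 iterations;
non-convergence is reported on the result, never silent.  A CSD with a
negative eigenvalue is ridge-regularised by 1e-8 × mean diagonal (logged)
and refused if still indefinite.  The reconstruction residual
`max_f ‖S − HΣH*‖/‖S‖` is stored; on converged analytic inputs it is
below 1e-6.

Directed GC uses the intrinsic-power decomposition
`S̃_xx = S_xx − (Σ_yy − Σ_xy²/Σ_xx)|H_xy|²`; non-positive intrinsic power
is clipped with a warning, and numerically tiny negative GC values
(> −1e-10) are floored at zero.  Pairs are ordered (IPL channel, other
channel), so positive net GC means the other region leads the IPL.

Peak-band selection takes the grand-average net-GC spectrum (all pairs,
periods, conditions), finds its maximum and minimum in 1–20 Hz, accepts
each extremum whose magnitude exceeds a robust noise floor (3 × the
MAD-based sigma of the spectrum — a flat spectrum selects nothing), and
returns extremum ± 1 Hz (half-width configurable).

## Mixed models

`value ~ 1 + C(period)*C(condition) + (1|patient) + (1|patient:unit)`,
treatment coding with the baseline period and the 'same' condition as
references (inferred from the way period main effects are reported).
Fitting delegates to statsmodels MixedLM (REML, lbfgs with powell
fallback); a non-converging nested variance component triggers a flagged
refit without the unit term.  Denominator degrees of freedom use the
residual-df fallback (n − p) — Satterthwaite is not available in
statsmodels; the df method is recorded on the result, and changing it
moves p-values but not estimates.  Bonferroni families: power α = 0.05/6
(three regions × two bands), PLV α = 0.05/3 (one per selected range),
net GC α = 0.05.  Post-hoc contrasts are built from cell-mean design rows
(marginal over conditions for period contrasts), use the fixed-effect
covariance, and are reference-level invariant; p-values are reported raw
and Bonferroni-adjusted within the contrast family.

## Synthetic sessions and ground truth

Each bipolar channel's content is synthesised directly (1/f background
with exponent 1 and 20 µV RMS, 50 Hz line noise at 5 µV with 1/3, 1/5,
1/7 harmonics, oscillators, couplings, 70 ms biphasic spikes at 5–10× the
background scale); contacts are then built as cumulative sums of channel
contents plus a common-mode reference signal, so bipolar derivation
recovers the contents exactly and common-mode rejection is testable.

Band effects multiply an oscillator's Hilbert envelope by `gain` inside
the chosen task periods (0.1 s raised-cosine ramps); the applied gain
time-course is stored in the ground truth, and at high oscillator SNR the
measured whitened-envelope ratio matches `gain` within 5 %.  Undirected
couplings share a narrowband oscillator between regions with a per-trial
von Mises phase offset of concentration κ on the target side, so the
expected PLV is the analytic resultant `I₁(κ)/I₀(κ)` (the drawn offsets
are stored).  Directed couplings add a *causally* band-passed
(2nd-order Butterworth), lagged, scaled copy of the source channel's band
content to the target — lagged linear mixing, so the source's past
genuinely predicts the target — with the phase offset realised as an
extra per-trial time shift δ/(2πf).  A zero-phase filter or Hilbert
rotation here would leak the source's future into the target and flip
the apparent GC direction; this is why the copy path is causal, and why
directed couplings should use κ ≳ 4 so the per-trial shifts stay inside
the copy filter's group delay.  Trial jitters are uniform (the ranges are
stated, the distribution is not); response scoring treats the target
square boundary as inclusive (unstated; documented here).

What a green test does and does not establish: the generator reproduces
the *statistical structure* the analyses target (band-limited power
modulations, phase-consistent coupling, lagged directed influence,
spikes, line noise, 1/f), not biophysics — no volume conduction beyond
the common-mode term, no cross-frequency coupling, no non-stationary
background, no realistic spike morphology variability, and directed
couplings have a deterministic single lag rather than a distributed
transfer kernel.  Detector sensitivities measured on it bound what the
same code does on real data only to the extent real effects resemble the
injected ones.

## Numerical and runtime choices

* EDF is written as 16-bit with one-second records and a symmetric
  digital range, so 0 µV is representable exactly; the true sample count
  is stashed in the header's reserved field to trim final-record padding.
  Round-trips are exact to one quantization step.
* The spike detector z-scores against a MAD-based sigma so the spikes
  themselves do not inflate the scale; zero-variance channels are treated
  as dead, not spiking.  Defaults: 6 SD amplitude, 8 SD first difference
  (within period segments).
* Scaled runs (tests, the acceptance script) restrict envelope
  computation to 2–13 Hz — the only bands any analysis consumes — and use
  20-trial-per-condition, 8-channel sessions; full-size defaults are
  80 trials and the 2–120 Hz envelope range.
* Known limitations: narrowband directed coupling with asymmetric
  in-band noise can bias nonparametric GC toward the cleaner channel
  (a known property of GC, visible in the simulator if a directed copy
  is drawn from a *separate* oscillator rather than the source's own
  band content); Wilson factorization may need > 100 iterations for
  strongly coherent pairs (reported via `converged`); MixedLM provides
  normal/residual-df inference rather than Satterthwaite, so small-sample
  p-values are approximate.
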