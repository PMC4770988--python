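# Methods

## Problem and approach

Classical event-related potential (ERP) analysis averages stimulus-locked
epochs, so it only detects brain responses that are both time- *and*
phase-locked to the stimulus. This package implements a complementary
statistic, the GW6 method: transient changes in *synchronization between EEG
channels* that are time-locked to a stimulus but need not be phase-locked to
it. The motivating application is paired-session ("hyperscanning") designs in
which one participant (the sender) receives 128 one-second audio-visual
stimuli separated by uniform 4–6 s pauses while a sensorily isolated partner
(the receiver) is recorded simultaneously; the question is whether the
receiver's EEG shows any stimulus-locked structure. The package also ships
the classical ERP baseline, the surrogate/Monte Carlo statistical machinery,
and a seeded generator of synthetic paired sessions so the entire chain is
testable without human recordings.

## The GW6 statistic

Given a recording of `NC` channels at rate `fs` (14 channels at 128/s in the
reference design) and a schedule of stimulus onsets:

1. **Filter + normalize.** Each channel is band-passed with a brick-wall DFT
   filter (zero every Fourier bin strictly outside the band, edges inclusive,
   then invert — exactly zero-phase by construction) and z-scored over the
   whole file. Filtering always acts on the full continuous record, never per
   epoch, so epochs carry no filter edge artifacts. Gibbs ringing of the
   sharp spectral edge is accepted; it is stationary and identical for
   experimental and surrogate schedules, so it cancels in the comparison.
2. **Sliding correlation.** For every unordered channel pair
   (`Nt = NC(NC−1)/2 = 91` for 14 channels) a window of `L` samples slides
   one sample at a time; the Pearson correlation of the two windows is
   recorded at the window centre, giving `R(x)` with the length of the
   recording. Pearson correlation is invariant to affine rescaling of either
   channel, which is what makes the statistic sensitive to phase alignment
   rather than amplitude.
3. **Epoch averaging.** `R` traces are cut into epochs (default 1.5 s
   pre-stimulus, 1 s stimulus, 1.5 s post-stimulus = 512 samples; the compact
   1/1/1 s epoch is 384 samples with the stimulus spanning epoch samples
   [128, 256)) and averaged over stimuli: `R'(I, X)` for pair `I` and epoch
   sample `X`.
4. **Baseline and rectification.** Per pair, the mean of `R'` over all
   samples outside the stimulus interval is subtracted and the absolute value
   taken: `Sync(I, X) = |R'(I, X) − baseline(I)|`. `Sync1(X)` is the mean
   over pairs, `Sync2(C, X)` the mean over the `NC − 1` pairs containing
   channel `C`.

Because of the rectification, `Sync1` has a positive noise floor even for
pure noise (the mean absolute value of the averaging noise); all inference is
therefore *relative to surrogate curves with the same floor*, never on the
absolute level.

## Surrogate null and Monte Carlo test

The null model is non-parametric: the identical analysis is re-run on the
same recordings with pseudo-stimulus onsets drawn uniformly from the range in
which a full epoch fits (≥ 20 repetitions per file; a 25-file cohort gives a
pool of ≥ 500 surrogate `Sync1` curves). Overlap between pseudo-epochs is
allowed (a minimum-gap option exists). The group statistic is the signed
**area difference**: the sum over an analysis window of (group-average
experimental `Sync1` − pool-mean surrogate curve), together with its maximum.
The window defaults to [stimulus onset, epoch end] and is always reported —
it is a free parameter of the statistic. The area is reported as the raw
sample-sum (the comparison value) and per-second (`area / fs`).

Significance: each Monte Carlo cycle draws `group_size` surrogate curves
without replacement (25, mirroring a 25-file cohort; with-replacement is a
flag), averages them, and computes the same area against the full-pool mean;
`p = (#null areas > observed) / n_cycles`, reported as `p < 1/n_cycles` when
the count is zero. The estimator is the plain exceedance fraction, matching
the procedure it emulates. Since filtering, normalization and sliding
correlation do not depend on the schedule, surrogate reruns share one
pair-correlation array per recording and only re-epoch it — numerically
identical to a full rerun, an order of magnitude faster.

Two calibration caveats are inherent to the design and visible in the tests:
null groups may contain several surrogates of the same file (within-file
curves are correlated), which widens the null slightly and makes the test
mildly conservative; and bands are tested separately with no multiplicity
correction — a reproduction of the original procedure, not an endorsement.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `band` | 9–10 Hz (receivers), 1–16 Hz (senders), 1–12 Hz (classical ERP) | analysis bands of the reference design; all configurable |
| `window_len` (`L`) | 64 samples (0.5 s) | never stated numerically in the source design; ~5 cycles of the 9–10 Hz band yet short against the 1 s stimulus |
| epoch | 1.5/1/1.5 s | the long analysis epoch; 1/1/1 s gives the canonical 384-sample epoch |
| baseline region | all epoch samples outside [onset, onset + stim) | the parameter-free reading of "pre- and post-stimulus areas" |
| area window | [onset, epoch end] | unrecoverable from the source description; explicit and logged |
| `n_boot_reps` | 20 per file | the stated minimum |
| `mc.n_cycles` | 2000 (500 in the timed suites) | reference value; granularity 1/n_cycles |
| `mc.group_size` | cohort size | null group averaging must match the experimental group |

Window alignment is centred on `x`; positions closer than `L/2` to a record
edge copy the nearest fully defined value so the output keeps the input
length (edges never fall inside analysis epochs given the ≥ 2-minute
lead-in). Whether the original implementation centred or trailed its window
is unknown; the choice is recorded in config so results are comparable either
way. A zero-variance window in either channel yields `R(x) = 0` with a
logged warning rather than an error. Sample indexing is 0-based half-open
everywhere; the 1-based prose convention ("the stimulus arrives with sample
no. 128 of the 384-sample epoch") corresponds to epoch slice [128, 256).

## Synthetic sessions

`gw6.synthetic` generates the stated world of the reference design: 14
channels at 128/s, 128 stimuli of 1 s, uniform 4–6 s pauses, a 2–3 minute
silent lead-in (sessions have a fixed worst-case length so shapes are
seed-independent). The background is per-channel 1/f noise plus an
independent per-channel alpha rhythm (`alpha_hz ± 2` Hz, equal variance to
the 1/f part, channels scaled to 10 µV SD). Channels are mutually
independent by construction, making the null exact; an optional static mixing
matrix exists as a realism knob but is off by default.

* **Sender effect** — a multi-peak Gaussian ERP template (negative peak at
  250 ms, positive at 300 ms, both σ = 40 ms and ±0.5 channel-SD; minor
  +0.2 SD peak 250 ms after stimulus offset) added identically to every
  channel. Amplitudes are measured in units of the *input* recording's
  channel SD, so repeated injection is additive to ~1%.
* **Receiver effect** — one shared narrow-band waveform
  (`band_center ± 0.5` Hz, default 9.5 Hz) added to every channel during
  each stimulus window, gated with 50 ms raised-cosine ramps. The default
  gain 0.094 was fixed by `calibrate_coupling_gain` (bisection on the
  measured within-stimulus 9–10 Hz inter-channel correlation increase,
  averaged over probe sessions) to the target Δr ≈ 0.015 — the upper end of
  the reported 0.5–2% effect range. A single session's measured Δr has
  seed-to-seed SD ≈ 0.006, so the calibration averages several probes.

What a green test does *not* establish: the generator has no volume
conduction, no eye/muscle artifacts, no non-stationarity and no inter-subject
variability; it validates the statistical machinery (type-I error, power at a
stated effect size, latency recovery), not the neurophysiological claims of
any particular dataset.

## Numerical choices

* Sliding correlations use running-sum kernels (numba-jitted when available,
  with an identical vectorised NumPy fallback); accumulator drift is O(n·eps)
  and the two paths agree to 1e-10 in the tests.
* `Sync1`/`Sync2` are exact means of `Sync(I, X)` (asserted to machine
  precision); `|R| ≤ 1` is enforced by a final clip against rounding.
* Degenerate inputs fail fast with named offenders: zero-variance channels in
  `normalize`, out-of-bounds epochs (listing the onsets), non-monotone
  schedules (an error, never a silent sort), group sizes exceeding the pool.
* All randomness flows through `numpy.random.Generator` seeded from explicit
  seeds; paired sessions split sender/receiver/schedule streams from one seed
  via `SeedSequence.spawn`, so every artifact is bit-reproducible.
* EDF files are written with a single data record covering the whole
  recording; 16-bit quantization of each channel's physical range bounds the
  round-trip error at `range/65535`.

## Known limitations

* The brick-wall filter rings at sharp transients; for the narrow 9–10 Hz
  band the impulse response is long, which smears very short events. This is
  intrinsic to the "DFT and inverse" filter definition being reproduced.
* The area statistic depends on the analysis window, which is a reported
  parameter, not an estimated quantity.
* Reproducing the archived human-data numbers requires those recordings; the
  package reproduces the *procedure* and validates it on synthetic cohorts.
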