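# Methods

## Scope and data model

`eegconn` analyses two-group (trained vs baseline) multichannel EEG recorded
during motor-imagery tasks. The unit of analysis is the 2 s epoch: each
one-minute recording is bandpass filtered, reduced to its middle 40 s, and cut
into twenty non-overlapping 1024-sample epochs, each of which becomes one
classification sample carrying its recording's group label. At the reference
geometry — 4 subjects per group, 2 tasks each, 60 s per task, 512 Hz,
19 channels in the 10-20 montage — this yields 160 epochs per group,
320 in total.

Epoch-level cross-validation means epochs from one subject appear in both
training and test folds; accuracies therefore quantify separability of the
group-conditional epoch distributions, not subject-level generalisation.
Leave-one-subject-out validation is a known limitation and deliberately out
of scope (the protocol being reproduced is epoch-level).

## Montage and feature indexing

The canonical channel order is Fp1, Fp2, F3, F4, C3, C4, P3, P4, O1, O2,
F7, F8, T3, T4, T5, T6, Cz, Fz, Pz, with the
midline electrodes last and Cz (position 17) before Fz (18). Features are the
strict upper triangle of the 19×19 correlation matrix flattened row-major,
1-based: feature k of pair (i, j), i<j, is k = Σ_{m<i}(19−m) + (j−i). This
puts F7-T3 at #137, O1-T6 at #123, T6-Fz at #167, T3-Cz at #154 — the indices
used in published selections with this montage; the ordering is the only one
consistent with all of them. The montage is a configurable default, not
hard-wired.

## Preprocessing

* **Filter**: 4th-order Butterworth bandpass 0.5–40 Hz applied forward and
  backward (`sosfiltfilt`). Zero phase is essential: phase distortion would
  desynchronise channels and corrupt interregional correlations. The filter
  family and order are not dictated by the protocol; Butterworth order 4 is
  standard EEG practice. Edge transients of the zero-phase filter (driven by
  the very long 0.5 Hz high-pass impulse response) fall in the discarded
  margins of the middle-segment extraction, which follows immediately.
* **Middle segment**: exactly centred window (t = 10 s … 50 s of a 60 s
  series). "Middle" is assumed centred; nothing downstream is sensitive to a
  shift of a few samples.
* **Epoching**: consecutive non-overlapping windows; a trailing remainder is
  discarded (none exists at the reference geometry, 20480/1024 = 20).
* **Artifact handling**: manual visual rejection is not reproducible, so an
  optional amplitude-threshold rule (drop epochs with any sample beyond
  k·channel-SD, default k = 6, disabled by default) stands in for it. The
  synthetic data contain no artifacts, so the default pipeline leaves it off.

## Wavelet subbands

Each epoch channel is decomposed with a 7-level Daubechies-4 DWT and each
subband is returned as a full-length reconstruction (inverse transform with
all other levels zeroed), keeping subbands time-aligned across channels so
Pearson correlation applies directly. Band naming follows the clinical
convention delta→A7, theta→D7, alpha→D6, beta→D5. At 512 Hz the dyadic ranges
(A7: 0–2, D7: 2–4, D6: 4–8, D5: 8–16 Hz) sit below the nominal clinical edges
(0–4, 4–8, 8–13, 13–20 Hz); the named mapping is applied verbatim for
fidelity to the original computation, and `dyadic_range_hz` exposes the true
ranges for reporting. Correlation is insensitive to this mismatch in the
synthetic tests because linear filtering applied identically to two coupled
channels preserves their correlation wherever the planted signal has power.

**Boundary handling** is periodization, not symmetric extension. On
1024-sample epochs with the 8-tap db4 filter, symmetric extension inflates
deep-level coefficient counts and breaks orthogonality: measured subband
energies then mis-sum the epoch energy by up to ~8%. Periodization keeps the
transform exactly orthogonal (energy partition to machine precision) and
perfectly reconstructing at this dyadic length. Symmetric extension remains
available through the `mode` argument.

## Connectivity features

Per epoch, `pearson_matrix` computes R from the covariance matrix exactly;
zero-variance channels get zero rows/columns (diagonal 1) with a warning.
`vectorize` flattens the strict upper triangle (171 features); signed values
are kept as features so that anti-correlated edges remain informative.
The per-channel baseline "energy" measurement is the epoch mean squared
amplitude — the natural reading of an energy feature vector per lead; this is
an interpretation, as the baseline was never formally defined.
"Overall" correlations are computed on the bandpassed signal itself (the
signal before wavelet decomposition); band correlations on the mapped subband
reconstructions.

## PLS-VIP feature selection

SIMPLS (direct deflation of the cross-product s = XᵀY; de Jong 1993) fits the
latent decomposition X = TPᵀ + E, Y = UQᵀ + F with orthonormal X-scores. For
a single binary response SIMPLS coincides exactly with classical PLS1; the
test suite verifies predictions and rotation vectors against scikit-learn's
NIPALS implementation to 1e−10, and the first weight against its closed form
w₁ ∝ Xᵀy. Component signs are fixed by forcing the largest-magnitude entry of
each weight vector positive, making fits bit-reproducible.

VIP uses the square-root form VIP_j = √(d Σ_k ρ_k² w_jk² / Σ_k ρ_k²) with
unit-norm weight columns, satisfying Σ_j VIP_j² = d; the ranking — the only
quantity consumed downstream — is invariant to the square root and the
factor d, which a property test asserts. Ties break by ascending feature
index. The number of latent components defaults to p = 5 (the planted
contrasts are low-rank and results are insensitive to p in 3–10; p is a
constructor argument).

During accuracy evaluation, VIP ranking and top-k restriction are refit
inside each training fold so no test information leaks into selection; a
`leaky=True` option reproduces the simpler whole-dataset-ranking workflow for
comparison.

## Classification

SVC with polynomial kernel, degree 3, C = 1, coef0 = 1 (a linear kernel is
selectable); kernel hyperparameters were never specified in the protocol and
these are the common defaults. Features are z-scored with training-fold
statistics. Folds are stratified by group, deterministic given the seed, and
shared across measurements so per-measurement accuracies are paired. Mean and
SD are over the 10 folds. k = n falls back to leave-one-out, where
stratification is vacuous.

## Group comparison

For each selected feature: Welch's two-sided t-test (robust to unequal
variances; a pooled-variance option exists — the two are indistinguishable on
the balanced synthetic data), group means of |r| (signed means would cancel
across positively and negatively correlated epochs), a direction label from
the trained-minus-baseline difference ("tie" when exactly equal), and a
retained flag at p < 0.05 per feature, without multiplicity correction, to
match the protocol; a Bonferroni column is reported alongside.

## Synthetic-data generator

The generator emulates the acquisition geometry (19 channels, 512 Hz, 60 s
per task, 4 subjects per group × 2 tasks) and plants pairwise correlations by
source mixing: for a coupling with target r, x = z and y = rz + √(1−r²)w with
z, w independent unit-variance noises band-limited (4th-order zero-phase
Butterworth) to the coupling's band — 0.5–40 Hz for "overall", else the
nominal clinical range. Filtering two channels identically preserves their
correlation, so the planted r survives both the preprocessing bandpass and
the DWT subband projection wherever the signal has in-band power.

Default planted contrasts use magnitudes representative of observed
motor-imagery connectivity differences (|r| 0.2–0.9, group differences
≈ 0.2): F7-T3 0.45 trained / 0.67 baseline, O1-T6 0.54 / 0.37, and a third
contrast of 0.34 / 0.53 placed on the disjoint midline pair Cz-Fz — pairs are
kept disjoint because two couplings sharing a channel dilute each other's
realized correlation (the shared channel's variance grows). The beta-band
demo config plants O1-T6 0.58/0.35, F7-T3 0.50/0.68, Cz-Fz 0.40/0.57.

Channels not named in a coupling carry independent unit-variance pink
background noise; all channels get additive white sensor noise at
`noise_sd` = 0.1 (amplitudes are arbitrary units — Pearson r is
scale-invariant). The pink spectrum is 1/(f + f₀) with a knee f₀ = 5 Hz, the
standard knee'd description of broadband EEG background; a pure 1/f process
band-limited to 0.5–40 Hz is long-memory enough that 2 s epochs would give
null correlation spreads of ≈0.16 SD, blurring the planted structure, whereas
the knee keeps the null median |r| below 0.1 at epoch length 1024. Coupled
channels receive their pink background at sensor-noise scale rather than unit
scale so the planted correlation is realized without analytic compensation
(in-band noise dilutes r by < 1%, far inside the ±0.05 recovery tolerance).

What the generator does *not* emulate: volume conduction and a forward head
model, evoked responses and task timing, eye-blink/EMG artifacts,
non-stationarity, and subject-level variability (all epochs of a group share
one population correlation). Passing tests therefore demonstrate that the
pipeline recovers known correlation structure and calibrates correctly under
null data — not that real trained/untrained groups are separable at any
particular accuracy.

## Determinism and numerics

One integer seed fixes the simulation bit-for-bit (a single PCG64 stream
consumed in a canonical recording order), the fold assignment, and the
label-permutation null. Correlations are clipped to [−1, 1] against rounding;
SIMPLS truncates with a warning when the cross-product deflates to numerical
zero (rank exhaustion) and VIP warns and returns zeros when Y is orthogonal
to X. Reported problem sizes in tests and the acceptance script are the full
study geometry (320 epochs); stochastic checks average over 3–10 simulation
seeds, a Monte-Carlo size chosen to keep the whole suite under a minute of
simulation while leaving comfortable margins on every threshold.
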