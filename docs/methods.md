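# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `cvepauth`. It is the place to look when a default
seems arbitrary: if a value is not derived from the acquisition protocol
itself, its rationale is here.

## The verification problem

A c-VEP authentication system asks a binary question per attempt: *is this
EEG from the claimed person?* Enrollment records one session of the
mild-burdened cognitive task (MBCT): 400 trials in four runs, each trial
flashing a ring and a disk for 1.05 s while four 63-bit m-sequences (one
per screen position) modulate the flicker at 60 Hz. The behavioural
response (where was the ring?) gates every trial: only correctly answered
trials — evidence the participant attended the stimulus — enter the data.
Verification repeats the protocol on another day and scores samples against
the enrolled model.

A *sample* is a quadruple of one left, one right, one top and one bottom
epoch. Epochs are cut 0.14–1.19 s after flicker onset (the 0.14 s accounts
for visual-pathway delay), notch- and band-pass-filtered (50 Hz; 5–86 Hz),
amplitude-screened (±100 µV), baseline-corrected and 4:1 block-averaged to
262 points. SNR is controlled by N, the number of same-class epochs
averaged in a length-N, step-1 sliding window before composition.

## The two back-ends

**c-EEGNet** is a four-branch compact convolutional network. Each branch
processes one position's epoch (C × 262): a temporal convolution (N1 = 32
kernels, length 60), a depthwise spatial convolution (N2 = 2 kernels per
virtual epoch) with ELU, average pooling by N3 = 4, and a depthwise second
temporal convolution (length 16); batch normalization follows every
convolution and dropout (0.5) every pooling stage. The combined block
concatenates the four branch outputs into a 4·N1·N2 = 256-long feature
axis, reduces it with N4 = 64 pointwise kernels plus ELU, pools by N5 = 8,
and classifies the flattened 512-vector with a softmax dense layer.

The network is implemented directly in NumPy — explicit forward pass,
hand-derived backward pass, Adam — so a training run is a pure function of
its seed. The heavy first convolution is evaluated as one BLAS matrix
product over a slice-filled column buffer, and the first batch-norm is
folded analytically into the (linear) channel convolution so the largest
intermediate tensor is never normalized in place. Gradient correctness is
pinned by a finite-difference test over every parameter tensor.

Training defaults (the protocol does not prescribe them): Adam at 1e-3,
batch 64, cross-entropy, a stratified 20 % validation split with early
stopping (patience 10 at the library default; the study drivers use
patience 4 with at most 12 epochs), plus a validation-loss floor of 0.01 —
once the split is essentially solved, further epochs only polish decimals.
The best-validation parameters are restored after stopping.

Two readings exist for how the pointwise convolution treats the four branch
outputs; the default merges the branch and feature axes (compact, shown
above), and `merge_mode="branch"` preserves the feature axis and combines
across branches only, one 4-weight kernel per feature.

**TRCA** (task-related component analysis) is the template-matching
baseline. Per position, the spatial filter w maximizes inter-trial
covariance relative to total variance — the leading generalized eigenvector
of (S, Q) with S the summed cross-trial covariance over all ordered trial
pairs and Q the covariance of the concatenated (per-trial centred) trials;
a singular Q is ridge-regularized with eps = 1e-6 · tr(Q)/C. The template
is the filtered class mean; a sample's score is the mean Pearson
correlation over the four positions, and the accept threshold θ maximizes
F1 on training-packet scores (averaged over 5 stratified folds). The
equivalence of the eigenvector solution with an exhaustive unit-sphere
search is asserted on 2-channel problems.

θ calibrated on training scores is systematically optimistic: the template
is built from the same epochs that the training samples average, so
training genuine scores are correlated with the template's own noise.
Fresh-session genuine scores land visibly lower, which is the mechanistic
reason the baseline loses recall across days while its precision stays
high. This is not a bug of the implementation; it is the known failure mode
of threshold-transfer template matching, and the deep model's main
practical advantage in this setting.

## The synthetic cohort

No public recordings accompany the protocol, so every claim is exercised on
a simulator whose forward model is the standard linear c-VEP superposition:
each lit frame triggers a subject- and position-specific evoked kernel
(sum of three damped oscillations near 7.5/11/16 Hz), delayed by
τ = 0.14 s, projected on a parieto-occipital topography, and added to
1/f background noise (exponent ≈ 1) with an alpha bump, a 50 Hz mains
component, partially common across channels, plus frontal-dominant blink
transients that exercise the ±100 µV rejection.

Identity is carried by two things: the kernel parameters (drawn per subject
around population means — amplitudes ±30 %, component latencies ±6 ms,
frequencies ±3 %, decays ±25 %) and a stable per-channel spatial signature
(lognormal, σ = 0.35). The narrow frequency/latency spread is deliberate:
real impostor VEPs are morphologically similar, and it is this similarity
that makes the correlation-threshold baseline genuinely confusable. The
spatial signature is the drift-robust part of identity, mirroring how real
electrode-level amplitude patterns are trait-like.

Nonstationarity comes in two layers. Within a session, kernel latency and
amplitude wander slowly (sinusoidal over the ~25 min session, inside a
subject-level trait band of 8–13 ms and 12–30 %), so enrollment data spans
variation comparable to what verification will see. Across days, session 2
applies kernel-amplitude (±15 %), latency (±5 ms) and per-channel gain
(±10 %) jitter. An earlier ±10 ms across-day latency default made
verification collapse for both back-ends — across-day shifts larger than
the between-subject latency spread turn a genuine user into a temporal
impostor — and day-to-day ERP latencies are in reality trait-stable, so the
latency component was reduced and the across-day burden shifted toward
amplitude and gain.

Background noise is 10 µV RMS with an alpha bump 2.0 ± 0.2 relative to the
1/f floor (exponent 1.0 ± 0.03). The noise-profile spreads are deliberately
narrow: background spectra in real EEG do carry identity, but with wide
spreads the simulator's subjects were identifiable from the noise alone at
N = 1, flattening the SNR sweep — the identity under study here is the
c-VEP-borne one, which averaging reveals. The operating point puts
single-epoch verification clearly below ceiling and N = 20 verification
near it, the dynamic range the averaging experiment needs. Behavioural
error rates are uniform on [0, 0.05].

What the simulator does **not** model: biophysical volume conduction (the
topography is a weight table, not a head model), non-blink artifacts
(muscle, electrode pops), correlated inter-subject noise structure, and any
nonlinearity or refractoriness in the evoked response (bits superpose
linearly). Passing tests therefore show that the pipeline and models
recover the structure this forward model generates — they do not certify
performance numbers on real EEG.

## Problem sizes in the shipped studies

The full published-protocol packet (1600 + 1600 samples, 17 subjects)
remains the default of `build_training_packet`. The study drivers
(`run_method_comparison`, `run_snr_sweep`, `run_area_comparison`) default
to a scaled study sized for a single CPU core: 8 subjects, 100 trials per
position and session, packets of 128 + 128 samples (auto-balanced across
impostors), test sets of 100 genuine + 100 impostor samples per claimed
identity, and training capped at 12 epochs with patience 4. The shipped
acceptance study further trims the repeated-training experiments: the
N-sweep uses 96 + 96 packets with 6 training epochs, and the area study
8 epochs with patience 3. All sizes are ordinary keyword arguments; the
scaled defaults are a choice of problem size, not of method.

## Numerical choices and conventions

- Epoch window [0.14, 1.19) s, half-open, 0-based: exactly 1050 samples at
  1 kHz, consistent with the 1.05 s flash. 1050/4 leaves remainder 2; the
  trailing samples are discarded (262 points).
- "Exceeded ±100 µV" is read strictly: an epoch peaking exactly at 100 µV
  is kept. Rejection is evaluated on the channel subset in use, so an area
  study sees the chain as if only those channels had been recorded.
- Zero-phase filtering: the band-pass is a linear-phase Hamming FIR
  (~1.1 s, transition ≈ 3 Hz) applied by FFT convolution with its group
  delay compensated; the notch is a Q = 30 IIR applied forward–backward.
  Zero phase preserves the 0.14 s alignment.
- Frame-to-sample mapping uses accumulated-phase rounding
  (edge_i = round(i · fs/60)), so bits span 16 or 17 samples and 63 bits
  span exactly 1050.
- Quadruple sampling is without replacement at the quadruple level only;
  component epochs recur across samples by necessity (1600 > pool size).
- A genuine probability of exactly 0.5 accepts (documented boundary).
- Wilcoxon signed-rank: zeros dropped, average ranks, tie-corrected
  variance, no continuity correction, two-sided normal p; for n ≤ 10 an
  exact enumeration p accompanies the approximation.
- Undefined precision/recall (zero denominator) is reported as 0 and
  flagged, keeping cohort means defined. Tables round half-up to two
  decimals at display time only.
- Multiple comparisons are reported raw (no correction), with the number of
  comparisons recorded in each manifest.

## Determinism

Every stochastic step — cohort draw, sample composition, weight
initialization, batch shuffling, dropout, threshold-calibration folds —
derives from explicit seeds via `numpy` `SeedSequence` spawning. Re-running
any driver from the seeds in its manifest reproduces tables bit-for-bit on
the same platform and BLAS.

## Known limitations

- The NumPy network trains on CPU only and at the shipped sizes; it is a
  faithful, reproducible implementation, not a performance-portable one.
- TRCA threshold calibration inherits the training-score optimism described
  above; a deployment would calibrate on a held-out enrollment split.
- EDF export is not implemented (recordings are exchanged in the HDF5
  container); EDF *reading* is supported through MNE.
- The ICA stage of the published preprocessing chain is intentionally
  absent — amplitude rejection stands in for it, consistent with the
  protocol's own observation that the ICA step is dispensable — but the
  pipeline leaves a hook (`filter_first`, channel subsets) for inserting
  one.
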