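# Methods

## Decoding model

The decoder assumes that each target's stimulus is a circular shift of a
common binary m-sequence and that the EEG response is code-locked: the
response to target k is the response to the base code, circularly
advanced by `shift_k` bits (one bit = `F_s / update_rate` samples, 10 at
the reference rates of 600 Hz / 60 Hz).  Training therefore rotates all
labelled trials back to bit-shift 0 **within each stimulation cycle**
(blocks of 630 samples), averages them into the grand-average response
`Z̄`, and recovers class templates by rotating `Z̄` forward.  Shifts are
applied per cycle, not across the whole trial, so cycle boundaries stay
aligned for multi-cycle trials.  The shift sign convention — a
left-shifted code *advances* the response, so the template is the grand
average rotated left — is pinned by the round-trip tests against the
synthetic forward model: template k must decode the stream generated
with code k.

Spatial filters are estimated by canonical correlation analysis between
the concatenated aligned trials `[Z_1 … Z_N]` and `N` repetitions of
`Z̄`.  The CCA is solved by row-centring, eigendecomposition-based
whitening of both auto-covariances, and SVD of the whitened
cross-covariance.  A relative ridge of 1e-9 × trace/m is added to each
auto-covariance before whitening; this guards the short-buffer case
(rank-deficient covariances from 0.25 s windows or from noise-free
synthetic data whose spatial rank is 1) and perturbs well-conditioned
solutions only at the 1e-9 level, which the unit tests budget for.  The
first s = 4 left weight vectors form the filter ensemble; s is
configurable for ablations.  Filters are defined up to sign, and every
downstream score is sign-invariant by construction (tested by negating
filters).

## Correlation scores and the ρ operator

The score between a buffer and a reference compares two stacked
s-variate signals (the s filter projections).  The field's notation
leaves the multivariate ρ operator open; this package defaults to the
**first canonical correlation** of the two stacks, consistent with how ρ
is defined for the filter-training step, and offers a flattened-Pearson
alternative (`score_method="pearson"`).  The choice is pinned by tests;
both are sign-invariant and bounded in [0, 1].  Ties in the argmax
resolve to the lowest class index for determinism, and the asynchronous
emission criterion is strict (`margin > β`).

## Filter bank and band weights

Sub-bands are (8–60), (12–60), (30–60) Hz Butterworth band-passes of
overall order 8 (four second-order sections; "order" counts the
band-pass poles).  Filtering is zero-phase (forward–backward) at both
training and test time: templates and buffers must be filtered
identically, and zero-phase filtering preserves the circular alignment
that the template shifting relies on.  A causal variant exists for
strictly online use but is not the default.  Zero-phase transients at
the buffer edges are not circularly shifted with the templates, which
leaves noise-free self-match scores slightly below 1 (≈0.99); the
classification argmax is unaffected.  Band weights are
`a_j = ρ⁽ʲ⁾/Σρ⁽ʲ⁾`, where ρ⁽ʲ⁾ is the leading canonical correlation of
the filter-training CCA in band j — bands where the evoked response is
weakly expressed relative to background activity receive small weights.
The "standard" (no filter bank) method used in comparisons is the same
pipeline with the single 8–60 Hz band, i.e. no decomposition beyond the
covered range.

## Asynchronous mechanics

Data arrive in 0.05 s blocks (30 samples).  Classification starts at
0.25 s (150 samples); the window extends block-by-block until the
template length n = 1260, after which the oldest n/2 = 630 samples (one
cycle) are shuffled out before each new block.  The block size must
divide n/2.  A selection is emitted when the margin between the two
highest combined scores strictly exceeds β; the buffer is then cleared
and a 1 s gaze-shifting pause follows.  Default thresholds are β = 0.15
(4 targets) and β = 0.1 (32 targets).  If no selection occurs within a
10 s dwell cap the session logs a timeout instead of blocking — the
reference protocol does not specify give-up behaviour, so this is a
simulation convenience, not a claim about the original system.

## Synthetic EEG

The generator emulates exactly the structure the decoder exploits, at
the reference recording conditions (32 channels, 600 Hz, 2.1 s training
trials, 1 s pauses):

- **Evoked response**: a unit-amplitude damped 20 Hz oscillation of
  ~100 ms, convolved circularly with the impulse train of the code's
  '1'-bit onsets within one cycle, projected through a fixed
  occipitally-weighted unit-norm topography.  Circular convolution makes
  the noise-free responses of different targets *exact* circular
  shifts — the property the shift-based templates assume.
- **Noise**: spatially mixed 1/f (pink) processes band-limited to
  2–100 Hz, mirroring a typical amplifier band-pass, plus an
  amplitude-modulated 10 Hz sinusoid on occipitally-weighted channels as
  the alpha contaminant (`alpha_amp` scales it relative to the pink
  noise; default 0.5, "strong contamination" experiments use 3.0).
- **SNR**: defined as evoked RMS over noise RMS on the channel where the
  evoked response is strongest; `snr=inf` yields bit-reproducible
  noise-free data.  The scaling is calibrated against a fixed probe
  simulation per model, so the realised per-trial ratio is accurate to a
  few percent (tested at ±10 %).

What the generator does **not** model: realistic head geometry and
volume conduction, eye/muscle artifacts, non-stationarity, latency
jitter of the evoked response, or inter-subject variability.  Passing
tests therefore demonstrate the correctness and internal consistency of
the decoding machinery and its qualitative behaviour (accuracy rising
with SNR and window length, filter-bank benefit under alpha
contamination, 4-vs-32-target contrast), not expected performance on
recorded EEG.

## Simulated experiments and problem sizes

Monte-Carlo experiments run at reduced size: 4–8 channels, the 4-target
codebook where the property under test allows it, 20 seeds for
monotonicity/comparison claims and 5 for the target-count contrast.
Sweeps operate around SNR 0.3, where the simulated decoder spans its
operating range (near-chance at 0.05, near-ceiling at 0.4–0.6); outside
that range accuracy saturates and window/SNR trends carry no
information.  The cross-validation harness is a stratified 4-fold split
(scikit-learn) with synchronous (β = 0) scoring, windows truncated from
trial onset, and ITR computed with t = window + 1 s gaze shift — the
same convention as online selection times.

## Metrics

Accuracy is correct selections over all selections.  The Wolpaw ITR uses
the number of stimulus classes as K (4 for the multi-step speller, i.e.
per-step classification), with 0·log 0 := 0.  The formula's bracket is
convex with its minimum of exactly 0 at chance level p = 1/K, so
below-chance accuracies would yield spuriously *positive* rates; the
implementation reports 0 with a warning in that regime, following common
BCI practice.  OCM divides the length of the final correct text by the
total spelling time — corrections cost time but do not add characters.

## Speller simulation

The 4-target speller is a depth-3 selection tree over 27 characters
(9-groups → 3-groups → single characters) whose fourth target deletes
the last character at the root and ascends one level elsewhere.  The
32-target speller has 28 characters, three suggestion slots and one
undo; undo removes the previous selection's entire output, including a
multi-character word completion (the reference design leaves this open;
whole-selection undo keeps the state machine invertible).  Selecting a
suggestion appends the word's remaining letters plus an underscore as
the word boundary.  Word suggestions are ranked by bigram count given
the previously completed word, then unigram frequency, then
alphabetically; the bundled corpus is ~200 uppercase everyday sentences
and any plain-text corpus (one sentence per line) can replace it.

Copy-spelling simulation uses a greedy intent policy (undo when the
typed text stops being a goal prefix; otherwise take a goal-consistent
suggestion if displayed, else the next character) and a per-selection
error model: correct with probability `accuracy`, otherwise uniform over
the other K−1 targets.  Any callable can replace the error model, e.g. a
decoder-in-the-loop oracle.  With accuracy > 0.5 expected progress is
positive and the simulation terminates; an iteration cap guards the
degenerate cases.

## Known limitations

- Performance numbers from synthetic data do not transfer to recorded
  EEG; only qualitative orderings are claimed, and human group means are
  out of reach by construction.
- Zero-phase sub-band filtering is an offline idealisation of the
  original causal online system.
- The regularized CCA deviates from the unregularized solution at the
  1e-9 level; for heavily rank-deficient inputs the trailing canonical
  directions are determined by the ridge and should not be interpreted.
- EDF ingestion requires all requested channels at one sampling rate and
  does not resample.
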