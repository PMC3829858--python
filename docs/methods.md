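# Methods

`gcflow` implements a frequency-resolved, directed analysis of how
large-scale cortical communication differs between two behavioural states
(canonically awake vs unconscious). This note describes the model and the
procedures, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## The analysis chain

**Pseudo-trials.** Recordings are cut into non-overlapping 2-s bins; each
selected bin is cut further into ten 200-ms short bins. A short bin is
treated as an independent realization of a common stationary stochastic
process ("pseudo-trial"). Per channel, every short bin is linearly
detrended and z-scored, which suppresses slow drift and per-bin amplitude
differences. A *condition sample* is a disjoint set of 60 two-second bins
(600 short bins = 120 s) drawn evenly from all sessions of one state; six
condition samples per state act as experimental replicates.

**Spectral Granger causality.** For every ordered pair of channels in
different regions a single bivariate VAR(p) is fitted to all short bins by
trial-pooled ordinary least squares — regression rows never cross bin
boundaries, and one coefficient set plus one residual covariance Σ are
estimated from the pooled rows. The default order is p = 7 (35 ms at
200 Hz); an AIC scan over orders 1..15 is available but the pipeline does
not auto-select, because causality spectra are rank-stable across orders
5–15 (a property the test suite asserts). Stationarity can be checked per
channel with the KPSS level test. From the fitted model, with transfer
function H(f) = (I − Σₖ Aₖ e^(−i2πfk/r))⁻¹ and spectral matrix
S(f) = H Σ H*, the causality from channel 2 to channel 1 is

    f_{2→1}(f) = ln [ S₁₁(f) / (S₁₁(f) − (Σ₂₂ − Σ₁₂²/Σ₁₁) |H₁₂(f)|²) ],

evaluated at the centres of 48 non-overlapping 2-Hz windows from 6 to
100 Hz (6 Hz ≈ one full cycle per 200-ms bin; point evaluation is used
because the VAR spectrum is smooth at 2-Hz resolution). Uncertainty comes
from a bootstrap over short bins: each of the (default 100) resamples
draws 600 bins with replacement — all channels of a bin move together —
and refits the model. Because rows never cross bin boundaries, the refit
reduces to re-weighting precomputed per-bin cross-product matrices, which
makes the bootstrap cheap and exactly equivalent to refitting on the
resampled rows (asserted by a test).

A caveat worth stating: the frequency integral of this decomposition
equals the time-domain measure ln(reduced/full innovation variance) only
when the intrinsic spectral factor is minimum-phase; with strong feedback
the integral is a strict lower bound. The oracle test therefore draws its
random models from the identity regime.

**Classification.** For every unordered pair of regions, one feature
vector per bootstrap resample concatenates both causal directions of all
inter-region electrode pairs × 48 frequencies (length 2·m·n·48). A linear
SVM (L2-regularized squared-hinge loss, cost 1, no feature
standardization — the inputs are non-negative causality values on a
common scale) is trained on the 100+100 bootstrap vectors of one awake
and one unconscious condition sample and tested on the vectors of the
held-out 5+5 samples; all 36 sample pairings are evaluated. Ties at
decision value 0 predict the lexicographically first class and are logged.

**Significance.** Each region pair's observed mean accuracy is compared
against a shuffled-label control: the 12 condition samples are randomly
reassigned to two pseudo-states (bootstrap structure intact), the same 10
assignments for every region pair, and a one-sided t-tail on the observed
mean vs the 10 shuffled means gives the p-value; Benjamini–Hochberg FDR
at 0.05 across region pairs. The classical alternative — a rank-sum test
of the 36 normal vs 36 shuffled per-classifier accuracies — is provided
in the API (`classify.significance`) but is *not* used for inference: the
36 accuracies share condition samples and are strongly dependent, and
simulation shows the rank-sum flags roughly half of all region pairs
under an exchangeable null. The studentized shuffled-label test keeps the
false-positive rate at the nominal level (≤ 5% in the null-control test)
without giving up power (planted differences still yield p < 0.002 for
every pair). Non-significant pairs are reported at accuracy 0.5; region
pairs without electrodes are missing, never 0.5.

**Weight tensor.** Each classifier's weight vector is divided by the sum
of absolute weights (L1 normalization), then split by sign: because the
features are non-negative, positive weights speak for the awake state and
negative weights (absolute value) for the unconscious state. The
non-negative parts are aligned into a 3-way array: condition-sample pairs
(36) × frequency (48) × state-tagged electrode-pair features,
concatenating datasets, region pairs, both directions and the two states
on the third axis (datasets concatenate; no cross-dataset electrode
alignment is attempted). Per classifier slice the awake and unconscious
parts sum to exactly 1. The 36 sample pairs are kept as a full axis (not
pre-averaged) so the decomposition can use their variation.

**Decomposition.** Non-negative PARAFAC is fitted by hierarchical
alternating least squares (HALS) from 5 random restarts (best fit kept),
converging when the fit changes by less than 1e-8 (relative) or after
2000 iterations. Two numerical details matter on weight tensors, whose
entries are O(1e-4): the random initialization is rescaled so the initial
model matches the data norm, and a component whose column dies during
optimization is revived at data scale at most 5 times — without these the
optimizer collapses to rank-1. Components are ordered by explained
variation. The number of components is chosen by the core consistency
diagnostic: the least-squares Tucker core implied by the loadings is
compared to a superdiagonal array, CCD = 100(1 − Σ(G−T)²/k), and the
largest k with CCD > 40% is kept (model refitted at each k, not nested);
if no k qualifies, k = 1 with a warning. On noisy desk-scale tensors CCD
is conservative — planted-structure recovery is therefore assessed at a
fixed component number while CCD selection is validated on planted-rank
fixtures.

**Component summaries.** Per component: the frequency peak (grid argmax,
ties to the lowest frequency, flat profiles are an error); the dominant
state (the state tag holding the larger share of electrode-pair score
mass); directed region-score matrices (sum of electrode-pair scores by
source/destination region, per dataset and state), their across-dataset
average, and the directional difference M − Mᵀ (net top-down vs
bottom-up); per-electrode total interaction and net outflow (outflow −
inflow; the nets sum to zero). Similarity between components of different
experiments is the spatial-frequency correlation R_f · R_s, the product
of Spearman correlations on the frequency and electrode-pair axes — the
product is symmetric, lives in [−1, 1], and reduces to the single-axis
rank correlation when the other axis matches perfectly. Cross-dataset
reproducibility is the fraction of dataset pairs whose flattened region
matrices correlate significantly (Spearman, BH-FDR across all component ×
state × pair tests). Components are matched across runs by brute-force
permutation maximizing the product of per-mode Tucker congruences.

## The synthetic-data generator

Each channel is a stochastic damped oscillator: an AR(2) resonator with
pole radius 0.95 at its region's intrinsic band, driven by unit-variance
Gaussian innovations. Directed couplings are lag-1..3 taps shaped as a
damped cosine at the coupling's band centre, active only in their state,
scaled by 1/n_source; the construction refuses configurations whose
companion matrix has spectral radius ≥ 1. On top of the oscillatory core
the generator adds 1/f background noise (0.2 × signal SD), a 50 Hz line
component (0.5 × SD, random phase per channel and session), a slow
0.05 Hz sinusoidal drift (2 × SD) and a linear ramp — enough to exercise
the line filter, detrending and robust amplitude gate non-trivially. Two
sessions per state are simulated by default so session pooling is
exercised. Everything is deterministic given (network, state, duration,
rate, seed, session).

The bundled demo network has 4 regions × 4 channels: awake-state
bottom-up beta (20 Hz) couplings from visual and somatomotor regions into
a frontal sink, and unconscious-state top-down theta (8 Hz) couplings out
of a frontal hub plus gamma (44 Hz) couplings out of temporal cortex —
i.e. a band-switching two-state design whose components, peaks, region
pairs and flow hubs are known exactly.

What the generator does **not** emulate: volume conduction and common
reference artifacts, anatomical geometry, non-stationarity within a
state, transient (non-sustained) interactions, muscle/eye artifacts, and
realistic 1-kHz acquisition chains (the pipeline supports 1 kHz →
downsampling, but the demo simulates at 200 Hz directly). Passing tests
therefore show that the machinery recovers sustained band-specific
directed structure under realistic nuisance components — not that it is
robust to every pathology of real recordings; in particular bivariate
causality still reports spurious links under common drive, which the
planted-truth tests make visible as extra (correctly band-tagged)
components.

## Problem sizes and defaults

Canonical parameters (model order 7, 6 condition samples × 60 bins, 100
bootstraps, 48-frequency grid, SVM cost 1, CCD threshold 40%, FDR 0.05,
slow-wave synchrony threshold 0.25) are the `RunConfig` defaults.
`desk_config` keeps those but drops to 20 bootstraps on the 16-channel
demo network, which runs the whole chain in ~2–3 minutes on one CPU; the
statistical test fixtures use 12 bins per condition sample (null control)
and 20 bootstraps (recovery), sizes chosen so the full suite completes on
a laptop-class machine while leaving every assertion statistically
comfortable. The sleep-state synchrony gate (mean pairwise correlation of
0.5–4 Hz band-passed signals, threshold 0.25) and the robust amplitude
gate (reject a 2-s bin if any channel exceeds 5 robust SDs of its
session distribution) are documented, tunable surrogates for acquisition-
specific rules.

## Known limitations

- Bivariate (not conditional) causality: common drive produces spurious
  links by design; the decomposition reports them as genuine structure.
- The weight tensor inherits SVM estimation noise; with few bootstraps
  the core consistency diagnostic under-selects, and component splitting
  of broad-band motifs (e.g. a theta motif splitting across 6/8/10 Hz
  windows) is common.
- EDF input is not supported; recordings move through a raw-array + JSON
  container (`synth.save_record` / `load_record`).
- The SSI and noisy-bin rules are surrogates specified here, not
  reimplementations of any acquisition pipeline's exact criteria.
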