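# Methods

## Stimulus protocol

One loading cycle is a 125 ms force protraction, a 250 ms plateau at 4 N
normal force, a 125 ms retraction and a 250 ms interstimulus period, always
on a 0.2 N normal background. The ramps follow half of a raised-cosine cycle
at the protocol's 4 Hz ramp frequency: during protraction the envelope is
`sin²(π t / (2 T_pr))`, which for `T_pr = 125 ms` spans exactly half a period
of a 4 Hz sinusoid; retraction is its mirror image. At the protraction
midpoint the normal force is therefore `0.2 + 3.8 · sin²(π/4) = 2.1 N`.
Tangential loadings (R, D, U, P) scale the same envelope to 1.4 N along the
direction's axis. The normal plateau (4 N) and tangential plateau (1.4 N)
are treated as independent controlled primitives; the nominal 20° angle is
metadata only, since 4·tan 20° ≈ 1.46 N ≠ 1.4 N and which quantity was
controlled exactly cannot be recovered from the published protocol.

Axis convention: x = radial(+)/ulnar(−), y = distal(+)/proximal(−),
z = normal compression(+); positions are relative to the unloaded rest
position.

The regular sequence repeats (R, D, U, P, N) six times; the first repeat is
warm-up and excluded from analysis, leaving 5 analysable trials per
direction. The irregular sequence is a seeded Eulerian circuit (Hierholzer's
algorithm) on the complete 5-node digraph with self-loops, starting at the
last regular direction (N): its 25 trials realize every ordered
(previous, current) pair exactly once.

## Fingertip mechanics

Each displacement axis follows a standard linear solid (Zener) creep model:
an instantaneous elastic term `F/k_inst` plus a delayed compartment with
`tau · du/dt = F/k_delayed − u`, integrated with the exact exponential
update per 2.5 ms step. A static 3×3 coupling matrix with unit diagonal and
small asymmetric off-diagonal terms mixes the axes (anisotropy); Gaussian
measurement noise (0.005 mm SD) is added to the recorded trace only. This is
a deliberately linear phenomenological model: the analyses require history
dependence with realistic time constants and millimetre-scale displacements,
not biofidelity, so nonlinear skin mechanics, fingerprint-ridge microslip
and FA-2/Pacinian dynamics are out of scope.

Defaults (N/mm, s): tangential axes `k_inst = 2, k_delayed = 1, tau = 1.2`;
normal axis `k_inst = 2, k_delayed = 6, tau = 1`. The tangential relaxation
time sits in the seconds range reported for fingertip tissue, and its value
balances two requirements of the study design: enough creep must survive
the 250 ms interstimulus period for the preceding loading to shape the next
trial's starting state, while the trace of trials further back must decay
fast enough that the residual state is dominated by the immediately
preceding direction (the quantity every analysis conditions on). With these
defaults the tangential starting position varies ~40× more across irregular
than across regular test trials, comfortably echoing the ~20× reported for
real fingertips, and trials sharing a preceding direction cluster tightly.
A single relaxation time per axis is a simplification — real tissue shows a
spectrum — and is the main reason deeper-history effects die off more
abruptly here than in skin.

The mechanics are simulated once, continuously, across all 55 trials, so
history crosses trial boundaries exactly as in the experiment. Afferents
are driven by the noiseless trajectory; measurement noise models the
position sensor, not the skin.

## Afferent models

Rate model: `rate(t + latency) = gain · softplus(w · f(t) + bias)` with a
21-dimensional feature vector `f`: three positions, three central-difference
velocities, and their 15 pairwise products. Features are scaled by fixed
physical constants (position scale 0.5 mm, velocity scale 10 mm/s) rather
than z-scored: the unloaded rest state then maps to exactly zero
drive, which gives the rest-rate semantics their meaning (FA-1 silent at
rest; a spontaneous SA-2's rest rate is `gain · softplus(bias)`, drawn in
5–30 imp/s). The 15 ms latency matches the conduction + transduction delay
the analysis side compensates, so the analysis-side advance is exactly
correct on synthetic data. Spikes are drawn by thinning an inhomogeneous
Poisson process at the rate trace, with a 1 ms absolute dead time
(non-paralyzable, so a constant rate λ yields λ/(1+λτ) output rate), and
quantized to a 12.8 kHz grid.

Archetypes (seeded draws; magnitudes have floors so most models respond):
FA-1 — velocity weights and velocity-containing products only, negative
bias, no background discharge; SA-1 — moderate position + velocity weights
and small interactions; SA-2 — tangential-position-dominant with a tonic
background discharge. Normal-axis weights are sign-biased positive (75–80%)
so that most, but not all, neurons are excited by indentation; the
negative-sign draws yield retraction/release-preferring neurons, which are
then typically dropped by the response-based inclusion filter, mirroring
the attrition of real samples.

A separate *designed* population with known coding categories exists for
category-recovery testing. Current coders are rest-silent, high-gain
velocity models whose dense bursts are refractoriness-regularized (precise
timing) and temporally skewed per direction through `Pz·dPx`/`Pz·dPy`
interaction weights. History coders are transient threshold-crossing
bursters: a normal-velocity drive against a negative bias produces one burst
per loading whose onset time is advanced or delayed by the tangential
residual deformation left by the preceding trial. Both designs encode
identity in spike *timing* because the spike-metric classifier at 8 ms
resolution handles timing codes far better than pure rate-level codes: for
sparse rate codes, any train's distance to a low-count class approximately
equals its own spike count, which makes sparse classes attract all
assignments (and can push bias-corrected information below zero). Real
afferents fire with sub-millisecond precision, so the timing-code design is
also the more faithful choice.

## Analyses

*Variability.* Instantaneous firing rate is the reciprocal of the
interspike interval, right-closed (`rate = 1/(t_{i+1}−t_i)` on
`(t_i, t_{i+1}]`, zero outside the first/last spike and for <2 spikes).
Across the 5 same-direction test trials we take the pointwise SD (n−1
denominator), average over directions, then over neurons; kinematic
variability is `sqrt(Σ‖vᵢ−v̄‖²/(n−1))` over the 2D tangential components.
Phase-wise scalars are time-averages of the SD trace within each phase
(protraction, plateau, retraction, interstimulus — the reduction the
source protocol leaves unstated; flagged in the output metadata). Sequence
contrasts use paired Wilcoxon signed-rank tests with Bonferroni correction
over the phases tested.

*Encoding.* Per neuron, over the 25 irregular trials: contactor positions
in the padded protraction window [−0.100 s, 0.225 s) are linearly resampled
400→1000 Hz, Gaussian-smoothed (σ = 10 ms, ±4σ kernel, reflect padding) and
differentiated; the target is the smoothed reciprocal-ISI rate advanced by
15 ms. Inclusion requires ≥2 spikes in protraction+100 ms in ≥5 trials.
Model classes: pos (3), vel (3), pos+vel (6), 2way (21). Ridge regression
with the alpha grid 0.001–1000 (13 log-spaced values) selected by an inner
5-fold search; reported R² is the mean over an independent outer 5-fold
split. Folds are whole trials (avoids temporal leakage between adjacent
1 ms samples) and features are standardized inside training folds; a config
switch restores the global standardization a scikit-learn
`StandardScaler`-then-CV workflow implies. Permutation importance is the
mean held-out R² drop over 10 seeded column permutations per outer fold,
ties broken by canonical column order; the reduced model refits the full
nested procedure on the top six columns. Population averages of r-values
use the Fisher transform. Three-way interaction models and cross-type
ANOVAs are out of scope.

*Information.* Victor–Purpura distance with insert/delete cost 1 and shift
cost `q·|Δt|`, computed by the standard O(nm) dynamic program;
`q = 2/resolution` (8 ms → 250 s⁻¹ for protraction, 32 ms → 62.5 s⁻¹ for
the interstimulus period) so spikes further apart than the resolution are
cheaper to delete-and-reinsert than to shift. Classification is
leave-one-out nearest class mean — the classified trial is excluded from
its own class mean, since including its zero self-distance would bias the
assignment (a divergence switch is deliberately not offered; the exclusion
is the defensible reading). Ties break toward the canonical direction order
(R, D, U, P, N). The plug-in mutual information of the 5×5 confusion matrix
(base-2, 0·log 0 = 0) is bias-corrected by subtracting the mean over 10
seeded label permutations (class sizes preserved); negative corrected
values are reported as-is and treated as "not above zero" for
categorization. Time courses evaluate cumulative windows from the phase
origin in 5 ms increments (including the zero-length window, which always
yields 0), once with current-direction and once with preceding-direction
labels. Neurons with <10 positive windows are excluded; otherwise the
fraction of positive windows with current ≥ preceding information maps to
'current' (≥0.70), 'previous' (≤0.30) or 'mixed'.

*Population geometry.* Per tonic SA-2 model, VP distance matrices over the
25 irregular trials are computed on windows running from the phase origin
to the analysis time point (interstimulus origin for −0.125 s and 0 s at
32 ms resolution; protraction onset for +0.125 s at 8 ms — the resolution
convention for the protraction point is configurable since the original is
unstated) and summed across neurons. Metric MDS (SMACOF stress
majorization, 8 seeded starts, best stress kept) embeds the matrix in 2D;
full Procrustes (translation, rotation, reflection, uniform scaling)
aligns it to the mean tangential contactor positions at the same time
point, with disparity = standardized residual in [0, 1] and output
coordinates in millimetres in the reference frame. Variance decomposition:
total = trace of the 2D covariance of all 25 points; within = mean trace
covariance within the five preceding-direction groups (n−1 throughout).

## Numerical and design notes

- All randomness flows from one root seed through named substreams
  (`mechanics`, `spikes/<id>`, `sequence`, fold/shuffle/MDS seeds), so any
  stage can be re-run in isolation bit-identically.
- Windows are half-open `[start, end)` everywhere; a spike exactly at a
  window end belongs to the next window.
- Session files are plain CSV/JSON/TOML. Times are written in seconds at
  6 decimals (exact for the 400 Hz grid); spike rows also carry their
  integer 12.8 kHz grid index so the read path reconstructs spike times
  exactly.
- Degenerate cases: zero-variance regression targets are flagged rather
  than scored; zero-variance point configurations are rejected by the
  Procrustes alignment; empty spike trains are valid (silent neuron) and
  yield zero rates and n-deletion VP distances.

## Problem sizes and what the tests show

The default session — 40 neurons (15 FA-1, 15 SA-1, 10 SA-2, all SA-2
tonic), 30 regular + 25 irregular trials — is the unit of analysis
throughout the test suite and the acceptance script; the encoding and
category analyses run on balanced subsets of it (or on a 20-neuron designed
population), sizes chosen so a full verification run completes in minutes
on one core. Monotonicity and dissociation checks summarize with medians,
which are robust to the occasional draw that lands deep in the softplus
nonlinearity where no linear encoder fits.

Passing tests demonstrate that the analysis chain recovers by construction
known properties of the generator: history-inflated variability, designed
coding categories, encoding-model ordering and archetype dissociation, and
preceding-direction clustering of the SA-2 population state. They do not
certify quantitative agreement with recorded microneurography data — the
synthetic fingertip is linear, afferent rates are softplus-linear in local
kinematic features of a single contactor point (no receptive-field
geometry, no partial slip), and spiking is Poisson-with-dead-time rather
than the near-deterministic firing of real afferents. Headline numbers from
the recorded dataset (mean R² per type, 20×/7×/4× variability ratios,
category counts) are therefore qualitative patterns to echo, not targets to
reproduce.
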