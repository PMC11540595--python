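# Methods

This note documents the models, estimators and numerical choices behind
`olfbilat`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what the synthetic data do and do not establish.

## Synthetic sessions

The generator emulates a unilateral odor-delivery experiment: 15 odors plus a
solvent-only blank, each presented to the ipsilateral and contralateral
nostril 7 times (224 presentations), with spike counts in a 4 s pre-stimulus
window and a 2 s response window. Defaults are the study's own summary
statistics wherever one is printed:

| parameter | default | unit | rationale |
|---|---|---|---|
| `p_respond` | 0.224 | — | responding probability per (neuron, odor); the AON's measured ipsilateral sparseness |
| `bcn_fraction` | 0.3 | — | share of neurons with coupled contra tuning; mid-range of the per-mouse BCN percentages |
| `slope` | 0.75 | — | contra = slope·ipsi + ε for coupled neurons; between the regional means 0.69 and 0.79 |
| `baseline_median_hz` | 3.9 (AON) / 2.8 (APC) | Hz | printed median spontaneous rates; baselines are log-normal (σ = 0.6) around the median |
| `magnitude_scale_hz` | 3.5 | Hz | γ of the Gaussian-tail magnitude law; gives a mean significant magnitude ≈ 1.6 Hz, the scale the recordings report |
| `positive_fraction` | 0.46 (AON) / 0.48 (APC) | — | per-neuron response sign, drawn once per neuron |
| `coupling_noise_hz` | 0.3 | Hz | jitter on the coupled contra tuning |
| `blank_delta_hz` | 0 | Hz | blank-evoked perturbation; a knob for robustness checks of blank subtraction |

Response magnitudes follow the cortical model's own law — the excess of
|N(0, γ²)| over the threshold matching `p_respond` — because no empirical
distribution family is printed; an exponential alternative is exposed as
config. The per-neuron sign convention reproduces the bimodal
positive–negative balance (most neurons all-excitatory or all-inhibitory).
Trial noise is Poisson on window counts, the same surrogate the study uses
for its variability analysis; rates are clamped at zero before sampling.
Sniff alignment, spike times, calcium dynamics and breathing are not modeled:
windows are taken as already aligned.

One deliberate consequence of these defaults: the *measured* significant
fraction on synthetic sessions (~0.10) sits below `p_respond`, because at
realistic magnitudes the 7-trial signed-rank test misses weak responses. The
printed 22.4% is itself a measured, power-limited number, so the generator's
ground truth and the measurement cannot both equal it; we keep the printed
value as the ground-truth responding probability and document the gap. Tests
that need near-complete power raise `magnitude_scale_hz` to ~14 Hz and say so.

The glomerular panel is built from a shared nonnegative profile plus sparse
half-normal noise per odor, with the shared weight bisected to a target mean
off-diagonal cosine similarity (tolerance 0.05, default target 0.3); rows are
then divisively normalized to equal Euclidean norm. Nonnegative activity puts
a floor on reachable similarity (~0.06 at the default sparsity); requests
below the floor raise.

## Response statistics

`R` is the blank-subtracted difference of window rates averaged over the 7
repetitions. Significance is a two-sided Wilcoxon signed-rank test of the
per-trial odor deltas against blank deltas, paired by repetition index (the
only shared structure between odor and blank trials). The implementation
enumerates the exact conditional null — all 2^m sign assignments of the
observed mid-ranks after dropping zero differences — which equals the classic
exact distribution when magnitudes are untied and remains exact under ties;
beyond m = 14 pairs it switches to the tie-corrected normal approximation
with continuity correction. It reproduces scipy's p-values (asserted in
tests) at ~130× the speed, which matters for the resampling stages. All-zero
differences return p = 1 with a degenerate flag. At n = 7 the exact test is
discrete and conservative: its realized size on the study-scale Poisson null
is ≈ 0.039 at the nominal 0.05, never anticonservative.

## BCN detection and nulls

The per-neuron criterion is OLS of contra on ipsi over the 15 odor responses
with the slope F test at 5%; degenerate fits (constant ipsi vector, e.g.
silent neurons) count as non-BCN. All per-neuron regressions run through one
closed-form vectorized OLS helper (cross-checked against
`scipy.stats.linregress`).

* **Bootstrap null**: odor labels permuted independently within each side,
  per neuron, per iteration (default 10,000); p = (1 + #{null ≥ obs})/(1 + N)
  so it is never zero.
* **Poisson ceiling**: per-(neuron, stimulus, side) window rates are the
  trial-mean counts (hence nonnegative); two independent sets of 7 surrogate
  trials are drawn and regressed against each other within a side. Because
  both sets share the *estimated* rates, estimation noise in a real (or
  noisy synthetic) recording contributes correlation; the fraction is a
  ceiling on detectable correlation, not a test-size estimate. With flat
  noiseless rates it collapses to the F-test size (verified).
* **Split-half bound**: all C(7,3) = 35 unordered {3,4} partitions of the
  repetitions (deterministic; other repetition counts generalize to
  C(n, ⌊n/2⌋) with a notice), blank-subtracted responses per group, same
  regression criterion. The bound holds under study-like conditions because
  every responsive neuron is self-consistent within a side while only the
  coupled subset matches across sides; it is *not* an upper bound when all
  neurons are tightly coupled (7-vs-7 cross-side estimates then beat 3-vs-4
  within-side ones).
* **Population regressions**: per odor, across neurons, with a
  neuron-identity shuffle null (default 1,000 permutations, independent per
  side), smoothed p as above.

## Decoding

Features are during-window spike counts minus the mean blank count of the
same side (no pre-window subtraction — the feature the decoders use).
Pseudotrials are re-aligned per decoding repetition by independently
permuting the trial axis per (neuron, odor, side), seeded by (seed, repeat).
Odor decoding holds out one trial per odor, builds centroids from the rest,
and assigns test trials (held-out same side, or one random trial per odor
from the other side — fully disjoint from training) to the nearest Euclidean
centroid, ties toward the lowest odor index. Side decoding removes one
odor-trial per side and classifies it to the nearer side mean; the side mean
averages per-odor means rather than raw trials, because depleting the
held-out odor's weight on one side only would otherwise bias classification
toward the opposite side (a ~0-accuracy artifact on statistically identical
sides). Accuracy dispersion is stored as SD over repeats; chance levels
(1/15, 1/2) ride on the result objects. "Linear classifier" here always
means nearest centroid — no margin-based decoder is used.

The BCN-fraction manipulation draws stratified samples (default 135 neurons)
at a controlled fraction of flagged neurons. The trial-free comparisons used
for the model are `match_centroids` (each odor centroid from one side
assigned independently to its nearest neighbor on the other side; Euclidean
or angular, zero vectors under the angular metric count incorrect) and
`classify_side_centroid` (leave-one-odor-out: the removed odor's two
centroids classified to the nearer mean of the remaining 14 per side).

## Two-hemisphere model

Inputs are sampled directly from the Gaussian law the random-projection
argument implies — `h ~ N(0, γ² cosθ)` i.i.d. across neurons — rather than by
instantiating the glomerulus-to-cortex matrix; the cosine matrix is
symmetrized and eigenvalue-clipped at zero if numerically non-PSD.
`y = shrink(h, φ)` with `φ/γ = √2·erfc⁻¹(S)` (checked to 1e-9). γ is fit by
1-D bounded MLE of the tail law `p(m) ∝ exp(−(m+φ)²/2γ²)`; with φ tied to γ
the normalizer is proportional to γ, and at φ = 0 the closed-form half-normal
MLE is recovered (oracle test).

The comparison pipeline draws two independent ipsilateral realizations: A is
the recorded-side stand-in, B the opposite cortex; the contralateral
representation is `shrink(s·G·Y_B, φ)` with s bisected on log₁₀ s ∈ [−6, 6]
(60 iterations, tolerance 0.005 absolute sparseness) to the contralateral
sparseness target (0.252 for the AON preset). The Hebbian matrix pairs A with
B (the covariance rule over shared odor experience); building it from B alone
is exposed for the self-consistency check. `G_Rand` has N(0,1) entries kept
with probability ξ (default 0.5 — no value is printed; χ-rescaling makes the
metrics insensitive to ξ), and χ equalizes Σ_o |G·Y_o| between components to
1e-6 relative.

Alignment metrics average over 200 samples of 385 neurons (the recorded AON
population size); the BCN fraction inside the metrics uses the same
trial-free per-neuron regression. The α fit minimizes
`z² = Σ_k ((model_k − data_k)/SD_k)²` over a grid (default 0:0.02:1, ties to
the smaller α; metrics whose sampling SD is zero — e.g. saturated odor
matching at high α — are dropped with a notice). Low-rank variants truncate
the SVD of `G_Struct` (best rank-Q Frobenius approximation; factors reusable
across a Q sweep) or rebuild it from the first Q principal components of the
centered opposite-cortex responses with the same coefficients applied
ipsilaterally; at Q = P the PCA construction reproduces the full Hebbian
matrix exactly.

**Problem sizes.** The modeled cortex defaults to 50,000 neurons; the
analyses, tests and acceptance script run at 1,200–20,000 neurons, the
package's choice for desk-scale work. The α fit is insensitive to this (a
halved population moves α̂ by ≤ 0.1, tested), matching the model's reported
robustness to population size. At 2,000 neurons α recovery over truths
{0.2, 0.42, 0.8} has mean error ≈ 0.02–0.03; identifiability flattens above
α ≈ 0.7 where all four metrics saturate, so errors there run up to one grid
step (0.05–0.1).

## What passing tests do and do not show

The synthetic data share the study's design, noise model and printed summary
statistics, but not its biology: glomerular similarity is a one-parameter
surrogate for measured odor chemistry, tuning magnitudes follow the model's
own tail law, and neurons are independent given their tuning (no correlated
noise, no sniff-locked dynamics, no electrode drift). Green tests therefore
establish that the estimators are calibrated (type-I errors, chance levels,
null uniformity), that parameters the generator controls are recovered
(responding probability, slope, BCN fraction, α), and that the model's
qualitative laws hold (erfc sparseness, zero correlation under random
connectivity, monotone alignment in α, rank-~7 sufficiency). They do not
certify the published per-mouse percentages or decoding curves, which depend
on the real recordings.

## Known limitations

* The signed-rank test at n = 7 is discrete; its realized size is ~0.039,
  so borderline pairs are called conservatively.
* The Poisson ceiling inherits rate-estimation noise (see above); it should
  be read as an upper bracket.
* Dense `G` matrices are materialized (memory ~n² doubles), which caps
  practical model sizes near 20,000 neurons on a laptop-class machine; the
  Hebbian part is rank-(P−1) and could be applied implicitly if larger
  cortices are needed.
* The generator's per-neuron response sign is absolute (balance exactly 0 or
  1 before measurement noise); real balance distributions have mass strictly
  inside (0, 1).
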