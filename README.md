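# olfbilat — bilateral alignment of odor responses in olfactory cortex

`olfbilat` is an analysis pipeline for the question of how the two olfactory
cortices come to respond alike when an odor is sampled through either nostril.
It is written for systems neuroscientists working with trial-resolved spike
counts from unilateral odor presentations (anterior olfactory nucleus, AON, or
anterior piriform cortex, APC): the package computes blank-subtracted odor
responses and their significance, detects *bilaterally correlated neurons*
(BCNs) against resampling nulls, decodes odor identity and stimulus side from
pseudopopulations (including cross-nostril transfer), and fits a
two-hemisphere cortical model that asks how much *structured* interhemispheric
connectivity the data demand.

A synthetic-data module generates complete sessions that emulate the study
design — 15 odors + 1 solvent blank × 2 sides × 7 repetitions = 224
presentations, sparse signed tuning, Poisson trial noise — so every stage is
testable without any recordings.

## The statistics and the model

**Response.** For neuron–odor pair (i, o) on one side, with firing rates
`Dur` in the 2 s response window and `Bef` in the 4 s pre-stimulus window,

    R = mean_t(Dur_o^t − Bef_o^t) − mean_t(Dur_b^t − Bef_b^t)   [Hz]

where *b* are the paired blank trials. Significance per pair is a two-sided
Wilcoxon signed-rank test of the odor deltas against the paired blank deltas
at the 5% level (exact null at n = 7).

**BCNs.** A neuron is bilaterally correlated when the OLS regression
`contra = a·ipsi + b` over its 15 per-odor responses is significant (F test,
p < 5%). Prevalence is judged against a 10,000-iteration odor-shuffle
bootstrap; a Poisson-surrogate ceiling and the C(7,3) = 35 split-half
fractions bracket what trial noise allows.

**Decoding.** Nearest-Euclidean-centroid classification of blank-subtracted
spike-count features with leave-one-trial-per-odor cross-validation; for
cross-side transfer the test trials come from the opposite nostril. Side
(laterality) decoding is two-class nearest-mean.

**Two-hemisphere model.** Each model neuron's input across the P = 15 odors
is Gaussian, `h ~ N(0, γ² cosθ)`, where cosθ is the odor–odor cosine
similarity of the glomerular panel; responses are `y = shrink(h, φ)` (the
symmetric soft threshold). Sparseness S fixes the threshold through
`S = erfc(φ/(γ√2))`, and γ (model units → Hz) is the MLE on the
significant-magnitude tail. The cortices are linked by

    G = α·G_Struct + (1−α)·G_Rand,   G_Struct ∝ Σ_o (Y_o − C)(Y_o' − C')ᵀ

a Hebbian covariance-rule matrix mixed with a sparse random matrix (χ-rescaled
to equal output magnitude). α is fit by minimizing the z² distance between
four model/data alignment metrics (pooled r, %BCN, centroid odor-matching,
side classification), each sampled 200× over 385-neuron subpopulations.
Rank-Q (SVD or PCA-subspace) approximations of `G_Struct` probe how little
structure suffices.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(tables land in `results/`):

```bash
python analysis/01_simulate_session.py --seed 0
python analysis/02_response_statistics.py
python analysis/03_bilateral_correlations.py --seed 0
python analysis/04_decoding.py --seed 0
python analysis/05_hemisphere_model.py --seed 0
```

`01` prints the design it generated:

```
panel: 15 odors x 155 glomeruli, mean off-diagonal cosine 0.300
session: 224 presentations (15 odors + blank x 2 sides x 7 reps)
tuning: 300 neurons, median baseline 3.68 Hz, 28% bilaterally coupled (slope 0.75)
```

`03` summarizes the BCN analysis — the observed fraction (0.157) beats all
10,000 odor-shuffle nulls (bootstrap p ≈ 1e-4, null mean at the 5% test
size), while the Poisson ceiling (0.84) and split-half bound (0.43) show that
trial noise alone caps what is detectable:

```
"bcn_fraction_observed": 0.1567,
"bcn_bootstrap_p": 9.999e-05,
"bcn_null_fraction_mean": 0.0535,
"poisson_ceiling_mean": 0.8426,
"split_half_mean": 0.4259
```

`05` calibrates the model from the measured statistics and recovers the
structure weight used to generate the reference run:

```
measured sparseness: ipsi 0.102, contra 0.100
phi/gamma = 1.635; fitted gamma = 6.24 Hz (from 459 significant magnitudes)
fitted alpha = 0.4 (true 0.42)
```

with the low-rank sweep showing a rank-7 structured link already reaches
~0.9 of the full-Hebbian odor-matching accuracy.

A `olfbilat` CLI (`simulate`, `respond`, `bcn`, `decode`, `modelfit`,
`run-all`) exposes the same stages over YAML configs; `olfbilat run-all
--seed 3 --out results/run` executes the whole pipeline with a manifest.

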