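# Methods

This note documents the statistical model and algorithms implemented in
`cfdeconv`, the default parameter choices and their rationale, and the design
of the synthetic data generators used for validation.

## 1. Quantification and filtering (`cfdeconv.io`)

Methylation arrays report a methylated intensity `M` and an unmethylated
intensity `U` per probe and sample. The beta-value is

```
beta = M / (M + U + offset),    offset = 100
```

The offset stabilizes the ratio when both channels are dim; 100 is the
conventional value for Illumina-style arrays. Probes are dropped if their
detection p-value is `>= 0.01` (inclusive) in **any** sample — a strict
all-samples rule, chosen because downstream deconvolution cannot tolerate
per-sample missingness in the marker panel.

For differential analysis, beta-values are mapped to M-values:

```
m = log2(beta / (1 - beta)),    beta clipped to [1e-6, 1 - 1e-6]
```

M-values are approximately homoscedastic and unbounded, which suits the
linear modeling below; beta-values remain the interpretable scale used for
mixing and deconvolution. The `1e-6` clip keeps the logit finite for
degenerate beta-values of exactly 0 or 1.

## 2. Moderated differential methylation (`cfdeconv.diffmeth`)

Per probe, a cell-means linear model (`~ 0 + group`) is fit by ordinary least
squares, giving group means, a residual variance `s²`, and residual degrees
of freedom `df`. Because methylation studies have many probes and few
samples, per-probe variances are noisy; we shrink them with the standard
empirical-Bayes scheme: assume `s² ~ s0² · F(df, d0)` and estimate the prior
`(d0, s0²)` by method of moments on `log s²`, matching the mean and variance
of the log-F distribution via digamma/trigamma functions (`trigammaInverse`
solved by Newton iteration). Degenerate inputs follow the same conventions
as the reference R implementation: variances are floored at zero, zeros are
offset to `1e-5 ×` the median with a warning, and when the observed spread of
`log s²` is no larger than the sampling noise the prior degrees of freedom
are infinite and `s0²` is the arithmetic mean of the variances. The
implementation is cross-validated against Bioconductor `limma` (3.58.1) in
`tests/test_diffmeth.py`, which compares `logFC`, moderated `t`, `P.Value`
and `adj.P.Val` on heteroscedastic data.

The posterior variance and moderated t-statistic for a contrast `c` are

```
s²_post = (d0·s0² + df·s²) / (d0 + df)
t = (cᵀ·coef) / (sqrt(Σ c_g²/n_g) · s_post),   reference t(d0 + df)
```

with a normal reference when `d0 = ∞`. Probes whose contrast is exactly zero
get `t = 0, p = 1`. P-values are adjusted by Benjamini–Hochberg
(`statsmodels`; a brute-force step-up oracle backs the tests).

**Tumor-specific marker rule.** Two contrasts are computed from one shared
variance prior: tumor tissue vs normal tissue, and normal tissue vs healthy
plasma. A probe is tumor-specific if it is strongly differential in the
tumor contrast (`adj_p < 0.01` and `|logFC| > 0.2`) while showing no tissue
signal against plasma (`adj_p >= 0.05` **or** `|logFC| < 0.01`). Survivors
are ranked by `|logFC|` descending (probe ID as deterministic tiebreak) and
capped at the **top 500** — a panel size small enough for stable training
yet large enough to average out per-probe noise.

## 3. Mixture simulation (`cfdeconv.simulate`)

Reference columns prefixed `plasma`/`tumor` define two donor populations.
For each of `samplenum` synthetic samples (default 5,000):

1. Draw fractions `(w_h, w_t)` from `Dirichlet(0.8, 0.2)` — a prior
   concentrated near low tumor burden, matching clinical plasma — or, with
   `method="uniform"`, `w_t ~ U(0, 1)`.
2. Build each population profile as the mean of `k = 5` donor columns drawn
   with replacement; averaging a few donors injects realistic biological
   variability without leaving the population's support.
3. Mix: `x = w_h · p_h + w_t · p_t`, optionally perturbed by Gaussian noise
   on the logit scale.

Labels `y = (w_h, w_t)` are returned alongside `x`. All draws come from one
`numpy.random.default_rng(random_state)`, so a simulation is reproducible
bit-for-bit from its seed.

## 4. Interpretable autoencoder (`cfdeconv.autoencoder`)

**Architecture.** For `N` input probes the encoder is a stack of linear
layers with widths `N → 512 → 256 → 128 → 64 → 2`, CELU activations and
dropout 0.5 on the hidden layers (training only). The 2-unit latent code is
used raw during training and rectified (ReLU) at inference, where it is
interpreted as the (healthy, tumor) fractions. The decoder is five
**bias-free** linear layers; because a composition of bias-free linear maps
is a single linear map, the decoder collapses to

```
W_eff = D5·D4·D3·D2·D1   (N × 2),      Atlas = sigmoid(W_eff)
```

Reconstruction is `x̂ = latent · Atlasᵀ` — the exact generative model of a
two-component mixture, with the atlas columns as the learned population
methylomes. Passing `W_eff` through a sigmoid keeps every atlas entry in
(0, 1), i.e. a valid beta-value, and is what makes the decoder directly
interpretable rather than an arbitrary linear read-out. For inputs smaller
than the narrowest hidden layer (64), hidden widths are capped at `N` with a
warning so tiny problems remain well-posed.

**Loss.** Four mean-absolute / likelihood terms, equally weighted by
default:

* `comp` — MAE between the latent code and the known mixing fractions
  (supervision from the simulator);
* `recon` — MAE between input and reconstruction;
* `methy_h`, `methy_t` — Bernoulli negative log-likelihood of the reference
  population mean beta-values under the corresponding atlas column. A
  beta-value is the mean of per-molecule binary methylation states, so the
  Bernoulli NLL is the natural likelihood anchoring each atlas column to its
  reference population; unlike an L2 penalty it weights errors more heavily
  near the informative extremes (beta near 0 or 1). Reference means are
  clipped to `[1e-6, 1 - 1e-6]` to keep the NLL finite.

**Optimization.** Adam (`lr = 1e-4`, β = (0.9, 0.999), ε = 1e-8), batch size
128, 256 epochs. We use `1e-4`: with `1e-5` the loss is still clearly
decreasing at 256 epochs on our problem sizes, while `1e-4` converges well
within budget and recovers held-out fractions accurately (RMSE ≈ 0.03 on
200 probes / 1,000 training mixtures; the test suite asserts ≤ 0.08). The
forward pass, analytic backpropagation (including the prefix/suffix products
for the collapsed decoder) and Adam are hand-written in NumPy; gradients are
verified against central finite differences in `tests/test_autoencoder.py`.
Initialization, batch shuffling and dropout masks all derive from the
configured seed, so training is fully reproducible. Models serialize to a
single `.npz` with a format version, config JSON and probe IDs; corrupt or
foreign files raise `ModelFormatError`.

**Inference.** `predict_fractions` aligns the input matrix to the model's
probe panel (missing probes are an error, not silently imputed), applies the
encoder with ReLU and no dropout, and by default normalizes the two
nonnegative activations to sum to one. An all-zero latent vector falls back
to (1, 0) with a warning.

## 5. Longitudinal monitoring (`cfdeconv.monitor`)

Per patient, technical replicates (same patient and timepoint) are averaged
first — they are not independent observations, and averaging them prevents
pseudo-replication in the cohort test. The sample at the smallest timepoint
is the baseline and the next smallest is the follow-up; patients with fewer
than two distinct timepoints are skipped with a warning. The per-patient
change in tumor fraction is tested against zero with a two-sided one-sample
(paired) t-test. Degenerate cases are handled explicitly: all-zero changes
give `t = 0, p = 1`; identical nonzero changes (zero variance) give `p = 0`
with a warning, since the t-statistic diverges.

## 6. Synthetic fixtures (`cfdeconv.fixtures`)

The generators produce data with **known ground truth** at sizes where every
pipeline stage can be validated in seconds.

* **Reference panels** (`make_reference`): each probe has a stratum mean —
  hypermethylated 0.8, hypomethylated 0.2, background 0.5 — and per-sample
  values are drawn from `Beta(mean·κ, (1−mean)·κ)` with κ = 50, giving a
  standard deviation ≈ 0.07 at mean 0.5, comparable to real array noise.
  Planted differential probes alternate hyper/hypo in tumor, so both
  directions of effect are covered.
* **Tissue groups** (`make_tissue_groups`): three populations (tumor tissue,
  normal tissue, healthy plasma) with separately planted *tumor-specific*
  and *tissue-specific* probe sets, so the two-contrast selection rule can
  be scored for recall and for leakage of tissue-only probes.
* **Cohorts** (`make_cohort`): per-patient tumor-fraction schedules —
  a *sensitive* arm with baseline `U(0.2, 0.6)` dropping to
  `baseline × U(0, 0.3)` at follow-up, and a *resistant* null arm with
  follow-up `= clip(baseline + N(0, 0.05), 0, 1)` — mixed through a given
  atlas and observed with Beta noise (κ = 100).

**Realism and limits.** The fixtures capture the features the algorithms
depend on: bounded beta-values with mean-dependent Beta noise, sparse strong
markers on a null background, low-tumor-burden mixtures, and paired designs.
They deliberately omit probe-probe correlation (CpG co-methylation blocks),
batch effects, copy-number distortion of intensities and cell-type
heterogeneity beyond two components, so absolute performance numbers on
fixtures are optimistic relative to clinical data; the fixtures validate
correctness and qualitative behavior, not clinical accuracy.

**Problem sizes used in validation.** The test suite trains one full
256-epoch model on 200 probes × 1,000 mixtures (shared across tests,
≈ 20 s), runs marker selection on 2,000-probe panels with 400 or 700 planted
markers, and evaluates monitoring on 16–50-patient cohorts. The
`scripts/acceptance.py` entry point reruns the simulator-mean and
selection-cap computations from scratch for any seed.
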