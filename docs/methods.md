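# Methods

## Problem

Clinical gene panels report tumor mutational burden (TMB) as mutations per Mb
over a footprint of ~1–4 Mb of coding sequence, while the biomarker of
interest is exome-wide TMB (~30+ Mb).  Panel TMB is a biased estimator:
panels concentrate on recurrently mutated cancer genes, so at low burden the
panel over-represents the genome, and the small-count statistics make the
error heteroscedastic and right-skewed.  Tumor-only assays add a second bias:
germline variants that survive population-frequency filtering ("private"
germline variants) inflate the panel count, with a mean that depends on how
well the patient's ancestry is represented in the reference databases.
`tmbcal` calibrates panel TMB to exomic TMB with a full predictive
distribution rather than a point estimate, so that threshold calls can be
gated by confidence.

## Labels and predictors

Exomic TMB is defined as the number of nonsynonymous mutations per Mb of the
sample's covered coding footprint (the intersection of its coverage mask with
a CDS mask).  Adjacent single-base substitutions with alt counts within 20%
relative difference are treated as one in-phase dinucleotide event, merged
greedily left-to-right into a single nonsynonymous record (callers report
dinucleotide substitutions as two rows, sometimes individually silent).  The
20% tolerance and the greedy order are deterministic design choices; the
merged record keeps the OR of the hotspot flags and drops SNV-keyed database
AFs, since the dinucleotide is a different allele.

The predictor vector holds per-Mb panel counts — nonsynonymous, all
(nonsynonymous + synonymous), hotspot-flagged — normalized by the panel's CDS
size, with optional one-hot ancestry (EUR/AFR/EAS/AMR/SAS/OTHER).
"Hotspots removed" configurations subtract hotspot variants from the counts
before normalization.  Training sets are capped at the 98th percentile of the
active panel-derived *input* (linear-interpolation percentile, ties
retained); the exomic label is never capped, which would truncate the target
distribution.  The cap is computed per input configuration.  Samples with
zero panel variants are legal inputs, never dropped.

## Model

A fully connected network (hidden layers 128, 64, 32; softplus activations)
maps the input vector to the parameters of a K-component log-normal mixture
over exomic TMB: weights by normalized exponential over K logits, log-scale
means unconstrained, log-scale SDs by softplus plus a floor of 1e-3 (the
floor prevents component collapse onto single observations).  K defaults
to 3: the conditional shapes to capture run from right-skewed unimodal to
nearly symmetric, which small K handles.  The loss is the mean negative
log-likelihood of the mixture, evaluated in log-space with a max-shift.

Count inputs are log1p-transformed; no further standardization is applied.
Labels are offset by δ = 0.01 mutations/Mb before the likelihood so zero-TMB
samples remain inside log-normal support; all public quantile/exceedance
queries subtract the offset again, so outputs are on the TMB scale.

Optimization: Adam (learning rate 1e-3, batch 512), at most 1000 epochs,
early stopping on a 10% validation split with patience 20, restoring the
best-validation weights.  The network, backpropagation and optimizer are
implemented directly on numpy arrays with analytic gradients; a single seed
determines initialization, the train/validation split and batch order, so
training is bit-for-bit reproducible (verified by test).  For degenerate
constant-input fits the default learning rate plateaus slowly; such fits use
3e-3 with patience 50.

The point estimate is the *median* of the predictive distribution (quantiles
by bisection on the mixture CDF, relative tolerance 1e-8, bracketed by
exp(μ_k ± 8σ_k)); the closed-form mean Σ w_k exp(μ_k + σ_k²/2) is also
exposed.  The reference model is a fixed-variance normal linear baseline:
OLS mean, single global residual-MSE variance — the probabilistic reading of
ordinary linear regression — whose quantiles and exceedance probabilities
come from Normal(mean(x), MSE).

## Evaluation and stratification

MAE and Spearman rho (average ranks for ties) are computed over samples with
panel input ≥ 5/Mb; rank correlation is invariant under monotone transforms
of the predictions.  Cross-validation uses a seeded uniform shuffle into k
folds (default 5), each sample predicted once out-of-fold.  Detection rates
report the fraction of true exomic TMB > t within the panel-above and
panel-below groups.

Tripartite stratification at threshold t: confident-above iff
P(TMB > t) ≥ c, confident-below iff 1 − P(TMB > t) ≥ c (default c = 0.95),
else indeterminate.  PPV is scored over confident-above only and NPV over
confident-below only.  Calibration is checked by the probability integral
transform (PIT = CDF_i(y_i)), from which central-interval coverage at any
level follows as P(|PIT − ½| ≤ level/2), plus a one-sample
Kolmogorov–Smirnov uniformity statistic.

## Tumor-only filtering

Labeled tumor-only data are built by concatenating a sample's germline calls
into its somatic calls (site collisions resolve to somatic; origin labels
are required).  Filtering removes a variant iff any database popmax AF
exceeds the policy threshold (permissive 1%, stringent 0.1%), or any
database overall AF exceeds its threshold (0.1% / 0.01%), or the
self-cohort frequency exceeds the popmax threshold and the site is not a
whitelisted hotspot.  Removal uses strict inequality ("greater than"), and
absence from a database passes — a database can only exclude what it has
seen.  The self-cohort frequency is the carrier fraction across samples of
the run (the fraction of samples carrying the site), a deliberate choice
over allele frequency: for rare sites in a tumor cohort the two are nearly
identical, and carrier fraction is well-defined without genotypes.  Samples
with fewer than 400 pre-filter germline variants over the union-of-panels
footprint are excluded from tumor-only training sets (incomplete germline
calls would understate contamination); the boundary is inclusive.

Filtering metrics treat somatic as the positive class: sensitivity is the
retained fraction of somatic variants, specificity the removed fraction of
germline.  The decision rule never reads the origin label.

## Synthetic cohorts

The generator draws, per sample: ancestry from a TCGA-like EUR-dominant mix;
TMB T from a two-component log-normal mixture (weights 0.9/0.1, log-means
ln 2.5 / ln 20, log-SDs 0.8 / 0.5 — a low-burden bulk plus a hypermutated
tail); exome size E ~ Uniform(28, 38) Mb; exome nonsynonymous count
~ Poisson(T·E), each mutation a hotspot with probability 0.03; synonymous
count ~ Poisson(0.35·T·E).  Panel capture is independent Bernoulli thinning:
probability panel_mb/E for non-hotspot mutations and min(1, 10·panel_mb/E)
for hotspots (the ×10 enrichment produces the over-estimation of exomic TMB
by panels at low burden).  Residual private germline counts are
Poisson(λ_ancestry · panel_mb/4) at the stringent level, multiplied by 2.15
at the permissive level — the multiplier reproduces a ≈43:20
permissive:stringent contamination ratio in expectation — and split 55/45
into nonsynonymous-like / synonymous-like (rare coding germline variants are
mostly missense-like; the split is a documented free parameter).  The
ancestry λ map (EUR 15 … AFR 60 per 4 Mb at stringent) encodes the
qualitative ordering of reference-database representation, not published
values; `scale_germline_lambda` rescales it to any target cohort mean.
True exomic TMB is the nonsynonymous exome count / E.

Counts, not positions, drive the regression, so panel membership is
simulated as thinning rather than positional intersection; positions are
synthesized only for the variant-level toy cohorts used to exercise the
filtering pipeline, whose allele-frequency spectrum is a log-uniform toy
chosen to straddle the thresholds rather than a population-genetic model.

What the generator does *not* emulate: sequencing depth, tumor purity and
clonality effects on variant detection; positional/gene-level structure of
panels; linkage between hotspot status and TMB; realistic site-frequency
spectra.  Passing tests therefore demonstrate that the estimator recovers
the structure this model encodes (nonlinear bias, heteroscedastic skewed
error, ancestry-dependent contamination), not performance on any real
cohort.

## Numerical and degenerate-input choices

Mixture NLL and responsibilities are computed via log-sum-exp; sigmoid
inputs are clipped at ±500.  Interval arithmetic is 0-based half-open
everywhere; 1-based MAF positions are converted at the boundary.  Intervals
that touch are merged; an empty coverage∩CDS intersection is an error (the
sample cannot be labeled).  CDF at t ≤ 0 returns 0 rather than erroring, so
threshold sweeps can start at 0.  Rank-deficient baseline designs raise
(full one-hot ancestry plus an intercept is collinear — baseline
comparisons use count-only inputs).  A non-finite training loss aborts with
the offending batch identified.

## Problem sizes

The shipped end-to-end runs use 20,000 training / 5,000 held-out simulated
samples for the model contrast, 50,000 samples for simulator-fidelity means,
100,000 Monte-Carlo draws for conditional oracles, and 10,000 draws for the
closed-form MLE recovery check; these sizes give stable estimates at the
stated tolerances while keeping a full run in minutes on one CPU.

## Known limitations

- The fitted distribution is only as good as the input vector: two samples
  with identical panel counts get identical predictive distributions.
- The germline contamination model is Poisson-additive and
  ancestry-homogeneous within a label; real private-variant burdens vary
  within ancestry groups.
- The linear baseline is intentionally the textbook fixed-variance reading;
  no heteroscedastic linear variant is provided.
- Carrier-fraction self-cohort filtering needs a reasonably large cohort to
  be meaningful; with a handful of samples every private variant clears the
  threshold.
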