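# Methods

This note documents the models, parameter choices, and numerical decisions in
`radiomet`, and what the synthetic experiments do and do not demonstrate.

## Problem setting

Two feature blocks are measured on the same renal tumors: quantitative CT
descriptors (first-order, texture, shape and filtered variants — "radiomics")
and MALDI-MSI metabolite intensities. The cohort has two conditions, benign
oncocytic tumors and malignant renal cell carcinoma, and is small (tens of
samples) and imbalanced. The goal is to find the features whose *network
role* differs between conditions and to quantify how well they classify.

## Preprocessing

**Inter-reader stability filter.** Manual segmentation is the dominant noise
source in radiomics, so features are kept only if they agree between two
readers. For reader values (a, b) per sample, the two-point CV is
`(|a−b|/√2)/|(a+b)/2|`; the per-feature CV is its mean over samples, and
features with CV > `cv_max` (default 0.10) are removed. The per-sample
aggregation is robust to scale differences across samples; an alternative
(CV of the two per-reader mean profiles) is selectable. A sample pair with
zero mean makes the CV infinite, which conservatively fails the feature.
The filter is monotone in `cv_max` and commutes with normalization.

**Normalization.** Columns are z-scored (sample sd, ddof = 1). Constant
columns are dropped with a logged warning. Inside the integration stage each
condition's sample subset is re-z-scored, so per-condition fits are invariant
to global location/scale structure (including the generator's factor means).

## Sparse-PLS association networks

Canonical-mode sparse PLS relates the two z-scored blocks symmetrically
(neither is a response). Per component, the dominant singular pair of the
current cross-covariance is refined by thresholded power iteration: the
candidate loading is soft-thresholded so at most `keep_x` (`keep_y`) entries
stay nonzero, re-normalized to unit L2 norm, and iterated to tolerance 1e−9
(max 500 iterations); both blocks are deflated on their own component scores,
which keeps successive scores orthogonal.

*Multi-start.* The sparse problem max u᷀ᵀMv is non-convex; at n ≈ 15 the dense
leading singular vector is noise-dominated and a single run can converge to a
spurious local optimum. Each component therefore starts from up to 8 leading
right singular vectors and keeps the converged pair with the largest
objective. With no sparsity every start reaches the dominant singular pair,
so the dense fit still matches the SVD oracle.

The association score matrix is M = Σ_h c_h·u_h v_hᵀ (clipped to [−1,1]),
where c_h is the Pearson correlation of the paired component scores. Because
loadings are unit-norm, a factor spread over s features per block yields
entries of order c_h/s — roughly 0.15 for the five-feature factors the
generator plants — *not* on the scale of feature–feature correlations. Edge
thresholds must respect this scale; the pipeline default is τ_assoc = 0.1.

**Defaults (calibrated, fixed once).** `n_components = 1`,
`keep_x = keep_y = 12`, `τ_assoc = 0.1`. With ~15 samples per condition only
the leading cross-covariance direction is estimable with any stability; a
dozen retained loadings per block covers factor supports of realistic size
while limiting noise admission. These values were chosen from the operating
characteristics measured on the synthetic generator (recovery vs false
selection across seeds) and are exposed in `IntegrationParams`.

**Centrality and selection.** Communities come from Louvain modularity
maximization on |weight| (seeded, deterministic numbering). Eigenvector
centrality is computed by power iteration on A + I — the identity shift gives
a strictly dominant eigenvalue on bipartite components, whose spectrum is
otherwise symmetric — restricted to the largest connected component
(ties broken by node id), max-normalized to 1, with EC = 0 outside. Delta
centrality DC = EC_benign − EC_malignant uses EC = 0 for nodes absent from a
network; selection takes |DC| > τ_DC (default 0.1). The absolute mode is the
default because discriminative nodes exist for both conditions; the signed
mode (DC > τ_DC) is available.

## Enrichment and clustering

Over-representation is the plain hypergeometric upper tail P(X ≥ k) with
universe N = all measured metabolites present in the pathway map (standard
ORA practice), pathway size K after intersection with the universe, selection
size n, and overlap k; Benjamini–Hochberg adjustment across pathways;
enrichment ratio (k/n)/(K/N). This is a deliberate simplification relative to
topology-weighted pathway tools: it is exactly specifiable and testable.
Sample clustering is agglomerative with Euclidean distance and Ward linkage
(complete/average/single selectable), cut at k clusters (default 3), cluster
ids renumbered by first appearance for determinism.

## Balancing, classification, evaluation

**SMOTE.** Every class below `target_per_class` (default 20) is grown by
interpolating a random real class member toward one of its `smote_k = 5`
nearest same-class neighbors with uniform(0,1) weight; real samples are kept
bitwise unchanged and synthetic ones flagged. Growing *both* classes mirrors
a 14/19 → 20/20 design; minority-only augmentation is a flag. Balancing
happens before the split by default (matching the emulated design); this
leaks synthetic–real correlations into validation and inflates absolute
AUCs — `smote_after_split=True` gives the leakage-free protocol.

**Split.** Per class: floor(0.6·n) to training, remainder to validation,
seeded permutation.

**Classifier.** XGBoost with logistic objective. The default booster is
*linear* (`gblinear`): with logistic loss the per-sample hessian is ≤ 0.25,
so the default `min_child_weight = 5.31` cannot be satisfied by any split of
a ~24-sample training set and a tree booster degenerates to a constant score;
boosted linear terms learn normally at this scale. The tree booster and its
parameters (gamma 0, max_depth 6, subsample 0.654, colsample 0.564) remain
available by config. 200 rounds with early stopping (20 rounds) on an
internal stratified 20% holdout; if a class is too small to spare holdout
samples, training uses all data without early stopping. Feature importances
are gain-based for trees and |coefficient| for the linear booster.
A random-search tuner draws from standard ranges (eta 0.01–0.3, depth 2–8,
min_child_weight 1–10, subsample/colsample 0.5–1, gamma 0–5) scored by
stratified k-fold CV AUC; SVM and random-forest baselines use library
defaults.

The three models (combined / radiomics-only / metabolite-only) are trained on
column subsets of *one* balanced, split dataset, so their validation samples
are identical — the precondition for paired DeLong tests — and each
single-block model is exactly the combined design restricted to its columns.

**Evaluation.** The ROC sweep groups tied scores; the trapezoid AUC equals
the Mann–Whitney U statistic on every input (ties = ½). CIs are stratified
case-resampling percentile bootstrap (B = 2000, level 0.95); stratification
keeps both classes in every resample. DeLong's test uses midrank structural
components; identical score vectors return p = 1, and zero variance with a
nonzero AUC difference is an error rather than a bogus p-value. Confusion
metrics with empty denominators are reported as null, never as 0. The default
decision threshold is 0.5; a Youden-optimal threshold helper is provided.

## Synthetic-data generator

Per condition, samples draw k latent factors: one *shared* factor loading
`n_shared_coupled_per_block` features in both blocks in both conditions, and
one *condition-specific* factor per condition loading half of the
`n_discriminative_per_block` features per block in that condition only; all
other features are N(0, noise_sd²) noise. For loading a and noise s, two
planted partner features correlate at a²/(a²+s²) (0.5 at the defaults
a = s = 1). Condition-specific factors have mean `factor_mean = 1.0`: planted
features then also differ in level between conditions, which is what makes
the signal visible to Euclidean sample clustering and to a linear classifier;
within-condition correlation structure — and hence the association networks —
is exactly invariant to this mean. Defaults: 14/19 samples, 60/80 features,
10 discriminative + 4 shared per block, seed 7.

Reader replicates multiply each value by a per-feature log-normal factor
(multiplicative because the CV is scale-free): log-sd 0.5 for features
designated unstable (mean CV ≈ 0.28, reliably failing the 10% filter) and
0.02 for stable ones (mean CV ≈ 0.01). Unstable designation is Bernoulli per
feature at `reader_cv_unstable_fraction`; the pipeline's synthetic path and
the study-scale fixture designate unstable features only among unplanted
ones, so the filter emulates segmentation noise without deleting the planted
biology. The study fixture reproduces the cohort geometry: 944 raw radiomics
features of which exactly 700 survive the filter, and 771 metabolites, at
scale 1 (proportional at smaller scales, floor 20 per block).

The pathway map is GMT-style: one pathway holds 80% of the planted
discriminative metabolites (padded to size 10), the rest draw uniformly from
the metabolite universe.

## What the synthetic experiments show — and don't

*Recovery.* At the generator's default conditions (seed 7), delta-centrality
selection recovers 80% of planted features with 8.3% false selections. Across
other seeds mean recovery is ≈ 0.5–0.6 at ≈ 10% false selection: with 14–19
samples, a planted pair correlation of 0.5 sits at the detection limit — the
empirical null correlation has sd ≈ 0.28, and among ~4,800 null pairs many
exceed the planted effect size — so recovery is intrinsically seed-dependent.
Passing tests demonstrate the machinery is correct and calibrated, not that
the method is reliable at these sample sizes.

*Model ordering.* In this generative design any latent factor that couples
the blocks is, by construction, common to both blocks, so the two blocks
carry largely redundant class information: the combined panel's theoretical
discriminability exceeds a single block's by only a few percent, and with an
8 + 8 validation set the combined model beats both single-block models in
roughly half the seeded runs rather than consistently. Real multi-modal data
can behave differently (modality-specific signal plus partial coupling); the
generator cannot express that without weakening the planted cross-block
correlation that the network stage needs.

*Statistical sanity.* Percentile-bootstrap coverage for the AUC measures
≈ 92–94% at the nominal 95% on binormal scores (n = 50/50) — the familiar
slight undercoverage of the percentile method at moderate n.

## Degenerate inputs and numerical conventions

Zero cross-covariance yields zero components and an empty network (handled,
warned). Empty networks skip centrality; missing nodes take EC = 0.
Exact-zero association scores never form edges, even at τ = 0. Sparse-PLS
signs are fixed by making the largest-|u| entry positive (the (u, v) pair
flips together). Community ids and cluster ids are renumbered deterministically.
All randomness flows from one global seed through stable per-stage hashes
(`derive_seed`), so any stage is reproducible in isolation; seeds stay below
2³¹.

## Problem sizes used by the shipped experiments

Tests run the generator at its 60/80-feature desk scale (the study-scale
33 × 944/771 fixture is exercised for shape and filtering contracts), 20-run
pipeline sweeps for the ordering experiment, and 200 × 2000-resample
bootstrap simulations for coverage; the acceptance script repeats these plus
one full study-scale pipeline run.
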