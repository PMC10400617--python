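# radiomet

Radiometabolomics data integration: a tested, reusable pipeline that relates a
CT-radiomics feature block and a mass-spectrometry-imaging metabolite block
measured on the same tumors, finds the features that discriminate benign
oncocytic from malignant renal lesions through condition-specific association
networks, and evaluates how well those features classify.

It is written for computational biologists and imaging scientists who have two
sample × feature tables (radiomics and metabolomics), a benign/malignant label
per sample, and optionally a GMT pathway annotation — and who want the whole
chain from reader-stability filtering to DeLong-compared classifiers in one
reproducible run. Because matched radiomics–metabolomics cohorts are rarely
public, the package ships a synthetic-data generator with planted ground truth
so every stage can be validated end to end.

## Method

1. **Preprocess.** Radiomics features segmented by two readers are filtered by
   inter-reader coefficient of variation: per feature, the two-point CV
   `sd(a,b)/|mean(a,b)|` is averaged over samples and features with CV > 10%
   are dropped. Both blocks are then z-score normalized.
2. **Integrate per condition.** For each condition c ∈ {benign, malignant},
   a canonical-mode sparse PLS is fitted to the condition's samples: each
   component is the dominant singular pair (u_h, v_h) of the current
   cross-covariance XᵀY, soft-thresholded to at most keepX/keepY nonzero
   loadings, iterated to convergence, with canonical deflation between
   components. An association matrix

       M(c) = Σ_h c_h · u_h v_hᵀ,   c_h = corr(X u_h, Y v_h),

   is thresholded at |M_ij| ≥ τ to give a bipartite radiomics–metabolite
   network; Louvain communities and eigenvector centrality EC(c) (power
   iteration on the largest connected component, max-normalized to 1) describe
   it.
3. **Select.** Delta centrality DC = EC(benign) − EC(malignant) per node;
   nodes with |DC| > 0.1 are the condition-discriminative panel (a signed
   DC > 0.1 mode is available).
4. **Characterize.** Selected metabolites go through hypergeometric
   over-representation against the pathway map (BH-adjusted, enrichment ratio
   (k/n)/(K/N)) and Ward/Euclidean hierarchical clustering of samples.
5. **Classify and evaluate.** The cohort is SMOTE-balanced to 20 samples per
   class, split 60:40 by class, and an XGBoost model (linear booster, eta
   0.104, early stopping) is trained for three panels — combined,
   radiomics-only, metabolite-only. Each model is scored by ROC/AUC with a
   2000-resample stratified percentile bootstrap CI, confusion metrics at the
   0.5 threshold, and pairwise DeLong tests on the shared validation set.

## Worked example

Run the full pipeline on the built-in synthetic study (14 benign / 19
malignant tumors, 60 radiomics × 80 metabolite features, 10 planted
discriminative features per block):

```bash
radiomet run --seed 5 --outdir demo_run
```

prints

```
selected nodes: 26 (11 radiomics + 15 metabolites)
  combined: AUC 92.2% [71.9, 100.0]
  radiomics_only: AUC 82.8% [56.2, 100.0]
  metabolomics_only: AUC 71.9% [42.2, 93.8]
report written to demo_run/report.json
```

Reading: delta-centrality selection returned a 26-node panel (the planted
truth at this seed is 10 + 10 discriminative features; the report's
`ground_truth` section shows which selections are planted vs spurious). The
three AUC lines are validation-set performance of the combined and
single-block classifiers with 95% bootstrap CIs; `demo_run/` also holds the
per-condition networks (GraphML + edge lists), the centrality table, the
enrichment table, the balanced dataset, and `report.json` with DeLong
comparisons and provenance (config hash, seed). Identical config + seed
reproduces the report bit for bit.

The same run is available from Python:

```python
from radiomet import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=5))
print(report.selection["n_selected"])
```

Subcommands `simulate`, `preprocess`, `integrate`, `enrich`, `classify` and
`evaluate` expose the individual stages on delimited text files; see
`radiomet <cmd> --help`.

## Limitations

The generator plants condition-specific latent-factor coupling; with ~15
samples per condition the sparse-PLS selection operates near its detection
limit, so recovery varies across seeds (see `docs/methods.md` for the
operating characteristics and for why the two blocks carry largely redundant
class information in this generative design).
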