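# lipidscore

Plasma lipidomics analysis for critical-illness cohorts: preprocessing of
wide concentration matrices, outcome-stratified differential analysis,
construction and application of a composite lipid reprogramming score (LRS),
constraint-based causal graph discovery on mixed clinical data with
cross-validated α-selection, correlation-network / Kaplan–Meier recovery
analyses, and prognostic model comparison. A synthetic cohort generator with
planted ground truth makes every stage testable without external data.

## Layout

| module | contents |
| --- | --- |
| `lipidscore.nomenclature` | lipid label parsing (`CLASS(c:d_c:d…)`, `/`-dialects, summed TAG) |
| `lipidscore.data` | `LipidomicsMatrix`, `ZMatrix`, `CohortTable`, TSV/CSV I/O |
| `lipidscore.preprocess` | missingness filter, minimum imputation, class summaries, z-scoring |
| `lipidscore.outcomes` | resolving / non-resolving / early-nonsurvivor labelling |
| `lipidscore.embed` | PCA → UMAP embedding (reporting only) |
| `lipidscore.simulate` | trauma / severity cohort generators, SEM sampler, reference suite |
| `lipidscore.differential` | covariate-adjusted logistic screen (BH-FDR), Wilcoxon screen |
| `lipidscore.lrs` + `lipidscore.pipeline` | candidate pooling, sign-consistency screen, sensitivity selection, scoring, tertiles |
| `lipidscore.causal` | mixed-data CI tests, PC-stable + FCI orientation rules, Markov blanket, LOOCV α-selection |
| `lipidscore.assoc` | correlation matrices/network (vst-style selection), recovery KM, clustered outcome models |
| `lipidscore.prognostic` | k-fold model comparison (AUC/Brier/calibration), LASSO→SVM feature ranking |

## CLI

All stages are exposed through a single entry point:

```bash
# synthetic data with planted truth
lipidscore simulate trauma --seed 1 --out sim/
lipidscore simulate sem --config sem.yaml --seed 1 --out sim_sem/

# preprocessing: filter > impute > z-score + JSON report
lipidscore preprocess --matrix sim/matrix.tsv --max-missing 0.2 --out prep/

# differential lipids (logistic or wilcoxon rule)
lipidscore diff --matrix sim/matrix.tsv --cohort sim/cohort.tsv \
    --rule logistic --out diff.tsv

# LRS construction and scoring
lipidscore lrs build --train sim/matrix.tsv --cohort sim/cohort.tsv \
    --aux severity:c1:covid/matrix.tsv:covid/cohort.tsv --out model.json
lipidscore lrs score --model model.json --matrix new.tsv --out scores.tsv

# causal discovery with cross-validated alpha
lipidscore causal --data d.tsv --types types.tsv --target early_death \
    --grid 0.01,0.05,0.1,0.15,0.2,0.25 --out pag.json --graphml pag.graphml

# correlation network / recovery analysis
lipidscore assoc network --matrix sim/matrix.tsv --r-thresh 0.7 --out net
lipidscore assoc recovery --cohort sim/cohort.tsv --out recovery

# prognostic feature-set comparison
lipidscore prognostic --data d.tsv --outcome y --models models.yaml \
    --out report.json
```

Matrices are wide TSV/CSV (first column sample id, remaining columns
canonical lipid labels, missing as empty or `NA`); cohort tables are per
sample-timepoint rows with 0/1 booleans.

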