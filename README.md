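# mapsig

Derivation and survival evaluation of a short proliferation gene-expression
signature — the MAPS (MUC1-Associated Proliferation Signature) workflow —
as a tested, reusable Python pipeline.

## The problem

Transfecting fibroblasts with the cytoplasmic domain of the MUC1
oncoprotein (MUC1-CD) rewires transcription toward cell-cycle and
proliferation programs. The analysis this package implements asks whether
the genes induced by that transformation carry prognostic information in
lung adenocarcinoma, and compresses them into a signature small enough for
clinical assays:

1. **Two-condition contrast** (transfected vs. empty-vector cell lines on
   duplicated microarrays): global median normalization, ROC-estimated
   signal-intensity filtration, linear fold changes, and SAM-style
   moderated statistics `d_i = (x̄₁ᵢ − x̄₂ᵢ)/(sᵢ + s₀)` with an
   exhaustively enumerated permutation null (4!/2!2! = 6 relabelings for a
   2+2 design) and a false-discovery-ratio scan over the band half-width
   δ. Probes passing both the two-sided 2.0-fold cutoff and the SAM call
   become the differential gene set.
2. **Outcome-blind cohort reduction**: patient expression is normalized to
   each gene's cohort median and log2-transformed; near-constant genes
   (IQR < 0.5 log2 units) are eliminated; k-means (k = 2, 50 restarts)
   partitions the patients; per gene, a variance-ratio F-test chooses
   between pooled and Welch t statistics (α = 0.05, no multiplicity
   correction); surviving genes are ranked by their empirical
   (Mann–Whitney) AUC as single-feature classifiers of cluster membership,
   and genes with AUC > 0.95 form the signature. Survival data are never
   consulted during derivation.
3. **Scoring and survival**: a patient's score is the mean normalized log2
   expression over the signature genes (down-oriented genes sign-flipped);
   score > 0 ⇒ MAPS+. Prognostic value is assessed with Kaplan–Meier
   curves, the log-rank test, and univariate/multivariate Cox proportional
   hazards (Efron ties) against binary T stage (T1-2 vs T3-4), nodal
   status (N0 vs N1-2) and grade (1 vs 2-3) — all implemented from the
   estimating equations in `mapsig.survival`.

Because the original cohorts are external data, the package ships a
fully ground-truthed synthetic generator (`mapsig.simulate`): duplicated
arrays with planted fold changes and a low-intensity background
population, and survival-linked cohorts in which a latent proliferation
factor z (two-component Gaussian mixture) drives a correlated 7-gene
module and the hazard of death, `h(t) = h₀ exp(β_z z + β_T T + β_N N)`,
with administrative censoring.

## Worked example

```bash
mapsig simulate --seed 7 --out demo
mapsig derive --seed 7 --out demo_run \
    --cell-matrix demo/cell_matrix.tsv --cohort-matrix demo/cohort_matrix.tsv \
    --clinical demo/clinical.csv --annotation demo/annotation.tsv
```

prints (abridged):

```
gene counts:
  probes_input: 1300
  probes_post_filtration: 980
  differential_genes: 90
  cohort_genes: 90
  post_elimination: 73
  post_t_test: 10
  signature: 7
partition sizes (expressor_candidate/other): 225/216
5-year survival:
  MAPS_neg: 74.9%
  MAPS_pos: 21.7%
log-rank: chi2=141.4019 p=1.314e-32
Cox proportional hazards:
              variable  p_univariate  p_multivariate  HR_multivariate
T stage (T1-2 vs T3-4)        0.0263          0.3574            1.203
  N stage (N0 vs N1-2)     7.705e-16       5.079e-13            2.441
      Grade (1 vs 2-3)        0.2683          0.8198            1.038
     MAPS (neg vs pos)     9.467e-29       7.245e-27             4.05
```

Reading this: 90 genes came out of the cell-line contrast; 17 were flat
across patients and eliminated; 10 discriminated the two k-means clusters
at α = 0.05; 7 had AUC > 0.95 — here exactly the seven genes planted by
the simulator (CDC20, RRM2, CCNB1, MAD2L1, PRC1, CDC2, CDKN3). Expressors
(MAPS+) have far worse 5-year survival (21.7% vs 74.9%), and the signature
remains an independent prognostic factor (multivariate HR ≈ 4) alongside
nodal status, mirroring the structure the generator planted. The run
directory contains every intermediate table (`differential.tsv`,
`partition.csv`, `selection.tsv`, `signature.tsv`, `scores.csv`,
`km_<class>.tsv`, `cox.tsv`, `report.txt`), each stamped with the config
hash and seed.

The same machinery is available as a library of sklearn-style estimators:

```python
from mapsig import CohortSimConfig, SignatureDeriver, simulate_cohort, cohort_median_normalize

expr, clinical, truth = simulate_cohort(CohortSimConfig(seed=7))
deriver = SignatureDeriver(random_state=7).fit(cohort_median_normalize(expr))
deriver.signature_.gene_symbols   # ['CDC20', 'CCNB1', 'RRM2', ...]
scores = deriver.transform(cohort_median_normalize(expr))
```

Validation of a frozen signature on an independent cohort (normalized
within itself, missing genes skipped) is `mapsig validate`, or
`mapsig.validate_signature` in code.

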