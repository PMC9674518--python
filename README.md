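# thyrotype

Transcriptome-based molecular subtyping of thyroid nodules — a tested,
reusable implementation of the analysis pipeline used to stratify papillary
thyroid carcinoma (PTC) and benign thyroid nodules (BTN) from bulk RNA-seq
expression profiles.

## Who this is for

Computational biologists who have a gene-by-sample RPKM matrix for a
nodule/adjacent-tissue cohort and want to:

- discover molecular subtypes by **consensus non-negative matrix
  factorization** (NMF) and extract per-subtype exemplar and marker genes;
- transfer those subtypes to an external cohort with **Nearest Template
  Prediction** (NTP);
- score samples for **thyroid differentiation** (TDS), **immune**,
  **stromal** and T-cell-inflamed **GEP** activity;
- find **hub genes** with an ARACNe-style mutual-information network, DPI
  pruning, Maximal Clique Centrality and pre-ranked GSEA;
- order samples on a benign→malignant **pseudotime trajectory** and test
  branch-dependent expression (a BEAM-style likelihood-ratio test);
- apply the standard post-call **filters** for fusion and somatic-mutation
  candidates;
- build a compact **diagnostic gene signature** (RFE over logistic
  regression, cross-validated, benchmarked against SVM/NB/RF/KNN by
  ROC/AUC).

Because the matching clinical cohort is not publicly available, the package
ships a first-class synthetic-data module that plants known subtype
structure, immune gradients, trajectories and variant-filter boundary cases,
so every stage is testable against ground truth.

## The core methods, briefly

**Consensus NMF.** The filtered log2 matrix V (genes × samples) is
factorized V ≈ WH, W,H ≥ 0, by Lee–Seung multiplicative updates on
‖V − WH‖_F. Samples are assigned by argmax over their column of H; the
consensus matrix C_ij is the co-assignment frequency over random restarts,
and the cophenetic correlation of 1 − C measures stability. Exemplar genes
of factor i are ranked by the margin W[g,i] − max_{j≠i} W[g,j].

**NTP.** A sample's standardized profile over the union of marker genes is
compared to each subtype's unit-normalized marker-indicator template by
cosine distance; significance comes from redrawing marker sets at random.

**TDS.** TDS(s) = Σ_g (log2(RPKM+1)[g,s] − median_s' log2(RPKM+1)[g,s'])
over the 16 thyroid differentiation genes.

**MI network.** Plug-in mutual information on equal-frequency bins; edges
below a permutation-null threshold are dropped; the data-processing
inequality removes the weakest edge of each triangle; hubs are ranked by
MCC(v) = Σ_{cliques C ∋ v} (|C|−1)!.

**Trajectory.** PCA → k-means centroids → minimum spanning tree; pseudotime
is geodesic distance from the centroid nearest the benign-adjacent samples;
the first degree-≥3 node past the root is the bifurcation. Branch-dependent
genes are found by a Gaussian likelihood-ratio test of branch-specific
spline trends.

**Diagnosis.** Stratified 80/20 split; RFE over L2 logistic regression with
pooled 4/6/8/10-fold CV AUC per subset size and the one-standard-error rule
for panel choice; five classifier families evaluated by held-out ROC/AUC.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from thyrotype import log2_transform
from thyrotype.synthetic_data import SimulationSpec, simulate_cohort
from thyrotype.subtyping import filter_genes, fit_consensus_nmf, rank_exemplar_genes
from thyrotype.scoring import ssgsea_score
from scipy.stats import spearmanr

cohort = simulate_cohort(SimulationSpec(seed=7))
nodules = cohort.samples[cohort.samples.tissue == "nodule"]
expr = cohort.expression.subset_samples(nodules.sample_id.tolist())

fm = filter_genes(expr)
print(f"retained {fm.n_retained} of {fm.n_input_genes} genes "
      f"({fm.n_removed_low_expression} low-expression, {fm.n_removed_low_cv} low-CV)")

nmf = fit_consensus_nmf(log2_transform(fm.matrix), k=6, restarts=30, seed=7)
print(f"cophenetic correlation: {nmf.cophenetic:.3f}")
ari = adjusted_rand_score(nodules.true_subtype, nmf.assignments.loc[nodules.sample_id])
print(f"adjusted Rand index vs planted subtypes: {ari:.3f}")

top = rank_exemplar_genes(nmf, 0).head(3)
print("factor 1 exemplars:", ", ".join(top.gene))

immune = ssgsea_score(expr, cohort.immune_genes, tau=0.25)
rho = spearmanr(immune.loc[nodules.sample_id], nodules.immune_level).statistic
print(f"immune score vs planted infiltration (Spearman): {rho:.3f}")
```

Output:

```
retained 165 of 1000 genes (80 low-expression, 755 low-CV)
cophenetic correlation: 1.000
adjusted Rand index vs planted subtypes: 1.000
factor 1 exemplars: G0174, G0165, G0179
immune score vs planted infiltration (Spearman): 0.987
```

The filter keeps mostly the planted marker blocks (the uninformative
background fails the variability rule), the six-factor consensus NMF
recovers the planted subtypes exactly (ARI 1.0) with a perfectly stable
consensus (cophenetic 1.0), the factor-1 exemplars are planted markers of
the subtype that factor captured, and the per-sample immune enrichment
score tracks the planted infiltration gradient.

The same pipeline is available from the shell:

```bash
thyrotype simulate --kind cohort --seed 7 --out sim/
thyrotype subtype --expr sim/expr.tsv --k 6 --restarts 30 --seed 7 --out subtypes/
thyrotype score --expr sim/expr.tsv --out scores.tsv
thyrotype diagnose --expr sim/expr.tsv --meta sim/meta.tsv --seed 7 --out diagnosis/
```

Re-running any subcommand with the same inputs and seed reproduces its
outputs byte for byte.

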