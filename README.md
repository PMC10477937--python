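# clustannot

Reference-based cell-type annotation for single-cell RNA-seq **clusters**.

After clustering an scRNA-seq dataset, each cluster needs a cell-type
label. `clustannot` transfers labels from an annotated reference dataset
to the query clusters by comparing cluster-level average expression
profiles — it never touches individual cells at prediction time, which
makes it fast enough to screen a query against many candidate references.
It is aimed at analysts who already have a clustered counts matrix (from
Seurat, Scanpy, or similar) and an annotated dataset of the same or a
related tissue to borrow labels from.

## Method

All profiles are pseudobulk: raw counts summed per cluster, scaled to
counts-per-10⁵ and log(1 + x) transformed.

**Reference preparation.** The reference is co-embedded and jointly
clustered with a broad multi-tissue *background atlas* (k-NN graph +
Leiden on a user-supplied joint embedding, or a built-in joint-PCA
fallback). From the joint clustering we form:

- `Eb` — genes × combined-cluster profile matrix of the joint clustering;
- `Wb` — a column-stochastic matrix whose entry (c, t) is the fraction of
  type-t reference cells in combined cluster c;
- `Er = Eb · Wb` — corrected genes × cell-type reference profiles;
- `Er-sub` — profiles of low-resolution sub-clusters found inside each
  annotated cell type (capturing sub-type heterogeneity);
- three marker sets (background / main-type / sub-cluster), scored by a
  specificity cosine: score(g, k) = e_gk / ‖e_g‖₂.

**Prediction** runs in three stages for a query profile `Eq`:

1. *Screen.* Pool the correlations corr(Eq, Eb) on background markers and
   decompose them into 1–3 Gaussians (deterministic EM, BIC). The cutoff
   is the 0.75 quantile of the single component (k = 1), the weighted
   density intersection of the two components (k = 2), or the 0.75
   quantile of the middle component (k = 3), clamped to [0.4, 0.6].
   Query clusters whose best corr(Eq, Er) stays below the cutoff are
   **unassigned**.
2. *Assign.* The same cutoff machinery on corr(Eq, Er-sub) over main-type
   markers. One sub-cluster above the cutoff (or several from a single
   cell type) decides the label; several from different cell types go on.
3. *Resolve.* For the top ≤ 3 candidate sub-clusters, one-sided Wilcoxon
   rank-sum tests compare each candidate's sub-markers against the
   others' within the query cluster; the candidate with the largest
   summed −log₁₀(p) wins.

Cross-species queries are handled by symbol-overlap species detection
(> 50 % rule) and one-to-one ortholog translation.

## Worked example

Everything below runs offline from the built-in generator (scenario 1:
query and reference share the same five cell types, different "platform"):

```sh
clustannot simulate --scenario 1 --seed 5 --n-types 3 --n-genes 1200 \
    --cells-per-type 30 --out fixture
clustannot prepare-ref \
    --counts fixture/reference_counts.tsv \
    --labels fixture/reference_labels.tsv \
    --background-counts fixture/background_counts.tsv \
    --background-labels fixture/background_labels.tsv \
    --species human --out bundle
clustannot predict --query fixture/query.tsv --ref bundle --out pred.tsv
clustannot evaluate --predictions pred.tsv --truth fixture/truth.tsv \
    --ref-types type00,type01,type02 --out outcomes.tsv
```

The final command prints

```
{"correct": 1.0, "correct_partial": 0.0, "correct_unclassified": 0.0,
 "failed": 0.0, "success": 1.0, "wrong": 0.0, "wrong_unclassified": 0.0}
```

i.e. all three query clusters were assigned their true type. `pred.tsv`
holds one row per query cluster with the predicted type, the winning
sub-cluster, the best stage-1/stage-2 correlations, the two adaptive
cutoffs, and which stage decided. An `unassigned` status means no
reference cell type passed the calibrated cutoff — the expected outcome
when the reference does not contain the query's cell types.

The same flow is available as library calls (`make_pair`,
`build_reference`, `predict`, `evaluate_predictions`); see the module
docstrings.

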