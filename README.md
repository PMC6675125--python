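# edtmda

Ensemble-of-decision-trees prediction of miRNA–disease associations from a
binary association matrix, a miRNA functional-similarity matrix, and a
disease-DAG corpus.

The pipeline:

1. **Similarity** — two DAG-based disease semantic-similarity models
   (distance-decay and DAG-frequency information content), Gaussian
   interaction-profile (GIP) kernels for miRNAs and diseases computed from
   the association matrix, and integrated `SM`/`SD` matrices with GIP
   fallback for entities lacking functional similarity or a DAG.
2. **Features** — per-entity feature matrices (32 columns per side by
   default): statistical summaries of the similarity rows, graph centralities
   of the weighted similarity network, and truncated-SVD factors of the
   association matrix plus degree statistics.
3. **Ensemble** — M = 50 base learners. Each draws a fresh balanced negative
   sample from the unlabeled pairs, a random feature subset
   (`d1 = floor(0.8 * d)` columns shared by both sides), fits one PCA per
   side (10 components), splices the reduced miRNA and disease vectors into a
   20-dimensional pair vector, and grows a CART regression tree from scratch
   by exact squared-error splitting. Scores are the mean tree output.
4. **Evaluation** — global/local leave-one-out and repeated 5-fold
   cross-validation with per-fold recomputation of the GIP kernels,
   similarities and features (a fingerprint guard makes stale features a hard
   error), Mann–Whitney rank AUC with an explicit ROC sweep, a
   label-randomization control, and a random-forest-style bagging baseline.
5. **Synthetic** — a planted-block fixture generator (association matrix,
   functional similarity, DAG corpus) so the whole pipeline is testable
   offline.

## CLI

```sh
# generate synthetic fixtures
edtmda simulate --seed 1 --out fixtures/

# train and persist a model
edtmda train --assoc fixtures/Y.tsv --mirna-sim fixtures/FS.tsv \
    --dag-edges fixtures/dag_edges.tsv --dag-roots fixtures/disease_roots.tsv \
    --out model/

# score all candidate pairs / rank candidates for one disease
edtmda predict --assoc fixtures/Y.tsv --mirna-sim fixtures/FS.tsv \
    --dag-edges fixtures/dag_edges.tsv --dag-roots fixtures/disease_roots.tsv \
    --model model/ --out scores.tsv
edtmda rank --assoc fixtures/Y.tsv --mirna-sim fixtures/FS.tsv \
    --dag-edges fixtures/dag_edges.tsv --dag-roots fixtures/disease_roots.tsv \
    --model model/ --disease dis-000 --top 50

# cross-validation (kfold | global-loocv | local-loocv; --fast approximates
# LOOCV by training once; --shuffle-labels runs the randomization control)
edtmda evaluate --assoc fixtures/Y.tsv --mirna-sim fixtures/FS.tsv \
    --dag-edges fixtures/dag_edges.tsv --dag-roots fixtures/disease_roots.tsv \
    --protocol kfold --repeats 10 --out result.json
```

Configuration files are YAML with the fields of `EnsembleConfig` /
`SyntheticConfig`; CLI flags override them.

## File formats

- **Matrices** (`Y.tsv`, `FS.tsv`, score matrices): TSV with a header row of
  column ids (empty leading cell) and row ids in the first column.
- **DAG corpus**: `dag_edges.tsv` (child `TAB` parent) plus
  `disease_roots.tsv` (disease `TAB` its own term).
- **Predictions**: long-format TSV `disease, mirna, score, rank`, candidates
  only, ranked per disease.

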