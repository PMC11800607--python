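# dtitwins

Drug–target interaction (DTI) prediction from 1D inputs — SMILES strings
and amino-acid sequences — using a cross-modal Barlow Twins network as a
feature extractor and a gradient-boosted tree ensemble as the predictor,
with a leaf-index Jaccard method that explains individual predictions by
ranking the training samples that influenced them.

The package is aimed at computational chemists and ML practitioners who
want a structure-agnostic DTI model that works in low-data regimes, plus a
fully synthetic, planted-rule benchmark to validate the pipeline end to end
without downloading external corpora.

## The method

A molecule is encoded as a binary circular fingerprint (default 1024 bits,
radius 2); a protein as a 20×l_max one-hot encoding or a precomputed
language-model embedding read from a table. One MLP encoder per modality
feeds a shared projector, trained self-supervised (no labels) by the
redundancy-reduction objective

    L_BT = Σ_i (1 − C_ii)²  +  λ Σ_{i≠j} C_ij²,
    C_ij = Σ_b zA_bi zB_bj / (‖zA_i‖ ‖zB_j‖),

which drives the batch cross-correlation matrix between the two modalities'
projections toward the identity. After pretraining, each record's joint
embedding is the concatenation of the two encoder outputs, and an XGBoost
head is trained on embeddings + labels (hyperparameters searched against a
validation objective, ROC AUC + PR AUC). Predictions are explained by
comparing leaf-index vectors: with m matching leaves over T trees, a
training sample's influence on a query is J = m/(2T − m), and the
most influential sample is the Jaccard argmax. See `docs/methods.md` for
the full account.

## Worked example

```python
import dtitwins as dt

# planted-rule benchmark: 2000 molecule/protein pairs; a pair interacts
# iff the molecule has a carboxylic acid AND the protein contains HKWW,
# with 5% label noise
result = dt.run_pipeline(seed=2, n_trials=25)
print(result.metrics)

ranking, sims = dt.pipeline.influence_for_query(result, query_index=0, top_k=3)
for s in ranking:
    print(s.record_id, round(s.similarity, 3))
```

Output:

```
{'roc_auc': 0.9476865638472822, 'pr_auc': 0.9214303673401019}
r000088 0.218
r000689 0.216
r000397 0.213
```

The test ROC AUC of ~0.95 means the hybrid model recovered the planted
conjunctive rule from the noisy labels nearly up to the fixture's noise
ceiling; the influence lines name the three training pairs whose leaf-index
vectors best match the first test query (J = 1.0 would be an exact
leaf-for-leaf match).

The same steps are available as a CLI:

```bash
dtitwins --seed 2 simulate --out dti.csv
dtitwins --seed 2 splits --table dti.csv --scheme random --out splits.tsv
dtitwins --seed 2 featurize --table dti.csv --out features.npz
dtitwins --seed 2 pretrain --features features.npz --table dti.csv \
         --splits splits.tsv --out bt_model
dtitwins --seed 2 train --features features.npz --table dti.csv \
         --splits splits.tsv --bt-model bt_model --feature-recipe embeddings \
         --optimize --trials 25 --out hybrid
dtitwins --seed 2 predict --model hybrid --features features.npz --out scores.csv
dtitwins --seed 2 explain --model hybrid --train-features features.npz \
         --query-features features.npz --top-k 10 --out influence.csv
```

Every command writes a `.manifest.json` recording inputs, seed and a config
hash. Cold-start evaluation uses `--scheme unseen_ligand` or
`--scheme unseen_protein`, which partition unique molecules/proteins so no
test entity is ever seen in training. `dtitwins benchmark` runs replicates
of several pipeline variants and emits a Welch-t/Benjamini–Hochberg
comparison table.

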