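# synscreen

Multimodal machine learning for drug-combination synergy prediction on
cell-line screens.

## The problem

Large combination screens such as NCI-ALMANAC measure a synergy score
(ComboScore) for triplets ⟨cell line, drug A, drug B⟩ — tens of cell
lines crossed with every unordered pair from a panel of ~10² compounds.
Predicting that score from what we know about the cell line (expression,
mutations, copy number) and the drugs (their structures) is a regression
problem with two awkward features: the two drugs of a pair are
interchangeable, and generalization claims differ sharply depending on
whether the model has seen the drugs, the cell line, or just the
specific pair before. `synscreen` is a library for building, training,
comparing and interpreting such models end to end, with a seeded
synthetic-screen generator whose ground truth is retrievable, so every
stage can be validated exactly.

## The model

A triplet is scored by a multimodal neural regressor

```
ŷ(c, a, b) = h( [ f_expr(x_c) ‖ f_mut(m_c) ‖ f_cnv(v_c) ‖ g(d_a) ‖ g(d_b) ] )
```

where each input block has its own feature-encoding subnetwork, the drug
encoder `g` is **shared** between the two drugs of a combination, and the
head `h` is a dense network ending in a single linear unit, trained with
MSE, Adam, mini-batches of 64 and validation-loss early stopping
(patience 15, best weights restored). The drug encoder family is
configurable over the six representations evaluated here: 1024-bit
Morgan (ECFP4-equivalent) and layered fingerprints, tokenized one-hot
SMILES (TextCNN), molecular graphs (GCN or GAT), precomputed 512-d
embeddings, and bare one-hot identifiers as a diagnostic baseline.
Expression can enter as gene-list selections, UMAP embeddings,
co-expression module eigengenes, or 1D/2D gene images ordered by
chromosome position or by correlation clustering with exact optimal leaf
ordering. Classical regressors (elastic net, linear/Nystroem SVR, random
forest, gradient boosting, XGBoost, LightGBM) share the predict
contract, and a heterogeneous ensemble simply averages member
predictions. Trained models are interpreted with Shapley-value
attributions (exact enumeration oracle plus a permutation-sampling
backend), grouped importances, waterfall decompositions, and pre-ranked
gene set enrichment on attribution-ranked genes.

The neural stack — including the reverse-mode autodiff it runs on — is
implemented in numpy inside the package and verified against finite
differences; featurization uses RDKit, scikit-learn, scipy and
umap-learn.

## Worked example

`examples/05_train_multimodal.py` generates a noiseless 10-cell-line ×
8-drug screen, trains the dense/Morgan model, and compares it with the
mean-score baseline:

```
trained 150 epochs; best validation epoch 142 (weights restored)
multimodal  test R^2 = 0.994, Spearman = 0.997
mean baseline test R^2 = -0.000
```

R² ≈ 1 on the noiseless screen means the model recovered the planted
structure almost exactly; the baseline's R² ≈ 0 is the no-skill floor.
The other scripts in `examples/` walk through screen simulation, table
canonicalization, omics and drug featurization, budgeted tuning plus
ensembling, and attribution-based interpretation, each printing the
numbers it computes.

A thin CLI covers the file-oriented stages:

```sh
synscreen simulate --seed 1 --out screen/
synscreen ingest --screen screen/triplets.csv --out canonical/
synscreen gsea --ranking ranking.tsv --gmt sets.gmt --out gsea.tsv
```

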