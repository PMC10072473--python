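"""Cell-line featurization: selection, scaling, eigengenes, gene images.

Expression features can enter a model as gene-list selections (min-max
scaled on the training partition only), as co-expression module
eigengenes, or reordered into 1D/2D image tensors for convolutional
encoders — either by chromosome position or by correlation clustering
with exact optimal leaf ordering.
"""

import numpy as np

from synscreen.omics_features import (
    GeneList,
    fit_apply_minmax,
    module_eigengenes,
    order_by_clustering,
    reshape_to_image,
    select_genes,
    unreshape_image,
)
from synscreen.synthetic import SyntheticScreenSpec, generate_screen

bundle = generate_screen(
    SyntheticScreenSpec(n_cell_lines=30, n_drugs=2, n_genes=60, n_modules=3, seed=5)
)
expr = bundle.expression

panel = GeneList("panel", frozenset(expr.gene_symbols[:40]))
selected = select_genes(expr, panel, drop_constant=True)
print(f"gene-list selection: {expr.n_features} -> {selected.n_features} genes")

scaled_train, _, state = fit_apply_minmax(selected.values[:20], [selected.values[20:]])
print(f"train scaled into [{scaled_train.min():.2f}, {scaled_train.max():.2f}] "
      "(validation/test reuse the train bounds, unclipped)")

modules = module_eigengenes(expr, n_modules=3)
sizes = {m: list(modules.module_assignment.values()).count(m)
         for m in sorted(set(modules.module_assignment.values()))}
print(f"co-expression modules (planted 3): sizes {sizes}, "
      f"eigengene matrix {modules.eigengenes.shape}")
# eigengenes condense each module to one feature per cell line; their
# explained-variance ratios show how coherent each module is:
print("explained variance per module:",
      {m: round(v, 2) for m, v in modules.explained_variance_ratio.items()})

layout = order_by_clustering(expr)
tensor, concrete = reshape_to_image(expr.values[0], layout, mode="2d")
print(f"gene image: {expr.n_features} genes -> {tensor.shape} grid "
      f"with {concrete.pad_count} zero pads; "
      f"round-trip exact: {np.array_equal(unreshape_image(tensor, concrete), expr.values[0])}")
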