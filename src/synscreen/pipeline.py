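"""End-to-end conveniences: from a screen bundle to model-ready tensors.

These helpers wire the pieces together the way the analysis protocol
prescribes — canonical triplets, per-drug featurization, triplet-level
splitting, min-max scaling fitted on the training partition only — and
are what the examples and the acceptance pipeline drive.
"""

from __future__ import annotations

import numpy as np

from synscreen.drug_features import (
    layered_fingerprint,
    morgan_fingerprint,
    one_hot_identity,
)
from synscreen.evaluation import SplitSpec
from synscreen.nn.model import _take
from synscreen.omics_features import MinMaxScalerState
from synscreen.synthetic import ScreenBundle

__all__ = ["build_dataset", "scale_expression", "take_inputs", "input_shapes"]


def _drug_matrix(bundle: ScreenBundle, scheme: str) -> dict[str, np.ndarray]:
    drug_ids = list(bundle.drug_smiles)
    if scheme == "morgan":
        return {d: morgan_fingerprint(s).bits.astype(float) for d, s in bundle.drug_smiles.items()}
    if scheme == "layered":
        return {d: layered_fingerprint(s).bits.astype(float) for d, s in bundle.drug_smiles.items()}
    if scheme == "onehot":
        return {d: one_hot_identity(d, drug_ids).astype(float) for d in drug_ids}
    raise ValueError(f"unknown drug featurization scheme {scheme!r}")


def build_dataset(
    bundle: ScreenBundle, drug_scheme: str = "morgan"
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Assemble model input blocks and targets for every triplet.

    Returns ``(inputs, y)`` where ``inputs`` has blocks ``expr`` (raw
    expression row of the triplet's cell line), ``drug_a`` and ``drug_b``
    (the chosen per-drug representation). Scaling is applied separately,
    after splitting, via :func:`scale_expression`.
    """
    triplets = bundle.triplets
    expr_frame = bundle.expression.to_frame()
    cell_rows = {c: expr_frame.loc[c].to_numpy(dtype=float) for c in expr_frame.index}
    drug_vecs = _drug_matrix(bundle, drug_scheme)
    inputs = {
        "expr": np.stack([cell_rows[c] for c in triplets["cell_line_id"]]),
        "drug_a": np.stack([drug_vecs[d] for d in triplets["drug_a_id"]]),
        "drug_b": np.stack([drug_vecs[d] for d in triplets["drug_b_id"]]),
    }
    y = triplets["combo_score"].to_numpy(dtype=float)
    return inputs, y


def scale_expression(
    inputs: dict[str, np.ndarray], split: SplitSpec
) -> tuple[dict[str, np.ndarray], MinMaxScalerState]:
    """Min-max scale the expression block, fitting on training rows only."""
    state = MinMaxScalerState.fit(inputs["expr"][split.train])
    out = dict(inputs)
    out["expr"] = state.transform(inputs["expr"])
    return out, state


def take_inputs(inputs: dict, idx: np.ndarray) -> dict:
    """Slice every input block along the sample axis."""
    return _take(inputs, np.asarray(idx))


def input_shapes(inputs: dict) -> dict[str, tuple[int, ...]]:
    """Per-sample shapes of the blocks, as the model builder expects."""
    shapes: dict[str, tuple[int, ...]] = {}
    for name, block in inputs.items():
        if name == "drug_b":
            continue
        key = "drug" if name == "drug_a" else name
        arr = block[0] if isinstance(block, tuple) else block
        shapes[key] = tuple(np.asarray(arr).shape[1:])
    return shapes
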