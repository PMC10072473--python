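"""Budgeted hyperparameter search and a heterogeneous ensemble.

Hyperparameters are searched under a fixed configuration budget with
successive halving: every candidate gets a small epoch budget, the best
fraction is promoted to a larger one, and the configuration with minimal
validation MSE wins. The heterogeneous ensemble then simply averages the
predictions of structurally different regressors, which can never be
worse (in MSE) than the average member.
"""

import numpy as np

from synscreen.evaluation import average_predictions, compute_scores, random_split
from synscreen.nn import (
    ModelConfig,
    SearchSpace,
    SubnetworkSpec,
    TrainConfig,
    build_multimodal,
    fit_classical,
    train,
    tune,
)
from synscreen.pipeline import build_dataset, input_shapes, scale_expression, take_inputs
from synscreen.synthetic import SyntheticScreenSpec, generate_screen

bundle = generate_screen(
    SyntheticScreenSpec(n_cell_lines=10, n_drugs=8, n_genes=60, noise_sd=1.0, seed=9)
)
inputs, y = build_dataset(bundle, "morgan")
split = random_split(len(y), seed=2)
inputs, _ = scale_expression(inputs, split)
shapes = input_shapes(inputs)


def evaluate(config, resource):
    model = build_multimodal(
        ModelConfig(
            expr_spec=SubnetworkSpec("expr", "dense", (int(config["width"]),)),
            drug_spec=SubnetworkSpec("drug", "dense", (int(config["width"]),)),
            head_layer_sizes=(16,),
            learning_rate=config["lr"],
        ),
        shapes,
        seed=0,
    )
    history = train(
        model,
        (take_inputs(inputs, split.train), y[split.train]),
        (take_inputs(inputs, split.val), y[split.val]),
        TrainConfig(max_epochs=resource, early_stop_patience=resource - 1, seed=0),
    )
    return min(history["val_loss"])


space = SearchSpace(
    {"lr": {"low": 3e-4, "high": 3e-2, "log": True}, "width": [16, 32]},
    budget=6,
    seed=0,
)
best, trials = tune(evaluate, space, min_resource=5, max_resource=20)
evaluated = [t for t in trials if "val_mse" in t]
print(f"{len(evaluated)} trials within budget {space.budget}; "
      f"best config {best} at val MSE {min(t['val_mse'] for t in evaluated):.3f}")

# heterogeneous ensemble: classical members on the concatenated features
X = np.hstack([inputs["expr"], inputs["drug_a"], inputs["drug_b"]])
members = {
    "elastic_net": fit_classical("elastic_net", X[split.train], y[split.train], {"alpha": 1e-3}),
    "random_forest": fit_classical("random_forest", X[split.train], y[split.train]),
    "lightgbm": fit_classical("lightgbm", X[split.train], y[split.train]),
}
preds = {name: m.predict(X[split.test]) for name, m in members.items()}
for name, p in preds.items():
    print(f"  member {name:13} test R^2 = {compute_scores(y[split.test], p).r2:.3f}")
ens = average_predictions(list(preds.values()))
print(f"  ensemble (mean)    test R^2 = {compute_scores(y[split.test], ens).r2:.3f}")
# the averaged prediction's MSE is bounded above by the mean member MSE.
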