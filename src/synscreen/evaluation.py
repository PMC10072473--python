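"""Splitting, scoring, and heterogeneous ensembling.

The study protocol is a single random triplet-level holdout of roughly
80/10/10; leave-drug-out and leave-cell-line-out constructors are
provided as alternative (stricter) generalization splits. Scores are R²
(coefficient of determination), Spearman rank correlation, Pearson
correlation and MSE over the whole evaluated partition. The
heterogeneous ensemble is the unweighted mean of member predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitSpec",
    "ScoreReport",
    "random_split",
    "drug_holdout_split",
    "cell_line_holdout_split",
    "compute_scores",
    "average_predictions",
    "ensemble_predict",
]


@dataclass
class SplitSpec:
    """Disjoint train/validation/test index lists covering 0..n-1."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.val = np.asarray(self.val, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        combined = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(combined)) != combined.size:
            raise ValueError("split partitions overlap")
        if not np.array_equal(np.sort(combined), np.arange(combined.size)):
            raise ValueError("split partitions must cover exactly 0..n-1")

    @property
    def n(self) -> int:
        return self.train.size + self.val.size + self.test.size

    def to_json(self) -> str:
        return json.dumps(
            {
                "train": self.train.tolist(),
                "val": self.val.tolist(),
                "test": self.test.tolist(),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        raw = json.loads(text)
        return cls(
            train=np.array(raw["train"]),
            val=np.array(raw["val"]),
            test=np.array(raw["test"]),
            seed=raw.get("seed", 0),
        )


def random_split(
    n: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> SplitSpec:
    """Single random triplet-level holdout split.

    Validation and test sizes are floored fractions of ``n``; the
    remainder goes to training (hence "around 80%"). Deterministic per
    seed.
    """
    if n < 3:
        raise ValueError("need at least 3 records to split three ways")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    return SplitSpec(
        train=perm[: n - n_val - n_test],
        val=perm[n - n_val - n_test : n - n_test],
        test=perm[n - n_test :],
        seed=seed,
    )


def drug_holdout_split(
    triplets: pd.DataFrame,
    n_holdout_drugs: int,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[SplitSpec, list[str]]:
    """Alternative split testing generalization to unseen drugs.

    ``n_holdout_drugs`` drugs are held out; every triplet involving a
    held-out drug goes to the test partition, and the remaining triplets
    are split randomly into train/validation.
    """
    rng = np.random.default_rng(seed)
    drugs = np.array(sorted(set(triplets["drug_a_id"]) | set(triplets["drug_b_id"])))
    if n_holdout_drugs >= drugs.size:
        raise ValueError("cannot hold out every drug")
    held = set(rng.choice(drugs, size=n_holdout_drugs, replace=False).tolist())
    in_test = (
        triplets["drug_a_id"].isin(held) | triplets["drug_b_id"].isin(held)
    ).to_numpy()
    test_idx = np.flatnonzero(in_test)
    rest = np.flatnonzero(~in_test)
    rest = rng.permutation(rest)
    n_val = int(np.floor(val_fraction * len(triplets)))
    return (
        SplitSpec(train=rest[n_val:], val=rest[:n_val], test=test_idx, seed=seed),
        sorted(held),
    )


def cell_line_holdout_split(
    triplets: pd.DataFrame,
    n_holdout_cells: int,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[SplitSpec, list[str]]:
    """Alternative split testing generalization to unseen cell lines."""
    rng = np.random.default_rng(seed)
    cells = np.array(sorted(set(triplets["cell_line_id"])))
    if n_holdout_cells >= cells.size:
        raise ValueError("cannot hold out every cell line")
    held = set(rng.choice(cells, size=n_holdout_cells, replace=False).tolist())
    in_test = triplets["cell_line_id"].isin(held).to_numpy()
    test_idx = np.flatnonzero(in_test)
    rest = rng.permutation(np.flatnonzero(~in_test))
    n_val = int(np.floor(val_fraction * len(triplets)))
    return (
        SplitSpec(train=rest[n_val:], val=rest[:n_val], test=test_idx, seed=seed),
        sorted(held),
    )


@dataclass(frozen=True)
class ScoreReport:
    """Regression scores over one evaluated partition."""

    r2: float
    spearman: float
    mse: float
    pearson: float
    n: int

    def to_json(self) -> str:
        return json.dumps(
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in self.__dict__.items()}
        )


def compute_scores(y: np.ndarray, yhat: np.ndarray) -> ScoreReport:
    """Score predictions: R², Spearman, MSE, Pearson over the whole set.

    ``r2 = 1 - Σ(y-ŷ)²/Σ(y-ȳ)²``; Spearman is the Pearson correlation of
    average-tie ranks. For constant ``y`` the correlations are undefined
    and reported as NaN while R² and MSE are still computed.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 observations to score")
    mse = float(np.mean((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if mse == 0.0 else -np.inf
        spearman = pearson = float("nan")
    else:
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
        if np.all(yhat == yhat[0]):
            spearman = pearson = float("nan")
        else:
            spearman = float(stats.spearmanr(y, yhat).statistic)
            pearson = float(stats.pearsonr(y, yhat).statistic)
    return ScoreReport(r2=r2, spearman=spearman, mse=mse, pearson=pearson, n=y.size)


def average_predictions(predictions: list[np.ndarray]) -> np.ndarray:
    """Unweighted arithmetic mean of member predictions per sample."""
    if len(predictions) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    mats = [np.asarray(p, dtype=float).ravel() for p in predictions]
    lengths = {m.size for m in mats}
    if len(lengths) != 1:
        raise ValueError(f"member predictions differ in length: {sorted(lengths)}")
    return np.mean(mats, axis=0)


def ensemble_predict(members, inputs) -> np.ndarray:
    """Average the predictions of heterogeneous members.

    ``members`` is a sequence of (name, model) pairs; ``inputs`` is
    either one shared input object or a list with one featurization per
    member (members may consume different featurizations of the same
    triplets). A failing member raises an error naming it.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    per_member = inputs if isinstance(inputs, (list, tuple)) else [inputs] * len(members)
    if len(per_member) != len(members):
        raise ValueError("one input object per member is required")
    predictions = []
    for (name, model), member_inputs in zip(members, per_member):
        try:
            predictions.append(np.asarray(model.predict(member_inputs), dtype=float).ravel())
        except Exception as exc:
            raise RuntimeError(f"ensemble member {name!r} failed: {exc}") from exc
    return average_predictions(predictions)
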