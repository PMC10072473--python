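"""Attribution-based model interpretation and gene set enrichment.

Per-feature additive attributions (Shapley values) explain individual
synergy predictions: the base value — the expected model output on a
background input — plus the per-feature attributions reconstructs the
prediction (local accuracy). The module provides an exact
subset-enumeration Shapley oracle for small feature counts, a
model-agnostic permutation-sampling backend for production use,
grouped-importance summaries (sum within an input group per sample, then
mean absolute value across samples), per-example waterfall
decompositions, and pre-ranked gene set enrichment on attribution-ranked
genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from synscreen.omics_features import GeneSetCollection

__all__ = [
    "AttributionSet",
    "GroupedImportance",
    "exact_shapley",
    "PermutationShapley",
    "group_attributions",
    "rank_features",
    "waterfall_data",
    "preranked_gsea",
]

MAX_EXACT_FEATURES = 14


@dataclass
class AttributionSet:
    """Per-sample, per-feature attributions with input-group labels.

    Local accuracy: ``base_value + values[i].sum()`` approximates the
    model prediction for sample ``i`` (exactly, for Shapley estimators
    built from complete permutations or full enumeration).
    """

    base_value: float
    values: np.ndarray  # samples x features
    feature_labels: list[str]
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_labels):
            raise ValueError("one label per feature column is required")


def exact_shapley(
    predict_fn,
    sample: np.ndarray,
    background: np.ndarray,
    max_features: int = MAX_EXACT_FEATURES,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by full coalition enumeration.

    For every subset S of features, the coalition value is the model
    output with features in S at their sample values and all others at
    background values; attributions are the classical weighted average
    of marginal contributions. Exponential in the feature count, hence
    capped at ``max_features``; intended as the independent oracle for
    approximate attribution backends. Satisfies local accuracy exactly:
    ``predict(background) + sum(phi) == predict(sample)``.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    background = np.asarray(background, dtype=float).ravel()
    n = sample.size
    if background.size != n:
        raise ValueError("sample and background must have equal length")
    if n > max_features:
        raise ValueError(
            f"{n} features exceeds the enumeration cap of {max_features} "
            "(2^n coalitions)"
        )
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # (2^n, n)
    points = np.where(masks.astype(bool), sample, background)
    values = np.asarray(predict_fn(points), dtype=float).ravel()
    if values.size != 2**n:
        raise ValueError("predict_fn must return one value per input row")
    sizes = masks.sum(axis=1)
    fact = [math.factorial(k) for k in range(n + 1)]
    phi = np.zeros(n)
    for i in range(n):
        without_i = np.flatnonzero(masks[:, i] == 0)
        s = sizes[without_i]
        weight = np.array([fact[k] * fact[n - k - 1] / fact[n] for k in s])
        phi[i] = np.sum(weight * (values[without_i | (1 << i)] - values[without_i]))
    base_value = float(values[0])
    return phi, base_value


class PermutationShapley:
    """Model-agnostic Shapley estimator by permutation sampling.

    For each sampled feature ordering, features are switched from
    background to sample values one at a time and the marginal output
    changes are credited to the switched feature; averaging over
    orderings converges to the Shapley values. Because every ordering's
    contributions telescope from the background output to the sample
    output, local accuracy holds exactly for any number of permutations.
    Antithetic pairs (each ordering together with its reverse) reduce
    variance.
    """

    def __init__(self, n_permutations: int = 64, seed: int = 0, antithetic: bool = True):
        if n_permutations < 1:
            raise ValueError("need at least one permutation")
        self.n_permutations = n_permutations
        self.seed = seed
        self.antithetic = antithetic

    def _single(self, predict_fn, sample, background, rng) -> tuple[np.ndarray, float]:
        n = sample.size
        phi = np.zeros(n)
        orders = []
        for _ in range(self.n_permutations):
            perm = rng.permutation(n)
            orders.append(perm)
            if self.antithetic:
                orders.append(perm[::-1])
        for perm in orders:
            # rows: background, then cumulatively switched features
            points = np.tile(background, (n + 1, 1))
            current = background.copy()
            for step, j in enumerate(perm, start=1):
                current = current.copy()
                current[j] = sample[j]
                points[step] = current
            outputs = np.asarray(predict_fn(points), dtype=float).ravel()
            phi[perm] += outputs[1:] - outputs[:-1]
        phi /= len(orders)
        base = float(np.asarray(predict_fn(background[None, :])).ravel()[0])
        return phi, base

    def attribute(
        self,
        predict_fn,
        samples: np.ndarray,
        background: np.ndarray,
        feature_labels: list[str] | None = None,
        group_labels: dict[str, str] | None = None,
    ) -> AttributionSet:
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        background = np.asarray(background, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        rows = []
        base = 0.0
        for sample in samples:
            phi, base = self._single(predict_fn, sample, background, rng)
            rows.append(phi)
        labels = feature_labels or [f"f{j}" for j in range(samples.shape[1])]
        return AttributionSet(
            base_value=base,
            values=np.stack(rows),
            feature_labels=list(labels),
            group_labels=dict(group_labels or {}),
        )


@dataclass
class GroupedImportance:
    """Input-group attribution summaries.

    ``per_sample`` sums the attributions of each group's features within
    every sample (the group sums partition each sample's total
    attribution exactly); ``mean_abs`` is the mean absolute group sum
    across samples — the grouped importance ranking.
    """

    per_sample: pd.DataFrame  # samples x groups
    mean_abs: pd.Series  # group -> importance


def group_attributions(attrs: AttributionSet) -> GroupedImportance:
    """Sum attributions within input groups, then mean-absolute across samples."""
    missing = [f for f in attrs.feature_labels if f not in attrs.group_labels]
    if missing:
        raise ValueError(f"features without a group label: {missing[:5]}")
    groups = sorted(set(attrs.group_labels.values()))
    frame = pd.DataFrame(attrs.values, columns=attrs.feature_labels)
    per_sample = pd.DataFrame(
        {g: frame[[f for f in attrs.feature_labels if attrs.group_labels[f] == g]].sum(axis=1)
         for g in groups}
    )
    return GroupedImportance(per_sample=per_sample, mean_abs=per_sample.abs().mean(axis=0))


def rank_features(attrs: AttributionSet, k: int, scope: str = "global", sample: int = 0):
    """Rank features by absolute attribution.

    ``global`` scope ranks by mean |value| across samples; ``sample``
    scope ranks one row by |value|. Ties break deterministically by
    feature label. Returns the top-``k`` (label, score) pairs.
    """
    if k > len(attrs.feature_labels):
        raise ValueError(f"k={k} exceeds the {len(attrs.feature_labels)} features")
    if scope == "global":
        scores = np.abs(attrs.values).mean(axis=0)
    elif scope == "sample":
        scores = np.abs(attrs.values[sample])
    else:
        raise ValueError("scope must be 'global' or 'sample'")
    order = sorted(
        range(len(attrs.feature_labels)),
        key=lambda j: (-scores[j], attrs.feature_labels[j]),
    )
    return [(attrs.feature_labels[j], float(scores[j])) for j in order[:k]]


def waterfall_data(
    attrs: AttributionSet, sample: int, k: int
) -> list[tuple[str, float, float]]:
    """Per-example waterfall: top-k signed contributions plus a residual.

    Returns (label, contribution, cumulative) rows ordered by decreasing
    |contribution|, with a final "all other features" residual so the
    cumulative series telescopes from the base value to the model
    prediction exactly.
    """
    row = attrs.values[sample]
    order = sorted(
        range(row.size), key=lambda j: (-abs(row[j]), attrs.feature_labels[j])
    )
    top = order[: min(k, row.size)]
    rows = []
    cumulative = attrs.base_value
    for j in top:
        cumulative += row[j]
        rows.append((attrs.feature_labels[j], float(row[j]), float(cumulative)))
    residual = float(row.sum() - row[top].sum())
    if len(top) < row.size:
        cumulative += residual
        rows.append(("all other features", residual, float(cumulative)))
    return rows


# --- pre-ranked gene set enrichment ---------------------------------------


def _enrichment_score(
    in_set: np.ndarray, scores: np.ndarray, weight_p: float
) -> tuple[float, np.ndarray]:
    """Signed maximum deviation of the weighted KS-like running sum."""
    n = scores.size
    n_hit = int(in_set.sum())
    hit_weights = np.abs(scores) ** weight_p * in_set
    total = hit_weights.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted hits
        hit_weights = in_set.astype(float)
        total = hit_weights.sum()
    running = np.cumsum(hit_weights / total - (1.0 - in_set) / (n - n_hit))
    peak = np.argmax(np.abs(running))
    return float(running[peak]), running


@dataclass(frozen=True)
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    size: int
    leading_edge: tuple[str, ...]


def preranked_gsea(
    ranking: pd.Series,
    sets: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 3,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA on an externally ranked gene list.

    Genes are sorted by descending score (ties broken by gene label);
    walking down the list, the running statistic rises by the normalized
    |score|^weight_p at set members and falls by 1/(N - N_hit) elsewhere.
    ES is the signed maximum deviation; NES normalizes ES by the mean
    |ES| of same-sign gene-label permutations, which also give the
    permutation p-value; Benjamini-Hochberg FDR is computed across sets.
    Sets outside [min_size, max_size] after intersection with the
    ranking, or with no ranked genes, are skipped with a warning.
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    order = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    scores = ranking.loc[order].to_numpy(dtype=float)
    genes = np.array(order)
    n = genes.size
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets.items():
        in_set = np.isin(genes, list(members))
        size = int(in_set.sum())
        if size < min_size or size > max_size or size == n:
            warnings.warn(
                f"gene set {name!r} skipped (size {size} outside "
                f"[{min_size}, {min(max_size, n - 1)}])",
                stacklevel=2,
            )
            continue
        es, running = _enrichment_score(in_set, scores, weight_p)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=size, replace=False)] = True
            perm_es[b], _ = _enrichment_score(perm, scores, weight_p)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same_sign.size == 0:
            nes, p_perm = float("nan"), 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p_perm = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            leading = tuple(genes[: peak + 1][in_set[: peak + 1]])
        else:
            leading = tuple(genes[peak:][in_set[peak:]])
        rows.append(
            GSEAResult(
                set_name=name,
                es=es,
                nes=float(nes),
                p_perm=float(p_perm),
                fdr=float("nan"),
                size=size,
                leading_edge=leading,
            )
        )
    if not rows:
        raise ValueError("no gene set passed the size filters")
    frame = pd.DataFrame([r.__dict__ for r in rows]).set_index("set_name")
    frame["fdr"] = false_discovery_control(frame["p_perm"].to_numpy(), method="bh")
    return frame
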