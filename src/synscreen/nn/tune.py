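"""Budgeted hyperparameter search via successive halving.

A fixed budget of configurations is drawn from the search space by a
pluggable suggester (seeded random sampling by default); trials are
evaluated at a small training resource (epochs), the best fraction
promoted to a larger resource, and so on — terminating poor trials
early. The returned configuration is the one with the minimal observed
validation MSE across the whole trial log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SearchSpace", "tune", "random_suggester"]


@dataclass(frozen=True)
class SearchSpace:
    """Per-hyperparameter domains plus a configuration budget.

    Domain forms: a list/tuple of categorical choices, or a dict
    ``{"low": .., "high": ..}`` with optional ``"log": True`` for
    continuous ranges.
    """

    domains: dict
    budget: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.domains:
            raise ValueError("search space has no hyperparameter domains")


def _sample_domain(rng: np.random.Generator, domain):
    if isinstance(domain, dict):
        lo, hi = domain["low"], domain["high"]
        if domain.get("log"):
            return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        value = rng.uniform(lo, hi)
        return int(round(value)) if domain.get("int") else float(value)
    return domain[rng.integers(len(domain))]


def random_suggester(rng: np.random.Generator, space: SearchSpace, history: list) -> dict:
    """Default suggester: independent random draws from each domain."""
    return {name: _sample_domain(rng, domain) for name, domain in space.domains.items()}


def tune(
    evaluate,
    space: SearchSpace,
    min_resource: int = 5,
    max_resource: int = 50,
    eta: int = 3,
    suggester=None,
    log_path=None,
) -> tuple[dict, list[dict]]:
    """Run a budgeted search and return (best config, full trial log).

    ``evaluate(config, resource)`` trains a model for ``resource`` units
    (epochs) and returns the validation MSE. At most ``space.budget``
    configurations are drawn; successive halving promotes the best
    ``1/eta`` fraction of trials to an ``eta``-fold larger resource until
    ``max_resource``. Failed trials (exceptions) are logged and skipped;
    if every trial fails the search raises with the log attached.
    """
    suggester = suggester or random_suggester
    rng = np.random.default_rng(space.seed)
    trials: list[dict] = []
    configs = []
    for _ in range(space.budget):
        configs.append(suggester(rng, space, trials))

    active = list(range(len(configs)))
    resource = min(min_resource, max_resource)
    while active:
        scores: dict[int, float] = {}
        for ci in active:
            entry = {"config": configs[ci], "resource": resource}
            try:
                entry["val_mse"] = float(evaluate(configs[ci], resource))
                scores[ci] = entry["val_mse"]
            except Exception as exc:  # noqa: BLE001 - trial failures are data
                entry["error"] = f"{type(exc).__name__}: {exc}"
            trials.append(entry)
        if resource >= max_resource or len(active) == 1:
            break
        keep = max(1, len(scores) // eta)
        active = sorted(scores, key=scores.get)[:keep]
        resource = min(resource * eta, max_resource)

    completed = [t for t in trials if "val_mse" in t]
    if not completed:
        raise RuntimeError(f"all {len(trials)} tuning trials failed; log: {trials}")
    best = min(completed, key=lambda t: t["val_mse"])
    if log_path is not None:
        with open(log_path, "w") as fh:
            json.dump(trials, fh, indent=1)
    return best["config"], trials
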