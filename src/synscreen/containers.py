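"""Typed containers for cell-line omics blocks.

Each container wraps a dense ``cell lines x features`` numpy matrix plus
ordered identifier lists, with the value-domain invariants of its data
type enforced at construction (binary mutation calls, integer GISTIC
copy-number codes in {-2..2}, nonnegative log2(FPKM+1) expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "ExpressionMatrix",
    "MutationMatrix",
    "CNVMatrix",
    "PathwayMatrix",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
        raise ValueError(f"duplicated {what}: {dupes[:5]}")


@dataclass
class OmicsMatrix:
    """Base cell-lines x features matrix with ordered labels."""

    cell_line_ids: list[str]
    feature_names: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cell_line_ids = list(self.cell_line_ids)
        self.feature_names = list(self.feature_names)
        self.values = np.asarray(self.values)
        _check_unique(self.cell_line_ids, "cell-line ids")
        _check_unique(self.feature_names, self._feature_kind + "s")
        if self.values.shape != (len(self.cell_line_ids), len(self.feature_names)):
            raise ValueError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.cell_line_ids)} cell lines x "
                f"{len(self.feature_names)} features"
            )
        self._validate_values()

    _feature_kind = "feature"

    def _validate_values(self) -> None:  # pragma: no cover - overridden
        pass

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_line_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OmicsMatrix":
        return cls(
            cell_line_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="cell_line_id")

    @classmethod
    def from_tsv(cls, path) -> "OmicsMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_line_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


class ExpressionMatrix(OmicsMatrix):
    """Gene expression on the log2(FPKM+1) scale (nonnegative pre-scaling)."""

    _feature_kind = "gene symbol"

    @property
    def gene_symbols(self) -> list[str]:
        return self.feature_names

    def _validate_values(self) -> None:
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(float)


class MutationMatrix(OmicsMatrix):
    """Binary gene-level mutation calls (1 = at least one retained variant)."""

    _feature_kind = "gene symbol"

    @property
    def gene_symbols(self) -> list[str]:
        return self.feature_names

    def _validate_values(self) -> None:
        vals = np.unique(self.values)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"mutation matrix must be binary, found values {vals[:6]}")
        self.values = self.values.astype(np.int8)


class PathwayMatrix(OmicsMatrix):
    """Binary pathway-level alteration calls (OR over member genes)."""

    _feature_kind = "pathway name"

    @property
    def pathway_names(self) -> list[str]:
        return self.feature_names

    def _validate_values(self) -> None:
        vals = np.unique(self.values)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"pathway matrix must be binary, found values {vals[:6]}")
        self.values = self.values.astype(np.int8)


class CNVMatrix(OmicsMatrix):
    """GISTIC-style discretized copy-number codes in {-2,-1,0,1,2}."""

    _feature_kind = "gene symbol"

    @property
    def gene_symbols(self) -> list[str]:
        return self.feature_names

    def _validate_values(self) -> None:
        vals = np.unique(self.values)
        if not np.isin(vals, [-2, -1, 0, 1, 2]).all():
            raise ValueError(f"CNV codes must lie in -2..2, found values {vals[:6]}")
        self.values = self.values.astype(np.int8)
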