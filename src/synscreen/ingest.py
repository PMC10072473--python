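"""Screen-table and compound-structure ingestion.

Canonicalization follows the screen-preprocessing conventions for
NCI-ALMANAC-style triplet tables: a <cell line, drug A, drug B> triplet
and its reverse-order twin describe the same experiment, so unordered
pairs are put in lexicographic drug-id order and replicate ComboScores
are averaged. Compound structures are read from SDF (with an optional
id->SMILES fallback table) and standardized by stripping salts/solvents
to the largest organic fragment, neutralizing charges where unambiguous,
and emitting the canonical SMILES form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenTable",
    "CompoundRecord",
    "read_screen_table",
    "deduplicate_triplets",
    "standardize_structure",
    "load_compound_structures",
    "DEFAULT_COLUMN_MAP",
]

DEFAULT_COLUMN_MAP = {
    "cell_line_id": "cell_line_id",
    "drug_a_id": "drug_a_id",
    "drug_b_id": "drug_b_id",
    "combo_score": "combo_score",
}

_CANONICAL_COLUMNS = ["cell_line_id", "drug_a_id", "drug_b_id", "combo_score"]


@dataclass
class ScreenTable:
    """Ordered triplet records plus the configured cell-line exclusions."""

    records: pd.DataFrame
    excluded_cell_lines: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = set(_CANONICAL_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"screen table missing columns: {sorted(missing)}")
        self.records = self.records[_CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CompoundRecord:
    """A screened compound with raw and standardized structure."""

    compound_id: str
    name: str
    smiles_raw: str
    smiles_standardized: str
    source: str = "sdf"  # "sdf" | "fallback"


class ScreenTableError(ValueError):
    """Raised for malformed screen tables, with row context."""


def read_screen_table(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
    excluded_cell_lines: set[str] | frozenset[str] = frozenset(),
) -> ScreenTable:
    """Read a CSV/TSV triplet table into typed records.

    ``column_map`` maps canonical field names (cell_line_id, drug_a_id,
    drug_b_id, combo_score) to the file's column headers. Malformed rows
    (non-numeric score, identical drug ids) raise with 1-based data-row
    numbers so the offending lines can be fixed at the source.
    """
    colmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("screen table %s is empty", path)
        warnings.warn(f"screen table {path} is empty", stacklevel=2)
        return ScreenTable(
            records=pd.DataFrame(columns=_CANONICAL_COLUMNS),
            excluded_cell_lines=frozenset(excluded_cell_lines),
        )
    missing = [col for col in colmap.values() if col not in raw.columns]
    if missing:
        raise ScreenTableError(
            f"screen table {path} missing required columns {missing}; "
            f"found {list(raw.columns)}"
        )
    frame = raw.rename(columns={v: k for k, v in colmap.items()})[_CANONICAL_COLUMNS]
    scores = pd.to_numeric(frame["combo_score"], errors="coerce")
    bad_score_rows = (frame.index[scores.isna() & frame["combo_score"].notna()] + 1).tolist()
    if bad_score_rows:
        raise ScreenTableError(
            f"non-numeric combo_score values at data rows {bad_score_rows[:10]}"
        )
    frame["combo_score"] = scores
    self_pairs = (frame.index[frame["drug_a_id"] == frame["drug_b_id"]] + 1).tolist()
    if self_pairs:
        raise ScreenTableError(
            f"drug_a_id equals drug_b_id at data rows {self_pairs[:10]} "
            "(a combination needs two distinct drugs)"
        )
    if frame.empty:
        logger.warning("screen table %s contains no data rows", path)
        warnings.warn(f"screen table {path} contains no data rows", stacklevel=2)
    return ScreenTable(records=frame, excluded_cell_lines=frozenset(excluded_cell_lines))


def deduplicate_triplets(table: ScreenTable) -> ScreenTable:
    """Collapse reverse-order duplicates by unordered pair and average scores.

    Reverse drug order <cell line, drugB, drugA> triplets are duplicates
    of <cell line, drugA, drugB>; scores of all replicates sharing a
    (cell line, unordered pair) key are averaged with an unweighted
    arithmetic mean. Records for excluded cell lines are dropped. The
    result stores each pair in lexicographic id order and the operation
    is idempotent.
    """
    frame = table.records.copy()
    frame = frame[~frame["cell_line_id"].isin(table.excluded_cell_lines)]
    if frame.empty:
        return ScreenTable(
            records=pd.DataFrame(columns=_CANONICAL_COLUMNS),
            excluded_cell_lines=table.excluded_cell_lines,
        )
    lo = frame[["drug_a_id", "drug_b_id"]].min(axis=1)
    hi = frame[["drug_a_id", "drug_b_id"]].max(axis=1)
    frame = frame.assign(drug_a_id=lo, drug_b_id=hi)
    out = (
        frame.groupby(["cell_line_id", "drug_a_id", "drug_b_id"], sort=True, as_index=False)[
            "combo_score"
        ]
        .mean()
    )
    return ScreenTable(records=out, excluded_cell_lines=table.excluded_cell_lines)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles_raw: str) -> str:
    """Standardize a raw SMILES: strip salts/solvents, neutralize, canonicalize.

    Keeps the largest organic fragment, normalizes charges where
    chemically unambiguous, and returns the canonical SMILES. The
    operation is a projection: standardizing an already-standardized
    string returns it unchanged.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles_raw!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def load_compound_structures(
    sdf_path=None,
    name_lookup: pd.DataFrame | dict[str, str] | None = None,
    required_ids: list[str] | None = None,
    id_property: str = "compound_id",
) -> tuple[list[CompoundRecord], list[str]]:
    """Resolve screened drug ids to standardized structures.

    Structures come from an SDF carrying ``id_property`` on each molecule;
    ids absent from the SDF are resolved from the optional ``name_lookup``
    id->SMILES fallback table (its provenance is flagged on the record).
    Returns the resolved records plus the list of ``required_ids`` found
    in neither source — unmapped ids are reported, never silently dropped.
    """
    if isinstance(name_lookup, pd.DataFrame):
        name_lookup = dict(
            zip(name_lookup.iloc[:, 0].astype(str), name_lookup.iloc[:, 1].astype(str))
        )
    name_lookup = name_lookup or {}

    records: dict[str, CompoundRecord] = {}
    if sdf_path is not None:
        supplier = Chem.SDMolSupplier(str(sdf_path))
        for mol in supplier:
            if mol is None:
                continue
            if not mol.HasProp(id_property):
                raise ValueError(
                    f"SDF molecule without the {id_property!r} property in {sdf_path}"
                )
            cid = mol.GetProp(id_property)
            raw = Chem.MolToSmiles(mol)
            records[cid] = CompoundRecord(
                compound_id=cid,
                name=mol.GetProp("_Name") if mol.HasProp("_Name") else cid,
                smiles_raw=raw,
                smiles_standardized=standardize_structure(raw),
                source="sdf",
            )
    for cid, raw in name_lookup.items():
        if cid not in records:
            records[cid] = CompoundRecord(
                compound_id=cid,
                name=cid,
                smiles_raw=raw,
                smiles_standardized=standardize_structure(raw),
                source="fallback",
            )
    unmapped: list[str] = []
    if required_ids is not None:
        unmapped = sorted(set(required_ids) - set(records))
        if unmapped:
            logger.warning("unmapped compound ids: %s", unmapped)
    return list(records.values()), unmapped


def write_unmapped_report(unmapped: list[str], path) -> None:
    Path(path).write_text("".join(f"{cid}\n" for cid in unmapped))
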