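"""Seeded synthetic combination screens with retrievable ground truth.

The generator emulates the statistical shape of a dense NCI-60-style
combination screen — tens of cell lines crossed with every unordered
pair from a drug panel of ~10^2 compounds — together with the omics
blocks downstream featurization consumes: block-correlated expression on
a log2(FPKM+1)-like scale, sparse binary mutations, and integer
copy-number codes. The synergy score is a known additive-plus-interaction
function of drug fingerprint bits and expression (a stand-in response,
not a Bliss-model simulator), so every downstream stage can be tested
against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from synscreen.containers import CNVMatrix, ExpressionMatrix, MutationMatrix
from synscreen.drug_features import N_BITS, morgan_fingerprint

__all__ = [
    "SyntheticScreenSpec",
    "GroundTruth",
    "ScreenBundle",
    "generate_drug_panel",
    "generate_screen",
    "truth_score",
    "write_bundle",
]

# Combinatorial SMILES templates: (plain ring, substituted-ring format).
_RING_TEMPLATES: list[tuple[str, str]] = [
    ("c1ccccc1", "c1ccc({r})cc1"),
    ("c1ccncc1", "c1cc({r})ncc1"),
    ("C1CCCCC1", "C1CCC({r})CC1"),
    ("c1ccsc1", "c1cc({r})sc1"),
    ("C1CCOC1", "C1CC({r})OC1"),
    ("c1ccc2ccccc2c1", "c1ccc2cc({r})ccc2c1"),
]
_CHAINS = ["", "C", "CC", "CCC", "CCCC", "OC", "OCC", "COC", "CCOC"]
_TAILS = ["", "O", "N", "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)N", "C(C)C"]

# Auto-selection sizes used when a spec leaves effect sets unspecified.
_DEFAULT_N_EFFECT_BITS = 12
_DEFAULT_N_DRIVER_GENES = 20
_DEFAULT_N_INTERACTIONS = 15


def _enumerate_panel() -> list[str]:
    smiles = []
    for plain, fmt in _RING_TEMPLATES:
        for chain in _CHAINS:
            for tail in _TAILS:
                r = chain + tail
                smiles.append(plain if r == "" else fmt.format(r=r))
    return smiles


def generate_drug_panel(n_drugs: int, seed: int) -> dict[str, str]:
    """Generate ``n_drugs`` distinct, parseable SMILES from templates.

    Structures are drawn from combinatorial substituted-ring / alkyl /
    ether / halide templates, deduplicated on canonical form, and
    assigned zero-padded drug ids in panel order. Deterministic per seed.
    """
    from rdkit import Chem

    if n_drugs < 2:
        raise ValueError("a screen needs at least 2 drugs")
    pool = _enumerate_panel()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    panel: list[str] = []
    seen: set[str] = set()
    for idx in order:
        mol = Chem.MolFromSmiles(pool[idx])
        if mol is None:  # pragma: no cover - templates are valid by construction
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        panel.append(pool[idx])
        if len(panel) == n_drugs:
            break
    else:
        raise ValueError(
            f"requested {n_drugs} drugs but the template space only yields "
            f"{len(panel)} distinct structures"
        )
    width = max(4, len(str(n_drugs - 1)))
    return {f"DRUG-{i:0{width}d}": smi for i, smi in enumerate(panel)}


@dataclass(frozen=True)
class SyntheticScreenSpec:
    """Conditions for one synthetic screen.

    ``driver_genes`` / ``effect_bits`` may be left as ``None`` to have the
    generator pick them: driver genes evenly spread over the transcript
    list, effect bits drawn from fingerprint bits with intermediate
    prevalence (20-80%) across the generated panel so the planted drug
    signal is expressed and shared between drugs.
    """

    n_cell_lines: int = 30
    n_drugs: int = 20
    n_genes: int = 500
    n_modules: int = 5
    driver_genes: frozenset[int] | None = None
    effect_bits: frozenset[int] | None = None
    interaction_scale: float = 0.25
    noise_sd: float = 5.0
    mutation_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_drugs", "n_genes", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.driver_genes is not None:
            bad = set(self.driver_genes) - set(range(self.n_genes))
            if bad:
                raise ValueError(f"driver_genes outside 0..{self.n_genes - 1}: {sorted(bad)[:5]}")
        if self.effect_bits is not None:
            bad = set(self.effect_bits) - set(range(N_BITS))
            if bad:
                raise ValueError(f"effect_bits outside 0..{N_BITS - 1}: {sorted(bad)[:5]}")


@dataclass(frozen=True)
class GroundTruth:
    """The noiseless score function, fully retrievable after generation.

    ``interaction_weights`` already include the spec's interaction scale,
    so the truth object alone determines the noiseless score.
    """

    intercept: float
    bit_weights: dict[int, float]
    gene_weights: dict[int, float]
    interaction_weights: dict[tuple[int, int, int], float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "bit_weights": {str(k): v for k, v in self.bit_weights.items()},
                "gene_weights": {str(k): v for k, v in self.gene_weights.items()},
                "interaction_weights": {
                    f"{k},{l},{g}": v for (k, l, g), v in self.interaction_weights.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            intercept=raw["intercept"],
            bit_weights={int(k): v for k, v in raw["bit_weights"].items()},
            gene_weights={int(k): v for k, v in raw["gene_weights"].items()},
            interaction_weights={
                tuple(int(x) for x in key.split(",")): v
                for key, v in raw["interaction_weights"].items()
            },
        )


def truth_score(
    truth: GroundTruth,
    fp_a: np.ndarray,
    fp_b: np.ndarray,
    expr_row: np.ndarray,
) -> float:
    """Noiseless synergy score for one (drug pair, cell line) triplet.

    score = intercept
          + sum_k w_k (fp_a[k] + fp_b[k])
          + sum_g v_g expr[g]
          + sum_{(k,l,g)} u_klg * (fp_a[k] fp_b[l] + fp_b[k] fp_a[l]) / 2 * expr[g]

    The interaction term is symmetrized, so the score is invariant under
    swapping the two drugs.
    """
    fp_a = np.asarray(fp_a)
    fp_b = np.asarray(fp_b)
    expr_row = np.asarray(expr_row)
    if fp_a.shape != fp_b.shape:
        raise ValueError("fingerprint vectors differ in length")
    needed_bit = max([*truth.bit_weights, *(k for k, _, _ in truth.interaction_weights),
                      *(l for _, l, _ in truth.interaction_weights)], default=-1)
    if needed_bit >= fp_a.shape[0]:
        raise ValueError(f"fingerprints too short for bit index {needed_bit}")
    needed_gene = max([*truth.gene_weights, *(g for _, _, g in truth.interaction_weights)],
                      default=-1)
    if needed_gene >= expr_row.shape[0]:
        raise ValueError(f"expression row too short for gene index {needed_gene}")

    score = truth.intercept
    for k, w in truth.bit_weights.items():
        score += w * (float(fp_a[k]) + float(fp_b[k]))
    for g, v in truth.gene_weights.items():
        score += v * float(expr_row[g])
    for (k, l, g), u in truth.interaction_weights.items():
        sym = 0.5 * (float(fp_a[k]) * float(fp_b[l]) + float(fp_b[k]) * float(fp_a[l]))
        score += u * sym * float(expr_row[g])
    return float(score)


@dataclass
class ScreenBundle:
    """One generated screen: triplet table, omics blocks, structures, truth."""

    triplets: pd.DataFrame
    expression: ExpressionMatrix
    mutations: MutationMatrix
    cnv: CNVMatrix
    drug_smiles: dict[str, str]
    truth: GroundTruth
    spec: SyntheticScreenSpec
    module_assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells = set(self.expression.cell_line_ids)
        drugs = set(self.drug_smiles)
        missing_cells = set(self.triplets["cell_line_id"]) - cells
        missing_drugs = (
            set(self.triplets["drug_a_id"]) | set(self.triplets["drug_b_id"])
        ) - drugs
        if missing_cells or missing_drugs:
            raise ValueError(
                f"triplets reference unknown cell lines {sorted(missing_cells)[:3]} "
                f"or drugs {sorted(missing_drugs)[:3]}"
            )


def _generate_expression(
    rng: np.random.Generator, n_cells: int, n_genes: int, n_modules: int
) -> tuple[np.ndarray, np.ndarray]:
    """Block-correlated expression: module latents + i.i.d. noise.

    Each gene loads on exactly one module latent (loading 0.9, residual
    sd 0.45), then values are shifted/scaled onto a nonnegative
    log2(FPKM+1)-like scale (location 4, scale 1.2, floored at 0).
    """
    modules = (np.arange(n_genes) * n_modules) // n_genes
    latents = rng.normal(size=(n_cells, n_modules))
    raw = 0.9 * latents[:, modules] + 0.45 * rng.normal(size=(n_cells, n_genes))
    expr = np.maximum(4.0 + 1.2 * raw, 0.0)
    return expr, modules


def _select_effect_bits(rng: np.random.Generator, fps: np.ndarray, n_bits: int) -> np.ndarray:
    prevalence = fps.mean(axis=0)
    eligible = np.flatnonzero((prevalence >= 0.2) & (prevalence <= 0.8))
    if eligible.size < n_bits:  # fall back to the most variable bits
        eligible = np.argsort(np.abs(prevalence - 0.5))[: max(n_bits, 1)]
    return np.sort(rng.choice(eligible, size=min(n_bits, eligible.size), replace=False))


def generate_screen(
    spec: SyntheticScreenSpec, emit_reversed_duplicates: bool = False
) -> ScreenBundle:
    """Generate a full screen bundle under ``spec``.

    The triplet table covers every unordered drug pair crossed with every
    cell line, drugs stored in lexicographic id order (canonical
    unordered-pair form). With ``emit_reversed_duplicates`` the table
    additionally contains a reversed copy of every triplet, which is what
    ingestion's deduplication is expected to collapse.
    """
    rng = np.random.default_rng(spec.seed)
    drug_smiles = generate_drug_panel(spec.n_drugs, seed=spec.seed)
    drug_ids = list(drug_smiles)
    fps = np.stack([morgan_fingerprint(s).bits for s in drug_smiles.values()]).astype(float)

    cell_ids = [f"CL-{i:03d}" for i in range(spec.n_cell_lines)]
    gene_symbols = [f"G{i:04d}" for i in range(spec.n_genes)]
    expr, modules = _generate_expression(rng, spec.n_cell_lines, spec.n_genes, spec.n_modules)

    if spec.effect_bits is None:
        effect_bits = _select_effect_bits(rng, fps, _DEFAULT_N_EFFECT_BITS)
    else:
        effect_bits = np.sort(np.fromiter(spec.effect_bits, dtype=int))
    if spec.driver_genes is None:
        driver_genes = np.unique(
            np.linspace(0, spec.n_genes - 1, min(_DEFAULT_N_DRIVER_GENES, spec.n_genes))
            .round()
            .astype(int)
        )
    else:
        driver_genes = np.sort(np.fromiter(spec.driver_genes, dtype=int))

    bit_weights = {int(k): float(rng.normal(0.0, 1.5)) for k in effect_bits}
    gene_weights = {int(g): float(rng.normal(0.0, 1.0)) for g in driver_genes}
    n_inter = min(_DEFAULT_N_INTERACTIONS, effect_bits.size**2 * driver_genes.size)
    interaction_weights: dict[tuple[int, int, int], float] = {}
    while len(interaction_weights) < n_inter:
        k = int(rng.choice(effect_bits))
        l = int(rng.choice(effect_bits))
        g = int(rng.choice(driver_genes))
        key = (min(k, l), max(k, l), g)
        if key not in interaction_weights:
            interaction_weights[key] = float(spec.interaction_scale * rng.normal(0.0, 1.0))
    truth = GroundTruth(
        intercept=float(rng.normal(0.0, 5.0)),
        bit_weights=bit_weights,
        gene_weights=gene_weights,
        interaction_weights=interaction_weights,
    )

    # vectorized scoring over (pair, cell)
    pairs = [(i, j) for i in range(spec.n_drugs) for j in range(i + 1, spec.n_drugs)]
    w = np.zeros(N_BITS)
    for k, wk in bit_weights.items():
        w[k] = wk
    v = np.zeros(spec.n_genes)
    for g, vg in gene_weights.items():
        v[g] = vg
    pair_idx = np.array(pairs)
    fa, fb = fps[pair_idx[:, 0]], fps[pair_idx[:, 1]]
    drug_term = (fa + fb) @ w  # (n_pairs,)
    gene_term = expr @ v  # (n_cells,)
    inter_keys = list(interaction_weights)
    if inter_keys:
        u = np.array([interaction_weights[key] for key in inter_keys])
        sym = np.stack(
            [0.5 * (fa[:, k] * fb[:, l] + fb[:, k] * fa[:, l]) for k, l, _ in inter_keys],
            axis=1,
        )  # (n_pairs, n_terms)
        expr_terms = expr[:, [g for _, _, g in inter_keys]]  # (n_cells, n_terms)
        interaction = (sym * u) @ expr_terms.T  # (n_pairs, n_cells)
    else:
        interaction = np.zeros((len(pairs), spec.n_cell_lines))

    scores = truth.intercept + drug_term[:, None] + gene_term[None, :] + interaction
    if spec.noise_sd > 0:
        scores = scores + rng.normal(0.0, spec.noise_sd, size=scores.shape)

    records = {
        "cell_line_id": np.repeat(cell_ids, len(pairs)).tolist(),
        "drug_a_id": [drug_ids[i] for _ in cell_ids for i, _ in pairs],
        "drug_b_id": [drug_ids[j] for _ in cell_ids for _, j in pairs],
        "combo_score": scores.T.ravel().tolist(),
    }
    triplets = pd.DataFrame(records)
    if emit_reversed_duplicates:
        reversed_copy = triplets.rename(
            columns={"drug_a_id": "drug_b_id", "drug_b_id": "drug_a_id"}
        )[triplets.columns]
        triplets = pd.concat([triplets, reversed_copy], ignore_index=True)

    mutations = MutationMatrix(
        cell_line_ids=cell_ids,
        feature_names=gene_symbols,
        values=(rng.random((spec.n_cell_lines, spec.n_genes)) < spec.mutation_rate).astype(int),
    )
    cnv = CNVMatrix(
        cell_line_ids=cell_ids,
        feature_names=gene_symbols,
        values=rng.choice(
            [-2, -1, 0, 1, 2],
            p=[0.05, 0.15, 0.60, 0.15, 0.05],
            size=(spec.n_cell_lines, spec.n_genes),
        ),
    )
    return ScreenBundle(
        triplets=triplets,
        expression=ExpressionMatrix(
            cell_line_ids=cell_ids, feature_names=gene_symbols, values=expr
        ),
        mutations=mutations,
        cnv=cnv,
        drug_smiles=drug_smiles,
        truth=truth,
        spec=spec,
        module_assignment={gene_symbols[i]: int(modules[i]) for i in range(spec.n_genes)},
    )


def write_bundle(bundle: ScreenBundle, outdir) -> None:
    """Write a bundle as plain-text files (CSV/TSV/SMILES/JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.triplets.to_csv(out / "triplets.csv", index=False)
    bundle.expression.to_tsv(out / "expression.tsv")
    bundle.mutations.to_tsv(out / "mutations.tsv")
    bundle.cnv.to_tsv(out / "cnv.tsv")
    with open(out / "drugs.smi", "w") as fh:
        for drug_id, smi in bundle.drug_smiles.items():
            fh.write(f"{drug_id}\t{smi}\n")
    (out / "truth.json").write_text(bundle.truth.to_json())
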