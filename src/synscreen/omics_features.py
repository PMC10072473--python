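"""Cell-line feature engineering for synergy models.

Covers every expression-variant used by the model family: gene-list
selection, train-fitted min-max scaling, UMAP embedding, co-expression
module eigengenes, and the two gene orderings (chromosome position /
hierarchical clustering with optimal leaf ordering) that turn expression
rows into 1D/2D image tensors for convolutional encoders; plus binary
mutation matrices at gene and pathway level and GISTIC copy-number
filtering.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import pdist, squareform

from synscreen.containers import CNVMatrix, ExpressionMatrix, MutationMatrix, PathwayMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneList",
    "GeneSetCollection",
    "MinMaxScalerState",
    "CoexpressionModules",
    "GeneImageLayout",
    "read_gene_list",
    "read_gmt",
    "select_genes",
    "fit_apply_minmax",
    "pearson_distance",
    "umap_reduce",
    "module_eigengenes",
    "CHROMOSOME_ORDER",
    "order_by_chromosome",
    "order_by_clustering",
    "reshape_to_image",
    "unreshape_image",
    "DEFAULT_EXCLUDED_CLASSES",
    "binarize_mutations",
    "pathway_mutation_matrix",
    "filter_matrix_by_list",
]


# --- gene lists and gene sets ---------------------------------------------


@dataclass(frozen=True)
class GeneList:
    """A named, non-empty set of gene symbols (landmark, DGI, COSMIC, ...)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene list {self.name!r} is empty")


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line text file."""
    symbols = frozenset(
        line.strip() for line in open(path) if line.strip() and not line.startswith("#")
    )
    return GeneList(name=name or str(path), symbols=symbols)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with GMT semantics (unique set names)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene set collection is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(open(path), start=1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r} at GMT line {lineno}")
        sets[name] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets)


# --- selection and scaling ------------------------------------------------


def select_genes(
    expr: ExpressionMatrix, lists: GeneList | list[GeneList], drop_constant: bool = False
) -> ExpressionMatrix:
    """Filter expression columns by one or more gene lists.

    Kept columns are the union of the list symbols intersected with the
    matrix symbols, in the matrix's original column order; combining
    several lists reproduces combined-list semantics (e.g. DGI+landmark).
    Columns constant across all cell lines are removed when
    ``drop_constant`` is set.
    """
    if isinstance(lists, GeneList):
        lists = [lists]
    if not lists:
        raise ValueError("at least one gene list is required")
    wanted = frozenset().union(*(gl.symbols for gl in lists))
    keep = [i for i, g in enumerate(expr.gene_symbols) if g in wanted]
    if not keep:
        names = [gl.name for gl in lists]
        raise ValueError(f"no matrix genes matched gene list(s) {names}")
    values = expr.values[:, keep]
    symbols = [expr.gene_symbols[i] for i in keep]
    if drop_constant:
        varying = [j for j in range(values.shape[1]) if not np.all(values[:, j] == values[0, j])]
        values = values[:, varying]
        symbols = [symbols[j] for j in varying]
        if not symbols:
            raise ValueError("all selected genes are constant across cell lines")
    return ExpressionMatrix(
        cell_line_ids=expr.cell_line_ids, feature_names=symbols, values=values
    )


@dataclass
class MinMaxScalerState:
    """Per-feature train-partition minima/maxima for [0,1] scaling.

    Fitted on training rows only; validation/test rows are transformed
    with these bounds without refitting or clipping, so out-of-range
    values map outside [0,1]. Features constant in training map to 0
    everywhere (the degenerate-range rule).
    """

    minima: np.ndarray
    maxima: np.ndarray

    @classmethod
    def fit(cls, train: np.ndarray) -> "MinMaxScalerState":
        train = np.asarray(train, dtype=float)
        if train.size == 0:
            raise ValueError("cannot fit a scaler on an empty training matrix")
        return cls(minima=train.min(axis=0), maxima=train.max(axis=0))

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        span = self.maxima - self.minima
        constant = span == 0
        safe_span = np.where(constant, 1.0, span)
        out = (matrix - self.minima) / safe_span
        out[:, constant] = 0.0
        return out

    def to_json(self) -> str:
        return json.dumps({"minima": self.minima.tolist(), "maxima": self.maxima.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "MinMaxScalerState":
        raw = json.loads(text)
        return cls(minima=np.array(raw["minima"]), maxima=np.array(raw["maxima"]))


def fit_apply_minmax(
    train: np.ndarray, others: list[np.ndarray] | tuple[np.ndarray, ...] = ()
) -> tuple[np.ndarray, list[np.ndarray], MinMaxScalerState]:
    """Fit min-max scaling on the training partition and apply everywhere."""
    state = MinMaxScalerState.fit(train)
    return state.transform(train), [state.transform(m) for m in others], state


# --- UMAP embedding -------------------------------------------------------


def pearson_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Correlation distance d = 1 - r (0 for perfectly correlated rows, 2 for
    anti-correlated)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc, vc = u - u.mean(), v - v.mean()
    denom = np.linalg.norm(uc) * np.linalg.norm(vc)
    if denom == 0:
        raise ValueError("correlation distance undefined for a constant vector")
    return float(1.0 - uc @ vc / denom)


def umap_reduce(
    train: np.ndarray,
    others: list[np.ndarray] | tuple[np.ndarray, ...] = (),
    n_components: int = 50,
    n_neighbors: int = 20,
    min_dist: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """UMAP embedding with Pearson-correlation distance, fit on train only.

    Defaults follow the study protocol for expression embeddings: 50
    components, 20 neighbors, correlation metric, min_dist 0.1. The
    embedding is learned on the (already scaled) training rows and then
    used to transform every partition; deterministic for a fixed seed.
    """
    import umap  # deferred: numba-jitted import is slow

    train = np.asarray(train, dtype=float)
    if n_components >= train.shape[1]:
        raise ValueError(
            f"n_components={n_components} must be smaller than the "
            f"{train.shape[1]} input features"
        )
    if train.shape[0] < n_neighbors:
        raise ValueError("need at least n_neighbors training rows")
    reducer = umap.UMAP(
        n_components=n_components,
        n_neighbors=n_neighbors,
        metric="correlation",
        min_dist=min_dist,
        random_state=seed,
    )
    embedded_train = np.asarray(reducer.fit_transform(train))
    return embedded_train, [np.asarray(reducer.transform(m)) for m in others]


# --- co-expression modules ------------------------------------------------


@dataclass
class CoexpressionModules:
    """Gene->module assignment and per-cell-line module eigengenes.

    The eigengene of a module is the first principal component of its
    gene-standardized submatrix, scaled by 1/sqrt(n_module_genes) so its
    variance equals the leading-eigenvalue fraction of the module
    correlation matrix, and sign-oriented to correlate non-negatively
    with the module's mean expression profile.
    """

    module_assignment: dict[str, int]
    eigengenes: pd.DataFrame  # cell lines x modules
    explained_variance_ratio: dict[int, float] = field(default_factory=dict)


def _eigengene(sub: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of the column-standardized submatrix, scaled by 1/sqrt(p)."""
    n, p = sub.shape
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (sub - mu) / sd_safe
    u_mat, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u_mat[:, 0] * s[0] / math.sqrt(p)
    evr = float((s[0] ** 2) / (n * p))  # lambda_1 / p of the correlation matrix
    mean_profile = sub.mean(axis=1)
    orient = np.corrcoef(scores, mean_profile)[0, 1] if mean_profile.std() > 0 else 1.0
    if orient < 0:
        scores = -scores
    return scores, evr


def module_eigengenes(
    train_expr: ExpressionMatrix, n_modules: int = 10, min_genes: int = 2
) -> CoexpressionModules:
    """Partition genes into co-expression modules and compute eigengenes.

    Correlation-based agglomerative clustering (d = 1 - r, complete
    linkage) cut to ``n_modules`` clusters on the training partition.
    With fewer than ``min_genes`` genes the matrix collapses to a single
    module with a warning.
    """
    genes = train_expr.gene_symbols
    X = np.asarray(train_expr.values, dtype=float)
    if len(genes) < min_genes:
        warnings.warn(
            f"only {len(genes)} genes; falling back to a single co-expression module",
            stacklevel=2,
        )
        labels = np.ones(len(genes), dtype=int)
    else:
        dist = pdist(X.T, metric="correlation")
        if np.isnan(dist).any():
            raise ValueError(
                "constant gene encountered: remove constant genes before clustering"
            )
        Z = linkage(dist, method="complete")
        labels = fcluster(Z, t=min(n_modules, len(genes)), criterion="maxclust")
    assignment = {g: int(m) for g, m in zip(genes, labels)}
    eigen = {}
    evr = {}
    for m in sorted(set(labels.tolist())):
        idx = [i for i, lab in enumerate(labels) if lab == m]
        scores, ratio = _eigengene(X[:, idx])
        eigen[m] = scores
        evr[int(m)] = ratio
    frame = pd.DataFrame(eigen, index=train_expr.cell_line_ids)
    frame.columns = [f"ME{m}" for m in frame.columns]
    return CoexpressionModules(
        module_assignment=assignment, eigengenes=frame, explained_variance_ratio=evr
    )


# --- gene ordering and image reshaping ------------------------------------

CHROMOSOME_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]


@dataclass
class GeneImageLayout:
    """A gene permutation plus target tensor shape.

    ``permutation[p]`` is the original gene index placed at position
    ``p``; ``prod(shape) == n_genes + pad_count`` with trailing cells
    zero-padded in row-major order.
    """

    permutation: np.ndarray
    shape: tuple[int, ...]
    pad_count: int = 0

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=int)
        if not np.array_equal(np.sort(perm), np.arange(perm.size)):
            raise ValueError("layout permutation is not a bijection over gene indices")
        if int(np.prod(self.shape)) != perm.size + self.pad_count:
            raise ValueError("prod(shape) must equal n_genes + pad_count")
        self.permutation = perm

    @property
    def n_genes(self) -> int:
        return self.permutation.size

    def to_json(self) -> str:
        return json.dumps(
            {
                "permutation": self.permutation.tolist(),
                "shape": list(self.shape),
                "pad_count": self.pad_count,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneImageLayout":
        raw = json.loads(text)
        return cls(
            permutation=np.array(raw["permutation"]),
            shape=tuple(raw["shape"]),
            pad_count=raw["pad_count"],
        )


def _strip_chr(ch: str) -> str:
    return ch[3:] if ch.lower().startswith("chr") else ch


def _chromosome_rank(ch: str) -> int:
    ch = _strip_chr(str(ch))
    try:
        return CHROMOSOME_ORDER.index(ch.upper() if ch.upper() in ("X", "Y", "MT") else ch)
    except ValueError:
        return len(CHROMOSOME_ORDER)


def order_by_chromosome(genes: list[str], annotation: pd.DataFrame) -> GeneImageLayout:
    """Order genes by genomic position for image tensorization.

    Sort key: (chromosome rank in 1..22, X, Y, MT, other; start position;
    symbol). Genes without an annotation row sort after all annotated
    genes, alphabetically — deterministic for any input.
    """
    ann = annotation.set_index("symbol") if "symbol" in annotation.columns else annotation
    keys = []
    for i, g in enumerate(genes):
        if g in ann.index:
            row = ann.loc[g]
            keys.append((_chromosome_rank(row["chromosome"]), int(row["start_bp"]), g, i))
        else:
            keys.append((len(CHROMOSOME_ORDER) + 1, 0, g, i))
    order = [i for *_, i in sorted(keys)]
    return GeneImageLayout(permutation=np.array(order), shape=(len(genes),), pad_count=0)


def _optimal_leaf_order(Z: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Exact optimal leaf ordering (Bar-Joseph dynamic program).

    Among the 2^(n-1) leaf orders consistent with the dendrogram (subtree
    flips), returns one minimizing the sum of distances between
    successive leaves. ``M[v][i, j]`` is the minimal cost of ordering
    node v's subtree with leftmost leaf i and rightmost leaf j; internal
    nodes combine child tables through a min-plus product over the pair
    of leaves adjacent at the merge boundary.
    """
    n = dist.shape[0]

    def solve(node: int):
        if node < n:
            return np.array([node]), np.zeros((1, 1)), None
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        l_leaves, l_m, _ = solved[left]
        r_leaves, r_m, _ = solved[right]
        d_lr = dist[np.ix_(l_leaves, r_leaves)]
        # T[i, k2] = min_k1 Ml[i, k1] + D[k1, k2]
        t = l_m[:, :, None] + d_lr[None, :, :]
        arg_k1 = t.argmin(axis=1)
        t_min = np.take_along_axis(t, arg_k1[:, None, :], axis=1)[:, 0, :]
        # M[i, j] = min_k2 T[i, k2] + Mr[k2, j]
        u = t_min[:, :, None] + r_m[None, :, :]
        arg_k2 = u.argmin(axis=1)
        m = np.take_along_axis(u, arg_k2[:, None, :], axis=1)[:, 0, :]
        return l_leaves, r_leaves, (m, arg_k1, arg_k2)

    solved: dict[int, tuple] = {}
    for node in range(n):
        solved[node] = solve(node)
    for node in range(n, 2 * n - 1):
        l_leaves, r_leaves, (m, arg_k1, arg_k2) = solve(node)
        leaves = np.concatenate([l_leaves, r_leaves])
        nl = l_leaves.size
        full = np.full((leaves.size, leaves.size), np.inf)
        full[:nl, nl:] = m
        full[nl:, :nl] = m.T  # reversal symmetry
        solved[node] = (leaves, full, (nl, arg_k1, arg_k2))

    def reconstruct(node: int, a: int, b: int) -> list[int]:
        """Emit leaf ids for node's subtree ordered with local endpoint
        indices (a leftmost, b rightmost)."""
        leaves, _, meta = solved[node]
        if meta is None:
            return [int(leaves[0])]
        nl, arg_k1, arg_k2 = meta
        if a >= nl:  # endpoints flipped: emit the reverse orientation
            return reconstruct(node, b, a)[::-1]
        j = b - nl
        k2 = int(arg_k2[a, j])
        k1 = int(arg_k1[a, k2])
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        return reconstruct(left, a, k1) + reconstruct(right, k2, j)

    root = 2 * n - 2
    if n == 1:
        return np.array([0])
    _, m, _ = solved[root]
    a, b = np.unravel_index(np.argmin(m), m.shape)
    return np.array(reconstruct(root, int(a), int(b)), dtype=int)


def order_by_clustering(train_expr: ExpressionMatrix) -> GeneImageLayout:
    """Order genes by correlation clustering with optimal leaf ordering.

    Agglomerative clustering of genes on d = 1 - r with complete linkage,
    computed on the training partition only; the dendrogram's leaves are
    rotated to the dendrogram-consistent order minimizing the sum of
    successive-leaf distances (Bar-Joseph optimal leaf ordering).
    """
    X = np.asarray(train_expr.values, dtype=float)
    if X.shape[1] < 2:
        return GeneImageLayout(
            permutation=np.arange(X.shape[1]), shape=(X.shape[1],), pad_count=0
        )
    dist = pdist(X.T, metric="correlation")
    if np.isnan(dist).any():
        raise ValueError(
            "constant gene encountered (undefined correlation): remove constant "
            "genes before computing the clustering order"
        )
    Z = linkage(dist, method="complete")
    order = _optimal_leaf_order(Z, squareform(dist))
    return GeneImageLayout(permutation=order, shape=(X.shape[1],), pad_count=0)


def _layout_for_mode(layout: GeneImageLayout, mode: str) -> GeneImageLayout:
    n = layout.n_genes
    if mode == "1d":
        return GeneImageLayout(permutation=layout.permutation, shape=(n, 1), pad_count=0)
    if mode == "2d":
        side = math.ceil(math.sqrt(n))
        return GeneImageLayout(
            permutation=layout.permutation, shape=(side, side), pad_count=side * side - n
        )
    raise ValueError(f"mode must be '1d' or '2d', got {mode!r}")


def reshape_to_image(
    row: np.ndarray, layout: GeneImageLayout, mode: str = "2d"
) -> tuple[np.ndarray, GeneImageLayout]:
    """Reshape one expression row into a CNN input tensor.

    1d: shape (n_genes, 1), no padding. 2d: the smallest square with side
    ceil(sqrt(n_genes)), filled row-major after applying the gene
    permutation, trailing cells zero-padded. Returns the tensor together
    with the concrete layout, from which the inverse mapping is
    recoverable.
    """
    row = np.asarray(row, dtype=float)
    if row.shape != (layout.n_genes,):
        raise ValueError(
            f"row length {row.shape} does not match layout with {layout.n_genes} genes"
        )
    concrete = _layout_for_mode(layout, mode)
    ordered = row[concrete.permutation]
    flat = np.concatenate([ordered, np.zeros(concrete.pad_count)])
    return flat.reshape(concrete.shape), concrete


def unreshape_image(tensor: np.ndarray, layout: GeneImageLayout) -> np.ndarray:
    """Invert :func:`reshape_to_image`, recovering the original row exactly."""
    flat = np.asarray(tensor).reshape(-1)
    ordered = flat[: layout.n_genes]
    row = np.empty(layout.n_genes)
    row[layout.permutation] = ordered
    return row


# --- mutations and copy number --------------------------------------------

# Silent plus non-coding variant classes excluded by default.
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"Silent", "Intron", "5'UTR", "3'UTR", "5'Flank", "3'Flank", "IGR", "RNA"}
)

_KNOWN_CLASSES = DEFAULT_EXCLUDED_CLASSES | {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Splice_Region",
    "Translation_Start_Site",
}


def binarize_mutations(
    records: pd.DataFrame,
    excluded_classes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CLASSES,
    sample_col: str = "Tumor_Sample_Barcode",
    gene_col: str = "Hugo_Symbol",
    class_col: str = "Variant_Classification",
) -> MutationMatrix:
    """Binary gene-level mutation matrix from MAF-like records.

    An entry is 1 iff the cell line carries at least one retained variant
    in the gene; silent and non-coding classes are excluded by default.
    Unknown variant classifications are retained with a warning rather
    than silently dropped.
    """
    for col in (sample_col, gene_col, class_col):
        if col not in records.columns:
            raise ValueError(f"mutation records missing required column {col!r}")
    unknown = sorted(set(records[class_col]) - _KNOWN_CLASSES - set(excluded_classes))
    if unknown:
        warnings.warn(
            f"unknown variant classifications treated as retained: {unknown[:5]}",
            stacklevel=2,
        )
    kept = records[~records[class_col].isin(excluded_classes)]
    cells = sorted(set(records[sample_col].astype(str)))
    genes = sorted(set(records[gene_col].astype(str)))
    values = np.zeros((len(cells), len(genes)), dtype=int)
    cell_pos = {c: i for i, c in enumerate(cells)}
    gene_pos = {g: j for j, g in enumerate(genes)}
    for cell, gene in zip(kept[sample_col].astype(str), kept[gene_col].astype(str)):
        values[cell_pos[cell], gene_pos[gene]] = 1
    return MutationMatrix(cell_line_ids=cells, feature_names=genes, values=values)


def pathway_mutation_matrix(
    gene_mut: MutationMatrix, sets: GeneSetCollection
) -> PathwayMatrix:
    """Binary pathway-level matrix: 1 iff >= 1 altered member gene.

    Pathways with no member gene present in the mutation matrix are
    dropped with a warning.
    """
    gene_pos = {g: j for j, g in enumerate(gene_mut.gene_symbols)}
    names: list[str] = []
    cols: list[np.ndarray] = []
    dropped: list[str] = []
    for name, members in sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if not idx:
            dropped.append(name)
            continue
        names.append(name)
        cols.append(gene_mut.values[:, idx].max(axis=1))
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene set(s) had no genes in the mutation matrix and "
            f"were dropped: {dropped[:5]}",
            stacklevel=2,
        )
    if not names:
        raise ValueError("no gene set overlaps the mutation matrix")
    return PathwayMatrix(
        cell_line_ids=gene_mut.cell_line_ids,
        feature_names=names,
        values=np.stack(cols, axis=1),
    )


def filter_matrix_by_list(matrix, gene_list: GeneList):
    """Keep only matrix columns whose gene is in the list (idempotent).

    Works on any omics matrix type (mutation, CNV, expression) and
    preserves the original column order; a list disjoint from the matrix
    is an error.
    """
    keep = [j for j, g in enumerate(matrix.feature_names) if g in gene_list.symbols]
    if not keep:
        raise ValueError(
            f"gene list {gene_list.name!r} shares no genes with the matrix"
        )
    return type(matrix)(
        cell_line_ids=matrix.cell_line_ids,
        feature_names=[matrix.feature_names[j] for j in keep],
        values=matrix.values[:, keep],
    )
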