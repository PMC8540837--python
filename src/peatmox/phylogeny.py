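"""Distance-based phylogenetics for pmoA sequences.

Jukes-Cantor corrected distances from a fixed multiple alignment,
neighbor-joining tree construction (Saitou-Nei Q-criterion, authored here
with a documented lowest-index tie-break), column-resampling bootstrap
support, and Newick round-tripping. Trees are scikit-bio TreeNode objects,
so downstream tooling that speaks Newick interoperates directly.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .gas_kinetics import ValidationError

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Alignment:
    """Fixed multiple alignment over {A,C,G,T,-,N}; rows of equal length."""

    ids: list[str]
    matrix: np.ndarray  # (n_seqs, n_cols), dtype S1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValidationError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValidationError("one id per alignment row is required")
        if len(self.ids) < 2:
            raise ValidationError("an alignment needs at least two sequences")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("alignment ids must be unique")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_sequences(cls, ids: list[str], sequences: list[str]) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValidationError("aligned sequences must have equal length")
        matrix = np.array(
            [np.frombuffer(s.upper().encode(), dtype="S1") for s in sequences]
        )
        return cls(ids=list(ids), matrix=matrix)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls.from_sequences(ids, seqs)

    def sequence(self, i: int) -> str:
        return self.matrix[i].tobytes().decode()

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.length, size=self.length)
        return Alignment(ids=self.ids, matrix=self.matrix[:, cols])


@dataclass
class JCDistanceResult:
    """Pairwise JC distances; saturated pairs are NaN and listed."""

    matrix: pd.DataFrame
    saturated: list[tuple[str, str]] = field(default_factory=list)


def jc_distance(alignment: Alignment, pairwise_deletion: bool = True) -> JCDistanceResult:
    """Jukes-Cantor distance matrix from an alignment.

    Columns with gaps or N are excluded per pair (pairwise deletion;
    complete deletion drops any column invalid in any row). With observed
    mismatch proportion p over the compared columns,

        d = -(3/4) * ln(1 - 4p/3),

    undefined at p >= 3/4: such pairs are flagged saturated and set NaN.
    """
    M = alignment.matrix
    valid = np.isin(M, _ACGT)
    n = alignment.n_sequences
    if not pairwise_deletion:
        keep = valid.all(axis=0)
        M = M[:, keep]
        valid = valid[:, keep]
    D = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            ncols = int(mask.sum())
            if ncols == 0:
                raise ValidationError(
                    f"no comparable columns between {alignment.ids[i]} and {alignment.ids[j]}"
                )
            p = float((M[i, mask] != M[j, mask]).sum()) / ncols
            if p >= 0.75:
                saturated.append((alignment.ids[i], alignment.ids[j]))
                D[i, j] = D[j, i] = np.nan
            else:
                D[i, j] = D[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    if saturated:
        logger.warning("%d sequence pair(s) saturated (p >= 0.75)", len(saturated))
    return JCDistanceResult(
        matrix=pd.DataFrame(D, index=alignment.ids, columns=alignment.ids),
        saturated=saturated,
    )


def _check_distance_matrix(D: pd.DataFrame) -> np.ndarray:
    arr = D.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValidationError("distance matrix must be symmetric")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("distance matrix contains non-finite entries")
    if np.any(np.diag(arr) != 0):
        raise ValidationError("distance matrix diagonal must be zero")
    return arr


def _clamp(length: float) -> float:
    if length < 0:
        logger.debug("negative NJ branch length %.3g clamped to 0", length)
        return 0.0
    return length


def neighbor_joining(D: pd.DataFrame) -> TreeNode:
    """Classic neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing Q_ij = (m-2) d_ij - r_i - r_j;
    ties are broken by the lowest index pair in the current node order.
    On an additive matrix the generating topology and branch lengths are
    recovered exactly. Negative branch-length estimates are clamped to 0.
    Returns an unrooted tree (root degree 3, or 2 for <=3 taxa).
    """
    arr = _check_distance_matrix(D)
    ids = list(D.index)
    n = len(ids)
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]

    if n == 2:
        half = arr[0, 1] / 2.0
        for node in nodes:
            node.length = _clamp(half)
        return TreeNode(children=nodes)

    d = arr.copy()
    active = list(range(n))
    all_nodes = list(nodes)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first occurrence: lowest-index tie-break
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        all_nodes[i].length = _clamp(vi)
        all_nodes[j].length = _clamp(vj)
        parent = TreeNode(children=[all_nodes[i], all_nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        all_nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(all_nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in zip((a, b, c), (la, lb, lc)):
        all_nodes[idx].length = _clamp(length)
    return TreeNode(children=[all_nodes[a], all_nodes[b], all_nodes[c]])


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, orientation-free.

    Each internal edge splits the leaves in two; the split is represented
    by its canonical side (smaller set, ties by sorted names).
    """
    taxa = frozenset(leaf.name for leaf in tree.tips())
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canon)
    return splits


def _fill_saturated(result: JCDistanceResult) -> pd.DataFrame:
    """Replace saturated (NaN) pairs with 2x the largest finite distance."""
    D = result.matrix
    if not result.saturated:
        return D
    arr = D.to_numpy().copy()
    finite = arr[np.isfinite(arr)]
    cap = 2.0 * finite.max() if finite.size else 1.0
    arr[~np.isfinite(arr)] = cap
    np.fill_diagonal(arr, 0.0)
    logger.warning(
        "replaced %d saturated pair distance(s) with cap %.3g", len(result.saturated), cap
    )
    return pd.DataFrame(arr, index=D.index, columns=D.columns)


def nj_from_alignment(alignment: Alignment) -> TreeNode:
    result = jc_distance(alignment)
    if result.saturated:
        raise ValidationError(f"saturated pairs in point estimate: {result.saturated}")
    return neighbor_joining(result.matrix)


@dataclass
class BootstrapResult:
    tree: TreeNode                      # point-estimate tree, supports attached
    supports: dict[frozenset, float]    # bipartition -> % of replicates
    n_replicates: int
    n_saturated_replicates: int = 0

    def high_support(self, threshold: float = 80.0) -> set[frozenset]:
        """Bipartitions above the annotation threshold (presentational)."""
        return {split for split, s in self.supports.items() if s > threshold}


def bootstrap_support(
    alignment: Alignment, n_replicates: int = 500, seed: int | None = None
) -> BootstrapResult:
    """Column-resampling bootstrap support for the NJ point-estimate tree.

    Resamples alignment columns with replacement, rebuilds the JC+NJ tree
    per replicate, and reports, for each internal bipartition of the point
    estimate, the percentage of replicates containing it. Replicates whose
    distance matrix has saturated pairs use the capped-distance fallback
    and are counted. Supports are written onto the internal nodes (name).
    """
    if alignment.n_sequences < 4:
        raise ValidationError("bootstrap support needs at least four sequences")
    point = nj_from_alignment(alignment)
    target = bipartitions(point)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    n_saturated = 0
    for _ in range(n_replicates):
        rep = alignment.resample_columns(rng)
        result = jc_distance(rep)
        if result.saturated:
            n_saturated += 1
        tree = neighbor_joining(_fill_saturated(result))
        seen = bipartitions(tree)
        for split in target:
            if split in seen:
                counts[split] += 1
    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    taxa = frozenset(alignment.ids)
    for node in point.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        canon = min(side, taxa - side, key=lambda s: (len(s), tuple(sorted(s))))
        if canon in supports:
            node.name = f"{supports[canon]:.0f}"
    return BootstrapResult(
        tree=point,
        supports=supports,
        n_replicates=n_replicates,
        n_saturated_replicates=n_saturated,
    )


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse Newick text; unbalanced parentheses are reported with offset."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValidationError(f"unbalanced ')' at offset {pos}")
    if depth != 0:
        raise ValidationError(f"{depth} unclosed '(' at end of input (length {len(text)})")
    try:
        return TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio parse failure
        raise ValidationError(f"malformed newick: {exc}") from exc
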