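"""Covariance PCA, neighbor-joining, bootstrap support and matrix correlations.

Clustering of TBP marker matrices follows the classical distance route:
Whittaker dissimilarities -> neighbor-joining (Saitou-Nei agglomeration on
the Q-criterion) -> unrooted tree, with branch support from bootstrap
resampling of marker columns.  Neighbor joining is implemented here rather
than delegated so that tie-breaking (lowest index pair on equal Q) and
negative-branch handling (clamp to zero, deficit moved to the sister branch)
are fixed conventions instead of library-dependent behaviour; on an additive
distance matrix the reconstruction is exact.

Ordination uses PCA on the *covariance* matrix of the 0/1 markers
(column-mean-centred, unscaled), the convention of classical morphometric
packages for binary data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .binning import MarkerMatrix
from .diversity import dissimilarity_matrix
from .errors import TBPKitError, ZeroVarianceError

__all__ = [
    "PcaResult",
    "TreeResult",
    "MatrixCorrelationResult",
    "pca_covariance",
    "nj_tree",
    "bootstrap_support",
    "cophenetic_correlation",
    "matrix_correlation",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: pd.DataFrame
    degenerate: bool = False


def pca_covariance(matrix: MarkerMatrix) -> PcaResult:
    """PCA of the samples on the covariance matrix of their markers.

    Columns are mean-centred but not scaled; eigenvalues are reported in
    descending order together with the percent of total variance each
    explains.  Scores are reproducible up to a sign flip per component
    (the usual eigenvector ambiguity).  If all rows are identical the total
    variance is zero and the result is flagged degenerate.
    """
    if np.isnan(matrix.values).any():
        raise TBPKitError("matrix has missing cells; PCA needs complete data")
    n, p = matrix.shape
    if n < 3:
        raise TBPKitError(f"PCA needs >= 3 samples, got {n}")
    if p < 2:
        raise TBPKitError(f"PCA needs >= 2 markers, got {p}")
    X = matrix.values
    Xc = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    total = w.sum()
    degenerate = bool(total <= 1e-12)
    pct = np.zeros_like(w) if degenerate else 100.0 * w / total
    scores = pd.DataFrame(
        Xc @ v,
        index=matrix.samples,
        columns=[f"PC{k + 1}" for k in range(p)],
    )
    return PcaResult(w, pct, scores, degenerate)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeResult:
    """An unrooted NJ tree (stored with a trifurcating root) plus supports.

    ``supports`` maps each internal-edge bipartition — canonicalised as the
    frozenset of leaf names on the side *not* containing the
    lexicographically smallest leaf — to a bootstrap percentage in [0, 100].
    """

    tree: TreeNode
    supports: dict[frozenset, float] | None = None
    n_redrawn_replicates: int = 0

    @property
    def leaf_names(self) -> frozenset:
        return frozenset(t.name for t in self.tree.tips())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one per internal edge."""
        tips = self.leaf_names
        ref = min(tips)
        splits: set[frozenset] = set()
        for node in self.tree.traverse(include_self=False):
            if node.is_tip():
                continue
            clade = frozenset(t.name for t in node.tips())
            if len(clade) < 2 or len(tips) - len(clade) < 2:
                continue
            splits.add(clade if ref not in clade else tips - clade)
        return splits

    def support_for(self, leaf_group) -> float | None:
        """Bootstrap support of the edge separating ``leaf_group`` from the
        rest, or None if no such edge exists in the tree."""
        if self.supports is None:
            return None
        tips = self.leaf_names
        group = frozenset(leaf_group)
        side = group if min(tips) not in group else tips - group
        return self.supports.get(side)

    def cophenetic(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length (cophenetic) distances."""
        return self.tree.tip_tip_distances()

    def newick(self) -> str:
        """Serialize with bootstrap supports as internal node labels and
        branch lengths at 6 significant digits."""
        tips = self.leaf_names
        ref = min(tips)

        def render(node: TreeNode) -> str:
            if node.is_tip():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if self.supports is not None and node.parent is not None:
                clade = frozenset(t.name for t in node.tips())
                if 2 <= len(clade) <= len(tips) - 2:
                    side = clade if ref not in clade else tips - clade
                    if side in self.supports:
                        label = f"{self.supports[side]:.4g}"
            length = "" if node.length is None else f":{node.length:.6g}"
            return f"({inner}){label}{length}"

        return render(self.tree) + ";"


def _validate_distance_matrix(d: DistanceMatrix) -> np.ndarray:
    a = np.asarray(d.data, dtype=float)
    if np.isnan(a).any():
        raise TBPKitError("distance matrix contains NaN")
    if (a < 0).any():
        raise TBPKitError("distance matrix contains negative entries")
    return a


def nj_tree(d: DistanceMatrix) -> TreeResult:
    """Neighbor-joining tree from a dissimilarity matrix (Saitou-Nei).

    At each step the pair minimising Q(i, j) = (m - 2) d(i, j) - r_i - r_j
    is joined; ties are broken by the lowest (i, j) index pair so the result
    is deterministic.  Negative branch lengths are clamped to zero with the
    deficit moved to the sister branch, preserving the joined pair's path
    length.  For an additive matrix the leaf-to-leaf path lengths of the
    returned tree reproduce the input distances exactly.
    """
    D = _validate_distance_matrix(d)
    ids = list(d.ids)
    n = len(ids)
    if n < 3:
        raise TBPKitError(f"neighbor joining needs >= 3 taxa, got {n}")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    D = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q = np.minimum(Q, Q.T)  # exact symmetry despite FP rounding of -r_i - r_j
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        i, j = next(
            (a, b)
            for a in range(m)
            for b in range(a + 1, m)
            if Q[a, b] == qmin
        )
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.append(nodes[i])
        parent.append(nodes[j])

        keep = [k for k in range(m) if k not in (i, j)]
        dnew = 0.5 * (D[i, keep] + D[j, keep] - dij)
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[m - 2, : m - 2] = dnew
        D2[: m - 2, m - 2] = dnew
        D2[m - 2, m - 2] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        D = D2

    # resolve the final three lineages around an unrooted (trifurcating) root
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = float(max(length, 0.0))
        root.append(node)
    return TreeResult(root)


def bootstrap_support(
    matrix: MarkerMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    max_redraws_per_replicate: int = 1000,
) -> TreeResult:
    """NJ tree with bootstrap support from resampling marker columns.

    Marker columns are the exchangeable unit of a binary marker matrix, so
    each replicate draws columns with replacement (keeping the column
    count), recomputes Whittaker distances and the NJ tree, and each
    internal edge of the full-data tree is supported by the percentage of
    replicates containing the same leaf bipartition.  A replicate that
    produces an all-zero row (a sample losing every marker) is redrawn; the
    number of redraws is logged and recorded on the result.

    Samples are put in canonical (sorted) order before any computation, so
    supports do not depend on the input row order; results are
    deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise TBPKitError(f"n_reps must be >= 1, got {n_reps}")
    order = sorted(matrix.samples)
    m = matrix.restrict(order)
    base = nj_tree(dissimilarity_matrix(m))
    targets = base.bipartitions()
    counts = {s: 0 for s in targets}

    rng = np.random.default_rng(seed)
    X = m.values
    n_cols = len(m.bins)
    redraws = 0
    for _ in range(n_reps):
        for _attempt in range(max_redraws_per_replicate):
            idx = rng.integers(0, n_cols, size=n_cols)
            Xb = X[:, idx]
            if (Xb.sum(axis=1) > 0).all():
                break
            redraws += 1
        else:
            raise TBPKitError(
                "could not draw a bootstrap replicate without an all-zero row"
            )
        rep = MarkerMatrix(order, [m.bins[k] for k in idx], Xb)
        splits = nj_tree(dissimilarity_matrix(rep)).bipartitions()
        for s in targets:
            if s in splits:
                counts[s] += 1
    if redraws:
        logger.info("bootstrap: %d replicate draw(s) redrawn (all-zero row)", redraws)
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return TreeResult(base.tree, supports=supports, n_redrawn_replicates=redraws)


# ---------------------------------------------------------------------------
# Matrix correlations (cophenetic fit and Mantel tests)
# ---------------------------------------------------------------------------


@dataclass
class MatrixCorrelationResult:
    r: float
    p: float | None
    n_permutations: int
    seed: int | None
    kind: str = "matrix"


def _offdiag_vectors(d1: DistanceMatrix, d2: DistanceMatrix):
    ids1 = list(d1.ids)
    if set(ids1) != set(d2.ids):
        only1 = sorted(set(ids1) - set(d2.ids))
        only2 = sorted(set(d2.ids) - set(ids1))
        raise TBPKitError(
            f"matrices disagree on samples: only in first={only1}, "
            f"only in second={only2}"
        )
    if list(d2.ids) != ids1:
        d2 = d2.filter(ids1)
    A = np.asarray(d1.data, float)
    B = np.asarray(d2.data, float)
    iu = np.triu_indices(len(ids1), k=1)
    return A[iu], B, iu


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError(
            "a distance vector is constant; correlation undefined"
        )
    return float(np.corrcoef(x, y)[0, 1])


def _mantel_p(
    x: np.ndarray,
    B: np.ndarray,
    iu,
    r_obs: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    """One-sided (greater) permutation p-value, permuting labels of B."""
    n = B.shape[0]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        rp = np.corrcoef(x, Bp[iu])[0, 1]
        if rp >= r_obs:
            count += 1
    return (count + 1) / (n_permutations + 1)


def matrix_correlation(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MatrixCorrelationResult:
    """Mantel-style correlation between two distance matrices.

    Pearson r over the off-diagonal upper triangles, with significance from
    permuting the sample labels of the second matrix (one-sided, greater;
    the add-one permutation p-value, so p is in (0, 1]).
    """
    x, B, iu = _offdiag_vectors(d1, d2)
    r = _pearson(x, B[iu])
    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        p = _mantel_p(x, B, iu, r, n_permutations, rng)
    return MatrixCorrelationResult(r, p, n_permutations, seed, kind="mantel")


def cophenetic_correlation(
    tree: TreeResult,
    d: DistanceMatrix,
    n_permutations: int = 0,
    seed: int | None = None,
) -> MatrixCorrelationResult:
    """Pearson correlation between input distances and tree path lengths.

    Measures how faithfully the tree represents the dissimilarity matrix it
    was built from (1.0 for an additive matrix).  A permutation p-value is
    computed only when ``n_permutations`` > 0.
    """
    if tree.leaf_names != set(d.ids):
        raise TBPKitError(
            f"tree leaves and matrix samples differ: "
            f"{sorted(tree.leaf_names.symmetric_difference(d.ids))}"
        )
    coph = tree.cophenetic().filter(list(d.ids))
    x, B, iu = _offdiag_vectors(d, coph)
    r = _pearson(x, B[iu])
    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        p = _mantel_p(x, B, iu, r, n_permutations, rng)
    return MatrixCorrelationResult(r, p, n_permutations, seed, kind="cophenetic")
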