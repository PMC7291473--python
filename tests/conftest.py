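import numpy as np
import pytest

from tbpkit.binning import MarkerMatrix, MarkerBin
from tbpkit.fragment_io import CERun, PeakRecord
from tbpkit.qc import ConsensusPeak, ConsensusProfile


def make_matrix(rows: dict[str, str], region: str = "first") -> MarkerMatrix:
    """Build a MarkerMatrix from rows like {'A': '110', 'B': '101'}."""
    samples = list(rows)
    n_bins = len(next(iter(rows.values())))
    bins = [
        MarkerBin(region, 100.0 + 10 * j, 100.0 + 10 * j, 100.0 + 10 * j)
        for j in range(n_bins)
    ]
    values = np.array([[int(c) for c in rows[s]] for s in samples], dtype=float)
    return MarkerMatrix(samples, bins, values)


def make_profile(code: str, region: str, sizes, support: int = 4) -> ConsensusProfile:
    return ConsensusProfile(
        code, region, [ConsensusPeak(float(s), support, 1000.0) for s in sizes]
    )


def make_run(sizes_heights, code="S1", region="first", amp="1", dil="1") -> CERun:
    return CERun(
        code,
        region,
        amp,
        dil,
        peaks=[PeakRecord(float(s), float(h)) for s, h in sizes_heights],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_additive_distances(rng, n_leaves: int) -> np.ndarray:
    """Leaf-to-leaf distances of a random tree with positive branch lengths.

    Serves as the independent oracle for neighbor joining: NJ must
    reconstruct such a matrix exactly.
    """
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    active = list(range(n_leaves))
    next_id = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        u = next_id
        next_id += 1
        adj[u] = []
        for child in (a, b):
            length = float(rng.uniform(0.1, 2.0))
            adj[u].append((child, length))
            adj[child].append((u, length))
        active = [x for x in active if x not in (a, b)] + [u]

    D = np.zeros((n_leaves, n_leaves))
    for s in range(n_leaves):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            v = stack.pop()
            for w, length in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + length
                    stack.append(w)
        for t in range(n_leaves):
            D[s, t] = dist[t]
    # mirror the upper triangle: path sums can differ by FP rounding per direction
    iu = np.triu_indices(n_leaves, 1)
    D[(iu[1], iu[0])] = D[iu]
    return D


def treenode_bipartitions(tree, leaf_names=None) -> set[frozenset]:
    """Non-trivial bipartitions of any (skbio) TreeNode, canonicalised as in
    tbpkit.trees.TreeResult."""
    tips = frozenset(t.name for t in tree.tips()) if leaf_names is None else frozenset(leaf_names)
    ref = min(tips)
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(tips) - len(clade) < 2:
            continue
        splits.add(clade if ref not in clade else tips - clade)
    return splits
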