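"""Distance-based treeness statistics: delta scores and Q-residuals.

For every quartet {i,j,k,l} the three pairings give sums
d(i,j)+d(k,l), d(i,k)+d(j,l), d(i,l)+d(j,k), ordered m1 >= m2 >= m3.  On an
additive (perfectly tree-like) distance matrix the two largest are equal
(the four-point condition), so

    delta = (m1 - m2) / (m1 - m3)        (0 when m1 = m3)

is 0 for tree-like quartets and approaches 1 for star/box-like ones.  The
Q-residual is the companion absolute statistic ((m1 - m2)/2)^2 computed on
distances rescaled so the mean off-diagonal entry is 1.  Both are averaged
over quartets; low values support predominantly vertical transmission.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .character_matrix import CharacterMatrix
from .tree import PhyloTree

__all__ = [
    "DistanceMatrix",
    "TreenessReport",
    "mean_character_distance",
    "delta_scores",
    "q_residual",
    "treeness_report",
    "patristic_distances",
]

#: exhaustive quartet enumeration is used up to this many quartets
DEFAULT_QUARTET_BUDGET = 500_000


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    taxa: tuple
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.taxa)


@dataclass(frozen=True)
class TreenessReport:
    mean_delta: float
    per_taxon_delta: dict
    mean_q_residual: float
    n_quartets: int


def mean_character_distance(matrix: CharacterMatrix) -> DistanceMatrix:
    """Mean character difference with pairwise deletion: d(i,j) is the
    proportion of characters scored (non-missing) in both taxa whose cells
    differ.  Intended for binarized matrices but defined for any coding."""
    n, m = matrix.shape
    # encode cells as integers: equal cells get equal codes; missing = -1
    codebook: dict = {}
    enc = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            cell = matrix.cells[i][j]
            key = None if cell.is_missing else cell.states
            if key is None:
                enc[i, j] = -1
            else:
                enc[i, j] = codebook.setdefault(key, len(codebook))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] >= 0) & (enc[j] >= 0)
            tot = int(both.sum())
            if tot == 0:
                raise ValueError(
                    f"taxa {matrix.taxa[i].name!r} and {matrix.taxa[j].name!r} "
                    "share no scored characters"
                )
            d[i, j] = d[j, i] = np.count_nonzero(enc[i][both] != enc[j][both]) / tot
    return DistanceMatrix(tuple(matrix.taxon_names()), d)


def _quartet_indices(n: int, max_quartets: Optional[int], seed: Optional[int]) -> np.ndarray:
    n_all = n * (n - 1) * (n - 2) * (n - 3) // 24
    budget = max_quartets or DEFAULT_QUARTET_BUDGET
    if n_all <= budget:
        return np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)
    rng = np.random.default_rng(seed)
    picks = set()
    while len(picks) < budget:
        q = rng.choice(n, size=4, replace=False)
        picks.add(tuple(sorted(int(x) for x in q)))
    return np.array(sorted(picks), dtype=np.int64)


def _pairing_sums(d: np.ndarray, q: np.ndarray) -> np.ndarray:
    i, j, k, l = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    sums = np.stack(
        [d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]], axis=1
    )
    sums.sort(axis=1)
    return sums[:, ::-1]  # m1 >= m2 >= m3


def treeness_report(
    D: DistanceMatrix,
    max_quartets: Optional[int] = None,
    seed: Optional[int] = None,
) -> TreenessReport:
    """Delta scores and Q-residuals over all quartets (or a seeded random
    sample when the quartet count exceeds the budget)."""
    if D.n < 4:
        raise ValueError("need at least 4 taxa")
    q = _quartet_indices(D.n, max_quartets, seed)
    sums = _pairing_sums(D.values, q)
    m1, m2, m3 = sums[:, 0], sums[:, 1], sums[:, 2]
    spread = m1 - m3
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(spread > 0, (m1 - m2) / spread, 0.0)

    off = D.values[np.triu_indices(D.n, k=1)]
    mean_off = off.mean()
    if mean_off <= 0:
        raise ValueError("degenerate all-zero distance matrix")
    sums_norm = _pairing_sums(D.values / mean_off, q)
    q_res = ((sums_norm[:, 0] - sums_norm[:, 1]) / 2.0) ** 2

    per_taxon: dict = {}
    sums_by_taxon = np.zeros(D.n)
    counts = np.zeros(D.n)
    for col in range(4):
        np.add.at(sums_by_taxon, q[:, col], delta)
        np.add.at(counts, q[:, col], 1)
    for idx, name in enumerate(D.taxa):
        per_taxon[name] = float(sums_by_taxon[idx] / counts[idx]) if counts[idx] else 0.0
    return TreenessReport(
        mean_delta=float(delta.mean()),
        per_taxon_delta=per_taxon,
        mean_q_residual=float(q_res.mean()),
        n_quartets=len(q),
    )


def delta_scores(
    D: DistanceMatrix, max_quartets: Optional[int] = None, seed: Optional[int] = None
) -> TreenessReport:
    """Quartet delta scores (mean and per-taxon); see module docstring."""
    return treeness_report(D, max_quartets, seed)


def q_residual(
    D: DistanceMatrix, max_quartets: Optional[int] = None, seed: Optional[int] = None
) -> float:
    """Mean Q-residual on mean-normalized distances."""
    return treeness_report(D, max_quartets, seed).mean_q_residual


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (requires branch lengths on every
    non-root edge); additive by construction, so delta and Q-residual vanish
    on the result."""
    leaves = tree.leaves()
    names = [l.label for l in leaves]
    # depth of every node from the root
    depth: dict[int, float] = {id(tree.root): 0.0}
    parent_chain: dict[int, list] = {}
    for n in tree.preorder():
        if n is tree.root:
            parent_chain[id(n)] = [n]
            continue
        if n.length is None:
            raise ValueError("missing branch length")
        depth[id(n)] = depth[id(n.parent)] + n.length
        parent_chain[id(n)] = parent_chain[id(n.parent)] + [n]
    d = np.zeros((len(leaves), len(leaves)))
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            pa, pb = parent_chain[id(leaves[a])], parent_chain[id(leaves[b])]
            lca_depth = 0.0
            for x, y in zip(pa, pb):
                if x is y:
                    lca_depth = depth[id(x)]
                else:
                    break
            d[a, b] = d[b, a] = (
                depth[id(leaves[a])] + depth[id(leaves[b])] - 2 * lca_depth
            )
    return DistanceMatrix(tuple(names), d)
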