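"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by brute force
(enumeration over ancestral-state assignments, over ambiguity resolutions,
over tree topologies) so that the package's optimized implementations are
checked against an independent route.
"""

from __future__ import annotations

import itertools
import random

import pytest

from culturetree.character_matrix import (
    CharacterDef,
    CharacterMatrix,
    StateSet,
    TaxonRecord,
    parse_cell,
)
from culturetree.tree import PhyloTree

# ---------------------------------------------------------------------------
# matrix builders


def build_matrix(rows: dict, alphabet=("a", "b", "c"), categories=None) -> CharacterMatrix:
    """rows: {taxon: [cell text, ...]} with cells like '0', '?', 'a', '{a,b}'."""
    names = list(rows)
    n_char = len(rows[names[0]])
    cats = categories or ["repertoire"] * n_char
    taxa = [TaxonRecord(name=n) for n in names]
    chars = [
        CharacterDef(index=j + 1, name=f"c{j + 1}", category=cats[j], alphabet=tuple(alphabet))
        for j in range(n_char)
    ]
    cells = [[parse_cell(c) for c in rows[n]] for n in names]
    return CharacterMatrix(taxa, chars, cells)


def random_matrix(
    rng: random.Random,
    n_taxa: int,
    n_char: int,
    states=("a", "b", "c"),
    p_absent: float = 0.2,
    p_missing: float = 0.1,
    p_ambiguous: float = 0.15,
) -> CharacterMatrix:
    rows = {}
    for i in range(n_taxa):
        cells = []
        for _ in range(n_char):
            u = rng.random()
            if u < p_missing:
                cells.append("?")
            elif u < p_missing + p_absent:
                cells.append("0")
            elif u < p_missing + p_absent + p_ambiguous:
                k = rng.randint(2, len(states))
                cells.append("{" + ",".join(rng.sample(list(states), k)) + "}")
            else:
                cells.append(rng.choice(states))
        rows[f"T{i + 1}"] = cells
    return build_matrix(rows, alphabet=states)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_steps(tree: PhyloTree, column: list[frozenset], taxon_names: list[str],
                      alphabet: list[str]) -> int:
    """Minimum changes for one character by enumerating every assignment of a
    single state to every internal node (leaves pick their cheapest state;
    an empty frozenset means missing and never costs anything)."""
    by_name = dict(zip(taxon_names, column))
    internals = [n for n in tree.postorder() if not n.is_leaf]

    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, combo)}
        cost = 0
        for n in internals:
            if n.parent is not None:
                cost += state[id(n)] != state[id(n.parent)]
        for leaf in tree.leaves():
            cell = by_name[leaf.label]
            if not cell:  # missing
                continue
            p = state[id(leaf.parent)]
            cost += 0 if p in cell else 1
        if best is None or cost < best:
            best = cost
    return best


def brute_force_min_steps(column: list[frozenset]) -> int:
    """Minimum distinct states over all resolutions of ambiguity, minus 1."""
    cells = [c for c in column if c]
    if not cells:
        return 0
    best = None
    for combo in itertools.product(*[sorted(c) for c in cells]):
        k = len(set(combo))
        if best is None or k < best:
            best = k
    return best - 1


def column_as_sets(matrix: CharacterMatrix, j: int) -> list[frozenset]:
    out = []
    for cell in matrix.column(j):
        out.append(frozenset() if cell.is_missing else frozenset(cell.states))
    return out


def matrix_alphabet(matrix: CharacterMatrix, j: int) -> list[str]:
    return list(matrix.characters[j].full_alphabet)


# ---------------------------------------------------------------------------
# small tree helpers


def newick_tree(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


@pytest.fixture
def rng():
    return random.Random(20160330)
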