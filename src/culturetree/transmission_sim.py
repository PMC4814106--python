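"""Synthetic cultural-evolution data: vertical innovation on a genealogy
with a tunable horizontal-borrowing rate.

The generator emulates the structure of the patrimony matrix (tens of taxa,
hundreds of characters in labeled categories, multi-state coding with
absence and missing cells) while providing complete ground truth: the
genealogy, every innovation event, and every borrowing event.

Model: a pure-birth (Yule) genealogy; every character starts absent ('0') at
the root — so rooting on the all-zero hypothetical ancestor is exactly
correct — and accrues Poisson(mu * branch length) state-change events along
each branch.  Under the infinite-allele model each innovation mints a fresh
state, which makes homoplasy impossible; under the finite-allele model
states are redrawn from a bounded alphabet and convergence/reversal can
occur.  Horizontal transmission is a single contact epoch after the vertical
phase: each leaf cell is independently replaced, with probability h, by the
corresponding cell of a donor taxon (uniform, or biased toward phylogenetic
neighbors).  Missing data is introduced at the leaf-scoring step of the
vertical phase, before borrowing, so that the vertical and borrowed matrices
differ exactly at the logged borrowing events.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .character_matrix import (
    ABSENT,
    ABSENT_SYMBOL,
    MISSING,
    CharacterDef,
    CharacterMatrix,
    S1_CATEGORY_RANGES,
    StateSet,
    TaxonRecord,
)
from .tree import Node, PhyloTree
from .treeness import patristic_distances

__all__ = [
    "SimParams",
    "SimOutput",
    "InnovationEvent",
    "BorrowingEvent",
    "default_category_counts",
    "simulate_genealogy",
    "evolve_characters",
    "apply_horizontal",
    "simulate",
    "write_events",
]

#: character-count proportions of the published 58x322 matrix
_S1_COUNTS = {cat: hi - lo + 1 for cat, (lo, hi) in S1_CATEGORY_RANGES.items()}


def default_category_counts(n_characters: int = 322) -> dict:
    """Scale the published per-category character counts (161/63/64/14/13/
    3/2/2) to ``n_characters`` by largest remainder."""
    total = sum(_S1_COUNTS.values())
    quotas = {c: n_characters * k / total for c, k in _S1_COUNTS.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    short = n_characters - sum(counts.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - int(quotas[c]), reverse=True)[:short]:
        counts[c] += 1
    return counts


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated dataset.

    ``innovation_rate`` is the expected number of state-change events per
    character per unit branch length (the Yule birth rate is 1, so branch
    lengths are in expected-splits units).  ``horizontal_rate`` is the
    per-cell probability of replacement during the contact epoch.
    ``allele_model`` may be a single model name or a per-category mapping;
    by default repertoire characters follow the infinite-allele model (every
    innovation is a fresh named repertoire) and all others draw from a
    bounded alphabet.
    """

    seed: int
    n_taxa: int = 58
    n_characters: int = 322
    category_counts: Optional[dict] = None
    alphabet_size: int = 8
    innovation_rate: float = 0.3
    allele_model: Union[str, dict, None] = None
    horizontal_rate: float = 0.0
    borrowing_locality: str = "uniform"
    missing_fraction: float = 0.02

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not 0.0 <= self.horizontal_rate <= 1.0:
            raise ValueError("horizontal_rate must be in [0, 1]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.innovation_rate < 0:
            raise ValueError("innovation_rate must be >= 0")
        if self.borrowing_locality not in ("uniform", "neighbor"):
            raise ValueError("borrowing_locality is 'uniform' or 'neighbor'")

    def resolved_counts(self) -> dict:
        counts = self.category_counts or default_category_counts(self.n_characters)
        return {c: k for c, k in counts.items() if k > 0}

    def model_for(self, category: str) -> str:
        if isinstance(self.allele_model, str):
            return self.allele_model
        if isinstance(self.allele_model, dict):
            return self.allele_model.get(category, "finite")
        return "infinite" if category == "repertoire" else "finite"


@dataclass(frozen=True)
class InnovationEvent:
    char_index: int  # 1-based
    node: str  # simulator id of the child node of the branch
    from_state: str
    to_state: str


@dataclass(frozen=True)
class BorrowingEvent:
    char_index: int
    recipient: str
    donor: str
    from_state: str
    to_state: str


@dataclass
class SimOutput:
    tree: PhyloTree
    matrix: CharacterMatrix  # after borrowing (and missing data)
    vertical_matrix: CharacterMatrix  # purely vertical phase
    events: list


# ---------------------------------------------------------------------------
# genealogy


def simulate_genealogy(params: SimParams, rng: Optional[np.random.Generator] = None) -> PhyloTree:
    """Pure-birth (Yule, rate 1) rooted binary genealogy with ``n_taxa``
    leaves.  All lineages open at the n-th speciation receive a final
    exponential hanging time, so every branch length is positive."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = params.n_taxa
    root = Node()
    root.annotations["sim_id"] = "N0"
    t_now = 0.0
    active: list[tuple[Node, float]] = [(root, 0.0), (root, 0.0)]
    # active entries are (parent node, birth time) of open lineages
    next_internal = 1
    while len(active) < n:
        t_now += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent, born = active.pop(i)
        node = Node(length=t_now - born)
        node.annotations["sim_id"] = f"N{next_internal}"
        next_internal += 1
        parent.add_child(node)
        active.append((node, t_now))
        active.append((node, t_now))
    t_end = t_now + rng.exponential(1.0 / n)
    for k, (parent, born) in enumerate(active, start=1):
        leaf = Node(f"T{k}", length=t_end - born)
        leaf.annotations["sim_id"] = leaf.label
        parent.add_child(leaf)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# vertical phase


def _letters() -> list[str]:
    return list(string.ascii_lowercase)


def _mint(counter: int) -> str:
    """Fresh state token: a..z, then aa, ab, ..."""
    letters = string.ascii_lowercase
    if counter < 26:
        return letters[counter]
    hi, lo = divmod(counter - 26, 26)
    return letters[hi] + letters[lo]


def evolve_characters(
    tree: PhyloTree,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CharacterMatrix, list]:
    """Evolve every character down ``tree`` from an all-absent root.

    Returns the leaf matrix (missing cells already injected) and the
    innovation-event log.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    counts = params.resolved_counts()
    chars: list[tuple[str, str, str]] = []  # (name, category, model)
    for cat in counts:
        model = params.model_for(cat)
        for i in range(counts[cat]):
            chars.append((f"{cat}_{i + 1}", cat, model))

    leaves = tree.leaves()
    events: list = []
    columns: list[list[StateSet]] = []
    defs: list[CharacterDef] = []
    finite_alpha = _letters()[: params.alphabet_size]
    finite_states = [ABSENT_SYMBOL] + finite_alpha
    order = tree.preorder()
    for j, (name, cat, model) in enumerate(chars):
        state: dict[int, str] = {id(tree.root): ABSENT_SYMBOL}
        minted = 0
        for node in order:
            if node is tree.root:
                continue
            s = state[id(node.parent)]
            n_ev = int(rng.poisson(params.innovation_rate * (node.length or 0.0)))
            for _ in range(n_ev):
                if model == "infinite":
                    new = _mint(minted)
                    minted += 1
                else:
                    options = [x for x in finite_states if x != s]
                    new = options[int(rng.integers(len(options)))]
                events.append(
                    InnovationEvent(
                        char_index=j + 1,
                        node=node.annotations.get("sim_id", node.label or "?"),
                        from_state=s,
                        to_state=new,
                    )
                )
                s = new
            state[id(node)] = s
        col = []
        observed = set()
        for leaf in leaves:
            if params.missing_fraction and rng.random() < params.missing_fraction:
                col.append(MISSING)
                continue
            s = state[id(leaf)]
            if s == ABSENT_SYMBOL:
                col.append(ABSENT)
            else:
                col.append(StateSet(frozenset((s,))))
                observed.add(s)
        columns.append(col)
        alphabet = tuple(finite_alpha) if model == "finite" else tuple(sorted(observed))
        defs.append(
            CharacterDef(index=j + 1, name=name, category=cat, alphabet=alphabet)
        )
    taxa = [TaxonRecord(name=l.label) for l in leaves]
    cells = [[columns[j][i] for j in range(len(chars))] for i in range(len(leaves))]
    return CharacterMatrix(taxa, defs, cells), events


# ---------------------------------------------------------------------------
# horizontal phase


def apply_horizontal(
    matrix: CharacterMatrix,
    tree: PhyloTree,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CharacterMatrix, list]:
    """Single contact epoch: each (taxon, character) cell is independently
    replaced with probability ``horizontal_rate`` by the corresponding cell
    of a donor taxon drawn from the pre-contact matrix."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    h = params.horizontal_rate
    n, m = matrix.shape
    names = matrix.taxon_names()
    cells = [list(row) for row in matrix.cells]
    events: list = []
    if h == 0.0 or n < 2:
        return CharacterMatrix(matrix.taxa, matrix.characters, cells), events

    if params.borrowing_locality == "neighbor":
        order = {name: k for k, name in enumerate(tree.leaf_names())}
        pd = patristic_distances(tree).values
        # weights toward phylogenetically adjacent taxa
        weights = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    weights[i, j] = 1.0 / max(pd[order[names[i]], order[names[j]]], 1e-9)
            weights[i] /= weights[i].sum()
    else:
        weights = None

    for i in range(n):
        for j in range(m):
            if rng.random() >= h:
                continue
            if weights is None:
                donor = int(rng.integers(n - 1))
                if donor >= i:
                    donor += 1
            else:
                donor = int(rng.choice(n, p=weights[i]))
            old, new = matrix.cells[i][j], matrix.cells[donor][j]
            cells[i][j] = new
            events.append(
                BorrowingEvent(
                    char_index=j + 1,
                    recipient=names[i],
                    donor=names[donor],
                    from_state=_cell_repr(old),
                    to_state=_cell_repr(new),
                )
            )
    return CharacterMatrix(matrix.taxa, matrix.characters, cells), events


def _cell_repr(cell: StateSet) -> str:
    from .character_matrix import format_cell

    return format_cell(cell)


# ---------------------------------------------------------------------------
# wrapper


def simulate(params: SimParams) -> SimOutput:
    """Genealogy + vertical evolution + horizontal contact, from one seed."""
    rng = np.random.default_rng(params.seed)
    tree = simulate_genealogy(params, rng)
    vertical, innovations = evolve_characters(tree, params, rng)
    borrowed, borrowings = apply_horizontal(vertical, tree, params, rng)
    return SimOutput(
        tree=tree,
        matrix=borrowed,
        vertical_matrix=vertical,
        events=list(innovations) + list(borrowings),
    )


def write_events(events: Sequence, path) -> None:
    """Tab-separated event log (innovations and borrowings)."""
    with open(path, "w") as fh:
        fh.write("type\tchar\twhere\tdonor\tfrom\tto\n")
        for e in events:
            if isinstance(e, InnovationEvent):
                fh.write(
                    f"innovation\t{e.char_index}\t{e.node}\t-\t{e.from_state}\t{e.to_state}\n"
                )
            else:
                fh.write(
                    f"borrowing\t{e.char_index}\t{e.recipient}\t{e.donor}\t"
                    f"{e.from_state}\t{e.to_state}\n"
                )
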