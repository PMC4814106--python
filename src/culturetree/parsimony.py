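"""Maximum parsimony for unordered multistate cultural characters.

Characters are optimized with Fitch state-set operations; a multi-state cell
is an ambiguity ("any-of") set, so two taxa whose cells overlap can be joined
without cost.  The module provides the per-character homoplasy profile (the
consistency index CI = M/S and retention index RI = (G-S)/(G-M), where M is
the minimum conceivable number of changes, S the realized number of steps on
the tree, and G the number of steps on a completely unresolved star tree),
heuristic tree search with random addition sequences and NNI/SPR/TBR branch
swapping, strict and majority-rule consensus, ACCTRAN ancestral-state
assignment, Bremer decay supports, and rooting on an all-zero hypothetical
ancestor.
"""

from __future__ import annotations

import itertools
import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .character_matrix import (
    ABSENT,
    ABSENT_SYMBOL,
    CharacterDef,
    CharacterMatrix,
    StateSet,
    TaxonRecord,
    informative_mask,
)
from .tree import Node, PhyloTree

__all__ = [
    "CharacterFit",
    "TreeScore",
    "SearchConfig",
    "SearchResult",
    "NodeSupport",
    "fitch_steps",
    "min_steps",
    "star_steps",
    "character_fit",
    "ensemble_fit",
    "profile_fits",
    "category_summary",
    "add_zero_ancestor",
    "root_at",
    "heuristic_search",
    "exhaustive_search",
    "enumerate_topologies",
    "strict_consensus",
    "majority_consensus",
    "acctran_assign",
    "bremer_supports",
]

ANCESTOR_NAME = "ANCESTOR"


# ---------------------------------------------------------------------------
# encoding: cells to bitmasks


class _Encoded:
    """Per-character bitmask encoding of a matrix (missing = full set)."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.n_char = matrix.n_characters
        self.symbols: list[tuple] = []
        self.full_masks = np.zeros(self.n_char, dtype=np.uint64)
        for j, cdef in enumerate(matrix.characters):
            syms = cdef.full_alphabet
            if len(syms) > 64:
                raise ValueError(
                    f"character {cdef.name!r} has {len(syms)} states; at most 64 supported"
                )
            self.symbols.append(syms)
            self.full_masks[j] = (1 << len(syms)) - 1
        self.codes: dict[str, np.ndarray] = {}
        for i, taxon in enumerate(matrix.taxa):
            row = np.zeros(self.n_char, dtype=np.uint64)
            for j in range(self.n_char):
                cell = matrix.cells[i][j]
                if cell.is_missing:
                    row[j] = self.full_masks[j]
                else:
                    bits = 0
                    idx = self.symbols[j]
                    for tok in cell.states:
                        bits |= 1 << idx.index(tok)
                    row[j] = bits
            self.codes[taxon.name] = row


def _fitch_vectors(root: Node, codes: dict[str, np.ndarray], n_char: int) -> np.ndarray:
    """Per-character Fitch step counts for the (sub)tree at ``root``.

    A labeled node with children (the rooted-at-leaf search representation)
    contributes its own state set as an extra child.  Multifurcations are
    folded left-to-right, i.e. resolved arbitrarily as a caterpillar.
    """
    steps = np.zeros(n_char, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    stack, order = [root], []
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(n.children)
    for n in reversed(order):
        if n.is_leaf:
            sets[id(n)] = codes[n.label]
            continue
        parts = [sets.pop(id(c)) for c in n.children]
        if n.label is not None:
            parts.append(codes[n.label])
        cur = parts[0]
        for other in parts[1:]:
            inter = cur & other
            zero = inter == 0
            steps += zero
            cur = np.where(zero, cur | other, inter)
        sets[id(n)] = cur
    return steps


def _tree_length(root: Node, enc: _Encoded) -> int:
    return int(_fitch_vectors(root, enc.codes, enc.n_char).sum())


def fitch_steps(tree: PhyloTree, matrix: CharacterMatrix):
    """Per-character minimum step counts of ``matrix`` on ``tree`` under
    unordered-state (Fitch) parsimony, plus the total length L.

    Terminal ambiguity sets cost nothing to match; missing cells behave as
    the full alphabet.  Raises if leaves and taxa differ.
    """
    leaf_set = set(tree.leaf_names())
    taxa_set = set(matrix.taxon_names())
    if leaf_set != taxa_set:
        only_tree = sorted(leaf_set - taxa_set)
        only_mat = sorted(taxa_set - leaf_set)
        raise ValueError(
            f"tree/matrix taxa mismatch: only in tree {only_tree}, only in matrix {only_mat}"
        )
    enc = _Encoded(matrix)
    steps = _fitch_vectors(tree.root, enc.codes, enc.n_char)
    return steps, int(steps.sum())


# ---------------------------------------------------------------------------
# per-character bounds m and g


def min_steps(column: Sequence[StateSet]) -> int:
    """Minimum conceivable changes M for one character: the smallest number
    of distinct states over all resolutions of ambiguity (ignoring missing),
    minus one.  Equivalently a minimum hitting set over the cells' sets."""
    cells = [frozenset(c.states) for c in column if not c.is_missing]
    if not cells:
        warnings.warn("all-missing character; M = 0")
        return 0
    universe = sorted(set().union(*cells))
    pos = {s: i for i, s in enumerate(universe)}
    masks = sorted({sum(1 << pos[s] for s in cell) for cell in cells})
    forced = 0
    for cell in cells:
        if len(cell) == 1:
            forced |= 1 << pos[next(iter(cell))]
    masks = [m for m in masks if not (m & forced)]
    if not masks:
        return bin(forced).count("1") - 1
    free = [i for i, s in enumerate(universe) if not (forced >> i) & 1]
    for extra in range(1, len(free) + 1):
        for combo in itertools.combinations(free, extra):
            pick = forced
            for i in combo:
                pick |= 1 << i
            if all(m & pick for m in masks):
                return bin(pick).count("1") - 1
    return len(universe) - 1  # pragma: no cover - loop always terminates


def star_steps(column: Sequence[StateSet]) -> int:
    """Steps G on a star tree: best single ancestral state, each cell not
    containing it costing one step (missing cells cost nothing)."""
    cells = [c.states for c in column if not c.is_missing]
    if not cells:
        return 0
    universe = set().union(*cells)
    return min(sum(1 for cell in cells if z not in cell) for z in universe)


# ---------------------------------------------------------------------------
# fit statistics


@dataclass(frozen=True)
class CharacterFit:
    """Homoplasy profile of one character on one tree (m = M, s = S, g = G)."""

    index: int
    m: int
    s: float
    g: int
    ci: float
    ri: Optional[float]


@dataclass(frozen=True)
class TreeScore:
    """Tree length and ensemble CI/RI, over all and informative-only
    characters."""

    length: int
    ci: float
    ri: float
    ci_informative: float
    ri_informative: float
    n_informative: int


def _fit_from_msg(index: int, m: int, s: float, g: int) -> CharacterFit:
    ci = 1.0 if s == 0 else m / s
    ri = (g - s) / (g - m) if g > m else None
    return CharacterFit(index=index, m=m, s=s, g=g, ci=ci, ri=ri)


def character_fit(tree: PhyloTree, matrix: CharacterMatrix) -> list[CharacterFit]:
    steps, _ = fitch_steps(tree, matrix)
    out = []
    for j in range(matrix.n_characters):
        col = matrix.column(j)
        out.append(_fit_from_msg(j + 1, min_steps(col), int(steps[j]), star_steps(col)))
    return out


def _ensemble(ms, ss, gs) -> tuple:
    sm, ssum, sg = sum(ms), sum(ss), sum(gs)
    ci = 1.0 if ssum == 0 else sm / ssum
    ri = 1.0 if sg == sm else (sg - ssum) / (sg - sm)
    return ci, ri


def ensemble_fit(tree: PhyloTree, matrix: CharacterMatrix) -> TreeScore:
    """Length and ensemble CI = sum(M)/sum(S), RI = (sum G - sum S)/(sum G - sum M)."""
    fits = character_fit(tree, matrix)
    info = informative_mask(matrix)
    ci_all, ri_all = _ensemble([f.m for f in fits], [f.s for f in fits], [f.g for f in fits])
    fi = [f for f, keep in zip(fits, info) if keep]
    if fi:
        ci_i, ri_i = _ensemble([f.m for f in fi], [f.s for f in fi], [f.g for f in fi])
    else:
        ci_i = ri_i = 1.0
    return TreeScore(
        length=int(sum(f.s for f in fits)),
        ci=ci_all,
        ri=ri_all,
        ci_informative=ci_i,
        ri_informative=ri_i,
        n_informative=sum(info),
    )


def profile_fits(trees: Sequence[PhyloTree], matrix: CharacterMatrix) -> list[CharacterFit]:
    """Per-character fits averaged across a set of (equally parsimonious)
    trees: s, ci and ri are means; m and g do not depend on the tree."""
    per_tree = [character_fit(t, matrix) for t in trees]
    out = []
    for j in range(matrix.n_characters):
        fits = [ft[j] for ft in per_tree]
        s = sum(f.s for f in fits) / len(fits)
        ci = sum(f.ci for f in fits) / len(fits)
        ris = [f.ri for f in fits if f.ri is not None]
        ri = sum(ris) / len(ris) if ris else None
        out.append(CharacterFit(index=j + 1, m=fits[0].m, s=s, g=fits[0].g, ci=ci, ri=ri))
    return out


def _hist(values: Iterable[float]) -> list[int]:
    """Counts in ten bins of width 0.1 over [0, 1]; 1.0 falls in the last."""
    bins = [0] * 10
    for v in values:
        bins[min(int(v * 10), 9)] += 1
    return bins


def category_summary(
    fits: Sequence[CharacterFit],
    defs: Sequence[CharacterDef],
    informative: Sequence[bool],
) -> dict:
    """Mean and binned CI/RI per character category and per category class,
    over parsimony-informative characters only."""

    def summarize(selected: list[CharacterFit]) -> dict:
        cis = [f.ci for f in selected]
        ris = [f.ri for f in selected if f.ri is not None]
        return {
            "n_informative": len(selected),
            "mean_ci": sum(cis) / len(cis) if cis else None,
            "mean_ri": sum(ris) / len(ris) if ris else None,
            "ci_hist": _hist(cis),
            "ri_hist": _hist(ris),
        }

    by_cat: dict[str, list[CharacterFit]] = {}
    by_class: dict[str, list[CharacterFit]] = {}
    for f, d, keep in zip(fits, defs, informative):
        by_cat.setdefault(d.category, [])
        by_class.setdefault(d.category_class, [])
        if keep:
            by_cat[d.category].append(f)
            by_class[d.category_class].append(f)
    return {
        "by_category": {c: summarize(v) for c, v in sorted(by_cat.items())},
        "by_class": {c: summarize(v) for c, v in sorted(by_class.items())},
    }


# ---------------------------------------------------------------------------
# all-zero ancestor rooting


def add_zero_ancestor(matrix: CharacterMatrix, name: str = ANCESTOR_NAME) -> CharacterMatrix:
    """Append a hypothetical taxon scored absent ('0') for every character,
    used to root the tree on the assumption that states appear from absence."""
    if name in matrix.taxon_names():
        raise ValueError(f"taxon {name!r} already present")
    taxa = list(matrix.taxa) + [TaxonRecord(name=name)]
    cells = [list(r) for r in matrix.cells] + [[ABSENT] * matrix.n_characters]
    return CharacterMatrix(taxa, matrix.characters, cells)


def root_at(tree: PhyloTree, taxon: str = ANCESTOR_NAME, prune: bool = False) -> PhyloTree:
    """Root ``tree`` on the branch leading to ``taxon``.  With ``prune`` the
    rooting taxon is removed and the attachment node becomes the root, which
    is how trees rooted by the all-zero ancestor are reported."""
    t = tree.rooted_above_leaf(taxon)
    if prune:
        rest = next(c for c in t.root.children if not (c.is_leaf and c.label == taxon))
        rest.parent = None
        rest.length = None
        return PhyloTree(rest)
    return t


# ---------------------------------------------------------------------------
# tree surgery helpers (search representation: root is a labeled leaf with
# exactly one child, i.e. the unrooted tree hung from one taxon)


def _insert_above(v: Node, leaf: Node) -> Node:
    u = Node()
    p = v.parent
    p.children[p.children.index(v)] = u
    u.parent = p
    u.children = [v, leaf]
    v.parent = u
    leaf.parent = u
    return u


def _undo_insert(u: Node) -> None:
    v = u.children[0]
    p = u.parent
    p.children[p.children.index(u)] = v
    v.parent = p


def _subtree_ids(v: Node) -> set:
    out, stack = set(), [v]
    while stack:
        n = stack.pop()
        out.add(id(n))
        stack.extend(n.children)
    return out


def _reroot_subtree(vroot: Node, x: Node) -> Node:
    """Fresh copy of the subtree at ``vroot`` rerooted on the edge above
    ``x`` (x inside the subtree, not vroot or a child of vroot); the old
    degree-2 root is suppressed."""
    adj: dict[int, list[Node]] = {}
    nodes = {}
    stack = [vroot]
    while stack:
        n = stack.pop()
        nodes[id(n)] = n
        for c in n.children:
            adj.setdefault(id(n), []).append(c)
            adj.setdefault(id(c), []).append(n)
            stack.append(c)
    if len(adj[id(vroot)]) == 2:
        a, b = adj[id(vroot)]
        adj[id(a)] = [m for m in adj[id(a)] if m is not vroot] + [b]
        adj[id(b)] = [m for m in adj[id(b)] if m is not vroot] + [a]
        del adj[id(vroot)]
        parent_side = x.parent if x.parent is not vroot else (b if x is a else a)
    else:
        parent_side = x.parent

    def build(n: Node, come_from: Node) -> Node:
        m = Node(n.label if n.is_leaf else None)
        for nb in adj[id(n)]:
            if nb is not come_from:
                m.add_child(build(nb, n))
        return m

    r = Node()
    r.add_child(build(x, parent_side))
    r.add_child(build(parent_side, x))
    return r


def _spr_tbr_neighbors(tree: PhyloTree, tbr: bool):
    """Yield neighbor trees under subtree pruning-regrafting; with ``tbr``
    the pruned subtree is additionally rerooted on each of its edges."""
    pre = tree.preorder()
    n_nodes = len(pre)
    for vi in range(n_nodes):
        v0 = pre[vi]
        if v0.parent is None or v0.parent.parent is None:
            continue  # root, or child of the root leaf (whole tree)
        sub_ids = _subtree_ids(v0)
        sibling_ids = {id(c) for c in v0.parent.children if c is not v0}
        reroots: list[Optional[int]] = [None]
        if tbr and not v0.is_leaf:
            child_ids = {id(c) for c in v0.children}
            sub_pre_idx = [
                i
                for i in range(n_nodes)
                if id(pre[i]) in sub_ids
                and pre[i] is not v0
                and id(pre[i]) not in child_ids
            ]
            reroots += sub_pre_idx
        for wi in range(n_nodes):
            w0 = pre[wi]
            if (
                id(w0) in sub_ids
                or w0.parent is None
                or id(w0) == id(v0.parent)
            ):
                continue
            for xr in reroots:
                if xr is None and id(w0) in sibling_ids:
                    continue  # plain reinsertion at the original place
                t2 = tree.copy()
                pre2 = t2.preorder()
                v, w = pre2[vi], pre2[wi]
                u = v.parent
                u.remove_child(v)
                graft = v
                if xr is not None:
                    graft = _reroot_subtree(v, pre2[xr])
                if len(u.children) == 1:
                    only = u.children[0]
                    g = u.parent
                    g.children[g.children.index(u)] = only
                    only.parent = g
                p = w.parent
                nu = Node()
                p.children[p.children.index(w)] = nu
                nu.parent = p
                nu.children = [w, graft]
                w.parent = nu
                graft.parent = nu
                yield t2


def _nni_neighbors(tree: PhyloTree):
    pre = tree.preorder()
    for vi, v0 in enumerate(pre):
        if v0.is_leaf or v0.parent is None or v0.parent.parent is None:
            continue
        u0 = v0.parent
        for si, s0 in enumerate(u0.children):
            if s0 is v0:
                continue
            for ci in range(len(v0.children)):
                t2 = tree.copy()
                pre2 = t2.preorder()
                v = pre2[vi]
                u = v.parent
                s = u.children[si]
                c = v.children[ci]
                u.children[si] = c
                c.parent = u
                v.children[ci] = s
                s.parent = v
                yield t2


def _neighbors(tree: PhyloTree, swap: str):
    swap = swap.lower()
    if swap == "nni":
        yield from _nni_neighbors(tree)
    elif swap == "spr":
        yield from _spr_tbr_neighbors(tree, tbr=False)
    elif swap == "tbr":
        yield from _spr_tbr_neighbors(tree, tbr=True)
    else:
        raise ValueError(f"unknown swap type {swap!r}")


def _standard_unrooted(tree: PhyloTree) -> PhyloTree:
    """Convert the rooted-at-leaf search form to the conventional unrooted
    form: a basal trifurcation with the former root leaf as one child."""
    t = tree.copy()
    root = t.root
    if root.label is None or len(root.children) != 1:
        return t
    inner = root.children[0]
    if inner.is_leaf:
        return t
    leaf = Node(root.label)
    inner.parent = None
    inner.add_child(leaf)
    return PhyloTree(inner)


# ---------------------------------------------------------------------------
# heuristic and exhaustive search


@dataclass
class SearchConfig:
    """Settings for the heuristic search (the published analysis used 1000
    random addition sequences with TBR swapping)."""

    n_addition_sequences: int = 1000
    swap: str = "TBR"
    seed: int = 0
    max_saved_trees: int = 100_000
    steepest_descent: bool = False
    #: extra saved trees to branch-swap on when harvesting equally (or, for
    #: Bremer, nearly) most-parsimonious trees
    max_plateau_sweeps: int = 200

    def __post_init__(self):
        if self.n_addition_sequences < 1:
            raise ValueError("need at least one addition sequence")
        if self.max_saved_trees < 1:
            raise ValueError("max_saved_trees must be >= 1")


@dataclass
class SearchResult:
    best_length: int
    trees: list  # most-parsimonious trees, conventional unrooted form
    saved: dict  # canonical key -> (length, search-form tree)
    log: list  # (replicate, best length) per addition sequence
    complete: bool = True
    warnings_: list = field(default_factory=list)

    def near_optimal(self, k: int) -> list:
        """Trees within ``k`` steps of the optimum (search form)."""
        return [
            (_standard_unrooted(t), ln)
            for (ln, t) in self.saved.values()
            if ln <= self.best_length + k
        ]


class _TreeStore:
    def __init__(self, slack: int, cap: int):
        self.slack = slack
        self.cap = cap
        self.best = math.inf
        self.saved: dict = {}
        self.overflow = False

    def record(self, tree: PhyloTree, length: int) -> bool:
        if length > self.best + self.slack:
            return False
        key = tree.canonical_key()
        if key in self.saved:
            return False
        if len(self.saved) >= self.cap:
            self.overflow = True
            if length >= self.best:
                return False
            # a strictly better tree still replaces the store's worst
            worst = max(self.saved, key=lambda k: self.saved[k][0])
            del self.saved[worst]
        self.saved[key] = (length, tree.copy())
        if length < self.best:
            self.best = length
            limit = self.best + self.slack
            for k in [k for k, (ln, _) in self.saved.items() if ln > limit]:
                del self.saved[k]
        return True


def _stepwise_addition(order: list[str], enc: _Encoded, rng: random.Random) -> PhyloTree:
    root = Node(order[0])
    first = Node()
    root.add_child(first)
    first.add_child(Node(order[1]))
    first.add_child(Node(order[2]))
    tree = PhyloTree(root)
    for name in order[3:]:
        leaf = Node(name)
        best_len, best_nodes = math.inf, []
        candidates = [n for n in tree.preorder() if n.parent is not None]
        for v in candidates:
            u = _insert_above(v, leaf)
            ln = _tree_length(tree.root, enc)
            _undo_insert(u)
            if ln < best_len:
                best_len, best_nodes = ln, [v]
            elif ln == best_len:
                best_nodes.append(v)
        _insert_above(rng.choice(best_nodes), leaf)
    return tree


def _local_search(
    tree: PhyloTree, enc: _Encoded, config: SearchConfig, store: _TreeStore
) -> tuple:
    cur, cur_len = tree, _tree_length(tree.root, enc)
    store.record(cur, cur_len)
    improved = True
    while improved:
        improved = False
        best_nbr, best_len = None, cur_len
        for nbr in _neighbors(cur, config.swap):
            ln = _tree_length(nbr.root, enc)
            store.record(nbr, ln)
            if ln < best_len:
                best_nbr, best_len = nbr, ln
                if not config.steepest_descent:
                    break
        if best_nbr is not None:
            cur, cur_len = best_nbr, best_len
            improved = True
    return cur, cur_len


def heuristic_search(
    matrix: CharacterMatrix, config: Optional[SearchConfig] = None, retain_slack: int = 0
) -> SearchResult:
    """Random-addition-sequence heuristic search with branch swapping.

    Returns all distinct trees of the best length found (up to
    ``max_saved_trees``), deterministically for a given seed.  With
    ``retain_slack`` > 0, suboptimal trees within that many steps of the
    optimum are kept as well (used for Bremer supports).
    """
    config = config or SearchConfig()
    names = matrix.taxon_names()
    if len(names) < 4:
        raise ValueError("need at least 4 taxa to search")
    enc = _Encoded(matrix)
    rng = random.Random(config.seed)
    store = _TreeStore(retain_slack, config.max_saved_trees)
    log = []
    for rep in range(config.n_addition_sequences):
        order = list(names)
        rng.shuffle(order)
        start = _stepwise_addition(order, enc, rng)
        _, ln = _local_search(start, enc, config, store)
        log.append((rep, ln))

    # plateau harvesting: swap on saved trees to pick up tied rearrangements
    sweeps = 0
    processed: set = set()
    while sweeps < config.max_plateau_sweeps:
        todo = [k for k in store.saved if k not in processed]
        if not todo:
            break
        key = min(todo, key=lambda k: store.saved[k][0])
        processed.add(key)
        ln0, t0 = store.saved.get(key, (None, None))
        if t0 is None:
            continue
        for nbr in _neighbors(t0, config.swap):
            store.record(nbr, _tree_length(nbr.root, enc))
        sweeps += 1

    best = int(store.best)
    mpts = [
        _standard_unrooted(t) for (ln, t) in store.saved.values() if ln == best
    ]
    warnings_ = []
    if store.overflow:
        warnings_.append("max_saved_trees reached; tree set may be incomplete")
    return SearchResult(
        best_length=best,
        trees=mpts,
        saved=store.saved,
        log=log,
        complete=not store.overflow,
        warnings_=warnings_,
    )


def enumerate_topologies(names: Sequence[str]):
    """Yield every unrooted binary topology over ``names`` (rooted-at-leaf
    form); (2n-5)!! trees, so intended for small n."""
    names = list(names)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")

    root = Node(names[0])
    first = Node()
    root.add_child(first)
    first.add_child(Node(names[1]))
    first.add_child(Node(names[2]))
    base = PhyloTree(root)

    def rec(tree: PhyloTree, remaining: list[str]):
        if not remaining:
            yield _standard_unrooted(tree)
            return
        name = remaining[0]
        spots = [n for n in tree.preorder() if n.parent is not None]
        for v in spots:
            leaf = Node(name)
            u = _insert_above(v, leaf)
            yield from rec(tree, remaining[1:])
            _undo_insert(u)

    yield from rec(base, names[3:])


def exhaustive_search(matrix: CharacterMatrix, max_taxa: int = 9) -> SearchResult:
    """Score every topology; exact but only feasible for small taxon sets."""
    names = matrix.taxon_names()
    if len(names) > max_taxa:
        raise ValueError(f"exhaustive search limited to {max_taxa} taxa")
    enc = _Encoded(matrix)
    saved: dict = {}
    best = math.inf
    for t in enumerate_topologies(names):
        ln = _tree_length(t.root, enc)
        saved[t.canonical_key()] = (ln, t)
        best = min(best, ln)
    mpts = [_standard_unrooted(t) for (ln, t) in saved.values() if ln == best]
    return SearchResult(best_length=int(best), trees=mpts, saved=saved, log=[])


# ---------------------------------------------------------------------------
# consensus


def _check_leafsets(trees: Sequence[PhyloTree]) -> frozenset:
    if not trees:
        raise ValueError("no trees given")
    ref = frozenset(trees[0].leaf_names())
    for t in trees[1:]:
        if frozenset(t.leaf_names()) != ref:
            raise ValueError("trees have different leaf sets")
    return ref


def _tree_from_clades(leafset: frozenset, clades: dict) -> PhyloTree:
    """Build a (multifurcating) rooted tree from a compatible clade set;
    ``clades`` maps frozenset -> support percent annotation (or None)."""
    items = sorted(clades, key=len, reverse=True)
    root = Node()
    node_of = {leafset: root}
    for s in items:
        node_of[s] = Node()
    for x in sorted(leafset):
        node_of[frozenset([x])] = Node(x)

    def parent_of(s: frozenset):
        best = leafset
        for other in items:
            if s < other and len(other) < len(best):
                best = other
        return node_of[best]

    for s in items:
        parent_of(s).add_child(node_of[s])
        if clades[s] is not None:
            node_of[s].annotations["support"] = clades[s]
    for x in sorted(leafset):
        s = frozenset([x])
        parent_of(s).add_child(node_of[s])
    return PhyloTree(root)


def _clade_counts(trees: Sequence[PhyloTree]) -> dict:
    counts: dict = {}
    for t in trees:
        for s in t.clades():
            counts[s] = counts.get(s, 0) + 1
    return counts


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Rooted strict consensus: clades present in every input tree."""
    leafset = _check_leafsets(trees)
    counts = _clade_counts(trees)
    clades = {s: None for s, c in counts.items() if c == len(trees)}
    return _tree_from_clades(leafset, clades)


def majority_consensus(trees: Sequence[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Rooted majority-rule consensus: clades in strictly more than
    ``threshold`` of the trees, annotated with integer-percent frequency."""
    leafset = _check_leafsets(trees)
    counts = _clade_counts(trees)
    n = len(trees)
    clades = {
        s: round(100 * c / n) for s, c in counts.items() if c / n > threshold
    }
    return _tree_from_clades(leafset, clades)


# ---------------------------------------------------------------------------
# ACCTRAN ancestral states


def acctran_assign(tree: PhyloTree, matrix: CharacterMatrix, char_index: int) -> dict:
    """Accelerated-transformation ancestral assignment for one character
    (1-based ``char_index``) on a rooted tree.

    Among all minimum-length assignments, changes are pulled as close to the
    root as possible, so homoplasy is preferred as a reversal over a parallel
    gain.  Returns {node: state symbol}; total implied changes equals the
    Fitch step count.
    """
    if len(tree.root.children) != 2:
        raise ValueError("ACCTRAN needs a rooted tree (root with two children)")
    j = char_index - 1
    cdef = matrix.characters[j]
    syms = list(cdef.full_alphabet)
    extra = set()
    for cell in matrix.column(j):
        if not cell.is_missing:
            extra |= cell.states
    syms += sorted(extra - set(syms))
    k = len(syms)
    idx = {s: i for i, s in enumerate(syms)}
    col = {t.name: c for t, c in zip(matrix.taxa, matrix.column(j))}

    INF = float("inf")
    cost: dict[int, np.ndarray] = {}
    order = tree.postorder()
    for n in order:
        if n.is_leaf:
            cell = col[n.label]
            c = np.full(k, INF)
            if cell.is_missing:
                c[:] = 0.0
            else:
                for s in cell.states:
                    c[idx[s]] = 0.0
            cost[id(n)] = c
        else:
            c = np.zeros(k)
            for chd in n.children:
                cc = cost[id(chd)]
                c += np.minimum(cc, cc.min() + 1.0)
            cost[id(n)] = c

    assign: dict = {}
    # root: minimal cost, ties broken toward absence then alphabet order
    c = cost[id(tree.root)]
    best = c.min()
    root_state = next(i for i in range(k) if c[i] == best)
    assign[tree.root] = syms[root_state]
    stack = [(ch, root_state) for ch in tree.root.children]
    while stack:
        n, p = stack.pop()
        c = cost[id(n)]
        totals = c + (np.arange(k) != p)
        best = totals.min()
        # accelerate: among ties prefer a state different from the parent
        cands = [i for i in range(k) if totals[i] == best]
        changed = [i for i in cands if i != p]
        s = changed[0] if changed else cands[0]
        assign[n] = syms[s]
        for chd in n.children:
            stack.append((chd, s))
    return assign


# ---------------------------------------------------------------------------
# Bremer decay supports


@dataclass(frozen=True)
class NodeSupport:
    """Decay index of one clade (identified by its leaf set)."""

    clade: frozenset
    bremer: int
    lower_bound: bool = False


def _comparison_clades(tree: PhyloTree, root_taxon: Optional[str]) -> set:
    """Clades used for support bookkeeping.

    In rooted mode (a rooting taxon is in play) trees still carrying the
    rooting leaf are rooted on it and pruned; trees already without it (e.g.
    a consensus of pruned trees) are read as rooted as-is.  Without a rooting
    taxon, unrooted bipartitions are compared instead.
    """
    if root_taxon is None:
        return tree.bipartitions()
    if root_taxon in tree.leaf_names():
        return root_at(tree, root_taxon, prune=True).clades()
    return tree.clades()


def bremer_supports(
    matrix: CharacterMatrix,
    reference: PhyloTree,
    config: Optional[SearchConfig] = None,
    kmax: int = 5,
    root_taxon: Optional[str] = ANCESTOR_NAME,
    exhaustive: Optional[bool] = None,
    result: Optional[SearchResult] = None,
) -> list[NodeSupport]:
    """Decay index for every clade of ``reference``: the smallest number of
    extra steps k at which the clade vanishes from the strict consensus of
    all trees within k steps of the optimum.

    Clades still present at ``kmax`` are reported with ``lower_bound=True``.
    Tree sets come from exhaustive enumeration when the matrix is small
    (<= 8 taxa) and otherwise from a relaxed heuristic search retaining
    suboptimal trees; if the tree cap is hit, supports are flagged as lower
    bounds.
    """
    if root_taxon is not None and root_taxon not in matrix.taxon_names():
        root_taxon = None
    if result is None:
        if exhaustive is None:
            exhaustive = matrix.n_taxa <= 8
        if exhaustive:
            result = exhaustive_search(matrix)
        else:
            result = heuristic_search(matrix, config, retain_slack=kmax)
    capped = not result.complete
    best = result.best_length

    ref_clades = _comparison_clades(reference, root_taxon)
    supports: dict = {}
    pool: list = []
    remaining = set(ref_clades)
    by_len: dict[int, list] = {}
    for (ln, t) in result.saved.values():
        by_len.setdefault(ln, []).append(t)
    for k in range(0, kmax + 1):
        pool.extend(by_len.get(best + k, []))
        clade_sets = [_comparison_clades(t, root_taxon) for t in pool]
        strict = set.intersection(*clade_sets) if clade_sets else set()
        gone = {s for s in remaining if s not in strict}
        for s in gone:
            supports[s] = NodeSupport(clade=s, bremer=k, lower_bound=False)
        remaining -= gone
    for s in remaining:
        supports[s] = NodeSupport(clade=s, bremer=kmax, lower_bound=True)
    if capped:
        supports = {
            s: NodeSupport(ns.clade, ns.bremer, True) for s, ns in supports.items()
        }
    return sorted(supports.values(), key=lambda ns: (-len(ns.clade), sorted(ns.clade)))
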