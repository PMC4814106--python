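"""Rooted phylogenetic trees over cultural taxa.

A light container shared by the parsimony search, consensus construction and
the transmission simulator.  Search output is binary; consensus trees may be
multifurcating.  Newick parsing goes through dendropy so the accepted syntax
is the standard one; writing is done directly.
"""

from __future__ import annotations

from typing import Optional

import dendropy

__all__ = ["Node", "PhyloTree"]


class Node:
    """Tree node: leaves carry a taxon ``label``, internals may be unlabeled."""

    __slots__ = ("children", "parent", "label", "length", "annotations")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.label = label
        self.length = length
        self.annotations: dict = {}

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} deg={len(self.children)}>"


class PhyloTree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        out.reverse()
        return out

    def preorder(self) -> list[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.label == name:
                return n
        raise KeyError(f"no leaf named {name!r}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        """True when every internal node has exactly two children (the root
        may have two or three, covering the rooted and unrooted conventions)."""
        for n in self.postorder():
            if n.is_leaf:
                continue
            k = len(n.children)
            if n is self.root:
                if k not in (2, 3):
                    return False
            elif k != 2:
                return False
        return True

    # -- copying & surgery -------------------------------------------------

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.annotations = dict(n.annotations)
            for c in n.children:
                m.add_child(rec(c))
            return m

        return PhyloTree(rec(self.root))

    def prune_leaf(self, name: str) -> None:
        """Remove a leaf and splice out its (then degree-2) parent."""
        leaf = self.find_leaf(name)
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.remove_child(leaf)
        if len(parent.children) == 1:
            only = parent.children[0]
            grand = parent.parent
            if grand is None:  # parent was root
                only.parent = None
                if only.length is not None and parent.length is not None:
                    only.length += parent.length
                self.root = only
            else:
                idx = grand.children.index(parent)
                grand.children[idx] = only
                only.parent = grand
                if only.length is not None and parent.length is not None:
                    only.length += parent.length

    # -- clades and bipartitions -------------------------------------------

    def clades(self, trivial: bool = False) -> set[frozenset]:
        """Leaf-name sets below each node of this *rooted* tree.

        Non-trivial by default: singletons and the full leaf set are omitted.
        """
        all_leaves = frozenset(self.leaf_names())
        below: dict[int, frozenset] = {}
        out: set[frozenset] = set()
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in n.children))
                below[id(n)] = s
                if trivial or (1 < len(s) < len(all_leaves)):
                    out.add(s)
        if trivial:
            out |= {frozenset([x]) for x in all_leaves} | {all_leaves}
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the *unrooted* topology, each written as the
        side not containing the lexicographically smallest leaf."""
        names = self.leaf_names()
        ref = min(names)
        full = frozenset(names)
        out = set()
        for s in self.clades():
            side = full - s if ref in s else s
            if 1 < len(side) < len(full) - 1:
                out.add(side)
        return out

    # -- rerooting ---------------------------------------------------------

    def rooted_above_leaf(self, name: str) -> "PhyloTree":
        """Return a copy rerooted on the pendant edge of ``name``: the new
        root has exactly two children, the leaf and everything else.

        Degree-2 nodes created by removing the old root are suppressed, so the
        result depends only on the unrooted topology.  Branch lengths are kept
        where unambiguous; the two root edges share the original pendant
        length (all on the leaf side).
        """
        # normalize the "hung from a leaf" form (labeled root with children):
        # detach the label into a proper leaf so adjacency sees it
        if self.root.label is not None and self.root.children:
            t = self.copy()
            inner = t.root.children[0]
            leaf = Node(t.root.label, inner.length)
            if len(t.root.children) == 1 and not inner.is_leaf:
                inner.parent = None
                inner.length = None
                inner.add_child(leaf)
                return PhyloTree(inner).rooted_above_leaf(name)
            t.root.label = None
            t.root.add_child(leaf)
            return t.rooted_above_leaf(name)

        adj: dict[int, list[tuple[Node, Optional[float]]]] = {}
        nodes: dict[int, Node] = {}

        def link(a: Node, b: Node, ln: Optional[float]) -> None:
            adj.setdefault(id(a), []).append((b, ln))
            adj.setdefault(id(b), []).append((a, ln))
            nodes[id(a)] = a
            nodes[id(b)] = b

        for n in self.postorder():
            for c in n.children:
                link(n, c, c.length)
        # suppress a degree-2 old root so rerooting is topology-pure
        r = self.root
        if len(adj.get(id(r), [])) == 2:
            (a, la), (b, lb) = adj[id(r)]
            adj[id(a)] = [(x, l) for x, l in adj[id(a)] if x is not r]
            adj[id(b)] = [(x, l) for x, l in adj[id(b)] if x is not r]
            ln = (la or 0.0) + (lb or 0.0) if (la is not None or lb is not None) else None
            adj[id(a)].append((b, ln))
            adj[id(b)].append((a, ln))
            del adj[id(r)]

        leaf = next(n for n in nodes.values() if n.is_leaf and n.label == name)
        (nbr, pend_len) = adj[id(leaf)][0]

        def build(n: Node, come_from: Node, ln: Optional[float]) -> Node:
            kids = [(x, l) for x, l in adj[id(n)] if x is not come_from]
            m = Node(n.label if n.is_leaf else None, ln)
            for x, l in kids:
                m.add_child(build(x, n, l))
            return m

        root = Node()
        root.add_child(Node(leaf.label, pend_len))
        root.add_child(build(nbr, leaf, 0.0 if pend_len is not None else None))
        return PhyloTree(root)

    # -- canonical form ----------------------------------------------------

    def canonical_key(self):
        """Hashable key identifying the unrooted topology (label-sorted nested
        tuples of the tree rerooted above its smallest leaf)."""
        t = self.rooted_above_leaf(min(self.leaf_names()))

        def key(n: Node):
            if n.is_leaf:
                return (n.label,)
            return tuple(sorted((key(c) for c in n.children), key=repr))

        return key(t.root)

    # -- newick ------------------------------------------------------------

    def newick(self, lengths: bool = True, support: bool = False) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                s = _quote(n.label)
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
                if support and "support" in n.annotations:
                    s += str(n.annotations["support"])
            if lengths and n.length is not None:
                s += f":{n.length:g}"
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(dt)

    # -- dendropy bridge ---------------------------------------------------

    def to_dendropy(self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
        tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
        dt = dendropy.Tree(taxon_namespace=tns)

        def rec(n: Node, dn):
            dn.edge.length = n.length
            if n.is_leaf:
                dn.taxon = tns.require_taxon(label=n.label)
            for c in n.children:
                rec(c, dn.new_child())

        rec(self.root, dt.seed_node)
        dt.is_rooted = True
        return dt

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def rec(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else None
            n = Node(label, dn.edge.length)
            for dc in dn.child_nodes():
                n.add_child(rec(dc))
            return n

        return cls(rec(dt.seed_node))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves}>"


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unrooted symmetric-difference (Robinson-Foulds) distance."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise ValueError("trees must share the same leaf set")
    return len(a.bipartitions() ^ b.bipartitions())
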