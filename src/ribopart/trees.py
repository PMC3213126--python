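"""Phylogenetic trees: Newick I/O, splits, tree length, consensus with supports.

The in-memory :class:`Tree` is a compact parent-array representation tuned
for the likelihood engine and the MCMC sampler: leaves are nodes
``0 .. n_taxa-1`` in taxon order, internal nodes follow, and every non-root
node carries the length of the edge to its parent.  Unrooted trees are stored
rooted at an internal node; for the reversible models used throughout, the
likelihood does not depend on that root placement.

Newick parsing and writing go through dendropy, so anything dendropy accepts
round-trips here, including internal-node support labels.  Split bookkeeping
uses taxon bitmasks normalized to exclude taxon 0, which makes split identity,
compatibility checks and tabulation order deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


class Tree:
    """Rooted representation of a phylogenetic tree with branch lengths.

    Parameters
    ----------
    taxa : list of str
        Leaf labels; leaf node ``i`` is ``taxa[i]``.
    parent : array of int
        Parent index per node, -1 for the root.
    length : array of float
        Branch length of the edge to the parent; ignored at the root.
    support : dict, optional
        Internal node index -> support value (consensus annotation).
    """

    def __init__(self, taxa, parent, length, support=None):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise TreeError("duplicate leaf labels")
        self.parent = np.asarray(parent, dtype=int).copy()
        self.length = np.asarray(length, dtype=float).copy()
        if self.parent.shape != self.length.shape:
            raise TreeError("parent/length shape mismatch")
        self.n_taxa = len(self.taxa)
        self.support: dict[int, float] = dict(support or {})
        self._check()
        self._postorder: np.ndarray | None = None
        self._csr = None  # cached traversal arrays for the likelihood kernel

    def _check(self):
        roots = np.nonzero(self.parent < 0)[0]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if self.root < self.n_taxa and self.n_nodes > 1:
            raise TreeError("root must be an internal node")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                ch[p].append(v)
        return ch

    def postorder(self) -> np.ndarray:
        """Node indices, children before parents (cached; call invalidate() after topology edits)."""
        if self._postorder is None:
            ch = self.children()
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(ch[v])
            self._postorder = np.array(order[::-1], dtype=int)
        return self._postorder

    def invalidate(self):
        self._postorder = None
        self._csr = None

    def copy(self) -> "Tree":
        return Tree(self.taxa, self.parent, self.length, self.support)

    # -- metrics ------------------------------------------------------------

    def tree_length(self) -> float:
        """Sum of branch lengths (TL)."""
        mask = self.parent >= 0
        lens = self.length[mask]
        if np.isnan(lens).any():
            raise TreeError("missing branch length")
        return float(lens.sum())

    # -- splits -------------------------------------------------------------

    def leafset_masks(self) -> np.ndarray:
        """Bitmask of leaves below each node (bit i = taxon i)."""
        masks = np.zeros(self.n_nodes, dtype=object)
        for v in self.postorder():
            masks[v] = (1 << v) if v < self.n_taxa else 0
        for v in self.postorder():
            p = self.parent[v]
            if p >= 0:
                masks[p] |= masks[v]
        return masks

    def splits(self) -> set[int]:
        """Nontrivial splits as normalized bitmasks (taxon 0 always on the off side)."""
        full = (1 << self.n_taxa) - 1
        masks = self.leafset_masks()
        out: set[int] = set()
        for v in range(self.n_nodes):
            if v == self.root or v < self.n_taxa:
                continue
            m = int(masks[v])
            if m & 1:
                m = full & ~m
            size = bin(m).count("1")
            if 2 <= size <= self.n_taxa - 2:
                out.add(m)
        return out

    def __repr__(self) -> str:
        return f"<Tree {self.n_taxa} leaves, TL={self.tree_length():.4g}>"


# ---------------------------------------------------------------------------
# Newick via dendropy


def _from_dendropy(dtree: dendropy.Tree, taxa: list[str] | None = None) -> Tree:
    leaves = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise TreeError("duplicate leaf names in newick")
    if taxa is None:
        taxa = sorted(leaves)
    if set(taxa) != set(leaves):
        raise TreeError("leaf labels do not match expected taxa")
    index = {t: i for i, t in enumerate(taxa)}
    n_taxa = len(taxa)
    # suppress a degree-2 root so the representation is canonical
    dtree = dtree.clone(depth=1)
    dtree.suppress_unifurcations()
    if len(dtree.seed_node.child_nodes()) == 2 and n_taxa > 2:
        dtree.collapse_basal_bifurcation()
    internal = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    node_id = {}
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            node_id[nd] = index[nd.taxon.label]
    for k, nd in enumerate(internal):
        node_id[nd] = n_taxa + k
    n_nodes = n_taxa + len(internal)
    parent = np.full(n_nodes, -1, dtype=int)
    length = np.full(n_nodes, np.nan)
    support: dict[int, float] = {}
    for nd in dtree.preorder_node_iter():
        v = node_id[nd]
        if nd.parent_node is not None:
            parent[v] = node_id[nd.parent_node]
            length[v] = nd.edge.length if nd.edge.length is not None else np.nan
        if not nd.is_leaf() and nd.label is not None:
            try:
                support[v] = float(nd.label)
            except ValueError:
                pass
    return Tree(taxa, parent, length, support)


def _to_dendropy(tree: Tree, tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    tns = tns or dendropy.TaxonNamespace(tree.taxa)
    dtree = dendropy.Tree(taxon_namespace=tns)
    ch = tree.children()
    nodes = {tree.root: dtree.seed_node}
    for v in tree.postorder()[::-1]:
        if v == tree.root:
            continue
        nd = dendropy.Node()
        nd.edge.length = None if np.isnan(tree.length[v]) else float(tree.length[v])
        nodes[tree.parent[v]].add_child(nd)
        nodes[v] = nd
    for v, nd in nodes.items():
        if v < tree.n_taxa:
            nd.taxon = tns.get_taxon(tree.taxa[v])
        elif v in tree.support:
            nd.label = format(tree.support[v], "g")
    return dtree


def read_newick(source: str, taxa: list[str] | None = None) -> Tree:
    """Parse one newick string (or the first tree in a file path)."""
    import os

    if os.path.exists(source):
        source = open(source).read()
    try:
        dtree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree, taxa)


def write_newick(tree: Tree, include_supports: bool = True) -> str:
    dtree = _to_dendropy(tree)
    if not include_supports:
        for nd in dtree.preorder_node_iter():
            if not nd.is_leaf():
                nd.label = None
    return dtree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def tree_length(tree: Tree) -> float:
    return tree.tree_length()


# ---------------------------------------------------------------------------
# tree sample sets, pooling, consensus


@dataclass
class TreeSampleSet:
    """Pooled posterior tree samples sharing one leaf set."""

    trees: list[Tree]
    provenance: list[tuple[str, int]] | None = None  # (run label, generation)

    def __post_init__(self):
        if not self.trees:
            raise TreeError("empty tree sample set")
        taxa0 = self.trees[0].taxa
        for t in self.trees[1:]:
            if set(t.taxa) != set(taxa0):
                raise TreeError("tree samples have differing leaf sets")

    @property
    def taxa(self) -> list[str]:
        return self.trees[0].taxa

    def __len__(self) -> int:
        return len(self.trees)


def pool_runs(*sample_sets: TreeSampleSet) -> TreeSampleSet:
    trees: list[Tree] = []
    prov: list[tuple[str, int]] = []
    for ss in sample_sets:
        trees.extend(ss.trees)
        prov.extend(ss.provenance or [("", -1)] * len(ss))
    return TreeSampleSet(trees, prov)


def split_frequencies(samples: TreeSampleSet) -> dict[int, float]:
    """Frequency of every observed nontrivial split, keyed by normalized bitmask."""
    counts: dict[int, int] = {}
    for t in samples.trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    n = len(samples)
    return {s: c / n for s, c in sorted(counts.items())}


def _mask_to_taxa(mask: int, taxa: list[str]) -> frozenset[str]:
    return frozenset(t for i, t in enumerate(taxa) if mask >> i & 1)


def majority_rule_consensus(samples: TreeSampleSet, threshold: float = 0.5) -> Tree:
    """Majority-rule consensus phylogram with split-frequency supports.

    Splits occurring in strictly more than ``threshold`` of the samples are
    retained (ties at the threshold are excluded, which guarantees pairwise
    compatibility at threshold >= 0.5).  Support on each retained internal
    edge is its split frequency — the Bayesian posterior probability when the
    samples come from a posterior.  Branch lengths are averaged over the
    trees containing the split (terminal edges: over all trees).  Anything
    unresolved is left as a polytomy.
    """
    if threshold < 0.5:
        raise TreeError("threshold below 0.5 can select incompatible splits")
    taxa = samples.taxa
    n_taxa = len(taxa)
    n = len(samples)
    full = (1 << n_taxa) - 1

    split_counts: dict[int, int] = {}
    split_lensum: dict[int, float] = {}
    term_lensum = np.zeros(n_taxa)
    for t in samples.trees:
        remap = [t.taxa.index(lbl) for lbl in taxa]  # t-leaf index per canonical taxon
        masks = t.leafset_masks()
        # aggregate edges by their unrooted split: in a rooted-binary
        # representation the two root children are the same unrooted edge,
        # so their lengths add and the split counts once
        edge_len: dict[int, float] = {}
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            m = int(masks[v])
            cm = 0
            for i in range(n_taxa):
                if m >> remap[i] & 1:
                    cm |= 1 << i
            norm = (full & ~cm) if cm & 1 else cm
            length = 0.0 if np.isnan(t.length[v]) else float(t.length[v])
            edge_len[norm] = edge_len.get(norm, 0.0) + length
        for norm, length in edge_len.items():
            pc = bin(norm).count("1")
            if pc == n_taxa - 1:  # terminal edge of taxon 0 (stored complemented)
                term_lensum[0] += length
            elif pc == 1:
                term_lensum[norm.bit_length() - 1] += length
            else:
                split_counts[norm] = split_counts.get(norm, 0) + 1
                split_lensum[norm] = split_lensum.get(norm, 0.0) + length

    kept = sorted(
        (m for m, c in split_counts.items() if c / n > threshold),
        key=lambda m: (-bin(m).count("1"), m),
    )

    # clusters must be expressed on one side consistently: grow the laminar
    # family of clades using the orientation that excludes taxon 0 (rooting at
    # taxon 0's side), which every normalized split already has.
    root_mask = full
    node_mask: list[int] = []  # internal node id (offset by n_taxa) -> cluster mask
    parent = np.full(n_taxa + 1, -1, dtype=int)
    length = np.full(n_taxa + 1, np.nan)
    support: dict[int, float] = {}
    node_mask.append(root_mask)
    root_id = n_taxa
    parent[:n_taxa] = root_id
    length[:n_taxa] = term_lensum / n
    for m in kept:
        # the smallest existing cluster strictly containing m becomes the parent
        cands = [k for k, cm in enumerate(node_mask) if (cm & m) == m and cm != m]
        host = min(cands, key=lambda k: bin(node_mask[k]).count("1"))
        new_id = n_taxa + len(node_mask)
        parent = np.append(parent, host + n_taxa)
        length = np.append(length, split_lensum.get(m, 0.0) / split_counts[m])
        support[new_id] = split_counts[m] / n
        # re-parent every current child of host whose mask is inside m
        for v in range(n_taxa):
            if parent[v] == host + n_taxa and (m >> v & 1):
                parent[v] = new_id
        for k in range(1, len(node_mask)):
            vid = n_taxa + k
            if parent[vid] == host + n_taxa and (node_mask[k] & m) == node_mask[k]:
                parent[vid] = new_id
        node_mask.append(m)
    return Tree(taxa, parent, length, support)


def clade_posterior(samples: TreeSampleSet, taxon_subset) -> float:
    """Fraction of sampled trees in which the subset forms a split (BPP)."""
    taxa = samples.taxa
    subset = set(taxon_subset)
    if not subset <= set(taxa):
        raise TreeError("subset contains unknown taxa")
    k = len(subset)
    if k < 2 or k > len(taxa) - 2:
        raise TreeError("trivial subset: need 2 <= |subset| <= n_taxa - 2")
    full = (1 << len(taxa)) - 1
    mask = 0
    for i, t in enumerate(taxa):
        if t in subset:
            mask |= 1 << i
    norm = (full & ~mask) if mask & 1 else mask
    hits = 0
    for t in samples.trees:
        if t.taxa == taxa:
            tm = norm
        else:
            remap = {lbl: i for i, lbl in enumerate(t.taxa)}
            tm = 0
            for i, lbl in enumerate(taxa):
                if norm >> i & 1:
                    tm |= 1 << remap[lbl]
            if tm & 1:
                tm = full & ~tm
        if tm in t.splits():
            hits += 1
    return hits / len(samples)
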