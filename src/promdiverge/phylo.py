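"""Maximum-parsimony inference on promoter alignments.

Implements Fitch's dynamic program for the minimum number of substitutions
per site on an unrooted binary topology, a heuristic search over topologies
using tree-bisection-reconnection (TBR) rearrangements from random-addition
starting trees, nonparametric bootstrap support per internal bipartition, and
the consistency index CI = M/L and retention index RI = (G-L)/(G-M), where
M is the minimum conceivable length (sum over sites of distinct states - 1),
L the observed tree length and G the maximum length on a star tree (sum over
sites of n_s minus the largest state-class size).  Gaps and N are treated as
missing data (they can take any state and contribute no changes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from ._util import PromdivergeError, stream_rng

__all__ = [
    "AlignedPromoterSet",
    "PhyloTree",
    "UnrootedTree",
    "fitch_length",
    "per_site_fitch",
    "tbr_search",
    "exhaustive_search",
    "bootstrap_support",
    "ci_ri",
    "build_tree",
]

# state encoding: bitmasks; missing (gap, N, anything else) = all four bits
_STATE = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15


@dataclass
class AlignedPromoterSet:
    """Equal-length gapped promoter sequences over A,C,G,T,N,-."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise PromdivergeError("taxa and sequences must align")
        if len(set(self.taxa)) != len(self.taxa):
            raise PromdivergeError("taxon labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise PromdivergeError("aligned sequences must have equal length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def encoded(self) -> np.ndarray:
        """(n_taxa, n_sites) uint8 bitmask matrix."""
        out = np.full((self.n_taxa, self.n_sites), _MISSING, dtype=np.uint8)
        for i, seq in enumerate(self.sequences):
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            for base, mask in _STATE.items():
                out[i, arr == ord(base)] = mask
        return out

    @classmethod
    def from_fasta(cls, text: str) -> "AlignedPromoterSet":
        taxa: list[str] = []
        seqs: list[str] = []
        cur: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if taxa:
                    seqs.append("".join(cur))
                taxa.append(line[1:].split()[0])
                cur = []
            else:
                cur.append(line)
        if taxa:
            seqs.append("".join(cur))
        return cls(taxa=taxa, sequences=seqs)

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{s}\n" for t, s in zip(self.taxa, self.sequences))


class UnrootedTree:
    """Unrooted binary tree over integer leaf ids 0..n-1 (adjacency sets)."""

    def __init__(self, n_leaves: int, adj: dict[int, set[int]], next_id: int):
        self.n_leaves = n_leaves
        self.adj = adj
        self.next_id = next_id

    # -- construction ------------------------------------------------------
    @classmethod
    def star3(cls, a: int, b: int, c: int, n_leaves: int) -> "UnrootedTree":
        hub = n_leaves
        adj = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
        return cls(n_leaves, adj, n_leaves + 1)

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(self.n_leaves, {k: set(v) for k, v in self.adj.items()},
                            self.next_id)

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def attach_leaf(self, leaf: int, edge: tuple[int, int]) -> None:
        """Subdivide `edge` with a new hub and hang `leaf` from it."""
        u, v = edge
        hub = self.next_id
        self.next_id += 1
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[hub] = {u, v, leaf}
        self.adj[u].add(hub)
        self.adj[v].add(hub)
        self.adj[leaf] = {hub}

    # -- traversal ---------------------------------------------------------
    def postorder(self, root: int) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents, rooted at `root`."""
        order: list[tuple[int, int]] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        order.reverse()
        return order

    def bipartitions(self) -> set[frozenset[int]]:
        """Non-trivial splits, each as the leaf side not containing leaf 0."""
        splits: set[frozenset[int]] = set()
        below: dict[int, set[int]] = {}
        for node, parent in self.postorder(0):
            if node < self.n_leaves:
                below[node] = {node}
            else:
                below[node] = set()
                for nb in self.adj[node]:
                    if nb != parent:
                        below[node] |= below[nb]
        for node, parent in self.postorder(0):
            if node >= self.n_leaves and parent != -1 and parent != 0:
                side = below[node]
                if 1 < len(side) < self.n_leaves - 1:
                    splits.add(frozenset(side))
        return splits

    def newick(self, taxa: Sequence[str]) -> str:
        """Canonical Newick: rooted at leaf 0's edge, children sorted by
        smallest descendant leaf label."""

        def render(node: int, parent: int) -> tuple[str, str]:
            if node < self.n_leaves:
                return taxa[node], taxa[node]
            parts = [render(nb, node) for nb in self.adj[node] if nb != parent]
            parts.sort(key=lambda p: p[1])
            return "(" + ",".join(p[0] for p in parts) + ")", min(p[1] for p in parts)

        hub = next(iter(self.adj[0]))
        inner, _ = render(hub, 0)
        return f"({taxa[0]},{inner});"


def build_tree(newick: str, taxa: Sequence[str]) -> UnrootedTree:
    """Parse a Newick topology (via dendropy) into an :class:`UnrootedTree`."""
    index = {t: i for i, t in enumerate(taxa)}
    dt = dendropy.Tree.get(data=newick, schema="newick",
                           preserve_underscores=True)
    labels = {lf.taxon.label for lf in dt.leaf_node_iter()}
    if labels != set(taxa):
        raise PromdivergeError(
            f"topology leaves {sorted(labels)} do not match alignment taxa")
    n = len(taxa)
    adj: dict[int, set[int]] = {}
    counter = [n]

    def add_edge(a: int, b: int) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def walk(node) -> int:
        if node.is_leaf():
            return index[node.taxon.label]
        kids = [walk(c) for c in node.child_nodes()]
        if len(kids) == 1:
            return kids[0]
        me = counter[0]
        counter[0] += 1
        for k in kids:
            add_edge(me, k)
        return me

    walk(dt.seed_node)
    tree = UnrootedTree(n, adj, counter[0])
    _suppress_degree_two(tree)
    return tree


def _suppress_degree_two(tree: UnrootedTree) -> None:
    for node in [n for n in list(tree.adj) if n >= tree.n_leaves]:
        if node in tree.adj and len(tree.adj[node]) == 2:
            a, b = tree.adj[node]
            tree.adj[a].discard(node)
            tree.adj[b].discard(node)
            tree.adj[a].add(b)
            tree.adj[b].add(a)
            del tree.adj[node]


@dataclass
class PhyloTree:
    """A parsimony tree with its score, homoplasy indices and edge support."""

    newick: str
    taxa: list[str]
    length: int
    ci: float = float("nan")
    ri: float = float("nan")
    ci_informative: float = float("nan")
    ri_informative: float = float("nan")
    supports: dict[frozenset, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def newick_with_support(self) -> str:
        """Newick string with bootstrap percentages as internal-node labels."""
        if not self.supports:
            return self.newick
        tree = build_tree(self.newick, self.taxa)
        index = {t: i for i, t in enumerate(self.taxa)}

        def render(node: int, parent: int) -> tuple[str, str, frozenset]:
            if node < tree.n_leaves:
                return self.taxa[node], self.taxa[node], frozenset([node])
            parts = [render(nb, node) for nb in tree.adj[node] if nb != parent]
            parts.sort(key=lambda p: p[1])
            leaves = frozenset().union(*(p[2] for p in parts))
            label = ""
            if 1 < len(leaves) < tree.n_leaves - 1 and leaves in self.supports:
                label = f"{self.supports[leaves]:.0f}"
            return ("(" + ",".join(p[0] for p in parts) + ")" + label,
                    min(p[1] for p in parts), leaves)

        hub = next(iter(tree.adj[0]))
        inner, _, _ = render(hub, 0)
        return f"({self.taxa[0]},{inner});"


# ---------------------------------------------------------------------------
# Fitch counting


def _compress(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical site patterns; returns (patterns, weights)."""
    patterns, weights = np.unique(states, axis=1, return_counts=True)
    return patterns, weights


def _fitch_counts(tree: UnrootedTree, patterns: np.ndarray) -> np.ndarray:
    """Per-pattern Fitch change counts on an unrooted binary tree."""
    changes = np.zeros(patterns.shape[1], dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node, parent in tree.postorder(0):
        if node < tree.n_leaves:
            sets[node] = patterns[node]
            continue
        acc = None
        for nb in tree.adj[node]:
            if nb == parent:
                continue
            child = sets[nb]
            if acc is None:
                acc = child
            else:
                inter = acc & child
                empty = inter == 0
                changes += empty
                acc = np.where(empty, acc | child, inter)
        sets[node] = acc
    # fold in the root leaf's own state
    hub = next(iter(tree.adj[0]))
    inter = sets[hub] & patterns[0]
    changes += inter == 0
    return changes


def fitch_length(aln: AlignedPromoterSet, topology: "UnrootedTree | str") -> int:
    """Total parsimony length (site changes summed over sites) of a topology."""
    tree = build_tree(topology, aln.taxa) if isinstance(topology, str) else topology
    if tree.n_leaves != aln.n_taxa:
        raise PromdivergeError("topology leaf count does not match alignment")
    patterns, weights = _compress(aln.encoded())
    return int((_fitch_counts(tree, patterns) * weights).sum())


def per_site_fitch(aln: AlignedPromoterSet, topology: "UnrootedTree | str") -> np.ndarray:
    """Fitch change count for every alignment column individually."""
    tree = build_tree(topology, aln.taxa) if isinstance(topology, str) else topology
    states = aln.encoded()
    patterns, inverse = np.unique(states, axis=1, return_inverse=True)
    counts = _fitch_counts(tree, patterns)
    return counts[np.ravel(inverse)]


# ---------------------------------------------------------------------------
# Topology search


def _random_addition_tree(n: int, rng: np.random.Generator) -> UnrootedTree:
    order = rng.permutation(n)
    tree = UnrootedTree.star3(int(order[0]), int(order[1]), int(order[2]), n)
    for leaf in order[3:]:
        edges = tree.edges()
        edge = edges[int(rng.integers(len(edges)))]
        tree.attach_leaf(int(leaf), edge)
    return tree


def _component(adj: dict[int, set[int]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _tbr_neighbors(tree: UnrootedTree) -> Iterable[UnrootedTree]:
    """All trees one tree-bisection-reconnection move away.

    Each edge is removed (bisection); degree-two nodes at the cut are
    suppressed; the two fragments are rejoined by subdividing one edge in
    each (every re-rooting of the detached fragment) and connecting the two
    new hubs.  Single-leaf fragments attach directly.
    """
    for u, v in tree.edges():
        base = tree.copy()
        base.adj[u].discard(v)
        base.adj[v].discard(u)
        _suppress_degree_two(base)
        comp_u = _component(base.adj, u) if u in base.adj else None
        if comp_u is None:
            # u was suppressed: recover its component from any old neighbour
            old_nb = next(iter(tree.adj[u] - {v}))
            comp_u = _component(base.adj, old_nb)
        comp_v = _component(base.adj, v) if v in base.adj else None
        if comp_v is None:
            old_nb = next(iter(tree.adj[v] - {u}))
            comp_v = _component(base.adj, old_nb)

        def attach_points(comp: set[int]):
            pts = [("edge", (a, b)) for a in comp for b in base.adj[a]
                   if a < b and b in comp]
            if not pts:
                pts = [("node", (next(iter(comp)), -1))]
            return pts

        for kind_a, ea in attach_points(comp_u):
            for kind_b, eb in attach_points(comp_v):
                nbr = base.copy()

                def hub_for(kind, edge, t: UnrootedTree) -> int:
                    if kind == "node":
                        return edge[0]
                    a, b = edge
                    h = t.next_id
                    t.next_id += 1
                    t.adj[a].discard(b)
                    t.adj[b].discard(a)
                    t.adj[h] = {a, b}
                    t.adj[a].add(h)
                    t.adj[b].add(h)
                    return h

                ha = hub_for(kind_a, ea, nbr)
                hb = hub_for(kind_b, eb, nbr)
                nbr.adj[ha].add(hb)
                nbr.adj[hb].add(ha)
                yield nbr


def tbr_search(
    aln: AlignedPromoterSet,
    restarts: int = 10,
    seed: int = 0,
    compute_indices: bool = True,
) -> PhyloTree:
    """Heuristic maximum-parsimony search with TBR hill climbing.

    Runs ``restarts`` random-addition starting trees, accepts the first
    strictly shorter TBR neighbour until none exists, and returns the
    shortest tree found; ties are broken by the lexicographically smallest
    canonical Newick string.  Deterministic given ``seed``.
    """
    if aln.n_taxa < 4:
        raise PromdivergeError("tree search needs at least 4 taxa")
    if restarts < 1:
        raise PromdivergeError("restarts must be >= 1")
    patterns, weights = _compress(aln.encoded())
    rng = stream_rng(seed, "tbr-search")

    def length_of(t: UnrootedTree) -> int:
        return int((_fitch_counts(t, patterns) * weights).sum())

    best_tree: UnrootedTree | None = None
    best_len = np.iinfo(np.int64).max
    best_newick = ""
    moves_accepted = 0
    for _ in range(restarts):
        tree = _random_addition_tree(aln.n_taxa, rng)
        cur_len = length_of(tree)
        improved = True
        while improved:
            improved = False
            for nbr in _tbr_neighbors(tree):
                nbr_len = length_of(nbr)
                if nbr_len < cur_len:
                    tree, cur_len = nbr, nbr_len
                    moves_accepted += 1
                    improved = True
                    break
        nwk = tree.newick(aln.taxa)
        if cur_len < best_len or (cur_len == best_len and nwk < best_newick):
            best_tree, best_len, best_newick = tree, cur_len, nwk
    result = PhyloTree(
        newick=best_newick, taxa=list(aln.taxa), length=int(best_len),
        metadata={"restarts": restarts, "seed": seed,
                  "moves_accepted": moves_accepted, "search": "TBR"},
    )
    if compute_indices:
        ci, ri, cii, rii = ci_ri(aln, best_tree)
        result.ci, result.ri = ci, ri
        result.ci_informative, result.ri_informative = cii, rii
    return result


def _all_topologies(n: int) -> Iterable[UnrootedTree]:
    """Every unrooted binary topology on n leaves (1*3*5*...*(2n-5) trees)."""

    def grow(tree: UnrootedTree, leaf: int):
        if leaf == n:
            yield tree
            return
        for edge in tree.edges():
            nxt = tree.copy()
            nxt.attach_leaf(leaf, edge)
            yield from grow(nxt, leaf + 1)

    yield from grow(UnrootedTree.star3(0, 1, 2, n), 3)


def exhaustive_search(aln: AlignedPromoterSet) -> PhyloTree:
    """Exact minimum-length tree by enumerating all topologies (small n)."""
    if aln.n_taxa > 9:
        raise PromdivergeError("exhaustive search limited to <= 9 taxa")
    patterns, weights = _compress(aln.encoded())
    best_len, best_newick, best_tree = np.iinfo(np.int64).max, "", None
    for tree in _all_topologies(aln.n_taxa):
        ln = int((_fitch_counts(tree, patterns) * weights).sum())
        nwk = tree.newick(aln.taxa)
        if ln < best_len or (ln == best_len and nwk < best_newick):
            best_len, best_newick, best_tree = ln, nwk, tree
    ci, ri, cii, rii = ci_ri(aln, best_tree)
    return PhyloTree(newick=best_newick, taxa=list(aln.taxa), length=int(best_len),
                     ci=ci, ri=ri, ci_informative=cii, ri_informative=rii,
                     metadata={"search": "exhaustive"})


# ---------------------------------------------------------------------------
# Support and homoplasy indices


def bootstrap_support(
    aln: AlignedPromoterSet,
    reps: int = 100,
    seed: int = 0,
    restarts: int = 2,
    tree: PhyloTree | None = None,
) -> PhyloTree:
    """Site-resampling bootstrap support for the best tree's bipartitions.

    Support of an internal edge is the percentage of replicate searches whose
    tree contains the same leaf bipartition.  Taxon input order does not
    matter: bipartitions are recorded as label sets.
    """
    if reps < 1:
        raise PromdivergeError("reps must be >= 1")
    if tree is None:
        tree = tbr_search(aln, restarts=max(restarts, 4), seed=seed)
    base = build_tree(tree.newick, aln.taxa)
    # normalise splits to label sets ordered by taxon name so input order is moot
    order = np.argsort(aln.taxa)
    ref_taxon = aln.taxa[order[0]]

    def label_splits(t: UnrootedTree, taxa: list[str]) -> set[frozenset]:
        out = set()
        for split in t.bipartitions():
            labels = frozenset(taxa[i] for i in split)
            if ref_taxon in labels:
                labels = frozenset(taxa) - labels
            out.add(labels)
        return out

    target = label_splits(base, aln.taxa)
    counts = {s: 0 for s in target}
    rng = stream_rng(seed, "bootstrap")
    n_sites = aln.n_sites
    for rep in range(reps):
        idx = rng.integers(0, n_sites, size=n_sites)
        res_seqs = ["".join(s[i] for i in idx) for s in aln.sequences]
        rep_aln = AlignedPromoterSet(taxa=list(aln.taxa), sequences=res_seqs)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_tree = tbr_search(rep_aln, restarts=restarts, seed=rep_seed,
                              compute_indices=False)
        rep_splits = label_splits(build_tree(rep_tree.newick, aln.taxa), aln.taxa)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    index = {t: i for i, t in enumerate(aln.taxa)}
    supports = {
        frozenset(index[lbl] for lbl in labels): 100.0 * c / reps
        for labels, c in counts.items()
    }
    tree.supports = supports
    tree.metadata = dict(tree.metadata, bootstrap_reps=reps, bootstrap_seed=seed)
    return tree


def _site_stats(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (m_s, g_s, informative) from the encoded state matrix."""
    n_taxa, n_sites = states.shape
    counts = np.zeros((4, n_sites), dtype=np.int64)
    for j, mask in enumerate((1, 2, 4, 8)):
        counts[j] = (states == mask).sum(axis=0)
    k_s = (counts > 0).sum(axis=0)  # distinct observed states
    n_s = counts.sum(axis=0)  # non-missing taxa
    m_s = np.maximum(k_s - 1, 0)
    g_s = np.where(n_s > 0, n_s - counts.max(axis=0), 0)
    informative = (counts >= 2).sum(axis=0) >= 2
    return m_s, g_s, informative


def ci_ri(
    aln: AlignedPromoterSet, tree: "UnrootedTree | PhyloTree | str"
) -> tuple[float, float, float, float]:
    """(CI, RI, CI informative-only, RI informative-only) for a tree.

    Conventions: L = 0 gives CI = 1; when G = M the RI is undefined and
    reported as NaN.  The informative-only variants restrict every sum to
    parsimony-informative sites (>= 2 states each present in >= 2 taxa).
    """
    if isinstance(tree, PhyloTree):
        tree = tree.newick
    per_site = per_site_fitch(aln, tree)
    m_s, g_s, informative = _site_stats(aln.encoded())

    def indices(mask: np.ndarray) -> tuple[float, float]:
        L = float(per_site[mask].sum())
        M = float(m_s[mask].sum())
        G = float(g_s[mask].sum())
        ci = 1.0 if L == 0 else M / L
        ri = float("nan") if G == M else (G - L) / (G - M)
        return ci, ri

    all_mask = np.ones_like(informative)
    ci, ri = indices(all_mask)
    cii, rii = indices(informative)
    return ci, ri, cii, rii
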