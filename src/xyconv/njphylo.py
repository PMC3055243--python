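"""Neighbor-joining trees, bootstrap support, and topology classification.

The tree-pattern vocabulary: *reciprocal monophyly* (all X sequences form one
clade and all Y another) is the expectation for a recombination-arrested
stratum with no conversion; *species pairing* (a species' X and Y sequences
are each other's closest relatives) is the signature of a lineage-specific
X-Y gene conversion. An ancestral conversion shows up as a clade containing
the complete X+Y leaf sets of all species descending from the converted
lineage.

NJ is the Saitou-Nei agglomeration on the Q criterion, with deterministic
tie-breaking (lexicographically smallest node-id pair) and negative branch
estimates clamped to zero. A brute-force least-squares topology search over
all unrooted topologies is provided as an independent reference for
validation on additive matrices.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignio import Alignment, AlignmentError, Interval, MISSING_CODE, TaxonLabel
from .distances import DistanceMatrix, distance_matrix, complete_columns

log = logging.getLogger(__name__)

RECIPROCAL_MONOPHYLY = "RECIPROCAL_MONOPHYLY"
SPECIES_PAIRING = "SPECIES_PAIRING"
MIXED = "MIXED"
UNRESOLVED = "UNRESOLVED"

DEFAULT_SUPPORT_THRESHOLD = 70.0
DEFAULT_BOOTSTRAP_REPS = 1000


def _canon(mask: int, full: int) -> int:
    """Canonical bipartition mask: the side not containing leaf 0."""
    return mask ^ full if (mask & 1) else mask


# ---------------------------------------------------------------------------
# Fast NJ kernel


def _nj_join(D: np.ndarray):
    """Run NJ agglomeration; return (joins, root_children, root_lengths).

    ``joins`` is a list of (new_id, child_i, child_j, len_i, len_j); leaves
    are ids 0..n-1 and each join allocates the next id. The last three
    surviving nodes attach to an implicit root with the returned lengths.
    Negative limb estimates are clamped to 0.
    """
    n = D.shape[0]
    if n < 3:
        raise ValueError("NJ needs >=3 taxa")
    d = np.array(D, dtype=float)
    ids = list(range(n))
    joins = []
    next_id = n
    while len(ids) > 3:
        m = len(ids)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = None
        for i, j in cand:
            if i < j:
                key = (ids[i], ids[j])
                if best is None or key < best[0]:
                    best = (key, int(i), int(j))
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        joins.append((next_id, ids[i], ids[j], li, lj))
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        last = dnew[keep]
        d = np.hstack([d, np.append(last, 0.0)[:, None]])
        ids = [ids[k] for k in keep] + [next_id]
        next_id += 1
    a, b, c = ids
    la = max(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), 0.0)
    lb = max(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), 0.0)
    lc = max(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), 0.0)
    return joins, (a, b, c), (la, lb, lc)


def nj_bipartition_masks(D: np.ndarray) -> set[int]:
    """Canonical internal-bipartition bitmasks of the NJ tree (topology only)."""
    n = D.shape[0]
    full = (1 << n) - 1
    joins, _, _ = _nj_join(D)
    mask = [1 << i for i in range(n)] + [0] * max(0, n - 3)
    out = set()
    for new_id, ci, cj, _, _ in joins:
        m = mask[ci] | mask[cj]
        if new_id >= len(mask):
            mask.append(0)
        mask[new_id] = m
        k = bin(m).count("1")
        if 2 <= k <= n - 2:
            out.add(_canon(m, full))
    return out


class PhyloTree:
    """Unrooted binary tree over TaxonLabels, stored rooted at a basal
    trifurcation (the standard unrooted-NJ rendering).

    Leaves are node ids ``0..n-1`` in taxon order; internal nodes follow in
    join order; the last id is the trifurcating base. Branch lengths are in
    substitutions/site; bootstrap supports (percent) attach to internal
    edges via their canonical bipartition mask.
    """

    def __init__(
        self,
        labels: Sequence[TaxonLabel],
        children: dict[int, tuple[int, ...]],
        blen: dict[int, float],
        root: int,
        supports: dict[int, float] | None = None,
    ):
        self.labels = list(labels)
        self.n = len(self.labels)
        self.children = children
        self.blen = blen
        self.root = root
        self.supports = supports  # canonical mask -> percent
        self._below: dict[int, int] | None = None
        self.full_mask = (1 << self.n) - 1

    # -- construction ---------------------------------------------------
    @classmethod
    def from_distance_matrix(cls, dm: DistanceMatrix) -> "PhyloTree":
        joins, root_children, root_lengths = _nj_join(dm.entries)
        children: dict[int, tuple[int, ...]] = {}
        blen: dict[int, float] = {}
        for new_id, ci, cj, li, lj in joins:
            children[new_id] = (ci, cj)
            blen[ci] = li
            blen[cj] = lj
        n = len(dm.taxa)
        root = max([n - 1] + [j[0] for j in joins]) + 1
        children[root] = root_children
        for ch, ln in zip(root_children, root_lengths):
            blen[ch] = ln
        return cls(dm.taxa, children, blen, root)

    # -- topology helpers ----------------------------------------------
    def below_masks(self) -> dict[int, int]:
        if self._below is None:
            below: dict[int, int] = {}

            def rec(v):
                if v < self.n:
                    below[v] = 1 << v
                else:
                    m = 0
                    for c in self.children[v]:
                        rec(c)
                        m |= below[c]
                    below[v] = m
                return below[v]

            rec(self.root)
            self._below = below
        return self._below

    def bipartitions(self) -> set[int]:
        """Canonical masks of all internal edges."""
        below = self.below_masks()
        out = set()
        for v, m in below.items():
            if v == self.root:
                continue
            k = bin(m).count("1")
            if 2 <= k <= self.n - 2:
                out.add(_canon(m, self.full_mask))
        return out

    def support_of(self, mask: int) -> float | None:
        """Bootstrap support of the edge splitting ``mask`` off, or None.

        Without computed supports the point-estimate tree is taken at face
        value: an edge present returns 100, an absent one 0.
        """
        cm = _canon(mask, self.full_mask)
        if cm not in self.bipartitions():
            return 0.0
        if self.supports is None:
            return 100.0
        return self.supports.get(cm, 0.0)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {v: [] for v in range(self.n)}
        for v, kids in self.children.items():
            adj.setdefault(v, [])
            for c in kids:
                adj.setdefault(c, [])
                adj[v].append((c, self.blen[c]))
                adj[c].append((v, self.blen[c]))
        return adj

    def rooted_clades(self, ref_leaf: int):
        """Clade leaf-masks when the tree is rooted at ``ref_leaf``.

        Returns (clade_mask, children_map, top) where ``clade_mask[v]`` is
        the leaf bitmask of v's subtree with edges directed away from the
        reference leaf and ``top`` is the reference leaf's single neighbor.
        """
        adj = self.adjacency()
        clade: dict[int, int] = {}
        kids: dict[int, list[int]] = {}

        order: list[tuple[int, int]] = []
        stack = [(ref_leaf, -1)]
        while stack:
            v, parent = stack.pop()
            order.append((v, parent))
            kids[v] = []
            for u, _ in adj[v]:
                if u != parent:
                    kids[v].append(u)
                    stack.append((u, v))
        for v, parent in reversed(order):
            m = (1 << v) if v < self.n else 0
            for u in kids[v]:
                m |= clade[u]
            clade[v] = m
        top = kids[ref_leaf][0]
        return clade, kids, top

    # -- metric helpers -------------------------------------------------
    def clade_anchor(self, mask: int) -> int:
        """Node subtending exactly the leaves in ``mask`` (any rooting).

        This is the coalescent node of the clade: the endpoint, on the clade
        side, of the edge separating ``mask`` from the rest.
        """
        below = self.below_masks()
        for v, m in below.items():
            if v != self.root and m == mask:
                return v
        # the clade may contain the storage root; root it elsewhere
        ref = 0
        while (1 << ref) & mask:
            ref += 1
        clade, _, _ = self.rooted_clades(ref)
        for v, m in clade.items():
            if v != ref and m == mask:
                return v
        raise ValueError("leaf set is not a clade in this tree")

    def mean_depth(self, mask: int, target_mask: int) -> float:
        """Mean path length from the clade anchor of ``mask`` to each leaf
        in ``target_mask`` (targets must lie inside the clade)."""
        if target_mask & ~mask:
            raise ValueError("target leaves outside clade")
        anchor = self.clade_anchor(mask)
        adj = self.adjacency()
        depths: dict[int, float] = {anchor: 0.0}
        stack = [(anchor, -1)]
        acc, cnt = 0.0, 0
        while stack:
            v, parent = stack.pop()
            if v < self.n and (1 << v) & target_mask:
                acc += depths[v]
                cnt += 1
            for u, ln in adj[v]:
                if u != parent and (u >= self.n or ((1 << u) & mask)):
                    # never leave the clade component
                    depths[u] = depths[v] + ln
                    stack.append((u, v))
        if cnt == 0:
            raise ValueError("no target leaves found")
        return acc / cnt

    def mrca_in_clade(self, clade_mask: int, target_mask: int) -> int:
        """Most recent common ancestor of ``target_mask`` leaves within the
        clade subtended by ``clade_mask`` (rooted at the clade anchor)."""
        if target_mask & ~clade_mask:
            raise ValueError("target leaves outside clade")
        anchor = self.clade_anchor(clade_mask)
        adj = self.adjacency()
        parent: dict[int, int] = {anchor: -1}
        sub_leaves: dict[int, int] = {}
        order = []
        stack = [(anchor, -1)]
        while stack:
            v, par = stack.pop()
            parent[v] = par
            order.append(v)
            for u, _ in adj[v]:
                if u != par and (u >= self.n or ((1 << u) & clade_mask)):
                    stack.append((u, v))
        for v in reversed(order):
            m = (1 << v) if v < self.n else 0
            for u, _ in adj[v]:
                if parent.get(u) == v:
                    m |= sub_leaves.get(u, 0)
            sub_leaves[v] = m
        # minimal subtree containing all targets
        best = anchor
        for v in order:
            if sub_leaves[v] & target_mask == target_mask and bin(sub_leaves[v]).count(
                "1"
            ) <= bin(sub_leaves[best]).count("1"):
                best = v
        return best

    def path_length(self, u: int, v: int) -> float:
        adj = self.adjacency()
        dist = {u: 0.0}
        stack = [(u, -1)]
        while stack:
            x, par = stack.pop()
            if x == v:
                return dist[x]
            for y, ln in adj[x]:
                if y != par:
                    dist[y] = dist[x] + ln
                    stack.append((y, x))
        raise ValueError("nodes not connected")

    def mean_path_from(self, node: int, target_mask: int) -> float:
        """Mean path length from ``node`` to each leaf in ``target_mask``."""
        adj = self.adjacency()
        dist = {node: 0.0}
        stack = [(node, -1)]
        acc, cnt = 0.0, 0
        while stack:
            x, par = stack.pop()
            if x < self.n and (1 << x) & target_mask:
                acc += dist[x]
                cnt += 1
            for y, ln in adj[x]:
                if y != par:
                    dist[y] = dist[x] + ln
                    stack.append((y, x))
        if cnt == 0:
            raise ValueError("no target leaves")
        return acc / cnt

    def leaf_mask(self, predicate) -> int:
        m = 0
        for i, lab in enumerate(self.labels):
            if predicate(lab):
                m |= 1 << i
        return m

    # -- output ---------------------------------------------------------
    def newick(self, with_supports: bool = True) -> str:
        below = self.below_masks()

        def rec(v):
            if v < self.n:
                return f"{self.labels[v].format()}:{self.blen[v]:.6g}"
            inner = ",".join(rec(c) for c in self.children[v])
            if v == self.root:
                return f"({inner})"
            lab = ""
            if with_supports and self.supports is not None:
                s = self.supports.get(_canon(below[v], self.full_mask))
                if s is not None:
                    lab = f"{s:.0f}"
            return f"({inner}){lab}:{self.blen[v]:.6g}"

        return rec(self.root) + ";"

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick(), schema="newick")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining from a p-distance matrix.

    Ties on the Q criterion break to the lexicographically smallest node-id
    pair; negative limb estimates are clamped to zero with the deficit
    logged.
    """
    if np.any(~np.isfinite(dm.entries)):
        raise ValueError("distance matrix contains missing entries")
    tree = PhyloTree.from_distance_matrix(dm)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def _pair_mismatch_matrix(codes: np.ndarray):
    """(n_pairs, n_cols) boolean mismatch indicators + pair index list."""
    n = codes.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    M = np.empty((len(pairs), codes.shape[1]), dtype=np.float64)
    for k, (i, j) in enumerate(pairs):
        M[k] = codes[i] != codes[j]
    return M, pairs


def _matrix_from_pair_values(vals: np.ndarray, pairs, n: int) -> np.ndarray:
    D = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        D[i, j] = D[j, i] = vals[k]
    return D


def bootstrap_mask_counts(
    codes_complete: np.ndarray, n_reps: int, rng: np.random.Generator
) -> dict[int, int]:
    """Counts of canonical bipartition masks over column-resampled NJ trees.

    ``codes_complete`` must already be restricted to complete (gap-free)
    columns; each replicate resamples columns with replacement.
    """
    n, m = codes_complete.shape
    M, pairs = _pair_mismatch_matrix(codes_complete)
    counts: dict[int, int] = {}
    p = np.full(m, 1.0 / m)
    for _ in range(n_reps):
        w = rng.multinomial(m, p)
        vals = (M @ w) / m
        D = _matrix_from_pair_values(vals, pairs, n)
        for mask in nj_bipartition_masks(D):
            counts[mask] = counts.get(mask, 0) + 1
    return counts


def bootstrap_tree(
    aln: Alignment,
    interval: Interval | None = None,
    n_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | np.random.Generator = 0,
    min_valid_sites: int = 1,
) -> PhyloTree:
    """NJ point tree with bootstrap supports on internal edges.

    Columns (complete-deletion set of the interval) are resampled with
    replacement ``n_reps`` times; an edge's support is the percentage of
    replicate trees containing its bipartition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dm = distance_matrix(aln, interval, min_valid_sites=min_valid_sites)
    tree = nj_tree(dm)
    cols = complete_columns(aln, interval)
    codes = aln.codes
    if interval is not None:
        codes = codes[:, interval.start : interval.end]
    sub = codes[:, cols]
    counts = bootstrap_mask_counts(sub, n_reps, rng)
    tree.supports = {
        mask: 100.0 * counts.get(mask, 0) / n_reps for mask in tree.bipartitions()
    }
    return tree


# ---------------------------------------------------------------------------
# Topology classification


@dataclass(frozen=True)
class TopologyCall:
    """Classification of one gene tree against the conversion vocabulary.

    ``paired_groups`` holds one frozenset of species per conversion clade
    detected (nested groups allowed: a recent species-specific event inside
    an older multi-species one contributes its own group).
    """

    call: str
    paired_groups: tuple[frozenset, ...] = ()
    support_ok: bool = True
    reason: str = ""

    @property
    def paired_species(self) -> frozenset:
        out: set = set()
        for g in self.paired_groups:
            out |= g
        return frozenset(out)

    def signature(self) -> tuple:
        """Hashable identity used when merging windows into sub-regions."""
        return (self.call, tuple(sorted(tuple(sorted(g)) for g in self.paired_groups)))


def classify_topology(
    tree: PhyloTree, support_threshold: float = DEFAULT_SUPPORT_THRESHOLD
) -> TopologyCall:
    """Call a gene tree as reciprocal monophyly / species pairing / mixed.

    Species cherries (a species' complete X+Y leaf set forming a 2+-leaf
    bipartition) are rooting-free. Multi-species conversion clades need a
    root; an outgroup leaf (any species lacking one of X/Y, e.g. a New World
    monkey X) is used when present, otherwise only cherries are reported.
    Deciding edges below ``support_threshold`` are discarded; a tree with no
    supported structure is UNRESOLVED.
    """
    labels = tree.labels
    by_species: dict[str, dict[str, int]] = {}
    for i, lab in enumerate(labels):
        by_species.setdefault(lab.species, {}).setdefault(lab.chromosome, 0)
        by_species[lab.species][lab.chromosome] |= 1 << i
    xy_species = sorted(
        s for s, c in by_species.items() if c.get("X", 0) and c.get("Y", 0)
    )
    if len(xy_species) < 2:
        return TopologyCall(UNRESOLVED, reason="fewer than 2 species with both X and Y")

    # all X-labelled leaves count, including an X-only outgroup: under no
    # conversion the outgroup X falls inside the X clade, so reciprocal
    # monophyly is judged on the strong X|Y split rather than on the short
    # internal edge separating the ingroup X set from the outgroup
    x_mask = tree.leaf_mask(lambda t: t.chromosome == "X")
    y_mask = tree.leaf_mask(lambda t: t.chromosome == "Y")
    species_mask = {
        s: tree.leaf_mask(lambda t, s=s: t.species == s) for s in by_species
    }

    def supported(mask: int) -> bool:
        s = tree.support_of(mask)
        return s is not None and s >= support_threshold

    def present(mask: int) -> bool:
        return _canon(mask, tree.full_mask) in tree.bipartitions()

    # --- conversion clades -------------------------------------------
    outgroup_species = [s for s in by_species if s not in xy_species]
    groups: list[frozenset] = []
    dropped_low_support = False

    # rooting-free: single-species cherries/clades
    for s in xy_species:
        m = species_mask[s]
        if bin(m).count("1") < 2 or bin(m).count("1") > tree.n - 2:
            continue
        if present(m):
            if supported(m):
                groups.append(frozenset([s]))
            else:
                dropped_low_support = True

    # rooted: multi-species clades, requires an outgroup reference
    if outgroup_species:
        ref = min(
            i for i, lab in enumerate(labels) if lab.species in outgroup_species
        )
        clade_mask, kids, top = tree.rooted_clades(ref)

        def species_of(mask: int) -> set[str]:
            return {labels[i].species for i in range(tree.n) if (1 << i) & mask}

        def is_signature(mask: int) -> frozenset | None:
            sp = species_of(mask)
            if not sp or not sp <= set(xy_species):
                return None
            want = 0
            for s in sp:
                want |= species_mask[s]
            return frozenset(sp) if want == mask else None

        explained_cache: dict[int, bool] = {}

        def explained(v: int) -> bool:
            """v's subtree is a union of complete pairs fully decomposed into
            per-species clades (so no extra ancestral event is implied)."""
            if v in explained_cache:
                return explained_cache[v]
            sig = is_signature(clade_mask[v])
            if sig is None:
                r = False
            elif len(sig) == 1:
                r = True
            else:
                r = all(explained(c) for c in kids[v])
            explained_cache[v] = r
            return r

        for v in clade_mask:
            if v == ref or v == top:
                continue
            m = clade_mask[v]
            sig = is_signature(m)
            if sig is None or len(sig) < 2:
                continue
            if not all(explained(c) for c in kids[v]):
                if supported(m):
                    groups.append(sig)
                else:
                    dropped_low_support = True

    groups = sorted(set(groups), key=lambda g: (len(g), sorted(g)))

    # --- verdict -------------------------------------------------------
    # a deciding edge below threshold means the window cannot be classified
    # with confidence; partial signatures are worse than none because the
    # segmentation merges on signature identity
    if dropped_low_support:
        return TopologyCall(
            UNRESOLVED, support_ok=False, reason="deciding edges below support threshold"
        )
    if groups:
        covered = frozenset().union(*groups)
        call = SPECIES_PAIRING if covered >= frozenset(xy_species) else MIXED
        return TopologyCall(call, tuple(groups))

    rm_edges_present = present(x_mask) and present(y_mask)
    if rm_edges_present and supported(x_mask) and supported(y_mask):
        return TopologyCall(RECIPROCAL_MONOPHYLY)
    reason = "deciding edges below support threshold" if (
        rm_edges_present or dropped_low_support
    ) else "no recognizable X/Y structure"
    return TopologyCall(UNRESOLVED, support_ok=False, reason=reason)


# ---------------------------------------------------------------------------
# Exhaustive least-squares reference (validation oracle)


def _all_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Built by stepwise leaf insertion; internal nodes are ids >= n.
    """
    base = [(0, n), (1, n), (2, n)]
    tops = [(base, n + 1)]
    for leaf in range(3, n):
        new = []
        for edges, next_id in tops:
            for k in range(len(edges)):
                u, v = edges[k]
                mid = next_id
                e2 = edges[:k] + edges[k + 1 :] + [(u, mid), (v, mid), (leaf, mid)]
                new.append((e2, next_id + 1))
        tops = new
    return [edges for edges, _ in tops]


def _topology_bipartitions(edges: list[tuple[int, int]], n: int) -> set[int]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    full = (1 << n) - 1
    out = set()

    def side(u, v):
        seen = {v}
        stack = [u]
        m = 0
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x < n:
                m |= 1 << x
            stack.extend(adj[x])
        return m

    for u, v in edges:
        m = side(u, v)
        k = bin(m).count("1")
        if 2 <= k <= n - 2:
            out.add(_canon(m, full))
    return out


def exhaustive_ls_topology(D: np.ndarray) -> set[int]:
    """Bipartition set of the best unrooted topology by ordinary least
    squares over branch lengths — brute force over all topologies.

    Exact reference for NJ on additive matrices (<=7 taxa is practical).
    """
    n = D.shape[0]
    if n > 8:
        raise ValueError("exhaustive search is for small taxon sets")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    y = np.array([D[i, j] for i, j in pairs])
    best = None
    for edges in _all_topologies(n):
        adj: dict[int, list[tuple[int, int]]] = {}
        for k, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((v, k))
            adj.setdefault(v, []).append((u, k))

        def path_edges(a, b):
            stack = [(a, -1, [])]
            while stack:
                x, parent, acc = stack.pop()
                if x == b:
                    return acc
                for u, k in adj[x]:
                    if u != parent:
                        stack.append((u, x, acc + [k]))
            raise RuntimeError

        X = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            for k in path_edges(i, j):
                X[row, k] = 1.0
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((X @ coef - y) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, edges)
    return _topology_bipartitions(best[1], n)
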