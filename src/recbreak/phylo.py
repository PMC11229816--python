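"""Breakpoint-based alignment slicing and local-tree reconstruction accuracy.

An alignment is sliced at a set of breakpoints, excluding a window of W
sites centered on each breakpoint (ceil(W/2) to the left, floor(W/2) to
the right); maximum-likelihood trees are reconstructed per remaining
segment under the equal-frequency single-rate model (neighbor-joining
start, per-branch length optimization, nearest-neighbor-interchange hill
climbing); and reconstruction accuracy is the per-site Robinson-Foulds
(RF) distance between the segment's tree and the site's true local tree,
normalized by the maximum 2(n-3) for unrooted binary trees.  Sites inside
an excluded window are interpolated: those left of the window midpoint are
scored with the neighboring tree to the left, the rest with the tree to
the right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from recbreak.detect import jc_distance, neighbor_joining
from recbreak.simulate import ARG, Alignment

__all__ = [
    "SlicePlan",
    "MLTree",
    "slice_alignment",
    "reconstruct_local_tree",
    "rf_distance",
    "rf_profile",
    "RFProfile",
]


@dataclass
class SlicePlan:
    """Partition of [0, L) into kept segments and excluded windows.

    Intervals are half-open boundary intervals; every excluded region
    contains at least one of the breakpoints used.  Segments shorter than
    ``min_segment`` are moved into the excluded set.
    """

    breakpoints: list
    window: int
    genome_length: int
    segments: list
    excluded: list

    def is_empty(self) -> bool:
        return not self.segments


def slice_alignment(aln: Alignment, breakpoints, window: int, min_segment: int = 20):
    """Slice an alignment at breakpoints with a centered exclusion window.

    Returns (plan, subalignments) where subalignments[i] is the Alignment
    restricted to plan.segments[i].
    """
    L = aln.length
    if window < 0:
        raise ValueError("window must be >= 0")
    bps = sorted({int(b) for b in breakpoints})
    if any(b <= 0 or b >= L for b in bps):
        raise ValueError("breakpoints must lie strictly inside (0, L)")
    half_l = math.ceil(window / 2)
    half_r = window // 2
    raw_excl = [(max(0, b - half_l), min(L, b + half_r)) for b in bps]
    # merge overlapping/contiguous exclusions (zero-width cuts kept as cut points)
    merged = []
    for lo, hi in raw_excl:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    segments = []
    excluded = []
    prev = 0
    for lo, hi in merged:
        if lo > prev:
            segments.append((prev, lo))
        if hi > lo:
            excluded.append((lo, hi))
        prev = max(prev, hi)
    if prev < L:
        segments.append((prev, L))
    # drop undersized segments into the excluded set, then re-merge
    kept = [s for s in segments if s[1] - s[0] >= min_segment]
    excluded = sorted(excluded + [s for s in segments if s[1] - s[0] < min_segment])
    merged_excl = []
    for lo, hi in excluded:
        if merged_excl and lo <= merged_excl[-1][1]:
            merged_excl[-1] = (merged_excl[-1][0], max(hi, merged_excl[-1][1]))
        else:
            merged_excl.append((lo, hi))
    plan = SlicePlan(bps, window, L, kept, merged_excl)
    subs = [Alignment(aln.ids, aln.matrix[:, a:b]) for a, b in kept]
    return plan, subs


# ---------------------------------------------------------------------------
# Maximum-likelihood tree search (NJ start + branch lengths + NNI)
# ---------------------------------------------------------------------------


def _patterns(matrix):
    m = np.asarray(matrix, dtype=np.int64)
    n = m.shape[0]
    pow4 = 4 ** np.arange(n, dtype=np.int64)
    codes = m.T @ pow4
    uniq, counts = np.unique(codes, return_counts=True)
    pat = np.empty((uniq.size, n), dtype=np.int64)
    c = uniq.copy()
    for i in range(n):
        pat[:, i] = c % 4
        c //= 4
    return pat, counts.astype(float)


def _pmat(t):
    e = math.exp(-4.0 / 3.0 * max(t, 0.0))
    return np.full((4, 4), 0.25 * (1.0 - e)) + e * np.eye(4)


class MLTree:
    """Unrooted tree with branch lengths and a JC pruning likelihood."""

    def __init__(self, edges, n_leaves, patterns, counts):
        self.n_leaves = n_leaves
        self.patterns = patterns
        self.counts = counts
        self.adj = {}
        for u, v, t in edges:
            self.adj.setdefault(u, {})[v] = float(t)
            self.adj.setdefault(v, {})[u] = float(t)
        self.degenerate = False
        self._leaf_onehot = None

    # -- likelihood machinery ------------------------------------------------

    def _partial(self, u, par, cache):
        """Subtree likelihood array at u viewed from its neighbor ``par``."""
        key = (u, par)
        if key in cache:
            return cache[key]
        if u < self.n_leaves and len(self.adj[u]) == 1:
            if self._leaf_onehot is None:
                npat = self.patterns.shape[0]
                oh = np.zeros((self.n_leaves, npat, 4))
                for lf in range(self.n_leaves):
                    oh[lf, np.arange(npat), self.patterns[:, lf]] = 1.0
                self._leaf_onehot = oh
            out = self._leaf_onehot[u]
        else:
            out = np.ones((self.patterns.shape[0], 4))
            for v, t in self.adj[u].items():
                if v == par:
                    continue
                out = out * (self._partial(v, u, cache) @ _pmat(t))
        cache[key] = out
        return out

    def _edge_ab(self, u, v, cache):
        A = self._partial(u, v, cache)
        G = self._partial(v, u, cache)
        sa = A.sum(axis=1)
        sg = G.sum(axis=1)
        a = sa * sg / 16.0
        b = 0.25 * np.einsum("px,px->p", A, G) - a
        return a, b

    def loglik(self) -> float:
        u = next(iter(self.adj))
        v = next(iter(self.adj[u]))
        a, b = self._edge_ab(u, v, {})
        e = math.exp(-4.0 / 3.0 * self.adj[u][v])
        return float(self.counts @ np.log(np.maximum(a + b * e, 1e-300)))

    # -- optimization --------------------------------------------------------

    @staticmethod
    def _opt_u(a, b, counts, u_min=1e-6):
        """Maximize sum(counts * log(a + b*u)) over u in [u_min, 1]."""

        def g(u):
            return float(np.sum(counts * b / np.maximum(a + b * u, 1e-300)))

        if g(1.0) >= 0:
            return 1.0
        if g(u_min) <= 0:
            return u_min
        lo, hi = u_min, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def optimize_branch_lengths(self, sweeps: int = 2):
        for _ in range(sweeps):
            for u in list(self.adj):
                for v in list(self.adj[u]):
                    if u < v:
                        a, b = self._edge_ab(u, v, {})
                        ustar = self._opt_u(a, b, self.counts)
                        t = -0.75 * math.log(ustar)
                        self.adj[u][v] = self.adj[v][u] = t

    def _internal_edges(self):
        return [
            (u, v)
            for u in self.adj
            for v in self.adj[u]
            if u < v and len(self.adj[u]) > 1 and len(self.adj[v]) > 1
        ]

    def nni_search(self, max_rounds: int = 30):
        """Greedy NNI hill climbing; each accepted move improves the likelihood."""
        for _ in range(max_rounds):
            cache = {}
            best = None
            for (u, v) in self._internal_edges():
                nb_u = [w for w in self.adj[u] if w != v]
                nb_v = [w for w in self.adj[v] if w != u]
                if len(nb_u) != 2 or len(nb_v) != 2:
                    continue
                W, X = nb_u
                Y, Z = nb_v
                msg = {
                    w: self._partial(w, node, cache) @ _pmat(self.adj[node][w])
                    for node, pairs in ((u, (W, X)), (v, (Y, Z)))
                    for w in pairs
                }

                def score(Aparts, Gparts):
                    A = msg[Aparts[0]] * msg[Aparts[1]]
                    G = msg[Gparts[0]] * msg[Gparts[1]]
                    sa = A.sum(axis=1)
                    sg = G.sum(axis=1)
                    a = sa * sg / 16.0
                    b = 0.25 * np.einsum("px,px->p", A, G) - a
                    ustar = self._opt_u(a, b, self.counts)
                    ll = float(self.counts @ np.log(np.maximum(a + b * ustar, 1e-300)))
                    return ll, -0.75 * math.log(ustar)

                ll0, t0 = score((W, X), (Y, Z))
                for swap, (Ap, Gp) in {
                    (X, Y): ((W, Y), (X, Z)),
                    (X, Z): ((W, Z), (Y, X)),
                }.items():
                    ll, t = score(Ap, Gp)
                    if ll > ll0 + 1e-7 and (best is None or ll - ll0 > best[0]):
                        best = (ll - ll0, u, v, swap[0], swap[1], t)
            if best is None:
                return
            _, u, v, x, y, t = best
            tx = self.adj[u].pop(x)
            ty = self.adj[v].pop(y)
            del self.adj[x][u], self.adj[y][v]
            self.adj[u][y] = self.adj[y][u] = ty
            self.adj[v][x] = self.adj[x][v] = tx
            self.adj[u][v] = self.adj[v][u] = t
            self.optimize_branch_lengths(sweeps=1)

    # -- topology ------------------------------------------------------------

    def bipartitions(self):
        """Nontrivial splits, each encoded as the leaf side excluding leaf 0."""
        out = set()
        full = frozenset(range(self.n_leaves))
        for (u, v) in self._internal_edges():
            side = set()
            stack = [(u, v)]
            while stack:
                node, par = stack.pop()
                if node < self.n_leaves and len(self.adj[node]) == 1:
                    side.add(node)
                for w in self.adj[node]:
                    if w != par:
                        stack.append((w, node))
            side = frozenset(side)
            if 0 in side:
                side = full - side
            if 2 <= len(side) <= self.n_leaves - 2:
                out.add(side)
        return out

    def newick(self, labels=None) -> str:
        if labels is None:
            labels = [f"s{i}" for i in range(self.n_leaves)]
        root = next(iter(self.adj[0]))  # internal node adjacent to leaf 0

        def rec(u, par):
            if u < self.n_leaves and len(self.adj[u]) == 1:
                return f"{labels[u]}:{self.adj[u][par]:.10g}"
            inner = ",".join(rec(v, u) for v in self.adj[u] if v != par)
            bl = f":{self.adj[u][par]:.10g}" if par is not None else ""
            return f"({inner}){bl}"

        return rec(root, None) + ";"


def reconstruct_local_tree(subaln: Alignment) -> MLTree:
    """ML local tree: NJ start, branch-length optimization, NNI hill climbing.

    With zero variable sites the NJ tree (arbitrary topology, zero branch
    lengths) is returned with ``degenerate`` set.  The returned tree's
    likelihood is never below the NJ starting tree's.
    """
    m = np.asarray(subaln.matrix)
    n = m.shape[0]
    pat, cnt = _patterns(m)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = jc_distance(np.mean(m[i] != m[j]))
    edges, n_nodes = neighbor_joining(dmat)
    tree = MLTree(edges, n, pat, cnt)
    if not np.any(dmat > 0):
        tree.degenerate = True
        return tree
    tree.optimize_branch_lengths(sweeps=2)
    tree.nni_search()
    tree.optimize_branch_lengths(sweeps=1)
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds evaluation
# ---------------------------------------------------------------------------


def rf_distance(bip_a, bip_b, n_tips: int, normalized: bool = True) -> float:
    """Symmetric difference of two bipartition sets (optionally /2(n-3))."""
    raw = len(bip_a ^ bip_b)
    if not normalized:
        return float(raw)
    denom = 2 * (n_tips - 3)
    return raw / denom if denom > 0 else 0.0


@dataclass
class RFProfile:
    """Per-site normalized RF distances with window interpolation provenance."""

    per_site: np.ndarray  # length L, values in [0, 1]
    assignment: list  # (start, end, segment_index or -1) coverage provenance

    @property
    def mean(self) -> float:
        return float(self.per_site.mean())

    def per_tree_mean(self, truth) -> float:
        """Mean RF weighting each true local tree equally (not by span)."""
        trees = truth.local_trees if isinstance(truth, ARG) else list(truth)
        vals = [float(self.per_site[t.start:t.end].mean()) for t in trees]
        return float(np.mean(vals))


def rf_profile(trees, plan: SlicePlan, truth) -> RFProfile:
    """Score reconstructed segment trees against the true local trees per site.

    ``trees`` holds one reconstructed tree per plan segment; ``truth`` is
    the source ARG or a list of true :class:`LocalTree` objects tiling the
    genome.  Sites in excluded windows are scored with the neighboring
    segment tree on their side of the window midpoint (single-neighbor
    interpolation at the genome edges).
    """
    if plan.is_empty():
        raise ValueError("empty slice plan: no segment trees to score")
    L = plan.genome_length
    true_trees = truth.local_trees if isinstance(truth, ARG) else list(truth)
    n = true_trees[0].n
    # site -> reconstructed-tree assignment, as intervals
    assign = [(a, b, i) for i, (a, b) in enumerate(plan.segments)]
    for (a, b) in plan.excluded:
        left = None
        right = None
        for i, (sa, sb) in enumerate(plan.segments):
            if sb <= a:
                left = i
            if right is None and sa >= b:
                right = i
        mid = (a + b) // 2
        if left is None and right is None:
            raise ValueError("no neighboring segment for excluded region")
        if left is None:
            assign.append((a, b, right))
        elif right is None:
            assign.append((a, b, left))
        else:
            if mid > a:
                assign.append((a, mid, left))
            if b > mid:
                assign.append((mid, b, right))
    assign.sort()
    rec_bips = [t.bipartitions() for t in trees]
    true_bips = [t.bipartitions() for t in true_trees]
    true_bounds = [(t.start, t.end) for t in true_trees]
    per_site = np.empty(L)
    cache = {}
    for (a, b, i) in assign:
        for j, (ta, tb) in enumerate(true_bounds):
            lo, hi = max(a, ta), min(b, tb)
            if lo >= hi:
                continue
            if (i, j) not in cache:
                cache[(i, j)] = rf_distance(rec_bips[i], true_bips[j], n)
            per_site[lo:hi] = cache[(i, j)]
    return RFProfile(per_site=per_site, assignment=assign)
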