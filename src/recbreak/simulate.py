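"""Coalescent-with-recombination simulation of ARGs and sequence alignments.

This module generates ancestral recombination graphs (ARGs) for a sample of
haploid sequences under the standard back-in-time coalescent with
recombination (Hudson's algorithm), optionally conditioned by rejection on
the number of recombination events realized.  Every recombination event is
recorded with its genomic breakpoint and classified into one of three types
according to where the two parental lineages of the recombinant next
coalesce:

* Type I   -- the two parent lineages coalesce immediately with each other;
              the event leaves no trace in the local trees and is
              undetectable from sequence data.
* Type II  -- one parent first coalesces with another ancestral lineage and
              the resulting lineage then immediately coalesces with the
              other parent; local-tree branch lengths change but the
              topology does not.
* Type III -- the parents coalesce with different lineages; the local-tree
              topology changes across the breakpoint.

Sequences are evolved along each local tree under a single-rate,
equal-frequency (Jukes-Cantor) substitution model and concatenated in
genomic order, so the alignment is an exact mosaic of the local genealogies.

Coordinates: sites are 1-based (1..L); a breakpoint b is an integer boundary
meaning sites 1..b descend from the left parental genealogy and b+1..L from
the right.  Genomic intervals are half-open boundary intervals [start, end)
covering 1-based sites start+1..end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "RecombinationEvent",
    "LocalTree",
    "ARG",
    "SubARG",
    "Alignment",
    "RejectionCapExceeded",
    "simulate_arg",
    "simulate_sequences",
    "extract_sub_arg",
    "TYPE_I",
    "TYPE_II",
    "TYPE_III",
]

TYPE_I = "I"
TYPE_II = "II"
TYPE_III = "III"

BASES = "ACGT"


class RejectionCapExceeded(RuntimeError):
    """Raised when no ARG satisfying the event constraint is found."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a single coalescent-with-recombination simulation.

    ``diversity`` is the expected pairwise heterozygosity pi = 2*Ne*mu, from
    which the per-site mutation rate is derived as mu = pi / (2*Ne).
    ``recomb_rate`` is the per-site, per-generation recombination rate.  The
    event constraint is an inclusive range [min_events, max_events]; ``None``
    leaves the corresponding bound open.

    ``child_is_sample`` additionally requires each recombination event to
    occur on a lineage whose material flanking the breakpoint is ancestral to
    exactly one sample, so that a unique recombinant child sequence exists
    (used in the single-breakpoint triplet study).  ``exclude_type1`` rejects
    ARGs containing any undetectable (Type I) event, as in the
    multiple-breakpoint study.
    """

    genome_length: int = 1000
    diversity: float = 0.05
    recomb_rate: float = 1e-4
    sample_size: int = 3
    effective_size: float = 1.0
    min_events: int | None = None
    max_events: int | None = None
    child_is_sample: bool = False
    exclude_type1: bool = False
    rejection_cap: int = 100_000

    def __post_init__(self) -> None:
        if self.genome_length < 2:
            raise ValueError("genome_length must be >= 2")
        if self.diversity <= 0:
            raise ValueError("diversity (pi) must be > 0")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if self.min_events is not None and self.min_events < 0:
            raise ValueError("event constraint lower bound must be >= 0")
        if (
            self.min_events is not None
            and self.max_events is not None
            and self.max_events < self.min_events
        ):
            raise ValueError("max_events < min_events")

    @property
    def mutation_rate(self) -> float:
        """Per-site substitution rate mu = pi / (2 Ne)."""
        return self.diversity / (2.0 * self.effective_size)


@dataclass
class RecombinationEvent:
    """A recombination event realized in a simulated ARG."""

    breakpoint: int  # integer boundary, 0 < b < L
    time: float  # coalescent-scaled time of the event
    event_type: str | None = None  # one of "I", "II", "III"
    child_samples: frozenset = frozenset()  # samples below the recombinant lineage
    # internal bookkeeping (lineage ids and position in the event history)
    _child_lid: int = -1
    _left_lid: int = -1
    _right_lid: int = -1
    _hist_index: int = -1


class LocalTree:
    """Rooted binary genealogy of the samples over one genomic interval.

    Parameters are a half-open boundary interval [start, end), a
    child -> parent map over node ids (samples are 0..n-1), and node times.
    """

    def __init__(self, start, end, parent, times, n):
        self.start = int(start)
        self.end = int(end)
        self.parent = dict(parent)
        self.times = dict(times)
        self.n = int(n)
        roots = set()
        for s in range(n):
            u = s
            while u in self.parent:
                u = self.parent[u]
            roots.add(u)
        if len(roots) != 1:
            raise ValueError("local tree does not have a single root")
        self.root = roots.pop()

    @property
    def span(self) -> int:
        return self.end - self.start

    def _children(self):
        ch = {}
        for c, p in self.parent.items():
            ch.setdefault(p, []).append(c)
        return ch

    def clade_map(self):
        """Map node id -> frozenset of descendant samples."""
        ch = self._children()
        clades = {}

        def rec(u):
            if u < self.n and u not in ch:
                clades[u] = frozenset([u])
            else:
                s = frozenset()
                for c in ch[u]:
                    s |= rec(c)
                clades[u] = s
            return clades[u]

        rec(self.root)
        return clades

    def tmrca(self, a: int, b: int) -> float:
        """Time of the most recent common ancestor of samples a and b."""
        anc = {}
        u = a
        while True:
            anc[u] = self.times.get(u, 0.0)
            if u not in self.parent:
                break
            u = self.parent[u]
        u = b
        while u not in anc:
            u = self.parent[u]
        return anc[u]

    def restricted_canonical(self, subset, ndigits: int = 9):
        """Canonical form of the marginal tree restricted to ``subset``.

        The restriction of a rooted tree (with branch lengths) to a sample
        subset is fully determined by the set of (clade, coalescence time)
        pairs over the pairwise MRCAs of the subset; two restrictions are
        equal iff these canonical sets are equal.
        """
        subset = sorted(subset)
        clades = self.clade_map()
        nodes = set()
        for i, a in enumerate(subset):
            for b in subset[i + 1:]:
                # climb from a until clade contains b
                u = a
                while b not in clades[u]:
                    u = self.parent[u]
                nodes.add(u)
        return frozenset(
            (clades[u] & frozenset(subset), round(self.times[u], ndigits))
            for u in nodes
        )

    def bipartitions(self):
        """Nontrivial unrooted splits, each encoded as the side without sample 0."""
        clades = self.clade_map()
        out = set()
        full = frozenset(range(self.n))
        for u, cl in clades.items():
            if u == self.root or len(cl) < 2 or len(cl) > self.n - 2:
                continue
            side = cl if 0 not in cl else full - cl
            if 2 <= len(side) <= self.n - 2:
                out.add(side)
        return out

    def newick(self, labels=None) -> str:
        if labels is None:
            labels = [f"s{i}" for i in range(self.n)]
        ch = self._children()

        def rec(u):
            t = self.times.get(u, 0.0)
            pt = self.times.get(self.parent.get(u), None)
            bl = "" if pt is None else f":{pt - t:.10g}"
            if u not in ch:
                return f"{labels[u]}{bl}"
            inner = ",".join(rec(c) for c in ch[u])
            return f"({inner}){bl}"

        return rec(self.root) + ";"


@dataclass
class SubARG:
    """An ARG restricted to a subset of the samples.

    ``breakpoints`` holds only the event breakpoints visible to the subset,
    i.e. those at which the restricted marginal genealogy changes (topology
    or branch lengths).  ``events`` are the corresponding original events.
    """

    samples: tuple
    breakpoints: list
    events: list
    trees: list  # canonical restricted marginal trees, one per interval of the parent ARG


class ARG:
    """A simulated ancestral recombination graph.

    Holds the realized recombination events (with types), the tiling of the
    genome into local-tree intervals, and one :class:`LocalTree` per
    interval.  Intervals are split at every distinct event breakpoint, so
    adjacent trees may be identical across a Type I breakpoint.
    """

    def __init__(self, config, events, local_trees, history):
        self.config = config
        self.events = events
        self.local_trees = local_trees
        self._history = history

    @property
    def breakpoints(self):
        """Sorted distinct event breakpoints."""
        return sorted({e.breakpoint for e in self.events})

    @property
    def num_events(self) -> int:
        return len(self.events)

    def tree_at(self, boundary_pos) -> LocalTree:
        """Local tree covering boundary position x in [0, L] (site i+0.5 -> x=i+0.5)."""
        for t in self.local_trees:
            if t.start <= boundary_pos < t.end:
                return t
        return self.local_trees[-1]

    def tree_for_site(self, site: int) -> LocalTree:
        """Local tree for 1-based site index."""
        return self.tree_at(site - 0.5)

    def sub_arg(self, subset) -> SubARG:
        return extract_sub_arg(self, subset)


class Alignment:
    """n sequences of equal length over {A,C,G,T}, optionally tied to an ARG."""

    def __init__(self, ids, matrix, source_arg=None):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(ids) != matrix.shape[0]:
            raise ValueError("number of ids must match number of rows")
        self.ids = list(ids)
        self.matrix = matrix
        self.source_arg = source_arg

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(BASES[b] for b in self.matrix[i])

    def pairwise_diversity(self) -> float:
        """Realized mean pairwise difference proportion (pi-hat)."""
        n = self.n
        tot = 0.0
        cnt = 0
        for i in range(n):
            for j in range(i + 1, n):
                tot += np.mean(self.matrix[i] != self.matrix[j])
                cnt += 1
        return tot / cnt

    def to_fasta(self) -> str:
        return "".join(f">{sid}\n{self.sequence(i)}\n" for i, sid in enumerate(self.ids))


# ---------------------------------------------------------------------------
# Hudson back-in-time simulation
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("lid", "segs")

    def __init__(self, lid, segs):
        self.lid = lid
        self.segs = segs  # sorted list of (left, right, node, samples)

    @property
    def left(self):
        return self.segs[0][0]

    @property
    def right(self):
        return self.segs[-1][1]

    @property
    def span(self):
        return self.right - self.left


def _merge_segments(segs_a, segs_b, t, n, node_time, edges):
    """Merge two ancestral-segment lists at a coalescence.

    Overlapping intervals coalesce into a new node (created lazily); fully
    coalesced intervals (all n samples ancestral) are dropped from the
    output after recording their edges.
    """
    bounds = sorted({x for s in segs_a for x in (s[0], s[1])}
                    | {x for s in segs_b for x in (s[0], s[1])})
    out = []
    w = None
    ia = ib = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        while ia < len(segs_a) and segs_a[ia][1] <= lo:
            ia += 1
        while ib < len(segs_b) and segs_b[ib][1] <= lo:
            ib += 1
        sa = segs_a[ia] if ia < len(segs_a) and segs_a[ia][0] <= lo else None
        sb = segs_b[ib] if ib < len(segs_b) and segs_b[ib][0] <= lo else None
        if sa is not None and sb is not None:
            if w is None:
                w = len(node_time)
                node_time.append(t)
            edges.append((lo, hi, w, sa[2]))
            edges.append((lo, hi, w, sb[2]))
            smp = sa[3] | sb[3]
            if len(smp) < n:
                out.append((lo, hi, w, smp))
        elif sa is not None:
            out.append((lo, hi, sa[2], sa[3]))
        elif sb is not None:
            out.append((lo, hi, sb[2], sb[3]))
    # coalesce adjacent output segments sharing node and samples
    merged = []
    for seg in out:
        if merged and merged[-1][1] == seg[0] and merged[-1][2] == seg[2] \
                and merged[-1][3] == seg[3]:
            merged[-1] = (merged[-1][0], seg[1], seg[2], seg[3])
        else:
            merged.append(list(seg))
            merged[-1] = tuple(merged[-1])
    return merged, w


def _simulate_raw(config: SimulationConfig, rng: np.random.Generator):
    """One unconditioned run of Hudson's algorithm.

    Returns (events, history, edges, node_time).  ``history`` is the
    time-ordered list of structural events:
      ("rec", child_lid, left_lid, right_lid, breakpoint)
      ("coal", lid_a, lid_b, new_lid)
    """
    L = config.genome_length
    n = config.sample_size
    r = config.recomb_rate
    Ne = config.effective_size

    node_time = [0.0] * n
    edges = []
    events = []
    history = []
    lineages = {}
    for i in range(n):
        lineages[i] = _Lineage(i, [(0, L, i, frozenset([i]))])
    next_lid = n
    t = 0.0

    while lineages:
        lids = list(lineages)
        k = len(lids)
        spans = np.array([lineages[l].span for l in lids], dtype=float)
        rate_c = k * (k - 1) / 2.0 / Ne
        rate_r = r * float(spans.sum())
        total = rate_c + rate_r
        if total <= 0:  # single lineage with zero span and r == 0 cannot occur
            break
        t += rng.exponential(1.0 / total)
        if rng.random() * total < rate_c:
            ia, ib = rng.choice(k, size=2, replace=False)
            la, lb = lineages.pop(lids[ia]), lineages.pop(lids[ib])
            segs, _ = _merge_segments(la.segs, lb.segs, t, n, node_time, edges)
            new_lid = next_lid
            next_lid += 1
            history.append(("coal", la.lid, lb.lid, new_lid))
            if segs:
                lineages[new_lid] = _Lineage(new_lid, segs)
        else:
            idx = rng.choice(k, p=spans / spans.sum())
            lin = lineages[lids[idx]]
            x = rng.uniform(lin.left, lin.right)
            b = int(math.ceil(x - 0.5))  # snap to nearest boundary, ties downward
            if b <= lin.left or b >= lin.right:
                continue  # split would be trivial; not a recombination event
            left_segs = [(l, min(rr, b), nd, sm) for (l, rr, nd, sm) in lin.segs if l < b]
            right_segs = [(max(l, b), rr, nd, sm) for (l, rr, nd, sm) in lin.segs if rr > b]
            del lineages[lin.lid]
            lid_l, lid_r = next_lid, next_lid + 1
            next_lid += 2
            lineages[lid_l] = _Lineage(lid_l, left_segs)
            lineages[lid_r] = _Lineage(lid_r, right_segs)
            smp_left = left_segs[-1][3]
            smp_right = right_segs[0][3]
            ev = RecombinationEvent(
                breakpoint=b,
                time=t,
                child_samples=smp_left | smp_right,
                _child_lid=lin.lid,
                _left_lid=lid_l,
                _right_lid=lid_r,
                _hist_index=len(history),
            )
            events.append(ev)
            history.append(("rec", lin.lid, lid_l, lid_r, b))
    return events, history, edges, node_time


def _classify_from_history(event: RecombinationEvent, history) -> str:
    """Classify one event by tracking its two parent lineages forward.

    The carriers of the genomic points just left/right of the breakpoint are
    followed through any subsequent recombinations; the verdict depends on
    the first two coalescences involving a carrier (see module docstring).
    """
    b = event.breakpoint
    cur = {"L": event._left_lid, "R": event._right_lid}
    pts = {"L": b - 0.5, "R": b + 0.5}
    stage = 0
    for entry in history[event._hist_index + 1:]:
        if entry[0] == "rec":
            _, child, lid_l, lid_r, bp = entry
            for side in ("L", "R"):
                if cur[side] == child:
                    cur[side] = lid_l if pts[side] < bp else lid_r
        else:
            _, la, lb, new = entry
            inv_l = cur["L"] in (la, lb)
            inv_r = cur["R"] in (la, lb)
            if not (inv_l or inv_r):
                continue
            if inv_l and inv_r:
                return TYPE_I if stage == 0 else TYPE_II
            if stage == 1:
                return TYPE_III
            stage = 1
            side = "L" if inv_l else "R"
            cur[side] = new
    return TYPE_III  # defensive: unreachable for a completed simulation


def _build_local_trees(config, events, edges, node_time):
    L = config.genome_length
    n = config.sample_size
    bps = sorted({e.breakpoint for e in events})
    bounds = [0] + bps + [L]
    trees = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo == hi:
            continue
        mid = (lo + hi) / 2.0
        parent = {}
        for (el, er, p, c) in edges:
            if el <= mid < er:
                parent[c] = p
        nodes = set()
        for s in range(n):
            u = s
            nodes.add(u)
            while u in parent:
                u = parent[u]
                nodes.add(u)
        times = {u: node_time[u] for u in nodes}
        trees.append(LocalTree(lo, hi, parent, times, n))
    return trees


def simulate_arg(config: SimulationConfig, rng) -> ARG:
    """Simulate an ARG satisfying the config's event constraint.

    Conditioning (on the event count, on a unique recombinant child per
    event when ``child_is_sample``, and on the absence of Type I events when
    ``exclude_type1``) is by rejection: unconditioned ARGs are drawn until
    one satisfies all constraints, up to ``rejection_cap`` attempts.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo = config.min_events
    hi = config.max_events
    for _ in range(config.rejection_cap):
        events, history, edges, node_time = _simulate_raw(config, rng)
        k = len(events)
        if lo is not None and k < lo:
            continue
        if hi is not None and k > hi:
            continue
        if config.child_is_sample and any(len(e.child_samples) != 1 for e in events):
            continue
        for e in events:
            e.event_type = _classify_from_history(e, history)
        if config.exclude_type1 and any(e.event_type == TYPE_I for e in events):
            continue
        trees = _build_local_trees(config, events, edges, node_time)
        return ARG(config, events, trees, history)
    raise RejectionCapExceeded(
        f"no ARG satisfying the event constraint in {config.rejection_cap} attempts"
    )


def classify_event(arg: ARG, event: RecombinationEvent) -> str:
    """Type of a recombination event belonging to ``arg`` (recomputed from history)."""
    if event not in arg.events:
        raise ValueError("event does not belong to this ARG")
    return _classify_from_history(event, arg._history)


# ---------------------------------------------------------------------------
# Sequence simulation (Jukes-Cantor along local trees)
# ---------------------------------------------------------------------------


def _jc_evolve(parent_seq, t, mu, rng):
    """Evolve a sequence for time t under JC with total substitution rate mu."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * mu * t))
    w = parent_seq.shape[0]
    mask = rng.random(w) < p_change
    child = parent_seq.copy()
    if mask.any():
        offs = rng.integers(1, 4, size=int(mask.sum()))
        child[mask] = (child[mask] + offs) % 4
    return child


def simulate_sequences(arg: ARG, mu: float | None = None, rng=None) -> Alignment:
    """Evolve an alignment along the ARG's local trees and concatenate.

    For each local-tree interval the root sequence is drawn from the equal
    equilibrium frequencies and substituted down the branches under the
    single-rate JC model with per-site rate ``mu`` (default: the config's
    pi/(2 Ne)).  Intervals are concatenated in genomic order, so the true
    breakpoint mosaic structure of the recombinant samples is preserved.
    """
    if mu is None:
        mu = arg.config.mutation_rate
    if mu < 0:
        raise ValueError("mu must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = arg.config.sample_size
    L = arg.config.genome_length
    matrix = np.empty((n, L), dtype=np.int8)
    for tree in arg.local_trees:
        w = tree.span
        order = sorted(tree.times, key=lambda u: -tree.times[u])
        seqs = {}
        seqs[tree.root] = rng.integers(0, 4, size=w).astype(np.int8)
        for u in order:
            if u == tree.root:
                continue
            p = tree.parent[u]
            dt = tree.times[p] - tree.times[u]
            seqs[u] = _jc_evolve(seqs[p], dt, mu, rng)
        for s in range(n):
            matrix[s, tree.start:tree.end] = seqs[s]
    ids = [f"s{i}" for i in range(n)]
    return Alignment(ids, matrix, source_arg=arg)


# ---------------------------------------------------------------------------
# Sub-ARG extraction
# ---------------------------------------------------------------------------


def extract_sub_arg(arg: ARG, subset) -> SubARG:
    """Restrict an ARG to a subset of its samples.

    An event breakpoint is retained iff the marginal genealogy of the subset
    changes across it (in topology or branch lengths); events invisible to
    the subset are dropped.  Breakpoint positions are unchanged.
    """
    subset = tuple(sorted(set(subset)))
    n = arg.config.sample_size
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 samples")
    if any(s < 0 or s >= n for s in subset):
        raise ValueError("subset contains unknown samples")
    canon = [t.restricted_canonical(subset) for t in arg.local_trees]
    visible = []
    vis_events = []
    by_bp = {}
    for e in arg.events:
        by_bp.setdefault(e.breakpoint, []).append(e)
    for i in range(len(arg.local_trees) - 1):
        b = arg.local_trees[i].end
        if canon[i] != canon[i + 1]:
            visible.append(b)
            vis_events.extend(by_bp.get(b, []))
    return SubARG(samples=subset, breakpoints=visible, events=vis_events, trees=canon)
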