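"""Native recombination breakpoint detectors.

Three detector families operating on nucleotide alignments:

* :func:`maxchi_scan` -- pairwise chi-square scan.  For every interior
  boundary k the 2x2 contingency table of (differing, matching) site counts
  to the left/right of k is formed for a sequence pair; the boundary
  maximizing the chi-square statistic is the candidate breakpoint, with
  significance assessed by permuting site order.  On a detection the scan
  recurses into each flank, so multiple breakpoints can be reported.

* :func:`threeseq_test` -- triplet exact test.  Sites where a candidate
  child sequence C matches exactly one of two candidate parents P/Q define
  a +-1 random walk in genomic order; the test statistic is the maximum
  descent of the walk and its exact p-value under the null of uniformly
  random orderings of the P-like and Q-like steps (a hypergeometric random
  walk) is computed by dynamic programming.  The breakpoint estimate is the
  midpoint of the uninformative gap bounding the maximal descent.

* :func:`gardlike_scan` -- phylogenetic incongruence scan.  For each
  candidate boundary, neighbor-joining trees are built from JC-corrected
  distances for the two flanking segments, segment log-likelihoods are
  computed by Felsenstein pruning under the equal-frequency single-rate
  model, and the two-tree model is compared against the single-tree model
  by small-sample-corrected AIC (AICc).  Multiple breakpoints are added
  greedily while the AICc improves.

Each detected event carries a site-wise breakpoint-probability profile
(length L, normalized to sum to one): scaled chi-square values for the
pairwise scan, uniform mass over the bounding gap for the triplet test,
and Akaike weights over candidate boundaries for the AICc scan.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from recbreak.simulate import Alignment

__all__ = [
    "DetectedEvent",
    "TripletWalk",
    "informative_labels",
    "max_descent",
    "max_descent_pvalue",
    "maxchi_scan",
    "threeseq_test",
    "gardlike_scan",
    "run_all_detectors",
    "neighbor_joining",
    "segment_loglik",
    "jc_distance",
    "aicc",
]


@dataclass
class DetectedEvent:
    """One detected recombination event.

    ``interval`` is an inclusive site-position range (lo, hi) containing the
    point estimate (degenerate for the point methods); ``point`` is the
    breakpoint point estimate on the boundary scale (sites <= point are
    left of the breakpoint).  ``profile`` is a length-L nonnegative vector
    summing to one; entry i is the support for the breakpoint lying at the
    boundary just right of 1-based site i+1.
    """

    method: str
    sequences: tuple
    statistic: float
    point: float
    interval: tuple
    pvalue: float | None = None
    roles: dict | None = None
    profile: np.ndarray | None = field(default=None, repr=False)
    extra_intervals: list = field(default_factory=list)

    def breakpoint_candidates(self):
        """Midpoints of every reported breakpoint interval."""
        return [(lo + hi) / 2.0 for lo, hi in [self.interval] + self.extra_intervals]


@dataclass
class TripletWalk:
    """The +-1 informative-site walk underlying the triplet exact test."""

    child: int
    parent_p: int
    parent_q: int
    positions: np.ndarray  # 1-based positions of informative sites
    steps: np.ndarray  # +1 P-like, -1 Q-like
    m: int  # number of P-like sites
    n_q: int  # number of Q-like sites
    descent: int  # maximum descent
    segment: tuple  # primary breakpoint gap (left_site, right_site)
    gaps: tuple = ()  # interior uninformative gaps bounding the maximal descent


# ---------------------------------------------------------------------------
# MaxChi-style pairwise chi-square scan
# ---------------------------------------------------------------------------


def _chi2_curve(d: np.ndarray, min_margin: int = 0) -> np.ndarray:
    """Chi-square statistic at every interior boundary of a 0/1 difference vector.

    Boundary k (1..M-1) splits the region into sites [0,k) and [k,M); the
    2x2 table rows are left/right, columns are differing/matching counts.
    Returns an array of length M-1 (boundary k at index k-1).  With
    ``min_margin`` > 0, boundaries leaving fewer than that many differing
    sites on either side are zeroed out: near-degenerate tables produce
    spurious chi-square spikes that would otherwise dominate both the scan
    and its permutation null.
    """
    M = d.size
    D = int(d.sum())
    k = np.arange(1, M, dtype=float)
    a = np.cumsum(d)[:-1].astype(float)  # differing, left
    b = k - a  # matching, left
    c = D - a  # differing, right
    e = (M - k) - c  # matching, right
    num = M * (a * e - b * c) ** 2
    den = (a + b) * (c + e) * (a + c) * (b + e)
    out = np.zeros(M - 1)
    valid = den > 0
    if min_margin > 0:
        valid &= (a >= min_margin) & (c >= min_margin)
    np.divide(num, den, out=out, where=valid)
    return out


#: Minimum differing-site count required on each side of a candidate
#: boundary (guards the chi-square against near-degenerate margins).
MIN_MARGIN = 5


def _perm_max_chi2(d: np.ndarray, num_permutations: int, rng,
                   min_margin: int = MIN_MARGIN) -> np.ndarray:
    """Null distribution of the maximum chi-square under site-order permutation."""
    M = d.size
    D = int(d.sum())
    perms = np.broadcast_to(d, (num_permutations, M)).copy()
    perms = rng.permuted(perms, axis=1)
    k = np.arange(1, M, dtype=float)
    a = np.cumsum(perms, axis=1)[:, :-1].astype(float)
    b = k[None, :] - a
    c = D - a
    e = (M - k)[None, :] - c
    num = M * (a * e - b * c) ** 2
    den = (a + b) * (c + e) * (a + c) * (b + e)
    chi = np.zeros_like(num)
    valid = den > 0
    if min_margin > 0:
        valid &= (a >= min_margin) & (c >= min_margin)
    np.divide(num, den, out=chi, where=valid)
    return chi.max(axis=1)


def maxchi_scan(
    aln: Alignment,
    pair,
    num_permutations: int = 1000,
    alpha: float = 0.05,
    rng=None,
    min_region: int = 10,
):
    """Pairwise chi-square scan with permutation significance.

    On a significant detection the scan recurses into each flank until no
    further breakpoint is found.  An identical pair yields an empty result.
    """
    if num_permutations < 1:
        raise ValueError("num_permutations must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    i, j = pair
    if i == j:
        raise ValueError("pair must consist of two distinct sequences")
    d_full = (aln.matrix[i] != aln.matrix[j]).astype(np.int8)
    L = aln.length
    events = []

    def scan(lo, hi):
        if hi - lo < min_region:
            return
        d = d_full[lo:hi]
        D = int(d.sum())
        if D < 2 * MIN_MARGIN or D > d.size - 2:
            return
        # Significance uses the margin-guarded statistic (degenerate tables
        # spike under permutation as well as in the observed scan), while
        # the breakpoint estimate is the unrestricted argmax: the guard
        # would otherwise bias the estimate away from breakpoints close to
        # diff-sparse flanks.
        chi = _chi2_curve(d)
        chi_test = _chi2_curve(d, min_margin=MIN_MARGIN)
        obs = float(chi_test.max())
        if obs <= 0:
            return
        kidx = int(np.argmax(chi))
        # permutations in batches with early stopping: once the exceedance
        # count already guarantees p > alpha, further permutations cannot
        # change the detection decision
        k_stop = math.floor(alpha * (1.0 + num_permutations))
        exceed = 0
        done = 0
        batch = max(1, min(100, num_permutations))
        while done < num_permutations:
            nb = min(batch, num_permutations - done)
            null = _perm_max_chi2(d, nb, rng)
            exceed += int(np.sum(null >= obs))
            done += nb
            if exceed > k_stop:
                break
        p = (1.0 + exceed) / (1.0 + done)
        if p > alpha:
            return
        b = lo + kidx + 1  # boundary in full coordinates
        profile = np.zeros(L)
        profile[lo:hi - 1][chi > 0] = chi[chi > 0]
        profile /= profile.sum()
        events.append(
            DetectedEvent(
                method="maxchi",
                sequences=(i, j),
                statistic=float(obs),
                point=float(b),
                interval=(b, b),
                pvalue=float(p),
                profile=profile,
            )
        )
        scan(lo, b)
        scan(b, hi)

    scan(0, L)
    return events


# ---------------------------------------------------------------------------
# 3SEQ-style triplet exact test
# ---------------------------------------------------------------------------


def informative_labels(seq_c, seq_p, seq_q):
    """Positions and parental labels of triplet-informative sites.

    A site is informative iff the child matches exactly one of the two
    parents.  Returns (positions, steps) with 1-based positions and steps
    +1 for P-like, -1 for Q-like sites.
    """
    seq_c = np.asarray(seq_c)
    p_like = (seq_c == seq_p) & (seq_c != seq_q)
    q_like = (seq_c == seq_q) & (seq_c != seq_p)
    idx = np.nonzero(p_like | q_like)[0]
    steps = np.where(p_like[idx], 1, -1).astype(np.int64)
    return idx + 1, steps


def max_descent(steps: np.ndarray):
    """Maximum descent of a +-1 walk.

    Returns (descent, peak_index, trough_index): the largest drop between a
    running maximum and a subsequent minimum, the index of the last step at
    which that running maximum is attained (-1 if the descent starts from
    the walk origin) and the index of the step reaching the minimum.
    """
    if steps.size == 0:
        return 0, -1, -1
    s = np.cumsum(steps)
    runmax = np.maximum.accumulate(np.concatenate(([0], s)))[1:]
    dd = runmax - s
    t_star = int(np.argmax(dd))
    descent = int(dd[t_star])
    if descent == 0:
        return 0, -1, -1
    target = runmax[t_star]
    peak = -1
    for jj in range(t_star, -1, -1):
        if s[jj] == target:
            peak = jj
            break
    return descent, peak, t_star


def max_descent_pvalue(m: int, n: int, k: int) -> float:
    """Exact P(maximum descent >= k) for a walk with m up- and n down-steps.

    Under the null, all C(m+n, n) orderings of the steps are equally likely
    (the hypergeometric random walk).  Computed by dynamic programming over
    the walk's drawdown (running maximum minus current value), propagating
    probability mass so no large combinatorial counts arise.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if k == 1:
        return 1.0 if n >= 1 else 0.0
    total = m + n
    C = np.zeros((m + 1, k))
    C[0, 0] = 1.0
    u = np.arange(m + 1, dtype=float)
    for s in range(total):
        rem = float(total - s)
        pu = np.clip((m - u) / rem, 0.0, 1.0)
        pd = np.clip((n - (s - u)) / rem, 0.0, 1.0)
        up = C * pu[:, None]
        down = C * pd[:, None]
        new = np.zeros_like(C)
        # up-step: drawdown decreases toward 0
        new[1:, 0] += up[:-1, 0] + up[:-1, 1]
        if k > 2:
            new[1:, 1:k - 1] += up[:-1, 2:k]
        # down-step: drawdown increases; mass reaching k is absorbed (lost)
        new[:, 1:] += down[:, :-1]
        C = new
    return float(min(1.0, max(0.0, 1.0 - C.sum())))


def _mc_descent_pvalue(m: int, n: int, k: int, rng, reps: int = 200) -> float:
    """Monte-Carlo estimate of P(max descent >= k) under random step orderings."""
    steps = np.concatenate([np.ones(m, dtype=np.int8), -np.ones(n, dtype=np.int8)])
    perms = rng.permuted(np.broadcast_to(steps, (reps, m + n)).copy(), axis=1)
    s = np.cumsum(perms, axis=1)
    runmax = np.maximum(np.maximum.accumulate(s, axis=1), 0)
    dd = (runmax - s).max(axis=1)
    return float((1 + np.sum(dd >= k)) / (1 + reps))


def _descent_pvalue(m: int, n: int, k: int, rng=None, screen_at: float = 0.05) -> float:
    """P(max descent >= k), exact whenever the p-value could be small.

    For long walks a cheap Monte-Carlo screen estimates the p-value first;
    only when the estimate falls below ``screen_at`` (i.e. the test could
    conceivably survive multiple-testing correction) is the exact dynamic
    program run.  Clearly null walks keep the Monte-Carlo estimate, which
    is never used for a detection decision.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if rng is None or m + n < 60:
        return max_descent_pvalue(m, n, k)
    p_mc = _mc_descent_pvalue(m, n, k, rng)
    if p_mc >= screen_at:
        return p_mc
    return max_descent_pvalue(m, n, k)


def _walk_changepoint(steps: np.ndarray) -> int:
    """Maximum-likelihood two-rate changepoint index of a +-1 step sequence.

    Splits the steps into a prefix and suffix with independent Bernoulli
    up-step rates and returns the split index j (1..T-1) maximizing the
    profile log-likelihood.  For a clean P-then-Q mosaic this is exactly
    the peak of the hypergeometric walk; when the walk drifts, it is far
    more stable than the descent's extreme points.
    """
    x = (steps == 1).astype(float)
    T = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    j = np.arange(1, T)
    k1 = cs[1:-1]
    k2 = cs[-1] - k1
    n1 = j.astype(float)
    n2 = T - n1

    def bll(k, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = k / n
            t1 = np.where(k > 0, k * np.log(p1), 0.0)
            t2 = np.where(n - k > 0, (n - k) * np.log(1 - p1), 0.0)
        return t1 + t2

    return int(np.argmax(bll(k1, n1) + bll(k2, n2))) + 1


def _directional_walk(aln, child, p, q):
    pos, steps = informative_labels(aln.matrix[child], aln.matrix[p], aln.matrix[q])
    m = int(np.sum(steps == 1))
    n_q = int(np.sum(steps == -1))
    descent, peak, trough = max_descent(steps)
    # The maximal descent detects the recombinant (Q-derived) segment; the
    # reported breakpoint is the uninformative gap at the walk's
    # maximum-likelihood two-rate changepoint, which coincides with the gap
    # bounding the maximal descent for clean mosaics but does not chase
    # drifting descent extremes.
    if descent > 0 and steps.size >= 2:
        j = _walk_changepoint(steps)
        gaps = [(int(pos[j - 1]), int(pos[j]))]
    else:
        gaps = []
    primary = gaps[0] if gaps else (0, aln.length)
    return TripletWalk(child, p, q, pos, steps, m, n_q, descent, primary, tuple(gaps))


def threeseq_test(aln: Alignment, child: int, parent_p: int, parent_q: int, rng=None):
    """Triplet exact test for a candidate recombinant child.

    Both parental orderings are examined (a descent under (P,Q) is an
    ascent under (Q,P)); the better direction's exact p-value is adjusted
    for the two dependent looks (Sidak).  Returns a :class:`DetectedEvent`
    with the uncorrected per-triplet p-value, or ``None`` when fewer than
    two informative sites exist.  ``rng`` enables the Monte-Carlo screen
    that skips the exact dynamic program for clearly null walks.
    """
    w1 = _directional_walk(aln, child, parent_p, parent_q)
    if w1.m + w1.n_q < 2:
        return None
    w2 = _directional_walk(aln, child, parent_q, parent_p)
    p1 = _descent_pvalue(w1.m, w1.n_q, w1.descent, rng)
    p2 = _descent_pvalue(w2.m, w2.n_q, w2.descent, rng)
    w, p_raw = (w1, p1) if (p1, -w1.descent) <= (p2, -w2.descent) else (w2, p2)
    pval = 1.0 - (1.0 - p_raw) ** 2
    gaps = list(w.gaps) if w.gaps else [(0, aln.length)]
    lo, hi = gaps[0]
    profile = np.zeros(aln.length)
    for (a, b) in gaps:
        profile[a:b] = 1.0  # uniform within each bounding gap (sites a+1..b)
    if profile.sum() == 0:
        profile[:] = 1.0
    profile /= profile.sum()
    return DetectedEvent(
        method="threeseq",
        sequences=(child, w.parent_p, w.parent_q),
        statistic=float(w.descent),
        point=(lo + hi) / 2.0,
        interval=(lo, hi),
        pvalue=float(pval),
        roles={"child": child, "p": w.parent_p, "q": w.parent_q},
        profile=profile,
        extra_intervals=gaps[1:],
    )


# ---------------------------------------------------------------------------
# GARD-like AICc phylogenetic incongruence scan
# ---------------------------------------------------------------------------


def jc_distance(p_hat):
    """Jukes-Cantor corrected distance from an observed difference proportion."""
    p = np.minimum(np.asarray(p_hat, dtype=float), 0.74999)
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    aic = 2.0 * n_params - 2.0 * loglik
    denom = n_obs - n_params - 1
    if denom <= 0:
        return math.inf
    return aic + 2.0 * n_params * (n_params + 1) / denom


def neighbor_joining(dist: np.ndarray):
    """Neighbor joining on a distance matrix.

    Returns (edges, n_nodes): edges are (u, v, length) with leaves 0..n-1
    and internal nodes numbered upward; negative branch-length estimates
    are clamped to zero.  For n == 3 the unique unrooted topology with
    closed-form branch lengths is returned.
    """
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need >= 2 taxa")
    if n == 2:
        return [(0, 1, max(d[0, 1], 0.0))], 2
    active = list(range(n))
    dm = {(i, j): d[i, j] for i in range(n) for j in range(n) if i != j}
    edges = []
    nxt = n
    while len(active) > 3:
        na = len(active)
        r = {i: sum(dm[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ii in range(na):
            for jj in range(ii + 1, na):
                a, b = active[ii], active[jj]
                q = (na - 2) * dm[(a, b)] - r[a] - r[b]
                if best is None or q < best[0]:
                    best = (q, a, b)
        _, a, b = best
        va = 0.5 * dm[(a, b)] + (r[a] - r[b]) / (2.0 * (na - 2))
        vb = dm[(a, b)] - va
        edges.append((a, nxt, max(va, 0.0)))
        edges.append((b, nxt, max(vb, 0.0)))
        for c in active:
            if c in (a, b):
                continue
            nd = 0.5 * (dm[(a, c)] + dm[(b, c)] - dm[(a, b)])
            dm[(nxt, c)] = dm[(c, nxt)] = max(nd, 0.0)
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    a, b, c = active
    va = 0.5 * (dm[(a, b)] + dm[(a, c)] - dm[(b, c)])
    vb = 0.5 * (dm[(a, b)] + dm[(b, c)] - dm[(a, c)])
    vc = 0.5 * (dm[(a, c)] + dm[(b, c)] - dm[(a, b)])
    edges.append((a, nxt, max(va, 0.0)))
    edges.append((b, nxt, max(vb, 0.0)))
    edges.append((c, nxt, max(vc, 0.0)))
    return edges, nxt + 1


def _jc_pmatrix(t: float) -> np.ndarray:
    e = math.exp(-4.0 / 3.0 * max(t, 0.0))
    return np.full((4, 4), 0.25 * (1 - e)) + e * np.eye(4)


def segment_loglik(edges, n_nodes, patterns, counts, n_leaves):
    """Felsenstein-pruning log-likelihood of site patterns on an unrooted tree.

    ``patterns`` is an (n_patterns, n_leaves) base-index matrix with
    ``counts`` per pattern; the substitution model is single-rate JC with
    equal equilibrium frequencies.
    """
    adj = {}
    for u, v, t in edges:
        adj.setdefault(u, []).append((v, t))
        adj.setdefault(v, []).append((u, t))
    root = n_nodes - 1
    npat = patterns.shape[0]

    partial = {}
    stack = [(root, -1, False)]
    order = []
    while stack:
        u, par, done = stack.pop()
        if done:
            order.append((u, par))
            continue
        stack.append((u, par, True))
        for v, t in adj[u]:
            if v != par:
                stack.append((v, u, False))
    for u, par in order:
        if u < n_leaves:
            pl = np.zeros((npat, 4))
            pl[np.arange(npat), patterns[:, u]] = 1.0
        else:
            pl = np.ones((npat, 4))
            for v, t in adj[u]:
                if v == par:
                    continue
                pl = pl * (partial[v] @ _jc_pmatrix(t))
        partial[u] = pl
    if root < n_leaves:  # degenerate 2-taxon tree rooted at a leaf
        (v, t), = [e for e in adj[root] if e[0] != root]
        like = 0.25 * (partial[v] @ _jc_pmatrix(t))[np.arange(npat), patterns[:, root]]
    else:
        like = 0.25 * partial[root].sum(axis=1)
    like = np.maximum(like, 1e-300)
    return float(np.dot(counts, np.log(like)))


class _AlnPatterns:
    """Cached site-pattern codes and cumulative pairwise differences."""

    def __init__(self, aln: Alignment):
        m = aln.matrix.astype(np.int64)
        n, L = m.shape
        self.n = n
        self.L = L
        pow4 = 4 ** np.arange(n, dtype=np.int64)
        self.codes = (m.T @ pow4)  # length L
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        self.pairs = pairs
        diffs = np.stack([(m[i] != m[j]) for i, j in pairs], axis=1).astype(np.int64)
        self.cum = np.vstack([np.zeros((1, len(pairs)), dtype=np.int64),
                              np.cumsum(diffs, axis=0)])

    def dist_matrix(self, a, b):
        """JC-corrected distance matrix for segment [a, b)."""
        p_hat = (self.cum[b] - self.cum[a]) / float(b - a)
        d = np.zeros((self.n, self.n))
        for (i, j), ph in zip(self.pairs, p_hat):
            d[i, j] = d[j, i] = jc_distance(ph)
        return d

    def patterns(self, a, b):
        codes, counts = np.unique(self.codes[a:b], return_counts=True)
        pat = np.empty((codes.size, self.n), dtype=np.int64)
        c = codes.copy()
        for i in range(self.n):
            pat[:, i] = c % 4
            c //= 4
        return pat, counts.astype(float)


def _segment_tree_loglik(ap: _AlnPatterns, a: int, b: int) -> float:
    dm = ap.dist_matrix(a, b)
    edges, n_nodes = neighbor_joining(dm)
    pat, cnt = ap.patterns(a, b)
    return segment_loglik(edges, n_nodes, pat, cnt, ap.n)


def _gard_triplet_scan(aln: Alignment, ks: np.ndarray):
    """Vectorized flank log-likelihoods over candidate boundaries for n == 3."""
    m = aln.matrix.astype(np.int64)
    L = aln.length
    codes = m[0] + 4 * m[1] + 16 * m[2]
    onehot = np.zeros((L, 64))
    onehot[np.arange(L), codes] = 1.0
    pc = np.vstack([np.zeros(64), np.cumsum(onehot, axis=0)])
    pat = np.empty((64, 3), dtype=np.int64)
    c = np.arange(64)
    for i in range(3):
        pat[:, i] = c % 4
        c = c // 4
    pairs = [(0, 1), (0, 2), (1, 2)]
    dmat = np.stack([(m[i] != m[j]).astype(float) for i, j in pairs], axis=1)
    cumd = np.vstack([np.zeros(3), np.cumsum(dmat, axis=0)])

    def flank_loglik(starts, ends):
        width = (ends - starts).astype(float)
        safe = np.maximum(width, 1.0)
        p_hat = (cumd[ends] - cumd[starts]) / safe[:, None]
        d = jc_distance(p_hat)  # (K, 3): d01, d02, d12
        v0 = np.maximum(0.5 * (d[:, 0] + d[:, 1] - d[:, 2]), 0.0)
        v1 = np.maximum(0.5 * (d[:, 0] + d[:, 2] - d[:, 1]), 0.0)
        v2 = np.maximum(0.5 * (d[:, 1] + d[:, 2] - d[:, 0]), 0.0)
        es = np.exp(-4.0 / 3.0 * np.stack([v0, v1, v2], axis=1))  # (K, 3)
        prob = np.full((starts.size, 4, 64), 0.25)
        for i in range(3):
            delta = (np.arange(4)[:, None] == pat[None, :, i]).astype(float)
            e = es[:, i][:, None, None]
            prob = prob * (0.25 * (1 - e) + e * delta[None])
        patprob = prob.sum(axis=1)  # (K, 64), includes the 1/4 root prior
        counts = pc[ends] - pc[starts]
        return np.einsum("kp,kp->k", counts, np.log(np.maximum(patprob, 1e-300)))

    left = flank_loglik(np.zeros_like(ks), ks)
    right = flank_loglik(ks, np.full_like(ks, L))
    return left, right


def gardlike_scan(
    aln: Alignment,
    max_breakpoints: int = 1,
    min_segment: int = 20,
    stride: int = 1,
):
    """AICc phylogenetic-incongruence scan.

    Single-breakpoint mode compares, at every candidate boundary on the
    stride grid, the two-NJ-tree model against the single-tree model for
    the whole alignment; multi-breakpoint mode adds breakpoints greedily
    while the AICc improves.  Returns a list of detected events (empty when
    the one-tree model is preferred everywhere).
    """
    n = aln.n
    L = aln.length
    if n < 3:
        raise ValueError("gardlike_scan requires >= 3 sequences")
    if min_segment < n:
        raise ValueError("min_segment must be >= the number of sequences")
    p_per_tree = 2 * n - 3
    ap = _AlnPatterns(aln) if n > 3 else None

    def seg_ll(a, b):
        if n == 3:
            sub = Alignment(aln.ids, aln.matrix[:, a:b])
            ll, _ = _gard_triplet_scan(sub, np.array([b - a], dtype=np.int64))
            return float(ll[0])
        return _segment_tree_loglik(ap, a, b)

    events = []
    segments = [(0, L)]
    seg_lls = {(0, L): seg_ll(0, L)}
    cur_aicc = aicc(seg_lls[(0, L)], p_per_tree, L)

    for _ in range(max_breakpoints):
        best = None
        all_ks = []
        all_aiccs = []
        n_segs = len(segments)
        base_ll = sum(seg_lls[s] for s in segments)
        new_p = (n_segs + 1) * p_per_tree
        for (a, b) in segments:
            ks = np.arange(a + min_segment, b - min_segment + 1, stride, dtype=np.int64)
            if ks.size == 0:
                continue
            if n == 3:
                sub = Alignment(aln.ids, aln.matrix[:, a:b])
                ll_l, ll_r = _gard_triplet_scan(sub, ks - a)
            else:
                ll_l = np.array([_segment_tree_loglik(ap, a, k) for k in ks])
                ll_r = np.array([_segment_tree_loglik(ap, k, b) for k in ks])
            tot_ll = base_ll - seg_lls[(a, b)] + ll_l + ll_r
            cand_aicc = np.array([aicc(ll, new_p, L) for ll in tot_ll])
            all_ks.append(ks)
            all_aiccs.append(cand_aicc)
            kidx = int(np.argmin(cand_aicc))
            if best is None or cand_aicc[kidx] < best[0]:
                best = (float(cand_aicc[kidx]), int(ks[kidx]), (a, b),
                        float(ll_l[kidx]), float(ll_r[kidx]))
        if best is None or best[0] >= cur_aicc:
            break
        new_aicc, k, (a, b), ll_l, ll_r = best
        ks_all = np.concatenate(all_ks)
        aiccs_all = np.concatenate(all_aiccs)
        w = np.exp(-(aiccs_all - aiccs_all.min()) / 2.0)
        profile = np.zeros(L)
        profile[ks_all - 1] = w
        profile /= profile.sum()
        events.append(
            DetectedEvent(
                method="gardlike",
                sequences=tuple(range(n)),
                statistic=float(cur_aicc - new_aicc),
                point=float(k),
                interval=(k, k),
                profile=profile,
            )
        )
        segments.remove((a, b))
        segments.extend([(a, k), (k, b)])
        segments.sort()
        seg_lls[(a, k)] = ll_l
        seg_lls[(k, b)] = ll_r
        cur_aicc = new_aicc
    return events


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_all_detectors(
    aln: Alignment,
    alpha: float = 0.05,
    num_permutations: int = 1000,
    max_breakpoints: int = 1,
    gard_stride: int = 1,
    gard_min_segment: int = 20,
    rng=None,
):
    """Run all three detectors truth-blind on an alignment.

    MaxChi is run on every sequence pair and the triplet test on every
    (triplet, child-role) assignment; both families are corrected for
    multiple testing across their tests by the Dunn-Sidak adjustment at
    level ``alpha``.  Returns ``{method: [DetectedEvent, ...]}``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = aln.n
    results = {"maxchi": [], "threeseq": [], "gardlike": []}

    pairs = list(itertools.combinations(range(n), 2))
    alpha_pair = 1.0 - (1.0 - alpha) ** (1.0 / len(pairs)) if pairs else alpha
    for pair in pairs:
        results["maxchi"].extend(
            maxchi_scan(aln, pair, num_permutations=num_permutations,
                        alpha=alpha_pair, rng=rng)
        )

    if n >= 3:
        tests = []
        for trip in itertools.combinations(range(n), 3):
            for child in trip:
                p, q = [x for x in trip if x != child]
                ev = threeseq_test(aln, child, p, q, rng=rng)
                if ev is not None:
                    tests.append(ev)
        n_tests = 3 * math.comb(n, 3)
        significant = []
        for ev in tests:
            corr = 1.0 - (1.0 - ev.pvalue) ** n_tests
            if corr <= alpha:
                ev.pvalue = corr
                significant.append(ev)
        # report one record per candidate recombinant child: the best
        # (lowest-p) parent pair, mirroring the triplet tool's per-child output
        best_by_child = {}
        for ev in significant:
            c = ev.roles["child"]
            cur = best_by_child.get(c)
            if cur is None or (ev.pvalue, -ev.statistic) < (cur.pvalue, -cur.statistic):
                best_by_child[c] = ev
        results["threeseq"] = [best_by_child[c] for c in sorted(best_by_child)]

        results["gardlike"] = gardlike_scan(
            aln, max_breakpoints=max_breakpoints,
            min_segment=gard_min_segment, stride=gard_stride,
        )
    return results
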