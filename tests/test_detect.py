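"""Tests for the three breakpoint detectors."""

import itertools
import math

import numpy as np
import pytest

from recbreak.detect import (
    DetectedEvent,
    aicc,
    gardlike_scan,
    informative_labels,
    max_descent,
    max_descent_pvalue,
    maxchi_scan,
    neighbor_joining,
    run_all_detectors,
    segment_loglik,
    threeseq_test,
    _chi2_curve,
)
from recbreak.simulate import Alignment, SimulationConfig, simulate_arg, simulate_sequences


def _aln(rows):
    return Alignment([f"s{i}" for i in range(len(rows))], np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# MaxChi
# ---------------------------------------------------------------------------


class TestMaxChi:
    def test_chi2_closed_form(self):
        # 6 differing sites then 6 matching: table [[6,0],[0,6]] at k=6 -> 12
        d = np.array([1] * 6 + [0] * 6)
        chi = _chi2_curve(d)
        assert chi[5] == pytest.approx(12.0)
        # closed form N(ad-bc)^2 / row/col products on a generic table
        a, b, c, e = 4, 2, 1, 5
        d2 = np.array([1] * a + [0] * b + [1] * c + [0] * e)
        N = a + b + c + e
        expect = N * (a * e - b * c) ** 2 / ((a + b) * (c + e) * (a + c) * (b + e))
        assert _chi2_curve(d2)[a + b - 1] == pytest.approx(expect)

    def test_identical_pair_empty(self):
        aln = _aln([[0, 1, 2, 3] * 25] * 2)
        assert maxchi_scan(aln, (0, 1), num_permutations=10, rng=1) == []

    def test_invalid_args(self):
        aln = _aln([[0] * 100, [1] * 100])
        with pytest.raises(ValueError):
            maxchi_scan(aln, (0, 0), rng=1)
        with pytest.raises(ValueError):
            maxchi_scan(aln, (0, 1), num_permutations=0, rng=1)

    def test_kmax_matches_bruteforce_argmax(self):
        """A block of mismatches on one flank puts kmax at the boundary the
        exhaustive scan oracle selects."""
        rng = np.random.default_rng(0)
        L = 400
        s0 = rng.integers(0, 4, L).astype(np.int8)
        s1 = s0.copy()
        s1[:40] = (s1[:40] + 1) % 4  # dense mismatches at sites 1..40
        noise = rng.choice(L, 25, replace=False)  # background differences
        s1[noise] = (s0[noise] + 1) % 4
        aln = _aln([s0, s1])
        d = (s0 != s1).astype(int)
        # brute-force oracle: recompute the 2x2 chi-square at every boundary
        best, bestk = -1.0, None
        D = d.sum()
        for k in range(1, L):
            a = d[:k].sum()
            b, c, e = k - a, D - a, (L - k) - (D - a)
            den = (a + b) * (c + e) * (a + c) * (b + e)
            chi = L * (a * e - b * c) ** 2 / den if den else 0.0
            if chi > best:
                best, bestk = chi, k
        events = maxchi_scan(aln, (0, 1), num_permutations=200, rng=rng)
        assert events and events[0].point == bestk

    def test_statistic_invariances(self):
        """Chi-square curve is invariant to swapping the pair and reverses
        with the genome (kmax -> L - kmax)."""
        rng = np.random.default_rng(1)
        m = rng.integers(0, 4, (2, 200)).astype(np.int8)
        d = (m[0] != m[1]).astype(np.int8)
        chi = _chi2_curve(d)
        assert np.allclose(chi, _chi2_curve((m[1] != m[0]).astype(np.int8)))
        assert np.allclose(chi[::-1], _chi2_curve(d[::-1]))

    def test_recursion_finds_second_breakpoint(self):
        rng = np.random.default_rng(2)
        L = 600
        s0 = rng.integers(0, 4, L).astype(np.int8)
        s1 = s0.copy()
        s1[200:400] = (s1[200:400] + 1 + rng.integers(0, 3, 200)) % 4
        aln = _aln([s0, s1])
        events = maxchi_scan(aln, (0, 1), num_permutations=500, rng=rng)
        pts = sorted(e.point for e in events)
        assert len(pts) >= 2
        assert min(abs(p - 200) for p in pts) < 30
        assert min(abs(p - 400) for p in pts) < 30


# ---------------------------------------------------------------------------
# 3SEQ-style triplet test
# ---------------------------------------------------------------------------


def brute_force_descent_pvalue(m, n, k):
    """Enumerate all C(m+n, m) step orderings and count max descents >= k."""
    if k <= 0:
        return 1.0
    total = exceed = 0
    for ups in itertools.combinations(range(m + n), m):
        up = set(ups)
        s = runmax = dd = 0
        for i in range(m + n):
            s += 1 if i in up else -1
            runmax = max(runmax, s)
            dd = max(dd, runmax - s)
        total += 1
        exceed += dd >= k
    return exceed / total


class TestTripletTest:
    @pytest.mark.parametrize("m,n", [(0, 5), (5, 0), (3, 3), (5, 4), (2, 7), (6, 4)])
    def test_exact_pvalue_against_enumeration(self, m, n):
        for k in range(0, n + 2):
            assert max_descent_pvalue(m, n, k) == pytest.approx(
                brute_force_descent_pvalue(m, n, k), abs=1e-12
            )

    def test_pvalue_monotone_in_descent(self):
        ps = [max_descent_pvalue(10, 10, k) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_clean_mosaic_walk(self):
        """m P-like sites followed by n Q-like sites: descent = n, and the
        p-value equals the enumeration oracle."""
        steps = np.array([1] * 5 + [-1] * 4)
        descent, peak, trough = max_descent(steps)
        assert descent == 4 and peak == 4 and trough == 8
        assert max_descent_pvalue(5, 4, 4) == pytest.approx(
            brute_force_descent_pvalue(5, 4, 4)
        )

    def test_child_identical_to_parent_no_detection(self):
        rng = np.random.default_rng(3)
        p = rng.integers(0, 4, 300).astype(np.int8)
        q = (p + rng.integers(0, 2, 300)) % 4
        aln = _aln([p, p.copy(), q])  # child (row 0) identical to P (row 1)
        ev = threeseq_test(aln, 0, 1, 2)
        assert ev is None or ev.pvalue > 0.9

    def test_interval_midpoint(self):
        """A clean transition between informative sites at 200 and 300 gives
        the gap (200, 300] and point estimate 250."""
        L = 500
        p = np.zeros(L, dtype=np.int8)
        q = np.zeros(L, dtype=np.int8)
        c = np.zeros(L, dtype=np.int8)
        p_sites = [50, 100, 150, 200]
        q_sites = [300, 350, 400, 450]
        for s in p_sites + q_sites:
            q[s - 1] = 1 if s in p_sites else 0
            p[s - 1] = 0 if s in p_sites else 1
            c[s - 1] = p[s - 1] if s in p_sites else q[s - 1]
        # make child match P at P-sites, Q at Q-sites, parents differing there
        for s in p_sites:
            p[s - 1], q[s - 1], c[s - 1] = 1, 2, 1
        for s in q_sites:
            p[s - 1], q[s - 1], c[s - 1] = 1, 2, 2
        aln = _aln([c, p, q])
        ev = threeseq_test(aln, 0, 1, 2)
        assert ev.interval == (200, 300)
        assert ev.point == pytest.approx(250.0)

    def test_informative_labels_definition(self):
        c = np.array([0, 1, 2, 3, 0], dtype=np.int8)
        p = np.array([0, 1, 0, 3, 1], dtype=np.int8)
        q = np.array([0, 2, 2, 3, 2], dtype=np.int8)
        pos, steps = informative_labels(c, p, q)
        # site 1: all equal -> uninformative; site 4: C=P=Q -> uninformative
        assert list(pos) == [2, 3]
        assert list(steps) == [1, -1]


# ---------------------------------------------------------------------------
# GARD-like AICc scan
# ---------------------------------------------------------------------------


class TestGardlike:
    def test_identical_sequences_no_detection(self):
        aln = _aln([[0, 1, 2, 3] * 50] * 3)
        assert gardlike_scan(aln) == []

    def test_min_segment_validation(self):
        aln = _aln([[0, 1] * 50] * 4)
        with pytest.raises(ValueError):
            gardlike_scan(aln, min_segment=2)

    def test_aicc_closed_form(self):
        # AICc = AIC + 2p(p+1)/(N-p-1)
        ll, p, N = -123.4, 7, 500
        assert aicc(ll, p, N) == pytest.approx(2 * p - 2 * ll + 2 * p * (p + 1) / (N - p - 1))
        assert math.isinf(aicc(0.0, 10, 11))

    def test_two_block_boundary_matches_likelihood_oracle(self):
        """Two 4-taxon blocks with discordant topologies: the detected
        boundary maximizes the two-tree likelihood, verified against an
        independently coded exhaustive-scan oracle."""
        rng = np.random.default_rng(4)
        L = 400

        def block(topology, length):
            # evolve 4 taxa on a comb with a long internal branch
            anc = rng.integers(0, 4, length).astype(np.int8)

            def mut(seq, t):
                pc = 0.75 * (1 - math.exp(-4 / 3 * t))
                mask = rng.random(seq.size) < pc
                out = seq.copy()
                out[mask] = (out[mask] + rng.integers(1, 4, mask.sum())) % 4
                return out

            a = mut(anc, 0.05)
            b = mut(anc, 0.05)
            c1 = mut(mut(anc, 0.4), 0.05)
            d = mut(mut(anc, 0.4), 0.05)
            rows = {"a": a, "b": b, "c": c1, "d": d}
            return [rows[x] for x in topology]

        left = block("abcd", 200)   # (a,b) vs (c,d)
        right = block("acbd", 200)  # pairing swapped -> discordant topology
        m = np.hstack([np.array(left), np.array(right)])
        aln = _aln(list(m))
        events = gardlike_scan(aln, max_breakpoints=1, stride=1, min_segment=20)
        assert events, "discordant blocks must be detected"
        k_det = events[0].point

        # independent oracle: direct likelihood scan coded with explicit loops
        def jc_p(i, j, t):
            e = math.exp(-4 / 3 * t)
            return 0.25 + 0.75 * e if i == j else 0.25 * (1 - e)

        def oracle_ll(cols, edges, n_nodes):
            tot = 0.0
            for col in cols.T:
                # enumerate internal-node states (n_nodes - 4 internals)
                states = [None] * n_nodes
                for i in range(4):
                    states[i] = int(col[i])
                internals = list(range(4, n_nodes))
                s = 0.0
                for assign in itertools.product(range(4), repeat=len(internals)):
                    for node, st in zip(internals, assign):
                        states[node] = st
                    pr = 0.25  # root prior on the last internal node
                    for (u, v, t) in edges:
                        pr *= jc_p(states[u], states[v], t)
                    s += pr
                tot += math.log(max(s, 1e-300))
            return tot

        from recbreak.detect import _AlnPatterns, jc_distance

        ap = _AlnPatterns(aln)
        best, bestk = -np.inf, None
        for k in range(100, 301, 10):
            ll = 0.0
            for (a0, b0) in [(0, k), (k, L)]:
                dm = ap.dist_matrix(a0, b0)
                edges, n_nodes = neighbor_joining(dm)
                ll += oracle_ll(aln.matrix[:, a0:b0], edges, n_nodes)
            if ll > best:
                best, bestk = ll, k
        assert abs(k_det - bestk) <= 10
        assert abs(k_det - 200) <= 40  # boundary near the true block edge

    def test_pruning_likelihood_matches_enumeration(self):
        """Felsenstein pruning equals brute-force summation over internal
        states on a small 4-taxon tree."""
        rng = np.random.default_rng(5)
        pat = rng.integers(0, 4, (6, 4))
        cnt = np.ones(6)
        edges = [(0, 4, 0.1), (1, 4, 0.2), (2, 5, 0.15), (3, 5, 0.05), (4, 5, 0.3)]

        def jc_p(i, j, t):
            e = math.exp(-4 / 3 * t)
            return 0.25 + 0.75 * e if i == j else 0.25 * (1 - e)

        expect = 0.0
        for row in pat:
            s = 0.0
            for x4 in range(4):
                for x5 in range(4):
                    pr = 0.25
                    st = [*row, x4, x5]
                    for (u, v, t) in edges:
                        pr *= jc_p(st[u], st[v], t)
                    s += pr
            expect += math.log(s)
        got = segment_loglik(edges, 6, pat, cnt, 4)
        assert got == pytest.approx(expect, rel=1e-10)


# ---------------------------------------------------------------------------
# Neighbor joining and the driver
# ---------------------------------------------------------------------------


def test_neighbor_joining_matches_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    rng = np.random.default_rng(6)
    n = 7
    pts = rng.normal(size=(n, 4))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    ids = [f"s{i}" for i in range(n)]
    sk_tree = nj(DistanceMatrix(d, ids))
    # compare unrooted topologies via split sets
    sk_splits = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(int(t.name[1:]) for t in node.tips())
        if 0 in side:
            side = frozenset(range(n)) - side
        if 2 <= len(side) <= n - 2:
            sk_splits.add(side)
    edges, n_nodes = neighbor_joining(d)
    adj = {}
    for u, v, t in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    my_splits = set()
    for u in adj:
        for v in adj[u]:
            if u < v and len(adj[u]) > 1 and len(adj[v]) > 1:
                side, stack = set(), [(u, v)]
                while stack:
                    x, par = stack.pop()
                    if x < n:
                        side.add(x)
                    stack.extend((y, x) for y in adj[x] if y != par)
                side = frozenset(side)
                if 0 in side:
                    side = frozenset(range(n)) - side
                if 2 <= len(side) <= n - 2:
                    my_splits.add(side)
    assert my_splits == sk_splits


class TestDriver:
    def test_monomorphic_alignment_all_empty(self):
        aln = _aln([[2] * 120] * 3)
        res = run_all_detectors(aln, rng=0)
        assert all(len(v) == 0 for v in res.values())

    def test_profiles_are_distributions(self, triplet_type3):
        _, aln = triplet_type3
        res = run_all_detectors(aln, rng=0)
        found = 0
        for events in res.values():
            for ev in events:
                assert ev.profile.min() >= 0
                assert ev.profile.sum() == pytest.approx(1.0, abs=1e-9)
                assert ev.interval[0] <= ev.point <= ev.interval[1]
                found += 1
        assert found > 0

    def test_type3_triplets_detected_by_majority(self):
        """Central Type III triplets at moderate diversity are detected by
        each detector family in a majority of replicates."""
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(
            sample_size=3, recomb_rate=1e-3, diversity=0.15,
            min_events=1, max_events=1, child_is_sample=True,
        )
        hits = {"maxchi": 0, "threeseq": 0, "gardlike": 0}
        n = 0
        while n < 12:
            arg = simulate_arg(cfg, rng)
            if arg.events[0].event_type != "III":
                continue
            if not 300 <= arg.events[0].breakpoint <= 700:
                continue
            aln = simulate_sequences(arg, rng=rng)
            res = run_all_detectors(aln, rng=rng)
            for m in hits:
                hits[m] += bool(res[m])
            n += 1
        for m, h in hits.items():
            assert h > n / 2, f"{m} detected only {h}/{n}"
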