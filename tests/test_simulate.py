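"""Unit and property tests for the coalescent-with-recombination simulator."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy import stats

from recbreak.simulate import (
    RejectionCapExceeded,
    SimulationConfig,
    TYPE_I,
    TYPE_III,
    extract_sub_arg,
    simulate_arg,
    simulate_sequences,
    _simulate_raw,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(genome_length=1),
        dict(diversity=0.0),
        dict(recomb_rate=-1e-4),
        dict(sample_size=1),
        dict(min_events=-1),
        dict(min_events=3, max_events=2),
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_no_recombination_gives_single_tree():
    rng = np.random.default_rng(0)
    arg = simulate_arg(SimulationConfig(sample_size=3, recomb_rate=0.0, diversity=0.05), rng)
    assert arg.num_events == 0
    assert len(arg.local_trees) == 1
    assert arg.local_trees[0].start == 0 and arg.local_trees[0].end == 1000


def test_infeasible_constraint_raises():
    cfg = SimulationConfig(
        sample_size=3, recomb_rate=0.0, diversity=0.05,
        min_events=1, rejection_cap=50,
    )
    with pytest.raises(RejectionCapExceeded):
        simulate_arg(cfg, np.random.default_rng(0))


def test_single_event_structure_and_tiling():
    """Conditioned single-event ARGs: 2 local trees, 1 interior breakpoint,
    intervals tiling [0, L], each tree with n labeled tips."""
    rng = np.random.default_rng(1)
    cfg = SimulationConfig(
        sample_size=3, recomb_rate=1e-3, diversity=0.1,
        min_events=1, max_events=1,
    )
    for _ in range(20):
        arg = simulate_arg(cfg, rng)
        assert arg.num_events == 1
        b = arg.events[0].breakpoint
        assert 0 < b < 1000
        assert len(arg.local_trees) == 2
        assert [t.start for t in arg.local_trees] == [0, b]
        assert [t.end for t in arg.local_trees] == [b, 1000]
        for t in arg.local_trees:
            assert t.clade_map()[t.root] == frozenset(range(3))
        assert arg.events[0].event_type in {"I", "II", "III"}


def test_multi_event_intervals_tile_and_match_breakpoints():
    rng = np.random.default_rng(2)
    cfg = SimulationConfig(
        sample_size=10, recomb_rate=2e-3, diversity=0.2,
        min_events=2, max_events=10,
    )
    arg = simulate_arg(cfg, rng)
    bounds = [arg.local_trees[0].start] + [t.end for t in arg.local_trees]
    assert bounds[0] == 0 and bounds[-1] == 1000
    interior = bounds[1:-1]
    assert interior == sorted(set(e.breakpoint for e in arg.events))
    for a, b in zip(arg.local_trees[:-1], arg.local_trees[1:]):
        assert a.end == b.start


def test_event_count_matches_coalescent_expectation():
    """Unconditioned mean event count at small r*L approaches the closed-form
    coalescent expectation r * L * E[total tree length] (= 3 for n = 3)."""
    rng = np.random.default_rng(3)
    r = 3e-5
    cfg = SimulationConfig(sample_size=3, recomb_rate=r, diversity=0.05)
    counts = [len(_simulate_raw(cfg, rng)[0]) for _ in range(8000)]
    expected = r * 1000 * 3.0  # 2 * (1 + 1/2) = 3 for n = 3
    m = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    # small negative bias from span shrinkage after events is O((rL)^2)
    assert abs(m - expected) < 4 * se + 0.1 * expected


def test_type_classification_matches_tree_comparison():
    """Type I: flanking local trees identical; Type II: same rooted topology
    with different branch lengths; Type III: rooted topology changes."""
    rng = np.random.default_rng(4)
    cfg = SimulationConfig(
        sample_size=3, recomb_rate=1e-3, diversity=0.1,
        min_events=1, max_events=1,
    )
    seen = set()
    for _ in range(60):
        arg = simulate_arg(cfg, rng)
        ev = arg.events[0]
        left, right = arg.local_trees
        full = (0, 1, 2)
        same_tree = left.restricted_canonical(full) == right.restricted_canonical(full)
        topo_l = frozenset(cl for cl in left.clade_map().values() if 1 < len(cl) < 3)
        topo_r = frozenset(cl for cl in right.clade_map().values() if 1 < len(cl) < 3)
        seen.add(ev.event_type)
        if ev.event_type == "I":
            assert same_tree
        elif ev.event_type == "II":
            assert topo_l == topo_r and not same_tree
        else:
            assert topo_l != topo_r
    assert seen == {"I", "II", "III"}


def test_breakpoint_positions_roughly_uniform():
    """Single-event breakpoints are approximately uniform on (0, L)."""
    rng = np.random.default_rng(5)
    cfg = SimulationConfig(
        sample_size=3, recomb_rate=1e-3, diversity=0.1,
        min_events=1, max_events=1,
    )
    bps = [simulate_arg(cfg, rng).events[0].breakpoint for _ in range(300)]
    ks = stats.kstest(np.asarray(bps) / 1000.0, "uniform")
    assert ks.pvalue > 0.001


def test_rejection_conditioning_is_unbiased():
    """Post-hoc filtering of unconditioned runs to one event gives the same
    breakpoint distribution as rejection-conditioned simulation."""
    rng = np.random.default_rng(6)
    cfg_free = SimulationConfig(sample_size=3, recomb_rate=1e-3, diversity=0.1)
    cfg_cond = SimulationConfig(
        sample_size=3, recomb_rate=1e-3, diversity=0.1,
        min_events=1, max_events=1,
    )
    filtered = []
    while len(filtered) < 150:
        events, *_ = _simulate_raw(cfg_free, rng)
        if len(events) == 1:
            filtered.append(events[0].breakpoint)
    conditioned = [simulate_arg(cfg_cond, rng).events[0].breakpoint for _ in range(150)]
    ks = stats.ks_2samp(filtered, conditioned)
    assert ks.pvalue > 0.001


def test_sequences_mu_zero_identical():
    rng = np.random.default_rng(7)
    arg = simulate_arg(SimulationConfig(sample_size=3, recomb_rate=0.0, diversity=0.05), rng)
    aln = simulate_sequences(arg, mu=0.0, rng=rng)
    assert np.all(aln.matrix == aln.matrix[0])
    with pytest.raises(ValueError):
        simulate_sequences(arg, mu=-1.0, rng=rng)


def test_pairwise_difference_matches_closed_form():
    """For n = 2 the expected observed difference proportion under JC with
    Exp(1) pair coalescence time is pi / (1 + 4*pi/3)."""
    rng = np.random.default_rng(8)
    pi = 0.05
    cfg = SimulationConfig(sample_size=2, recomb_rate=0.0, diversity=pi)
    diffs = []
    for _ in range(1500):
        arg = simulate_arg(cfg, rng)
        aln = simulate_sequences(arg, rng=rng)
        diffs.append(np.mean(aln.matrix[0] != aln.matrix[1]))
    expected = pi / (1.0 + 4.0 * pi / 3.0)
    se = np.std(diffs) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs) - expected) < 4 * se


def test_observed_diversity_monotone_in_pi():
    rng = np.random.default_rng(9)
    means = []
    for pi in (0.01, 0.05, 0.2):
        cfg = SimulationConfig(sample_size=3, recomb_rate=0.0, diversity=pi)
        vals = []
        for _ in range(120):
            aln = simulate_sequences(simulate_arg(cfg, rng), rng=rng)
            vals.append(aln.pairwise_diversity())
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_mosaic_structure_at_breakpoint():
    """Sites left/right of the breakpoint evolve on the flanking local trees:
    with an extreme branch-length contrast the child-parent identity differs
    across the breakpoint (checked via the realized alignment mosaic)."""
    rng = np.random.default_rng(10)
    cfg = SimulationConfig(
        sample_size=3, recomb_rate=1e-3, diversity=0.2,
        min_events=1, max_events=1, child_is_sample=True,
    )
    found = 0
    for _ in range(60):
        arg = simulate_arg(cfg, rng)
        if arg.events[0].event_type != TYPE_III:
            continue
        b = arg.events[0].breakpoint
        if not 200 < b < 800:
            continue
        child = next(iter(arg.events[0].child_samples))
        others = [s for s in range(3) if s != child]
        left, right = arg.local_trees
        nn_l = min(others, key=lambda s: left.tmrca(child, s))
        nn_r = min(others, key=lambda s: right.tmrca(child, s))
        if nn_l == nn_r:
            continue
        aln = simulate_sequences(arg, rng=rng)
        m = aln.matrix

        def mismatch(a, bseq, sl):
            return np.mean(m[a, sl] != m[bseq, sl])

        # the child should be closer to its left-tree neighbor on the left
        # side and to its right-tree neighbor on the right side
        assert mismatch(child, nn_l, slice(0, b)) <= mismatch(child, nn_r, slice(0, b)) + 0.05
        assert mismatch(child, nn_r, slice(b, 1000)) <= mismatch(child, nn_l, slice(b, 1000)) + 0.05
        found += 1
        if found >= 5:
            break
    assert found >= 3


class TestSubArg:
    def test_full_subset_keeps_all_visible_structure(self, multi_arg_aln):
        arg, _ = multi_arg_aln
        sub = extract_sub_arg(arg, range(10))
        assert set(sub.breakpoints) <= set(arg.breakpoints)

    def test_invalid_subsets(self, multi_arg_aln):
        arg, _ = multi_arg_aln
        with pytest.raises(ValueError):
            extract_sub_arg(arg, [0])
        with pytest.raises(ValueError):
            extract_sub_arg(arg, [0, 99])

    def test_restriction_matches_dendropy_oracle(self):
        """Visible sub-ARG breakpoints equal the points where the pruned
        (dendropy) marginal trees' pairwise TMRCA matrices change."""
        rng = np.random.default_rng(11)
        cfg = SimulationConfig(
            sample_size=10, recomb_rate=2e-3, diversity=0.25,
            min_events=2, max_events=10,
        )
        tns = dendropy.TaxonNamespace([f"s{i}" for i in range(10)])
        for _ in range(3):
            arg = simulate_arg(cfg, rng)
            for subset in [(0, 1, 2), (3, 6, 9), (2, 7)]:
                mats = []
                for t in arg.local_trees:
                    dt = dendropy.Tree.get(
                        data=t.newick(), schema="newick", taxon_namespace=tns
                    )
                    pdm = dt.phylogenetic_distance_matrix()
                    tax = {int(x.label[1:]): x for x in dt.taxon_namespace}
                    mats.append(
                        tuple(
                            round(pdm.patristic_distance(tax[a], tax[b]) / 2, 6)
                            for a, b in itertools.combinations(subset, 2)
                        )
                    )
                oracle = [
                    arg.local_trees[i].end
                    for i in range(len(mats) - 1)
                    if mats[i] != mats[i + 1]
                ]
                assert extract_sub_arg(arg, subset).breakpoints == oracle
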