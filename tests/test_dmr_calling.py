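import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcseed.dmp_calling import (
    DIRECTION_DEMETHYLATED,
    DIRECTION_METHYLATED,
    binomial_lrt,
)
from mcseed.dmr_calling import (
    DEFAULT_WINDOW_LENGTHS,
    call_dmrs,
    cluster_dmps,
    optimize_window,
)
from mcseed.dmr_calling import test_cluster as region_test  # avoid pytest collection
from mcseed.errors import StateError

from conftest import chain_oracle, make_dmp, make_metadata, make_relmeth

M = DIRECTION_METHYLATED
D = DIRECTION_DEMETHYLATED


class TestClusterDmps:
    def test_singleton_excluded(self):
        assert cluster_dmps([make_dmp(100)], 400) == []

    def test_hand_executed_scan(self):
        # anchor at 100 (covers to 500), include 150, re-anchor (covers 550),
        # 700 outside -> cluster {100, 150}; 700 left as a dropped singleton
        dmps = [make_dmp(100), make_dmp(150), make_dmp(700)]
        clusters = cluster_dmps(dmps, 400)
        assert len(clusters) == 1
        assert [d.pos for d in clusters[0].members] == [100, 150]

    def test_chain_of_four(self):
        dmps = [make_dmp(p) for p in (0, 300, 600, 900)]
        clusters = cluster_dmps(dmps, 400)
        assert len(clusters) == 1
        assert [d.pos for d in clusters[0].members] == [0, 300, 600, 900]

    def test_opposite_direction_terminates(self):
        dmps = [
            make_dmp(0, M),
            make_dmp(100, M),
            make_dmp(200, D),
            make_dmp(300, D),
        ]
        clusters = cluster_dmps(dmps, 400)
        assert len(clusters) == 2
        assert clusters[0].direction == M
        assert [d.pos for d in clusters[0].members] == [0, 100]
        assert clusters[1].direction == D
        assert [d.pos for d in clusters[1].members] == [200, 300]

    def test_unsorted_rejected(self):
        with pytest.raises(StateError):
            cluster_dmps([make_dmp(500), make_dmp(100)], 400)

    def test_directions_uniform_within_cluster(self, rng):
        dmps = sorted(
            (
                make_dmp(int(p), M if rng.random() < 0.5 else D)
                for p in rng.choice(10_000, size=40, replace=False)
            ),
            key=lambda d: d.pos,
        )
        for c in cluster_dmps(dmps, 300):
            assert all(d.direction == c.direction for d in c.members)
            gaps = np.diff([d.pos for d in c.members])
            assert np.all(gaps <= 300)

    def test_spans_disjoint_per_direction(self, rng):
        dmps = sorted(
            (
                make_dmp(int(p), M if rng.random() < 0.5 else D)
                for p in rng.choice(20_000, size=60, replace=False)
            ),
            key=lambda d: d.pos,
        )
        clusters = cluster_dmps(dmps, 500)
        spans = sorted((c.start, c.end) for c in clusters)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    @settings(max_examples=200, deadline=None)
    @given(
        positions=st.lists(
            st.integers(min_value=0, max_value=5000), min_size=1, max_size=50,
            unique=True,
        ),
        directions=st.lists(st.booleans(), min_size=50, max_size=50),
        window=st.integers(min_value=1, max_value=1500),
    )
    def test_brute_force_oracle_property(self, positions, directions, window):
        dmps = [
            make_dmp(p, M if directions[i] else D)
            for i, p in enumerate(sorted(positions))
        ]
        got = cluster_dmps(dmps, window)
        expected = chain_oracle(dmps, window)
        assert [[d.pos for d in c.members] for c in got] == [
            [d.pos for d in run] for run in expected
        ]

    def test_window_monotonicity_same_direction(self, rng):
        positions = np.sort(rng.choice(50_000, size=40, replace=False))
        dmps = [make_dmp(int(p), M) for p in positions]
        prev_sizes = None
        for L in (100, 300, 600, 1200, 2400):
            clusters = cluster_dmps(dmps, L, min_cluster_size=1)
            sizes = sorted((c.start, c.size) for c in clusters)
            if prev_sizes is not None:
                # every previous chain is contained in some new chain
                assert len(clusters) <= prev_n
                assert max(s for _, s in sizes) >= max(s for _, s in prev_sizes)
            prev_sizes = sizes
            prev_n = len(clusters)


def relmeth_for_positions(positions, values):
    meta = make_metadata(3, 3)
    return make_relmeth(np.asarray(values), metadata=meta, positions=positions)


class TestTestCluster:
    def test_maximal_separation_significant(self):
        positions = [100, 200]
        r = relmeth_for_positions(positions, [[1, 1, 1, 0, 0, 0]] * 2)
        dmps = [make_dmp(p) for p in positions]
        [cluster] = cluster_dmps(dmps, 400)
        dmrs = call_dmrs(dmps, r, window_length=400)
        assert len(dmrs) == 1
        assert dmrs[0].direction == M
        assert dmrs[0].start == 100 and dmrs[0].end == 201
        assert dmrs[0].n_dmps == 2

    def test_statistic_matches_pooled_table(self, rng):
        # group means 0.55 vs 0.45 with within-group scatter
        vals = np.clip(
            0.5
            + np.array([[0.05] * 3 + [-0.05] * 3] * 2)
            + rng.normal(0, 0.2, size=(2, 6)),
            0,
            1,
        )
        positions = [100, 250]
        r = relmeth_for_positions(positions, vals)
        dmps = [make_dmp(p) for p in positions]
        [cluster] = cluster_dmps(dmps, 400)
        res = region_test(cluster, r)
        # independent pooled 2x2 computation
        num_c = np.rint(vals * 100)
        k1, k2 = num_c[:, :3].sum(), num_c[:, 3:].sum()
        stat, _ = binomial_lrt(
            np.array([k1]), np.array([600.0]), np.array([k2]), np.array([600.0])
        )
        np.testing.assert_allclose(res.statistic, stat[0])

    def test_null_clusters_type_i_error(self, rng):
        """500 synthetic null clusters: region q < 0.05 rate within 2 s.e."""
        n_clusters, per = 500, 3
        n_pos = n_clusters * per
        vals = np.clip(rng.normal(0.5, 0.15, size=(n_pos, 6)), 0, 1)
        # cluster anchors 10 kb apart, members 100 bp apart within a cluster
        base = np.arange(n_clusters)[:, None] * 10_000
        positions = (base + np.arange(per) * 100).ravel()
        r = relmeth_for_positions(positions, vals)
        pvals = []
        dmps = [make_dmp(int(p)) for p in positions]
        clusters = cluster_dmps(dmps, 400)
        assert len(clusters) == n_clusters
        for c in clusters:
            pvals.append(region_test(c, r).p_value)
        rate = np.mean(np.array(pvals) < 0.05)
        se = np.sqrt(0.05 * 0.95 / n_clusters)
        assert rate <= 0.05 + 2 * se

    def test_member_absent_raises(self):
        r = relmeth_for_positions([100], [[0.5] * 6])
        dmps = [make_dmp(100), make_dmp(200)]
        [cluster] = cluster_dmps(dmps, 400)
        from mcseed.errors import DataError

        with pytest.raises(DataError):
            region_test(cluster, r)


class TestOptimizeWindow:
    def test_equally_spaced_500(self):
        positions = [0, 500, 1000, 1500]
        r = relmeth_for_positions(positions, [[1, 1, 1, 0, 0, 0]] * 4)
        dmps = [make_dmp(p) for p in positions]
        scan = optimize_window(dmps, r, lengths=range(100, 2001, 100))
        assert scan.chosen_length == 500
        assert scan.counts[400] == 0
        assert scan.counts[500] == 1
        assert scan.counts[2000] == 1

    def test_tie_breaks_to_smallest(self):
        positions = [100, 150]
        r = relmeth_for_positions(positions, [[1, 1, 1, 0, 0, 0]] * 2)
        dmps = [make_dmp(p) for p in positions]
        scan = optimize_window(dmps, r, lengths=range(100, 2001, 100))
        assert scan.chosen_length == 100
        assert all(v == 1 for v in scan.counts.values())

    def test_brute_force_argmax(self, rng):
        n = 30
        positions = np.sort(rng.choice(40_000, size=n, replace=False))
        vals = np.tile([1.0, 1, 1, 0, 0, 0], (n, 1))
        r = relmeth_for_positions(positions, vals)
        dmps = [make_dmp(int(p)) for p in positions]
        grid = range(100, 2001, 100)
        scan = optimize_window(dmps, r, lengths=grid)
        brute = {
            L: len(call_dmrs(dmps, r, window_length=L)) for L in grid
        }
        assert scan.counts == brute
        best = max(brute.values())
        assert scan.chosen_length == min(L for L in grid if brute[L] == best)

    def test_empty_input_flagged(self):
        r = relmeth_for_positions([100], [[0.5] * 6])
        scan = optimize_window([], r, lengths=range(100, 501, 100))
        assert scan.empty_input
        assert scan.chosen_length == 100


class TestDefaults:
    def test_published_window_length_table(self):
        assert DEFAULT_WINDOW_LENGTHS["FVS"] == {
            "CG": 900, "CHG": 1000, "CHH": 700, "6mA": 400
        }
        assert DEFAULT_WINDOW_LENGTHS["AVS"] == {
            "CG": 1000, "CHG": 900, "CHH": 700, "6mA": 400
        }
        assert DEFAULT_WINDOW_LENGTHS["AVF"] == {
            "CG": 700, "CHG": 900, "CHH": 900, "6mA": 400
        }
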