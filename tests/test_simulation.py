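"""Scenario generator: surfaces, unusual-area selection, injected trends."""

import numpy as np
import pytest

from baystmix.graphs import build_adjacency, lattice_adjacency
from baystmix.model_core import common_linpred
from baystmix.simulation import (SCENARIO_TABLE, batch_simulate,
                                 default_expected_counts,
                                 generate_common_surface, make_unusual_trend,
                                 scenario_spec, select_unusual_areas,
                                 simulate_scenario)


class TestScenarioTable:
    def test_all_ten_defined(self):
        assert set(SCENARIO_TABLE) == {f"S{i}" for i in range(1, 11)}

    def test_long_series_scenario(self):
        assert scenario_spec("S7").T == 30

    def test_expected_scales(self):
        assert scenario_spec("S8").expected_scale == 2.0
        assert scenario_spec("S9").expected_scale == 0.5

    def test_null_scenario_injects_nothing(self):
        assert scenario_spec("S10").n_unusual_areas == 0

    def test_default_unusual_count(self):
        assert scenario_spec("S1").n_unusual_areas == 15

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            scenario_spec("S11")


class TestCommonSurface:
    def test_zero_trend_variance_degenerate(self, small_lattice, rng):
        p = generate_common_surface(small_lattice, 6,
                                    {"sigma2_gamma": 0.0}, rng)
        np.testing.assert_allclose(p.gamma, 0.0)

    def test_centering(self, small_lattice, rng):
        p = generate_common_surface(small_lattice, 8, None, rng)
        assert p.gamma.sum() == pytest.approx(0.0, abs=1e-10)
        assert p.v.sum() == pytest.approx(0.0, abs=1e-10)

    def test_rw1_increment_variance(self, rng):
        """Monte-Carlo moment check on the trend increments."""
        W = lattice_adjacency(2, 2)
        s2 = 0.05
        incs = []
        for _ in range(400):
            p = generate_common_surface(W, 10, {"sigma2_gamma": s2}, rng)
            incs.append(np.diff(p.gamma))
        var = np.var(np.concatenate(incs))
        assert var == pytest.approx(s2, rel=0.15)

    def test_spatial_variance_scales(self, rng):
        W = lattice_adjacency(6, 6)
        small = [generate_common_surface(W, 4, {"sigma2_v": 0.01}, rng).v.var()
                 for _ in range(50)]
        big = [generate_common_surface(W, 4, {"sigma2_v": 1.0}, rng).v.var()
               for _ in range(50)]
        assert np.mean(big) > 10 * np.mean(small)


class TestSelectUnusualAreas:
    def test_isolated_on_path5(self, rng):
        # {0, 2, 4} is the only independent set of size 3 on a path of 5
        A = build_adjacency(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        sel = select_unusual_areas(A, 3, "isolated", rng)
        np.testing.assert_array_equal(sel, [0, 2, 4])

    def test_isolated_pairwise_non_adjacent(self, rng):
        W = lattice_adjacency(8, 8)
        sel = select_unusual_areas(W, 10, "isolated", rng)
        edge_set = {tuple(e) for e in W.edges}
        for a in sel:
            for b in sel:
                if a < b:
                    assert (a, b) not in edge_set

    def test_clustered_connected_pockets(self, rng):
        import networkx as nx

        W = lattice_adjacency(8, 8)
        sel = select_unusual_areas(W, 15, "clustered", rng, cluster_size=5)
        assert sel.size == 15
        g = nx.Graph()
        g.add_nodes_from(sel.tolist())
        g.add_edges_from((int(a), int(b)) for a, b in W.edges
                         if a in set(sel) and b in set(sel))
        comps = list(nx.connected_components(g))
        assert len(comps) == 3
        assert sorted(len(c) for c in comps) == [5, 5, 5]

    def test_infeasible_pattern_raises(self, rng):
        A = build_adjacency(3, [(0, 1), (1, 2), (0, 2)])  # triangle
        with pytest.raises(ValueError):
            select_unusual_areas(A, 2, "isolated", rng, max_tries=20)

    def test_stratified_selection_covers_strata(self, rng):
        W = lattice_adjacency(9, 9)
        strata = np.repeat([0, 1, 2], 27)
        sel = select_unusual_areas(W, 9, "isolated", rng, strata=strata)
        counts = np.bincount(strata[sel], minlength=3)
        assert counts.min() >= 2


class TestUnusualTrends:
    def test_stable_window_constant(self, rng):
        dep, times = make_unusual_trend("consecutive_stable", 15, 0.4, rng)
        assert times.size == 5  # ceil(15/3)
        np.testing.assert_allclose(dep[times], 0.4)
        assert np.all(dep[np.setdiff1d(np.arange(15), times)] == 0.0)

    def test_isolated_spikes_non_adjacent(self, rng):
        for _ in range(50):
            dep, times = make_unusual_trend("isolated", 10, 0.5, rng)
            assert times.size == 2
            assert times[1] - times[0] > 1
            np.testing.assert_allclose(np.abs(dep[times]), 0.5)

    def test_variable_window_alternates_sign(self, rng):
        dep, times = make_unusual_trend("consecutive_variable", 15, 0.4, rng)
        signs = np.sign(dep[times])
        assert np.all(signs[:-1] * signs[1:] == -1)
        assert np.all(np.abs(dep[times]) >= 0.4 * 0.75 - 1e-12)
        assert np.all(np.abs(dep[times]) <= 0.4 * 1.25 + 1e-12)

    def test_zero_magnitude_keeps_truth_set(self, rng):
        dep, times = make_unusual_trend("consecutive_stable", 12, 0.0, rng)
        np.testing.assert_allclose(dep, 0.0)
        assert times.size == 4

    def test_too_short_series(self, rng):
        with pytest.raises(ValueError):
            make_unusual_trend("isolated", 3, 0.4, rng)


class TestSimulateScenario:
    def _setup(self, sid, seed=5, n_unusual=6):
        W = lattice_adjacency(6, 6)
        spec = scenario_spec(sid, seed=seed,
                             n_unusual_areas=0 if sid == "S10" else n_unusual)
        E = default_expected_counts(W.n, spec.T, 99)
        return spec, W, E

    def test_null_scenario_all_common(self):
        spec, W, E = self._setup("S10")
        sim = simulate_scenario(spec, W, E)
        assert np.all(sim.z_true == 1)
        assert sim.unusual_areas.size == 0

    def test_truth_bookkeeping(self):
        spec, W, E = self._setup("S3")
        sim = simulate_scenario(spec, W, E)
        n_zero = int(np.sum(sim.z_true == 0))
        expected = sum(len(v) for v in sim.unusual_times.values())
        assert n_zero == expected == 6 * 5  # 6 areas x ceil(15/3) times

    def test_expected_scaling(self):
        spec, W, E = self._setup("S8")
        sim = simulate_scenario(spec, W, E)
        np.testing.assert_allclose(sim.data.E, 2.0 * E)

    def test_counts_match_injected_risk_surface(self):
        """Law of large numbers: mean of Y/E - exp(log-risk) vanishes."""
        W = lattice_adjacency(5, 5)
        spec = scenario_spec("S6", seed=11, n_unusual_areas=5)
        spec = type(spec)(**{**spec.__dict__, "n_sims": 200})
        E = np.full((W.n, spec.T), 200.0)
        sims = batch_simulate(spec, W, E)
        resid = np.mean([(s.data.Y / s.data.E - np.exp(s.log_risk)).mean()
                         for s in sims])
        assert abs(resid) < 0.005
        # the injected surface is the common one plus the departures
        s = sims[0]
        recon = common_linpred(s.generator_params).copy()
        mismatch = (s.log_risk != recon)
        assert np.all(s.z_true[mismatch] == 0)

    def test_batch_determinism_and_variation(self):
        spec, W, E = self._setup("S1")
        spec2, _, _ = self._setup("S1")
        a = batch_simulate(type(spec)(**{**spec.__dict__, "n_sims": 3}), W, E)
        b = batch_simulate(type(spec2)(**{**spec2.__dict__, "n_sims": 3}), W, E)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data.Y, y.data.Y)
        assert not np.array_equal(a[0].data.Y, a[1].data.Y)

    def test_metadata_roundtrip(self):
        spec, W, E = self._setup("S2")
        sim = simulate_scenario(spec, W, E)
        assert sim.spec == spec
        assert set(sim.unusual_times) == set(int(i) for i in sim.unusual_areas)
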