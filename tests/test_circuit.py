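"""Spatial connectivity generator: distance laws, wiring rules, weights."""

import numpy as np
import pytest

from striatal_lsm.circuit import (
    EDGE_TYPES,
    Circuit,
    ScaleFactors,
    SynapseRanges,
    build_circuit,
    connect_fsi_msn,
    connect_msn_msn,
    draw_weights,
    place_neurons,
    torus_distance,
    wire_cortex,
)


class TestTorusDistance:
    def test_identical_points(self):
        assert torus_distance([0.3, 0.4], [0.3, 0.4]) == 0.0

    def test_wraparound(self):
        assert torus_distance([0.05, 0.5], [0.95, 0.5]) == pytest.approx(0.1)

    def test_no_wrap_diagonal(self):
        assert torus_distance([0.0, 0.0], [0.5, 0.5]) == pytest.approx(np.sqrt(0.5))

    def test_upper_bound(self, rng):
        p = rng.random((200, 2))
        q = rng.random((200, 2))
        assert np.all(torus_distance(p, q) <= np.sqrt(2) / 2 + 1e-12)


class TestPlacement:
    def test_counts_and_bounds(self, rng):
        msn, fsi = place_neurons(500, 50, 1.0, rng)
        assert msn.shape == (500, 2) and fsi.shape == (50, 2)
        assert np.all((msn >= 0) & (msn < 1.0))

    def test_uniform_moments(self):
        rng = np.random.default_rng(0)
        msn, _ = place_neurons(10_000, 1, 1.0, rng)
        se = np.sqrt(1 / 12 / 10_000)
        assert abs(msn.mean() - 0.5) < 3 * se

    def test_seed_reproducibility(self):
        a = place_neurons(100, 10, 1.0, np.random.default_rng(5))
        b = place_neurons(100, 10, 1.0, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestFsiMsnConnectivity:
    @pytest.fixture(scope="class")
    def positions(self):
        rng = np.random.default_rng(2)
        return place_neurons(500, 50, 1.0, rng)

    def test_p_zero_no_edges(self, positions, rng):
        msn, fsi = positions
        assert len(connect_fsi_msn(fsi, msn, 1.0, rng, p=0.0)) == 0

    def test_p_one_all_in_radius(self, positions, rng):
        msn, fsi = positions
        edges = connect_fsi_msn(fsi, msn, 1.0, rng, p=1.0)
        d = torus_distance(fsi[:, None, :], msn[None, :, :], 1.0)
        assert len(edges) == int((d <= 0.1).sum())

    def test_empirical_probability(self, positions):
        msn, fsi = positions
        rng = np.random.default_rng(3)
        edges = connect_fsi_msn(fsi, msn, 1.0, rng)
        d = torus_distance(fsi[:, None, :], msn[None, :, :], 1.0)
        n_pairs = int((d <= 0.1).sum())
        p_hat = len(edges) / n_pairs
        se = np.sqrt(0.74 * 0.26 / n_pairs)
        assert abs(p_hat - 0.74) < 3 * se

    def test_bad_radius_rejected(self, positions, rng):
        msn, fsi = positions
        with pytest.raises(ValueError):
            connect_fsi_msn(fsi, msn, 1.0, rng, radius=0.0)


class TestMsnMsnConnectivity:
    def test_profile_values(self):
        # p(sigma) = p_at_sigma; p(0) = p_at_sigma*e^(1/2); p(2 sigma)
        sigma, p_s = 0.2, 0.2
        prof = lambda d: p_s * np.exp(0.5) * np.exp(-(d**2) / (2 * sigma**2))
        assert prof(sigma) == pytest.approx(0.2)
        assert prof(0.0) == pytest.approx(0.2 * np.exp(0.5))
        assert prof(2 * sigma) == pytest.approx(0.2 * np.exp(-1.5))

    def test_profile_above_one_rejected(self, rng):
        msn, _ = place_neurons(10, 2, 1.0, rng)
        with pytest.raises(ValueError):
            connect_msn_msn(msn, 1.0, rng, p_at_sigma=0.9)

    def test_no_self_connections(self, rng):
        msn, _ = place_neurons(200, 2, 1.0, rng)
        edges = connect_msn_msn(msn, 1.0, rng)
        assert np.all(edges.source != edges.target)

    def test_distance_law_recovered(self):
        """Connected-pair fraction per distance bin follows the Gaussian law."""
        rng = np.random.default_rng(8)
        msn, _ = place_neurons(500, 2, 1.0, rng)
        edges = connect_msn_msn(msn, 1.0, rng, sigma=0.2, p_at_sigma=0.2)
        d = torus_distance(msn[:, None, :], msn[None, :, :], 1.0)
        np.fill_diagonal(d, np.nan)
        connected = np.zeros_like(d, dtype=bool)
        connected[edges.source, edges.target] = True
        for lo, hi in ((0.05, 0.15), (0.15, 0.25), (0.3, 0.4)):
            mask = (d >= lo) & (d < hi)
            n = mask.sum()
            p_hat = connected[mask].mean()
            mid = (lo + hi) / 2
            p_theory = 0.2 * np.exp(0.5) * np.exp(-(mid**2) / (2 * 0.2**2))
            se = np.sqrt(p_theory * (1 - p_theory) / n)
            assert abs(p_hat - p_theory) < 4 * se + 0.01


class TestCortexWiring:
    def test_fixed_fan_in(self, rng):
        edges = wire_cortex(500, 50, rng)
        counts = np.bincount(edges.target, minlength=500)
        assert np.all(counts == 12)  # floor(0.25 * 50)

    def test_sources_distinct(self, rng):
        edges = wire_cortex(20, 50, rng)
        for j in range(20):
            src = edges.source[edges.target == j]
            assert len(np.unique(src)) == len(src)

    def test_all_to_all(self, rng):
        edges = wire_cortex(10, 8, rng, fraction=1.0)
        assert len(edges) == 80

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            wire_cortex(10, 50, rng, fraction=0.0)

    def test_seed_reproducibility(self):
        a = wire_cortex(50, 50, np.random.default_rng(4))
        b = wire_cortex(50, 50, np.random.default_rng(4))
        np.testing.assert_array_equal(a.source, b.source)


class TestWeights:
    def test_ws_zero_zeroes_intra_striatal(self):
        circuit = build_circuit(scale=ScaleFactors(w_s=0.0, w_c=113.0), seed=1)
        assert np.all(circuit.edges["FSI_MSN"].weight == 0.0)
        assert np.all(circuit.edges["MSN_MSN"].weight == 0.0)
        assert np.all(circuit.edges["CTX_MSN"].weight >= 0.0)

    def test_wc_doubling_doubles_cortical_weights(self):
        c1 = build_circuit(scale=ScaleFactors(w_s=18.0, w_c=100.0), seed=3)
        c2 = build_circuit(scale=ScaleFactors(w_s=18.0, w_c=200.0), seed=3)
        for etype in ("CTX_MSN", "CTX_FSI"):
            np.testing.assert_allclose(
                c2.edges[etype].weight, 2 * c1.edges[etype].weight, rtol=1e-12
            )

    def test_empirical_mean_matches_scaled_midpoint(self, rng):
        edges = wire_cortex(500, 50, rng, fraction=1.0)  # 25000 draws
        ranges = SynapseRanges(ctx_msn=(1.0, 3.0))
        scale = ScaleFactors(w_s=18.0, w_c=10.0)
        draw_weights(edges, ranges, scale, rng)
        expect = 2.0 * 10.0
        se = (3.0 - 1.0) * 10.0 / np.sqrt(12 * len(edges))
        assert abs(edges.weight.mean() - expect) < 3 * se

    def test_fsi_input_factor_applied(self):
        circuit = build_circuit(
            scale=ScaleFactors(w_s=18.0, w_c=113.0, fsi_input_factor=0.35), seed=5
        )
        lo, hi = SynapseRanges().ctx_fsi
        w = circuit.edges["CTX_FSI"].weight
        assert w.max() <= hi * 113.0 * 0.35 + 1e-9


class TestCircuitStructure:
    def test_edge_type_exclusivity(self, reference_circuit):
        assert set(reference_circuit.edges) == set(EDGE_TYPES)
        reference_circuit.validate()

    def test_scale_factor_identifiability(self):
        """Same seed at different w_s: identical topology, only intra-striatal
        weights differ."""
        a = build_circuit(scale=ScaleFactors(w_s=18.0, w_c=113.0), seed=9)
        b = build_circuit(scale=ScaleFactors(w_s=0.0, w_c=113.0), seed=9)
        for etype in EDGE_TYPES:
            np.testing.assert_array_equal(a.edges[etype].source, b.edges[etype].source)
            np.testing.assert_array_equal(a.edges[etype].target, b.edges[etype].target)
        for etype in ("CTX_MSN", "CTX_FSI"):
            np.testing.assert_allclose(a.edges[etype].weight, b.edges[etype].weight)
        assert np.all(b.edges["MSN_MSN"].weight == 0.0)
        assert np.any(a.edges["MSN_MSN"].weight > 0.0)

    def test_csr_signs(self, small_circuit):
        indptr, post, weight = small_circuit.to_csr()
        n_ctx = small_circuit.n_cortex
        ctx_w = np.concatenate(
            [weight[indptr[i]: indptr[i + 1]] for i in range(n_ctx)]
        )
        str_w = np.concatenate(
            [weight[indptr[i]: indptr[i + 1]]
             for i in range(n_ctx, small_circuit.n_cortex + small_circuit.n_striatal)]
        )
        assert np.all(ctx_w >= 0)
        assert np.all(str_w <= 0)

    def test_serialization_roundtrip(self, tmp_path, small_circuit):
        small_circuit.save(tmp_path)
        loaded = Circuit.load(tmp_path)
        assert loaded.n_msn == small_circuit.n_msn
        assert loaded.scale == small_circuit.scale
        for etype in EDGE_TYPES:
            np.testing.assert_allclose(
                loaded.edges[etype].weight, small_circuit.edges[etype].weight
            )
        np.testing.assert_allclose(loaded.msn_positions, small_circuit.msn_positions)
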