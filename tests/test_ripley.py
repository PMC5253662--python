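import numpy as np
import pytest

from neuromosaic.geometry import Box3D, PointPattern
from neuromosaic.ripley import (
    k_csr, default_radii, ripley_k, clustering_degree, clustering_length,
    csr_envelope, RipleyK,
)
from neuromosaic.synthetic import gen_csr, gen_cluster, gen_hardcore


def brute_force_k(pattern, radii, edge_correction):
    """Independent O(n²) double-loop estimator."""
    pts, box = pattern.points, pattern.box
    n = len(pts)
    V = box.volume
    out = np.zeros(len(radii))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = pts[i] - pts[j]
            d = np.sqrt((diff ** 2).sum())
            if edge_correction == "translation":
                w = V / np.prod(box.sides - np.abs(diff))
            else:
                w = 1.0
            out += w * (d <= radii)
    return V / (n * (n - 1)) * out


class TestKcsr:
    def test_sphere_volume_values(self):
        np.testing.assert_allclose(k_csr([0.0, 1.0]), [0.0, 4.0 * np.pi / 3.0])

    def test_cubic_scaling(self):
        r = np.array([3.0, 6.0])
        k = k_csr(r)
        assert k[1] == pytest.approx(8.0 * k[0])


class TestEstimator:
    def test_two_point_pattern_closed_form(self):
        # 2 points distance d apart, no correction: K̂ jumps from 0 to V at d
        box = Box3D.cube(10.0)
        pat = PointPattern([[2.0, 5.0, 5.0], [6.0, 5.0, 5.0]], box)
        k = ripley_k(pat, np.array([1.0, 3.9, 4.0, 8.0]), "none")
        np.testing.assert_allclose(k, [0.0, 0.0, 1000.0, 1000.0])

    def test_zero_below_minimum_pair_distance(self, box100, rng):
        pat = gen_hardcore(30, 20.0, box100, 2)
        assert ripley_k(pat, np.array([5.0, 19.0]), "translation").max() == 0.0

    @pytest.mark.parametrize("correction", ["translation", "none"])
    def test_matches_brute_force_oracle(self, correction, rng):
        box = Box3D((0, 0, 0), (80.0, 100.0, 120.0))
        for seed in range(5):
            pat = gen_csr(int(rng.integers(10, 60)), box, seed)
            radii = np.linspace(5.0, 80.0, 12)
            np.testing.assert_allclose(
                ripley_k(pat, radii, correction),
                brute_force_k(pat, radii, correction),
                rtol=1e-10,
            )

    def test_monotone_nondecreasing_in_radius(self, box100):
        for seed in range(5):
            pat = gen_cluster(1e-4, 4, 8.0, box100, seed)
            if pat.n < 2:
                continue
            k = ripley_k(pat, default_radii(pat.box), "translation")
            assert np.all(np.diff(k) >= -1e-9)

    def test_input_validation(self, box100):
        one = PointPattern([[1.0, 1.0, 1.0]], box100)
        with pytest.raises(ValueError, match="at least 2"):
            ripley_k(one, np.array([10.0]))
        pat = gen_csr(10, box100, 0)
        with pytest.raises(ValueError, match="smaller size of the examined volume"):
            ripley_k(pat, np.array([150.0]))
        with pytest.raises(ValueError, match="increasing"):
            ripley_k(pat, np.array([10.0, 5.0]))


class TestClusteringDegree:
    def test_csr_fixed_point_and_excess(self):
        radii = np.array([10.0, 20.0])
        kc = k_csr(radii)
        assert clustering_degree(kc, kc, radii, 20.0) == 0.0
        assert clustering_degree(1.2 * kc, kc, radii, 20.0) == pytest.approx(0.2)

    def test_hardcore_range_gives_minus_one(self, box100):
        pat = gen_hardcore(40, 25.0, box100, 3)
        radii = np.array([10.0, 20.0, 50.0])
        k_hat = ripley_k(pat, radii)
        # no pairs below the hard core: K̂ = 0, hence ρ = −1
        assert clustering_degree(k_hat, k_csr(radii), radii, 20.0) == -1.0

    def test_zero_and_off_grid_delta_rejected(self):
        radii = np.array([1.0, 2.0])
        kc = k_csr(radii)
        with pytest.raises(ValueError, match="Δx = 0"):
            clustering_degree(kc, kc, radii, 0.0)
        with pytest.raises(ValueError, match="not on the radius grid"):
            clustering_degree(kc, kc, radii, 1.5)


class TestClusteringLength:
    def test_undefined_when_never_above_csr(self):
        radii = np.linspace(1, 10, 10)
        kc = k_csr(radii)
        assert clustering_length(kc, kc, radii) is None
        assert clustering_length(0.5 * kc, kc, radii) is None

    def test_end_of_contiguous_excess_interval(self):
        radii = np.linspace(10.0, 100.0, 10)
        kc = k_csr(radii)
        k_hat = kc.copy()
        k_hat[:5] *= 1.1  # above on [10, 50], at/below after
        assert clustering_length(k_hat, kc, radii) == 50.0

    def test_first_run_only(self):
        radii = np.linspace(10.0, 100.0, 10)
        kc = k_csr(radii)
        k_hat = kc.copy()
        k_hat[1:4] *= 1.2
        k_hat[6:] *= 1.3  # later excess does not extend L_c
        assert clustering_length(k_hat, kc, radii) == radii[3]


class TestEnvelope:
    def test_low_below_high_and_deterministic(self, box100):
        radii = np.linspace(10.0, 90.0, 9)
        lo1, hi1 = csr_envelope(40, box100, radii, n_sims=19, alpha=0.05, seed=5)
        lo2, hi2 = csr_envelope(40, box100, radii, n_sims=19, alpha=0.05, seed=5)
        assert np.all(lo1 <= hi1)
        np.testing.assert_array_equal(lo1, lo2)
        np.testing.assert_array_equal(hi1, hi2)

    def test_too_few_simulations_rejected(self, box100):
        with pytest.raises(ValueError, match="at least 19"):
            csr_envelope(40, box100, np.array([10.0]), n_sims=10, alpha=0.05, seed=0)

    def test_envelope_brackets_theoretical_csr_curve(self, box100):
        radii = np.linspace(10.0, 90.0, 20)
        low, high = csr_envelope(500, box100, radii, n_sims=99, alpha=0.01, seed=3)
        kc = k_csr(radii)
        assert np.mean((kc >= low) & (kc <= high)) >= 0.95


class TestModelInterface:
    def test_fit_returns_consistent_results(self, box100):
        pat = gen_csr(100, box100, 8)
        res = RipleyK(pat).fit()
        assert res.n_points == 100
        assert len(res.k_hat) == len(res.radii)
        np.testing.assert_allclose(res.ratio, res.k_hat / res.k_csr)
        assert "Ripley" in res.summary()

    def test_rho_reported_at_requested_scale(self, box100):
        pat = gen_csr(200, box100, 9)
        radii = np.linspace(10.0, 100.0, 10)
        res = RipleyK(pat, radii=radii).fit(delta_x=50.0)
        assert res.delta_x == 50.0
        assert res.rho == pytest.approx(
            clustering_degree(res.k_hat, res.k_csr, radii, 50.0))

    def test_summary_dict_round_trips_to_json(self, box100):
        import json
        pat = gen_csr(50, box100, 10)
        res = RipleyK(pat).fit()
        assert json.loads(json.dumps(res.summary_dict()))["n"] == 50
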