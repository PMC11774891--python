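import numpy as np
import pytest

from rapespec.indices import (CorrelationSurface, SpectralIndexSpec,
                              compute_index, correlation_surface,
                              select_best_pair)

from conftest import toy_samples


def brute_force_surface(samples, family, channel):
    """Independent oracle: explicit double loop with np.corrcoef per pair."""
    grid = samples.wavelengths
    y = samples.channel(channel)
    cc = np.full((grid.size, grid.size), np.nan)
    for i in range(grid.size):
        for j in range(grid.size):
            a, b = samples.reflectance[:, i], samples.reflectance[:, j]
            if family == "RSI":
                v = a / b
            elif family == "DSI":
                v = a - b
            else:
                v = (a - b) / (a + b)
            if np.std(v) == 0 or np.std(y) == 0:
                continue
            cc[i, j] = np.corrcoef(v, y)[0, 1]
    return cc


class TestComputeIndex:
    def test_identity_pair(self, rng):
        s = toy_samples(rng.uniform(0.1, 0.9, (5, 8)))
        wl = s.wavelengths[2]
        np.testing.assert_array_equal(compute_index("RSI", s, wl, wl), np.ones(5))
        np.testing.assert_array_equal(compute_index("DSI", s, wl, wl), np.zeros(5))
        np.testing.assert_array_equal(compute_index("NDSI", s, wl, wl), np.zeros(5))

    def test_arithmetic(self):
        s = toy_samples([[0.6, 0.3]])
        l1, l2 = s.wavelengths
        assert compute_index("RSI", s, l1, l2)[0] == pytest.approx(2.0)
        assert compute_index("DSI", s, l1, l2)[0] == pytest.approx(0.3)
        assert compute_index("NDSI", s, l1, l2)[0] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("family", ["DSI", "NDSI"])
    def test_antisymmetry(self, family, rng):
        s = toy_samples(rng.uniform(0.05, 0.95, (20, 6)))
        l1, l2 = s.wavelengths[1], s.wavelengths[4]
        np.testing.assert_allclose(compute_index(family, s, l1, l2),
                                   -compute_index(family, s, l2, l1), rtol=1e-12)

    def test_ndsi_bounded_for_positive_reflectance(self, rng):
        s = toy_samples(rng.uniform(1e-3, 1.0, (50, 10)))
        for _ in range(20):
            l1, l2 = rng.choice(s.wavelengths, 2, replace=False)
            v = compute_index("NDSI", s, l1, l2)
            assert np.all(np.abs(v) < 1)

    def test_off_grid_wavelength_rejected(self, rng):
        s = toy_samples(rng.uniform(0.1, 0.9, (5, 8)))
        with pytest.raises(ValueError, match="not on the grid"):
            compute_index("RSI", s, 400.5, 401.0)

    def test_zero_denominator_identifies_seed(self):
        refl = np.array([[0.5, 0.2], [0.5, 0.0]])
        s = toy_samples(refl)
        with pytest.raises(ZeroDivisionError, match="seed 1"):
            compute_index("RSI", s, s.wavelengths[0], s.wavelengths[1])


class TestCorrelationSurface:
    @pytest.mark.parametrize("family", ["RSI", "DSI", "NDSI"])
    def test_matches_brute_force_oracle_on_toy_grid(self, family, rng):
        refl = rng.uniform(0.05, 0.95, (25, 10))
        rgb = np.column_stack([rng.uniform(50, 200, 25) for _ in range(3)])
        s = toy_samples(refl, rgb=rgb)
        surf = correlation_surface(family, s, "R", use_full=True)
        oracle = brute_force_surface(s, family, "R")
        np.testing.assert_allclose(surf.cc, oracle, rtol=0, atol=1e-10)
        assert np.array_equal(np.isnan(surf.cc), np.isnan(oracle))

    @pytest.mark.parametrize("family", ["DSI", "NDSI"])
    def test_surface_antisymmetry(self, family, rng):
        refl = rng.uniform(0.05, 0.95, (30, 8))
        rgb = np.tile(rng.uniform(0, 255, (30, 1)), (1, 3))
        s = toy_samples(refl, rgb=rgb)
        surf = correlation_surface(family, s, "G", use_full=True).cc
        mask = np.isfinite(surf) & np.isfinite(surf.T)
        np.testing.assert_allclose(surf[mask], -surf.T[mask], atol=1e-10)

    def test_planted_pair_attains_unit_correlation(self, rng):
        refl = rng.uniform(0.1, 0.9, (40, 12))
        wl = 500.0 + 10.0 * np.arange(12)  # 500 … 610, includes 600
        i, j = 0, 10
        ndsi = (refl[:, i] - refl[:, j]) / (refl[:, i] + refl[:, j])
        rgb = np.column_stack([150 + 30 * ndsi, np.full(40, 120.0), np.full(40, 60.0)])
        s = toy_samples(refl, rgb=rgb, wavelengths=wl)
        surf = correlation_surface("NDSI", s, "R", n_reps=5, seed=0)
        spec = select_best_pair(surf)
        assert (spec.lambda1, spec.lambda2) == (500.0, 600.0)
        assert spec.mean_cc == pytest.approx(1.0, abs=1e-9)

    def test_rep_averaging_idempotent_when_split_is_whole_set(self, rng):
        refl = rng.uniform(0.1, 0.9, (20, 6))
        rgb = rng.uniform(10, 240, (20, 3))
        s = toy_samples(refl, rgb=rgb)
        one = correlation_surface("DSI", s, "R", n_reps=1, split_fraction=1.0, seed=1)
        five = correlation_surface("DSI", s, "R", n_reps=5, split_fraction=1.0, seed=2)
        np.testing.assert_allclose(one.cc, five.cc, atol=1e-12)

    def test_constant_channel_rejected(self, rng):
        s = toy_samples(rng.uniform(0.1, 0.9, (10, 5)))  # default rgb constant
        with pytest.raises(ValueError, match="zero-variance target"):
            correlation_surface("RSI", s, "R", n_reps=1, seed=0)

    def test_deterministic_under_seed(self, rng):
        refl = rng.uniform(0.1, 0.9, (30, 6))
        rgb = rng.uniform(10, 240, (30, 3))
        s = toy_samples(refl, rgb=rgb)
        a = correlation_surface("NDSI", s, "G", n_reps=3, seed=5)
        b = correlation_surface("NDSI", s, "G", n_reps=3, seed=5)
        np.testing.assert_array_equal(a.cc, b.cc)


class TestSelectBestPair:
    def test_single_entry_surface(self):
        cc = np.full((3, 3), np.nan)
        cc[1, 2] = 0.4
        spec = select_best_pair(CorrelationSurface("RSI", "R", np.array([1.0, 2, 3]), cc))
        assert (spec.lambda1, spec.lambda2, spec.mean_cc) == (2.0, 3.0, 0.4)

    def test_signed_report_absolute_argmax(self):
        cc = np.full((4, 4), np.nan)
        cc[0, 1] = 0.9
        cc[2, 3] = -0.95
        grid = np.array([10.0, 20, 30, 40])
        spec = select_best_pair(CorrelationSurface("DSI", "G", grid, cc))
        assert (spec.lambda1, spec.lambda2) == (30.0, 40.0)
        assert spec.mean_cc == -0.95

    def test_tie_breaks_toward_smallest_wavelengths(self):
        cc = np.full((3, 3), np.nan)
        cc[0, 2] = -0.8
        cc[2, 0] = 0.8
        cc[0, 1] = 0.8
        grid = np.array([5.0, 6, 7])
        spec = select_best_pair(CorrelationSurface("NDSI", "B", grid, cc))
        assert (spec.lambda1, spec.lambda2) == (5.0, 6.0)

    def test_all_missing_rejected(self):
        surf = CorrelationSurface("RSI", "R", np.arange(3.0), np.full((3, 3), np.nan))
        with pytest.raises(ValueError, match="no non-missing"):
            select_best_pair(surf)


def test_spec_serialization_round_trip(tmp_path):
    spec = SpectralIndexSpec("NDSI", 646, 995, 0.966, "R")
    path = spec.to_json(tmp_path / "spec.json")
    assert SpectralIndexSpec.from_json(path) == spec
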