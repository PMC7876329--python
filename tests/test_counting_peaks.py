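import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomcount.counting_peaks import (PeakConfig, extract_peaks,
                                       integrate_count, peak_count_deficit)
from bloomcount.density_targets import (KernelConfig, PointAnnotationSet,
                                        gaussian_density_map)


def pset(points):
    return PointAnnotationSet("img", np.array(points, float).reshape(-1, 2))


class TestIntegrateCount:
    def test_uniform_density(self):
        assert integrate_count(np.full((100, 100), 0.001)) \
            == pytest.approx(10.0)

    def test_zero_map(self):
        assert integrate_count(np.zeros((32, 32))) == 0.0

    def test_additive_over_disjoint_halves(self, rng):
        arr = rng.random((40, 60))
        left = integrate_count(arr, (0, 0, 40, 30))
        right = integrate_count(arr, (0, 30, 40, 60))
        assert left + right == pytest.approx(integrate_count(arr))

    def test_mask_region(self, rng):
        arr = rng.random((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10] = True
        assert integrate_count(arr, mask) \
            == pytest.approx(float(arr[:10].sum()))

    def test_region_out_of_bounds(self):
        with pytest.raises(ValueError):
            integrate_count(np.zeros((10, 10)), (0, 0, 11, 10))

    def test_ground_truth_target_integrates_to_count(self, rng):
        pts = rng.uniform(24, 104, size=(12, 2))
        dm = gaussian_density_map(pset(pts), (128, 128),
                                  KernelConfig(sigma=6))
        assert integrate_count(dm) == pytest.approx(12.0, abs=0.12)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2 ** 31), split=st.integers(1, 19))
def test_integrate_count_additive_property(seed, split):
    arr = np.random.default_rng(seed).random((20, 20))
    top = integrate_count(arr, (0, 0, split, 20))
    bottom = integrate_count(arr, (split, 0, 20, 20))
    assert top + bottom == pytest.approx(integrate_count(arr), rel=1e-12)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2 ** 31),
       gamma=st.floats(0.0, 1.0), delta=st.floats(1.0, 10.0))
def test_extract_peaks_invariants_property(seed, gamma, delta):
    arr = np.random.default_rng(seed).random((24, 24))
    ps = extract_peaks(arr, PeakConfig(gamma, delta))
    assert all(v >= gamma for _, _, v in ps.peaks)
    coords = ps.coords
    if len(coords) > 1:
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= delta


def bump(shape, center, amplitude, sigma=2.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return amplitude * np.exp(-d2 / (2 * sigma * sigma))


class TestExtractPeaks:
    def test_all_below_gamma_empty(self):
        arr = np.full((32, 32), 0.04)
        assert extract_peaks(arr, PeakConfig(0.05, 4)).count == 0

    def test_single_bump(self):
        arr = bump((32, 32), (10, 10), 0.1)
        ps = extract_peaks(arr, PeakConfig(0.05, 4))
        assert ps.count == 1
        assert ps.peaks[0][:2] == (10, 10)

    def test_close_pair_suppressed(self):
        # narrow bumps so both stay local maxima; the weaker one sits
        # 3 px < delta away and is greedily suppressed
        arr = bump((32, 32), (10, 10), 0.2, sigma=1.2) \
            + bump((32, 32), (10, 13), 0.15, sigma=1.2)
        ps = extract_peaks(arr, PeakConfig(0.05, 4))
        assert [(r, c) for r, c, _ in ps.peaks] == [(10, 10)]

    def test_far_pair_kept_in_value_order(self):
        arr = bump((40, 40), (10, 10), 0.15) + bump((40, 40), (30, 30), 0.3)
        ps = extract_peaks(arr, PeakConfig(0.05, 4))
        assert [(r, c) for r, c, _ in ps.peaks] == [(30, 30), (10, 10)]

    def test_plateau_yields_topleft_candidate(self):
        arr = np.zeros((16, 16))
        arr[5:7, 5:7] = 0.2
        ps = extract_peaks(arr, PeakConfig(0.05, 4))
        assert [(r, c) for r, c, _ in ps.peaks] == [(5, 5)]

    def test_peak_values_respect_gamma_and_delta(self, rng):
        arr = rng.random((48, 48))
        cfg = PeakConfig(0.5, 5)
        ps = extract_peaks(arr, cfg)
        assert all(v >= cfg.gamma for _, _, v in ps.peaks)
        coords = ps.coords
        if len(coords) > 1:
            d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            assert d.min() >= cfg.delta

    @pytest.mark.parametrize("gamma", [0.0, 0.05, 0.2])
    @pytest.mark.parametrize("delta", [1.0, 4.0, 8.0])
    def test_matches_brute_force_oracle(self, gamma, delta, rng,
                                        brute_peaks_oracle):
        for _ in range(5):
            arr = rng.random((32, 32))
            arr[arr < 0.3] = 0.0  # some flat zero background
            got = extract_peaks(arr, PeakConfig(gamma, delta)).peaks
            expected = brute_peaks_oracle(arr, gamma, delta)
            assert [(r, c) for r, c, _ in got] \
                == [(r, c) for r, c, _ in expected]

    def test_recovers_separated_target_points(self, rng):
        # ground-truth target, points pairwise far apart: with a threshold
        # below the single-point peak value, every point is recovered
        pts = [(30.0, 30.0), (30.0, 90.0), (90.0, 30.0), (90.0, 90.0),
               (60.0, 60.0)]
        dm = gaussian_density_map(pset(pts), (120, 120),
                                  KernelConfig(sigma=6))
        ps = extract_peaks(dm, PeakConfig(gamma=0.002, delta=4))
        assert ps.count == 5
        d = np.sqrt(((np.array(pts)[:, None] - ps.coords[None]) ** 2)
                    .sum(-1)).min(axis=1)
        assert d.max() <= 1.0

    def test_gamma_delta_monotonicity(self, rng):
        arr = rng.random((48, 48))
        base = extract_peaks(arr, PeakConfig(0.1, 2)).count
        assert extract_peaks(arr, PeakConfig(0.3, 2)).count <= base
        assert extract_peaks(arr, PeakConfig(0.1, 6)).count <= base

    def test_idempotent_on_reduced_map(self, rng):
        arr = rng.random((32, 32))
        cfg = PeakConfig(0.2, 4)
        ps = extract_peaks(arr, cfg)
        reduced = np.zeros_like(arr)
        for r, c, v in ps.peaks:
            reduced[r, c] = v
        again = extract_peaks(reduced, cfg)
        assert again.peaks == ps.peaks


class TestPeakCountDeficit:
    def test_zero_map(self):
        assert peak_count_deficit(np.zeros((16, 16))) == (0.0, 0)

    def test_single_unit_gaussian(self):
        import warnings

        dm = gaussian_density_map(pset([(50, 50)]), (101, 101),
                                  KernelConfig(sigma=6))
        with warnings.catch_warnings():
            # T_c = 0.9996 < T_d = 1 by the truncation tail: benign
            warnings.simplefilter("ignore", UserWarning)
            t_c, t_d = peak_count_deficit(dm,
                                          PeakConfig(gamma=0.002, delta=4))
        assert t_c == pytest.approx(1.0, abs=1e-3)
        assert t_d == 1

    def test_warns_when_deficit_negative(self):
        arr = np.zeros((32, 32))
        for r in range(2, 32, 8):
            for c in range(2, 32, 8):
                arr[r, c] = 0.06  # isolated just-above-threshold pixels
        with pytest.warns(UserWarning, match="exceeds"):
            peak_count_deficit(arr, PeakConfig(0.05, 4))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PeakConfig(gamma=-0.1)
        with pytest.raises(ValueError):
            PeakConfig(delta=0.5)
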