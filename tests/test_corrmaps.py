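"""Pearson correlation, per-map median thresholding and RGB composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saxseg.corrmaps import (
    CorrelationMaps,
    compose_rgb,
    correlation_maps,
    pearson,
    threshold_median,
)
from saxseg.preprocess import CurveMatrix
from saxseg.representatives import RepresentativeSignal
from saxseg.scattering_io import ScanGrid


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        assert pearson(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_exact_anticorrelation(self):
        assert pearson([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_value(self):
        # cov([1,2,3,4],[1,3,2,4]) = 4/3; sd = sqrt(5/3) each -> 0.8
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_returns_nan_not_zero(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pearson([1.0, 2.0], [3.0, 4.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
    )
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=16)
        y = rng.normal(size=16)
        rho = pearson(x, y)
        assert pearson(y, x) == pytest.approx(rho, abs=1e-12)
        assert pearson(a * x + b, y) == pytest.approx(
            np.sign(a) * rho, abs=1e-9
        )

    def test_matches_numpy_corrcoef(self, rng):
        for _ in range(100):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert pearson(x, y) == pytest.approx(
                np.corrcoef(x, y)[0, 1], abs=1e-12
            )


def make_reps(curves, ids):
    return [
        RepresentativeSignal(
            cluster_id=i,
            curve=curves.values[k],
            q=curves.q_centers,
            method="furthest_mean",
            member_indices=np.array([k]),
        )
        for k, i in enumerate(ids)
    ]


class TestCorrelationMaps:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.q = np.geomspace(1, 10, 30)
        self.grid = ScanGrid(4, 4)
        self.curves = CurveMatrix(
            values=rng.uniform(0.5, 3, size=(16, 30)), q_centers=self.q
        )

    def test_pixel_equal_to_representative_scores_one(self):
        reps = make_reps(self.curves, [1, 2])
        maps = correlation_maps(self.curves, reps, self.grid)
        # rep 2 is the curve of flat index 1 -> pixel (0, 1)
        assert maps.rho[1, 0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_one_map_per_representative(self):
        reps = make_reps(self.curves, [1, 2, 3, 4])
        maps = correlation_maps(self.curves, reps, self.grid)
        assert maps.rho.shape == (4, 4, 4)

    def test_vectorized_equals_per_pixel_loop(self):
        reps = make_reps(self.curves, [1, 2, 3])
        maps = correlation_maps(self.curves, reps, self.grid)
        for k in range(3):
            for flat in range(16):
                row, col = flat // 4, flat % 4
                assert maps.rho[k, row, col] == pytest.approx(
                    pearson(self.curves.values[flat], reps[k].curve), abs=1e-12
                )

    def test_excluded_pixels_are_missing(self):
        self.curves.excluded[5] = True
        maps = correlation_maps(self.curves, make_reps(self.curves, [1]), self.grid)
        assert np.isnan(maps.rho[0, 1, 1])


class TestThresholdMedian:
    def _maps(self, arr):
        arr = np.asarray(arr, float)[None, :, :]
        return CorrelationMaps(
            rho=arr, cluster_ids=[1], grid=ScanGrid(*arr.shape[1:])
        )

    def test_even_count_median_convention(self):
        maps = threshold_median(self._maps([[0.1, 0.2], [0.3, 0.4]]))
        assert np.allclose(maps.thresholded[0], [[0.0, 0.0], [0.3, 0.4]])
        assert maps.medians[0] == pytest.approx(0.25)

    def test_constant_map_unchanged(self):
        maps = threshold_median(self._maps(np.full((3, 3), 0.7)))
        assert np.allclose(maps.thresholded[0], 0.7)

    def test_idempotent(self, rng):
        arr = rng.uniform(-1, 1, size=(6, 6))
        once = threshold_median(self._maps(arr)).thresholded.copy()
        again = threshold_median(
            CorrelationMaps(rho=once.copy(), cluster_ids=[1], grid=ScanGrid(6, 6))
        ).thresholded
        assert np.array_equal(once, again)

    def test_survivor_count_matches_sort_oracle(self, rng):
        arr = rng.uniform(-1, 1, size=(5, 8))
        maps = threshold_median(self._maps(arr))
        flat = np.sort(arr.ravel())
        med = (flat[19] + flat[20]) / 2
        assert np.array_equal(maps.thresholded[0] != 0, arr >= med)


class TestComposeRGB:
    def _maps(self, planes):
        arr = np.asarray(planes, float)
        return CorrelationMaps(
            rho=arr, cluster_ids=[1, 2, 3], grid=ScanGrid(*arr.shape[1:])
        )

    def test_pixel_correlated_with_single_cluster_is_pure_red(self):
        planes = np.zeros((3, 2, 2))
        planes[0, 0, 0] = 0.9  # only cluster 1 correlates at (0,0)
        planes[1, 1, 1] = 0.8
        planes[2, 1, 0] = 0.7
        rgb = compose_rgb(self._maps(planes), (1, 2, 3))
        assert rgb[0, 0].tolist() == [1.0, 0.0, 0.0]

    def test_equal_maximal_correlation_renders_white(self):
        planes = np.zeros((3, 2, 2))
        planes[:, 0, 1] = 0.9
        rgb = compose_rgb(self._maps(planes), (1, 2, 3))
        assert rgb[0, 1].tolist() == [1.0, 1.0, 1.0]

    def test_all_zero_maps_render_black_with_warning(self, caplog):
        planes = np.zeros((3, 2, 2))
        maps = self._maps(planes)
        maps.thresholded = planes.copy()
        maps.medians = np.zeros(3)
        with caplog.at_level("WARNING"):
            rgb = compose_rgb(maps, (1, 2, 3))
        assert np.all(rgb == 0)
        assert "all zero" in caplog.text

    def test_fewer_than_three_ids_rejected(self):
        with pytest.raises(ValueError, match="grayscale"):
            compose_rgb(self._maps(np.zeros((3, 2, 2))), (1, 1, 2))
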