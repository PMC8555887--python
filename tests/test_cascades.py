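import numpy as np
import pytest
from scipy.stats import norm

from cascadenet.cascades import (
    Avalanche, CascadeConfig, DegenerateSignalError, binarize,
    cascade_magnitude, cascade_signal_from_raw, classify_nodes,
    detect_avalanches, smooth_downsample,
)
from cascadenet.network import RawTimeseries, SimConfig


class TestBinarize:
    def test_gaussian_tail_fraction(self, rng):
        X = rng.normal(size=(3, 100_000))
        frac = binarize(X, CascadeConfig(z_threshold=3.0)).mean()
        p = 2 * norm.sf(3.0)  # two-sided normal tail, ~0.0027
        se = np.sqrt(p * (1 - p) / X.size)
        assert abs(frac - p) < 3 * se

    def test_zero_threshold_marks_everything(self, rng):
        X = rng.normal(size=(2, 500))
        cfg = CascadeConfig(z_threshold=1e-300)
        assert binarize(X, cfg).mean() > 0.999

    def test_two_sided_symmetry(self, rng):
        X = rng.normal(size=(4, 2000))
        np.testing.assert_array_equal(binarize(X), binarize(-X))

    def test_constant_region_rejected(self):
        X = np.vstack([np.ones(100), np.random.default_rng(0).normal(size=100)])
        with pytest.raises(DegenerateSignalError, match="region 0"):
            binarize(X)


class TestMagnitude:
    def test_counting(self):
        raster = np.array([[1, 1, 0], [0, 1, 0]], dtype=np.uint8)
        np.testing.assert_array_equal(cascade_magnitude(raster), [1, 2, 0])

    def test_bounded_by_regions(self, rng):
        raster = (rng.random((7, 300)) < 0.4).astype(np.uint8)
        m = cascade_magnitude(raster)
        assert m.max() <= 7 and m.min() >= 0


class TestSmoothDownsample:
    def test_constant_preserved(self):
        cfg = CascadeConfig(kernel_width=2.0, target_rate=0.5)
        out = smooth_downsample(np.full(20000, 3.7), cfg, fast_rate=1000.0)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_mass_conservation_away_from_edges(self):
        cfg = CascadeConfig(kernel_width=2.0, target_rate=0.5)
        x = np.zeros(40_000)
        x[20_000] = 1000.0  # centred impulse, 4 SD within the signal
        out = smooth_downsample(x, cfg, fast_rate=1000.0)
        assert np.sum(out) * 2.0 == pytest.approx(np.sum(x) / 1000.0, rel=1e-6)

    def test_impulse_matches_truncated_gaussian_kernel(self):
        # oracle: closed-form truncated+renormalised Gaussian, bin-averaged
        fast, tr = 200.0, 2.0
        cfg = CascadeConfig(kernel_width=tr, target_rate=1 / tr)
        n = 40_000
        c = 20_000
        x = np.zeros(n)
        x[c] = 1.0
        out = smooth_downsample(x, cfg, fast_rate=fast)
        sigma = tr * fast
        radius = int(4.0 * sigma + 0.5)
        d = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (d / sigma) ** 2)
        k /= k.sum()
        kernel_at = dict(zip(d + c, k))
        bin_len = int(fast * tr)
        expect = np.array([
            np.mean([kernel_at.get(s, 0.0) for s in range(b * bin_len, (b + 1) * bin_len)])
            for b in range(n // bin_len)
        ])
        np.testing.assert_allclose(out, expect, atol=1e-6)

    def test_target_rate_validation(self):
        with pytest.raises(ValueError, match="target rate"):
            smooth_downsample(np.zeros(100), CascadeConfig(target_rate=500.0),
                              fast_rate=200.0)


class TestAvalanches:
    def test_run_detection(self):
        raster = np.array([[1, 1, 0, 1]], dtype=np.uint8)
        cat = detect_avalanches(raster)
        assert [(a.start_sample, a.lifetime_samples) for a in cat] == [(0, 2), (3, 1)]

    def test_size_counts_distinct_regions(self):
        raster = np.array([[1, 1, 0], [0, 1, 0]], dtype=np.uint8)
        cat = detect_avalanches(raster)
        assert len(cat) == 1
        a = cat.avalanches[0]
        assert a.lifetime_samples == 2 and a.size == 2 and a.regions == {0, 1}

    def test_concatenation_locality(self, rng):
        r1 = (rng.random((4, 50)) < 0.2).astype(np.uint8)
        r2 = (rng.random((4, 60)) < 0.2).astype(np.uint8)
        gap = np.zeros((4, 3), dtype=np.uint8)
        joint = detect_avalanches(np.hstack([r1, gap, r2]))
        c1, c2 = detect_avalanches(r1), detect_avalanches(r2)
        assert len(joint) == len(c1) + len(c2)
        offsets = [a.start_sample for a in joint]
        expect = [a.start_sample for a in c1] + [a.start_sample + 53 for a in c2]
        assert offsets == expect

    def test_magnitude_inside_avalanches(self, rng):
        raster = (rng.random((5, 400)) < 0.05).astype(np.uint8)
        mag = cascade_magnitude(raster)
        inside = np.zeros(400, dtype=bool)
        for a in detect_avalanches(raster):
            inside[a.start_sample : a.start_sample + a.lifetime_samples] = True
        assert np.all(mag[inside] >= 1)
        assert np.all(mag[~inside] == 0)


class TestCascadeAvalancheCoupling:
    def test_bold_magnitude_tracks_avalanche_density(self, rng):
        """Cascades are the slow clustering of avalanches: bin-summed
        avalanche activity correlates strongly with the smoothed signal."""
        fast, tr = 200.0, 2.0
        n = 60_000  # 300 s
        X = rng.normal(size=(20, n))
        # plant clustered high-amplitude epochs
        for start in (6_000, 18_000, 30_000, 42_000, 52_000):
            for _ in range(30):
                s = start + rng.integers(0, 2000)
                X[rng.integers(0, 20), s : s + 60] += 10.0
        cfg = CascadeConfig(kernel_width=tr, target_rate=1 / tr)
        sig = cascade_signal_from_raw(X, fast, cfg)
        raster = binarize(X, cfg)
        bin_len = int(fast * tr)
        binned = cascade_magnitude(raster)[: (n // bin_len) * bin_len]
        binned = binned.reshape(-1, bin_len).sum(axis=1)
        rho = np.corrcoef(sig.magnitude_bold, binned)[0, 1]
        assert rho > 0.9


class TestClassification:
    def _raw(self, r):
        r = np.asarray(r, dtype=float)
        return RawTimeseries(r=r, V=np.zeros_like(r), dt_record=1.0,
                             config=SimConfig(duration=r.shape[1] / 1000.0,
                                              burn_in=0.0))

    def test_constructed_classes(self, rng):
        # bounded wobble so that pure D/U nodes genuinely never cross 3 sigma
        T = 100_000
        wobble = 0.002 * np.sin(np.arange(T) / 37.0)
        down = np.full(T, 0.057) + wobble
        up = np.full(T, 1.01) + wobble
        square = np.where((np.arange(T) // 5000) % 2 == 0, 1.01, 0.057) + wobble
        ustar = np.full(T, 1.01) + wobble.copy()
        ustar[50_000:50_400] = 0.02  # one rare deep excursion
        raw = self._raw(np.vstack([down, up, square, ustar]))
        cls = classify_nodes(raw, min_duration_s=60.0)
        assert cls.labels == ["D", "U", "J", "U*"]
        assert cls.n_threshold_crossings[3] >= 1
        assert cls.n_state_jumps[2] >= 15

    def test_dstar_label(self, rng):
        T = 100_000
        dstar = np.full(T, 0.057) + 0.001 * rng.normal(size=T)
        dstar[20_000:20_400] = 1.0
        raw = self._raw(np.vstack([dstar, dstar + 0.0]))
        cls = classify_nodes(raw, min_duration_s=60.0)
        assert cls.labels[0] == "D*"

    def test_labels_partition_and_deterministic(self, rng):
        T = 80_000
        R = 0.5 + 0.2 * rng.normal(size=(5, T))
        raw = self._raw(np.abs(R))
        c1 = classify_nodes(raw, min_duration_s=60.0)
        c2 = classify_nodes(raw, min_duration_s=60.0)
        assert c1.labels == c2.labels
        assert set(c1.labels) <= {"D", "U", "J", "D*", "U*"}
        assert np.all((c1.up_occupancy >= 0) & (c1.up_occupancy <= 1))

    def test_too_short_rejected(self):
        raw = self._raw(np.random.default_rng(0).random((2, 5000)))
        with pytest.raises(ValueError, match="60"):
            classify_nodes(raw)
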