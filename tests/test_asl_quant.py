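"""Polar resampling, angular filtering, Buxton quantification, PN/TN."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioquant.asl_quant import (
    PolarMap,
    estimate_noise,
    mbf_segments,
    polar_resample,
    quantify_mbf,
    spatiotemporal_filter,
    _bin_index,
    _segment_bins,
)
from cardioquant.asl_sim import ASLGeometry, ASLProtocol, ASLTruth, simulate_series
from cardioquant.core import MBFResult


GEO = ASLGeometry()
RING = GEO.ring_mask()


class TestPolarResample:
    def test_uniform_image_gives_uniform_bins(self):
        img = np.full(GEO.shape, 7.5)
        pmap = polar_resample(img, RING, GEO.center_px)
        assert not pmap.missing.any()
        assert np.allclose(pmap.values, 7.5)

    def test_half_ring_marks_missing_bins_without_interpolation(self):
        half = RING.copy()
        iy = np.indices(GEO.shape)[0]
        half[iy > GEO.center_px[0]] = False
        pmap = polar_resample(np.ones(GEO.shape), half, GEO.center_px)
        assert pmap.missing.any()
        assert np.isnan(pmap.values[pmap.missing]).all()
        assert np.allclose(pmap.values[~pmap.missing], 1.0)

    def test_wedge_of_doubled_signal_doubles_exactly_those_bins(self):
        img = np.ones(GEO.shape)
        idx_map = np.full(GEO.shape, -1)
        idx_map[RING] = _bin_index(GEO.shape, GEO.center_px, RING, 60)
        wedge_bins = set(range(10, 20))  # pi/3 wedge aligned to bin edges
        img[np.isin(idx_map, list(wedge_bins))] *= 2.0
        pmap = polar_resample(img, RING, GEO.center_px)
        for b in range(60):
            expected = 2.0 if b in wedge_bins else 1.0
            assert pmap.values[b] == pytest.approx(expected)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError, match="centre"):
            polar_resample(np.ones(GEO.shape), RING, (999.0, 0.0))


class TestAngularFilter:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        return PolarMap(values=values, missing=np.isnan(values), center_px=(0, 0))

    def test_full_circle_filter_reduces_to_global_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=60)
        out = spatiotemporal_filter(self._map(vals), 2 * math.pi)
        assert np.allclose(out.values, vals.mean())

    def test_one_bin_width_is_identity(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=60)
        out = spatiotemporal_filter(self._map(vals), 2 * math.pi / 60)
        assert np.allclose(out.values, vals)

    def test_impulse_response_is_flat_boxcar(self):
        vals = np.zeros(60)
        vals[0] = 1.0
        width = 10  # bins
        out = spatiotemporal_filter(self._map(vals), width * 2 * math.pi / 60)
        assert out.values.sum() == pytest.approx(1.0)
        assert (out.values > 0).sum() == width
        assert np.allclose(out.values[out.values > 0], 1.0 / width)
        # boxcar wraps around the 0 / 2*pi seam
        assert out.values[-1] > 0 or out.values[1] > 0

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            spatiotemporal_filter(self._map(np.zeros(60)), 0.0)

    def test_missing_bins_are_averaged_over_available_neighbours(self):
        vals = np.ones(60)
        vals[5] = np.nan
        out = spatiotemporal_filter(self._map(vals), 2 * math.pi / 6)
        assert np.allclose(out.values, 1.0)


class TestQuantifyMBF:
    def test_hand_computed_example(self):
        # 2*1000*1000*exp(-1000/1650) * 1.20/60000 = 21.82 signal units
        assert quantify_mbf(1021.82, 1000.0, 1000.0, 1000.0) == pytest.approx(
            1.2000, abs=1e-3
        )

    def test_equal_control_and_tag_gives_zero(self):
        assert quantify_mbf(500.0, 500.0, 1000.0, 983.6) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(dm=st.floats(0.1, 100.0), k=st.floats(0.1, 10.0))
    def test_linearity_in_signal_difference(self, dm, k):
        base = quantify_mbf(1000.0 + dm, 1000.0, 1000.0, 1000.0)
        scaled = quantify_mbf(1000.0 + k * dm, 1000.0, 1000.0, 1000.0)
        assert scaled == pytest.approx(k * base, rel=1e-9)

    def test_negative_values_pass_through_with_flag(self):
        mbf, flag = quantify_mbf(990.0, 1000.0, 1000.0, 1000.0, return_flag=True)
        assert mbf < 0 and bool(flag)

    def test_nonpositive_m0_rejected(self):
        with pytest.raises(ValueError, match="M0"):
            quantify_mbf(1.0, 0.0, 0.0, 1000.0)


class TestSegments:
    def test_noise_free_segments_all_equal_truth(self):
        series = simulate_series(
            ASLProtocol(), ASLTruth(mbf_true=1.20, motion_amplitude=0.0, thermal_sd=0.0)
        )
        result = mbf_segments(series, with_noise=False)
        assert result.global_mbf == pytest.approx(1.20, abs=1e-9)
        assert np.allclose(result.regional_mbf, 1.20, atol=1e-9)
        assert np.allclose(result.septal_mbf, 1.20, atol=1e-9)

    def test_septal_deficit_lowers_septal_segments_only(self):
        series = simulate_series(
            ASLProtocol(), ASLTruth(mbf_true=1.20, motion_amplitude=0.0, thermal_sd=0.0)
        )
        # halve the perfusion difference over the septal half of the ring
        # (angles pi/2 .. 3*pi/2, i.e. rows above the centre line)
        iy = np.indices(GEO.shape)[0]
        septal = RING & (iy < GEO.center_px[0])
        dm = series.controls[0] - series.tags[0]
        for p in range(len(series.tags)):
            series.tags[p][septal] += 0.5 * dm[septal]
        result = mbf_segments(series, with_noise=False)
        assert result.septal_mbf.max() < 1.0
        # lateral-most regional segments (angles near 0) stay at truth
        assert result.regional_mbf[0] == pytest.approx(1.20, rel=0.15)
        assert result.global_mbf < 1.20

    def test_single_pair_quantifies_but_noise_is_undefined(self):
        series = simulate_series(
            ASLProtocol(n_pairs=1),
            ASLTruth(mbf_true=1.0, motion_amplitude=0.0, thermal_sd=0.0),
        )
        result = mbf_segments(series)
        assert result.global_mbf == pytest.approx(1.0, abs=1e-9)
        assert result.pn is None and result.tn is None
        with pytest.raises(ValueError, match="at least 2"):
            estimate_noise(result, series)

    def test_segment_means_rotate_with_whole_segment_shifts(self):
        """Rotating the polar data by one regional segment permutes values."""
        series = simulate_series(
            ASLProtocol(), ASLTruth(mbf_true=1.0, motion_amplitude=0.0, thermal_sd=0.0)
        )
        idx_map = np.full(GEO.shape, -1)
        idx_map[RING] = _bin_index(GEO.shape, GEO.center_px, RING, 60)
        bump = np.isin(idx_map, list(range(0, 10)))
        shifted = np.isin(idx_map, list(range(10, 20)))
        a = [c.copy() for c in series.controls]
        for p in range(len(series.controls)):
            series.controls[p][bump] += 30.0
        r1 = mbf_segments(series, with_noise=False)
        for p in range(len(series.controls)):
            series.controls[p] = a[p]
            series.controls[p][shifted] += 30.0
        r2 = mbf_segments(series, with_noise=False)
        assert r2.regional_mbf[1] == pytest.approx(r1.regional_mbf[0], rel=1e-6)
        assert r2.regional_mbf[2] == pytest.approx(r1.regional_mbf[1], rel=1e-6)


class TestNoiseDecomposition:
    def _zero_noise_series(self):
        return simulate_series(
            ASLProtocol(), ASLTruth(mbf_true=1.0, motion_amplitude=0.0, thermal_sd=0.0)
        )

    def test_noise_free_series_has_zero_pn_and_tn(self):
        result = mbf_segments(self._zero_noise_series())
        assert result.pn == pytest.approx(0.0, abs=1e-12)
        assert result.tn == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pn_from_per_pair_values(self):
        series = self._zero_noise_series()
        result = MBFResult(
            global_mbf=1.0,
            regional_mbf=np.full(6, 1.0),
            septal_mbf=np.full(3, 1.0),
            per_pair_mbf=np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.0]),
        )
        pn, tn = estimate_noise(result, series)
        assert tn == 0.0
        assert pn == pytest.approx(0.028867513459, abs=1e-9)  # sd/sqrt(6)

    def test_pn_clamped_at_zero_when_thermal_dominates(self):
        series = simulate_series(
            ASLProtocol(), ASLTruth(mbf_true=1.0, motion_amplitude=0.0,
                                    thermal_sd=25.0, seed=4)
        )
        result = MBFResult(
            global_mbf=1.0,
            regional_mbf=np.full(6, 1.0),
            septal_mbf=np.full(3, 1.0),
            per_pair_mbf=np.full(6, 1.0),  # zero temporal variance
        )
        pn, tn = estimate_noise(result, series)
        assert tn > 0.0
        assert pn == 0.0

    def test_thermal_floor_matches_propagated_closed_form(self):
        """MC spread of the global estimate at zero motion vs the TN formula."""
        mbfs, tns = [], []
        for i in range(150):
            series = simulate_series(
                ASLProtocol(),
                ASLTruth(mbf_true=1.2, motion_amplitude=0.0, thermal_sd=25.0,
                         seed=3000 + i),
            )
            result = mbf_segments(series)
            mbfs.append(result.global_mbf)
            tns.append(result.tn)
        mc_sd = np.std(mbfs, ddof=1)
        assert np.mean(tns) == pytest.approx(mc_sd, rel=0.10)


def test_segment_bins_tile_the_requested_ranges():
    segs = _segment_bins(60, 6)
    assert sorted(b for s in segs for b in s) == list(range(60))
    septal = _segment_bins(60, 3, (math.pi / 2, 3 * math.pi / 2))
    covered = sorted(b for s in septal for b in s)
    assert len(covered) == 30
    assert all(len(s) == 10 for s in septal)
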