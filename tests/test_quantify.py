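"""Intensity quantification: crop geometries, background models,
classification, colocalization, and nucleus segmentation."""

import numpy as np
import pytest

from tnt.detect import Spot, Track
from tnt.quantify import (
    CropGeometry,
    SpotMeasurement,
    best_z_plane,
    best_z_trace,
    classify_spot,
    colocalization_fraction,
    fraction_translating,
    measure_spot,
    segment_nuclei,
)
from tnt.simulate import _render_emitter
from tnt.stack import ImageStack

ALL_GEOMETRIES = [CropGeometry.hilo_maxz(), CropGeometry.hilo_bestz(),
                  CropGeometry.confocal()]


def _meas(intensity, bg_sd=1.0, missing=False):
    return SpotMeasurement(intensity=intensity, central_mean=intensity,
                           background=0.0, background_sd=bg_sd,
                           missing=missing)


class TestMeasureSpot:
    @pytest.mark.parametrize("geom", ALL_GEOMETRIES)
    def test_flat_field_measures_zero(self, geom):
        img = np.full((64, 64), 37.2)
        m = measure_spot(img, (32.0, 32.0), geom)
        assert m.intensity == pytest.approx(0.0, abs=1e-12)
        assert m.background == pytest.approx(37.2)
        assert m.background_sd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("geom", ALL_GEOMETRIES)
    def test_constant_offset_invariance(self, geom):
        rng = np.random.default_rng(1)
        img = rng.normal(50.0, 3.0, (64, 64))
        m0 = measure_spot(img, (30.0, 33.0), geom)
        m1 = measure_spot(img + 123.0, (30.0, 33.0), geom)
        assert m1.intensity == pytest.approx(m0.intensity, abs=1e-9)
        assert m1.background == pytest.approx(m0.background + 123.0)

    @pytest.mark.parametrize("geom", ALL_GEOMETRIES)
    def test_linearity_in_amplitude(self, geom):
        vol = np.zeros((1, 64, 64))
        _render_emitter(vol, 32.0, 32.0, 0.0, 1000.0, 1.3, 1.0)
        m1 = measure_spot(vol[0] + 5.0, (32.0, 32.0), geom)
        m3 = measure_spot(3.0 * vol[0] + 5.0, (32.0, 32.0), geom)
        assert m3.intensity == pytest.approx(3.0 * m1.intensity, rel=1e-9)

    def test_gaussian_disc_recovers_central_mean(self):
        """For a centered Gaussian the disc-3 mean matches the analytic mean
        of the PSF over those pixels to 10%; far-corner quadrants see ~0."""
        sigma = 1.3
        vol = np.zeros((1, 64, 64))
        _render_emitter(vol, 32.0, 32.0, 0.0, 1000.0, sigma, 1.0)
        m = measure_spot(vol[0], (32.0, 32.0), CropGeometry.hilo_maxz())
        # disc of diameter 3: all offsets with hypot < 1.5 (diagonals included)
        disc_px = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
        from scipy.special import erf
        def pix(dx, dy):
            def cdf(u):
                return 0.5 * (1 + erf(u / (sigma * np.sqrt(2))))
            return 1000.0 * (cdf(dx + 0.5) - cdf(dx - 0.5)) \
                          * (cdf(dy + 0.5) - cdf(dy - 0.5))
        expected = np.mean([pix(dx, dy) for dx, dy in disc_px])
        assert m.background == pytest.approx(0.0, abs=1e-6)
        assert m.intensity == pytest.approx(expected, rel=0.10)

    def test_quadrant_median_rejects_bright_corner(self):
        """One contaminated corner does not shift the quadrant-median
        background (robustness the ring mean does not have)."""
        img = np.full((31, 31), 10.0)
        img[:3, :3] = 500.0  # a second particle in one corner quadrant
        m = measure_spot(img, (15.0, 15.0), CropGeometry.hilo_maxz())
        assert m.background == pytest.approx(10.0)

    def test_gradient_background_ring_tracks_local_mean(self):
        yy = np.arange(64, dtype=float)[:, None]
        img = np.broadcast_to(2.0 * yy, (64, 64)).copy()
        m = measure_spot(img, (32.0, 32.0), CropGeometry.hilo_bestz())
        # symmetric ring around row 32 averages to the central value
        assert m.background == pytest.approx(64.0, abs=1e-9)
        assert m.intensity == pytest.approx(0.0, abs=1e-9)

    def test_edge_crop_is_missing(self):
        img = np.ones((32, 32))
        m = measure_spot(img, (2.0, 16.0), CropGeometry.hilo_maxz())
        assert m.missing and np.isnan(m.intensity)

    def test_all_nan_crop_is_missing(self):
        img = np.full((32, 32), np.nan)
        assert measure_spot(img, (16.0, 16.0)).missing

    def test_geometry_validation(self):
        with pytest.raises(ValueError, match="odd"):
            CropGeometry(crop_size_px=14)
        with pytest.raises(ValueError, match="ring"):
            CropGeometry(crop_size_px=11, background_mode="ring",
                         ring_diameter_px=13)
        with pytest.raises(ValueError, match="background mode"):
            CropGeometry(background_mode="annulus2")


class TestBestZ:
    def test_picks_brightest_plane(self):
        vol = np.zeros((13, 33, 33))
        _render_emitter(vol, 16.0, 16.0, 8.0, 1000.0, 1.3, 1.4)
        assert best_z_plane(vol, (16.0, 16.0)) == 8

    def test_trace_uses_neighbor_projection_and_channel_times(self):
        """A 5-plane stack with two channels on a staggered clock: the trace
        measures only exposed frames and reports the right Z_best."""
        n_t, n_z = 4, 5
        data = np.full((n_t, n_z, 2, 33, 33), np.nan)
        times = [0.0, 10.0, 20.0, 30.0]
        for f in range(n_t):
            vol = np.zeros((n_z, 33, 33))
            _render_emitter(vol, 16.0, 16.0, 2.0, 1000.0, 1.3, 1.0)
            data[f, :, 0] = vol + 5.0
            if times[f] in (0.0, 20.0):  # slow channel exposed half the time
                data[f, :, 1] = 2.0 * vol + 5.0
        stack = ImageStack(data=data, channels=("mrna", "tether"),
                           frame_times_s=times,
                           channel_times_s={"mrna": times,
                                            "tether": [0.0, 20.0]})
        spots = [Spot(frame_index=f, channel="mrna", centroid_xy=(16.0, 16.0),
                      area_px=4, component_pixels=np.empty((0, 2)),
                      raw_peak=1.0) for f in range(n_t)]
        track = Track(track_id=0, times_s=list(times), spots=spots)
        traces = best_z_trace(stack, track)
        assert traces["mrna"].times_s == times
        assert traces["tether"].times_s == [0.0, 20.0]
        assert all(z == 2 for z in traces["mrna"].z_best)
        # tether signal is 2x the mRNA signal at shared times
        assert traces["tether"].intensity[0] == pytest.approx(
            2.0 * traces["mrna"].intensity[0], rel=1e-6)

    def test_trace_requires_three_planes(self):
        stack = ImageStack(data=np.zeros((1, 2, 1, 8, 8)), channels=("mrna",))
        with pytest.raises(ValueError, match="3 planes"):
            best_z_trace(stack, Track(track_id=0))


class TestClassification:
    def test_trivial_positive_and_negative(self):
        c = classify_spot({"tether": _meas(10.0, bg_sd=1.0),
                           "translation": _meas(0.5, bg_sd=1.0)})
        assert c.tethered and not c.translating

    def test_threshold_is_strict(self):
        assert not classify_spot({"tether": _meas(3.0, bg_sd=1.0)}).tethered
        assert classify_spot({"tether": _meas(3.0 + 1e-9, bg_sd=1.0)}).tethered

    def test_missing_channel_is_negative(self):
        c = classify_spot({"tether": SpotMeasurement.missing_value()})
        assert not c.tethered and not c.translating

    def test_high_snr_spots_classified_reliably(self):
        """SNR-10 particles on rendered noisy crops: >= 95% called positive,
        pure-background crops essentially never."""
        rng = np.random.default_rng(11)
        bg, gain = 10.0, 2.0
        peak = 10.0 * np.sqrt(bg)
        photons = peak * 2 * np.pi * 1.3**2
        pos = neg = 0
        n = 200
        for _ in range(n):
            vol = np.zeros((1, 31, 31))
            _render_emitter(vol, 15.0, 15.0, 0.0, photons, 1.3, 1.0)
            noisy = rng.poisson(vol[0] + bg) * gain
            blank = rng.poisson(np.full((31, 31), bg)) * gain
            geom = CropGeometry.hilo_maxz()
            pos += classify_spot(
                {"tether": measure_spot(noisy.astype(float), (15, 15), geom)}
            ).tethered
            neg += classify_spot(
                {"tether": measure_spot(blank.astype(float), (15, 15), geom)}
            ).tethered
        assert pos / n >= 0.95
        assert neg / n <= 0.05


class TestFractions:
    def test_fraction_translating_worked_example(self):
        cls = (
            [classify_spot({"tether": _meas(10.0), "translation": _meas(10.0)},
                           track_id=i) for i in range(6)]
            + [classify_spot({"tether": _meas(10.0), "translation": _meas(0.0)},
                             track_id=6 + i) for i in range(19)]
            + [classify_spot({"tether": _meas(0.0), "translation": _meas(10.0)},
                             track_id=100 + i) for i in range(5)]
        )
        assert fraction_translating(cls) == pytest.approx(6 / 25)
        assert fraction_translating(cls, scope="all") == pytest.approx(11 / 30)

    def test_empty_pool_is_none(self):
        assert fraction_translating([]) is None
        only_free = [classify_spot({"tether": _meas(0.0)})]
        assert fraction_translating(only_free) is None
        with pytest.raises(ValueError, match="scope"):
            fraction_translating([], scope="everything")

    def test_colocalization_mask_mode(self):
        mask = np.zeros((32, 32), bool)
        mask[:, :16] = True
        pts = [(4.0, 4.0), (8.0, 20.0), (24.0, 8.0)]  # 2 of 3 inside
        assert colocalization_fraction(pts, mask_b=mask) == pytest.approx(2 / 3)

    def test_colocalization_spot_mode_binomial(self):
        """Independent uniform B spots: expected colocalization ~ the area
        fraction covered by the 2-px discs."""
        rng = np.random.default_rng(3)
        a = rng.uniform(10, 246, (300, 2))
        b = rng.uniform(10, 246, (300, 2))
        frac = colocalization_fraction(a, spots_b=b, distance_threshold_px=2.0)
        p = 1.0 - (1.0 - np.pi * 4.0 / 256.0**2) ** 300  # ~0.056
        assert abs(frac - p) < 0.04

    def test_colocalization_empty_inputs(self):
        assert colocalization_fraction([], spots_b=[(1.0, 1.0)]) is None
        assert colocalization_fraction([(1.0, 1.0)], spots_b=[]) == 0.0


class TestSegmentNuclei:
    def _field(self):
        dna = np.zeros((128, 128))
        other = np.zeros((128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        # nucleus fully inside
        inside = np.hypot(yy - 40, xx - 40) < 12
        dna[inside] = 100.0
        other[inside] = 2.0
        # nucleus touching the border
        border = np.hypot(yy - 5, xx - 100) < 12
        dna[border] = 100.0
        # tiny debris
        dna[100:102, 100:102] = 100.0
        return dna, other, inside

    def test_border_and_small_objects_rejected(self):
        dna, other, inside = self._field()
        df = segment_nuclei(dna, other, threshold=50.0, min_area_px=50)
        assert len(df) == 1
        assert df.iloc[0]["area_px"] == inside.sum()
        assert df.iloc[0]["total_intensity"] == pytest.approx(2.0 * inside.sum())
        assert df.iloc[0]["x_px"] == pytest.approx(40.0, abs=0.5)

    def test_eccentric_object_rejected(self):
        dna = np.zeros((64, 64))
        dna[30:33, 10:54] = 100.0  # elongated streak
        df = segment_nuclei(dna, dna, threshold=50.0, min_area_px=10,
                            max_eccentricity=0.95)
        assert len(df) == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            segment_nuclei(np.zeros((8, 8)), np.zeros((9, 8)))
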