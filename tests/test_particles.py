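"""Program A: local-maxima detection, zone partition, zone densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmjquant as nq
from nmjquant.errors import ValidationError
from nmjquant.synthetic import NoiseModel

from conftest import match_particles


def _full_mask(shape) -> nq.BoutonMask:
    fp = np.ones(shape, bool)
    return nq.BoutonMask(
        1, fp, float(fp.sum() * nq.STED.pixel_area_um2), 0, (0, 0, *shape)
    )


def _stack(frame: np.ndarray) -> nq.CalibratedStack:
    return nq.CalibratedStack(frame[np.newaxis].astype(np.float32), nq.STED)


class TestDetectLocalMaxima:
    def test_constant_image_has_no_maxima(self):
        pset = nq.detect_local_maxima(
            _stack(np.full((32, 32), 50.0)), _full_mask((32, 32)), min_intensity=0
        )
        assert pset.n_total == 0

    def test_single_bright_pixel(self):
        frame = np.zeros((32, 32))
        frame[10, 12] = 100.0
        pset = nq.detect_local_maxima(
            _stack(frame), _full_mask((32, 32)), min_intensity=50
        )
        assert pset.n_total == 1
        y, x, v = pset.particles[0]
        assert (y, x, v) == (10, 12, 100.0)

    def test_below_threshold_rejected(self):
        frame = np.zeros((32, 32))
        frame[10, 12] = 40.0
        pset = nq.detect_local_maxima(
            _stack(frame), _full_mask((32, 32)), min_intensity=50
        )
        assert pset.n_total == 0

    def test_plateau_yields_one_particle_at_centroid(self):
        frame = np.zeros((32, 32))
        frame[10:12, 10:12] = 80.0  # 2x2 plateau, centroid (10.5, 10.5)
        pset = nq.detect_local_maxima(
            _stack(frame), _full_mask((32, 32)), min_intensity=10
        )
        assert pset.n_total == 1
        y, x, _ = pset.particles[0]
        assert (y, x) == (10, 10)  # rounded toward top-left

    def test_particles_respect_mask(self):
        frame = np.zeros((32, 32))
        frame[5, 5] = 100.0
        frame[20, 20] = 100.0
        fp = np.zeros((32, 32), bool)
        fp[:10, :10] = True
        mask = nq.BoutonMask(1, fp, 1.0, 0, (0, 0, 10, 10))
        pset = nq.detect_local_maxima(_stack(frame), mask, min_intensity=10)
        assert pset.n_total == 1
        assert tuple(pset.coords[0]) == (5, 5)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_threshold_monotonicity(self, seed):
        """Raising the intensity floor never increases the particle count."""
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 100, (24, 24))
        mask = _full_mask((24, 24))
        counts = [
            nq.detect_local_maxima(_stack(frame), mask, min_intensity=t).n_total
            for t in (0, 25, 50, 75, 101)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recovery_of_planted_puncta(self):
        """Well-separated planted puncta with peaks at 10x the noise s.d.
        are nearly all recovered within 1 px with no false positives."""
        sd = 3.0
        sigma_px = 60.0 / 27.5
        amp = 10 * sd * 2 * np.pi * sigma_px**2  # integrated -> peak = 10 sd
        matched = total = fps = 0
        for seed in range(4):
            truth = nq.make_zone_truth(
                2, 1.5, 1.5, area_range=(6, 10), seed=seed, amplitude=amp,
                min_spacing_px=8,
            )
            scene = nq.render_scene(
                truth, noise=NoiseModel(gaussian_sd=sd), background_level=20,
                seed=seed + 50,
            )
            segs = nq.segment_boutons(scene.channel("membrane"))
            for b in truth.boutons:
                m = max(segs, key=lambda s: (s.footprint & b.footprint).sum())
                pset = nq.detect_local_maxima(
                    scene.channel("vesicle"), m, min_intensity=20 + 5 * sd,
                    background_masks=segs, smooth_sigma_px=1.0,
                )
                mt, fp = match_particles(pset.particles, b.puncta[:, 1:3])
                matched += mt
                total += len(b.puncta)
                fps += fp
        assert matched / total >= 0.96
        assert fps <= 4  # <= 1 per scene


class TestPartitionZones:
    def test_small_disk_is_all_peripheral(self, disk_mask):
        # radius 150 nm < 200 nm band at STED calibration
        m = disk_mask(radius_px=150 / 27.5)
        zones = nq.partition_zones(m, nq.STED)
        assert zones.central_area_um2 == 0
        assert zones.peripheral_area_um2 == pytest.approx(m.area_um2)

    def test_annulus_closed_form(self, disk_mask):
        """Measured peripheral fraction of a disk matches the analytic
        annulus fraction 1 - ((R - 200 nm)/R)^2 within 2 pixel-rows."""
        for r_um in (0.5, 1.0, 2.0):
            r_px = r_um * 1000 / 27.5
            m = disk_mask(radius_px=r_px)
            zones = nq.partition_zones(m, nq.STED)
            frac = zones.peripheral_area_um2 / m.area_um2
            analytic = 1 - ((r_um - 0.2) / r_um) ** 2
            tol = 2 * (2 * np.pi * r_px) / m.n_pixels  # 2 rows of pixels
            assert abs(frac - analytic) <= tol

    def test_huge_band_is_all_peripheral(self, disk_mask):
        m = disk_mask()
        zones = nq.partition_zones(m, nq.STED, band_nm=1e9)
        np.testing.assert_array_equal(zones.peripheral, m.footprint)

    def test_partition_exact_on_random_masks(self, random_masks):
        """Peripheral + central pixel counts equal the footprint count,
        for every mask and band width."""
        for m in random_masks(10, seed=100):
            for band in (100.0, 200.0, 500.0):
                z = nq.partition_zones(m, nq.STED, band_nm=band)
                assert not (z.peripheral & z.central).any()
                assert (z.peripheral | z.central).sum() == m.n_pixels
                assert z.peripheral_area_um2 + z.central_area_um2 == pytest.approx(
                    m.area_um2
                )


class TestZoneDensity:
    def _pset(self, coords):
        arr = np.array([(y, x, 100.0) for y, x in coords]) if coords else np.empty((0, 3))
        return nq.ParticleSet(1, arr, {})

    def test_simple_arithmetic(self, disk_mask):
        m = disk_mask(radius_px=40)
        zones = nq.partition_zones(m, nq.STED)
        ys, xs = np.nonzero(zones.peripheral)
        pset = self._pset(list(zip(ys[:10], xs[:10])))
        d_per, d_cen = nq.zone_density(pset, zones)
        assert d_per == pytest.approx(10 / zones.peripheral_area_um2)
        assert d_cen == 0.0

    def test_empty_particles(self, disk_mask):
        zones = nq.partition_zones(disk_mask(), nq.STED)
        assert nq.zone_density(self._pset([]), zones) == (0.0, 0.0)

    def test_zero_area_central_is_nan_not_zero(self, disk_mask):
        m = disk_mask(radius_px=5)  # entirely inside the band
        zones = nq.partition_zones(m, nq.STED)
        _, d_cen = nq.zone_density(self._pset([]), zones)
        assert np.isnan(d_cen)

    def test_particle_outside_footprint_rejected(self, disk_mask):
        m = disk_mask(radius_px=10, pad=20)
        zones = nq.partition_zones(m, nq.STED)
        with pytest.raises(ValidationError):
            nq.zone_density(self._pset([(0, 0)]), zones)

    def test_uniform_field_flatness(self):
        """Uniform planting yields equal peripheral and central density
        estimates (within 3 s.e.), measured through the full detection
        path on segmented masks."""
        diffs = []
        for seed in range(30):
            truth = nq.make_zone_truth(1, 1.5, 1.5, area_range=(5, 9), seed=seed)
            scene = nq.render_scene(
                truth, noise=NoiseModel(gaussian_sd=3.0), seed=seed + 1000
            )
            segs = nq.segment_boutons(scene.channel("membrane"))
            m = segs[0]
            pset = nq.detect_local_maxima(
                scene.channel("vesicle"), m, min_intensity=20 + 5 * 3.0,
                background_masks=segs, smooth_sigma_px=1.0,
            )
            zones = nq.partition_zones(m, nq.STED)
            d_per, d_cen = nq.zone_density(pset, zones)
            if np.isfinite(d_per) and np.isfinite(d_cen):
                diffs.append(d_per - d_cen)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se
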