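"""Dose tallies, estimators, conversion chain and map analyses."""

import math

import numpy as np
import pytest

from scattershield import fixtures as F
from scattershield import tally as TA
from scattershield.materials import lookup_mu_en
from scattershield.transport import RunConfig, run_histories

from conftest import mono_spectrum


def make_tally(batch_data, masses=None, spacing=0.01, n_per_batch=None,
               kind="analog"):
    batch_data = np.asarray(batch_data, dtype=np.float64)
    nb = batch_data.shape[0]
    if n_per_batch is None:
        n_per_batch = np.ones(nb, dtype=int)
    return TA.TallyGrid(origin=np.zeros(3), spacing=np.full(3, spacing),
                        batch_data=batch_data, n_per_batch=np.asarray(n_per_batch),
                        kind=kind, voxel_mass_g=masses)


class TestDosePerPhoton:
    def test_unit_arithmetic(self):
        """1 keV into 1 g over 1 history = 1.602e-13 Gy."""
        t = make_tally(np.ones((1, 1, 1, 1)), masses=np.ones((1, 1, 1)))
        assert t.dose_per_photon((0, 0, 0)) == pytest.approx(1.602176634e-13)

    def test_zero_energy_zero_dose(self):
        t = make_tally(np.zeros((2, 1, 1, 1)), masses=np.ones((1, 1, 1)),
                       n_per_batch=[5, 5])
        assert t.dose_per_photon((0, 0, 0)) == 0.0

    def test_doubling_histories_halves_dose(self):
        data = np.ones((1, 1, 1, 1))
        masses = np.ones((1, 1, 1))
        d1 = make_tally(data, masses, n_per_batch=[10]).dose_per_photon((0, 0, 0))
        d2 = make_tally(data, masses, n_per_batch=[20]).dose_per_photon((0, 0, 0))
        assert d2 == pytest.approx(d1 / 2)

    def test_zero_mass_voxel_rejected(self):
        t = make_tally(np.ones((1, 1, 1, 1)), masses=np.zeros((1, 1, 1)))
        with pytest.raises(ValueError, match="mass"):
            t.dose_per_photon((0, 0, 0))


class TestDoseRateConversion:
    def test_worked_arithmetic(self):
        """1e-12 Gy/ph x 1e6 ph/mAs x 1.10 x 3 mA -> 1.188e4 uGy/h."""
        conv = TA.ConversionMeta(photons_per_mAs=1e6, mA=3.0,
                                 scaling_factor=1.10)
        assert TA.to_dose_rate(1e-12, conv) == pytest.approx(1.188e4, rel=1e-12)

    def test_unit_factors_only(self):
        conv = TA.ConversionMeta(photons_per_mAs=1.0, mA=1.0, scaling_factor=1.0)
        assert TA.to_dose_rate(1.0, conv) == pytest.approx(3600.0 * 1e6)

    def test_linear_in_current_and_factor(self):
        base = TA.ConversionMeta(photons_per_mAs=1e5, mA=2.0, scaling_factor=1.0)
        double_ma = TA.ConversionMeta(photons_per_mAs=1e5, mA=4.0,
                                      scaling_factor=1.0)
        double_sf = TA.ConversionMeta(photons_per_mAs=1e5, mA=2.0,
                                      scaling_factor=2.0)
        d = 3.3e-14
        assert TA.to_dose_rate(d, double_ma) == 2 * TA.to_dose_rate(d, base)
        assert TA.to_dose_rate(d, double_sf) == 2 * TA.to_dose_rate(d, base)

    def test_default_scaling_factor_is_published_value(self):
        conv = TA.ConversionMeta(photons_per_mAs=1e6)
        assert conv.scaling_factor == 1.10

    def test_missing_calibration_instructs(self):
        conv = TA.ConversionMeta(photons_per_mAs=1e6, scaling_factor=None)
        with pytest.raises(ValueError, match="calibration"):
            TA.to_dose_rate(1e-12, conv)


class TestTrackLengthScore:
    def test_segment_within_one_voxel(self):
        idx, contrib = TA.track_length_kerma_score(
            [0.012, 0.015, 0.011], [0.018, 0.013, 0.016], 60.0,
            np.zeros(3), np.full(3, 0.05), (4, 4, 4))
        assert len(idx) == 1
        seg = np.linalg.norm(np.array([0.018, 0.013, 0.016])
                             - np.array([0.012, 0.015, 0.011]))
        expected = 60.0 * lookup_mu_en("air", 60.0) * seg * 100
        assert contrib[0] == pytest.approx(expected, rel=1e-9)

    def test_axis_aligned_equal_chords(self):
        idx, contrib = TA.track_length_kerma_score(
            [0.025, 0.025, 0.0], [0.025, 0.025, 0.20], 60.0,
            np.zeros(3), np.full(3, 0.05), (4, 4, 4))
        assert len(idx) == 4
        assert np.allclose(contrib, contrib[0], rtol=1e-9)
        total_len = contrib.sum() / (60.0 * lookup_mu_en("air", 60.0) * 100)
        assert total_len == pytest.approx(0.20, rel=1e-9)

    def test_estimator_matches_analog_with_lower_variance(self, mono60):
        """Track-length kerma vs analog deposition in real-density air:
        same mean within 3 sigma, and at least 5x lower variance."""
        scene, src, _ = F.make_air_box(side_m=1.0, spacing_m=0.05,
                                       density_g_cm3=1.205e-3)
        res = run_histories(RunConfig(n_histories=150_000, n_batches=10, seed=4),
                            scene, mono60, src)
        air = TA.air_tally(res)
        from scattershield.tally import body_tally
        body = body_tally(res, scene)
        # compare over a shell region away from the source singularity
        centers = [air.origin[a] + (np.arange(air.dims[a]) + 0.5) * 0.05
                   for a in range(3)]
        R = np.sqrt(((centers[0] - 0.5) ** 2)[:, None, None]
                    + ((centers[1] - 0.5) ** 2)[None, :, None]
                    + ((centers[2] - 0.5) ** 2)[None, None, :])
        sel = np.abs(R - 0.3) < 0.05
        tl_b = air.batch_dose_per_photon()[:, sel].mean(axis=1)
        an_b = body.batch_dose_per_photon()[:, sel].mean(axis=1)
        nb = len(tl_b)
        diff = tl_b.mean() - an_b.mean()
        sig = math.hypot(tl_b.std(ddof=1), an_b.std(ddof=1)) / math.sqrt(nb)
        assert abs(diff) < 3 * sig
        # variance advantage (kerma vs analog energy-deposition noise)
        var_tl = air.batch_dose_per_photon()[:, sel].var(axis=0, ddof=1).mean()
        var_an = body.batch_dose_per_photon()[:, sel].var(axis=0, ddof=1).mean()
        assert var_an / var_tl >= 5.0


class TestRoiDoseRate:
    conv = TA.ConversionMeta(photons_per_mAs=1.0, mA=1.0, scaling_factor=1.0)

    def test_uniform_tally_mean_equals_voxel_sigma_zero(self):
        data = np.ones((4, 3, 3, 3))
        masses = np.full((3, 3, 3), 2.0)
        t = make_tally(data, masses, n_per_batch=[7] * 4)
        roi = np.zeros((3, 3, 3), dtype=bool)
        roi[1, 1, :] = True
        mean, sigma = TA.roi_dose_rate(t, roi, self.conv)
        single = TA.to_dose_rate(t.dose_per_photon((1, 1, 1)), self.conv)
        assert mean == pytest.approx(single, rel=1e-9)
        assert sigma == pytest.approx(0.0, abs=1e-12 * mean)

    def test_disjoint_union_is_mass_weighted(self):
        rng = np.random.default_rng(0)
        data = rng.random((5, 4, 4, 4))
        masses = rng.random((4, 4, 4)) + 0.5
        t = make_tally(data, masses, n_per_batch=[3] * 5)
        roi_a = np.zeros((4, 4, 4), dtype=bool)
        roi_b = np.zeros((4, 4, 4), dtype=bool)
        roi_a[0, :2] = True
        roi_b[2, 2:] = True
        m_a, _ = TA.roi_dose_rate(t, roi_a, self.conv)
        m_b, _ = TA.roi_dose_rate(t, roi_b, self.conv)
        m_u, _ = TA.roi_dose_rate(t, roi_a | roi_b, self.conv)
        w_a, w_b = masses[roi_a].sum(), masses[roi_b].sum()
        assert m_u == pytest.approx((m_a * w_a + m_b * w_b) / (w_a + w_b),
                                    rel=1e-9)

    def test_empty_mask_rejected(self):
        t = make_tally(np.ones((2, 2, 2, 2)), np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            TA.roi_dose_rate(t, np.zeros((2, 2, 2), dtype=bool), self.conv)

    def test_batch_sigma_close_to_bootstrap(self):
        """Between-batch SE agrees with a bootstrap over batches within 20%."""
        rng = np.random.default_rng(42)
        data = rng.gamma(2.0, 1.0, size=(10, 3, 3, 3))
        masses = np.ones((3, 3, 3))
        t = make_tally(data, masses, n_per_batch=[11] * 10)
        roi = np.ones((3, 3, 3), dtype=bool)
        _, sigma = TA.roi_dose_rate(t, roi, self.conv)
        batch_means = t.batch_dose_per_photon()[:, roi].mean(axis=1)
        boots = np.array([
            batch_means[rng.integers(0, 10, 10)].mean() for _ in range(4000)])
        sigma_boot = TA.to_dose_rate(boots.std(ddof=1), self.conv)
        assert sigma == pytest.approx(sigma_boot, rel=0.20)


class TestHeightSliceMap:
    conv = TA.ConversionMeta(photons_per_mAs=1.0, mA=1.0, scaling_factor=1.0)

    def test_lens_band_is_single_layer_on_5cm_grid(self):
        """With z = -0.2 m origin and 5 cm cells, 145-150 cm is layer 29."""
        data = np.ones((2, 4, 4, 68))
        t = TA.TallyGrid(origin=np.array([0, 0, -0.2]), spacing=np.full(3, 0.05),
                         batch_data=data, n_per_batch=np.array([1, 1]),
                         kind="air_kerma")
        _, layers = TA.height_slice_map(t, (145.0, 150.0), self.conv)
        assert list(layers) == [33]  # (1.45 - (-0.2)) / 0.05 = 33rd layer
        z_lo = -0.2 + 33 * 0.05
        assert z_lo == pytest.approx(1.45)

    def test_uniform_tally_constant_map(self):
        data = np.ones((2, 5, 6, 40))
        t = TA.TallyGrid(origin=np.zeros(3), spacing=np.full(3, 0.05),
                         batch_data=data, n_per_batch=np.array([1, 1]),
                         kind="air_kerma")
        m, _ = TA.height_slice_map(t, (80.0, 85.0), self.conv)
        assert m.shape == (5, 6)
        assert np.allclose(m, m[0, 0])

    def test_band_outside_grid_rejected(self):
        t = TA.TallyGrid(origin=np.zeros(3), spacing=np.full(3, 0.05),
                         batch_data=np.ones((2, 3, 3, 10)),
                         n_per_batch=np.array([1, 1]), kind="air_kerma")
        with pytest.raises(ValueError, match="band"):
            TA.height_slice_map(t, (300.0, 305.0), self.conv)


def test_collision_kerma_agrees_with_analog_dose(beam):
    """The collision-kerma estimator is unbiased for the analog dose.

    On well-scored water voxels the two estimators must agree within
    statistics; the kerma estimator must also be the quieter one in the
    thinly-hit skin-like periphery.
    """
    scene, src, _ = F.make_slab_scene("water", 10.0, spacing_cm=1.0,
                                      pencil=False)
    res = run_histories(RunConfig(n_histories=60_000, n_batches=10, seed=13),
                        scene, beam, src)
    analog = TA.body_tally(res, scene)
    kerma = TA.kerma_tally(res, scene)
    # geometric region (beam path through the slab): selecting voxels by
    # their analog score would bias the analog mean upward
    xs = scene.voxel_centers(0)
    ys = scene.voxel_centers(1)
    near_axis = (np.abs(xs)[:, None, None] < 0.04) \
        & (np.abs(ys)[None, :, None] < 0.04)
    region = (scene.materials > 0) & np.broadcast_to(near_axis, scene.dims)
    a_b = analog.batch_dose_per_photon()[:, region].mean(axis=1)
    k_b = kerma.batch_dose_per_photon()[:, region].mean(axis=1)
    nb = len(a_b)
    diff = a_b.mean() - k_b.mean()
    sig = math.hypot(a_b.std(ddof=1), k_b.std(ddof=1)) / math.sqrt(nb)
    assert abs(diff) < max(3 * sig, 0.02 * a_b.mean())


def test_analog_sum_matches_transport_ledger(mono60):
    """Sum of analog voxel deposits equals the engine's deposited energy."""
    scene, src, _ = F.make_slab_scene("water", 8.0, spacing_cm=1.0,
                                      pencil=False)
    res = run_histories(RunConfig(n_histories=30_000, n_batches=5, seed=9),
                        scene, mono60, src)
    for b in range(5):
        assert res.body_batches[b].sum(dtype=np.float64) == \
            pytest.approx(res.deposited[b], rel=1e-6)


def test_contour_area_above():
    m = np.zeros((10, 10))
    m[:3, :4] = 60.0
    assert TA.contour_area_above(m, (0.05, 0.05), 50.0) == \
        pytest.approx(12 * 0.0025)
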