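"""Phantom simulator: geometry rasterization, dilution table, dipole physics,
signal synthesis, noise statistics, and the in-vivo-like variant."""

import math

import numpy as np
import pytest

from spiolocate.config import PhantomConfig, RunConfig
from spiolocate.core import AcquisitionProtocol, ValidationError
from spiolocate.phantom import (
    CELLS_TO_UM_TABLE,
    ContrastModel,
    InlaySpec,
    NoiseSpec,
    PhantomSpec,
    apply_rigid_misalignment,
    build_invivo_like_spec,
    build_block_phantom_spec,
    build_phantom_truth,
    cells_to_concentration,
    dipole_phase_field,
    protocol_from_config,
    synthesize_dataset,
)
from spiolocate.pipeline import simulate_phantom
from spiolocate.registration import RigidTransform


class TestCellsToConcentration:
    @pytest.mark.parametrize("cells,um", CELLS_TO_UM_TABLE)
    def test_dilution_series_pairs(self, cells, um):
        assert cells_to_concentration(cells) == pytest.approx(um)

    def test_zero_density(self):
        assert cells_to_concentration(0.0) == 0.0

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            cells_to_concentration(-1.0)

    def test_analytic_mode_is_approximate(self):
        # 30 cells/mm^3 * 90 pg / M(Fe2O3) ~ 16.9 uM, deliberately not 19
        c = cells_to_concentration(30.0, ContrastModel(), mode="analytic")
        assert c == pytest.approx(30 * 90 / 159.69, rel=1e-9)
        assert c != pytest.approx(19.0, rel=0.05)


class TestPhantomTruth:
    def test_default_block_has_five_dilution_steps(self, noiseless_phantom):
        spec, truth, _, _ = noiseless_phantom
        concs = sorted(np.unique(truth.concentration.data))
        assert concs == [0.0, 19.0, 38.0, 78.0, 156.0, 313.0]
        assert sorted(np.unique(truth.inlay_labels)) == [0, 1, 2, 3, 4, 5]

    def test_zero_inlays_gives_empty_truth(self, tiny_protocol):
        spec = PhantomSpec(block_size=(8, 8, 5), block_center=(4.8, 4.8, 3.2))
        truth = build_phantom_truth(spec, tiny_protocol)
        assert not truth.positive_mask.data.any()
        assert truth.inlay_labels.max() == 0

    def test_cylinder_voxel_count_matches_analytic_volume(self):
        protocol = AcquisitionProtocol(
            [2.54, 3.78], 200, 25, 4.7, [0.4] * 3, [40, 40, 30]
        )
        spec = PhantomSpec(
            block_size=(14, 14, 10),
            block_center=(8, 8, 6),
            inlays=[InlaySpec((8, 8, 6), radius=5.0, height=8.0, cell_density=30, iron_concentration=19)],
        )
        truth = build_phantom_truth(spec, protocol)
        expected = math.pi * 5.0**2 * 8.0 / 0.4**3
        assert truth.positive_mask.count() == pytest.approx(expected, rel=0.05)

    def test_inlay_outside_block_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            PhantomSpec(
                block_size=(8, 8, 8),
                block_center=(4, 4, 4),
                inlays=[InlaySpec((1, 4, 4), 2.0, 2.0, 30, 19)],
            )

    def test_overlapping_inlays_rejected(self):
        with pytest.raises(ValidationError, match="disjoint"):
            PhantomSpec(
                block_size=(20, 20, 10),
                block_center=(10, 10, 5),
                inlays=[
                    InlaySpec((8, 10, 5), 3.0, 4.0, 30, 19),
                    InlaySpec((11, 10, 5), 3.0, 4.0, 60, 38),
                ],
            )


class TestDipoleField:
    def test_linear_in_echo_time(self, noiseless_phantom, noiseless_run_cfg):
        _, truth, _, contrast = noiseless_phantom
        model = ContrastModel()
        f1 = dipole_phase_field(truth, model, contrast.protocol, 2.54)
        f2 = dipole_phase_field(truth, model, contrast.protocol, 11.34)
        assert np.allclose(f2.data, f1.data * (11.34 / 2.54), atol=1e-10)

    def test_linear_in_concentration(self, noiseless_phantom):
        _, truth, _, contrast = noiseless_phantom
        f1 = dipole_phase_field(truth, ContrastModel(susceptibility_per_concentration=1e-3), contrast.protocol, 3.78)
        f2 = dipole_phase_field(truth, ContrastModel(susceptibility_per_concentration=2e-3), contrast.protocol, 3.78)
        assert np.allclose(f2.data, 2.0 * f1.data, atol=1e-10)

    def test_volume_mean_is_zero(self, noiseless_phantom):
        _, truth, _, contrast = noiseless_phantom
        f = dipole_phase_field(truth, ContrastModel(), contrast.protocol, 3.78)
        assert abs(f.data.mean()) < 1e-10 * np.abs(f.data).max()

    def test_point_source_angular_ratio(self):
        """On-axis vs equatorial field of a point source has the analytic
        dipole ratio 2 : -1 (angular factor 3cos^2(theta) - 1)."""
        protocol = AcquisitionProtocol(
            [2.54, 3.78], 200, 25, 4.7, [0.4] * 3, [48, 48, 48]
        )
        from spiolocate.core import MaskVolume, ScalarVolume
        from spiolocate.phantom import PhantomTruth

        conc = np.zeros((48, 48, 48))
        conc[24, 24, 24] = 100.0
        truth = PhantomTruth(
            ScalarVolume(conc, protocol.voxel_size),
            (conc > 0).astype(np.int32),
            MaskVolume(conc > 0, protocol.voxel_size),
        )
        f = dipole_phase_field(truth, ContrastModel(), protocol, 3.78).data
        r = 6  # voxels from the source
        on_axis = 0.5 * (f[24, 24, 24 + r] + f[24, 24, 24 - r])
        equatorial = 0.25 * (
            f[24 + r, 24, 24] + f[24 - r, 24, 24] + f[24, 24 + r, 24] + f[24, 24 - r, 24]
        )
        assert on_axis / equatorial == pytest.approx(-2.0, rel=0.05)


class TestSynthesis:
    def test_zero_noise_zero_concentration_matches_baseline(self, tiny_protocol):
        spec = PhantomSpec(block_size=(8, 8, 5), block_center=(4.8, 4.8, 3.2))
        truth = build_phantom_truth(spec, tiny_protocol)
        base, contrast = synthesize_dataset(
            truth, spec, ContrastModel(), tiny_protocol, NoiseSpec(0.0, seed=0)
        )
        for b, c in zip(base.magnitude + base.phase_wrapped, contrast.magnitude + contrast.phase_wrapped):
            assert np.array_equal(b.data, c.data)

    def test_noiseless_decay_is_monoexponential(self, noiseless_phantom, noiseless_run_cfg):
        _, truth, _, contrast = noiseless_phantom
        te = contrast.protocol.echo_times_s
        r = noiseless_run_cfg.phantom.r2star_relaxivity
        bg = noiseless_run_cfg.phantom.background_r2star
        for lab, conc in [(1, 313.0), (3, 78.0), (5, 19.0)]:
            sel = truth.inlay_labels == lab
            m = np.stack([v.data[sel] for v in contrast.magnitude])
            expected_r2s = bg + r * conc
            est = np.log(m[0] / m[2]) / (te[2] - te[0])
            assert np.allclose(est, expected_r2s, rtol=1e-6)

    def test_log_magnitude_linear_in_te(self, noiseless_phantom):
        _, truth, _, contrast = noiseless_phantom
        te = contrast.protocol.echo_times_s
        logs = np.stack([np.log(np.maximum(v.data, 1e-30)) for v in contrast.magnitude], axis=-1)
        block = contrast.magnitude[0].data > 1.0  # inside the agarose
        slope01 = (logs[..., 1] - logs[..., 0]) / (te[1] - te[0])
        slope02 = (logs[..., 2] - logs[..., 0]) / (te[2] - te[0])
        assert np.allclose(slope01[block], slope02[block], rtol=1e-9)

    def test_background_magnitude_matches_rician_mean(self):
        """Mean background magnitude agrees with a Monte-Carlo Rician oracle."""
        cfg = RunConfig(seed=5)
        cfg.phantom.noise_sigma = 0.05
        spec, truth, _, contrast = simulate_phantom(cfg)
        bg = (truth.inlay_labels == 0) & (contrast.magnitude[0].data > 50)
        te1 = contrast.protocol.echo_times_s[0]
        A = spec.background_proton_density * math.exp(-spec.background_r2star * te1)
        sigma = 0.05 * A
        rng = np.random.default_rng(123)
        draws = np.abs(A + sigma * (rng.standard_normal(10**5) + 1j * rng.standard_normal(10**5)))
        assert contrast.magnitude[0].data[bg].mean() == pytest.approx(draws.mean(), rel=0.03)

    def test_seeded_synthesis_is_bit_identical(self, tiny_protocol):
        spec = PhantomSpec(
            block_size=(8, 8, 5),
            block_center=(4.8, 4.8, 3.2),
            inlays=[InlaySpec((4.8, 4.8, 3.2), 2.0, 2.4, 120, 78)],
        )
        truth = build_phantom_truth(spec, tiny_protocol)
        out1 = synthesize_dataset(truth, spec, ContrastModel(), tiny_protocol, NoiseSpec(0.05, seed=9))
        out2 = synthesize_dataset(truth, spec, ContrastModel(), tiny_protocol, NoiseSpec(0.05, seed=9))
        for ds1, ds2 in zip(out1, out2):
            for a, b in zip(ds1.magnitude + ds1.phase_wrapped, ds2.magnitude + ds2.phase_wrapped):
                assert np.array_equal(a.data, b.data)
        out3 = synthesize_dataset(truth, spec, ContrastModel(), tiny_protocol, NoiseSpec(0.05, seed=10))
        assert not np.array_equal(out1[1].magnitude[0].data, out3[1].magnitude[0].data)


class TestMisalignment:
    def test_identity_transform_is_identity(self, noiseless_phantom):
        _, _, baseline, _ = noiseless_phantom
        moved = apply_rigid_misalignment(baseline, RigidTransform())
        assert np.allclose(moved.magnitude[0].data, baseline.magnitude[0].data, atol=1e-9)

    def test_integer_voxel_shift_is_exact(self, noiseless_phantom):
        _, _, baseline, _ = noiseless_phantom
        t = RigidTransform(translation=(0.8, 0.0, 0.0))  # 2 voxels along x
        from spiolocate.registration import resample_dataset

        moved = resample_dataset(baseline, t, mode="nearest")
        orig = baseline.magnitude[0].data
        assert np.allclose(moved.magnitude[0].data[2:], orig[:-2], atol=1e-9)

    def test_subvoxel_shift_roundtrip_bounded_by_interp_error(self, noiseless_phantom):
        _, _, baseline, _ = noiseless_phantom
        t = RigidTransform(translation=(1.0, 0.0, 0.0))  # 2.5 voxels
        moved = apply_rigid_misalignment(baseline, t)
        back = apply_rigid_misalignment(moved, t.inverse())
        orig = baseline.magnitude[0].data
        interior = np.s_[6:-6, 6:-6, 3:-3]
        err = np.abs(back.magnitude[0].data - orig)
        assert err[interior].max() < 0.02 * np.ptp(orig)


class TestInvivoLikeSpec:
    def test_has_low_density_confounders_without_iron(self):
        spec = build_invivo_like_spec(seed=4)
        low = [r for r in spec.low_density_regions if r.pd_multiplier <= 0.1]
        assert len(low) >= 2

    def test_two_inlays_in_distinct_half_spaces(self):
        spec = build_invivo_like_spec(seed=4)
        assert len(spec.inlays) == 2
        cfg = PhantomConfig()
        mid = spec.block_center[1]
        ys = sorted(i.center[1] for i in spec.inlays)
        assert ys[0] < mid < ys[1]
        assert spec.inlays[0].iron_concentration != spec.inlays[1].iron_concentration

    def test_same_seed_same_spec(self):
        assert build_invivo_like_spec(seed=4) == build_invivo_like_spec(seed=4)
        assert build_invivo_like_spec(seed=4) != build_invivo_like_spec(seed=5)


def test_confounder_regions_mimic_iron_in_magnitude_but_not_phase():
    """Low-proton-density regions show low signal and elevated apparent R2*
    but near-zero short-range phase perturbation — the discriminative premise."""
    cfg = RunConfig(seed=6)
    cfg.phantom.kind = "invivo-like"
    spec, truth, baseline, contrast = simulate_phantom(cfg)
    from spiolocate.magnitude import compute_voi, fit_r2star
    from spiolocate.phase import short_range_perturbations, unwrap_phase_3d

    protocol = contrast.protocol
    X, Y, Z = np.meshgrid(*[np.arange(n) * 0.4 for n in protocol.matrix_size], indexing="ij")
    conf = np.zeros(contrast.shape, dtype=bool)
    for reg in spec.low_density_regions:
        d2 = (X - reg.center[0]) ** 2 + (Y - reg.center[1]) ** 2 + (Z - reg.center[2]) ** 2
        conf |= d2 <= (reg.radius - 0.4) ** 2
    block = contrast.magnitude[0].data > 0.3 * np.median(contrast.magnitude[0].data)
    bg = block & ~conf & (truth.inlay_labels == 0)

    mag = contrast.magnitude[0].data
    assert mag[conf].mean() < 0.3 * mag[bg].mean()

    voi = compute_voi(contrast.magnitude[0])
    r2map = fit_r2star(contrast, noise_floor=0.0)
    assert np.median(r2map.r2star.data[conf]) > 1.3 * np.median(r2map.r2star.data[bg])

    # the phase inside a signal void is noise; the reliability screen flags it
    from scipy import ndimage
    from spiolocate.phase import unwrap_dataset, unreliable_phase_mask

    unwrapped = unwrap_dataset(contrast, voi)
    unrel = unreliable_phase_mask(unwrapped, protocol, mask=voi)
    assert unrel.data[conf].mean() > 0.8
    interior_bg = ndimage.binary_erosion(bg, np.ones((3, 3, 3)), 2)
    # voxels whose smoothing neighborhood touches a signal void legitimately
    # lose their local intercept reference; judge the clean interior
    interior_bg &= ~ndimage.binary_dilation(conf, np.ones((3, 3, 3)), 3)
    assert unrel.data[interior_bg].mean() < 0.05

    # no organized short-range perturbation surrounds a confounder, unlike an
    # iron inlay whose dipole halo extends into the reliable tissue around it
    s = short_range_perturbations(unwrapped.phase[1], voi).s.data
    struct = np.ones((3, 3, 3), dtype=bool)
    good = voi.data & ~unrel.data
    conf_shell = ndimage.binary_dilation(conf, struct, 2) & ~conf & good
    inlay_shell = (
        ndimage.binary_dilation(truth.positive_mask.data, struct, 2)
        & ~truth.positive_mask.data
        & good
    )
    assert np.abs(s[conf_shell]).mean() < 0.5 * np.abs(s[inlay_shell]).mean()
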