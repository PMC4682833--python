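"""Phase features: unwrapping (with Itoh and library cross-check oracles),
reliability screening, band-pass s-map, source localization, p-map."""

import numpy as np
import pytest
from scipy import ndimage

from spiolocate.core import (
    AcquisitionProtocol,
    MaskVolume,
    ScalarVolume,
    ValidationError,
    wrap_to_pi,
)
from spiolocate.phantom import (
    ContrastModel,
    InlaySpec,
    NoiseSpec,
    PhantomSpec,
    build_phantom_truth,
    dipole_phase_field,
    synthesize_dataset,
)
from spiolocate.phase import (
    PerturbationMap,
    UnwrappedPhaseSet,
    band_pass,
    localize_sources,
    perturbation_propagation,
    short_range_perturbations,
    unreliable_phase_mask,
    unwrap_dataset,
    unwrap_phase_3d,
    wrapped_phase,
)

TE3 = [2.54, 3.78, 11.34]


def _protocol(shape):
    return AcquisitionProtocol(TE3, 200, 25, 4.7, [0.4] * 3, list(shape))


class TestWrappedPhase:
    @pytest.mark.parametrize(
        "re,im,expected",
        [(1.0, 0.0, 0.0), (0.0, -1.0, -np.pi / 2), (0.0, 1.0, np.pi / 2)],
    )
    def test_quadrants(self, re, im, expected):
        out = wrapped_phase(np.array([[[re + 1j * im]]]))
        assert out[0, 0, 0] == pytest.approx(expected)

    def test_branch_cut_sides(self):
        near_pi = wrapped_phase(np.array([[[-1.0 + 1e-12j]]]))[0, 0, 0]
        near_minus_pi = wrapped_phase(np.array([[[-1.0 - 1e-12j]]]))[0, 0, 0]
        assert near_pi == pytest.approx(np.pi, abs=1e-9) and near_pi < np.pi
        assert near_minus_pi == pytest.approx(-np.pi, abs=1e-9)

    def test_dataset_roundtrip(self, noiseless_phantom):
        _, _, _, contrast = noiseless_phantom
        out = wrapped_phase(contrast)
        signal = contrast.magnitude[1].data > 0  # zero-magnitude phase is undefined
        assert np.allclose(
            out[1].data[signal], contrast.phase_wrapped[1].data[signal], atol=1e-12
        )


class TestUnwrap:
    def test_wrap_free_field_is_identity_up_to_constant(self):
        rng = np.random.default_rng(0)
        smooth = ndimage.gaussian_filter(rng.standard_normal((16, 16, 10)), 4)
        smooth *= 2.5 / np.abs(smooth).max()  # |phi| < pi, no wraps
        vol = ScalarVolume(smooth)
        out = unwrap_phase_3d(vol)
        diff = out.data - smooth
        assert np.allclose(diff, diff.flat[0], atol=1e-9)
        assert np.isclose(diff.flat[0] % (2 * np.pi), 0, atol=1e-9) or np.isclose(
            diff.flat[0] % (2 * np.pi), 2 * np.pi, atol=1e-9
        )

    def test_linear_ramp_matches_itoh_oracle(self):
        """~3 wraps of a 0.5 rad/voxel ramp recovered against 1D path
        integration of wrapped differences."""
        ramp = 0.5 * np.arange(40)
        wrapped = wrap_to_pi(ramp)
        # Itoh oracle: cumulative sum of wrapped first differences
        oracle = np.concatenate([[wrapped[0]], wrapped[0] + np.cumsum(wrap_to_pi(np.diff(wrapped)))])
        vol = ScalarVolume(np.tile(wrapped[:, None, None], (1, 4, 3)))
        out = unwrap_phase_3d(vol)
        rec = out.data[:, 0, 0]
        rec = rec - 2 * np.pi * np.round((rec[0] - oracle[0]) / (2 * np.pi))
        assert np.max(np.abs(rec - oracle)) < 1e-9
        assert np.max(np.abs(rec - ramp)) < 1e-9

    def test_simulated_dipole_phase_recovered(self):
        """Wrapped dipole phase peaking at ~2.5 pi around a strong smooth
        source unwraps to the simulator's pre-wrap truth (modulo one global
        offset).  A smooth (Gaussian) source keeps the inter-voxel gradients
        below pi, which a sharp inlay boundary at this strength would not."""
        from spiolocate.phantom import PhantomTruth

        protocol = _protocol((32, 32, 24))
        conc = np.zeros((32, 32, 24))
        conc[16, 16, 12] = 9e5
        conc = ndimage.gaussian_filter(conc, 2.5)
        truth = PhantomTruth(
            ScalarVolume(conc, protocol.voxel_size),
            (conc > 1e-9).astype(np.int32),
            MaskVolume(conc > 1e-9, protocol.voxel_size),
        )
        true_phase = dipole_phase_field(truth, ContrastModel(), protocol, 3.78).data
        peak = np.abs(true_phase).max()
        assert 2.0 * np.pi < peak < 3.5 * np.pi  # the intended regime
        grads = [np.abs(np.diff(true_phase, axis=a)).max() for a in range(3)]
        assert max(grads) < np.pi  # recoverable (no aliasing)
        out = unwrap_phase_3d(ScalarVolume(wrap_to_pi(true_phase)))
        err = out.data - true_phase
        err -= 2 * np.pi * np.round(np.median(err) / (2 * np.pi))
        assert np.max(np.abs(err)) < 1e-6

    def test_congruence_with_input_mod_2pi(self, noiseless_phantom):
        _, _, _, contrast = noiseless_phantom
        mask = MaskVolume(contrast.magnitude[0].data > 1.0, contrast.magnitude[0].voxel_size)
        out = unwrap_phase_3d(contrast.phase_wrapped[1], contrast.magnitude[1], mask)
        d = (out.data - contrast.phase_wrapped[1].data)[mask.data]
        assert np.max(np.abs(d - 2 * np.pi * np.round(d / (2 * np.pi)))) < 1e-6

    def test_agrees_with_library_unwrapper(self):
        """Independent cross-check against scikit-image's 3D unwrapper on a
        smooth multi-wrap field."""
        from skimage.restoration import unwrap_phase as sk_unwrap

        rng = np.random.default_rng(3)
        smooth = ndimage.gaussian_filter(rng.standard_normal((20, 20, 12)), 5)
        smooth *= 12.0 / np.abs(smooth).max()  # several wraps
        wrapped = wrap_to_pi(smooth)
        ours = unwrap_phase_3d(ScalarVolume(wrapped)).data
        theirs = np.asarray(sk_unwrap(wrapped))
        for rec in (ours, theirs):
            err = rec - smooth
            err -= 2 * np.pi * np.round(np.median(err) / (2 * np.pi))
            assert np.max(np.abs(err)) < 1e-6

    def test_empty_mask_rejected(self):
        vol = ScalarVolume(np.zeros((4, 4, 4)))
        with pytest.raises(ValidationError):
            unwrap_phase_3d(vol, mask=MaskVolume(np.zeros((4, 4, 4), bool)))


class TestUnreliablePhase:
    def _uniform_noise_set(self, n, seed=0):
        rng = np.random.default_rng(seed)
        shape = (n, 10, 10)
        vols = [ScalarVolume(rng.uniform(-np.pi, np.pi, shape)) for _ in TE3]
        return UnwrappedPhaseSet(vols, tuple(TE3))

    def test_linear_phase_voxel_is_reliable(self):
        shape = (6, 6, 4)
        vols = [ScalarVolume(np.full(shape, 0.1 + 0.05 * te)) for te in TE3]
        protocol = _protocol(shape)
        mask = unreliable_phase_mask(UnwrappedPhaseSet(vols, tuple(TE3)), protocol)
        assert not mask.data.any()

    def test_noise_dominated_voxels_flagged(self):
        """Monte-Carlo: i.i.d. uniform phase voxels flagged with P > 0.99."""
        protocol = _protocol((100, 10, 10))
        mask = unreliable_phase_mask(self._uniform_noise_set(100, seed=2), protocol)
        assert mask.data.mean() > 0.99

    def test_offset_intercept_flagged(self):
        shape = (7, 7, 5)
        base = [np.full(shape, 0.2 + 0.04 * te) for te in TE3]
        for b in base:
            b[3, 3, 2] += 1.0  # 1 rad intercept offset vs flat neighborhood
        vols = [ScalarVolume(b) for b in base]
        protocol = _protocol(shape)
        mask = unreliable_phase_mask(UnwrappedPhaseSet(vols, tuple(TE3)), protocol)
        assert mask.data[3, 3, 2]
        assert mask.data.sum() == 1

    def test_requires_three_echoes(self):
        vols = [ScalarVolume(np.zeros((4, 4, 4)))] * 2
        protocol = AcquisitionProtocol([2.54, 3.78], 200, 25, 4.7, [0.4] * 3, [4, 4, 4])
        with pytest.raises(ValidationError):
            unreliable_phase_mask(UnwrappedPhaseSet(vols, (2.54, 3.78)), protocol)


class TestBandPass:
    def test_constant_phase_maps_to_zero(self):
        vol = ScalarVolume(np.full((16, 16, 12), 1.3))
        s = band_pass(vol, None)
        assert np.abs(s.data).max() < 1e-10

    def test_long_ramp_suppressed(self):
        x = np.arange(64)
        ramp = np.tile((x / 64.0)[:, None, None], (1, 8, 8))  # period >> 10 voxels
        s = band_pass(ScalarVolume(ramp), None)
        interior = s.data[8:-8]
        assert np.abs(interior).max() < 0.02 * np.ptp(ramp)

    def test_idempotence_within_one_percent_rms(self):
        rng = np.random.default_rng(4)
        vol = ScalarVolume(rng.standard_normal((24, 24, 16)))
        once = band_pass(vol, None)
        twice = band_pass(once, None)
        rms = np.sqrt(np.mean(once.data**2))
        assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 0.01 * rms

    def test_inverted_band_rejected(self):
        vol = ScalarVolume(np.zeros((8, 8, 8)))
        with pytest.raises(ValidationError):
            band_pass(vol, None, low_period=2.0, high_period=10.0)

    def test_s_map_correlates_with_filtered_true_dipole(self):
        """s computed from the synthesized wrapped data correlates > 0.9 with
        the band-pass of the ground-truth dipole phase in the source shell."""
        protocol = _protocol((32, 32, 24))
        spec = PhantomSpec(
            block_size=(12.4, 12.4, 9.2),
            block_center=(6.2, 6.2, 4.7),
            inlays=[InlaySpec((6.2, 6.2, 4.7), 1.2, 2.0, 480, 313)],
        )
        truth = build_phantom_truth(spec, protocol)
        model = ContrastModel()
        _, contrast = synthesize_dataset(truth, spec, model, protocol, NoiseSpec(0.0, 0))
        voi = MaskVolume(contrast.magnitude[0].data > 1.0, (0.4,) * 3)
        unwrapped = unwrap_phase_3d(contrast.phase_wrapped[1], contrast.magnitude[1], voi)
        s = short_range_perturbations(unwrapped, voi).s.data

        true_dipole = dipole_phase_field(truth, model, protocol, 3.78)
        oracle = band_pass(true_dipole, voi).data

        shell = ndimage.binary_dilation(truth.positive_mask.data, np.ones((3, 3, 3)), 5)
        sel = shell & voi.data
        corr = np.corrcoef(s[sel], oracle[sel])[0, 1]
        assert corr > 0.9


class TestLocalizeSources:
    def test_zero_map_gives_empty_list(self):
        s = PerturbationMap(ScalarVolume(np.zeros((8, 8, 8))), 3.78)
        assert localize_sources(s, threshold=0.1) == []

    def _phantom_s_map(self, centers):
        protocol = _protocol((64, 64, 24))
        spec = PhantomSpec(
            block_size=(24.8, 24.8, 9.2),
            block_center=(12.6, 12.6, 4.7),
            inlays=[InlaySpec(c, 1.2, 2.0, 480, 313) for c in centers],
        )
        truth = build_phantom_truth(spec, protocol)
        model = ContrastModel()
        _, contrast = synthesize_dataset(truth, spec, model, protocol, NoiseSpec(0.0, 0))
        voi = MaskVolume(contrast.magnitude[0].data > 1.0, (0.4,) * 3)
        unwrapped = unwrap_phase_3d(contrast.phase_wrapped[1], contrast.magnitude[1], voi)
        return short_range_perturbations(unwrapped, voi), truth

    def test_single_inlay_centroid_within_one_voxel(self):
        center = (12.8, 12.8, 4.8)
        s_map, _ = self._phantom_s_map([center])
        sources = localize_sources(s_map, threshold=0.3)
        assert len(sources) == 1
        assert np.linalg.norm(np.asarray(sources[0].centroid) - center) < 0.4

    def test_two_separated_inlays_give_two_sources(self):
        centers = [(12.8, 6.4, 4.8), (12.8, 19.2, 4.8)]  # 32 voxels apart
        s_map, _ = self._phantom_s_map(centers)
        sources = localize_sources(s_map, threshold=0.3)
        assert len(sources) == 2
        found = sorted(s.centroid[1] for s in sources)
        assert found[0] == pytest.approx(6.4, abs=0.8)
        assert found[1] == pytest.approx(19.2, abs=0.8)


class TestPropagation:
    def _unwrapped_pair(self, spec, protocol, noise=0.0, seed=0):
        truth = build_phantom_truth(spec, protocol)
        base, contrast = synthesize_dataset(
            truth, spec, ContrastModel(), protocol, NoiseSpec(noise, seed)
        )
        voi = MaskVolume(base.magnitude[0].data > 1.0, (0.4,) * 3)
        return unwrap_dataset(contrast, voi), unwrap_dataset(base, voi), voi, truth

    def test_identical_sets_give_zero_map(self, noiseless_phantom):
        _, _, _, contrast = noiseless_phantom
        voi = MaskVolume(contrast.magnitude[0].data > 1.0, (0.4,) * 3)
        u = unwrap_dataset(contrast, voi)
        p = perturbation_propagation(u, u, voi)
        assert np.abs(p.p.data).max() < 1e-12

    def test_p_scales_linearly_with_concentration(self):
        """Inlays at c and 2c: mean p over equal shells has ratio ~2."""
        protocol = _protocol((32, 72, 20))
        mk = lambda dens, conc, y: InlaySpec((6.4, y, 4.0), 1.6, 2.4, dens, conc)
        spec = PhantomSpec(
            block_size=(12.4, 27.6, 7.6),
            block_center=(6.4, 14.4, 4.0),
            inlays=[mk(120, 78.0, 7.2), mk(240, 156.0, 21.6)],
        )
        u_c, u_b, voi, truth = self._unwrapped_pair(spec, protocol)
        p = perturbation_propagation(u_c, u_b, voi).p.data
        shells = []
        for lab in (1, 2):
            core = truth.inlay_labels == lab
            shell = ndimage.binary_dilation(core, np.ones((3, 3, 3)), 2) & ~core & voi.data
            shells.append(p[shell].mean())
        assert shells[1] / shells[0] == pytest.approx(2.0, rel=0.10)

    def test_noise_only_null_below_weakest_inlay_shell(self):
        """The shell-aggregated p of the weakest (19 uM) inlay exceeds the
        99th percentile of identically aggregated p in a noise-only phantom
        (Monte-Carlo null over translated shells, fixed seed)."""
        protocol = _protocol((28, 48, 16))
        spec_inlay = PhantomSpec(
            block_size=(9.2, 16.4, 5.2),
            block_center=(5.6, 9.6, 3.2),
            inlays=[InlaySpec((5.6, 9.6, 3.2), 1.6, 2.4, 30, 19.0)],
        )
        truth = build_phantom_truth(spec_inlay, protocol)
        base, contrast = synthesize_dataset(
            truth, spec_inlay, ContrastModel(), protocol, NoiseSpec(0.05, 7)
        )
        voi = MaskVolume(base.magnitude[0].data > 50.0, (0.4,) * 3)
        u_c, u_b = unwrap_dataset(contrast, voi), unwrap_dataset(base, voi)
        p_signal = perturbation_propagation(u_c, u_b, voi).p.data
        core = truth.positive_mask.data
        shell = ndimage.binary_dilation(core, np.ones((3, 3, 3)), 2) & ~core & voi.data
        signal_level = p_signal[shell].mean()

        spec_null = PhantomSpec(block_size=(9.2, 16.4, 5.2), block_center=(5.6, 9.6, 3.2))
        truth0 = build_phantom_truth(spec_null, protocol)
        base0, contrast0 = synthesize_dataset(
            truth0, spec_null, ContrastModel(), protocol, NoiseSpec(0.05, 42)
        )
        voi0 = MaskVolume(base0.magnitude[0].data > 50.0, (0.4,) * 3)
        p_null = perturbation_propagation(
            unwrap_dataset(contrast0, voi0), unwrap_dataset(base0, voi0), voi0
        ).p.data
        # null distribution of the same aggregate: shell translated along y
        means = []
        for dy in range(-12, 13, 1):
            moved = np.roll(shell, dy, axis=1) & voi0.data
            if moved.sum() > 0.8 * shell.sum():
                means.append(p_null[moved].mean())
        assert len(means) >= 20
        assert np.percentile(means, 99) < signal_level

    def test_echo_mismatch_rejected(self):
        a = UnwrappedPhaseSet([ScalarVolume(np.zeros((4, 4, 4)))] * 3, (2.54, 3.78, 11.34))
        b = UnwrappedPhaseSet([ScalarVolume(np.zeros((4, 4, 4)))] * 3, (2.54, 3.9, 11.34))
        with pytest.raises(ValidationError):
            perturbation_propagation(a, b, None)
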