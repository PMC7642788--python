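"""Phantom construction, far-field rendering and frame sampling."""

import numpy as np
import pytest

from spivolve.background import spherical_psd
from spivolve.simulate import (PhantomSpec, SimConfig, corrupt_stack,
                               half_panel_mask, icosahedron_geometry,
                               make_phantom, render_intensity, sample_patterns)

SPHERE_FIRST_ZERO = 4.493409457909064


class TestPhantoms:
    def test_sphere_volume_matches_analytic(self):
        ph = make_phantom(PhantomSpec("sphere", 60.0, 8.0, 1.0), 64, 2.2)
        measured = ph.values.sum() * 2.2 ** 3
        expected = 4.0 / 3.0 * np.pi * 30.0 ** 3
        assert measured == pytest.approx(expected, rel=0.02)

    def test_icosahedron_axis_ratio(self):
        # circumradius / inradius of a regular icosahedron ~ 1.258
        _, _, inradius = icosahedron_geometry()
        assert 1.0 / inradius == pytest.approx(1.258, abs=0.02)

    def test_shell_has_requested_interior_contrast(self):
        ph = make_phantom(
            PhantomSpec("icosahedral_shell", 70.0, 8.0, 0.4), 72, 2.0)
        centre = ph.values[36, 36, 36]
        assert centre == pytest.approx(0.4, abs=0.05)
        assert ph.values.max() == pytest.approx(1.0, abs=0.05)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec("sphere", 60.0, 0.0, 1.0)       # zero capsid
        with pytest.raises(ValueError):
            PhantomSpec("sphere", 10.0, 8.0, 1.0)       # too thick
        with pytest.raises(ValueError):
            PhantomSpec("cube", 60.0, 8.0, 1.0)
        with pytest.raises(ValueError):
            make_phantom(PhantomSpec("sphere", 60.0, 8.0, 1.0), 32, 2.0)


class TestRendering:
    def test_friedel_symmetry_exact(self, sphere70_volume):
        v = sphere70_volume.values
        core = v[1:, 1:, 1:]
        assert np.allclose(core, core[::-1, ::-1, ::-1], rtol=1e-10)

    def test_parseval_and_origin(self, sphere70_phantom):
        iv = render_intensity(sphere70_phantom, 2)
        total = iv.values.sum()
        expected = iv.values.size * (sphere70_phantom.values ** 2).sum()
        assert total == pytest.approx(expected, rel=1e-10)
        c = iv.center
        assert iv.values[c, c, c] == pytest.approx(
            sphere70_phantom.values.sum() ** 2, rel=1e-10)

    def test_sphere_form_factor_minimum_position(self, sphere70_volume):
        # first intensity zero of a solid sphere sits at q*R = 4.4934
        psd = spherical_psd(sphere70_volume, n_bins=240, q_range=(0.0, 0.6))
        bin_w = 0.6 / 240
        lo = int(0.08 / bin_w)
        hi = int(0.18 / bin_w)
        vals = psd.value[lo:hi]
        q_min = psd.q_centers[lo:hi][np.nanargmin(vals)]
        assert q_min == pytest.approx(SPHERE_FIRST_ZERO / 35.0, abs=bin_w / 2)

    def test_rejects_low_oversampling(self, sphere70_phantom):
        with pytest.raises(ValueError):
            render_intensity(sphere70_phantom, 1)


class TestSampling:
    def _config(self, **kw):
        base = dict(n_frames=60, fluence_scale=300.0, size_jitter_sd=0.0,
                    single_fraction=1.0, multi_fraction=0.0,
                    blank_fraction=0.0, background_level=0.0,
                    pixel_offset_sd=0.0, readout_noise_sd=0.0, seed=5)
        base.update(kw)
        return SimConfig(**base)

    def test_fluence_scaling_is_linear(self, sphere70_volume, binned_geometry):
        cfg1 = self._config(n_frames=200, fluence_scale=100.0)
        cfg2 = self._config(n_frames=200, fluence_scale=200.0)
        tot1 = sample_patterns(sphere70_volume, binned_geometry,
                               cfg1).counts.sum(axis=(1, 2))
        tot2 = sample_patterns(sphere70_volume, binned_geometry,
                               cfg2).counts.sum(axis=(1, 2))
        ratio = tot2.mean() / tot1.mean()
        se = ratio * np.sqrt(tot1.std() ** 2 / tot1.mean() ** 2
                             + tot2.std() ** 2 / tot2.mean() ** 2) / np.sqrt(200)
        assert abs(ratio - 2.0) < 3 * max(se, 1e-3)

    def test_blank_frames_have_no_signal(self, sphere70_volume, binned_geometry):
        cfg = self._config(blank_fraction=1.0, single_fraction=0.0)
        stack = sample_patterns(sphere70_volume, binned_geometry, cfg)
        assert stack.counts.sum() == 0
        assert set(stack.annotations["hit_type"]) == {"blank"}

    def test_identity_orientation_flat_map_slices_central_plane(
            self, sphere70_volume, binned_geometry):
        cfg = self._config(n_frames=1, poisson=False)
        stack = sample_patterns(sphere70_volume, binned_geometry, cfg,
                                curved=False)
        # the sphere is isotropic: a flat central cut must reproduce the
        # spherically averaged profile at every pixel's |q|
        from spivolve.geometry import build_pixel_map
        from spivolve.sizing import sphere_form_factor_psd
        pm = build_pixel_map(binned_geometry, curved=False)
        frame = stack.counts[0]
        model = sphere_form_factor_psd(pm.qmag, 70.0)
        sel = (pm.qmag > 0.25) & (pm.qmag < 0.45) & (model > 1e-4)
        ratio = frame[sel] / model[sel]
        assert np.std(np.log(ratio)) < 0.35

    def test_seeded_reproducibility(self, sphere70_volume, binned_geometry):
        cfg = self._config(size_jitter_sd=2.0, blank_fraction=0.1,
                           single_fraction=0.9)
        a = sample_patterns(sphere70_volume, binned_geometry, cfg)
        b = sample_patterns(sphere70_volume, binned_geometry, cfg)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.annotations["true_quat"],
                              b.annotations["true_quat"])

    def test_orientation_average_matches_spherical_average(
            self, sphere70_volume, binned_geometry):
        from spivolve.geometry import build_pixel_map
        from spivolve.sizing import compute_psd
        cfg = self._config(n_frames=500, poisson=False)
        stack = sample_patterns(sphere70_volume, binned_geometry, cfg)
        pm = build_pixel_map(binned_geometry)
        mean_frame = stack.counts.mean(axis=0)
        psd2d = compute_psd(mean_frame, pm, n_bins=40, q_range=(0.0, 0.6))
        psd3d = spherical_psd(sphere70_volume, n_bins=40, q_range=(0.0, 0.6))
        ok = (psd2d.q_centers > 0.05) & psd2d.valid & psd3d.valid
        a = psd2d.value[ok]
        b = psd3d.value[ok]
        b = b * a.sum() / b.sum()
        # intensity-weighted relative RMS: near-zero fringe-minimum bins
        # would otherwise dominate through their diverging relative scale
        w = b ** 2
        rms = np.sqrt(np.sum(w * (a - b) ** 2 / np.maximum(b, 1e-12) ** 2)
                      / w.sum())
        assert rms < 0.05


class TestCorruption:
    def test_noop_when_disabled(self, sphere70_volume, binned_geometry):
        cfg = SimConfig(n_frames=20, fluence_scale=100.0, size_jitter_sd=0.0,
                        single_fraction=1.0, multi_fraction=0.0,
                        blank_fraction=0.0, background_level=0.0,
                        pixel_offset_sd=0.0, readout_noise_sd=0.0, seed=3)
        stack = sample_patterns(sphere70_volume, binned_geometry, cfg)
        out = corrupt_stack(stack, cfg)
        assert np.array_equal(out.counts, stack.counts)

    def test_background_raises_frame_mean(self, sphere70_volume,
                                          binned_geometry):
        cfg = SimConfig(n_frames=60, fluence_scale=100.0, size_jitter_sd=0.0,
                        single_fraction=1.0, multi_fraction=0.0,
                        blank_fraction=0.0, background_level=0.4,
                        pixel_offset_sd=0.0, readout_noise_sd=0.0, seed=3)
        stack = sample_patterns(sphere70_volume, binned_geometry, cfg)
        out = corrupt_stack(stack, cfg)
        delta = out.counts.mean() - stack.counts.mean()
        se = 3 * np.sqrt(0.4 / out.counts.size)
        assert delta == pytest.approx(0.4, abs=5 * se)

    def test_all_multi_annotated(self, sphere70_volume, binned_geometry):
        cfg = SimConfig(n_frames=30, fluence_scale=100.0, size_jitter_sd=0.0,
                        single_fraction=0.0, multi_fraction=1.0,
                        blank_fraction=0.0, background_level=0.0,
                        pixel_offset_sd=0.0, readout_noise_sd=0.0, seed=3)
        stack = sample_patterns(sphere70_volume, binned_geometry, cfg)
        out = corrupt_stack(stack, cfg)
        assert set(out.annotations["hit_type"]) == {"multi"}

    def test_mask_applied(self, sphere70_volume, binned_geometry):
        cfg = SimConfig(n_frames=10, fluence_scale=100.0, size_jitter_sd=0.0,
                        single_fraction=1.0, multi_fraction=0.0,
                        blank_fraction=0.0, background_level=0.2,
                        pixel_offset_sd=0.1, readout_noise_sd=0.1, seed=3)
        stack = sample_patterns(sphere70_volume, binned_geometry, cfg)
        mask = half_panel_mask(binned_geometry.panel_shape)
        out = corrupt_stack(stack, cfg, mask=mask)
        assert np.all(out.counts[:, ~mask] == 0)
        assert out.mask.sum() == mask.sum()
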