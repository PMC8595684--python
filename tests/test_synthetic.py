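"""Generator correctness: determinism, activity ODE, image formation."""

import numpy as np
import pytest

from optofret import (KineticsParams, OpticsModel, SceneParams,
                      StimulusEvent, make_scene, render_bleach,
                      render_frames)
from optofret.bleach import BleachField, BleachModel
from optofret.synthetic import integrate_activity


def euler_reference(t_end, events, kp, dt, a0=None):
    """Independent fine-step explicit-Euler integration of the same ODE."""
    if a0 is None:
        a, f1, f2 = kp.steady_state()
    else:
        a, f1, f2 = a0
    n = int(round(t_end / dt))
    ts = np.arange(n + 1) * dt
    out = np.empty(n + 1)
    out[0] = a
    for i in range(n):
        t = ts[i]
        u = kp.k_in * kp.basal_drive
        for t_on, t_off, power, g in events:
            if t_on <= t < t_off:
                u += kp.k_in * power * g
        da = u - (kp.k_off + kp.k1 * f1 + kp.k2 * f2) * a
        df1 = kp.a1 * a - kp.d1 * f1
        df2 = kp.a2 * a - kp.d2 * f2
        a += dt * da
        f1 += dt * df1
        f2 += dt * df2
        out[i + 1] = a
    return ts, out


class TestMakeScene:
    def test_same_seed_gives_bitwise_identical_scenes(self):
        p = SceneParams(n_frames=6, n_cells=5, field_shape=(96, 96))
        a = make_scene(p, 7)
        b = make_scene(p, 7)
        assert np.array_equal(a.label_stack, b.label_stack)
        for ca, cb in zip(a.cells, b.cells):
            assert np.array_equal(ca.centroids_um, cb.centroids_um)
            assert np.array_equal(ca.activity, cb.activity)
            assert ca.baseline_ratio == cb.baseline_ratio

    def test_no_stimulus_with_zero_basal_drive_gives_zero_activity(self):
        kin = KineticsParams(basal_drive=0.0)
        p = SceneParams(n_frames=5, n_cells=3, kinetics=kin,
                        dead_fraction=0.0)
        scene = make_scene(p, 3)
        for cell in scene.cells:
            assert np.all(cell.activity == 0.0)

    def test_overdense_placement_raises(self):
        p = SceneParams(n_cells=40, field_shape=(64, 64), n_frames=2,
                        cell_radius_um=6.0)
        with pytest.raises(ValueError, match="dense|field too small"):
            make_scene(p, 0)

    def test_masks_fit_inside_field(self):
        p = SceneParams(n_frames=20, n_cells=6, field_shape=(96, 96),
                        speed_um_min=30.0)
        scene = make_scene(p, 11)
        border = np.zeros((96, 96), dtype=bool)
        border[[0, -1], :] = True
        border[:, [0, -1]] = True
        assert not (scene.label_stack[:, border].any())

    def test_dead_cells_have_low_constant_ratio_and_zero_activity(self):
        p = SceneParams(n_frames=5, n_cells=12, field_shape=(160, 160),
                        dead_fraction=0.8)
        scene = make_scene(p, 5)
        dead = [c for c in scene.cells if c.is_dead]
        assert dead
        for c in dead:
            assert c.baseline_ratio < 0.8
            assert np.all(c.activity == 0)


class TestActivityODE:
    def test_matches_fine_step_reference_integrator(self):
        """Single global pulse with one feedback pool: RK4 at the frame
        grid agrees with a 1000x finer independent Euler solve."""
        kp = KineticsParams(k_in=5.0, k_off=0.1, a1=0.1, d1=0.05, k1=2.0,
                            a2=0.0, d2=0.01, k2=0.0, basal_drive=0.02)
        events = [(5.0, 5.5, 0.25, 1.0)]
        frame_times = np.arange(0, 40.0, 1.5)
        ours = integrate_activity(frame_times, events, kp, dt_max=0.05)
        ts, ref = euler_reference(40.0, events, kp, dt=0.0005)
        ref_at = np.interp(frame_times, ts, ref)
        assert np.max(np.abs(ours - ref_at)) / ref_at.max() < 1e-3

    def test_pulse_causes_undershoot_only_from_nonzero_baseline(self):
        """With a slow feedback pool, activity transiently undershoots its
        pre-pulse steady state, but never goes negative."""
        kp = KineticsParams(k_in=5.0, k_off=0.1, a1=0.1, d1=0.02, k1=3.0,
                            a2=0.0, k2=0.0, basal_drive=0.02)
        frame_times = np.arange(0, 200.0, 1.5)
        a = integrate_activity(frame_times, [(5.0, 5.5, 1.0, 1.0)], kp)
        a_ss = kp.steady_state()[0]
        assert a.min() >= 0.0
        assert a.max() > a_ss * 1.5
        post = a[frame_times > 10.0]
        assert post.min() < a_ss * 0.97  # undershoot
        # from a zero baseline there is nothing to undershoot
        kp0 = KineticsParams(k_in=5.0, k_off=0.1, a1=0.1, d1=0.02, k1=3.0,
                             a2=0.0, k2=0.0, basal_drive=0.0)
        a0 = integrate_activity(frame_times, [(5.0, 5.5, 1.0, 1.0)], kp0)
        assert a0.min() >= 0.0

    def test_activity_bounded_by_input_over_decay(self):
        kp = KineticsParams(k_in=2.0, k_off=0.5, basal_drive=0.0)
        frame_times = np.arange(0, 30.0, 1.5)
        a = integrate_activity(frame_times, [(3.0, 20.0, 1.0, 1.0)], kp)
        assert np.all(a >= 0)
        assert np.all(a <= kp.k_in * 1.0 / kp.k_off + 1e-9)


class TestRendering:
    def _static_scene(self, **kw):
        p = SceneParams(n_frames=1, n_cells=2, field_shape=(64, 64),
                        dead_fraction=0.0, speed_um_min=0.0, **kw)
        return make_scene(p, 2), p

    def test_noiseless_identity_ratio_equals_baseline(self):
        scene, p = self._static_scene()
        optics = OpticsModel.identity((64, 64), noiseless=True)
        stack = render_frames(scene, optics, noise=False)
        for cell in scene.cells:
            m = scene.mask(cell.index, 0)
            ratio = stack.acceptor[0][m] / stack.donor[0][m]
            expected = cell.baseline_ratio * (
                1 + p.response_amplitude * cell.activity[0])
            assert np.allclose(ratio, expected, rtol=1e-12)

    def test_photon_conservation_under_activity(self):
        """FRET redistributes but does not create signal: donor+acceptor
        inside a cell is invariant to activity (noiseless, unit optics)."""
        optics = OpticsModel.identity((64, 64), noiseless=True)
        kin = KineticsParams(k_off=0.01, a1=0, a2=0, basal_drive=0)
        stim = [StimulusEvent(time=0.5, power=1.0)]
        p_hi = SceneParams(n_frames=3, n_cells=1, field_shape=(64, 64),
                           dead_fraction=0.0, speed_um_min=0.0,
                           kinetics=kin, stimuli=stim)
        p_lo = SceneParams(n_frames=3, n_cells=1, field_shape=(64, 64),
                           dead_fraction=0.0, speed_um_min=0.0, kinetics=kin)
        s_hi = make_scene(p_hi, 4)
        s_lo = make_scene(p_lo, 4)
        st_hi = render_frames(s_hi, optics, noise=False)
        st_lo = render_frames(s_lo, optics, noise=False)
        assert s_hi.cells[0].activity[-1] > 0.3  # stimulus took effect
        m = s_hi.mask(0, 2)
        tot_hi = (st_hi.donor[2][m] + st_hi.acceptor[2][m]).sum()
        tot_lo = (st_lo.donor[2][m] + st_lo.acceptor[2][m]).sum()
        assert abs(tot_hi - tot_lo) / tot_lo < 1e-9

    def test_noise_variance_matches_model(self):
        """Var(counts) ~ gain^2 * photon mean + read_noise^2."""
        p = SceneParams(n_frames=1, n_cells=1, field_shape=(24, 24),
                        dead_fraction=0.0, speed_um_min=0.0,
                        cell_radius_um=4.0, radius_sd_um=0.0)
        scene = make_scene(p, 6)
        optics = OpticsModel((24, 24))
        rendered = [render_frames(scene, optics, seed=s).donor[0]
                    for s in range(10_000)]
        rendered = np.asarray(rendered, dtype=float)
        m = scene.mask(0, 0)
        pix = np.argwhere(m)[0]
        vals = rendered[:, pix[0], pix[1]]
        mean_photons = (vals.mean() - optics.dark_offset) / optics.gain
        expected_var = optics.gain ** 2 * mean_photons + optics.read_noise_sd ** 2
        assert abs(vals.var() - expected_var) / expected_var < 0.05

    def test_determinism_same_seed_bitwise(self):
        scene, _ = self._static_scene()
        a = render_frames(scene, seed=9)
        b = render_frames(scene, seed=9)
        assert np.array_equal(a.donor, b.donor)
        assert np.array_equal(a.acceptor, b.acceptor)

    def test_saturation_clips_never_rescales(self):
        scene, p = self._static_scene()
        optics = OpticsModel((64, 64), bit_depth=8, background_photons=500.0)
        stack = render_frames(scene, optics, noise=False)
        assert stack.donor.max() == 255.0


class TestRenderBleach:
    def _scene(self):
        p = SceneParams(n_frames=3, n_cells=1, field_shape=(64, 64),
                        dead_fraction=0.0, speed_um_min=0.0,
                        cell_radius_um=8.0, radius_sd_um=0.0,
                        shape_irregularity=0.0)
        return make_scene(p, 8), p

    def _model(self, b0, alpha, center=(32.0, 32.0)):
        return BleachModel(b0=b0, sigma0=1.5, center=center,
                           pixel_size=0.65, diffusion=0.0, alpha=alpha)

    def test_zero_bleach_identical_to_render_frames(self):
        scene, _ = self._scene()
        field = BleachField(self._model(0.0, 1.0), [(0.0, 37.0)])
        a = render_frames(scene, seed=3)
        b = render_bleach(scene, field, seed=3)
        assert np.array_equal(a.donor, b.donor)
        assert np.array_equal(a.acceptor, b.acceptor)

    def test_symmetric_bleach_preserves_ratio_reduces_intensity(self):
        scene, _ = self._scene()
        optics = OpticsModel.identity((64, 64), noiseless=True)
        field = BleachField(self._model(0.4, 0.0), [(0.0, 37.0)])
        plain = render_frames(scene, optics, noise=False)
        bleached = render_bleach(scene, field, optics, noise=False)
        m = scene.mask(0, 0)
        r_plain = plain.acceptor[0][m] / plain.donor[0][m]
        r_bl = bleached.acceptor[0][m] / bleached.donor[0][m]
        assert np.allclose(r_plain, r_bl, rtol=1e-12)
        assert bleached.donor[0][m].sum() < plain.donor[0][m].sum()

    def test_asymmetric_bleach_dips_ratio_by_one_minus_b(self):
        scene, _ = self._scene()
        optics = OpticsModel.identity((64, 64), noiseless=True)
        b0 = 0.3
        field = BleachField(self._model(b0, 1.0), [(0.0, 37.0)])
        plain = render_frames(scene, optics, noise=False)
        bleached = render_bleach(scene, field, optics, noise=False)
        c = (32, 32)
        assert scene.mask(0, 0)[c]
        r_plain = plain.acceptor[0][c] / plain.donor[0][c]
        r_bl = bleached.acceptor[0][c] / bleached.donor[0][c]
        assert r_bl == pytest.approx((1 - b0) * r_plain, rel=1e-9)


def test_scene_roundtrips_through_writer_reader(tmp_path):
    from optofret.io import read_scene, write_scene
    p = SceneParams(n_frames=4, n_cells=3, field_shape=(64, 64),
                    stimuli=[StimulusEvent(time=2.0, power=0.5)])
    scene = make_scene(p, 13)
    write_scene(tmp_path, scene)
    back = read_scene(tmp_path)
    assert np.array_equal(back.label_stack, scene.label_stack)
    for a, b in zip(scene.cells, back.cells):
        assert np.array_equal(a.centroids_um, b.centroids_um)
        assert np.array_equal(a.activity, b.activity)
        assert a.is_dead == b.is_dead
    assert back.params.stimuli[0].time == 2.0
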