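import numpy as np
import pytest

from neureit.phantom import (
    ActivityEvent,
    DistortionSpec,
    FasciclePhantom,
    make_phantom,
    noise_sd_for_snr,
    perturbation_field,
    protocol_timing,
    render_reference_images,
    synthesize_recording,
)
from neureit.mesh import REGION_NERVE


class TestMakePhantom:
    def test_deterministic_for_fixed_seed(self):
        a, b = make_phantom(11), make_phantom(11)
        assert a == b

    def test_default_nerve_diameter_is_cuff_id(self):
        assert 2 * make_phantom(0).nerve_radius_um == pytest.approx(1400.0)

    def test_three_uniquely_labelled_fascicles(self):
        ph = make_phantom(1)
        labels = [f.label for f in ph.fascicles]
        assert sorted(labels) == ["peroneal", "sural", "tibial"]

    def test_nonoverlap_invariant_over_many_seeds(self):
        """Every sampled phantom keeps fascicles disjoint and inside the
        nerve disk."""
        for seed in range(1000):
            ph = make_phantom(seed)
            polys = [f.polygon() for f in ph.fascicles]
            for i in range(3):
                r, th = ph.fascicles[i].center_r_um, None
                assert polys[i].bounds[0] >= -ph.nerve_radius_um
                for j in range(i + 1, 3):
                    assert polys[i].distance(polys[j]) > 0
            from shapely.geometry import Point

            disk = Point(0, 0).buffer(ph.nerve_radius_um, quad_segs=64)
            assert all(disk.contains(p) for p in polys)

    def test_left_side_mirrors_right(self):
        r = make_phantom(4, side="right")
        l = make_phantom(4, side="left")
        for fr, fl in zip(r.fascicles, l.fascicles):
            assert fl.center_theta_deg == pytest.approx((360 - fr.center_theta_deg) % 360)

    def test_infeasible_packing_raises(self):
        from neureit.phantom import PackingError

        with pytest.raises(PackingError):
            make_phantom(0, gap_margin_um=2000.0, max_attempts=20)
        with pytest.raises(ValueError):
            make_phantom(0, nerve_radius_um=-1.0)


class TestActivityEvent:
    def test_profile_peak_normalized(self):
        ev = ActivityEvent()
        t = np.linspace(0, 5, 20001)
        assert ev.profile(t).max() == pytest.approx(1.0, abs=1e-6)

    def test_duration_at_30pct_matches_parameter(self):
        ev = ActivityEvent(duration30_ms=0.7)
        t = np.linspace(0, 5, 200001)
        p = ev.profile(t)
        width = (p >= 0.3).sum() * (t[1] - t[0])
        assert width == pytest.approx(0.7, abs=0.01)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            ActivityEvent(fractional_change=-1e-4)
        with pytest.raises(ValueError):
            ActivityEvent(onset_ms=-0.1)

    def test_timing_arithmetic(self):
        t = protocol_timing()
        assert t["trials_per_injection"] == 300
        assert t["total_minutes"] == pytest.approx(14.0)


class TestPerturbationField:
    def test_zero_fraction_gives_zero_field(self, system):
        ph = make_phantom(0)
        ev = ActivityEvent(fractional_change=0.0)
        assert not np.any(perturbation_field(ph, ev, system.mesh))

    def test_integral_matches_ellipse_area(self, system):
        """Area integral of δσ ≈ fraction × σ × ellipse area (mesh
        discretization error < 2%)."""
        ph = make_phantom(3)
        ev = ActivityEvent(fascicle="tibial", fractional_change=5e-4)
        delta = perturbation_field(ph, ev, system.mesh)
        integral = (delta * system.mesh.element_areas()).sum()  # S/m * m^2
        expected = 5e-4 * 0.3 * ph.fascicle("tibial").area_um2() * 1e-12
        assert integral == pytest.approx(expected, rel=0.02)

    def test_disjoint_fascicles_have_disjoint_supports(self, system):
        ph = make_phantom(5)
        supports = []
        for lab in ("tibial", "peroneal", "sural"):
            d = perturbation_field(ph, ActivityEvent(fascicle=lab), system.mesh)
            supports.append(d > 0)
        assert not np.any(supports[0] & supports[1])
        assert not np.any(supports[0] & supports[2])
        assert not np.any(supports[1] & supports[2])

    def test_support_restricted_to_nerve_region(self, system):
        ph = make_phantom(5)
        d = perturbation_field(ph, ActivityEvent(), system.mesh)
        assert not np.any(d[system.mesh.region != REGION_NERVE])


class TestSynthesizeRecording:
    @pytest.fixture()
    def tiny_kwargs(self, system):
        return dict(
            layout=system.layout,
            protocol=system.protocol,
            sample_rate=25e3,
            mesh=system.mesh,
            n_trials=6,
            baseline_system=system.cem,
            sigma=system.sigma,
        )

    def test_deterministic_for_fixed_seed(self, system, tiny_kwargs):
        ph = make_phantom(0)
        ev = ActivityEvent()
        a = synthesize_recording(ph, event=ev, noise_sd=1e-6, seed=9, **tiny_kwargs)
        b = synthesize_recording(ph, event=ev, noise_sd=1e-6, seed=9, **tiny_kwargs)
        for wa, wb in zip(a.waveforms, b.waveforms):
            assert np.array_equal(wa, wb)

    def test_trigger_count_is_rate_times_duration(self, system, tiny_kwargs):
        rec = synthesize_recording(
            make_phantom(0), event=ActivityEvent(), noise_sd=0.0, seed=0, **tiny_kwargs
        )
        assert len(rec.triggers_s) == 6
        assert np.allclose(np.diff(rec.triggers_s), 0.2)

    def test_no_modulation_gives_flat_envelope(self, system, tiny_kwargs):
        from neureit.signal import demodulate

        ev = ActivityEvent(fractional_change=0.0, cap_amplitude_uv=0.0)
        rec = synthesize_recording(
            make_phantom(0), event=ev, noise_sd=0.0, seed=0, **tiny_kwargs
        )
        env = demodulate(rec.waveforms[0], rec.sample_rate)
        mid = env[:, 2000:-2000]
        flat = np.abs(mid - mid.mean(axis=1, keepdims=True)).max(axis=1)
        assert np.all(flat < 1e-9 + 1e-6 * np.abs(mid).max(axis=1))

    def test_envelope_dip_matches_forward_dv(self, system, tiny_kwargs):
        """The demodulated, trial-averaged dip equals the forward-model ΔV
        within 5% on channels with a resolvable change."""
        from neureit.signal import demodulate, epoch_average

        ev = ActivityEvent(cap_amplitude_uv=0.0, duration30_ms=1.5)
        ph = make_phantom(0)
        rec = synthesize_recording(ph, event=ev, noise_sd=0.0, seed=0, **tiny_kwargs)
        dU = rec.perturbed_voltages - rec.baseline_voltages
        inj, ch = np.unravel_index(np.argmax(np.abs(dU)), dU.shape)
        env = demodulate(rec.waveforms[inj], rec.sample_rate)
        tr = epoch_average(env[ch], rec.triggers_s[1:-1], rec.sample_rate)
        peak = np.abs(tr.dv_uv).max() * 1e-6
        expected = np.abs(dU[inj, ch]) * np.abs(
            np.sign(rec.baseline_voltages[inj, ch])
        )
        assert peak == pytest.approx(expected, rel=0.05)

    def test_aliasing_sample_rate_rejected(self, system, tiny_kwargs):
        kw = dict(tiny_kwargs)
        kw["sample_rate"] = 20e3  # below 4x the 6 kHz carrier
        with pytest.raises(ValueError):
            synthesize_recording(
                make_phantom(0), event=ActivityEvent(), noise_sd=0.0, seed=0, **kw
            )

    def test_noise_targeting_hits_requested_snr(self, system, tiny_kwargs):
        """noise_sd_for_snr produces an averaged-trace SNR near the request."""
        from neureit.signal import demodulate, epoch_average

        ev = ActivityEvent(cap_amplitude_uv=0.0)
        ph = make_phantom(0)
        kw = dict(tiny_kwargs)
        kw["n_trials"] = 40
        rec0 = synthesize_recording(ph, event=ev, noise_sd=0.0, seed=0, **kw)
        dU = rec0.perturbed_voltages - rec0.baseline_voltages
        peak = np.abs(dU).max()
        inj, ch = np.unravel_index(np.argmax(np.abs(dU)), dU.shape)
        sd = noise_sd_for_snr(17.0, peak, 38, kw["sample_rate"])
        rec = synthesize_recording(ph, event=ev, noise_sd=sd, seed=1, **kw)
        env = demodulate(rec.waveforms[inj], rec.sample_rate)
        tr = epoch_average(env[ch], rec.triggers_s[1:-1], rec.sample_rate)
        snr = np.abs(tr.dv_uv[(tr.time_ms > 0) & (tr.time_ms < 5)]).max() / tr.noise_sd_uv
        assert 10.0 < snr < 30.0


class TestReferenceImages:
    def test_identity_distortion_preserves_coms(self):
        ph = make_phantom(2)
        ref = render_reference_images(
            ph, "microct", DistortionSpec(1.0, 1.0, 0.0), seed=0
        )
        for lab, (cx, cy) in ref.com_true_um.items():
            dx, dy = ref.com_distorted_um[lab]
            assert (dx, dy) == pytest.approx((cx, cy), abs=1e-9)

    def test_isotropic_shrinkage_scales_radii(self):
        ph = make_phantom(2)
        ref = render_reference_images(
            ph, "histology", DistortionSpec(0.9, 0.9, 0.0), seed=0
        )
        for lab, (cx, cy) in ref.com_true_um.items():
            dx, dy = ref.com_distorted_um[lab]
            assert np.hypot(dx, dy) == pytest.approx(0.9 * np.hypot(cx, cy), rel=1e-9)

    def test_recorded_inverse_recovers_coms(self):
        """Mask centroids, inverse-transformed, land on the undistorted
        ground truth within one pixel."""
        ph = make_phantom(7)
        ref = render_reference_images(ph, "microct", seed=5)
        ps = ref.pixel_size_um
        h = ref.image.shape[0]
        for key, mask in ref.masks.items():
            if key == "nerve":
                continue
            lab = ref.mask_labels[key]
            lab = "sural" if lab == "?" else lab
            ys, xs = np.nonzero(mask)
            cx_px, cy_px = xs.mean(), ys.mean()
            x_um = (cx_px - (h - 1) / 2.0) * ps
            y_um = ((h - 1) / 2.0 - cy_px) * ps
            rec = ref.distortion.inverse(np.array([x_um, y_um]))
            true = np.array(ref.com_true_um[lab])
            assert np.hypot(*(rec - true)) < ps

    def test_masks_carry_ground_truth_sidecar(self):
        ph = make_phantom(1)
        ref = render_reference_images(ph, "histology", seed=2)
        assert set(ref.com_true_um) == {"tibial", "peroneal", "sural"}
        # sural carries no tracer in histology -> unlabeled mask key
        assert "?" in ref.mask_labels.values()

    def test_out_of_range_distortion_rejected(self):
        with pytest.raises(ValueError):
            DistortionSpec(scale_x=0.4)
        with pytest.raises(ValueError):
            DistortionSpec(rotation_deg=200.0)
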