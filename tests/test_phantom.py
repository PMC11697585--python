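"""Generator checks: ground-truth construction, signal models, determinism."""

import numpy as np
import pytest

from qrelax.phantom import (
    PhantomSpec,
    RegionBox,
    build_ground_truth,
    simulate_multiecho,
    simulate_dwi,
    generate_study,
    default_bvals_bvecs,
    isotropic_directions,
    wm_r2star,
    DEFAULT_ECHO_TIMES_MS,
)
from .conftest import make_mini_spec, mini_layout, mini_gm_r2star


class TestGroundTruth:
    @pytest.mark.parametrize(
        "theta, expected",
        [(0.0, 19.6), (45.0, 20.85), (90.0, 22.1)],
    )
    def test_wm_orientation_model_values(self, mini_spec, theta, expected):
        """R2*(theta) = a + b sin^2(theta) with the default left WM (19.6, 2.5)."""
        val = wm_r2star(mini_spec, theta, "left", "migraine-free")
        assert val == pytest.approx(expected, abs=1e-12)

    def test_zero_anisotropy_makes_wm_flat(self):
        spec = make_mini_spec(orientation_effect={
            (h, c): (19.6, 0.0)
            for h in ("left", "right")
            for c in ("migraine-free", "migraine")
        })
        gt = build_ground_truth(spec)
        wm_vals = gt.r2star_by_condition["migraine-free"][gt.wm_mask]
        assert np.allclose(wm_vals, 19.6)

    def test_condition_contrast_is_exact(self, mini_gt):
        """Condition-level truth differs by exactly the configured shift."""
        sel = mini_gt.label_volume == 11  # left caudate
        diff = (mini_gt.r2star_by_condition["migraine"][sel]
                - mini_gt.r2star_by_condition["migraine-free"][sel])
        assert np.allclose(diff, 1.0)

    def test_fiber_directions_unit_norm_in_wm(self, mini_gt):
        norms = np.linalg.norm(mini_gt.fiber_direction_volume[mini_gt.wm_mask], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_fan_covers_all_angle_bins(self, mini_gt):
        theta = mini_gt.theta_true[mini_gt.wm_mask]
        bins = np.minimum((theta // 5).astype(int), 17)
        assert set(bins.tolist()) == set(range(18))

    def test_deterministic_given_spec(self):
        a = build_ground_truth(make_mini_spec(seed=3))
        b = build_ground_truth(make_mini_spec(seed=3))
        for d in range(a.spec.n_days):
            assert np.array_equal(a.r2star_per_day[d], b.r2star_per_day[d])

    def test_overlapping_regions_rejected_with_label_names(self):
        lay = mini_layout()
        lay[99] = RegionBox("Thalamus", "left", "gm", (5, 11), (7, 13), (7, 13))
        r2 = mini_gm_r2star()
        r2.update({("Thalamus", "left", c): 20.0 for c in ("migraine-free", "migraine")})
        with pytest.raises(ValueError, match="overlapping region extents.*99|11"):
            build_ground_truth(make_mini_spec(region_layout=lay,
                                              true_r2star_by_region_condition=r2))

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="at least 3 days"):
            make_mini_spec(n_days=5, day_schedule=("migraine-free", "migraine"))
        with pytest.raises(ValueError, match="each condition"):
            make_mini_spec(day_schedule=("migraine-free",) * 4)
        with pytest.raises(ValueError, match="positive"):
            make_mini_spec(true_r2star_by_region_condition={
                **mini_gm_r2star(), ("Caudate", "left", "migraine"): -1.0})


class TestMultiEchoSignal:
    def test_noiseless_closed_form(self):
        """S(TE) = S0 exp(-R2* TE): 1000 * exp(-20 * 0.02951) = 554.21."""
        spec = make_mini_spec(noise_sigma=0.0, day_jitter_sd=0.0,
                              true_r2star_by_region_condition={
                                  **mini_gm_r2star(),
                                  ("Caudate", "left", "migraine-free"): 20.0})
        gt = build_ground_truth(spec)
        sig = simulate_multiecho(gt, noise_sigma=0.0, day=1)
        vox = np.argwhere(gt.label_volume == 11)[0]
        last = sig[tuple(vox)][-1]
        assert last == pytest.approx(1000.0 * np.exp(-20.0 * 29.51e-3), abs=1e-9)
        assert last == pytest.approx(554.21, abs=0.01)

    def test_signal_positive_and_decaying(self, mini_gt):
        sig = simulate_multiecho(mini_gt, day=2)
        assert np.all(sig >= 0)
        clean = simulate_multiecho(mini_gt, noise_sigma=0.0, day=2)
        inside = mini_gt.label_volume > 0
        assert np.all(np.diff(clean[inside], axis=-1) < 0)

    def test_background_magnitude_is_rayleigh(self, mini_gt):
        """With S0 = 0 the magnitude mean converges to sigma * sqrt(pi/2)."""
        sigma = 10.0
        sig = simulate_multiecho(mini_gt, noise_sigma=sigma, seed=11, day=1)
        bg = sig[mini_gt.label_volume == 0]
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((2 - np.pi / 2) / bg.size)
        assert abs(bg.mean() - expected) < 5 * se

    def test_echo_time_validation(self, mini_gt):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_multiecho(mini_gt, echo_times=[-1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="increasing"):
            simulate_multiecho(mini_gt, echo_times=[5.0, 4.0, 6.0])

    def test_reproducible_under_seed(self, mini_gt):
        a = simulate_multiecho(mini_gt, seed=5, day=1)
        b = simulate_multiecho(mini_gt, seed=5, day=1)
        c = simulate_multiecho(mini_gt, seed=6, day=1)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestDiffusionSignal:
    def test_attenuation_along_fiber(self, noiseless_mini_gt):
        """g parallel to the fiber: S/S0 = exp(-b * lambda1) = exp(-1.7)."""
        gt = noiseless_mini_gt
        wm = np.argwhere((gt.label_volume == 2) & (np.abs(gt.theta_true) < 1e-9))
        vox = tuple(wm[0])
        d = gt.fiber_direction_volume[vox]
        bvals = np.array([0.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0])
        base = isotropic_directions(6)
        bvecs = np.vstack([np.zeros(3), d, base])
        sig = simulate_dwi(gt, bvals=bvals, bvecs=bvecs, noise_sigma=0.0)
        s0 = gt.s0_volume[vox]
        assert sig[vox][0] == pytest.approx(s0, abs=1e-9)
        assert sig[vox][1] == pytest.approx(s0 * np.exp(-1.7), rel=1e-9)

    def test_isotropic_tensor_rotationally_symmetric(self):
        spec = make_mini_spec(noise_sigma=0.0, day_jitter_sd=0.0,
                              diffusivities=(0.7e-3, 0.7e-3, 0.7e-3))
        gt = build_ground_truth(spec)
        sig = simulate_dwi(gt, noise_sigma=0.0)
        bvals, _ = default_bvals_bvecs(spec)
        wm_sig = sig[gt.wm_mask][:, bvals > 0]
        assert np.allclose(wm_sig, wm_sig[:, [0]], rtol=1e-12)

    def test_nonunit_bvec_rejected(self, mini_gt):
        bvals = np.concatenate([[0.0], np.full(6, 1000.0)])
        bvecs = np.vstack([np.zeros(3), isotropic_directions(6) * 1.1])
        with pytest.raises(ValueError, match="unit vectors"):
            simulate_dwi(mini_gt, bvals=bvals, bvecs=bvecs)

    def test_directions_are_isotropicish_unit_vectors(self):
        g = isotropic_directions(30)
        assert np.allclose(np.linalg.norm(g, axis=1), 1.0)
        # mean direction tensor close to isotropy for an even spread
        m = g.T @ g / 30
        assert np.allclose(np.diag(m), 1 / 3, atol=0.08)


class TestGenerateStudy:
    def test_mini_study_layout_and_determinism(self, tmp_path):
        spec = make_mini_spec(n_days=3)
        m1 = generate_study(spec, tmp_path / "a")
        m2 = generate_study(spec, tmp_path / "b")
        assert len(m1["days"]) == 3
        conds = [d["condition"] for d in m1["days"]]
        assert conds.count("migraine") == 1
        assert m1["days"] == m2["days"]
        for rel in ["bvals", "bvecs", "lut.tsv"]:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
        import gzip
        for d in m1["days"]:
            for key in ("gre", "dwi"):
                ba = gzip.decompress((tmp_path / "a" / d[key]).read_bytes())
                bb = gzip.decompress((tmp_path / "b" / d[key]).read_bytes())
                assert ba == bb

    def test_default_schedule_has_21_days_2_migraine(self, default_study):
        days = default_study["manifest"]["days"]
        assert len(days) == 21
        migraine_days = [d["day"] for d in days if d["condition"] == "migraine"]
        assert migraine_days == [12, 16]

    def test_default_regional_day_sd_in_plausible_range(self, default_study):
        """Across-day regional SDs should sit in the 0.2-1.0 1/s band."""
        table = default_study["result"].table
        assert (table["sd_free"] > 0.1).all()
        assert (table["sd_free"] < 1.0).all()
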