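"""Generators: ground-truth consistency, determinism, protocol constants."""

import numpy as np
import pytest
from scipy import stats

from corneomech.afm import HertzModelParams, fit_hertz
from corneomech.cohort import unpaired_t
from corneomech.synthetic import (
    SyntheticCohortSpec,
    SyntheticCurveSpec,
    TractionPatch,
    TractionScene,
    make_cell_mask,
    make_traction_field,
    render_bead_images,
    simulate_cohort,
    simulate_force_curve,
)
from corneomech.dic import DisplacementField


def _scene(patches, n=64, ps=1.0):
    return TractionScene(grid_shape=(n, n), pixel_size=ps, patches=tuple(patches))


class TestMakeTractionField:
    def test_empty_scene_is_all_zero(self):
        f = make_traction_field(_scene([]))
        assert not f.tx.any() and not f.ty.any()

    def test_dipole_is_balanced_before_correction(self):
        patches = [
            TractionPatch((20.0, 32.0), 100.0, 3.0, (1.0, 0.0)),
            TractionPatch((44.0, 32.0), 100.0, 3.0, (-1.0, 0.0)),
        ]
        f = make_traction_field(_scene(patches))
        raw_sum = abs(f.meta["tx_raw"].sum()) + abs(f.meta["ty_raw"].sum())
        raw_mag = np.abs(f.meta["tx_raw"]).sum()
        assert raw_sum < 1e-9 * raw_mag

    def test_net_force_zero_after_correction(self):
        f = make_traction_field(
            _scene([TractionPatch((30.0, 30.0), 100.0, 4.0, (1.0, 0.0))])
        )
        assert abs(f.tx.sum()) < 1e-9 * np.abs(f.meta["tx_raw"]).sum()

    def test_single_patch_peak_equals_amplitude_minus_uniform_offset(self):
        """Oracle: direct summation of the analytic Gaussian on the grid."""
        amp, w, n, ps = 100.0, 4.0, 64, 1.0
        f = make_traction_field(_scene([TractionPatch((32.5, 32.5), amp, w, (1.0, 0.0))], n, ps))
        x = (np.arange(n) + 0.5) * ps
        X, Y = np.meshgrid(x, x)
        gauss = amp * np.exp(-((X - 32.5) ** 2 + (Y - 32.5) ** 2) / (2 * w**2))
        offset = gauss.mean()  # hand-computed uniform correction
        assert np.isclose(f.tx.max(), amp - offset, rtol=1e-12)

    def test_patch_outside_grid_is_reported_by_index(self):
        with pytest.raises(ValueError, match="patch 1"):
            make_traction_field(
                _scene(
                    [
                        TractionPatch((30.0, 30.0), 10.0, 2.0, (1.0, 0.0)),
                        TractionPatch((999.0, 30.0), 10.0, 2.0, (1.0, 0.0)),
                    ]
                )
            )

    def test_invalid_patch_parameters_are_rejected(self):
        with pytest.raises(ValueError):
            TractionPatch((0, 0), 10.0, -1.0, (1.0, 0.0))
        with pytest.raises(ValueError):
            TractionPatch((0, 0), 10.0, 1.0, (1.0, 1.0))  # not a unit vector


class TestRenderBeadImages:
    def test_zero_displacement_zero_noise_gives_identical_images(self):
        d = DisplacementField.from_dense(np.zeros((64, 64)), np.zeros((64, 64)), 0.5)
        pair = render_bead_images(d, seed=3)
        np.testing.assert_array_equal(pair.image_pre, pair.image_post)

    def test_deterministic_under_fixed_seed(self):
        d = DisplacementField.from_dense(np.zeros((64, 64)), np.zeros((64, 64)), 0.5)
        a = render_bead_images(d, noise_sigma=5.0, seed=7)
        b = render_bead_images(d, noise_sigma=5.0, seed=7)
        np.testing.assert_array_equal(a.image_pre, b.image_pre)
        np.testing.assert_array_equal(a.image_post, b.image_post)

    def test_uniform_shift_moves_bead_centroids_exactly(self):
        """Post image beads sit at pre positions plus (3, -2) px."""
        ps = 1.0
        d = DisplacementField.from_dense(
            np.full((128, 128), 3.0 * ps), np.full((128, 128), -2.0 * ps), ps
        )
        pair = render_bead_images(d, bead_density=0.002, seed=11)
        rolled = np.roll(np.roll(pair.image_pre, -2, axis=0), 3, axis=1)
        core = np.s_[10:-10, 10:-10]
        np.testing.assert_allclose(pair.image_post[core], rolled[core], atol=1e-9)

    def test_bead_centroid_shift_error_under_noise(self):
        """With 5% noise and psf sigma >= 1.5 px, per-bead centroid shifts
        stay within 0.2 px of the imposed displacement."""
        ps, shift = 1.0, 0.4
        d = DisplacementField.from_dense(
            np.full((128, 128), shift * ps), np.zeros((128, 128)), ps
        )
        pair = render_bead_images(
            d, bead_density=0.002, psf_sigma_um=1.5, noise_sigma=50.0, seed=5
        )
        errs = []
        for bx, by in pair.bead_positions_true:
            cx, cy = bx / ps - 0.5, by / ps - 0.5
            i, j = int(round(cx)), int(round(cy))
            if not (6 <= i < 122 and 6 <= j < 122):
                continue
            win = np.s_[j - 5 : j + 6, i - 5 : i + 6]
            ii = np.arange(i - 5, i + 6)
            w_pre = np.clip(pair.image_pre[win] - 60.0, 0, None)
            w_post = np.clip(pair.image_post[win] - 60.0, 0, None)
            cx_pre = (w_pre.sum(axis=0) * ii).sum() / w_pre.sum()
            cx_post = (w_post.sum(axis=0) * ii).sum() / w_post.sum()
            errs.append(abs((cx_post - cx_pre) - shift))
        assert len(errs) > 10
        assert np.mean(errs) < 0.2

    def test_excessive_displacement_warns(self):
        d = DisplacementField.from_dense(
            np.full((64, 64), 40.0), np.zeros((64, 64)), 1.0
        )
        with pytest.warns(UserWarning, match="quarter"):
            render_bead_images(d, seed=0)


class TestSimulateForceCurve:
    def test_sample_count_follows_ramp_protocol(self):
        """floor(1.2 um / 500 nm/s * 1.7 kHz) + 1 approach samples."""
        spec = SyntheticCurveSpec()
        curve = simulate_force_curve(spec)
        expected = int(np.floor(1200.0 / 500.0 * 1700.0)) + 1
        assert spec.n_approach_samples == expected == 4081
        assert curve.z.size == 2 * expected - 1  # approach + mirrored withdraw

    def test_quadratic_force_law_on_noiseless_segment(self):
        """F(delta) / F(delta/2) = 4 for the Hertz cone."""
        spec = SyntheticCurveSpec(contact_z0_nm=100.0)
        curve = simulate_force_curve(spec)
        n = spec.n_approach_samples
        z, d = curve.z[:n], curve.d[:n]
        delta = (z - 100.0) - d
        f = curve.spring_constant * d
        tgt = 400.0
        f1 = np.interp(tgt, delta, f)
        f2 = np.interp(tgt / 2, delta, f)
        assert np.isclose(f1 / f2, 4.0, rtol=1e-6)  # linear-interp limited
        # exact statement on the samples: F / delta^2 is constant post-contact
        post = delta > 50.0
        ratio = f[post] / delta[post] ** 2
        assert np.ptp(ratio) / ratio.mean() < 1e-9

    def test_noiseless_round_trip_with_true_contact_recovers_e(self):
        spec = SyntheticCurveSpec(e_true_pa=2000.0)
        curve = simulate_force_curve(spec)
        n = spec.n_approach_samples
        from corneomech.afm import ForceCurve

        approach = ForceCurve(curve.z[:n], curve.d[:n], curve.spring_constant)
        fit = fit_hertz(approach, spec.contact_z0_nm, HertzModelParams())
        assert abs(fit.modulus_pa / 2000.0 - 1) < 1e-6

    def test_deterministic_under_fixed_seed(self):
        a = simulate_force_curve(SyntheticCurveSpec(noise_sigma_nn=0.05, seed=9))
        b = simulate_force_curve(SyntheticCurveSpec(noise_sigma_nn=0.05, seed=9))
        np.testing.assert_array_equal(a.d, b.d)


class TestMakeCellMask:
    def test_disc_carries_analytic_geometry(self):
        m = make_cell_mask("disc", (64, 64), 1.0, radius_um=20.0)
        assert np.isclose(m.area_analytic, np.pi * 400.0)
        assert np.isclose(m.perimeter_analytic, 2 * np.pi * 20.0)
        assert not m.perimeter_is_approximate

    def test_ellipse_ramanujan_perimeter_matches_polygonal_oracle(self):
        """Oracle: high-resolution polygonal perimeter of the ellipse."""
        a, b = 10.0, 5.0
        m = make_cell_mask("ellipse", (64, 64), 0.5, a_um=a, b_um=b)
        th = np.linspace(0, 2 * np.pi, 1_000_001)
        pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
        poly = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum()
        assert abs(m.perimeter_analytic / poly - 1) < 1e-4
        assert m.perimeter_is_approximate

    def test_blob_is_bitwise_reproducible(self):
        a = make_cell_mask("blob", (64, 64), 1.0, seed=21, radius_um=15.0)
        b = make_cell_mask("blob", (64, 64), 1.0, seed=21, radius_um=15.0)
        np.testing.assert_array_equal(a.mask, b.mask)

    @pytest.mark.parametrize(
        "shape,params",
        [("disc", {"radius_um": 0.0}), ("ellipse", {"a_um": -1.0, "b_um": 2.0})],
    )
    def test_degenerate_parameters_raise(self, shape, params):
        with pytest.raises(ValueError):
            make_cell_mask(shape, (32, 32), 1.0, **params)


class TestSimulateCohort:
    def test_zero_variance_reproduces_group_means(self):
        spec = SyntheticCohortSpec(
            n_per_group={"high": 5, "low": 4},
            parameter_means={"SP-A1": {"high": 110.0, "low": 100.0}},
            parameter_sds={"SP-A1": {"high": 0.0, "low": 0.0}},
        )
        t = simulate_cohort(spec)
        assert (t.loc[t.group == "high", "SP-A1"] == 110.0).all()
        assert (t.loc[t.group == "low", "SP-A1"] == 100.0).all()

    def test_default_group_sizes_match_study_design(self):
        t = simulate_cohort(SyntheticCohortSpec())
        assert (t.group == "high").sum() == 113
        assert (t.group == "low").sum() == 105

    def test_determinism(self):
        spec = SyntheticCohortSpec(
            parameter_means={"DA": {"high": 1.0, "low": 1.1}},
            parameter_sds={"DA": {"high": 0.1, "low": 0.1}},
            seed=4,
        )
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        assert a.equals(b)

    def test_null_cohort_p_values_are_uniform(self):
        """Equal group means: downstream t-test p values are U(0,1)
        (Kolmogorov-Smirnov over 200 replicate seeds)."""
        ps = []
        for seed in range(200):
            spec = SyntheticCohortSpec(
                n_per_group={"high": 20, "low": 20},
                parameter_means={"DA": {"high": 1.0, "low": 1.0}},
                parameter_sds={"DA": {"high": 0.2, "low": 0.2}},
                seed=seed,
            )
            t = simulate_cohort(spec)
            cmp = unpaired_t(
                t.loc[t.group == "high", "DA"], t.loc[t.group == "low", "DA"]
            )
            ps.append(cmp.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
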