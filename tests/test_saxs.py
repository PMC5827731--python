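"""Guinier fits, P(r) inversion, Debye scattering, ensembles, and χ² scoring."""

import numpy as np
import pytest

from phasekit import saxs
from phasekit import synthetic_data as synth

SPHERE_RG_FACTOR = np.sqrt(3.0 / 5.0)


@pytest.fixture(scope="module")
def pentamer_core():
    return saxs.make_pentamer_core(seed=0)


@pytest.fixture(scope="module")
def small_ensemble(pentamer_core):
    core, attach = pentamer_core
    return saxs.generate_ensemble(core, attach, tail_length=40, n_conformers=40, seed=7)


class TestGuinier:
    def test_exact_guinier_curve(self):
        q = np.linspace(0.005, 0.05, 60)
        curve = saxs.ScatteringCurve(q=q, i=100.0 * np.exp(-(q**2) * 44.0**2 / 3.0))
        res = saxs.guinier_fit(curve)
        assert res.rg == pytest.approx(44.0, abs=1e-9)
        assert res.i0 == pytest.approx(100.0, rel=1e-9)
        assert res.q_max_rg <= 1.3

    def test_sphere_form_factor(self):
        # low-q coverage below the diffraction window keeps the Guinier
        # truncation bias of the sphere inside 2%
        q = np.linspace(0.008, 0.31, 200)
        curve, _ = synth.gen_saxs_sphere(radius=30.0, q=q)
        res = saxs.guinier_fit(curve)
        assert res.rg == pytest.approx(SPHERE_RG_FACTOR * 30.0, rel=0.02)

    def test_flat_curve_gives_zero_rg(self):
        q = np.linspace(0.01, 0.1, 30)
        res = saxs.guinier_fit(saxs.ScatteringCurve(q=q, i=np.full_like(q, 5.0)))
        assert res.rg == 0.0
        assert not res.flagged

    def test_rising_curve_flagged(self):
        q = np.linspace(0.01, 0.1, 30)
        res = saxs.guinier_fit(saxs.ScatteringCurve(q=q, i=np.exp(+(q**2) * 900.0)))
        assert res.flagged


class TestPrInversion:
    def test_sphere_distribution_recovered(self):
        curve, _ = synth.gen_saxs_sphere(radius=30.0)
        pr = saxs.pr_invert(curve, d_max=60.0)
        analytic = saxs.sphere_pr(pr.r, 30.0)
        recovered = pr.p / np.trapezoid(pr.p, pr.r)
        l2 = np.sqrt(
            np.trapezoid((recovered - analytic) ** 2, pr.r)
            / np.trapezoid(analytic**2, pr.r)
        )
        assert l2 < 0.02
        assert pr.rg == pytest.approx(SPHERE_RG_FACTOR * 30.0, rel=0.01)

    def test_endpoints_vanish_by_construction(self):
        curve, _ = synth.gen_saxs_sphere(radius=25.0)
        pr = saxs.pr_invert(curve, d_max=55.0)
        assert pr.p[0] == 0.0
        assert pr.p[-1] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_reproduces_curve_within_noise(self):
        curve, _ = synth.gen_saxs_sphere(radius=30.0, relative_noise=0.02, seed=5)
        pr = saxs.pr_invert(curve, d_max=60.0)
        back = pr.back_transform(curve.q)
        scale = np.sum(back * curve.i / curve.sigma**2) / np.sum(back**2 / curve.sigma**2)
        avg_resid = np.mean(np.abs(scale * back - curve.i) / curve.sigma)
        assert avg_resid < 1.0

    def test_alpha_stability(self):
        curve, _ = synth.gen_saxs_sphere(radius=30.0)
        pr1 = saxs.pr_invert(curve, d_max=60.0)
        pr2 = saxs.pr_invert(curve, d_max=60.0, alpha=2.0 * pr1.alpha)
        assert pr2.rg == pytest.approx(pr1.rg, rel=0.01)

    def test_invalid_inputs_rejected(self):
        curve, _ = synth.gen_saxs_sphere(radius=30.0)
        with pytest.raises(ValueError):
            saxs.pr_invert(curve, d_max=60.0, alpha=-1.0)
        with pytest.raises(ValueError, match="q range"):
            saxs.pr_invert(curve.crop(0.018, 0.05), d_max=60.0)


class TestDebye:
    def test_single_bead_is_flat_unity(self):
        q = np.linspace(0.01, 0.3, 20)
        curve = saxs.debye_intensity(saxs.Conformer(coords=np.zeros((1, 3))), q)
        np.testing.assert_allclose(curve.i, 1.0)

    def test_two_beads_closed_form(self):
        d = 10.0
        conf = saxs.Conformer(coords=np.array([[0.0, 0, 0], [d, 0, 0]]))
        q = np.array([0.02, 0.05, 0.1, 0.2, 0.3])
        curve = saxs.debye_intensity(conf, q)
        np.testing.assert_allclose(curve.i, 2.0 + 2.0 * np.sin(q * d) / (q * d), rtol=1e-12)

    def test_guinier_of_cloud_matches_coordinate_rg(self, rng):
        coords = rng.normal(scale=15.0, size=(500, 3))
        conf = saxs.Conformer(coords=coords)
        q = np.linspace(0.002, 0.05, 60)
        res = saxs.guinier_fit(saxs.debye_intensity(conf, q))
        assert res.rg == pytest.approx(conf.rg, rel=0.02)

    def test_binned_path_matches_exact(self, rng):
        conf = saxs.Conformer(coords=rng.normal(scale=15.0, size=(150, 3)))
        q = np.linspace(0.018, 0.31, 80)
        exact = saxs.debye_intensity(conf, q).i
        binned = saxs.debye_intensity(conf, q, bin_width=0.02).i
        # documented bound: phase error < q·bin_width/2 ≈ 3e-3 rad
        np.testing.assert_allclose(binned, exact, rtol=1e-3)


class TestEnsemble:
    def test_core_is_rigid_across_conformers(self, small_ensemble, pentamer_core):
        core, _ = pentamer_core
        n_core = core.shape[0]
        for conf in small_ensemble.conformers:
            np.testing.assert_array_equal(conf.coords[:n_core], core)

    def test_seed_determinism(self, pentamer_core, small_ensemble):
        core, attach = pentamer_core
        again = saxs.generate_ensemble(core, attach, tail_length=40, n_conformers=40, seed=7)
        for a, b in zip(small_ensemble.conformers, again.conformers):
            np.testing.assert_array_equal(a.coords, b.coords)
        other = saxs.generate_ensemble(core, attach, tail_length=40, n_conformers=40, seed=8)
        assert not np.allclose(small_ensemble.rgs(), other.rgs())

    def test_no_steric_clashes(self, small_ensemble):
        from scipy.spatial.distance import pdist

        conf = small_ensemble.conformers[0]
        d = pdist(conf.coords)
        # only bonded neighbours may sit below the bead diameter
        close = d[d < 4.0]
        assert np.all(close > 3.8 - 1e-9)

    def test_tail_end_to_end_scaling_exponent(self, pentamer_core):
        """Excluded-volume walks scale as <R²> ~ N^(2ν) with ν between 0.5 and 0.65."""
        core, attach = pentamer_core
        lengths = [20, 40, 80]
        mean_sq = []
        for n in lengths:
            ens = saxs.generate_ensemble(core, attach, tail_length=n, n_conformers=25, seed=3)
            ee = []
            for conf in ens.conformers:
                for t in range(len(attach)):
                    tail = conf.coords[core.shape[0] + t * n : core.shape[0] + (t + 1) * n]
                    ee.append(np.sum((tail[-1] - core[attach[t]]) ** 2))
            mean_sq.append(np.mean(ee))
        nu = np.polyfit(np.log(lengths), np.log(mean_sq), 1)[0] / 2.0
        assert 0.5 <= nu <= 0.65


class TestChi2:
    def test_self_target_is_order_unity(self, small_ensemble):
        k = 10
        target, _ = synth.gen_saxs_from_conformer(
            small_ensemble.conformers[k], relative_noise=0.02, seed=11
        )
        res = saxs.chi2_score(small_ensemble, target)
        assert 0.5 <= res.table.loc[k, "chi2"] <= 1.5

    def test_identical_noiseless_curves_give_zero(self):
        conf = saxs.Conformer(coords=np.random.default_rng(0).normal(scale=10, size=(50, 3)))
        q = np.linspace(0.018, 0.31, 60)
        model = saxs.debye_intensity(conf, q, bin_width=0.02)
        target = saxs.ScatteringCurve(q=q, i=model.i, sigma=np.full_like(q, 1.0))
        res = saxs.chi2_score([conf], target)
        assert res.table["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-20)

    def test_scale_freedom(self, small_ensemble):
        target, _ = synth.gen_saxs_from_conformer(
            small_ensemble.conformers[5], relative_noise=0.02, seed=2
        )
        res1 = saxs.chi2_score([small_ensemble.conformers[5]], target)
        scaled = saxs.Conformer(coords=small_ensemble.conformers[5].coords)
        bigger = saxs.ScatteringCurve(q=target.q, i=10.0 * target.i, sigma=10.0 * target.sigma)
        res2 = saxs.chi2_score([scaled], bigger)
        assert res2.table["chi2"].iloc[0] == pytest.approx(res1.table["chi2"].iloc[0], rel=1e-9)

    def test_missing_sigma_rejected(self, small_ensemble):
        q = np.linspace(0.018, 0.31, 30)
        curve = saxs.ScatteringCurve(q=q, i=np.ones_like(q))
        with pytest.raises(ValueError, match="sigma"):
            saxs.chi2_score(small_ensemble, curve)

    def test_basin_minimum_near_target_rg(self, small_ensemble):
        rgs = small_ensemble.rgs()
        k = int(np.argsort(rgs)[len(rgs) // 2])
        target, truth = synth.gen_saxs_from_conformer(
            small_ensemble.conformers[k], relative_noise=0.02, seed=19
        )
        res = saxs.chi2_score(small_ensemble, target)
        assert res.best["rg"] == pytest.approx(truth["rg"], rel=0.05)


class TestRgConsistency:
    def test_three_routes_agree_on_sphere(self):
        q = np.linspace(0.008, 0.31, 200)
        curve, truth = synth.gen_saxs_sphere(radius=30.0, q=q)
        rg_guinier = saxs.guinier_fit(curve).rg
        rg_pr = saxs.pr_invert(curve, d_max=60.0).rg
        assert rg_guinier == pytest.approx(truth["rg"], rel=0.02)
        assert rg_pr == pytest.approx(truth["rg"], rel=0.02)

    def test_guinier_matches_coordinates_on_bead_cloud(self, small_ensemble):
        conf = small_ensemble.conformers[0]
        q = np.linspace(0.002, 1.2 / conf.rg, 50)
        rg_guinier = saxs.guinier_fit(saxs.debye_intensity(conf, q)).rg
        assert rg_guinier == pytest.approx(conf.rg, rel=0.02)


def test_curve_file_round_trip(tmp_path):
    curve, _ = synth.gen_saxs_sphere(radius=20.0, relative_noise=0.01, seed=3)
    path = tmp_path / "curve.dat"
    saxs.write_curve(curve, path)
    back = saxs.read_curve(path)
    np.testing.assert_allclose(back.q, curve.q)
    np.testing.assert_allclose(back.i, curve.i)
    np.testing.assert_allclose(back.sigma, curve.sigma)
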