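"""K_D estimation: pseudo-chi2, global fits, bootstrap, replicate summaries."""

import numpy as np
import pytest

from msbind import (
    BindingModel,
    GeneratorConfig,
    TitrationPoint,
    TitrationSeries,
    bootstrap_uncertainty,
    fit_titration,
    generate_titration,
    mole_fractions,
    pseudo_chi2,
    replicate_summary,
)
from msbind.exceptions import (
    IdentifiabilityError,
    InvalidInputError,
    ShapeError,
)


def noise_free_series(k_d, l_grid=(5, 10, 20, 40, 80, 160), p_total=0.5,
                      replicate="rep1"):
    model = BindingModel.from_kd(k_d)
    pts = [TitrationPoint(p_total=p_total, l_total=float(l),
                          f_obs=mole_fractions(model, p_total, float(l)).fractions,
                          replicate=replicate)
           for l in l_grid]
    return TitrationSeries(ligand="nuc", points=tuple(pts), n_max=model.n_max)


class TestTitrationTypes:
    def test_fraction_sum_tolerance_and_renormalization(self):
        f = np.array([0.700, 0.250, 0.055])  # sums to 1.005, inside tolerance
        p = TitrationPoint(p_total=0.5, l_total=10.0, f_obs=f)
        assert p.f_obs.sum() == pytest.approx(1.0, abs=1e-15)
        with pytest.raises(InvalidInputError):
            TitrationPoint(p_total=0.5, l_total=10.0,
                           f_obs=np.array([0.7, 0.25, 0.10]))

    def test_identifiability_requires_enough_concentrations(self):
        model = BindingModel.from_kd([10.0, 20.0])
        pts = tuple(
            TitrationPoint(p_total=0.5, l_total=l,
                           f_obs=mole_fractions(model, 0.5, l).fractions)
            for l in (10.0, 10.0, 20.0))
        with pytest.raises(IdentifiabilityError):
            TitrationSeries(ligand="nuc", points=pts, n_max=2)


class TestPseudoChi2:
    def test_zero_at_generating_model(self, adp_model):
        series = noise_free_series([17.8, 62.3])
        assert pseudo_chi2(adp_model, series) == pytest.approx(0.0, abs=1e-20)

    def test_single_perturbed_point(self, adp_model):
        series = noise_free_series([17.8, 62.3])
        pts = list(series.points)
        f = pts[0].f_obs.copy()
        f[0] -= 0.1
        f[1] += 0.1  # keep the sum at 1 so only two squared terms move
        pts[0] = TitrationPoint(p_total=0.5, l_total=pts[0].l_total, f_obs=f)
        perturbed = TitrationSeries(ligand="nuc", points=tuple(pts), n_max=2)
        assert pseudo_chi2(adp_model, perturbed) == pytest.approx(0.02, abs=1e-10)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k_d = 10.0 ** rng.uniform(0, 3, size=2)
            model = BindingModel.from_kd(k_d)
            pts = []
            for l in rng.uniform(1, 300, size=6):
                f = rng.dirichlet(np.ones(3))
                pts.append(TitrationPoint(p_total=0.5, l_total=float(l), f_obs=f))
            series = TitrationSeries(ligand="nuc", points=tuple(pts), n_max=2)
            naive = 0.0
            for p in series.points:
                f_calc = mole_fractions(model, p.p_total, p.l_total).fractions
                for i in range(3):
                    naive += (p.f_obs[i] - f_calc[i]) ** 2
            assert pseudo_chi2(model, series) == pytest.approx(naive, rel=1e-12)

    def test_shape_mismatch_raises(self, adp_model):
        series = noise_free_series([50.0])
        with pytest.raises(ShapeError):
            pseudo_chi2(adp_model, series)


class TestFitTitration:
    def test_noise_free_recovery(self):
        truth = np.array([17.8, 62.3])
        series = noise_free_series(truth)
        res = fit_titration(series, n_starts=4)
        assert res.converged
        assert np.allclose(res.k_d, truth, rtol=1e-6)
        assert res.chi2 < 1e-16

    def test_far_init_converges_with_multistart(self):
        truth = np.array([17.8, 62.3])
        series = noise_free_series(truth)
        res = fit_titration(series, init=truth * 100.0, n_starts=8, seed=0)
        assert np.allclose(res.k_d, truth, rtol=1e-5)

    def test_reparameterization_invariant_optimum(self):
        # the chi2 minimum must not depend on where optimization starts
        series = noise_free_series([47.8, 124.4])
        a = fit_titration(series, init=np.array([10.0, 10.0]), n_starts=6, seed=1)
        b = fit_titration(series, init=np.array([500.0, 500.0]), n_starts=6, seed=2)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-8)

    def test_point_order_irrelevant(self):
        series = noise_free_series([47.8, 124.4])
        rev = TitrationSeries(ligand="nuc", points=series.points[::-1], n_max=2)
        a = fit_titration(series, n_starts=2)
        b = fit_titration(rev, n_starts=2)
        assert np.allclose(a.k_d, b.k_d, rtol=1e-10)

    def test_per_replicate_mode_reports_mean_and_sd(self):
        cfg = GeneratorConfig(kd_nuc=(47.8, 124.4), noise_sd=0.02,
                              replicates=3, seed=5)
        series = generate_titration(cfg)
        res = fit_titration(series, mode="per_replicate", n_starts=2)
        assert res.mode == "per_replicate"
        assert len(res.per_replicate) == 3
        stacked = np.stack(list(res.per_replicate.values()))
        mean, sd = replicate_summary(stacked)
        assert np.allclose(res.k_d, mean)
        assert np.allclose(res.k_d_sd, sd)

    def test_chi2_at_optimum_not_above_truth(self):
        cfg = GeneratorConfig(kd_nuc=(47.8, 124.4), noise_sd=0.03,
                              replicates=1, seed=9)
        series = generate_titration(cfg)
        truth_chi2 = pseudo_chi2(BindingModel.from_kd([47.8, 124.4]), series)
        res = fit_titration(series, mode="pooled", n_starts=4)
        assert res.chi2 <= truth_chi2 + 1e-12
        assert res.chi2 > 0


class TestBootstrap:
    def test_noise_free_intervals_collapse(self):
        series = noise_free_series([17.8, 62.3],
                                   l_grid=(5, 10, 20, 40, 80, 160))
        bs = bootstrap_uncertainty(series, n_boot=100, seed=3)
        assert np.all(bs.k_d_upper - bs.k_d_lower < 1e-4 * bs.k_d_upper)

    def test_seed_determinism(self):
        cfg = GeneratorConfig(kd_nuc=(47.8, 124.4), noise_sd=0.03, seed=2)
        series = generate_titration(cfg)
        a = bootstrap_uncertainty(series, n_boot=100, seed=4)
        b = bootstrap_uncertainty(series, n_boot=100, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_small_n_boot_rejected(self):
        series = noise_free_series([17.8, 62.3])
        with pytest.raises(InvalidInputError):
            bootstrap_uncertainty(series, n_boot=50)


class TestReplicateSummary:
    def test_mean_and_sample_sd(self):
        mean, sd = replicate_summary([[40.0], [50.0], [60.0]])
        assert mean[0] == pytest.approx(50.0)
        assert sd[0] == pytest.approx(10.0)

    def test_identical_replicates_zero_sd(self):
        mean, sd = replicate_summary([[47.8, 124.4]] * 3)
        assert np.allclose(sd, 0.0)

    def test_matches_numpy_oracle_on_random_triples(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            trip = rng.uniform(10, 200, size=(3, 2))
            mean, sd = replicate_summary(trip)
            assert np.allclose(mean, trip.mean(axis=0))
            assert np.allclose(sd, trip.std(axis=0, ddof=1))

    def test_single_replicate_rejected(self):
        with pytest.raises(InvalidInputError):
            replicate_summary([[47.8, 124.4]])
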