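"""Likelihood, MCMC machinery and posterior behaviour."""

import numpy as np
import pytest

from cardioclock import (
    FitConfig,
    SampleRecord,
    build_scenario,
    cohort_from_csv,
    cohort_to_frame,
    decompose_fitted,
    f_to_delta,
    fit_constant_model,
    fit_group,
    fit_subject,
    forward_c14,
    log_likelihood,
)
from cardioclock.inference import run_adaptive_metropolis


def make_record(delta14c, group="NICM", sigma2_rel=0.02, **kw):
    defaults = dict(
        sample_id="s1", group=group, birth=1970.0, onset=2005.0,
        collection=2015.0, delta14c=delta14c, sigma2_rel=sigma2_rel,
        degree_of_nuclear_ploidy=291.7, binucleated_fraction=0.346,
    )
    defaults.update(kw)
    return SampleRecord(**defaults)


def noise_free_record(curve, free_rates, config=None, phase_mode=None, **kw):
    """A record whose Δ¹⁴C equals the forward prediction at the given rates."""
    config = config or FitConfig()
    rec = make_record(0.0, **kw)
    sc = build_scenario(rec, free_rates, config, phase_mode)
    return make_record(float(f_to_delta(forward_c14(sc, curve))), **kw)


class TestLogLikelihood:
    def test_peak_value_is_gaussian_normalizer(self, curve):
        rec = noise_free_record(curve, (0.01,))
        peak = -np.log(rec.sigma_f * np.sqrt(2 * np.pi))
        assert log_likelihood((0.01,), rec, curve) == pytest.approx(peak, abs=1e-6)

    def test_two_sigma_deviation_costs_two(self, curve):
        rec = noise_free_record(curve, (0.01,))
        # σ is relative to the measured F, so place the measurement where the
        # prediction sits exactly 2 of the *shifted* record's σ away:
        # F_new − F_pred = sigma2_rel·F_new  ⇔  F_new = F_pred/(1 − sigma2_rel)
        f_new = rec.f_measured / (1.0 - rec.sigma2_rel)
        shifted = make_record(float(f_to_delta(f_new)))
        peak = -np.log(shifted.sigma_f * np.sqrt(2 * np.pi))
        ll = log_likelihood((0.01,), shifted, curve)
        assert ll == pytest.approx(peak - 2.0, abs=1e-6)

    def test_negative_rate_returns_minus_inf(self, curve):
        rec = make_record(300.0)
        assert log_likelihood((-0.01,), rec, curve) == -np.inf

    def test_matches_independent_forward_evaluation_on_grid(self, curve):
        # grid oracle: rebuild the likelihood from forward_c14 + Gaussian
        rec = make_record(350.0)
        config = FitConfig()
        for r in np.geomspace(1e-5, 0.5, 12):
            sc = build_scenario(rec, (r,), config)
            pred = forward_c14(sc, curve)
            z = (rec.f_measured - pred) / rec.sigma_f
            expected = -0.5 * z * z - np.log(rec.sigma_f * np.sqrt(2 * np.pi))
            assert log_likelihood((r,), rec, curve) == pytest.approx(expected, abs=1e-8)


class TestSampler:
    def test_prior_only_reproduces_uniform_quantiles(self):
        bounds = np.array([[-2.0, 3.0]])
        chain, acc = run_adaptive_metropolis(
            lambda th: 0.0, bounds, 40_000, 2_000, np.random.default_rng(0)
        )
        q = np.quantile(chain[:, 0], [0.25, 0.5, 0.75])
        np.testing.assert_allclose(q, [-0.75, 0.5, 1.75], atol=0.15)
        assert 0.1 < acc < 0.9

    def test_determinism_same_seed_identical_output(self, curve):
        rec = make_record(350.0)
        cfg = FitConfig(seed=42, n_samples=2_000, n_burn=500)
        r1, r2 = fit_subject(rec, curve, cfg), fit_subject(rec, curve, cfg)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert r1.acceptance_fraction == r2.acceptance_fraction

    def test_rejects_infeasible_start(self):
        with pytest.raises(ValueError, match="zero posterior"):
            run_adaptive_metropolis(
                lambda th: -np.inf, np.array([[0.0, 1.0]]), 10, 10,
                np.random.default_rng(0),
            )


class TestPosteriors:
    def test_zero_rate_truth_concentrates_at_lower_bound(self, curve):
        rec = noise_free_record(curve, (0.0,), sigma2_rel=0.002)
        cfg = FitConfig(seed=1, n_samples=8_000, n_burn=2_000)
        res = fit_subject(rec, curve, cfg)
        # identifiability limit: posterior piles on the prior's lower decades
        assert res.median[0] < 0.01  # %/y, far below any renewal signal

    def test_recovers_strong_rate_within_factor_two(self, curve):
        rec = noise_free_record(curve, (0.03,), sigma2_rel=0.01)
        cfg = FitConfig(seed=2, n_samples=8_000, n_burn=2_000)
        res = fit_subject(rec, curve, cfg)
        assert 1.5 <= res.median[0] <= 6.0  # truth 3 %/y

    def test_median_matches_grid_map_at_low_noise(self, curve):
        rec = noise_free_record(curve, (0.03,), sigma2_rel=0.004)
        cfg = FitConfig(seed=3, n_samples=10_000, n_burn=3_000)
        res = fit_subject(rec, curve, cfg)
        grid = np.geomspace(1e-6, 1.0, 4001)
        ll = np.array([log_likelihood((r,), rec, curve) for r in grid])
        map_pct = 100.0 * grid[np.argmax(ll)]
        assert res.median[0] == pytest.approx(map_pct, rel=0.25)

    def test_interval_endpoints_bracket_median(self, curve):
        res = fit_subject(make_record(350.0), curve,
                          FitConfig(seed=4, n_samples=3_000, n_burn=500))
        assert res.ci50[0, 0] <= res.median[0] <= res.ci50[0, 1]
        assert res.ci95[0, 0] <= res.ci50[0, 0]
        assert res.ci95[0, 1] >= res.ci50[0, 1]


class TestGroupFits:
    def test_single_record_group_matches_subject_fit(self, curve):
        rec = make_record(350.0)
        cfg = FitConfig(seed=5, n_samples=6_000, n_burn=1_500)
        assert fit_group([rec], curve, cfg).median[0] == pytest.approx(
            fit_subject(rec, curve, cfg).median[0]
        )

    def test_duplicated_record_narrows_posterior(self, curve):
        rec = noise_free_record(curve, (0.03,), sigma2_rel=0.02)
        cfg = FitConfig(seed=6, n_samples=8_000, n_burn=2_000)
        one = fit_subject(rec, curve, cfg)
        two_recs = [rec, make_record(rec.delta14c, sample_id="s2")]
        two = fit_group(two_recs, curve, cfg)
        width = lambda res: np.log(res.ci50[0, 1] / res.ci50[0, 0])
        assert width(two) < width(one)

    def test_mixed_groups_rejected(self, curve):
        recs = [make_record(350.0), make_record(340.0, group="ICM", sample_id="s2")]
        with pytest.raises(ValueError, match="multiple groups"):
            fit_group(recs, curve)

    def test_merge_mode_runs_and_pools_draws(self, curve):
        recs = [make_record(350.0), make_record(360.0, sample_id="s2")]
        cfg = FitConfig(seed=7, n_samples=2_000, n_burn=500, group_mode="merge")
        res = fit_group(recs, curve, cfg)
        assert res.samples.shape[0] == 4_000


class TestConstantModel:
    def test_zero_noise_limit_collapses_to_grid_solution(self, curve):
        rec = noise_free_record(
            curve, (0.0055,), phase_mode="constant", group="healthy", onset=None,
            sigma2_rel=0.002, degree_of_nuclear_ploidy=176.9,
            binucleated_fraction=0.193,
        )
        cfg = FitConfig(seed=8, n_samples=10_000, n_burn=3_000)
        res = fit_constant_model(rec, curve, cfg)
        # grid-search oracle over the lifelong rate
        grid = np.geomspace(1e-5, 0.1, 3001)
        cfg_c = FitConfig(phase_mode="constant")
        ll = [log_likelihood((r,), rec, curve, cfg_c, "constant") for r in grid]
        best_pct = 100.0 * grid[int(np.argmax(ll))]
        assert best_pct == pytest.approx(0.55, rel=0.05)
        assert res.median[0] == pytest.approx(best_pct, rel=0.3)
        assert res.param_names == ("lifelong_rate",)


class TestDecomposition:
    def _degenerate_posterior(self, curve, rec, rate_pct):
        cfg = FitConfig(seed=9, n_samples=200, n_burn=50)
        res = fit_subject(rec, curve, cfg)
        object.__setattr__(res, "samples", np.full_like(res.samples, rate_pct))
        return res

    def test_degenerate_posterior_equals_point_evaluation(self, curve):
        from cardioclock import synthesis_flux_decomposition
        rec = make_record(350.0)
        post = self._degenerate_posterior(curve, rec, 0.03)
        out = decompose_fitted(rec, post, at="collection")
        sc = build_scenario(rec, (0.0003,), FitConfig())
        point = synthesis_flux_decomposition(sc, rec.collection)
        assert out["renewal_fraction"]["median"] == pytest.approx(
            point.renewal_fraction, abs=1e-12
        )
        assert out["renewal_fraction"]["ci50"][0] == out["renewal_fraction"]["ci50"][1]

    def test_high_rate_scenario_has_larger_renewal_share(self, curve):
        rec = make_record(350.0)
        low = decompose_fitted(rec, self._degenerate_posterior(curve, rec, 0.03))
        high = decompose_fitted(rec, self._degenerate_posterior(curve, rec, 3.0))
        assert high["renewal_fraction"]["median"] > 10 * low["renewal_fraction"]["median"]

    def test_pre_onset_timepoint_is_renewal_dominated(self, curve):
        rec = make_record(350.0)
        post = self._degenerate_posterior(curve, rec, 0.03)
        out = decompose_fitted(rec, post, at="pre_onset_minus_1y")
        assert out["renewal_fraction"]["median"] > 0.5


class TestRecordIO:
    def test_roundtrip_through_csv(self, tmp_path, curve):
        recs = [make_record(350.0), make_record(300.0, sample_id="s2",
                                                lvad_implant=2013.0,
                                                group="LVAD_responder")]
        path = tmp_path / "cohort.csv"
        cohort_to_frame(recs).to_csv(path, index=False)
        back = cohort_from_csv(path)
        assert [r.sample_id for r in back] == ["s1", "s2"]
        assert back[1].lvad_implant == 2013.0
        assert back[0].lvad_implant is None

    def test_schema_error_carries_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        frame = cohort_to_frame([make_record(350.0)])
        frame.loc[0, "birth"] = 2020.0  # after collection
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 2"):
            cohort_from_csv(path)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="ploidy"):
            make_record(350.0, degree_of_nuclear_ploidy=80.0)
        with pytest.raises(ValueError, match="onset"):
            make_record(350.0, onset=1960.0)
        with pytest.raises(ValueError, match="implant"):
            make_record(350.0, onset=None, lvad_implant=2010.0)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        cfg = FitConfig(seed=11, n_samples=1000, phase_mode="three_phase")
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert FitConfig.from_yaml(path) == cfg

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="phase mode"):
            FitConfig(phase_mode="four_phase")
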