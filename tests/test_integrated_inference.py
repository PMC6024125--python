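import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import logit

from reintroipm.data_model_io import (
    CaptureHistory,
    Dataset,
    FecundityRecord,
    Individual,
    ModelConfig,
)
from reintroipm.integrated_inference import (
    ConvergenceError,
    PosteriorResult,
    carrying_capacity,
    derive_lambda,
    fit,
    prior_only_lambda,
    reduce_model,
    sequential_analysis,
)
from reintroipm.priors import (
    PriorDistribution,
    informative_priors,
    placeholder_informative_path,
    uninformative_priors,
)
from reintroipm.synthetic_data import simulate_population, tawharanui_preset


def fake_result(draws: dict, config: ModelConfig | None = None, **kw) -> PosteriorResult:
    """Wrap plain draw vectors in a PosteriorResult (single chain)."""
    return PosteriorResult(
        draws={k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in draws.items()},
        re_draws={},
        diagnostics={},
        config=config or ModelConfig.reduced(),
        n_years_used=9,
        **kw,
    )


class TestDeriveLambda:
    def test_plugin_arithmetic(self):
        res = fake_result({
            "phi_a": [0.78], "phi_j_mean": [0.25], "alpha_f": [np.log(3.8)],
        })
        lam = derive_lambda(res)
        assert lam["mean"] == pytest.approx(1.255)

    def test_zero_juvenile_survival_boundary(self):
        res = fake_result({
            "phi_a": [0.78], "phi_j_mean": [1e-12], "alpha_f": [np.log(3.8)],
        })
        assert derive_lambda(res)["mean"] == pytest.approx(0.78, abs=1e-6)

    def test_density_required_under_dd(self):
        cfg = ModelConfig.reduced(density_on_fecundity=True)
        res = fake_result(
            {"phi_a": [0.78], "phi_j_mean": [0.25], "alpha_f": [np.log(4.8)],
             "beta_dens_f_raw": [-0.004]},
            config=cfg,
        )
        with pytest.raises(ValueError, match="density"):
            derive_lambda(res)
        at80 = derive_lambda(res, density=80.0)
        assert at80["mean"] < derive_lambda(res, density=0.0)["mean"]

    def test_formula_conservation_per_draw(self):
        rng = np.random.default_rng(0)
        draws = {
            "phi_a": rng.uniform(0.6, 0.9, 100),
            "phi_j_mean": rng.uniform(0.1, 0.4, 100),
            "alpha_f": rng.normal(np.log(3.8), 0.2, 100),
        }
        res = fake_result(draws)
        lam = derive_lambda(res)["draws"]
        expected = draws["phi_a"] + 0.5 * draws["phi_j_mean"] * np.exp(draws["alpha_f"])
        assert np.array_equal(lam, expected)


class TestCarryingCapacity:
    @staticmethod
    def _dd_result(phi_a, phi_j, f0, f80, n=1):
        beta = (np.log(f80) - np.log(f0)) / 80.0
        cfg = ModelConfig.reduced(density_on_fecundity=True)
        return fake_result(
            {
                "phi_a": [phi_a] * n,
                "phi_j_mean": [phi_j] * n,
                "alpha_f": [np.log(f0)] * n,
                "beta_dens_f_raw": [beta] * n,
            },
            config=cfg,
        )

    def test_closed_form_matches_root_find(self):
        res = self._dd_result(0.78, 0.25, 4.8, 3.3)
        K = carrying_capacity(res)["mean"]

        # independent oracle: numeric root of lambda(N) = 1
        beta = (np.log(3.3) - np.log(4.8)) / 80.0

        def lam(N):
            return 0.78 + 0.5 * 0.25 * np.exp(np.log(4.8) + beta * N) - 1.0

        K_oracle = brentq(lam, 0.0, 2000.0)
        assert K == pytest.approx(K_oracle, abs=1e-8)
        assert K == pytest.approx(214.2, abs=0.5)

    def test_boundary_lambda0_equal_1_gives_zero(self):
        # choose f0 so that lambda(0) == 1 exactly
        phi_a, phi_j = 0.78, 0.25
        f0 = 2 * (1 - phi_a) / phi_j
        res = self._dd_result(phi_a, phi_j, f0, f0 * 0.7)
        assert carrying_capacity(res)["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_undefined_draws_excluded_and_reported(self):
        cfg = ModelConfig.reduced(density_on_fecundity=True)
        res = fake_result(
            {
                "phi_a": [0.78, 0.78],
                "phi_j_mean": [0.25, 0.25],
                "alpha_f": [np.log(4.8), np.log(4.8)],
                "beta_dens_f_raw": [-0.004, +0.002],  # second draw has no K
            },
            config=cfg,
        )
        out = carrying_capacity(res)
        assert out["proportion_undefined"] == pytest.approx(0.5)
        assert out["draws"].size == 1

    def test_all_undefined_is_an_error(self):
        cfg = ModelConfig.reduced(density_on_fecundity=True)
        res = fake_result(
            {"phi_a": [0.5], "phi_j_mean": [0.1], "alpha_f": [0.0],
             "beta_dens_f_raw": [0.01]},
            config=cfg,
        )
        with pytest.raises(ValueError, match="undefined"):
            carrying_capacity(res)

    def test_requires_dd_config(self):
        res = fake_result({"phi_a": [0.8]})
        with pytest.raises(ValueError, match="density-dependent"):
            carrying_capacity(res)


class TestReduceModel:
    def test_all_positive_coefficient_retained(self):
        cfg = ModelConfig.reduced(sex_on_adult=True)
        res = fake_result({"beta_sex": np.linspace(0.1, 0.5, 50)}, config=cfg)
        assert reduce_model(res, cfg).sex_on_adult

    def test_interval_containing_zero_dropped(self):
        cfg = ModelConfig.reduced(sex_on_adult=True)
        res = fake_result({"beta_sex": np.linspace(-0.2, 0.3, 50)}, config=cfg)
        assert not reduce_model(res, cfg).sex_on_adult

    def test_sd_concentrated_near_zero_dropped(self):
        cfg = ModelConfig.reduced(year_re_on_juvenile=True)
        res = fake_result({"sigma_year_j": np.full(50, 0.01)}, config=cfg)
        assert not reduce_model(res, cfg).year_re_on_juvenile
        res2 = fake_result({"sigma_year_j": np.full(50, 0.5)}, config=cfg)
        assert reduce_model(res2, cfg).year_re_on_juvenile

    def test_zero_truth_year_effect_usually_dropped(self):
        """Data generated with no year effect on fecundity: the reduction rule
        should drop it in nearly all replicates (scaled-down replicate count
        for runtime)."""
        cfg = ModelConfig.reduced(
            year_re_on_fecundity=True, iterations=4000, burn_in=1500,
            chains=1, thin=2, check_convergence=False,
        )
        drops = 0
        n_rep = 8
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            T = 10
            inds, rows, recs = [], [], []
            for i in range(150):
                fid = f"f{i}"
                inds.append(Individual(id=fid, sex="female", origin="translocated",
                                       banding_method="not-applicable", first_occasion=0))
                rows.append([1] * T)
                ef = 0.3 * rng.standard_normal()
                for yr in range(1, 9):
                    recs.append(FecundityRecord(
                        fid, yr, int(rng.poisson(np.exp(np.log(3.0) + ef))), 30.0))
            hist = CaptureHistory(inds, np.array(rows), [str(t) for t in range(T)])
            data = Dataset(history=hist, fecundity=recs, unbanded=[])
            res = fit(data, uninformative_priors(), cfg.replace(seed=rep))
            drops += not reduce_model(res, cfg).year_re_on_fecundity
        assert drops >= int(0.9 * n_rep)


class TestFit:
    def test_recovers_truth_on_preset(self, preset_dataset, quick_config):
        data, truth, _ = preset_dataset
        res = fit(data, uninformative_priors(), quick_config.replace(seed=21))
        for name, true_val in (
            ("phi_a", truth.phi_a),
            ("p", truth.p),
            ("f0", float(np.exp(truth.alpha_f))),
        ):
            s = res.summary(name)
            assert s["lower95"] < true_val < s["upper95"], (name, s, true_val)

    def test_near_degenerate_priors_dominate(self, preset_dataset):
        """Priors almost point-mass far from the data's truth: the posterior
        must sit at the prior (dominated-prior limit)."""
        data, truth, _ = preset_dataset
        pri = uninformative_priors()
        target = logit(0.60)  # far from truth 0.78
        pri.entries["logit_phi_a"] = PriorDistribution("normal", "logit", target, 0.005)
        cfg = ModelConfig.reduced(iterations=5000, burn_in=2000, chains=1,
                                  thin=2, check_convergence=False, seed=5)
        res = fit(data, pri, cfg)
        post = res.flat("logit_phi_a")
        assert abs(post.mean() - target) < 0.05
        assert post.std() < 0.05

    def test_convergence_error_carries_offenders(self, preset_dataset):
        data, _, _ = preset_dataset
        cfg = ModelConfig.reduced(iterations=220, burn_in=200, chains=3, seed=1,
                                  rhat_threshold=1.0001)
        with pytest.raises(ConvergenceError) as err:
            fit(data, uninformative_priors(), cfg)
        assert err.value.offenders

    def test_reproducible_given_seed(self, preset_dataset):
        data, _, _ = preset_dataset
        cfg = ModelConfig.reduced(iterations=1200, burn_in=600, chains=1,
                                  check_convergence=False, seed=77)
        a = fit(data, uninformative_priors(), cfg)
        b = fit(data, uninformative_priors(), cfg)
        for name in a.names:
            assert np.array_equal(a.draws[name], b.draws[name])


class TestPriorOnlyLambda:
    def test_two_code_paths_agree(self):
        """The packaged prior-predictive push-forward must match an
        independent Monte-Carlo through the growth-rate formula."""
        import yaml
        from scipy.special import expit

        pri = informative_priors(placeholder_informative_path())
        lam = prior_only_lambda(pri, n_draws=200_000, seed=3)

        blocks = yaml.safe_load(placeholder_informative_path().read_text())["priors"]
        rng = np.random.default_rng(99)
        n = 200_000
        sa = expit(rng.normal(blocks["logit_phi_a"]["par1"],
                              blocks["logit_phi_a"]["par2"], n))
        sj = expit(rng.normal(blocks["logit_phi_j"]["par1"],
                              blocks["logit_phi_j"]["par2"], n))
        f = np.exp(rng.normal(blocks["alpha_f"]["par1"], blocks["alpha_f"]["par2"], n))
        oracle = sa + 0.5 * sj * f
        assert lam["mean"] == pytest.approx(oracle.mean(), abs=0.01)
        assert lam["lower95"] == pytest.approx(np.quantile(oracle, 0.025), abs=0.01)
        assert lam["upper95"] == pytest.approx(np.quantile(oracle, 0.975), abs=0.02)


class TestSequential:
    def test_k_below_two_rejected(self, preset_dataset, quick_config):
        data, _, _ = preset_dataset
        pair = {"informative": informative_priors(placeholder_informative_path()),
                "uninformative": uninformative_priors()}
        with pytest.raises(ValueError, match="2 years"):
            sequential_analysis(data, pair, quick_config, [1])

    def test_truncation_at_full_length_is_identity(self, preset_dataset):
        data, _, _ = preset_dataset
        cfg = ModelConfig.reduced(iterations=1500, burn_in=700, chains=1,
                                  check_convergence=False, seed=31)
        full = fit(data, uninformative_priors(), cfg)
        trunc = fit(data.truncate(data.history.n_occasions),
                    uninformative_priors(), cfg)
        for name in full.names:
            assert np.array_equal(full.draws[name], trunc.draws[name])

    def test_rows_and_year_re_schedule(self, preset_dataset, quick_config):
        data, _, _ = preset_dataset
        pair = {"informative": informative_priors(placeholder_informative_path()),
                "uninformative": uninformative_priors()}
        cfg = quick_config.replace(iterations=2000, burn_in=900, seed=41)
        seq = sequential_analysis(data, pair, cfg, [2, 5])
        assert len(seq["rows"]) == 4
        ks = sorted({r["k"] for r in seq["rows"]})
        assert ks == [2, 5]
        for row in seq["rows"]:
            assert row["lower95"] < row["mean"] < row["upper95"]
        assert set(seq["first_k_above_1"]) == {"informative", "uninformative"}
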