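"""Joint posterior inference for the integrated model, plus derived
quantities: growth rate, carrying capacity, model reduction and the
sequential year-by-year precision analysis.

The survival (mark-resighting) and fecundity likelihoods share no
parameters, so the joint posterior factorizes into the two submodel
posteriors; each is sampled with an adaptive Metropolis global block plus
vectorized conditionally-independent random-effect updates (non-centered
parameterization).  Draw columns are aligned across submodels so a row of
the combined draw matrix is one draw from the joint posterior.

Density covariates are standardized internally (centering/scaling by the
observed density series) for sampler geometry; all reported slopes and
intercepts are back-transformed to the raw bird-count scale, with the
intercept at density 0.
"""

from __future__ import annotations

import types
from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.special import expit, gammaln, logit


from ._mcmc import AdaptiveSampler, REBlock
from .data_model_io import Dataset, ModelConfig
from .fecundity_model import FecundityData
from .priors import PriorSet
from .survival_model import SurvivalData, per_individual_loglik

__all__ = [
    "PosteriorResult",
    "ConvergenceError",
    "fit",
    "derive_lambda",
    "prior_only_lambda",
    "carrying_capacity",
    "reduce_model",
    "sequential_analysis",
]


class ConvergenceError(RuntimeError):
    """Raised when R-hat exceeds the threshold; carries the offenders."""

    def __init__(self, offenders: dict[str, float]):
        self.offenders = offenders
        detail = ", ".join(f"{k}: rhat={v:.3f}" for k, v in offenders.items())
        super().__init__(f"MCMC did not converge ({detail})")


@dataclass
class PosteriorResult:
    """MCMC draws, diagnostics and derived quantities for one fit.

    ``draws`` maps parameter name -> array of shape (chains, n_draws); use
    :meth:`flat` for the pooled vector.  Natural-scale aliases (``phi_a``,
    ``p``, ``phi_j_mean``, ``f0``) are included alongside the sampled
    link-scale parameters.  ``re_draws`` maps random-effect block name ->
    (chains, n_draws, size).
    """

    draws: dict[str, np.ndarray]
    re_draws: dict[str, np.ndarray]
    diagnostics: dict[str, dict[str, float]]
    config: ModelConfig
    n_years_used: int
    density_mean: float = 0.0  # fecundity-covariate standardization
    density_sd: float = 1.0
    sdens_mean: float = 0.0  # juvenile-survival-covariate standardization
    sdens_sd: float = 1.0
    derived: dict = field(default_factory=dict)
    female_ids: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_draws_total(self) -> int:
        first = next(iter(self.draws.values()))
        return first.shape[0] * first.shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def re_flat(self, name: str) -> np.ndarray:
        arr = self.re_draws[name]
        return arr.reshape(-1, arr.shape[-1])

    def summary(self, name: str) -> dict[str, float]:
        x = self.flat(name)
        return {
            "mean": float(x.mean()),
            "lower95": float(np.quantile(x, 0.025)),
            "upper95": float(np.quantile(x, 0.975)),
        }


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------

def _survival_globals(config: ModelConfig, n_occasions: int) -> list[str]:
    names = ["logit_phi_a", "logit_p", "logit_phi_j"]
    if config.sex_on_adult:
        names.append("beta_sex")
    if config.translocation_effect:
        names.append("delta_trans")
    if config.banding_age_effect:
        names.append("gamma_band")
    if config.density_on_juvenile:
        names.append("beta_dens_j")
    if config.year_re_on_juvenile:
        names.append("sigma_year_j")
    if config.year_re_on_resighting:
        names.append("sigma_year_p")
        names.extend(f"z_p_{t}" for t in range(1, n_occasions))
    return names


def _fecundity_globals(config: ModelConfig) -> list[str]:
    names = ["alpha_c"]
    if config.density_on_fecundity:
        names.append("beta_dens_f")
    if config.female_re_on_fecundity:
        names.append("sigma_female")
    if config.year_re_on_fecundity:
        names.append("sigma_year_f")
    return names


_PRIOR_KEY = {  # sampled name -> PriorSet entry
    "logit_phi_a": "logit_phi_a",
    "logit_p": "logit_p",
    "logit_phi_j": "logit_phi_j",
    "beta_sex": "beta_sex",
    "delta_trans": "delta_trans",
    "gamma_band": "gamma_band",
    "beta_dens_j": "beta_dens_j",
    "sigma_year_j": "sigma_year_j",
    "sigma_year_p": "sigma_year_p",
    "alpha_c": "alpha_f",
    "beta_dens_f": "beta_dens_f",
    "sigma_female": "sigma_female",
    "sigma_year_f": "sigma_year_f",
}


_HALF_LOG_2PI = 0.9189385332046727


def _std_normal_logpdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * z * z - _HALF_LOG_2PI


def _prior_logpdf_fn(names: list[str], priors: PriorSet):
    """Vectorized prior over a global parameter vector.  Normal entries (and
    the z coordinates of a resighting year effect, which are standard-normal
    by non-centering) contribute quadratics; uniform entries contribute a
    constant inside their bounds and -inf outside."""
    dists = [None if n.startswith("z_p_") else priors[_PRIOR_KEY[n]] for n in names]
    mean = np.array([0.0 if d is None else (d.par1 if d.family == "normal" else 0.0) for d in dists])
    sd = np.array([1.0 if d is None else (d.par2 if d.family == "normal" else 1.0) for d in dists])
    is_norm = np.array([d is None or d.family == "normal" for d in dists])
    unif_idx = np.where(~is_norm)[0]
    unif_lo = np.array([dists[i].par1 for i in unif_idx])
    unif_hi = np.array([dists[i].par2 for i in unif_idx])
    unif_const = -np.sum(np.log(unif_hi - unif_lo)) if unif_idx.size else 0.0
    norm_log_sd = float(np.log(sd[is_norm]).sum())
    n_norm = int(is_norm.sum())

    def support(theta: np.ndarray) -> bool:
        u = theta[unif_idx]
        return bool(((u >= unif_lo) & (u <= unif_hi)).all())

    def logpdf(theta: np.ndarray) -> float:
        if not support(theta):
            return float("-inf")
        z = (theta[is_norm] - mean[is_norm]) / sd[is_norm]
        return float(-0.5 * z @ z - norm_log_sd - n_norm * _HALF_LOG_2PI + unif_const)

    return logpdf, support


# ---------------------------------------------------------------------------
# survival submodel
# ---------------------------------------------------------------------------

class _SurvivalSampler:
    def __init__(self, data: SurvivalData, config: ModelConfig, priors: PriorSet):
        self.data = data
        self.config = config
        T = data.n_occasions
        self.T = T
        self.names = _survival_globals(config, T)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.prior_logpdf, self.support = _prior_logpdf_fn(self.names, priors)
        # standardized density per interval year (used for juvenile survival)
        if config.density_on_juvenile:
            if data.density is None:
                raise ValueError("density series required for density_on_juvenile")
            d = np.asarray(data.density, dtype=float)
            self.dens_mean = float(d.mean())
            self.dens_sd = float(d.std()) or 1.0
            self.dens_std = (d - self.dens_mean) / self.dens_sd
        else:
            self.dens_mean, self.dens_sd, self.dens_std = 0.0, 1.0, None
        # sub-data restricted to rows whose likelihood depends on z_year_j
        wild = np.where(data.wild_born & (data.first < T - 1))[0]
        self.wild_rows = wild
        self.sub = SurvivalData(
            y=data.y[wild],
            first=data.first[wild],
            is_male=data.is_male[wild],
            is_female=data.is_female[wild],
            translocated=data.translocated[wild],
            fledgling_banded=data.fledgling_banded[wild],
            wild_born=data.wild_born[wild],
            first_interval_fraction=data.first_interval_fraction,
            weights=data.weights[wild],
            density=data.density,
        )
        self.juv_year = data.first[wild]

    def _params(self, theta: np.ndarray, z_year_j: np.ndarray) -> types.SimpleNamespace:
        g = lambda n, default=0.0: theta[self.index[n]] if n in self.index else default
        sigma_j = g("sigma_year_j")
        eps_j = sigma_j * z_year_j if self.config.year_re_on_juvenile else np.zeros(0)
        if self.config.density_on_juvenile and not eps_j.size:
            eps_j = np.zeros(self.T - 1)
        if self.config.year_re_on_resighting:
            sigma_p = g("sigma_year_p")
            z_p = np.array([theta[self.index[f"z_p_{t}"]] for t in range(1, self.T)])
            eps_p = np.concatenate([[0.0], sigma_p * z_p])
        else:
            eps_p = np.zeros(0)
        beta_j = g("beta_dens_j") / self.dens_sd if self.config.density_on_juvenile else 0.0
        return types.SimpleNamespace(
            phi_a=expit(theta[self.index["logit_phi_a"]]),
            p=expit(theta[self.index["logit_p"]]),
            phi_j_mean=expit(theta[self.index["logit_phi_j"]]),
            beta_sex=g("beta_sex"),
            delta_trans=g("delta_trans"),
            gamma_band=g("gamma_band"),
            beta_dens_j=beta_j,
            # shift so the sampled coefficient acts on the standardized scale
            eps_year_j=eps_j - beta_j * self.dens_mean if self.config.density_on_juvenile else eps_j,
            eps_year_p=eps_p,
        )

    def logdens_global(self, theta: np.ndarray, re: dict[str, np.ndarray]) -> float:
        lp = self.prior_logpdf(theta)
        if not np.isfinite(lp):
            return float("-inf")
        z = re.get("z_year_j", np.zeros(self.T - 1))
        params = self._params(theta, z)
        ll = per_individual_loglik(self.data, params)
        total = float(np.dot(self.data.weights, ll))
        if not np.isfinite(total):
            return float("-inf")
        if self.config.year_re_on_juvenile:
            lp += float(_std_normal_logpdf(z).sum())
        return lp + total

    def unit_logdens_year_j(self, z: np.ndarray, theta: np.ndarray, re: dict) -> np.ndarray:
        params = self._params(theta, z)
        ll = per_individual_loglik(self.sub, params) * self.sub.weights
        out = np.bincount(self.juv_year, weights=ll, minlength=self.T - 1)
        return out + _std_normal_logpdf(z)

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(len(self.names))
        theta[self.index["logit_phi_a"]] = logit(0.7)
        theta[self.index["logit_p"]] = logit(0.85)
        theta[self.index["logit_phi_j"]] = logit(0.2)
        if "sigma_year_j" in self.index:
            theta[self.index["sigma_year_j"]] = 0.3
        if "sigma_year_p" in self.index:
            theta[self.index["sigma_year_p"]] = 0.3
        jitter = 0.05 * rng.standard_normal(theta.size)
        for n in self.names:  # keep SDs positive under jitter
            if n.startswith("sigma"):
                jitter[self.index[n]] = abs(jitter[self.index[n]])
        return theta + jitter

    def run_chain(self, config: ModelConfig, seed: int):
        blocks = []
        if config.year_re_on_juvenile:
            blocks.append(
                REBlock("z_year_j", self.T - 1, self.unit_logdens_year_j)
            )
        rng = np.random.default_rng(seed)
        sampler = AdaptiveSampler(
            self.logdens_global, self.initial(rng), blocks, self.support
        )
        return sampler.run(config.iterations, config.burn_in, seed, config.thin)


# ---------------------------------------------------------------------------
# fecundity submodel
# ---------------------------------------------------------------------------

class _FecunditySampler:
    def __init__(self, data: FecundityData, config: ModelConfig, priors: PriorSet):
        self.data = data
        self.config = config
        self.names = _fecundity_globals(config)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.prior_logpdf, self.support = _prior_logpdf_fn(self.names, priors)
        if config.density_on_fecundity:
            d = data.density
            self.dens_mean = float(d.mean()) if d.size else 0.0
            self.dens_sd = (float(d.std()) or 1.0) if d.size else 1.0
            self.dens_std = (d - self.dens_mean) / self.dens_sd
        else:
            self.dens_mean, self.dens_sd = 0.0, 1.0
            self.dens_std = np.zeros(data.n_records)
        self.n_years = int(data.year.max()) + 1 if data.n_records else 1

    def _eta(self, theta, z_fem, z_yr):
        eta = theta[self.index["alpha_c"]] + np.zeros(self.data.n_records)
        if self.config.density_on_fecundity:
            eta = eta + theta[self.index["beta_dens_f"]] * self.dens_std
        if self.config.female_re_on_fecundity:
            eta = eta + theta[self.index["sigma_female"]] * z_fem[self.data.female_index]
        if self.config.year_re_on_fecundity:
            eta = eta + theta[self.index["sigma_year_f"]] * z_yr[self.data.year]
        return eta

    def _record_loglik(self, eta):
        return self.data.counts * eta - np.exp(eta) - gammaln(self.data.counts + 1.0)

    def logdens_global(self, theta, re):
        lp = self.prior_logpdf(theta)
        if not np.isfinite(lp):
            return float("-inf")
        z_fem = re.get("z_female", np.zeros(self.data.n_females))
        z_yr = re.get("z_year_f", np.zeros(self.n_years))
        ll = float(self._record_loglik(self._eta(theta, z_fem, z_yr)).sum())
        if self.config.female_re_on_fecundity:
            lp += float(_std_normal_logpdf(z_fem).sum())
        if self.config.year_re_on_fecundity:
            lp += float(_std_normal_logpdf(z_yr).sum())
        return lp + ll

    def unit_logdens_female(self, z, theta, re):
        z_yr = re.get("z_year_f", np.zeros(self.n_years))
        ll = self._record_loglik(self._eta(theta, z, z_yr))
        return np.bincount(self.data.female_index, weights=ll, minlength=self.data.n_females) + _std_normal_logpdf(z)

    def unit_logdens_year(self, z, theta, re):
        z_fem = re.get("z_female", np.zeros(self.data.n_females))
        ll = self._record_loglik(self._eta(theta, z_fem, z))
        return np.bincount(self.data.year, weights=ll, minlength=self.n_years) + _std_normal_logpdf(z)

    def run_chain(self, config: ModelConfig, seed: int):
        blocks = []
        if config.female_re_on_fecundity and self.data.n_females:
            blocks.append(
                REBlock("z_female", self.data.n_females, self.unit_logdens_female)
            )
        if config.year_re_on_fecundity:
            blocks.append(
                REBlock("z_year_f", self.n_years, self.unit_logdens_year)
            )
        rng = np.random.default_rng(seed)
        theta0 = np.zeros(len(self.names))
        mean_count = self.data.counts.mean() if self.data.n_records else 1.0
        theta0[self.index["alpha_c"]] = np.log(max(mean_count, 0.2))
        if "sigma_female" in self.index:
            theta0[self.index["sigma_female"]] = 0.3
        if "sigma_year_f" in self.index:
            theta0[self.index["sigma_year_f"]] = 0.3
        jitter = 0.05 * rng.standard_normal(theta0.size)
        for n in self.names:
            if n.startswith("sigma"):
                jitter[self.index[n]] = abs(jitter[self.index[n]])
        sampler = AdaptiveSampler(
            self.logdens_global, theta0 + jitter, blocks, self.support
        )
        return sampler.run(config.iterations, config.burn_in, seed, config.thin)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def _density_series(data: Dataset) -> np.ndarray:
    """Per-occasion density covariate assembled from the fecundity records
    (each record carries the season-start breeding population size); gaps are
    filled by nearest-neighbour interpolation."""
    T = data.history.n_occasions
    dens = np.full(T, np.nan)
    for r in data.fecundity:
        dens[r.year] = r.density
    if np.isnan(dens).all():
        return np.ones(T)
    idx = np.arange(T)
    known = ~np.isnan(dens)
    return np.interp(idx, idx[known], dens[known])


def fit(data: Dataset, priors: PriorSet, config: ModelConfig) -> PosteriorResult:
    """Sample the joint posterior of the integrated model.

    Raises :class:`ConvergenceError` if any monitored parameter has R-hat
    above ``config.rhat_threshold`` (when ``config.check_convergence``).
    """
    density = _density_series(data)
    sdata = SurvivalData.from_history(data.history, density=density)
    fdata = FecundityData.from_records(data.fecundity)
    s_sampler = _SurvivalSampler(sdata, config, priors)
    f_sampler = _FecunditySampler(fdata, config, priors)

    seeds = np.random.SeedSequence(config.seed).spawn(2 * config.chains)
    s_draws, s_re, f_draws, f_re = [], [], [], []
    for c in range(config.chains):
        sd, sre, _ = s_sampler.run_chain(config, seeds[c].generate_state(1)[0])
        fd, fre, _ = f_sampler.run_chain(config, seeds[config.chains + c].generate_state(1)[0])
        s_draws.append(sd)
        s_re.append(sre)
        f_draws.append(fd)
        f_re.append(fre)

    n_keep = min(min(d.shape[0] for d in s_draws), min(d.shape[0] for d in f_draws))
    draws: dict[str, np.ndarray] = {}
    for j, name in enumerate(s_sampler.names):
        draws[name] = np.stack([d[:n_keep, j] for d in s_draws])
    for j, name in enumerate(f_sampler.names):
        draws[name] = np.stack([d[:n_keep, j] for d in f_draws])

    re_draws: dict[str, np.ndarray] = {}
    for block_name in (s_re[0] or {}):
        re_draws[block_name] = np.stack([r[block_name][:n_keep] for r in s_re])
    for block_name in (f_re[0] or {}):
        re_draws[block_name] = np.stack([r[block_name][:n_keep] for r in f_re])

    # natural-scale aliases
    draws["phi_a"] = expit(draws["logit_phi_a"])
    draws["p"] = expit(draws["logit_p"])
    draws["phi_j_mean"] = expit(draws["logit_phi_j"])
    if config.density_on_fecundity:
        beta_raw = draws["beta_dens_f"] / f_sampler.dens_sd
        alpha_raw = draws["alpha_c"] - beta_raw * f_sampler.dens_mean
        draws["alpha_f"] = alpha_raw
        draws["beta_dens_f_raw"] = beta_raw
    else:
        draws["alpha_f"] = draws["alpha_c"]
    draws["f0"] = np.exp(draws["alpha_f"])

    monitored = s_sampler.names + f_sampler.names
    diagnostics: dict[str, dict[str, float]] = {}
    idata = az.from_dict(posterior={n: draws[n] for n in monitored})
    ess = az.ess(idata)
    if config.chains >= 2:
        rhat = az.rhat(idata)
    else:  # split R-hat needs >= 2 chains; flag as unavailable, not failed
        rhat = {n: types.SimpleNamespace(values=np.nan) for n in monitored}
    offenders = {}
    for n in monitored:
        r = float(rhat[n].values)
        e = float(ess[n].values)
        diagnostics[n] = {"rhat": r, "ess": e}
        if np.isfinite(r) and r > config.rhat_threshold:
            offenders[n] = r
    if config.check_convergence and offenders:
        raise ConvergenceError(offenders)

    result = PosteriorResult(
        draws=draws,
        re_draws=re_draws,
        diagnostics=diagnostics,
        config=config,
        n_years_used=data.history.n_occasions - 2,
        density_mean=f_sampler.dens_mean,
        density_sd=f_sampler.dens_sd,
        sdens_mean=s_sampler.dens_mean,
        sdens_sd=s_sampler.dens_sd,
        female_ids=list(fdata.females),
    )
    lam = derive_lambda(result, density=0.0 if config.density_on_fecundity else None)
    result.derived["lambda"] = lam
    return result


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def _lambda_from_draws(
    phi_a: np.ndarray,
    phi_j: np.ndarray,
    alpha_f: np.ndarray,
    beta_f: np.ndarray | float,
    density: float,
) -> np.ndarray:
    f = np.exp(alpha_f + np.asarray(beta_f) * density)
    return phi_a + 0.5 * phi_j * f


def derive_lambda(result: PosteriorResult, density: float | None = None) -> dict:
    """Per-draw finite rate of increase ``lambda = phi_a + phi_j * f / 2``.

    ``phi_j`` is the mean-year juvenile survival (year effects at zero) and
    ``f`` the average-female, average-year fecundity at the given density.
    ``density`` is required iff the fit includes density-dependent fecundity.
    """
    dd = result.config.density_on_fecundity
    if dd and density is None:
        raise ValueError("density required under a density-dependent fecundity model")
    if not dd:
        density = 0.0
    phi_a = result.flat("phi_a")
    phi_j = result.flat("phi_j_mean")
    if result.config.density_on_juvenile:
        # phi_j_mean is the survival at mean observed density; shift to target
        eta = logit(phi_j) + result.flat("beta_dens_j") / result.sdens_sd * (
            density - result.sdens_mean
        )
        phi_j = expit(eta)
    alpha = result.flat("alpha_f")
    beta = result.flat("beta_dens_f_raw") if dd else 0.0
    lam = _lambda_from_draws(phi_a, phi_j, alpha, beta, float(density))
    return {
        "draws": lam,
        "mean": float(lam.mean()),
        "lower95": float(np.quantile(lam, 0.025)),
        "upper95": float(np.quantile(lam, 0.975)),
        "density": float(density),
    }


def prior_only_lambda(
    priors: PriorSet, n_draws: int = 100_000, seed: int = 0
) -> dict:
    """Prior-predictive growth rate: push draws of adult survival, juvenile
    survival and mean fecundity from the prior set through the growth-rate
    formula, with no data term."""
    rng = np.random.default_rng(seed)
    phi_a = expit(priors["logit_phi_a"].sample(n_draws, rng))
    phi_j = expit(priors["logit_phi_j"].sample(n_draws, rng))
    f = np.exp(priors["alpha_f"].sample(n_draws, rng))
    lam = phi_a + 0.5 * phi_j * f
    return {
        "draws": lam,
        "mean": float(lam.mean()),
        "lower95": float(np.quantile(lam, 0.025)),
        "upper95": float(np.quantile(lam, 0.975)),
        "density": 0.0,
    }


def carrying_capacity(result: PosteriorResult) -> dict:
    """Population size at which the growth rate declines to 1, per draw:
    ``K = (log(2 (1 - phi_a) / phi_j) - alpha_f) / beta_f``.

    Draws with a non-negative density slope or with growth already <= 1 at
    density 0 have no finite positive K; they are excluded and their
    proportion reported.
    """
    if not result.config.density_on_fecundity:
        raise ValueError("carrying capacity requires a density-dependent fecundity fit")
    phi_a = result.flat("phi_a")
    phi_j = result.flat("phi_j_mean")
    alpha = result.flat("alpha_f")
    beta = result.flat("beta_dens_f_raw")
    lam0 = _lambda_from_draws(phi_a, phi_j, alpha, beta, 0.0)
    defined = (beta < 0) & (lam0 >= 1.0)
    if not defined.any():
        raise ValueError("carrying capacity undefined for every posterior draw")
    with np.errstate(divide="ignore", invalid="ignore"):
        K = (np.log(2.0 * (1.0 - phi_a) / phi_j) - alpha) / beta
    K = K[defined]
    return {
        "draws": K,
        "mean": float(K.mean()),
        "median": float(np.median(K)),
        "lower95": float(np.quantile(K, 0.025)),
        "upper95": float(np.quantile(K, 0.975)),
        "proportion_undefined": float(1.0 - defined.mean()),
    }


# ---------------------------------------------------------------------------
# model reduction
# ---------------------------------------------------------------------------

_FIXED_EFFECT_FLAGS = {
    "beta_dens_f": "density_on_fecundity",
    "beta_dens_j": "density_on_juvenile",
    "beta_sex": "sex_on_adult",
    "delta_trans": "translocation_effect",
    "gamma_band": "banding_age_effect",
}
_RE_SD_FLAGS = {
    "sigma_female": "female_re_on_fecundity",
    "sigma_year_f": "year_re_on_fecundity",
    "sigma_year_j": "year_re_on_juvenile",
    "sigma_year_p": "year_re_on_resighting",
}


def reduce_model(result: PosteriorResult, config: ModelConfig) -> ModelConfig:
    """One backwards-elimination pass: drop each fixed effect whose central
    95% interval contains 0, and each random-effect SD whose posterior
    ``sd_drop_quantile`` quantile falls below ``sd_drop_threshold``."""
    changes = {}
    for name, flag in _FIXED_EFFECT_FLAGS.items():
        if getattr(config, flag) and name in result.draws:
            x = result.flat(name)
            lo, hi = np.quantile(x, [0.025, 0.975])
            if lo <= 0.0 <= hi:
                changes[flag] = False
    for name, flag in _RE_SD_FLAGS.items():
        if getattr(config, flag) and name in result.draws:
            q = float(np.quantile(result.flat(name), config.sd_drop_quantile))
            if q < config.sd_drop_threshold:
                changes[flag] = False
    return config.replace(**changes)


# ---------------------------------------------------------------------------
# sequential analysis
# ---------------------------------------------------------------------------

def sequential_analysis(
    data: Dataset,
    priors_pair: dict[str, PriorSet],
    config: ModelConfig,
    k_range: range | list[int],
    year_re_from: int = 5,
) -> dict:
    """Fit on the first k years of monitoring for each k, under both prior
    modes, and track the growth-rate summary.

    ``k`` counts annual survey intervals: k years keeps occasions
    0..k+1 (release plus k+1 surveys).  The random year effect on juvenile
    survival is enabled only once ``k >= year_re_from``.  Returns a dict with
    rows ``(k, prior_mode, mean, lower95, upper95)`` and, per mode, the
    smallest k whose lower limit exceeds 1 (``None`` if never).
    """
    rows = []
    first_k_above_1: dict[str, int | None] = {}
    for mode in ("informative", "uninformative"):
        if mode not in priors_pair:
            raise ValueError(f"priors_pair missing {mode!r}")
    for k in k_range:
        if k < 2:
            raise ValueError("at least 2 years are needed to estimate survival")
        n_occ = min(k + 2, data.history.n_occasions)
        sub = data.truncate(n_occ)
        cfg_k = config.replace(year_re_on_juvenile=config.year_re_on_juvenile and k >= year_re_from)
        for mode, priors in priors_pair.items():
            res = fit(sub, priors, cfg_k.replace(prior_mode=mode, seed=config.seed + 1000 * k))
            lam = res.derived["lambda"]
            rows.append(
                {
                    "k": int(k),
                    "prior_mode": mode,
                    "mean": lam["mean"],
                    "lower95": lam["lower95"],
                    "upper95": lam["upper95"],
                }
            )
    for mode in priors_pair:
        ks = sorted(r["k"] for r in rows if r["prior_mode"] == mode and r["lower95"] > 1.0)
        first_k_above_1[mode] = ks[0] if ks else None
    return {"rows": rows, "first_k_above_1": first_k_above_1}
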