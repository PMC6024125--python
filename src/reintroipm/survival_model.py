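"""Cormack-Jolly-Seber mark-resighting likelihood.

Two routes to the same quantity:

* :func:`cjs_marginal_loglik` — the production path; latent alive/dead states
  are summed out with the standard forward recursion, conditioning on first
  capture.
* :func:`cjs_enumeration_oracle` — a brute-force enumerator over all latent
  state sequences, usable for small occasion counts only.  Exists purely to
  verify the marginal implementation.

Interval survival probabilities follow the linear-predictor structure of the
full model: adults get ``logit(phi_a) + beta_sex*I[male] + delta_trans*
I[founder first interval]`` with the first (half-year) interval corrected by
raising the annual probability to ``interval_fraction``; wild-born birds
spend exactly their first interval as juveniles with
``logit(phi_j_mean) + eps_year_j[t] + beta_dens_j*density + gamma_band*
I[fledgling-banded]``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .data_model_io import CaptureHistory, ParameterSet

__all__ = [
    "adult_survival_prob",
    "juvenile_survival_prob",
    "cjs_marginal_loglik",
    "cjs_enumeration_oracle",
    "SurvivalData",
]


def adult_survival_prob(
    params: ParameterSet,
    sex: str,
    is_first_interval: bool = False,
    interval_fraction: float = 1.0,
) -> float:
    """Per-interval adult survival probability.

    ``interval_fraction`` corrects for intervals shorter than a year: the
    annual probability is raised to that power.
    """
    if not 0.0 < interval_fraction <= 1.0:
        raise ValueError(f"interval_fraction {interval_fraction} not in (0, 1]")
    eta = logit(params.phi_a)
    if sex == "male":
        eta = eta + params.beta_sex
    if is_first_interval:
        eta = eta + params.delta_trans
    return float(expit(eta) ** interval_fraction)


def juvenile_survival_prob(
    params: ParameterSet,
    year_index: int = 0,
    density: float = 0.0,
    banding_method: str = "nestling",
) -> float:
    """Apparent survival from fledging to adulthood for one cohort year.

    ``density`` enters on the raw (bird count) scale.
    """
    if banding_method not in ("nestling", "fledgling"):
        raise ValueError(f"unknown banding method {banding_method!r}")
    eta = logit(params.phi_j_mean)
    if params.eps_year_j.size:
        if not 0 <= year_index < params.eps_year_j.size:
            raise ValueError(f"year_index {year_index} outside eps_year_j range")
        eta = eta + params.eps_year_j[year_index]
    eta = eta + params.beta_dens_j * density
    if banding_method == "fledgling":
        eta = eta + params.gamma_band
    return float(expit(eta))


@dataclass
class SurvivalData:
    """Pre-extracted arrays for fast repeated likelihood evaluation.

    ``collapse=True`` groups individuals with identical (first occasion,
    covariate class, detection pattern) and weights their single likelihood
    contribution by the group size; the grouped and ungrouped likelihoods are
    identical.
    """

    y: np.ndarray  # (n, T) detections
    first: np.ndarray  # (n,)
    is_male: np.ndarray  # (n,) bool
    is_female: np.ndarray  # (n,) bool
    translocated: np.ndarray  # (n,) bool
    fledgling_banded: np.ndarray  # (n,) bool
    wild_born: np.ndarray  # (n,) bool
    first_interval_fraction: float
    weights: np.ndarray  # (n,) multiplicities
    density: np.ndarray | None = None  # (T,) per-occasion density covariate

    @classmethod
    def from_history(
        cls,
        history: CaptureHistory,
        density: np.ndarray | None = None,
        collapse: bool = True,
    ) -> "SurvivalData":
        inds = history.individuals
        data = cls(
            y=history.detections.astype(np.int8),
            first=history.first_occasions,
            is_male=np.array([i.sex == "male" for i in inds]),
            is_female=np.array([i.sex == "female" for i in inds]),
            translocated=np.array([i.origin == "translocated" for i in inds]),
            fledgling_banded=np.array([i.banding_method == "fledgling" for i in inds]),
            wild_born=np.array([i.origin == "wild-born" for i in inds]),
            first_interval_fraction=history.first_interval_fraction,
            weights=np.ones(len(inds)),
            density=None if density is None else np.asarray(density, dtype=float),
        )
        return data.collapsed() if collapse else data

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def collapsed(self) -> "SurvivalData":
        key = np.column_stack(
            [
                self.first,
                self.is_male,
                self.is_female,
                self.translocated,
                self.fledgling_banded,
                self.wild_born,
                self.y,
            ]
        ).astype(np.int64)
        _, idx, inverse, counts = np.unique(
            key, axis=0, return_index=True, return_inverse=True, return_counts=True
        )
        return SurvivalData(
            y=self.y[idx],
            first=self.first[idx],
            is_male=self.is_male[idx],
            is_female=self.is_female[idx],
            translocated=self.translocated[idx],
            fledgling_banded=self.fledgling_banded[idx],
            wild_born=self.wild_born[idx],
            first_interval_fraction=self.first_interval_fraction,
            weights=counts.astype(float),
            density=self.density,
        )


def _interval_survival_matrix(data: SurvivalData, params: ParameterSet) -> np.ndarray:
    """phi[i, t] = P(individual i survives interval t -> t+1 | alive at t),
    for t >= first[i]; arbitrary values elsewhere (never used)."""
    n, T = data.y.shape
    eta_adult = logit(params.phi_a) + params.beta_sex * data.is_male[:, None]
    eta_adult = np.broadcast_to(eta_adult, (n, T - 1)).copy()
    # founders' first interval gets the translocation effect
    first_int = np.zeros((n, T - 1), dtype=bool)
    founder_rows = data.translocated & (data.first < T - 1)
    first_int[founder_rows, data.first[founder_rows]] = True
    eta_adult[first_int] += params.delta_trans
    phi = expit(eta_adult)
    # interval 0 is a fraction of a year (release -> first survey)
    if data.first_interval_fraction != 1.0 and T > 1:
        phi[:, 0] = phi[:, 0] ** data.first_interval_fraction
    # wild-born birds are juveniles over their first interval
    juv_rows = np.where(data.wild_born & (data.first < T - 1))[0]
    if juv_rows.size:
        t_j = data.first[juv_rows]
        eta_j = np.full(juv_rows.size, logit(params.phi_j_mean))
        if params.eps_year_j.size:
            if params.eps_year_j.size < T - 1:
                raise ValueError("eps_year_j shorter than the number of intervals")
            eta_j = eta_j + params.eps_year_j[t_j]
        if params.beta_dens_j != 0.0:
            if data.density is None:
                raise ValueError("density covariate required when beta_dens_j != 0")
            eta_j = eta_j + params.beta_dens_j * data.density[t_j]
        eta_j = eta_j + params.gamma_band * data.fledgling_banded[juv_rows]
        phi[juv_rows, t_j] = expit(eta_j)
    return phi


def _detection_probs(data: SurvivalData, params: ParameterSet) -> np.ndarray:
    """p[t] = resighting probability at occasion t (p[0] unused: occasion 0 is
    the release event and detection there is conditioned on)."""
    T = data.y.shape[1]
    eta = np.full(T, logit(params.p))
    if params.eps_year_p.size:
        if params.eps_year_p.size < T:
            raise ValueError("eps_year_p shorter than the number of occasions")
        eta = eta + params.eps_year_p[:T]
    return expit(eta)


def _forward_loglik_numpy(y, first, phi, p):
    n, T = y.shape
    alive = np.ones(n)
    dead = np.zeros(n)
    for t in range(T - 1):
        active = first <= t
        yt = y[:, t + 1]
        obs_alive = np.where(yt == 1, p[t + 1], 1.0 - p[t + 1])
        obs_dead = (yt == 0).astype(float)
        a_new = alive * phi[:, t] * obs_alive
        d_new = (alive * (1.0 - phi[:, t]) + dead) * obs_dead
        alive = np.where(active, a_new, alive)
        dead = np.where(active, d_new, dead)
    with np.errstate(divide="ignore"):
        return np.log(alive + dead)


try:  # fast path; the numpy implementation is the behavioural reference
    from numba import njit

    @njit(cache=True)
    def _forward_loglik_numba(y, first, phi, p):  # pragma: no cover
        n, T = y.shape
        out = np.empty(n)
        for i in range(n):
            alive = 1.0
            dead = 0.0
            for t in range(first[i], T - 1):
                obs_alive = p[t + 1] if y[i, t + 1] == 1 else 1.0 - p[t + 1]
                obs_dead = 0.0 if y[i, t + 1] == 1 else 1.0
                a_new = alive * phi[i, t] * obs_alive
                dead = (alive * (1.0 - phi[i, t]) + dead) * obs_dead
                alive = a_new
            out[i] = np.log(alive + dead)
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def per_individual_loglik(data: SurvivalData, params: ParameterSet) -> np.ndarray:
    """Forward-recursion log-likelihood per (possibly collapsed) row,
    conditioning on first capture.  Not weighted."""
    phi = _interval_survival_matrix(data, params)
    p = _detection_probs(data, params)
    if _HAVE_NUMBA:
        return _forward_loglik_numba(
            np.ascontiguousarray(data.y),
            np.ascontiguousarray(data.first),
            np.ascontiguousarray(phi),
            np.ascontiguousarray(p),
        )
    return _forward_loglik_numpy(data.y, data.first, phi, p)


def cjs_marginal_loglik(
    history: CaptureHistory | SurvivalData, params: ParameterSet
) -> float:
    """Exact CJS log-likelihood with latent states summed out.

    Accepts either a :class:`CaptureHistory` or a pre-built
    :class:`SurvivalData` (for repeated evaluation inside a sampler).
    Returns ``-inf`` for data impossible under ``params``.
    """
    data = (
        history
        if isinstance(history, SurvivalData)
        else SurvivalData.from_history(history)
    )
    ll = per_individual_loglik(data, params)
    if np.isneginf(ll).any():
        return float("-inf")
    return float(np.dot(data.weights, ll))


def cjs_enumeration_oracle(
    history: CaptureHistory | SurvivalData,
    params: ParameterSet,
    max_occasions: int = 12,
) -> float:
    """Brute-force CJS log-likelihood: explicit sum over every latent
    alive/dead state sequence (2^(T-1) per individual).  Test oracle only."""
    data = (
        history
        if isinstance(history, SurvivalData)
        else SurvivalData.from_history(history, collapse=False)
    )
    y = data.y
    n, T = y.shape
    if T > max_occasions:
        raise ValueError(f"enumeration oracle limited to {max_occasions} occasions, got {T}")
    phi = _interval_survival_matrix(data, params)
    p = _detection_probs(data, params)
    total = 0.0
    for i in range(n):
        f = data.first[i]
        m = T - 1 - f  # number of intervals after first capture
        lik = 0.0
        # m == 0 (first capture at the last occasion): the single empty state
        # sequence contributes probability 1 (conditioning on first capture)
        for states in itertools.product((1, 0), repeat=m):
            # states[k] = alive at occasion f+k+1; dead is absorbing
            prob = 1.0
            prev_alive = 1
            ok = True
            for k, s in enumerate(states):
                t = f + k
                if prev_alive:
                    prob *= phi[i, t] if s else (1.0 - phi[i, t])
                elif s:
                    ok = False
                    break
                if s:
                    prob *= p[t + 1] if y[i, t + 1] else (1.0 - p[t + 1])
                elif y[i, t + 1]:
                    ok = False
                    break
                prev_alive = s
            if ok:
                lik += prob
        if lik <= 0.0:
            return float("-inf")
        total += data.weights[i] * np.log(lik)
    return float(total)
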