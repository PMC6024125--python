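"""Poisson log-link fecundity likelihood with female and year random effects.

The reported "mean fecundity" is the average-female, average-year value
``exp(alpha_f + beta_dens_f * density)`` (random effects at zero), not the
marginal mean ``exp(alpha + sigma^2/2)``; both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data_model_io import FecundityRecord, ParameterSet

__all__ = [
    "expected_fecundity",
    "marginal_mean_fecundity",
    "fecundity_loglik",
    "FecundityData",
]


def expected_fecundity(
    params: ParameterSet,
    density: float = 0.0,
    female_effect: float = 0.0,
    year_effect: float = 0.0,
) -> float:
    """Expected fledglings for one female-year on the response scale."""
    if density < 0:
        raise ValueError("density must be >= 0")
    return float(
        np.exp(params.alpha_f + params.beta_dens_f * density + female_effect + year_effect)
    )


def marginal_mean_fecundity(params: ParameterSet, density: float = 0.0) -> float:
    """Population-marginal mean over the random-effect distributions,
    ``exp(alpha + beta*d + (sigma_female^2 + sigma_year^2)/2)``."""
    return float(
        np.exp(
            params.alpha_f
            + params.beta_dens_f * density
            + 0.5 * (params.sigma_female**2 + params.sigma_year_f**2)
        )
    )


@dataclass
class FecundityData:
    """Column-extracted fecundity records for fast repeated evaluation."""

    counts: np.ndarray  # (m,) fledgling counts
    density: np.ndarray  # (m,)
    female_index: np.ndarray  # (m,) index into `females`
    year: np.ndarray  # (m,) occasion index of the season
    females: list[str]  # distinct female ids, in first-appearance order

    @classmethod
    def from_records(cls, records: list[FecundityRecord]) -> "FecundityData":
        females: list[str] = []
        fmap: dict[str, int] = {}
        fidx = np.empty(len(records), dtype=int)
        for k, r in enumerate(records):
            if r.female_id not in fmap:
                fmap[r.female_id] = len(females)
                females.append(r.female_id)
            fidx[k] = fmap[r.female_id]
        return cls(
            counts=np.array([r.fledglings for r in records], dtype=float),
            density=np.array([r.density for r in records], dtype=float),
            female_index=fidx,
            year=np.array([r.year for r in records], dtype=int),
            females=females,
        )

    @property
    def n_records(self) -> int:
        return self.counts.size

    @property
    def n_females(self) -> int:
        return len(self.females)


def _log_means(data: FecundityData, params: ParameterSet) -> np.ndarray:
    eta = params.alpha_f + params.beta_dens_f * data.density
    if data.n_records and (params.eps_female or params.sigma_female > 0):
        try:
            fem_eff = np.array([params.eps_female[f] for f in data.females])
        except KeyError as err:
            raise ValueError(f"missing eps_female entry for female {err.args[0]!r}") from None
        eta = eta + fem_eff[data.female_index]
    if params.eps_year_f.size:
        if data.n_records and data.year.max() >= params.eps_year_f.size:
            raise ValueError("eps_year_f shorter than the record years")
        eta = eta + params.eps_year_f[data.year]
    return eta


def fecundity_loglik(
    records: list[FecundityRecord] | FecundityData, params: ParameterSet
) -> float:
    """Sum of Poisson log-pmfs at each record's expected fecundity.

    Records of females with a female random effect must have an
    ``eps_female`` entry under ``params``; with no female effect configured
    (``sigma_female == 0`` and empty ``eps_female``) the effect is taken as 0.
    """
    data = records if isinstance(records, FecundityData) else FecundityData.from_records(records)
    if data.n_records == 0:
        return 0.0
    eta = _log_means(data, params)
    ll = data.counts * eta - np.exp(eta) - gammaln(data.counts + 1.0)
    return float(ll.sum())
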