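"""Minimal adaptive MCMC engine used by the inference module.

Two update blocks per sweep:

* a joint adaptive random-walk Metropolis step (Haario-style empirical
  covariance with Robbins-Monro scale tuning, adaptation frozen after
  burn-in) over the low-dimensional "global" parameters, and
* vectorized single-site Metropolis updates for random-effect vectors whose
  coordinates are conditionally independent given the globals (each
  coordinate touches a disjoint slice of the likelihood), with per-coordinate
  adaptive scales.

The model supplies a joint log-density for the global block and, per
random-effect block, a function returning per-unit log-density contributions
so acceptance can be decided coordinate-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["REBlock", "AdaptiveSampler"]

_TARGET_JOINT = 0.25
_TARGET_SITE = 0.44


@dataclass
class REBlock:
    """A conditionally independent random-effect vector.

    ``unit_logdens(z, globals_vec, re_values)`` must return an array with one
    entry per coordinate of ``z``: that coordinate's likelihood slice plus
    its own prior term.  Coordinates may not share likelihood terms.
    ``re_values`` carries the current state of every block so one block's
    slice can condition on the others.
    """

    name: str
    size: int
    unit_logdens: Callable[[np.ndarray, np.ndarray, dict], np.ndarray]
    init: np.ndarray | None = None
    scales: np.ndarray = field(init=False)

    def __post_init__(self):
        self.scales = np.full(self.size, 0.5)


class AdaptiveSampler:
    """Adaptive Metropolis-within-Gibbs over globals + RE blocks.

    Parameters
    ----------
    logdens_global
        ``f(theta, re_values) -> float`` joint log density (likelihood +
        priors) as a function of the global vector, at fixed random effects.
    support
        ``f(theta) -> bool`` quick in-support test (e.g. SD bounds); out-of-
        support proposals are rejected without a density evaluation.
    """

    def __init__(
        self,
        logdens_global: Callable[[np.ndarray, dict[str, np.ndarray]], float],
        init: np.ndarray,
        re_blocks: list[REBlock] | None = None,
        support: Callable[[np.ndarray], bool] | None = None,
    ):
        self.logdens_global = logdens_global
        self.init = np.asarray(init, dtype=float)
        self.re_blocks = re_blocks or []
        self.support = support or (lambda theta: True)
        self.d = self.init.size

    def run(
        self,
        n_iter: int,
        burn_in: int,
        seed: int,
        thin: int = 1,
    ) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
        """Run one chain; returns (global draws, RE draws per block, final
        acceptance rate of the joint block)."""
        rng = np.random.default_rng(seed)
        d = self.d
        theta = self.init.copy()
        if not self.support(theta):
            raise ValueError("initial point outside the support")
        re_values = {
            b.name: (b.init.copy() if b.init is not None else np.zeros(b.size))
            for b in self.re_blocks
        }
        lp = self.logdens_global(theta, re_values)
        if not np.isfinite(lp):
            raise ValueError("initial point has non-finite log density")

        # adaptive state for the joint block
        log_scale = 0.0
        mean = theta.copy()
        cov = np.eye(d) * 0.01
        chol = np.linalg.cholesky(cov * np.exp(log_scale) + 1e-9 * np.eye(d))
        accepted = 0
        proposed = 0

        n_keep = (n_iter - burn_in) // thin
        draws = np.empty((n_keep, d))
        re_draws = {b.name: np.empty((n_keep, b.size)) for b in self.re_blocks}
        kept = 0

        for it in range(n_iter):
            adapting = it < burn_in
            # ---- joint global update -------------------------------------
            prop = theta + chol @ rng.standard_normal(d)
            proposed += 1
            if self.support(prop):
                lp_prop = self.logdens_global(prop, re_values)
                if np.log(rng.random()) < lp_prop - lp:
                    theta, lp = prop, lp_prop
                    accepted += 1
                    acc = 1.0
                else:
                    acc = 0.0
            else:
                acc = 0.0
            if adapting:
                gamma = min(0.5, 5.0 / (it + 10))
                log_scale += gamma * (acc - _TARGET_JOINT)
                delta = theta - mean
                mean += gamma * delta
                cov += gamma * (np.outer(delta, delta) - cov)
                if it % 25 == 0 or it == burn_in - 1:
                    chol = np.linalg.cholesky(
                        (2.38**2 / d) * np.exp(log_scale) * cov + 1e-9 * np.eye(d)
                    )

            # ---- vectorized RE updates -----------------------------------
            for block in self.re_blocks:
                z = re_values[block.name]
                cur = block.unit_logdens(z, theta, re_values)
                prop_z = z + block.scales * rng.standard_normal(block.size)
                new = block.unit_logdens(prop_z, theta, re_values)
                accept = np.log(rng.random(block.size)) < new - cur
                z[accept] = prop_z[accept]
                if adapting:
                    gamma = min(0.5, 5.0 / (it + 10))
                    block.scales *= np.exp(gamma * (accept - _TARGET_SITE))
                    np.clip(block.scales, 1e-3, 10.0, out=block.scales)
                if accept.any():
                    # unit contributions are disjoint slices of the joint
                    # density, so the joint log density shifts by their sum
                    lp += float((new - cur)[accept].sum())

            if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
                draws[kept] = theta
                for b in self.re_blocks:
                    re_draws[b.name][kept] = re_values[b.name]
                kept += 1

        return draws[:kept], {k: v[:kept] for k, v in re_draws.items()}, accepted / max(proposed, 1)
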