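"""Structural model equations: individual parameters, state chain, emissions.

All quantities here are *conditional on* a subject's random effects; the
marginalization over random effects lives in :mod:`bimhmm.inference`.

States
------
The hidden chain has exactly two states, remission ``R`` (index 0) and
exacerbation ``E`` (index 1).  ``R`` indexes the first row/column of the
transition matrix.

Model summary
-------------
* FEV1 is log-normal around state modes:
  ``FEV1_R = theta_fev1_r * exp(eta_fev1_r)`` and
  ``FEV1_E = FEV1_R - theta_fev1_e * exp(eta_fev1_e)``.
* PRO has additive random effects and a placebo time course:
  ``PRO_R(t) = (theta_pro_r + eta_pro_r) * (1 - pe*(1 - exp(-log(2)*t/phl)))``
  and ``PRO_E(t) = PRO_R(t) + (theta_pro_e + eta_pro_e)``; ``pe`` is the
  maximum fractional decrease, reached with half-life ``phl`` weeks.
* The chain starts in remission with probability ``init``; the weekly
  transition probability out of remission is
  ``pi_re = expit(logit(theta_pi_re) + eta_pi_re - trt*slp)`` and out of
  exacerbation ``pi_er = theta_pi_er``.
* Given the state, the two endpoints are jointly Gaussian with state-shared
  residual variances ``sigma2_fev1``, ``sigma2_pro`` and state-specific
  correlation ``rho_r`` / ``rho_e``.  With one endpoint missing the
  emission is the corresponding univariate normal density.

Densities are evaluated in log space internally; the natural-scale
functions exponentiate at the end.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from .parameters import IndividualEffects, PopulationParameters

__all__ = [
    "StateLabel",
    "logit",
    "inverse_logit",
    "individual_fev1",
    "individual_pro",
    "placebo_factor",
    "initial_state_prob",
    "transition_matrix",
    "drug_effect_reduction",
    "IndividualParameters",
    "individual_parameters",
    "emission_logpdf",
    "emission_density",
]

_LN2 = math.log(2.0)
_LN2PI = math.log(2.0 * math.pi)


class StateLabel(enum.IntEnum):
    """Hidden disease state: remission (``R``) or exacerbation (``E``)."""

    R = 0
    E = 1


def _as_state(state) -> StateLabel:
    if isinstance(state, str):
        return StateLabel[state]
    return StateLabel(state)


def logit(p, name: str = "p"):
    """log(p / (1 - p)); domain error naming the offending parameter."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {p!r}")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_logit(x):
    """1 / (1 + exp(-x)), strictly inside (0, 1) for finite x."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def individual_fev1(pop: PopulationParameters, eta: IndividualEffects) -> tuple[float, float]:
    """Individual FEV1 state values ``(fev1_r, fev1_e)`` in L/s."""
    fev1_r = pop.theta_fev1_r * math.exp(eta.eta_fev1_r)
    fev1_e = fev1_r - pop.theta_fev1_e * math.exp(eta.eta_fev1_e)
    return fev1_r, fev1_e


def placebo_factor(pop: PopulationParameters, time):
    """Multiplicative placebo factor ``1 - pe*(1 - exp(-log(2)*t/phl))``.

    Equals 1 at ``t = 0`` and decays with half-life ``phl`` towards the
    maximum fractional decrease ``pe``.
    """
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"time must be non-negative; got {time!r}")
    out = 1.0 - pop.pe * (1.0 - np.exp(-_LN2 * t / pop.phl))
    return float(out) if np.isscalar(time) or out.ndim == 0 else out


def individual_pro(pop: PopulationParameters, eta: IndividualEffects, time):
    """Individual PRO state values ``(pro_r, pro_e)`` at ``time`` (weeks)."""
    fac = placebo_factor(pop, time)
    pro_r = (pop.theta_pro_r + eta.eta_pro_r) * fac
    pro_e = pro_r + (pop.theta_pro_e + eta.eta_pro_e)
    return pro_r, pro_e


def initial_state_prob(pop: PopulationParameters) -> float:
    """Probability of starting in remission (complement starts in E)."""
    return inverse_logit(logit(pop.init, "init"))


def transition_matrix(pop: PopulationParameters, eta_pi_re: float = 0.0, trt: int = 0) -> np.ndarray:
    """2x2 row-stochastic one-step transition matrix, rows/cols (R, E).

    ``pi_re`` carries the subject random effect and, in the treated arm
    (``trt = 1``), the drug effect ``-slp`` on the logit scale.
    """
    if trt not in (0, 1):
        raise ValueError(f"trt must be 0 or 1; got {trt!r}")
    pi_re = inverse_logit(logit(pop.theta_pi_re, "theta_pi_re") + eta_pi_re - trt * pop.slp)
    pi_er = inverse_logit(logit(pop.theta_pi_er, "theta_pi_er"))
    return np.array([[1.0 - pi_re, pi_re], [pi_er, 1.0 - pi_er]])


def drug_effect_reduction(theta_pi_re: float, slp: float) -> float:
    """Fractional reduction of ``pi_re`` caused by the drug term.

    ``1 - expit(logit(theta) - slp) / theta``; e.g. ``slp = 1`` reduces a
    baseline weekly transition probability of 0.05 by 62%.
    """
    theta = float(theta_pi_re)
    p1 = inverse_logit(logit(theta, "theta_pi_re") - slp)
    return 1.0 - p1 / theta


@dataclasses.dataclass
class IndividualParameters:
    """One subject's state-level parameters given the random effects.

    ``pro_r_of_t`` / ``pro_e_of_t`` are callables of time (weeks) because
    the PRO modes carry the placebo time course.
    """

    fev1_r: float
    fev1_e: float
    pro_r_of_t: Callable[[float], float]
    pro_e_of_t: Callable[[float], float]
    p_init_r: float
    pi_re: float
    pi_er: float


def individual_parameters(
    pop: PopulationParameters,
    eta: Optional[IndividualEffects] = None,
    trt: int = 0,
) -> IndividualParameters:
    """Assemble :class:`IndividualParameters` from population values and eta."""
    eta = eta or IndividualEffects.zero()
    fev1_r, fev1_e = individual_fev1(pop, eta)
    mat = transition_matrix(pop, eta.eta_pi_re, trt)
    return IndividualParameters(
        fev1_r=fev1_r,
        fev1_e=fev1_e,
        pro_r_of_t=lambda t: individual_pro(pop, eta, t)[0],
        pro_e_of_t=lambda t: individual_pro(pop, eta, t)[1],
        p_init_r=initial_state_prob(pop),
        pi_re=float(mat[0, 1]),
        pi_er=float(mat[1, 0]),
    )


def _is_missing(y) -> bool:
    return y is None or (isinstance(y, float) and math.isnan(y)) or (
        np.isscalar(y) and np.isnan(y)
    )


def emission_logpdf(
    y_fev1,
    y_pro,
    state,
    indiv: IndividualParameters,
    pop: PopulationParameters,
    time: float = 0.0,
) -> float:
    """Log emission density of one observation row given the hidden state.

    Both endpoints present: correlated bivariate normal centered at the
    state-specific individual values with the state's ``rho``.  Exactly one
    present: the univariate normal density in that endpoint.  Both missing
    is an error — the row carries no emission information.
    """
    s = _as_state(state)
    miss_f, miss_p = _is_missing(y_fev1), _is_missing(y_pro)
    if miss_f and miss_p:
        raise ValueError("both endpoints missing: row carries no emission information")
    if s == StateLabel.R:
        mu_f, mu_p, rho = indiv.fev1_r, indiv.pro_r_of_t(time), pop.rho_r
    else:
        mu_f, mu_p, rho = indiv.fev1_e, indiv.pro_e_of_t(time), pop.rho_e
    s2f, s2p = pop.sigma2_fev1, pop.sigma2_pro
    if miss_f:
        z = (float(y_pro) - mu_p) ** 2 / s2p
        return -0.5 * (_LN2PI + math.log(s2p)) - 0.5 * z
    if miss_p:
        z = (float(y_fev1) - mu_f) ** 2 / s2f
        return -0.5 * (_LN2PI + math.log(s2f)) - 0.5 * z
    zf = (float(y_fev1) - mu_f) / math.sqrt(s2f)
    zp = (float(y_pro) - mu_p) / math.sqrt(s2p)
    one_m_r2 = 1.0 - rho * rho
    quad = (zf * zf - 2.0 * rho * zf * zp + zp * zp) / one_m_r2
    return -_LN2PI - 0.5 * math.log(s2f * s2p * one_m_r2) - 0.5 * quad


def emission_density(
    y_fev1,
    y_pro,
    state,
    indiv: IndividualParameters,
    pop: PopulationParameters,
    time: float = 0.0,
) -> float:
    """Natural-scale emission density (see :func:`emission_logpdf`)."""
    return math.exp(emission_logpdf(y_fev1, y_pro, state, indiv, pop, time))
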