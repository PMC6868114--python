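"""Parameter containers for the bivariate mixed hidden Markov model.

The model describes two continuous endpoints observed longitudinally in a
two-arm parallel trial — a lung-function biomarker (FEV1, L/s) and a
patient-reported outcome score (PRO) — emitted from a hidden two-state
disease chain (remission ``R`` / exacerbation ``E``).  Subjects carry up to
five independent normal random effects (on the FEV1 and PRO state modes and
on the logit of the remission-to-exacerbation transition probability), and
a binary treatment indicator shifts that same logit by ``-slp``.

:class:`PopulationParameters` holds the population-level fixed effects,
random-effect variances, residual variances and within-state residual
correlations.  The default values are the reference parameterization used
throughout the package's simulation studies.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "PopulationParameters",
    "IndividualEffects",
    "PARAM_ORDER",
    "ETA_ORDER",
    "DEFAULT_FREE",
    "reference_parameters",
]

#: Canonical field order.  This is also the layout of the flat parameter
#: vector consumed by the numerical kernels.
PARAM_ORDER = (
    "theta_fev1_r",
    "theta_fev1_e",
    "theta_pro_r",
    "theta_pro_e",
    "init",
    "theta_pi_re",
    "theta_pi_er",
    "slp",
    "pe",
    "phl",
    "omega2_fev1_r",
    "omega2_fev1_e",
    "omega2_pro_r",
    "omega2_pro_e",
    "omega2_pi_re",
    "sigma2_fev1",
    "sigma2_pro",
    "rho_r",
    "rho_e",
)

#: Order of the subject random-effect vector; dimension ``d`` is paired with
#: the variance field ``PARAM_ORDER[10 + d]``.
ETA_ORDER = (
    "eta_fev1_r",
    "eta_fev1_e",
    "eta_pro_r",
    "eta_pro_e",
    "eta_pi_re",
)

#: Parameters estimated by default (the placebo-effect kinetics ``pe`` and
#: ``phl`` are structural constants of the PRO time course and are fixed
#: unless explicitly freed).
DEFAULT_FREE = tuple(n for n in PARAM_ORDER if n not in ("pe", "phl"))


@dataclasses.dataclass
class PopulationParameters:
    """Population parameters of the bivariate mixed HMM.

    Defaults are the reference values: FEV1 modes 2.00 / 1.75 L/s
    (remission / exacerbation), PRO modes 2.5 / 3.0, 90% probability of
    starting in remission, weekly transition probabilities
    ``pi_re = 0.05`` and ``pi_er = 0.15``, drug effect ``slp = 1`` on the
    logit of ``pi_re``, a 20% maximum placebo decrease of PRO with a
    10-week half-life, and residual correlation −0.33 in both states.
    """

    theta_fev1_r: float = 2.00    # mode of FEV1 in remission, L/s
    theta_fev1_e: float = 0.25    # subtracted from FEV1_R in exacerbation, L/s
    theta_pro_r: float = 2.50     # mode of PRO in remission, score
    theta_pro_e: float = 0.50     # added to PRO_R in exacerbation, score
    init: float = 0.90            # P(start in remission)
    theta_pi_re: float = 0.05     # remission -> exacerbation probability
    theta_pi_er: float = 0.15     # exacerbation -> remission probability
    slp: float = 1.00             # drug effect on logit(pi_re)
    pe: float = 0.20              # maximum fractional placebo decrease of PRO
    phl: float = 10.0             # placebo-effect half-life, weeks
    omega2_fev1_r: float = 0.03
    omega2_fev1_e: float = 0.03
    omega2_pro_r: float = 0.09
    omega2_pro_e: float = 0.09
    omega2_pi_re: float = 0.06
    sigma2_fev1: float = 0.015
    sigma2_pro: float = 0.05
    rho_r: float = -0.33
    rho_e: float = -0.33

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("init", "theta_pi_re", "theta_pi_er", "pe"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1); got {v!r}")
        if not self.phl > 0:
            raise ValueError(f"phl must be positive; got {self.phl!r}")
        for name in PARAM_ORDER[10:15]:
            v = getattr(self, name)
            if not v >= 0.0:
                raise ValueError(f"{name} must be non-negative; got {v!r}")
        for name in ("sigma2_fev1", "sigma2_pro"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be positive; got {v!r}")
        for name in ("rho_r", "rho_e"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (-1, 1); got {v!r}")

    # -- conversions --------------------------------------------------

    def replace(self, **changes: float) -> "PopulationParameters":
        """Return a copy with the given fields replaced (and re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_ORDER}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "PopulationParameters":
        unknown = set(mapping) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_vector(self) -> np.ndarray:
        """Flat float64 vector in :data:`PARAM_ORDER` layout."""
        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: Iterable[float]) -> "PopulationParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_ORDER),):
            raise ValueError(f"expected a vector of length {len(PARAM_ORDER)}")
        return cls(**dict(zip(PARAM_ORDER, vec.tolist())))

    # -- serialization ------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PopulationParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclasses.dataclass
class IndividualEffects:
    """One subject's random-effect vector (eta), zero-mean normal deviations.

    Components are drawn independently, each with the matching ``omega2``
    variance of :class:`PopulationParameters` (no cross-correlation).
    """

    eta_fev1_r: float = 0.0
    eta_fev1_e: float = 0.0
    eta_pro_r: float = 0.0
    eta_pro_e: float = 0.0
    eta_pi_re: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in ETA_ORDER], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "IndividualEffects":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError("expected a length-5 eta vector")
        return cls(**dict(zip(ETA_ORDER, arr.tolist())))

    @classmethod
    def zero(cls) -> "IndividualEffects":
        return cls()

    @classmethod
    def draw(cls, pop: PopulationParameters, rng: np.random.Generator) -> "IndividualEffects":
        sd = np.sqrt(pop.to_vector()[10:15])
        return cls.from_array(rng.standard_normal(5) * sd)


def reference_parameters() -> PopulationParameters:
    """The reference population parameterization (all defaults)."""
    return PopulationParameters()
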