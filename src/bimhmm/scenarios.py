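"""The 14-scenario grid of the simulation-estimation study.

Each scenario perturbs the reference parameterization along one axis:
transition-probability magnitude (2), drug-effect magnitude (3-6),
between-subject variability of the remission-to-exacerbation transition
(7-10), residual correlation magnitude (11-12), or FEV1 sampling
frequency (13-14, monthly instead of weekly biomarker sampling).
Scenario 1 is the untouched reference.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np
import yaml

from .parameters import PopulationParameters, reference_parameters

__all__ = ["ScenarioSpec", "scenario_table", "get_scenario"]


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: parameter overrides plus the sampling schedule."""

    scenario_id: int
    overrides: Mapping[str, float]
    n_fev1_samples: int = 60
    n_pro_samples: int = 60

    def population(self, base: Optional[PopulationParameters] = None) -> PopulationParameters:
        base = base or reference_parameters()
        return base.replace(**dict(self.overrides))

    def fev1_times(self) -> np.ndarray:
        """FEV1 sampling times: weekly (weeks 0..59) or monthly (0,4,...,56)."""
        if self.n_fev1_samples == 60:
            return np.arange(60, dtype=float)
        if self.n_fev1_samples == 15:
            return np.arange(0, 60, 4, dtype=float)
        raise ValueError(f"unsupported FEV1 sample count {self.n_fev1_samples}")

    def pro_times(self) -> np.ndarray:
        if self.n_pro_samples != 60:
            raise ValueError(f"unsupported PRO sample count {self.n_pro_samples}")
        return np.arange(60, dtype=float)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "scenario_id": self.scenario_id,
                    "overrides": dict(self.overrides),
                    "n_fev1_samples": self.n_fev1_samples,
                    "n_pro_samples": self.n_pro_samples,
                },
                fh,
                sort_keys=False,
            )


# Columns of the scenario grid, scenarios 1..14.
_SLP = (1.00, 1.00, 2.00, 0.50, 2.00, 0.50, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00)
_PI_RE = (0.05, 0.10, 0.05, 0.05, 0.10, 0.30, 0.05, 0.05, 0.10, 0.10, 0.05, 0.10, 0.05, 0.10)
_PI_ER = (0.15, 0.30, 0.15, 0.15, 0.30, 0.30, 0.15, 0.15, 0.30, 0.30, 0.15, 0.30, 0.15, 0.30)
_W2_PI_RE = (0.06, 0.06, 0.06, 0.06, 0.06, 0.06, 0.00, 0.12, 0.00, 0.12, 0.06, 0.06, 0.06, 0.06)
_RHO = (-0.33, -0.33, -0.33, -0.33, -0.33, -0.33, -0.33, -0.33, -0.33, -0.33, -0.66, -0.66, -0.33, -0.33)
_N_FEV1 = (60, 60, 60, 60, 60, 60, 60, 60, 60, 60, 60, 60, 15, 15)


def scenario_table() -> tuple[ScenarioSpec, ...]:
    """All 14 scenarios; overrides list only fields that differ from the
    reference."""
    ref = reference_parameters()
    specs = []
    for i in range(14):
        full = {
            "slp": _SLP[i],
            "theta_pi_re": _PI_RE[i],
            "theta_pi_er": _PI_ER[i],
            "omega2_pi_re": _W2_PI_RE[i],
            "rho_r": _RHO[i],
            "rho_e": _RHO[i],
        }
        overrides = {k: v for k, v in full.items() if v != getattr(ref, k)}
        specs.append(
            ScenarioSpec(
                scenario_id=i + 1,
                overrides=overrides,
                n_fev1_samples=_N_FEV1[i],
                n_pro_samples=60,
            )
        )
    return tuple(specs)


def get_scenario(scenario_id: int) -> ScenarioSpec:
    if not 1 <= scenario_id <= 14:
        raise ValueError(f"scenario_id must be in 1..14; got {scenario_id!r}")
    return scenario_table()[scenario_id - 1]
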