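"""Trial simulator: hidden chains, random effects, correlated emissions.

Simulates a two-arm placebo-controlled parallel trial (default 250
subjects per arm, 60 weeks) of the bivariate mixed HMM.  Per subject: one
five-component random-effect draw, an initial state draw, a weekly
first-order Markov chain, and at each observation time a draw from the
state's correlated bivariate normal emission.  FEV1 is masked at times
outside the FEV1 schedule (weekly, or monthly in the sparse-biomarker
design); the hidden chain always advances on the full weekly grid.

Randomness is counter-based: subject ``j`` of arm ``a`` uses the stream
seeded by ``SeedSequence((seed, a, j))``, so a subject's data is invariant
to how many subjects are simulated alongside them.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .datasets import SubjectRecord, TrialData
from .model import initial_state_prob, transition_matrix
from .parameters import IndividualEffects, PopulationParameters
from .scenarios import ScenarioSpec

__all__ = ["TrialDesign", "simulate_subject", "simulate_trial"]


@dataclasses.dataclass
class TrialDesign:
    """Sampling design of a two-arm trial.

    ``pro_times`` / ``fev1_times`` are the per-endpoint observation weeks;
    the hidden chain advances on their union (weekly by default).
    """

    n_per_arm: int = 250
    duration: float = 60.0
    pro_times: Optional[np.ndarray] = None
    fev1_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.pro_times is None:
            self.pro_times = np.arange(int(self.duration), dtype=float)
        if self.fev1_times is None:
            self.fev1_times = np.asarray(self.pro_times, dtype=float).copy()
        self.pro_times = np.asarray(self.pro_times, dtype=float)
        self.fev1_times = np.asarray(self.fev1_times, dtype=float)
        grid = self.grid()
        for name, t in (("pro_times", self.pro_times), ("fev1_times", self.fev1_times)):
            if np.any(t < 0) or np.any(t > self.duration):
                raise ValueError(f"{name} must lie within [0, {self.duration}]")
        if not np.isin(self.fev1_times, grid).all():
            raise ValueError("fev1_times must be a subset of the observation grid")

    def grid(self) -> np.ndarray:
        """Union observation grid on which the hidden chain advances."""
        return np.union1d(self.pro_times, self.fev1_times)

    @classmethod
    def weekly(cls, n_per_arm: int = 250, duration: float = 60.0) -> "TrialDesign":
        """Weekly sampling of both endpoints (60 samples each by default)."""
        return cls(n_per_arm=n_per_arm, duration=duration)

    @classmethod
    def monthly_fev1(cls, n_per_arm: int = 250, duration: float = 60.0) -> "TrialDesign":
        """Weekly PRO, monthly FEV1 (weeks 0, 4, ..., 56: 15 samples)."""
        return cls(
            n_per_arm=n_per_arm,
            duration=duration,
            pro_times=np.arange(int(duration), dtype=float),
            fev1_times=np.arange(0, int(duration), 4, dtype=float),
        )

    @classmethod
    def from_scenario(cls, scenario: ScenarioSpec, n_per_arm: int = 250) -> "TrialDesign":
        return cls(
            n_per_arm=n_per_arm,
            duration=60.0,
            pro_times=scenario.pro_times(),
            fev1_times=scenario.fev1_times(),
        )


def _simulate_states(pop, eta_pi_re, trt, n_steps, rng) -> np.ndarray:
    p_r0 = initial_state_prob(pop)
    mat = transition_matrix(pop, eta_pi_re, trt)
    states = np.empty(n_steps, dtype=np.int8)
    u = rng.random(n_steps)
    states[0] = 0 if u[0] < p_r0 else 1
    for j in range(1, n_steps):
        stay = 1.0 - mat[states[j - 1], 1 - states[j - 1]]
        states[j] = states[j - 1] if u[j] < stay else 1 - states[j - 1]
    return states


def simulate_subject(
    pop: PopulationParameters,
    design: TrialDesign,
    trt: int,
    rng: np.random.Generator,
    subject_id: int = 1,
    eta: Optional[IndividualEffects] = None,
) -> SubjectRecord:
    """Simulate one subject (states, random effects, observations).

    ``eta`` overrides the random-effect draw (useful for forcing
    eta = 0 in checks); when given, no eta randomness is consumed.
    """
    if trt not in (0, 1):
        raise ValueError(f"trt must be 0 or 1; got {trt!r}")
    if eta is None:
        eta = IndividualEffects.draw(pop, rng)
    times = design.grid()
    T = times.size
    states = _simulate_states(pop, eta.eta_pi_re, trt, T, rng)

    fev1_r = pop.theta_fev1_r * np.exp(eta.eta_fev1_r)
    fev1_e = fev1_r - pop.theta_fev1_e * np.exp(eta.eta_fev1_e)
    fac = 1.0 - pop.pe * (1.0 - np.exp(-np.log(2.0) * times / pop.phl))
    pro_r = (pop.theta_pro_r + eta.eta_pro_r) * fac
    pro_e = pro_r + (pop.theta_pro_e + eta.eta_pro_e)

    mu_f = np.where(states == 0, fev1_r, fev1_e)
    mu_p = np.where(states == 0, pro_r, pro_e)
    rho = np.where(states == 0, pop.rho_r, pop.rho_e)

    z1 = rng.standard_normal(T)
    z2 = rng.standard_normal(T)
    y_fev1 = mu_f + np.sqrt(pop.sigma2_fev1) * z1
    y_pro = mu_p + np.sqrt(pop.sigma2_pro) * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    obs_fev1 = np.isin(times, design.fev1_times)
    obs_pro = np.isin(times, design.pro_times)
    return SubjectRecord(
        subject_id=subject_id,
        trt=trt,
        times=times,
        y_fev1=np.where(obs_fev1, y_fev1, np.nan),
        y_pro=np.where(obs_pro, y_pro, np.nan),
        obs_fev1=obs_fev1,
        obs_pro=obs_pro,
        true_states=states,
        eta=eta.as_array(),
    )


def simulate_trial(
    pop: PopulationParameters,
    design: TrialDesign,
    seed: int,
    out_csv=None,
) -> TrialData:
    """Simulate a full two-arm trial; deterministic given ``seed``.

    Arm 0 (placebo) gets IDs ``1..n``, arm 1 (treated) ``n+1..2n``.
    ``out_csv`` optionally writes the long-format analysis dataset.
    """
    times = design.grid()
    n = design.n_per_arm
    T = times.size
    n_tot = 2 * n
    yf = np.empty((n_tot, T))
    yp = np.empty((n_tot, T))
    obf = np.empty((n_tot, T), dtype=bool)
    obp = np.empty((n_tot, T), dtype=bool)
    states = np.empty((n_tot, T), dtype=np.int8)
    etas = np.empty((n_tot, 5))
    ids = np.arange(1, n_tot + 1, dtype=np.int64)
    trt = np.repeat(np.array([0, 1], dtype=np.int64), n)
    for arm in (0, 1):
        for j in range(n):
            i = arm * n + j
            rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, arm, j))))
            rec = simulate_subject(pop, design, arm, rng, subject_id=int(ids[i]))
            yf[i] = rec.y_fev1
            yp[i] = rec.y_pro
            obf[i] = rec.obs_fev1
            obp[i] = rec.obs_pro
            states[i] = rec.true_states
            etas[i] = rec.eta
    data = TrialData(
        times=times,
        ids=ids,
        trt=trt,
        y_fev1=yf,
        y_pro=yp,
        obs_fev1=obf,
        obs_pro=obp,
        states=states,
        etas=etas,
    )
    if out_csv is not None:
        try:
            data.to_csv(out_csv)
        except OSError as exc:
            raise OSError(f"could not write dataset to {out_csv}: {exc}") from exc
    return data
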