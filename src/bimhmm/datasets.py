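"""Trial dataset containers and long-format CSV input/output.

The analysis dataset is long-format with one row per subject-time:
columns ``ID, TIME, TRT, FEV1, PRO, MDV_FEV1, MDV_PRO`` (``MDV_* = 1``
marks a missing endpoint, written as an empty cell).  All subjects in a
dataset share one observation time grid — the weekly grid on which the
hidden chain advances — and per-endpoint missingness masks say which
endpoints were sampled when.

Simulation truth (hidden states and random-effect draws) is carried in
optional side arrays and written to separate sidecar files, never into
the analysis dataset.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

__all__ = ["SubjectRecord", "TrialData"]

_COLUMNS = ["ID", "TIME", "TRT", "FEV1", "PRO", "MDV_FEV1", "MDV_PRO"]


@dataclasses.dataclass
class SubjectRecord:
    """One subject: time grid, arm, per-time observations and masks.

    ``true_states`` (0 = remission, 1 = exacerbation) and ``eta`` are
    simulation truth, present only for simulated data and withheld from
    estimation.
    """

    subject_id: int
    trt: int
    times: np.ndarray
    y_fev1: np.ndarray
    y_pro: np.ndarray
    obs_fev1: np.ndarray
    obs_pro: np.ndarray
    true_states: Optional[np.ndarray] = None
    eta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"subject {self.subject_id}: times must be strictly increasing")
        if not np.all(self.obs_fev1 | self.obs_pro):
            raise ValueError(
                f"subject {self.subject_id}: every row needs at least one observed endpoint"
            )


@dataclasses.dataclass
class TrialData:
    """A rectangular trial dataset (n subjects x T shared times)."""

    times: np.ndarray          # (T,) weeks
    ids: np.ndarray            # (n,) subject IDs
    trt: np.ndarray            # (n,) 0/1
    y_fev1: np.ndarray         # (n, T), NaN where unobserved
    y_pro: np.ndarray          # (n, T)
    obs_fev1: np.ndarray       # (n, T) bool
    obs_pro: np.ndarray        # (n, T) bool
    states: Optional[np.ndarray] = None   # (n, T) int8 truth
    etas: Optional[np.ndarray] = None     # (n, 5) truth

    @property
    def n_subjects(self) -> int:
        return int(self.ids.shape[0])

    @property
    def n_times(self) -> int:
        return int(self.times.shape[0])

    def subject(self, i: int) -> SubjectRecord:
        return SubjectRecord(
            subject_id=int(self.ids[i]),
            trt=int(self.trt[i]),
            times=self.times,
            y_fev1=self.y_fev1[i],
            y_pro=self.y_pro[i],
            obs_fev1=self.obs_fev1[i],
            obs_pro=self.obs_pro[i],
            true_states=None if self.states is None else self.states[i],
            eta=None if self.etas is None else self.etas[i],
        )

    def subjects(self) -> Iterator[SubjectRecord]:
        for i in range(self.n_subjects):
            yield self.subject(i)

    # -- masking / endpoint selection ---------------------------------

    def restrict(
        self,
        fev1: bool = True,
        pro: bool = True,
        fev1_times: Optional[np.ndarray] = None,
    ) -> "TrialData":
        """Copy with endpoints masked out of the likelihood.

        ``fev1=False`` (or ``pro=False``) drops that endpoint entirely;
        ``fev1_times`` keeps FEV1 only at the given times (e.g. a monthly
        subset of a weekly grid).  Rows may end up with no observed
        endpoint; such rows carry no emission information but the hidden
        chain still advances through them.
        """
        obs_f = self.obs_fev1.copy()
        obs_p = self.obs_pro.copy()
        if not fev1:
            obs_f[:] = False
        elif fev1_times is not None:
            keep = np.isin(self.times, np.asarray(fev1_times, dtype=float))
            obs_f &= keep[None, :]
        if not pro:
            obs_p[:] = False
        yf = np.where(obs_f, self.y_fev1, np.nan)
        yp = np.where(obs_p, self.y_pro, np.nan)
        return dataclasses.replace(
            self, y_fev1=yf, y_pro=yp, obs_fev1=obs_f, obs_pro=obs_p
        )

    # -- frames and files ---------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format analysis frame (truth columns excluded)."""
        n, T = self.y_fev1.shape
        return pd.DataFrame(
            {
                "ID": np.repeat(self.ids, T),
                "TIME": np.tile(self.times, n),
                "TRT": np.repeat(self.trt, T),
                "FEV1": np.where(self.obs_fev1, self.y_fev1, np.nan).ravel(),
                "PRO": np.where(self.obs_pro, self.y_pro, np.nan).ravel(),
                "MDV_FEV1": (~self.obs_fev1).astype(int).ravel(),
                "MDV_PRO": (~self.obs_pro).astype(int).ravel(),
            }
        )

    def to_nonmem_frame(self) -> pd.DataFrame:
        """Stacked DV/DVID export (DVID 1 = FEV1, 2 = PRO) for cross-checks."""
        long = self.to_frame()
        parts = []
        for dvid, col in ((1, "FEV1"), (2, "PRO")):
            part = long[["ID", "TIME", "TRT"]].copy()
            part["DVID"] = dvid
            part["DV"] = long[col]
            part["MDV"] = long[f"MDV_{col}"]
            parts.append(part)
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["ID", "TIME", "DVID"], kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def save(self, directory) -> dict:
        """Write ``dataset.csv`` plus truth sidecars; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"dataset": directory / "dataset.csv"}
        self.to_csv(paths["dataset"])
        if self.states is not None:
            n, T = self.states.shape
            truth = pd.DataFrame(
                {
                    "ID": np.repeat(self.ids, T),
                    "TIME": np.tile(self.times, n),
                    "STATE": np.where(self.states.ravel() == 0, "R", "E"),
                }
            )
            paths["states"] = directory / "truth_states.csv"
            truth.to_csv(paths["states"], index=False)
        if self.etas is not None:
            eta_cols = ["ETA_FEV1_R", "ETA_FEV1_E", "ETA_PRO_R", "ETA_PRO_E", "ETA_PI_RE"]
            etas = pd.DataFrame(self.etas, columns=eta_cols)
            etas.insert(0, "ID", self.ids)
            paths["etas"] = directory / "truth_etas.csv"
            etas.to_csv(paths["etas"], index=False, float_format="%.10g")
        return paths

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialData":
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset is missing required column(s): {missing}")
        frame = frame.sort_values(["ID", "TIME"], kind="stable")
        times = np.sort(frame["TIME"].unique()).astype(float)
        ids = frame["ID"].unique()
        n, T = len(ids), len(times)
        if len(frame) != n * T:
            raise ValueError("dataset is not rectangular: subjects must share one time grid")
        yf = frame["FEV1"].to_numpy(dtype=float).reshape(n, T)
        yp = frame["PRO"].to_numpy(dtype=float).reshape(n, T)
        obs_f = frame["MDV_FEV1"].to_numpy(dtype=int).reshape(n, T) == 0
        obs_p = frame["MDV_PRO"].to_numpy(dtype=int).reshape(n, T) == 0
        trt = frame.groupby("ID", sort=False)["TRT"].first().to_numpy(dtype=np.int64)
        if np.any(obs_f & ~np.isfinite(yf)) or np.any(obs_p & ~np.isfinite(yp)):
            raise ValueError("observed endpoint (MDV = 0) with a missing value")
        return cls(
            times=times,
            ids=np.asarray(ids),
            trt=trt,
            y_fev1=np.where(obs_f, yf, np.nan),
            y_pro=np.where(obs_p, yp, np.nan),
            obs_fev1=obs_f,
            obs_pro=obs_p,
        )

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        try:
            frame = pd.read_csv(path)
        except (OSError, pd.errors.ParserError) as exc:
            raise type(exc)(f"{path}: {exc}") from exc
        return cls.from_frame(frame)

    # -- kernel views --------------------------------------------------

    def as_arrays(self):
        """C-contiguous float64/bool/int64 views for the compiled kernels."""
        return (
            np.ascontiguousarray(np.where(self.obs_fev1, self.y_fev1, 0.0), dtype=np.float64),
            np.ascontiguousarray(np.where(self.obs_pro, self.y_pro, 0.0), dtype=np.float64),
            np.ascontiguousarray(self.obs_fev1),
            np.ascontiguousarray(self.obs_pro),
            np.ascontiguousarray(self.times, dtype=np.float64),
            np.ascontiguousarray(self.trt, dtype=np.int64),
        )
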