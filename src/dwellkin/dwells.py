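"""Dwell collections and empirical cumulative distributions.

A dwell is the continuous duration spent in one observable class (unbound /
bound) before switching. The empirical CDF is built on a regular grid whose
spacing equals the imaging exposure time; it is the surface all fitting
operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["DwellSet", "EmpiricalCDF", "build_cdf"]


@dataclass
class DwellSet:
    """Per-class dwell durations at a stated ligand concentration.

    ``censored`` flags dwells truncated by the start or end of observation;
    they are stored only when explicitly requested and are never part of
    ``complete()``.
    """

    durations: np.ndarray          # seconds
    classes: np.ndarray            # str per dwell
    censored: np.ndarray           # bool per dwell
    concentration: float = 0.0     # nM
    frame_dt: float | None = None  # seconds

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (len(self.durations) == len(self.classes) == len(self.censored)):
            raise ValueError("durations, classes and censored must have equal length")
        if np.any(self.durations < 0):
            raise ValueError("negative dwell duration")

    def __len__(self) -> int:
        return len(self.durations)

    def complete(self, cls: str | None = None) -> np.ndarray:
        """Durations of complete (non-censored) dwells, optionally one class."""
        mask = ~self.censored
        if cls is not None:
            mask &= self.classes == cls
        return self.durations[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.classes, "dwell_s": self.durations, "censored": self.censored}
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, concentration: float = 0.0, frame_dt: float | None = None
    ) -> "DwellSet":
        return cls(
            durations=df["dwell_s"].to_numpy(float),
            classes=df["class"].to_numpy(object),
            censored=df["censored"].to_numpy(bool),
            concentration=concentration,
            frame_dt=frame_dt,
        )

    @classmethod
    def concatenate(cls, sets: Iterable["DwellSet"]) -> "DwellSet":
        sets = list(sets)
        if not sets:
            return cls(np.array([]), np.array([], dtype=object), np.array([], dtype=bool))
        conc = sets[0].concentration
        dt = sets[0].frame_dt
        return cls(
            durations=np.concatenate([s.durations for s in sets]),
            classes=np.concatenate([s.classes for s in sets]),
            censored=np.concatenate([s.censored for s in sets]),
            concentration=conc,
            frame_dt=dt,
        )


@dataclass
class EmpiricalCDF:
    """Step CDF of dwell durations on a regular time grid.

    ``values[i]`` is the fraction of dwells with duration <= ``times[i]``;
    grid spacing equals the exposure time and the grid runs from one frame
    to the longest dwell.
    """

    times: np.ndarray
    values: np.ndarray
    n_dwells: int
    concentration: float = 0.0  # nM
    frame_dt: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("CDF values must be non-decreasing")
        if self.values.size and (self.values[-1] > 1 + 1e-12 or self.values[0] < 0):
            raise ValueError("CDF values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "cdf": self.values})


def build_cdf(
    dwells: DwellSet | np.ndarray,
    cls: str | None = None,
    frame_dt: float | None = None,
    concentration: float | None = None,
) -> EmpiricalCDF:
    """Empirical CDF on a grid with step ``frame_dt`` from one frame to the max dwell.

    Accepts either a :class:`DwellSet` (complete dwells of ``cls``) or a bare
    array of durations with an explicit ``frame_dt``.
    """
    if isinstance(dwells, DwellSet):
        data = dwells.complete(cls)
        if frame_dt is None:
            frame_dt = dwells.frame_dt
        if concentration is None:
            concentration = dwells.concentration
    else:
        data = np.asarray(dwells, dtype=float)
    if frame_dt is None or frame_dt <= 0:
        raise ValueError("frame_dt must be a positive number")
    if data.size == 0:
        raise ValueError("no complete dwells to build a CDF from")
    data = np.sort(data)
    n_steps = max(int(np.ceil(data[-1] / frame_dt - 1e-9)), 1)
    times = frame_dt * np.arange(1, n_steps + 1)
    # count dwells <= t with a half-frame tolerance against float jitter
    values = np.searchsorted(data, times + 0.5 * frame_dt * 1e-6, side="right") / data.size
    return EmpiricalCDF(
        times=times,
        values=values,
        n_dwells=int(data.size),
        concentration=float(concentration or 0.0),
        frame_dt=float(frame_dt),
    )
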