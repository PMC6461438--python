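"""Raw trace processing: FRET efficiencies, histograms, two-limit
threshold idealization and dwell extraction.

Efficiency: ``E = I_A' / (I_A' + I_D')`` after background subtraction and
donor-leakage correction. Idealization uses hysteresis between two limits so
that noise excursions between the limits do not create spurious transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dwells import DwellSet, EmpiricalCDF, build_cdf  # noqa: F401  (re-export)
from .simulate import Trajectory

__all__ = [
    "Trajectory",
    "IdealizedTrace",
    "fret_efficiency",
    "fret_histogram",
    "threshold_idealize",
    "extract_dwells",
    "build_cdf",
]

LOW = "low"
HIGH = "high"

#: plotting clip range for efficiencies (raw values are kept alongside)
E_CLIP = (-0.2, 1.2)


@dataclass
class IdealizedTrace:
    """Alternating low/high segments in frame units.

    ``starts``/``ends`` are inclusive/exclusive frame indices; segments are
    contiguous and classes alternate.
    """

    classes: list[str]
    starts: np.ndarray
    ends: np.ndarray
    frame_dt: float
    low_limit: float | None = None
    high_limit: float | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        if len(self.classes) != len(self.starts) or len(self.classes) != len(self.ends):
            raise ValueError("ragged idealized trace")
        if len(self.classes):
            if np.any(self.ends <= self.starts):
                raise ValueError("empty segment")
            if np.any(self.starts[1:] != self.ends[:-1]):
                raise ValueError("segments must be contiguous")
            for a, b in zip(self.classes, self.classes[1:]):
                if a == b:
                    raise ValueError("adjacent segments must alternate class")

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def n_frames(self) -> np.ndarray:
        return self.ends - self.starts

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"class": self.classes, "start_frame": self.starts, "end_frame": self.ends}
        )


def fret_efficiency(
    trace: Trajectory,
    leakage: float = 0.0,
    background_d: float = 0.0,
    background_a: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame FRET efficiency and validity mask.

    Corrections: ``I_D' = I_D - background_d``;
    ``I_A' = I_A - background_a - leakage * I_D'``. Frames with non-positive
    total corrected intensity are flagged invalid (they carry no FRET
    information and are excluded from histograms). Raw values are returned
    unclipped; use :data:`E_CLIP` when plotting.
    """
    if not 0.0 <= leakage < 1.0:
        raise ValueError("leakage must be in [0, 1)")
    if not (np.isfinite(background_d) and np.isfinite(background_a)):
        raise ValueError("backgrounds must be finite")
    i_d = trace.donor - background_d
    i_a = trace.acceptor - background_a - leakage * i_d
    total = i_a + i_d
    valid = total > 0
    e = np.full(len(trace), np.nan)
    np.divide(i_a, total, out=e, where=valid)
    return e, valid


def fret_histogram(
    traces: Sequence[Trajectory],
    n_frames: int = 5,
    bins: np.ndarray | int = 40,
    leakage: float = 0.0,
    background_d: float = 0.0,
    background_a: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pooled first-``n_frames`` efficiencies across molecules.

    Returns ``(counts, bin_edges)``; counts sum to the number of valid
    pooled frames.
    """
    pooled: list[np.ndarray] = []
    for trace in traces:
        if len(trace) < n_frames:
            raise ValueError(f"trace has {len(trace)} frames, need at least {n_frames}")
        e, valid = fret_efficiency(trace, leakage, background_d, background_a)
        pooled.append(e[:n_frames][valid[:n_frames]])
    values = np.concatenate(pooled) if pooled else np.array([])
    if values.size == 0:
        raise ValueError("no valid frames to histogram")
    if np.isscalar(bins):
        bins = np.linspace(E_CLIP[0], E_CLIP[1], int(bins) + 1)
    counts, edges = np.histogram(np.clip(values, E_CLIP[0], E_CLIP[1]), bins=bins)
    return counts, edges


def threshold_idealize(
    signal: np.ndarray,
    low_limit: float,
    high_limit: float,
    frame_dt: float = 1.0,
) -> IdealizedTrace:
    """Two-limit (hysteresis) idealization of a frame series.

    The class switches low->high only when the signal rises above
    ``high_limit`` and high->low only when it falls below ``low_limit``;
    values between the limits keep the previous class. The initial class is
    set by whichever limit the first frame is nearer to.
    """
    if low_limit >= high_limit:
        raise ValueError("low_limit must be strictly below high_limit")
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")

    first = signal[0]
    if first > high_limit:
        cls = HIGH
    elif first < low_limit:
        cls = LOW
    else:
        cls = HIGH if abs(first - high_limit) <= abs(first - low_limit) else LOW

    classes: list[str] = []
    starts: list[int] = []
    seg_start = 0
    for i, x in enumerate(signal):
        if cls == LOW and x > high_limit:
            classes.append(LOW)
            starts.append(seg_start)
            seg_start = i
            cls = HIGH
        elif cls == HIGH and x < low_limit:
            classes.append(HIGH)
            starts.append(seg_start)
            seg_start = i
            cls = LOW
    classes.append(cls)
    starts.append(seg_start)
    ends = starts[1:] + [signal.size]

    if len(classes) == 1 and np.all((signal >= low_limit) & (signal <= high_limit)):
        warnings.warn("signal never crosses either limit; single ambiguous segment", stacklevel=2)
    return IdealizedTrace(
        classes=classes,
        starts=np.array(starts),
        ends=np.array(ends),
        frame_dt=frame_dt,
        low_limit=low_limit,
        high_limit=high_limit,
    )


def extract_dwells(
    ideal: IdealizedTrace,
    include_censored: bool = False,
    concentration: float = 0.0,
) -> DwellSet:
    """Segment lengths x frame time, with first/last segments censored.

    The first and last segments are truncated by the observation window and
    are flagged censored; by default only interior (complete) dwells are
    returned. Fewer than three segments therefore yields zero complete
    dwells.
    """
    n = len(ideal)
    if n < 3 and not include_censored:
        warnings.warn("fewer than 3 segments: no complete dwells", stacklevel=2)
    durations = ideal.n_frames * ideal.frame_dt
    classes = np.array(ideal.classes, dtype=object)
    censored = np.zeros(n, dtype=bool)
    if n:
        censored[0] = True
        censored[-1] = True
    if not include_censored:
        keep = ~censored
        durations, classes, censored = durations[keep], classes[keep], censored[keep]
    return DwellSet(
        durations, classes, censored,
        concentration=concentration, frame_dt=ideal.frame_dt,
    )
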