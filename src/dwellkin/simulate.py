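"""Stochastic ground truth for the four-state scheme.

Exact (Gillespie) continuous-time Markov chain sampling of state paths,
reduction of paths to observable-class dwells, and emission of noisy
two-channel intensity traces. Everything is seeded and reproducible; the
ligand concentration is held constant (pseudo-first-order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dwells import DwellSet
from .scheme import (
    BOUND,
    UNBOUND,
    KineticScheme,
    RateConstantSet,
    build_four_state_scheme,
    rate_matrix,
    stationary_distribution,
)

__all__ = [
    "SimulationConfig",
    "StatePath",
    "Trajectory",
    "gillespie_simulate",
    "dwells_from_path",
    "emit_trace",
    "sample_first_passage_times",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for one simulated molecule.

    ``fret_levels`` maps observable class -> FRET efficiency; ``noise_sd``
    is the per-channel Gaussian intensity noise. An optional exponential
    ``bleach_rate`` (s^-1) truncates the trace (off by default).
    """

    rate_constants: RateConstantSet
    dna_concentration: float  # nM, constant
    t_max: float              # s
    frame_dt: float           # s
    fret_levels: Mapping[str, float] = field(
        default_factory=lambda: {UNBOUND: 0.0, BOUND: 0.45}
    )
    noise_sd: float = 0.0
    total_intensity: float = 100.0
    seed: int = 0
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.dna_concentration < 0:
            raise ValueError("dna_concentration must be >= 0")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be > 0")
        if self.t_max <= self.frame_dt:
            raise ValueError("t_max must exceed frame_dt")
        for cls, e in self.fret_levels.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"fret level for {cls!r} outside [0, 1]: {e}")
        if self.noise_sd < 0 or self.total_intensity <= 0 or self.bleach_rate < 0:
            raise ValueError("noise_sd/bleach_rate must be >= 0 and total_intensity > 0")

    def metadata(self) -> dict:
        d = {
            "seed": self.seed,
            "dna_nM": self.dna_concentration,
            "t_max_s": self.t_max,
            "frame_dt_s": self.frame_dt,
            "noise_sd": self.noise_sd,
            "total_intensity": self.total_intensity,
        }
        d.update(self.rate_constants.as_dict())
        return d


@dataclass
class StatePath:
    """Ordered, contiguous state segments; the terminal segment ends at t_max.

    ``trapped`` names the state if the chain hit an all-zero exit rate
    (absorbing trap) before ``t_max``.
    """

    states: list[str]
    entry_times: np.ndarray
    exit_times: np.ndarray
    t_max: float
    seed: int | None = None
    trapped: str | None = None

    def __post_init__(self) -> None:
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        self.exit_times = np.asarray(self.exit_times, dtype=float)
        if len(self.states) != len(self.entry_times) or len(self.states) != len(self.exit_times):
            raise ValueError("ragged state path")
        if len(self.states):
            if self.entry_times[0] != 0.0:
                raise ValueError("path must start at t = 0")
            if np.any(self.exit_times <= self.entry_times):
                raise ValueError("segment times must strictly increase")
            if np.any(self.entry_times[1:] != self.exit_times[:-1]):
                raise ValueError("segments must be contiguous")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def durations(self) -> np.ndarray:
        return self.exit_times - self.entry_times

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"state": self.states, "t_start": self.entry_times, "t_stop": self.exit_times}
        )


@dataclass
class Trajectory:
    """Per-frame two-channel intensity trace."""

    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_dt: float
    acceptor_direct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.times) == len(self.donor) == len(self.acceptor)):
            raise ValueError("channel length mismatch")
        if not (np.isfinite(self.donor).all() and np.isfinite(self.acceptor).all()):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.times)),
                "time_s": self.times,
                "donor": self.donor,
                "acceptor": self.acceptor,
            }
        )
        if self.acceptor_direct is not None:
            df["acceptor_direct"] = self.acceptor_direct
        return df


def _exit_channels(scheme: KineticScheme, rates: RateConstantSet, dna: float):
    """Per-state lists of (target index, propensity)."""
    rd = rates.as_dict()
    channels: list[list[tuple[int, float]]] = [[] for _ in scheme.states]
    for tr in scheme.transitions:
        k = rd[tr.rate_symbol] * (dna if tr.ligand_order else 1.0)
        channels[scheme.index(tr.source)].append((scheme.index(tr.target), k))
    return channels


def gillespie_simulate(
    config: SimulationConfig,
    scheme: KineticScheme | None = None,
    initial_state: str | None = None,
    rng: np.random.Generator | None = None,
) -> StatePath:
    """Exact CTMC sample path of the scheme up to ``t_max``.

    The initial state defaults to a draw from the stationary distribution of
    the full scheme. A state with no exit channels ends the path early and
    is reported via ``StatePath.trapped``.
    """
    if scheme is None:
        scheme = build_four_state_scheme()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    channels = _exit_channels(scheme, config.rate_constants, config.dna_concentration)
    if initial_state is None:
        pi = stationary_distribution(scheme, config.rate_constants, config.dna_concentration)
        current = int(rng.choice(scheme.n_states, p=pi))
    else:
        current = scheme.index(initial_state)

    t_stop = config.t_max
    if config.bleach_rate > 0:
        t_stop = min(t_stop, rng.exponential(1.0 / config.bleach_rate))
        t_stop = max(t_stop, 2 * config.frame_dt)

    states: list[str] = []
    entries: list[float] = []
    exits: list[float] = []
    t = 0.0
    trapped: str | None = None
    while t < t_stop:
        outs = channels[current]
        total = sum(k for _, k in outs)
        if total <= 0.0:
            trapped = scheme.states[current]
            states.append(scheme.states[current])
            entries.append(t)
            exits.append(t_stop)
            t = t_stop
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        states.append(scheme.states[current])
        entries.append(t)
        exits.append(min(t_next, t_stop))
        if t_next >= t_stop:
            t = t_stop
            break
        u = rng.random() * total
        acc = 0.0
        for target, k in outs:
            acc += k
            if u <= acc:
                current = target
                break
        t = t_next
    return StatePath(
        states=states,
        entry_times=np.array(entries),
        exit_times=np.array(exits),
        t_max=t_stop,
        seed=config.seed,
        trapped=trapped,
    )


def dwells_from_path(
    path: StatePath,
    class_map: Mapping[str, str] | None = None,
    include_censored: bool = False,
    concentration: float = 0.0,
    frame_dt: float | None = None,
) -> DwellSet:
    """Merge consecutive same-class segments into observable dwells.

    The terminal dwell is right-censored (cut by ``t_max``) and excluded
    unless ``include_censored``; censored dwells are flagged, never mixed
    into the complete set.
    """
    if class_map is None:
        class_map = build_four_state_scheme().observable_class
    if len(path) == 0:
        warnings.warn("empty state path; returning empty dwell set", stacklevel=2)
        return DwellSet(
            np.array([]), np.array([], dtype=object), np.array([], dtype=bool),
            concentration=concentration, frame_dt=frame_dt,
        )
    missing = set(path.states) - set(class_map)
    if missing:
        raise ValueError(f"class_map misses states: {sorted(missing)}")

    durations: list[float] = []
    classes: list[str] = []
    censored: list[bool] = []
    cur_cls = class_map[path.states[0]]
    cur_start = path.entry_times[0]
    for state, t0, t1 in zip(path.states[1:], path.entry_times[1:], path.exit_times[1:]):
        cls = class_map[state]
        if cls != cur_cls:
            durations.append(t0 - cur_start)
            classes.append(cur_cls)
            censored.append(False)
            cur_cls = cls
            cur_start = t0
    # terminal dwell: right-censored by end of observation
    durations.append(path.exit_times[-1] - cur_start)
    classes.append(cur_cls)
    censored.append(True)

    durations_a = np.array(durations)
    classes_a = np.array(classes, dtype=object)
    censored_a = np.array(censored)
    if not include_censored:
        keep = ~censored_a
        durations_a, classes_a, censored_a = durations_a[keep], classes_a[keep], censored_a[keep]
    return DwellSet(
        durations_a, classes_a, censored_a,
        concentration=concentration, frame_dt=frame_dt,
    )


def emit_trace(
    path: StatePath,
    config: SimulationConfig,
    class_map: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Render a state path as a noisy donor/acceptor frame series.

    Within each frame the true efficiency is the time-weighted mean over the
    states occupied during that frame; each channel then gets independent
    Gaussian noise of width ``noise_sd``.
    """
    if class_map is None:
        class_map = build_four_state_scheme().observable_class
    if rng is None:
        # decorrelate from the path stream but stay a pure function of the seed
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7ACE)))
    dt = config.frame_dt
    n_frames = int(np.floor(path.t_max / dt))
    if n_frames < 1:
        raise ValueError("path shorter than one frame")
    frame_edges = dt * np.arange(n_frames + 1)
    e_sum = np.zeros(n_frames)
    levels = {s: config.fret_levels[class_map[s]] for s in set(path.states)}
    for state, t0, t1 in zip(path.states, path.entry_times, path.exit_times):
        first = int(np.searchsorted(frame_edges, t0, side="right")) - 1
        last = int(np.searchsorted(frame_edges, t1, side="left")) - 1
        first = max(first, 0)
        last = min(last, n_frames - 1)
        if last < first:
            continue
        idx = np.arange(first, last + 1)
        overlap = np.minimum(t1, frame_edges[idx + 1]) - np.maximum(t0, frame_edges[idx])
        e_sum[idx] += levels[state] * np.clip(overlap, 0.0, None)
    e_frame = e_sum / dt
    acceptor = config.total_intensity * e_frame
    donor = config.total_intensity * (1.0 - e_frame)
    if config.noise_sd > 0:
        acceptor = acceptor + rng.normal(0.0, config.noise_sd, n_frames)
        donor = donor + rng.normal(0.0, config.noise_sd, n_frames)
    times = frame_edges[:-1] + 0.5 * dt
    return Trajectory(times=times, donor=donor, acceptor=acceptor, frame_dt=dt)


def sample_first_passage_times(
    q: np.ndarray,
    p0: Sequence[float],
    n: int,
    rng: np.random.Generator,
    max_rounds: int = 100_000,
) -> np.ndarray:
    """Gillespie first-passage sampling for a condensed scheme.

    ``q`` is the (column-convention) transient generator; absorption
    happens with the leftover exit rate of each transient state. Vectorized
    over ``n`` walkers; used as a fast stochastic oracle for dwell sampling.
    """
    q = np.asarray(q, dtype=float)
    m = q.shape[0]
    exit_total = -np.diag(q)                      # total exit rate per state
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    jump = jump.T                                 # jump[i, j]: rate i -> j
    absorb = exit_total - jump.sum(axis=1)        # rate into the absorbing state
    if np.any(absorb < -1e-12):
        raise ValueError("generator has negative absorption rates")
    absorb = np.clip(absorb, 0.0, None)

    state = rng.choice(m, size=n, p=np.asarray(p0, dtype=float))
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    for _ in range(max_rounds):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            return t
        rates = exit_total[state[idx]]
        if np.any(rates <= 0):
            raise RuntimeError("transient state with zero exit rate: walker trapped")
        t[idx] += rng.exponential(1.0 / rates)
        u = rng.random(idx.size) * rates
        # absorption first, then transient targets in order
        absorbed = u < absorb[state[idx]]
        alive[idx[absorbed]] = False
        rem = idx[~absorbed]
        if rem.size:
            u_rem = u[~absorbed] - absorb[state[rem]]
            cum = np.cumsum(jump[state[rem]], axis=1)
            new_state = (u_rem[:, None] > cum).sum(axis=1)
            state[rem] = np.minimum(new_state, m - 1)
    raise RuntimeError("first-passage sampling did not absorb within max_rounds")
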