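"""File-format plumbing: CSV/JSON/YAML readers and writers, config
validation, and the end-to-end pipeline runner.

All numeric artifacts are flat CSV with a ``#``-comment metadata header
(seed and parameter values), so every file round-trips and is
self-describing.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detfit import BINDING, UNBINDING, bootstrap_ci, fit_global
from .dwells import DwellSet, EmpiricalCDF, build_cdf
from .expfit import fit_exp_cdf, ftest_compare
from .scheme import BOUND, UNBOUND, RateConstantSet, build_four_state_scheme
from .simulate import SimulationConfig, Trajectory, dwells_from_path, emit_trace, gillespie_simulate
from .thermo import equilibrium_summary
from .traces import HIGH, LOW, extract_dwells, fret_efficiency, threshold_idealize

logger = logging.getLogger("dwellkin")

__all__ = [
    "write_csv",
    "read_csv",
    "load_config",
    "read_trajectory_csv",
    "read_dwells_csv",
    "read_cdf_csv",
    "validate_inputs",
    "run_pipeline",
    "config_hash",
]


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with ``# key: value`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_csv`; returns ``(frame, meta)``."""
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                lines.append(line)
    # exact float round-trip: the default parser can be off by 1 ulp
    df = pd.read_csv(_io.StringIO("".join(lines)), float_precision="round_trip")
    return df, meta


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:10]


def read_trajectory_csv(path) -> Trajectory:
    df, meta = read_csv(path)
    for col in ("time_s", "donor", "acceptor"):
        if col not in df.columns:
            raise ValueError(f"trajectory file {path} missing column {col!r}")
    times = df["time_s"].to_numpy(float)
    diffs = np.diff(times)
    if len(diffs) and not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"trajectory file {path} has non-uniform frame spacing")
    frame_dt = float(meta.get("frame_dt_s", diffs[0] if len(diffs) else 1.0))
    direct = df["acceptor_direct"].to_numpy(float) if "acceptor_direct" in df else None
    return Trajectory(
        times=times,
        donor=df["donor"].to_numpy(float),
        acceptor=df["acceptor"].to_numpy(float),
        frame_dt=frame_dt,
        acceptor_direct=direct,
    )


def read_dwells_csv(path) -> DwellSet:
    df, meta = read_csv(path)
    for col in ("class", "dwell_s", "censored"):
        if col not in df.columns:
            raise ValueError(f"dwell file {path} missing column {col!r}")
    if (df["dwell_s"] < 0).any():
        bad = int(df.index[df["dwell_s"] < 0][0]) + 1
        raise ValueError(f"dwell file {path}: negative dwell at data row {bad}")
    return DwellSet.from_frame(
        df,
        concentration=float(meta.get("dna_nM", 0.0)),
        frame_dt=float(meta["frame_dt_s"]) if "frame_dt_s" in meta else None,
    )


def read_cdf_csv(path) -> EmpiricalCDF:
    df, meta = read_csv(path)
    for col in ("time_s", "cdf"):
        if col not in df.columns:
            raise ValueError(f"CDF file {path} missing column {col!r}")
    values = df["cdf"].to_numpy(float)
    if np.any(np.diff(values) < 0):
        raise ValueError(f"CDF file {path} has non-monotone values")
    times = df["time_s"].to_numpy(float)
    return EmpiricalCDF(
        times=times,
        values=values,
        n_dwells=int(meta.get("n_dwells", 0)),
        concentration=float(meta.get("dna_nM", 0.0)),
        frame_dt=float(meta["frame_dt_s"]) if "frame_dt_s" in meta else None,
    )


DEFAULT_CONFIG = {
    "concentrations": [1.0, 5.0, 15.0],
    "n_traces": 20,
    "t_max": 300.0,
    "frame_dt": 0.05,
    "fret_levels": {UNBOUND: 0.0, BOUND: 0.45},
    "noise_sd": 5.0,
    "total_intensity": 100.0,
    "thresholds": {"low": 0.2, "high": 0.3},
    "n_bootstrap": 200,
    "ci_level": 0.68,
    "seed": 0,
}


def validate_inputs(config: dict, data_dir: Path | None = None) -> dict:
    """Schema/consistency checks before any stage runs.

    Returns ``{"errors": [...], "warnings": [...]}``; errors make the
    pipeline refuse to start.
    """
    errors: list[str] = []
    warnings_: list[str] = []

    concs = config.get("concentrations", [])
    if not concs:
        errors.append("no concentrations given")
    elif any(c <= 0 for c in concs):
        errors.append(f"concentrations must be > 0, got {concs}")
    if config.get("frame_dt", 0) <= 0:
        errors.append("frame_dt must be > 0")
    if config.get("t_max", 0) <= config.get("frame_dt", 0):
        errors.append("t_max must exceed frame_dt")
    th = config.get("thresholds", {})
    if th and not th.get("low", 0) < th.get("high", 1):
        errors.append("thresholds: low must be < high")
    if config.get("n_bootstrap", 1) < 0:
        errors.append("n_bootstrap must be >= 0")
    level = config.get("ci_level", 0.68)
    if not 0 < level < 1:
        errors.append("ci_level must be in (0, 1)")

    scheme_file = config.get("scheme_file")
    if scheme_file is not None and not Path(scheme_file).exists():
        errors.append(f"scheme file not found: {scheme_file}")
    rates = config.get("rate_constants")
    if rates is not None:
        try:
            RateConstantSet(**rates)
        except (TypeError, ValueError) as exc:
            errors.append(f"bad rate_constants: {exc}")

    if data_dir is not None:
        data_dir = Path(data_dir)
        for conc in concs:
            matches = list(data_dir.glob(f"*dwells*{conc:g}nM*.csv"))
            if not matches:
                warnings_.append(f"no dwell file for concentration {conc:g} nM in {data_dir}")
    return {"errors": errors, "warnings": warnings_}


def _simulate_stage(config: dict, run_dir: Path) -> dict[float, dict[str, EmpiricalCDF]]:
    """simulate -> idealize -> dwells -> cdf, per concentration."""
    rates = RateConstantSet(**config["rate_constants"])
    scheme = build_four_state_scheme()
    th = config["thresholds"]
    cdfs: dict[float, dict[str, EmpiricalCDF]] = {}
    for ci_, conc in enumerate(config["concentrations"]):
        pooled: list[DwellSet] = []
        for ti in range(config["n_traces"]):
            seed = int(np.random.SeedSequence((config["seed"], ci_, ti)).generate_state(1)[0])
            sim = SimulationConfig(
                rate_constants=rates,
                dna_concentration=conc,
                t_max=config["t_max"],
                frame_dt=config["frame_dt"],
                fret_levels=config["fret_levels"],
                noise_sd=config["noise_sd"],
                total_intensity=config["total_intensity"],
                seed=seed,
            )
            path = gillespie_simulate(sim, scheme)
            trace = emit_trace(path, sim, scheme.observable_class)
            e, _ = fret_efficiency(trace)
            ideal = threshold_idealize(e, th["low"], th["high"], frame_dt=config["frame_dt"])
            pooled.append(extract_dwells(ideal, concentration=conc))
        dwells = DwellSet.concatenate(pooled)
        write_csv(
            dwells.to_frame(),
            run_dir / f"dwells_{conc:g}nM.csv",
            meta={"dna_nM": conc, "frame_dt_s": config["frame_dt"], "seed": config["seed"]},
        )
        per_class: dict[str, EmpiricalCDF] = {}
        for cls, side_cls in ((LOW, UNBOUND), (HIGH, BOUND)):
            durations = dwells.complete(cls)
            if durations.size == 0:
                logger.warning("no complete %s dwells at %g nM", cls, conc)
                continue
            cdf = build_cdf(durations, frame_dt=config["frame_dt"], concentration=conc)
            write_csv(
                cdf.to_frame(),
                run_dir / f"cdf_{side_cls}_{conc:g}nM.csv",
                meta={
                    "dna_nM": conc,
                    "frame_dt_s": config["frame_dt"],
                    "n_dwells": cdf.n_dwells,
                    "seed": config["seed"],
                },
            )
            per_class[side_cls] = cdf
        cdfs[conc] = per_class
        logger.info("concentration %g nM: %d complete dwells", conc, len(dwells))
    return cdfs


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Full pipeline: simulate -> idealize -> dwells -> cdf -> fits -> derive.

    Deterministic given the config seeds; every stage writes its artifacts
    into ``out_dir`` and the machine-readable ``summary.json`` aggregates
    rate constants, CIs and derived quantities.
    """
    config = {**DEFAULT_CONFIG, **config}
    if seed is not None:
        config["seed"] = seed
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("invalid pipeline config: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning("%s", w)
    if "rate_constants" not in config:
        raise ValueError("pipeline config needs 'rate_constants' to simulate")

    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cdfs = _simulate_stage(config, run_dir)

        stage = "fit"
        summary: dict = {"config": {k: v for k, v in config.items()}, "fits": {}}
        binding_cdfs = [cc[UNBOUND] for cc in cdfs.values() if UNBOUND in cc]
        unbinding_cdfs = [cc[BOUND] for cc in cdfs.values() if BOUND in cc]
        fits = {}
        for side, side_cdfs in ((BINDING, binding_cdfs), (UNBINDING, unbinding_cdfs)):
            if not side_cdfs:
                continue
            fit = fit_global(side_cdfs, side=side)
            stage = "bootstrap"
            if config["n_bootstrap"] > 0:
                fit = bootstrap_ci(
                    fit, side_cdfs, n_iter=config["n_bootstrap"],
                    seed=config["seed"] + 1, level=config["ci_level"],
                )
                pd.DataFrame(fit.bootstrap_samples, columns=list(fit.param_names)).to_csv(
                    run_dir / f"bootstrap_{side}.csv", index=False
                )
            fits[side] = fit
            summary["fits"][side] = fit.to_dict()
            # model-independent companion fits on the same CDFs
            stage = "fit-exp"
            exp_rows = []
            for cdf in side_cdfs:
                one = fit_exp_cdf(cdf, 1)
                two = fit_exp_cdf(cdf, 2)
                row = {"dna_nM": cdf.concentration, "k_single": float(one.rates[0]),
                       "chi2_single": one.chi2, "chi2_double": two.chi2}
                if two.n_phases == 2:
                    f_stat, p = ftest_compare(one, two)
                    row.update(
                        k_fast=float(two.rates[0]), k_slow=float(two.rates[1]),
                        amp_fast=float(two.amplitudes[0]), f_two_phase=f_stat, p_two_phase=p,
                    )
                exp_rows.append(row)
            write_csv(pd.DataFrame(exp_rows), run_dir / f"expfit_{side}.csv",
                      meta={"side": side, "seed": config["seed"]})

        stage = "derive"
        if BINDING in fits and UNBINDING in fits:
            merged = {**fits[BINDING].params, **fits[UNBINDING].params}
            summary["derived"] = equilibrium_summary(RateConstantSet(**merged)).as_dict()

        summary["seed"] = config["seed"]
        summary["config_hash"] = config_hash(config)
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        logger.info("pipeline complete: %s", run_dir / "summary.json")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
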