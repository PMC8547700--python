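"""TOML run configuration: schema validation, execution, provenance.

A run config has five flat sections — ``[model]``, ``[grid]``,
``[solver]``, ``[protocol]``, ``[output]`` — documented in
``docs/config_schema.md``.  Every output of a run is a deterministic
function of the resolved configuration; the resolved config, package
version and a timestamp are written next to the results as
``provenance.json``.
"""

from __future__ import annotations

import datetime as _dt
import json
import tomllib
from pathlib import Path
from typing import Any, Optional, Union

from .params import PARAM_NAMES, ModelParameters

__all__ = ["RunConfig", "run_from_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration failed schema validation; message names the field."""


_SECTIONS = {"model", "grid", "solver", "protocol", "output"}

_GRID_KEYS = {"kind", "length", "lx", "ly", "dx"}
_SOLVER_KEYS = {"scheme", "dt", "mass_blend"}
_PROTOCOL_KEYS = {
    "kind", "t_end", "cl", "n_beats", "amplitude", "amplitude_factor",
    "s1_cl", "n_s1", "offset_step", "s2_time", "s2_fraction", "s2_height",
    "t_after_s2", "snapshot_cadence", "pulse_duration", "seed",
}
_PROTOCOL_KINDS = {"cell", "cable", "s1s2", "dynamic", "spiral", "convergence"}
_OUTPUT_KEYS = {"dir"}


class RunConfig:
    """Validated run configuration (see docs/config_schema.md)."""

    def __init__(self, data: dict[str, Any], base_dir: Optional[Path] = None):
        unknown = set(data) - _SECTIONS
        if unknown:
            raise ConfigError(f"unknown section(s): {sorted(unknown)}")
        self.base_dir = Path(base_dir) if base_dir else Path.cwd()

        model = dict(data.get("model", {}))
        params_file = model.pop("params_file", None)
        bad = set(model) - set(PARAM_NAMES)
        if bad:
            raise ConfigError(f"[model] unknown parameter(s): {sorted(bad)}")
        if params_file is not None:
            base = ModelParameters.from_file(self.base_dir / params_file)
            self.params = base.replace(**model)
        else:
            self.params = ModelParameters(**model)

        grid = dict(data.get("grid", {}))
        bad = set(grid) - _GRID_KEYS
        if bad:
            raise ConfigError(f"[grid] unknown key(s): {sorted(bad)}")
        self.grid_kind = grid.get("kind", "cable")
        if self.grid_kind not in ("cable", "sheet"):
            raise ConfigError("[grid] kind must be 'cable' or 'sheet'")
        self.grid_opts = grid

        solver = dict(data.get("solver", {}))
        bad = set(solver) - _SOLVER_KEYS
        if bad:
            raise ConfigError(f"[solver] unknown key(s): {sorted(bad)}")
        self.scheme = solver.get("scheme", "split")
        if self.scheme not in ("split", "explicit"):
            raise ConfigError("[solver] scheme must be 'split' or 'explicit'")
        self.dt = float(solver.get("dt", 1e-4))
        self.mass_blend = solver.get("mass_blend", None)

        protocol = dict(data.get("protocol", {}))
        bad = set(protocol) - _PROTOCOL_KEYS
        if bad:
            raise ConfigError(f"[protocol] unknown key(s): {sorted(bad)}")
        self.protocol = protocol.get("kind")
        if self.protocol not in _PROTOCOL_KINDS:
            raise ConfigError(
                f"[protocol] kind must be one of {sorted(_PROTOCOL_KINDS)}"
            )
        self.protocol_opts = protocol

        output = dict(data.get("output", {}))
        bad = set(output) - _OUTPUT_KEYS
        if bad:
            raise ConfigError(f"[output] unknown key(s): {sorted(bad)}")
        self.out_dir = Path(output.get("dir", "epicard_out"))

        self._raw = data

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(data, base_dir=path.parent)

    def resolved(self) -> dict[str, Any]:
        return {
            "model": self.params.as_dict(),
            "grid": {"kind": self.grid_kind, **self.grid_opts},
            "solver": {"scheme": self.scheme, "dt": self.dt,
                       "mass_blend": self.mass_blend},
            "protocol": self.protocol_opts,
            "output": {"dir": str(self.out_dir)},
        }


def _write_provenance(cfg: RunConfig, out: Path) -> None:
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("epicard")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    record = {
        "package": "epicard",
        "version": ver,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": cfg.resolved(),
    }
    (out / "provenance.json").write_text(json.dumps(record, indent=2) + "\n")


def run_from_config(path: Union[str, Path]) -> Path:
    """Execute the protocol named in a config file; return the output dir."""
    import numpy as np

    cfg = RunConfig.from_file(path)
    p = cfg.params
    out = cfg.out_dir if cfg.out_dir.is_absolute() else cfg.base_dir / cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    opts = cfg.protocol_opts
    solver_kw = {"dt": cfg.dt, "scheme": cfg.scheme}
    dx = float(cfg.grid_opts.get("dx", 0.025))

    if cfg.protocol == "cell":
        from .cell import StimulusEvent, extract_ap_features, integrate_cell
        from .protocols import diastolic_threshold_cell

        amp = opts.get("amplitude")
        if amp is None:
            amp = (opts.get("amplitude_factor", 2.0)
                   * diastolic_threshold_cell(p))
        trace = integrate_cell(
            p, [StimulusEvent(0.05, opts.get("pulse_duration", 2e-3), amp)],
            t_end=opts.get("t_end", 0.6),
        )
        trace.to_csv(out / "trace.csv")
        extract_ap_features(trace).to_csv(out / "features.csv")

    elif cfg.protocol == "cable":
        from .cell import extract_ap_features
        from .protocols import diastolic_threshold
        from .tissue import end_stimulus, measure_cv, simulate_cable

        length = float(cfg.grid_opts.get("length", 2.0))
        amp = opts.get("amplitude")
        if amp is None:
            amp = (opts.get("amplitude_factor", 2.0)
                   * diastolic_threshold(p, length, dx, **solver_kw))
        rec = simulate_cable(
            p, [end_stimulus(0.0, amp)], length=length,
            t_end=opts.get("t_end", 0.5), dx=dx, **solver_kw,
        )
        rec.to_csv(out / "probes.csv")
        extract_ap_features(rec.probe_trace("mid")).to_csv(out / "features.csv")
        (out / "cv.txt").write_text(f"cv_cm_per_s = {measure_cv(rec)}\n")

    elif cfg.protocol in ("s1s2", "dynamic"):
        from .protocols import (dynamic_restitution, restitution_slope,
                                s1s2_restitution)

        length = float(cfg.grid_opts.get("length", 2.0))
        if cfg.protocol == "s1s2":
            curve = s1s2_restitution(
                p, s1_cl=opts.get("s1_cl", 1.0), n_s1=opts.get("n_s1", 10),
                length=length, dx=dx, **solver_kw,
            )
            curve.to_csv(out / "restitution_s1s2.csv")
            slope, at_di = restitution_slope(curve)
            (out / "endpoints.txt").write_text(
                f"max_slope = {slope}\nslope_di_ms = {at_di}\n")
        else:
            curve, endpoints = dynamic_restitution(
                p, length=length, dx=dx, **solver_kw)
            curve.to_csv(out / "restitution_dynamic.csv")
            endpoints.to_file(out / "endpoints.txt")

    elif cfg.protocol == "spiral":
        from .spiral import initiate_spiral, period_statistics

        run = initiate_spiral(
            p, lx=float(cfg.grid_opts.get("lx", 10.0)),
            ly=float(cfg.grid_opts.get("ly", 10.0)), dx=dx,
            s2_time=opts.get("s2_time"),
            s2_fraction=opts.get("s2_fraction", 0.8),
            s2_height=opts.get("s2_height"),
            t_after_s2=opts.get("t_after_s2", 4.0),
            snapshot_cadence=opts.get("snapshot_cadence"),
            **solver_kw,
        )
        metrics = period_statistics(run)
        np.savetxt(out / "period_map_ms.csv", metrics.mean_period_map,
                   delimiter=",")
        np.savetxt(out / "egm.csv",
                   np.column_stack([run.egm_t, run.egm_v]), delimiter=",",
                   header="t_s,egm_mV_per_mm", comments="")
        hist = np.column_stack([metrics.period_bins, metrics.period_counts])
        np.savetxt(out / "period_histogram.csv", hist, delimiter=",",
                   header="period_ms,count", comments="")
        (out / "metrics.txt").write_text(
            f"s2_time_s = {run.s2_time}\n"
            f"dominant_period_ms = {metrics.dominant_period}\n")

    elif cfg.protocol == "convergence":
        from .tissue import convergence_gate, convergence_study

        table = convergence_study(p, scheme=cfg.scheme)
        table.to_csv(out / "convergence.csv", index=False)
        gate = convergence_gate(p, scheme=cfg.scheme)
        (out / "gate.txt").write_text(
            "\n".join(f"{k} = {v}" for k, v in gate.items()) + "\n")

    _write_provenance(cfg, out)
    return out
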