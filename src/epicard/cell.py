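"""Single-cell (0D) integration and action-potential feature extraction."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .ionic import reaction_rates
from .params import ModelParameters

__all__ = [
    "StimulusEvent",
    "UpstrokeContext",
    "Trace",
    "APFeatures",
    "NoActionPotentialError",
    "integrate_cell",
    "extract_ap_features",
    "APD_THRESHOLD_MV",
]

#: Repolarization threshold used for APD90, activation and DI measurements (mV).
APD_THRESHOLD_MV = -72.5

#: Default single-cell time step (s): forward Euler at 0.01 ms.
DEFAULT_CELL_DT = 1e-5


@dataclass(frozen=True)
class StimulusEvent:
    """A timed rectangular external-current pulse.

    ``amplitude`` is in mV/s, depolarizing positive.  ``region`` is a
    spatial predicate used by the tissue solvers; in 0D the whole cell is
    stimulated and the field is ignored.  ``region`` may be a slice/index
    tuple, a boolean mask, or a callable mapping node coordinates (cm) to
    a boolean mask.
    """

    t_start: float
    duration: float
    amplitude: float
    region: object = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


def check_non_overlapping(stimuli: Sequence[StimulusEvent]) -> None:
    """Raise if two events of one protocol overlap in time."""
    events = sorted(stimuli, key=lambda s: s.t_start)
    for prev, nxt in zip(events, events[1:]):
        if nxt.t_start < prev.t_end:
            raise ValueError(
                f"overlapping stimuli at t={prev.t_start}s and t={nxt.t_start}s"
            )


@dataclass
class UpstrokeContext:
    """Previous-step finite-difference context gating the upstroke rates.

    The upstroke is the interval where both dV/dt >= 0 and dw/dt >= 0;
    discretely the flag is computed from the previous step's backward
    differences and is False at t = 0.
    """

    dV_prev: float = 0.0
    dw_prev: float = 0.0
    is_upstroke: bool = False

    def update(self, dV: float, dw: float) -> None:
        self.dV_prev = dV
        self.dw_prev = dw
        self.is_upstroke = (dV >= 0.0) and (dw >= 0.0)


@dataclass
class Trace:
    """Uniformly sampled (t, V, u, w) trajectory of a single site."""

    t: np.ndarray
    V: np.ndarray
    u: np.ndarray
    w: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.V) == len(self.u) == len(self.w) == n):
            raise ValueError("trace arrays must have equal length")

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.t, "V": self.V, "u": self.u, "w": self.w}).to_csv(
            path, index=False
        )

    def to_npz(self, path: Union[str, Path]) -> None:
        np.savez_compressed(path, t=self.t, V=self.V, u=self.u, w=self.w, dt=self.dt)

    @classmethod
    def from_npz(cls, path: Union[str, Path]) -> "Trace":
        d = np.load(path)
        return cls(t=d["t"], V=d["V"], u=d["u"], w=d["w"], dt=float(d["dt"]))


@dataclass
class APFeatures:
    """Morphology features of a single action potential.

    ``apd90`` in ms; voltages in mV; ``upstroke_vmax`` in V/s.  The notch
    fields are None when the AP repolarizes monotonically (no phase-1
    notch detected).
    """

    apd90: float
    amplitude: float
    upstroke_vmax: float
    peak_V: float
    resting_V: float
    notch_min: Optional[float] = None
    plateau_max: Optional[float] = None

    @property
    def has_notch(self) -> bool:
        return self.notch_min is not None

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        pd.DataFrame([self.__dict__]).to_csv(path, index=False)


class NoActionPotentialError(RuntimeError):
    """The trace contains no threshold crossing (no AP)."""


def integrate_cell(
    p: ModelParameters,
    stimuli: Sequence[StimulusEvent] = (),
    t_end: float = 1.0,
    dt: float = DEFAULT_CELL_DT,
    initial_state: Optional[tuple[float, float, float]] = None,
) -> Trace:
    """Forward-Euler trajectory of an isolated cell.

    Parameters are in the package-wide unit convention: time in seconds,
    V in mV, external current in mV/s.  The run is fully deterministic.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite (with step and state diagnostics).
    """
    check_non_overlapping(stimuli)
    n_steps = int(round(t_end / dt))
    V = np.empty(n_steps + 1)
    u = np.empty(n_steps + 1)
    w = np.empty(n_steps + 1)
    V[0], u[0], w[0] = initial_state if initial_state is not None else p.resting_state

    ctx = UpstrokeContext()
    events = sorted(stimuli, key=lambda s: s.t_start)
    for n in range(n_steps):
        t = n * dt
        i_ext = 0.0
        for ev in events:
            if ev.active(t):
                i_ext += ev.amplitude
        dV, du, dw = reaction_rates(V[n], u[n], w[n], ctx.is_upstroke, p)
        V[n + 1] = V[n] + dt * (dV + i_ext)
        u[n + 1] = u[n] + dt * du
        w[n + 1] = w[n] + dt * dw
        if not (
            math.isfinite(V[n + 1]) and math.isfinite(u[n + 1]) and math.isfinite(w[n + 1])
        ):
            raise FloatingPointError(
                f"non-finite state at step {n + 1} (t={t + dt:.6f}s): "
                f"V={V[n + 1]}, u={u[n + 1]}, w={w[n + 1]}"
            )
        if u[n + 1] > p.u_M:
            raise RuntimeError(
                f"recovery variable exceeded u_M at step {n + 1}: u={u[n + 1]}"
            )
        ctx.update(V[n + 1] - V[n], w[n + 1] - w[n])

    t_grid = np.arange(n_steps + 1) * dt
    return Trace(t=t_grid, V=V, u=u, w=w, dt=dt)


# ---------------------------------------------------------------------------
# Feature extraction


def _interp_crossing(t: np.ndarray, V: np.ndarray, i: int, threshold: float) -> float:
    """Linearly interpolated crossing time between samples i and i+1."""
    v0, v1 = V[i], V[i + 1]
    if v1 == v0:
        return t[i]
    frac = (threshold - v0) / (v1 - v0)
    return t[i] + frac * (t[i + 1] - t[i])


def threshold_crossings(
    t: np.ndarray, V: np.ndarray, threshold: float = APD_THRESHOLD_MV
) -> tuple[np.ndarray, np.ndarray]:
    """All interpolated upward and downward crossings of ``threshold``.

    Returns (up_times, down_times) in the units of ``t``.
    """
    V = np.asarray(V, float)
    above = V >= threshold
    up_idx = np.nonzero(~above[:-1] & above[1:])[0]
    down_idx = np.nonzero(above[:-1] & ~above[1:])[0]
    ups = np.array([_interp_crossing(t, V, i, threshold) for i in up_idx])
    downs = np.array([_interp_crossing(t, V, i, threshold) for i in down_idx])
    return ups, downs


def extract_ap_features(
    trace: Trace,
    apd_threshold: float = APD_THRESHOLD_MV,
    which: int = -1,
) -> APFeatures:
    """Extract morphology features of one AP from a voltage trace.

    ``which`` selects the AP when the trace contains several (default:
    the last complete one).  APD90 is the time between the interpolated
    upward and downward crossings of ``apd_threshold``; the maximum
    upstroke velocity is the maximum finite-difference dV/dt during the
    upstroke; the notch is the first strict local minimum between the
    upstroke peak and the later plateau maximum, searched within the
    first 100 ms of the AP (phase 1 is early).
    """
    t, V = trace.t, np.asarray(trace.V, float)
    ups, downs = threshold_crossings(t, V, apd_threshold)
    if len(ups) == 0:
        raise NoActionPotentialError("no upward threshold crossing in trace")
    # pair each up-crossing with the first later down-crossing
    pairs = []
    for tu in ups:
        later = downs[downs > tu]
        if len(later):
            pairs.append((tu, later[0]))
    if not pairs:
        raise NoActionPotentialError("no complete AP (missing repolarization)")
    t_up, t_down = pairs[which]
    apd90 = (t_down - t_up) * 1e3

    in_ap = (t >= t_up) & (t <= t_down)
    seg_V = V[in_ap]
    seg_t = t[in_ap]
    peak_V = float(np.max(seg_V))

    # resting V: minimum between the previous repolarization (or trace
    # start) and this upstroke
    prior = downs[downs < t_up]
    t_rest0 = prior[-1] if len(prior) else t[0]
    rest_mask = (t >= t_rest0) & (t <= t_up)
    resting_V = float(np.min(V[rest_mask])) if rest_mask.any() else float(V[0])

    # maximum upstroke velocity around the up-crossing (finite differences)
    dv = np.diff(V) / np.diff(t)
    mid_t = 0.5 * (t[:-1] + t[1:])
    up_win = (mid_t >= t_up - 5e-3) & (mid_t <= t_up + 5e-3)
    upstroke_vmax = float(np.max(dv[up_win])) / 1e3 if up_win.any() else float("nan")

    notch_min = plateau_max = None
    early = seg_t <= seg_t[0] + 0.1
    eV = seg_V[early]
    if len(eV) >= 5:
        interior = np.arange(1, len(eV) - 1)
        is_max = (eV[interior] > eV[interior - 1]) & (eV[interior] >= eV[interior + 1])
        maxima = interior[is_max]
        if len(maxima):
            i_peak = maxima[0]
            after = np.arange(i_peak + 1, len(eV) - 1)
            is_min = (eV[after] < eV[after - 1]) & (eV[after] <= eV[after + 1])
            minima = after[is_min]
            if len(minima):
                i_notch = minima[0]
                # plateau: maximum after the notch, up to repolarization
                start = i_notch + 1
                tail = seg_V[start:]
                if len(tail):
                    cand = float(np.max(tail))
                    if cand > eV[i_notch]:
                        notch_min = float(eV[i_notch])
                        plateau_max = cand

    return APFeatures(
        apd90=apd90,
        amplitude=peak_V - resting_V,
        upstroke_vmax=upstroke_vmax,
        peak_V=peak_V,
        resting_V=resting_V,
        notch_min=notch_min,
        plateau_max=plateau_max,
    )
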