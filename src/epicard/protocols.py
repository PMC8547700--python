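"""Pacing protocols on the 1D cable: threshold search and restitution.

All measurements are taken in the middle of the cable to minimize
stimulus and boundary artifacts; activation and repolarization times are
interpolated crossings of the -72.5 mV threshold (90% repolarization).
Durations in the returned curves are expressed in ms, conduction
velocities in cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cell import APD_THRESHOLD_MV, StimulusEvent, threshold_crossings
from .params import ModelParameters
from .tissue import (
    DEFAULT_DX,
    DEFAULT_TISSUE_DT,
    FieldRecording,
    Grid,
    ProbeRecorder,
    TissueSimulator,
    end_stimulus,
)

__all__ = [
    "RestitutionPoint",
    "RestitutionCurve",
    "DynamicEndpoints",
    "diastolic_threshold",
    "s1s2_restitution",
    "dynamic_restitution",
    "restitution_slope",
    "cv_dispersion",
]

#: Default stimulus pulse duration (s).
PULSE_DURATION = 2e-3

#: Cable used by every protocol unless overridden.
DEFAULT_CABLE_LENGTH = 2.0


@dataclass(frozen=True)
class RestitutionPoint:
    """One (CL, DI, APD, CV) measurement; times in ms, CV in cm/s."""

    cl: float
    di: float
    apd: float
    cv: float
    protocol: str  # "s1s2" | "dynamic"

    def __post_init__(self) -> None:
        if min(self.cl, self.di, self.apd, self.cv) <= 0:
            raise ValueError(f"restitution point has non-positive entry: {self}")


@dataclass
class RestitutionCurve:
    """Restitution points sorted by DI (no duplicate DIs)."""

    points: list[RestitutionPoint]
    s1_cl: Optional[float] = None  # ms, for s1s2 curves

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda q: q.di)
        dis = [q.di for q in self.points]
        if len(set(dis)) != len(dis):
            raise ValueError("duplicate DI values in restitution curve")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def di(self) -> np.ndarray:
        return np.array([q.di for q in self.points])

    @property
    def apd(self) -> np.ndarray:
        return np.array([q.apd for q in self.points])

    @property
    def cv(self) -> np.ndarray:
        return np.array([q.cv for q in self.points])

    @property
    def cl(self) -> np.ndarray:
        return np.array([q.cl for q in self.points])

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "protocol": [q.protocol for q in self.points],
                "CL": self.cl, "DI": self.di, "APD": self.apd, "CV": self.cv,
            }
        ).to_csv(path, index=False)


@dataclass
class DynamicEndpoints:
    """Endpoints of the dynamic (steady-state) restitution protocol.

    ``min_cl`` is the shortest cycle length (ms) still propagating 1:1;
    ``block_cl`` the first tested cycle length with 2:1 conduction block.
    """

    min_cl: float
    block_cl: float
    min_di: float
    min_apd: float
    cv_max: float
    cv_min: float

    def to_file(self, path: Union[str, Path]) -> None:
        lines = [f"{k} = {v}" for k, v in self.__dict__.items()]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Diastolic threshold


def _captures(p: ModelParameters, amplitude: float, length: float, dx: float,
              dt: float, scheme: str, pulse_duration: float) -> bool:
    """Does a single end stimulus of this strength excite the cable middle?"""
    grid = Grid.cable(length=length, dx=dx)
    sim = TissueSimulator(p, grid, dt=dt, scheme=scheme)
    rec = ProbeRecorder(grid, {"mid": length / 2.0})
    stim = StimulusEvent(0.0, pulse_duration, amplitude,
                         region=lambda x: x <= 0.1 + 1e-12)
    sim.run(0.08, stimuli=[stim], recorders=[rec])
    return bool(np.max(rec.V["mid"]) >= APD_THRESHOLD_MV)


def diastolic_threshold(
    p: ModelParameters,
    length: float = DEFAULT_CABLE_LENGTH,
    dx: float = DEFAULT_DX,
    dt: float = DEFAULT_TISSUE_DT,
    scheme: str = "split",
    pulse_duration: float = PULSE_DURATION,
    rel_tol: float = 0.01,
) -> float:
    """Minimal 2 ms stimulus amplitude (mV/s) that excites the cable middle.

    Deterministic bisection to ``rel_tol`` relative tolerance after an
    exponential bracket scan.  Raises if no capturing amplitude is found
    within the scan range.
    """
    lo, hi = 0.0, 5.0e4
    for _ in range(12):
        if _captures(p, hi, length, dx, dt, scheme, pulse_duration):
            break
        lo = hi
        hi *= 2.0
    else:
        raise RuntimeError("no capturing amplitude found in bracket scan")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _captures(p, mid, length, dx, dt, scheme, pulse_duration):
            hi = mid
        else:
            lo = mid
    return hi


def diastolic_threshold_cell(
    p: ModelParameters,
    pulse_duration: float = PULSE_DURATION,
    dt: float = 1e-5,
    rel_tol: float = 0.01,
) -> float:
    """Minimal 2 ms stimulus amplitude (mV/s) exciting an isolated cell.

    Capture requires a regenerative response (overshoot above 0 mV), not
    merely a passive excursion past the APD threshold; in tissue the
    analogous criterion is propagation to the cable middle.
    """
    from .cell import integrate_cell

    def captures(amp: float) -> bool:
        tr = integrate_cell(p, [StimulusEvent(0.0, pulse_duration, amp)],
                            t_end=0.05, dt=dt)
        return bool(np.max(tr.V) >= 0.0)

    lo, hi = 0.0, 5.0e4
    for _ in range(12):
        if captures(hi):
            break
        lo = hi
        hi *= 2.0
    else:
        raise RuntimeError("no capturing amplitude found in bracket scan")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Shared measurement helpers


def _beat_measurements(t: np.ndarray, v_mid: np.ndarray, v_a: np.ndarray,
                       v_b: np.ndarray, probe_sep: float, after: float):
    """(up, down) crossings at mid plus CV of the first front after ``after``."""
    ups, downs = threshold_crossings(t, v_mid, APD_THRESHOLD_MV)
    sel = t >= after
    ta_ups, _ = threshold_crossings(t[sel], v_a[sel], APD_THRESHOLD_MV)
    tb_ups, _ = threshold_crossings(t[sel], v_b[sel], APD_THRESHOLD_MV)
    cv = None
    if len(ta_ups) and len(tb_ups):
        dt_act = abs(tb_ups[0] - ta_ups[0])
        if dt_act > 0:
            cv = probe_sep / dt_act
    return ups, downs, cv


def _cable_sim(p: ModelParameters, length: float, dx: float, dt: float,
               scheme: str) -> tuple[TissueSimulator, ProbeRecorder]:
    grid = Grid.cable(length=length, dx=dx)
    sim = TissueSimulator(p, grid, dt=dt, scheme=scheme)
    rec = ProbeRecorder(grid, {
        "mid": length / 2.0,
        "cv_a": length / 2.0 - 0.25,
        "cv_b": length / 2.0 + 0.25,
    })
    return sim, rec


# ---------------------------------------------------------------------------
# S1-S2 restitution


def s1s2_restitution(
    p: ModelParameters,
    s1_cl: float = 1.0,
    n_s1: int = 10,
    s2_offsets: Optional[Sequence[float]] = None,
    amplitude: Optional[float] = None,
    length: float = DEFAULT_CABLE_LENGTH,
    dx: float = DEFAULT_DX,
    dt: float = DEFAULT_TISSUE_DT,
    scheme: str = "split",
    offset_step: float = 5e-3,
    offset_margin: float = 0.3,
) -> RestitutionCurve:
    """S1-S2 restitution on the cable.

    ``n_s1`` conditioning beats at cycle length ``s1_cl`` (s) establish a
    steady state; a premature S2 is then delivered at decreasing coupling
    intervals (measured from the last S1 stimulus) in ``offset_step``
    decrements until it fails to capture.  Each captured S2 contributes a
    (DI, APD, CV) point measured at mid-cable.  Stimuli are 2 ms pulses
    at twice the diastolic threshold unless ``amplitude`` is given.
    """
    if amplitude is None:
        amplitude = 2.0 * diastolic_threshold(p, length, dx, dt, scheme)
    sim, rec = _cable_sim(p, length, dx, dt, scheme)
    s1_events = [end_stimulus(i * s1_cl, amplitude) for i in range(n_s1)]
    t_last_s1 = (n_s1 - 1) * s1_cl
    # run conditioning up to (but not including) the last S1, save state
    sim.run(t_last_s1, stimuli=s1_events, recorders=[rec])
    base_state = sim.get_state()
    base_len = len(rec.t)

    # steady-state APD from beat n_s1-1 sets the starting offset
    t_arr = np.asarray(rec.t)
    ups, downs = threshold_crossings(t_arr, np.asarray(rec.V["mid"]))
    if len(ups) < n_s1 - 1 or len(downs) < n_s1 - 1:
        raise RuntimeError("conditioning beats did not all capture")
    steady_apd = downs[-1] - ups[-1]

    if s2_offsets is None:
        start = steady_apd + offset_margin
        n_off = int(np.floor(start / offset_step))
        s2_offsets = [round(start - i * offset_step, 10) for i in range(n_off)]

    points: list[RestitutionPoint] = []
    seen_di: set[float] = set()
    for offset in s2_offsets:
        sim.set_state(base_state)
        for lst in (rec.t, *rec.V.values()):
            del lst[base_len:]
        t_s2 = t_last_s1 + offset
        stims = [end_stimulus(t_last_s1, amplitude),
                 end_stimulus(t_s2, amplitude)]
        sim.run(t_s2 + 0.6, stimuli=stims, recorders=[rec])
        t_arr = np.asarray(rec.t)
        v_mid = np.asarray(rec.V["mid"])
        ups, downs, cv = _beat_measurements(
            t_arr, v_mid, np.asarray(rec.V["cv_a"]), np.asarray(rec.V["cv_b"]),
            probe_sep=0.5, after=t_s2,
        )
        # crossings after the final S1 activation: need S1 beat + S2 beat
        ups_seg = ups[ups > t_last_s1]
        downs_seg = downs[downs > t_last_s1]
        if len(ups_seg) < 2 or len(downs_seg) < 2 or cv is None:
            break  # S2 below refractoriness: end of the curve
        di = (ups_seg[1] - downs_seg[0]) * 1e3
        apd = (downs_seg[1] - ups_seg[1]) * 1e3
        di_r = round(di, 6)
        if di_r in seen_di:
            continue
        seen_di.add(di_r)
        points.append(RestitutionPoint(cl=offset * 1e3, di=di, apd=apd, cv=cv,
                                       protocol="s1s2"))
    return RestitutionCurve(points=points, s1_cl=s1_cl * 1e3)


# ---------------------------------------------------------------------------
# Dynamic (steady-state) restitution


def default_cl_schedule() -> list[float]:
    """CL sweep (s): 1.2->0.4 in 100 ms steps, ->0.3 in 20 ms, then 5 ms steps.

    The terminal 5 ms resolution brackets the conduction-block endpoint;
    the schedule below 0.3 s is extended automatically until block.
    """
    cls = [round(1.2 - 0.1 * i, 10) for i in range(9)]           # 1.2 .. 0.4
    cls += [round(0.38 - 0.02 * i, 10) for i in range(5)]        # 0.38 .. 0.3
    cls += [round(0.295 - 0.005 * i, 10) for i in range(48)]     # 0.295 .. 0.06
    return cls


def dynamic_restitution(
    p: ModelParameters,
    cl_schedule: Optional[Sequence[float]] = None,
    beats_per_cl: int = 6,
    amplitude: Optional[float] = None,
    length: float = DEFAULT_CABLE_LENGTH,
    dx: float = DEFAULT_DX,
    dt: float = DEFAULT_TISSUE_DT,
    scheme: str = "split",
) -> tuple[RestitutionCurve, DynamicEndpoints]:
    """Dynamic restitution: steady pacing with monotonically decreasing CL.

    Six beats per cycle length suffice to reach steady state; the curve
    point is measured on the last beat of each cycle length.  Pacing
    continues down the schedule until 2:1 conduction block (mid-cable
    activation count below the stimulus count); the endpoints collect the
    minimum 1:1 cycle length and the extreme DI/APD/CV values.
    """
    if cl_schedule is None:
        cl_schedule = default_cl_schedule()
    if amplitude is None:
        amplitude = 2.0 * diastolic_threshold(p, length, dx, dt, scheme)

    sim, rec = _cable_sim(p, length, dx, dt, scheme)
    segments = []  # (cl, stim_times)
    t0 = 0.0
    blocked_cl = None
    for cl in cl_schedule:
        stim_times = [t0 + i * cl for i in range(beats_per_cl)]
        seg_end = t0 + beats_per_cl * cl
        sim.run(seg_end,
                stimuli=[end_stimulus(ts, amplitude) for ts in stim_times],
                recorders=[rec])
        segments.append((cl, stim_times))
        # quick 1:1 check on this segment
        t_arr = np.asarray(rec.t)
        v_mid = np.asarray(rec.V["mid"])
        ups, _ = threshold_crossings(t_arr, v_mid)
        n_act = int(np.sum((ups >= t0) & (ups < seg_end)))
        t0 = seg_end
        if n_act < beats_per_cl:
            blocked_cl = cl
            break
    if blocked_cl is None:
        raise RuntimeError("CL schedule exhausted without conduction block")
    # tail so the final measured beat can repolarize
    sim.run(t0 + 0.6, recorders=[rec])

    t_arr = np.asarray(rec.t)
    v_mid = np.asarray(rec.V["mid"])
    v_a = np.asarray(rec.V["cv_a"])
    v_b = np.asarray(rec.V["cv_b"])
    ups, downs = threshold_crossings(t_arr, v_mid)

    points: list[RestitutionPoint] = []
    seen_di: set[float] = set()
    for cl, stim_times in segments:
        if cl == blocked_cl:
            break
        last = stim_times[-1]
        seg_ups = ups[ups > last]
        seg_downs_prev = downs[downs < seg_ups[0]] if len(seg_ups) else np.empty(0)
        if not len(seg_ups) or not len(seg_downs_prev):
            continue
        t_up = seg_ups[0]
        t_down = downs[downs > t_up][0]
        di = (t_up - seg_downs_prev[-1]) * 1e3
        apd = (t_down - t_up) * 1e3
        _, _, cv = _beat_measurements(t_arr, v_mid, v_a, v_b, 0.5, after=last)
        if cv is None:
            continue
        di_r = round(di, 6)
        if di_r in seen_di:
            continue
        seen_di.add(di_r)
        points.append(RestitutionPoint(cl=cl * 1e3, di=di, apd=apd, cv=cv,
                                       protocol="dynamic"))
    curve = RestitutionCurve(points=points)
    one_to_one = [q for q in curve.points]
    min_cl_pt = min(one_to_one, key=lambda q: q.cl)
    endpoints = DynamicEndpoints(
        min_cl=min_cl_pt.cl,
        block_cl=blocked_cl * 1e3,
        min_di=float(np.min(curve.di)),
        min_apd=float(np.min(curve.apd)),
        cv_max=float(np.max(curve.cv)),
        cv_min=float(np.min(curve.cv)),
    )
    return curve, endpoints


# ---------------------------------------------------------------------------
# Curve statistics


def restitution_slope(curve: RestitutionCurve) -> tuple[float, float]:
    """Maximum centered finite-difference slope d(APD)/d(DI) and its DI.

    The curve is evaluated as sorted by DI; no smoothing is applied.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 points for a centered slope")
    di, apd = curve.di, curve.apd
    slopes = (apd[2:] - apd[:-2]) / (di[2:] - di[:-2])
    i = int(np.argmax(slopes))
    return float(slopes[i]), float(di[i + 1])


def cv_dispersion(curve: RestitutionCurve) -> tuple[float, float, float]:
    """(max CV, min CV, dispersion %) with dispersion = (max-min)/max*100."""
    if len(curve) < 2:
        raise ValueError("need at least 2 points for CV dispersion")
    cv = curve.cv
    cv_max, cv_min = float(np.max(cv)), float(np.min(cv))
    return cv_max, cv_min, (cv_max - cv_min) / cv_max * 100.0
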