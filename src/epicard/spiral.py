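"""Spiral-wave (reentry) simulation and analysis on a 2D sheet.

A cross-field S1-S2 protocol starts the reentry: a planar S1 wave from
the left edge, then a premature S2 over the lower-half rectangle of the
sheet, delivered while tissue beyond mid-sheet is still refractory.
The part of the rectangle behind the S1 recovery boundary is excited,
the rest blocks, and the broken front pivots around the boundary into a
sustained rotating wave.  The
module also provides the zero-normal-velocity tip tracker (intersection
of the V = -60 mV isopotential with the dV/dt = 0 contour), per-node
period statistics, and a pseudo-electrogram from the dipole source
density -grad(V) under an infinite homogeneous volume conductor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cell import APD_THRESHOLD_MV, StimulusEvent
from .params import ModelParameters
from .tissue import (
    DEFAULT_DX,
    DEFAULT_TISSUE_DT,
    ActivationRecorder,
    Grid,
    SnapshotRecorder,
    TissueSimulator,
)

__all__ = [
    "SpiralRun",
    "SpiralMetrics",
    "NoReentryError",
    "initiate_spiral",
    "track_tip",
    "period_statistics",
    "pseudo_egm",
    "egm_value",
    "dominant_period_ms",
]

#: Default out-of-plane electrode offset (cm): 0.1 mm above the sheet center.
EGM_Z_OFFSET = 0.01

#: Isopotential used by the zero-normal-velocity tip tracker (mV).
TIP_ISO_V = -60.0


class NoReentryError(RuntimeError):
    """The S2 produced no sustained rotating wave (fully blocked or fully
    captured); rescan the S2 delivery time."""


@dataclass
class SpiralRun:
    """Raw products of a reentry simulation.

    ``activations``/``repolarizations`` hold (flat node index, time)
    events inside the analysis window; ``egm_t``/``egm_v`` the
    pseudo-electrogram samples (1 ms cadence by default); snapshots are
    optional V frames for tip tracking.
    """

    grid: Grid
    dt: float
    s2_time: float
    window: tuple[float, float]
    act_nodes: np.ndarray
    act_times: np.ndarray
    rep_nodes: np.ndarray
    rep_times: np.ndarray
    egm_t: np.ndarray
    egm_v: np.ndarray
    snapshot_times: Optional[np.ndarray] = None
    snapshot_frames: Optional[list] = None
    threshold: float = APD_THRESHOLD_MV


@dataclass
class SpiralMetrics:
    """Derived reentry statistics."""

    dominant_period: float              # ms, modal 1 ms bin
    periods: np.ndarray                 # all per-node periods (ms)
    period_counts: np.ndarray           # histogram counts per 1 ms bin
    period_bins: np.ndarray             # bin centers (ms)
    mean_period_map: np.ndarray         # per-node mean period (ms), NaN if <2 act.
    apd_map: Optional[np.ndarray] = None  # per-node mean APD (ms)
    tip_trajectory: Optional[np.ndarray] = None  # (n, 3) columns t, x, y


# ---------------------------------------------------------------------------
# Pseudo-electrogram


def egm_value(V: np.ndarray, dx: float, electrode: tuple[float, float, float],
              beta: float = 1.0) -> float:
    """Unipolar pseudo-electrogram sample (mV/mm) from one V frame.

    Discrete sum over cells of -grad(V) . r / |r|^3 times the cell area,
    with r the vector from each source cell to the electrode and the
    gradient by centered differences.  ``beta`` is the adimensional
    lumped conductivity ratio; the trace is defined up to this scale.
    """
    gx, gy = np.gradient(V, dx)
    nx, ny = V.shape
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    rx = electrode[0] - x[:, None]
    ry = electrode[1] - y[None, :]
    rz = electrode[2]
    r3 = (rx * rx + ry * ry + rz * rz) ** 1.5
    integrand = -(gx * rx + gy * ry) / r3
    # mV/cm integrated over cm^2 / cm^2 -> mV/cm; report mV/mm
    return float(beta * np.sum(integrand) * dx * dx / 10.0)


class _EGMKernel:
    """Precomputed geometry for repeated EGM evaluation on one grid."""

    def __init__(self, grid: Grid, electrode: tuple[float, float, float],
                 beta: float = 1.0):
        nx, ny = grid.shape
        dx = grid.dx
        x = np.arange(nx) * dx
        y = np.arange(ny) * dx
        rx = electrode[0] - x[:, None]
        ry = electrode[1] - y[None, :]
        r3 = (rx * rx + ry * ry + electrode[2] ** 2) ** 1.5
        scale = beta * dx * dx / 10.0
        self.kx = rx / r3 * scale
        self.ky = ry / r3 * scale
        self.dx = dx

    def __call__(self, V: np.ndarray) -> float:
        gx, gy = np.gradient(V, self.dx)
        return float(-np.sum(gx * self.kx) - np.sum(gy * self.ky))


class _EGMRecorder:
    def __init__(self, grid: Grid, electrode, beta: float, cadence: float,
                 window: tuple[float, float]):
        self.kernel = _EGMKernel(grid, electrode, beta)
        self.cadence = cadence
        self.window = window
        self.t: list[float] = []
        self.v: list[float] = []
        self._next = window[0]

    def on_step(self, t: float, sim: TissueSimulator) -> None:
        if t + 0.5 * sim.dt >= self._next and t <= self.window[1] + 0.5 * sim.dt:
            self.t.append(t)
            self.v.append(self.kernel(sim.V))
            self._next += self.cadence


def pseudo_egm(frames: Sequence[np.ndarray], grid: Grid,
               electrode: Optional[tuple[float, float, float]] = None,
               beta: float = 1.0) -> np.ndarray:
    """EGM trace (mV/mm) from a sequence of V frames.

    Default electrode: sheet center, 0.1 mm out of plane.
    """
    if electrode is None:
        electrode = (grid.extent[0] / 2.0, grid.extent[1] / 2.0, EGM_Z_OFFSET)
    kernel = _EGMKernel(grid, electrode, beta)
    return np.array([kernel(np.asarray(f, float)) for f in frames])


# ---------------------------------------------------------------------------
# Spiral initiation


def _auto_s2_time(sim: TissueSimulator, s1: StimulusEvent, trial_region,
                  strip_idx, s2_margin: float, pulse_duration: float,
                  amplitude: float, coarse_step: float = 5e-3,
                  fine_step: float = 1e-3, scan_span: float = 0.15,
                  horizon: float = 0.03) -> float:
    """Find an S2 delivery time inside the vulnerable window.

    The S1 wave is advanced until the S2 strip has repolarized below the
    APD threshold minus ``s2_margin``; because the recovery variable
    outlasts the voltage, candidate delivery times from that instant
    onward are probed with short trial runs.  Trial stimuli over a thin
    (2 mm) vertical strip at mid-sheet probe the medium's state: two
    probes 4 mm either side of the strip classify each trial as blocked,
    unidirectional (proximal capture with distal block -- the substrate
    for a broken front) or bidirectional; the unidirectional window
    (typically a few ms wide) is located with a coarse scan plus 1 ms
    refinement and its midpoint is returned.  The thin strip is only a
    probe of the vulnerable window; the caller delivers the actual S2
    over its own region at the returned time.  The simulator is left at
    the strip-repolarization instant.
    """
    dt = sim.dt
    sim.run(pulse_duration, stimuli=[s1])
    activated = False
    trigger = APD_THRESHOLD_MV - s2_margin
    check = max(1, int(round(1e-3 / dt)))
    while sim.t < 2.0:
        for _ in range(check):
            sim.step()
        vmax_strip = float(sim.V[strip_idx].max())
        if not activated and vmax_strip >= APD_THRESHOLD_MV:
            activated = True
        elif activated and vmax_strip < trigger:
            break
    else:
        raise NoReentryError("S1 wave never cleared the S2 strip; "
                             "cannot time S2")
    t0 = sim.t
    base = sim.get_state()

    lx, ly = sim.grid.extent
    y_probe = ly * 0.4
    left = sim.grid.node_index((lx / 2.0 - 0.4, y_probe))
    right = sim.grid.node_index((lx / 2.0 + 0.4, y_probe))
    depol = -30.0  # clear regenerative depolarization (mV)

    def classify(delay: float) -> str:
        sim.set_state(base)
        t_s2 = t0 + delay
        trial = StimulusEvent(t_s2, pulse_duration, amplitude,
                              region=trial_region)
        sim.run(t_s2 + pulse_duration, stimuli=[trial])
        got_left = got_right = False
        n = int(round(horizon / dt))
        for _ in range(n):
            sim.step()
            got_left = got_left or sim.V[left] >= depol
            got_right = got_right or sim.V[right] >= depol
        if got_left and not got_right:
            return "unidirectional"
        if got_left and got_right:
            return "bidirectional"
        return "blocked"

    # coarse scan for the first delay with any retrograde capture
    last_blocked = 0.0
    first_capture = None
    delay = 0.0
    while delay <= scan_span + 1e-12:
        verdict = classify(delay)
        if verdict == "blocked":
            last_blocked = delay
        else:
            first_capture = (delay, verdict)
            break
        delay = round(delay + coarse_step, 9)
    if first_capture is None:
        sim.set_state(base)
        raise NoReentryError(
            "S2 found no excitable gap within the scan span; adjust "
            "s2_margin or supply s2_time explicitly"
        )

    # 1 ms refinement across [last_blocked, first_capture]
    window: list[float] = []
    delay = round(last_blocked + fine_step, 9)
    end = first_capture[0] + coarse_step
    while delay <= end + 1e-12:
        verdict = classify(delay)
        if verdict == "unidirectional":
            window.append(delay)
        elif verdict == "bidirectional":
            break
        delay = round(delay + fine_step, 9)
    sim.set_state(base)
    if not window:
        raise NoReentryError(
            "no unidirectional S2 response found between full block and "
            "full capture; adjust s2_margin or supply s2_time explicitly"
        )
    mid = window[len(window) // 2]
    return t0 + mid


def initiate_spiral(
    p: ModelParameters,
    lx: float = 10.0,
    ly: float = 10.0,
    dx: float = DEFAULT_DX,
    dt: float = DEFAULT_TISSUE_DT,
    scheme: str = "split",
    amplitude: Optional[float] = None,
    s2_fraction: float = 0.8,
    s2_height: Optional[float] = None,
    s2_time: Optional[float] = None,
    s2_margin: float = 2.0,
    t_after_s2: float = 4.0,
    analysis_window: tuple[float, float] = (2.0, 4.0),
    pulse_duration: float = 2e-3,
    egm_cadence: float = 1e-3,
    egm_beta: float = 1.0,
    snapshot_cadence: Optional[float] = None,
    snapshot_window: Optional[tuple[float, float]] = None,
    record_repolarizations: bool = True,
    progress: bool = False,
) -> SpiralRun:
    """Cross-field S1-S2 reentry on an lx-by-ly cm sheet.

    S1: 2 ms pulse at twice the diastolic threshold over the full left
    edge (1 mm deep), producing a rightward planar wave.  S2: 2 ms pulse
    at three times the threshold over the lower-half rectangle —
    ``s2_fraction`` of the x-extent by ``s2_height`` (default ly/2) —
    delivered in the refractory tail of S1: the region left of the
    recovery boundary is excited, the part still refractory blocks, and
    the resulting broken front pivots around the recovery boundary into
    a single spiral rotating about a core near mid-sheet.  If
    ``s2_time`` is None, delivery is timed automatically: the run
    advances until a 2 mm-wide mid-sheet monitor strip repolarizes below
    the APD threshold minus ``s2_margin`` (mV), then trial stimuli
    locate the unidirectional-response window (see
    :func:`_auto_s2_time`).

    ``analysis_window`` (s, relative to S2) bounds the per-node
    activation recording and the EGM; snapshots are recorded at
    ``snapshot_cadence`` inside ``snapshot_window`` (also relative to
    S2) when requested.

    Raises :class:`NoReentryError` if no activations occur inside the
    analysis window (no sustained rotation).
    """
    from .protocols import diastolic_threshold

    if amplitude is None:
        amplitude = 2.0 * diastolic_threshold(p, dx=dx, dt=dt, scheme=scheme)
    grid = Grid.sheet(lx, ly, dx=dx)
    sim = TissueSimulator(p, grid, dt=dt, scheme=scheme)

    s1 = StimulusEvent(0.0, pulse_duration, amplitude,
                       region=lambda X, Y: X <= 0.1 + 1e-12)
    x_mid = lx / 2.0
    if s2_height is None:
        s2_height = ly / 2.0
    s2_region = lambda X, Y: ((X <= s2_fraction * lx + 1e-12)
                              & (Y <= s2_height + 1e-12))
    # timing monitor: 2 mm-wide strip at mid-sheet inside the S2 region
    monitor = lambda X, Y: ((X >= x_mid - 0.1 - 1e-12)
                            & (X <= x_mid + 0.1 + 1e-12)
                            & (Y <= s2_height + 1e-12))
    strip_idx = np.nonzero(grid.resolve_region(monitor))

    if s2_time is None:
        s2_time = _auto_s2_time(sim, s1, monitor, strip_idx, s2_margin,
                                pulse_duration, 1.5 * amplitude)
        sim.run(s2_time, stimuli=[s1])
    else:
        sim.run(s2_time, stimuli=[s1])

    s2 = StimulusEvent(s2_time, pulse_duration, 1.5 * amplitude,
                       region=s2_region)

    window = (s2_time + analysis_window[0], s2_time + analysis_window[1])
    act = ActivationRecorder(window=window)
    rep = ActivationRecorder(window=window, direction="down") \
        if record_repolarizations else None
    egm = _EGMRecorder(grid, (lx / 2.0, ly / 2.0, EGM_Z_OFFSET), egm_beta,
                       egm_cadence, (s2_time, s2_time + t_after_s2))
    recorders: list = [egm]
    snap = None
    if snapshot_cadence is not None:
        if snapshot_window is None:
            snapshot_window = (t_after_s2 - 0.5, t_after_s2)
        snap = SnapshotRecorder(
            snapshot_cadence,
            (s2_time + snapshot_window[0], s2_time + snapshot_window[1]),
        )
        recorders.append(snap)
    transition = [act] + ([rep] if rep is not None else [])

    t_end = s2_time + t_after_s2
    if progress:  # pragma: no cover - cosmetic
        import sys
        step_chunk = int(round(0.1 / dt))
        while sim.t < t_end - 1e-9:
            chunk_end = min(sim.t + step_chunk * dt, t_end)
            sim.run(chunk_end, stimuli=[s2], recorders=recorders,
                    transition_recorders=transition)
            print(f"\r  spiral t = {sim.t - s2_time:6.2f} / {t_after_s2:.2f} s"
                  " after S2", end="", file=sys.stderr)
        print(file=sys.stderr)
    else:
        sim.run(t_end, stimuli=[s2], recorders=recorders,
                transition_recorders=transition)

    act_nodes, act_times = act.events()
    if len(act_nodes) == 0:
        raise NoReentryError(
            "no activations in the analysis window: S2 was fully blocked "
            "or fully captured; rescan s2_time"
        )
    rep_nodes, rep_times = rep.events() if rep is not None else (
        np.empty(0, np.int64), np.empty(0))
    return SpiralRun(
        grid=grid, dt=dt, s2_time=s2_time, window=window,
        act_nodes=act_nodes, act_times=act_times,
        rep_nodes=rep_nodes, rep_times=rep_times,
        egm_t=np.asarray(egm.t), egm_v=np.asarray(egm.v),
        snapshot_times=np.asarray(snap.times) if snap is not None else None,
        snapshot_frames=snap.frames if snap is not None else None,
    )


# ---------------------------------------------------------------------------
# Period statistics


def _per_node_intervals(nodes: np.ndarray, times: np.ndarray,
                        n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Successive event intervals per node: (node index, interval seconds)."""
    order = np.lexsort((times, nodes))
    nodes = nodes[order]
    times = times[order]
    same = nodes[1:] == nodes[:-1]
    return nodes[1:][same], np.diff(times)[same]


def dominant_period_ms(periods_ms: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Modal 1 ms bin of a period sample; ties break toward the longer period.

    Returns (dominant period, counts, bin centers); periods are rounded
    to the nearest ms first.
    """
    rounded = np.round(periods_ms).astype(int)
    counts = np.bincount(rounded)
    best = np.nonzero(counts == counts.max())[0][-1]
    centers = np.arange(len(counts), dtype=float)
    return float(best), counts, centers


def period_statistics(run: SpiralRun,
                      window: Optional[tuple[float, float]] = None) -> SpiralMetrics:
    """Per-node period map, pooled histogram and dominant period.

    Periods are differences of successive activation times (upward
    -72.5 mV crossings) inside the analysis window; the map holds the
    per-node mean (NaN where fewer than two activations were seen), and
    the dominant period is the modal 1 ms histogram bin.
    """
    nodes, times = run.act_nodes, run.act_times
    if window is not None:
        keep = (times >= window[0]) & (times <= window[1])
        nodes, times = nodes[keep], times[keep]
    n = run.grid.n_nodes
    inode, ival = _per_node_intervals(nodes, times, n)
    if len(ival) == 0:
        raise NoReentryError("fewer than two activations everywhere")
    periods_ms = ival * 1e3

    sums = np.bincount(inode, weights=periods_ms, minlength=n)
    cnts = np.bincount(inode, minlength=n)
    with np.errstate(invalid="ignore"):
        mean_map = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    mean_map = mean_map.reshape(run.grid.shape)

    dom, counts, centers = dominant_period_ms(periods_ms)

    apd_map = None
    if len(run.rep_nodes):
        apd_map = _apd_map(run)
    return SpiralMetrics(
        dominant_period=dom, periods=periods_ms,
        period_counts=counts, period_bins=centers,
        mean_period_map=mean_map, apd_map=apd_map,
    )


def _apd_map(run: SpiralRun) -> np.ndarray:
    """Per-node mean AP duration (ms): each down-crossing minus the latest
    preceding up-crossing at that node."""
    n = run.grid.n_nodes
    events = np.concatenate([
        np.stack([run.act_nodes, run.act_times,
                  np.zeros_like(run.act_times)], axis=1),
        np.stack([run.rep_nodes, run.rep_times,
                  np.ones_like(run.rep_times)], axis=1),
    ])
    order = np.lexsort((events[:, 2], events[:, 1], events[:, 0]))
    ev = events[order]
    sums = np.zeros(n)
    cnts = np.zeros(n)
    last_up = {}
    for node_f, t, kind in ev:
        node = int(node_f)
        if kind == 0.0:
            last_up[node] = t
        elif node in last_up:
            sums[node] += (t - last_up[node]) * 1e3
            cnts[node] += 1
            del last_up[node]
    with np.errstate(invalid="ignore"):
        out = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return out.reshape(run.grid.shape)


# ---------------------------------------------------------------------------
# Tip tracking


def _contour_intersections(c1: list[np.ndarray], c2: list[np.ndarray]):
    """Intersection points of two families of polylines (index coords)."""
    from shapely.geometry import LineString, MultiLineString
    from shapely.ops import unary_union

    def to_geom(contours):
        lines = [LineString(c[:, ::-1]) for c in contours if len(c) >= 2]
        return unary_union(MultiLineString(lines)) if lines else None

    g1, g2 = to_geom(c1), to_geom(c2)
    if g1 is None or g2 is None:
        return []
    inter = g1.intersection(g2)
    if inter.is_empty:
        return []
    pts = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if g.geom_type == "Point":
            pts.append((g.x, g.y))
        else:  # lines/collections: take representative vertices
            for x, y in np.asarray(g.coords if hasattr(g, "coords") else []):
                pts.append((x, y))
    return pts


def track_tip(frames: Sequence[np.ndarray], times: Sequence[float], dx: float,
              iso_V: float = TIP_ISO_V) -> np.ndarray:
    """Zero-normal-velocity spiral tip trajectory.

    Per consecutive frame pair the tip is the intersection of the
    V = ``iso_V`` isopotential of the newer frame with the dV/dt = 0
    iso-contour of the pair's finite-difference rate field, both
    extracted by marching squares with sub-cell linear interpolation.
    At most one tip is kept per frame by nearest-to-previous continuity.
    Returns an (n, 3) array of (t, x, y) in seconds and cm; frames with
    no intersection are skipped.
    """
    from skimage import measure

    out = []
    prev: Optional[tuple[float, float]] = None
    for i in range(1, len(frames)):
        V1 = np.asarray(frames[i], float)
        V0 = np.asarray(frames[i - 1], float)
        dvdt = (V1 - V0) / (times[i] - times[i - 1])
        iso = measure.find_contours(V1, iso_V)
        zero = measure.find_contours(dvdt, 0.0)
        pts = _contour_intersections(iso, zero)
        if not pts:
            continue
        # contours are (row=x-index, col=y-index); shapely got (col,row)->(y,x)
        cand = [(px * dx, py * dx) for py, px in pts]
        if prev is None:
            tip = cand[0]
        else:
            tip = min(cand, key=lambda q: (q[0] - prev[0]) ** 2
                      + (q[1] - prev[1]) ** 2)
        prev = tip
        out.append((times[i], tip[0], tip[1]))
    return np.asarray(out).reshape(-1, 3)
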