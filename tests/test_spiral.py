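"""Spiral-wave analysis: electrogram kernel, tip tracking and period
statistics on synthetic fields, plus properties of the real reentry run."""

import numpy as np
import pytest

from epicard import Grid, ModelParameters
from epicard.spiral import (
    NoReentryError,
    SpiralRun,
    dominant_period_ms,
    egm_value,
    period_statistics,
    pseudo_egm,
    track_tip,
)

P = ModelParameters()


# ---------------------------------------------------------------------------
# Pseudo-electrogram


class TestEGM:
    def test_uniform_field_zero(self):
        V = np.full((40, 40), -20.0)
        assert egm_value(V, 0.025, (0.5, 0.5, 0.01)) == 0.0

    def test_beta_scales_linearly(self):
        rng = np.random.default_rng(5)
        V = rng.normal(size=(30, 30))
        a = egm_value(V, 0.025, (0.4, 0.4, 0.01), beta=1.0)
        b = egm_value(V, 0.025, (0.4, 0.4, 0.01), beta=2.0)
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_vectorized_matches_brute_force(self):
        """Direct double-loop dipole sum equals the vectorized kernel."""
        rng = np.random.default_rng(6)
        n = 25
        dx = 0.025
        V = rng.normal(scale=30.0, size=(n, n))
        electrode = (0.3, 0.2, 0.01)
        gx, gy = np.gradient(V, dx)
        total = 0.0
        for i in range(n):
            for j in range(n):
                rx = electrode[0] - i * dx
                ry = electrode[1] - j * dx
                r3 = (rx * rx + ry * ry + electrode[2] ** 2) ** 1.5
                total += -(gx[i, j] * rx + gy[i, j] * ry) / r3
        expected = total * dx * dx / 10.0
        assert egm_value(V, dx, electrode) == pytest.approx(expected,
                                                            abs=1e-10)

    def test_pseudo_egm_over_frames(self):
        grid = Grid.sheet(1.0, 1.0, 0.05)
        frames = [np.full(grid.shape, -85.0), np.full(grid.shape, 20.0)]
        trace = pseudo_egm(frames, grid)
        assert trace.shape == (2,)
        assert np.allclose(trace, 0.0)


# ---------------------------------------------------------------------------
# Tip tracking


def _rotating_field(center, t, n=81, dx=0.025, omega=2 * np.pi / 0.25):
    """Rigidly rotating spiral-like pattern with its phase singularity at
    ``center``; V passes through -60 mV at the singularity."""
    x = np.arange(n) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    rx, ry = X - center[0], Y - center[1]
    r = np.hypot(rx, ry)
    theta = np.arctan2(ry, rx)
    k = 2 * np.pi / 1.5  # radial wavenumber (Archimedean pitch)
    return -60.0 + 40.0 * np.tanh(r / 0.1) * np.cos(theta - omega * t - k * r)


class TestTipTracking:
    def test_planar_frames_have_no_tip(self):
        n, dx = 61, 0.025
        x = np.arange(n) * dx
        frames = [np.tile(-85.0 + 120.0 * (x > 0.5 + 0.06 * i), (n, 1)).T
                  for i in range(3)]
        tr = track_tip(frames, [0.0, 0.005, 0.01], dx)
        assert len(tr) == 0

    def test_synthetic_rotor_tip_at_construction_center(self):
        dx = 0.025
        center = (1.013, 0.987)  # deliberately off the node lattice
        times = np.arange(6) * 0.005
        frames = [_rotating_field(center, t, dx=dx) for t in times]
        tr = track_tip(frames, times, dx)
        assert len(tr) >= 4
        err = np.hypot(tr[:, 1] - center[0], tr[:, 2] - center[1])
        assert np.all(err < dx)  # within one cell of the true singularity


# ---------------------------------------------------------------------------
# Period statistics on synthetic activation sequences


def _synthetic_run(act_nodes, act_times, shape=(5, 5)):
    grid = Grid.sheet((shape[0] - 1) * 0.025, (shape[1] - 1) * 0.025, 0.025)
    return SpiralRun(
        grid=grid, dt=1e-4, s2_time=0.0, window=(0.0, 10.0),
        act_nodes=np.asarray(act_nodes, np.int64),
        act_times=np.asarray(act_times, float),
        rep_nodes=np.empty(0, np.int64), rep_times=np.empty(0),
        egm_t=np.empty(0), egm_v=np.empty(0),
    )


class TestPeriodStatistics:
    def test_uniform_pacing_gives_flat_map(self):
        n_nodes = 25
        nodes, times = [], []
        for beat in range(5):
            nodes.extend(range(n_nodes))
            times.extend([beat * 0.4] * n_nodes)
        m = period_statistics(_synthetic_run(nodes, times))
        assert m.dominant_period == 400.0
        assert np.allclose(m.mean_period_map, 400.0)

    def test_sparse_nodes_flagged_undefined(self):
        nodes = [0, 0, 1]          # node 1 has a single activation
        times = [0.0, 0.3, 0.1]
        m = period_statistics(_synthetic_run(nodes, times))
        assert np.isnan(m.mean_period_map.ravel()[1])
        assert m.mean_period_map.ravel()[0] == pytest.approx(300.0)

    def test_no_periods_raises(self):
        with pytest.raises(NoReentryError):
            period_statistics(_synthetic_run([0, 1, 2], [0.0, 0.1, 0.2]))

    def test_dominant_period_tie_breaks_to_longer(self):
        dom, _, _ = dominant_period_ms(np.array([250.0, 250.0, 270.0, 270.0]))
        assert dom == 270.0


# ---------------------------------------------------------------------------
# Properties of the actual reentry simulation (session fixture)


class TestReentryRun:
    def test_sustained_rotation(self, spiral_result):
        run, metrics = spiral_result
        # activations continue throughout the 2 s analysis window
        assert run.act_times.max() > run.window[1] - 0.3
        assert len(metrics.periods) > 10_000

    @staticmethod
    def _core_center(run):
        tr = track_tip(run.snapshot_frames, run.snapshot_times, run.grid.dx)
        return float(np.mean(tr[:, 1])), float(np.mean(tr[:, 2]))

    def test_period_map_uniform_away_from_core(self, spiral_result):
        run, metrics = spiral_result
        pmap = metrics.mean_period_map
        X, Y = run.grid.coords()
        cx, cy = self._core_center(run)
        far = (np.hypot(X - cx, Y - cy) >= 2.0) & ~np.isnan(pmap)
        assert np.nanstd(pmap[far]) < 5.0  # ms

    def test_tip_path_extent_about_2cm(self, spiral_result):
        run, _ = spiral_result
        tr = track_tip(run.snapshot_frames, run.snapshot_times, run.grid.dx)
        assert len(tr) > 20
        ext_x = tr[:, 1].max() - tr[:, 1].min()
        ext_y = tr[:, 2].max() - tr[:, 2].min()
        assert 1.0 < max(ext_x, ext_y) < 3.5  # cm, S-shaped core ~2 cm

    def test_egm_becomes_regular_with_dominant_period(self, spiral_result):
        """After the 2 s settling window the electrogram is periodic with
        the dominant reentry period (autocorrelation peak within 5 ms)."""
        run, metrics = spiral_result
        sel = run.egm_t >= run.s2_time + 2.0
        v = run.egm_v[sel] - np.mean(run.egm_v[sel])
        ac = np.correlate(v, v, mode="full")[len(v) - 1:]
        # first local max beyond half the dominant period
        start = int(metrics.dominant_period / 2)
        lag = start + int(np.argmax(ac[start:int(metrics.dominant_period * 1.5)]))
        assert abs(lag - metrics.dominant_period) <= 5.0

    def test_min_apd_in_core_region(self, spiral_result):
        """The shortest APs occur at the spiral core."""
        run, metrics = spiral_result
        apd = metrics.apd_map
        assert apd is not None
        X, Y = run.grid.coords()
        cx, cy = self._core_center(run)
        imin = np.unravel_index(np.nanargmin(apd), apd.shape)
        assert np.hypot(X[imin] - cx, Y[imin] - cy) < 2.5
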