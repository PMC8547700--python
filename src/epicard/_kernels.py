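"""Low-level reaction stepping kernels.

The Heun (RK2) reaction substep is the hot spot of tissue simulations
(two right-hand-side evaluations per node per substep).  A fused numba
kernel is used when numba is importable; a numpy fallback implements the
identical two-stage update via :func:`epicard.ionic.reaction_rates`
(agreement is at rounding level, ~1e-16 relative).
"""

from __future__ import annotations

import numpy as np

from .ionic import reaction_rates
from .params import ModelParameters

__all__ = ["heun_reaction_inplace", "param_tuple", "HAVE_NUMBA"]


def param_tuple(p: ModelParameters) -> tuple:
    return (p.k, p.c1, p.c2, p.c3, p.a, p.A, p.B, p.e10, p.e2,
            p.g0, p.gamma0, p.gamma1, p.alpha, p.theta_u, p.u_M,
            p.ew0, p.dw0)


def _heun_numpy(V, u, w, ups, iext, dt, p: ModelParameters) -> None:
    dV1, du1, dw1 = reaction_rates(V, u, w, ups, p)
    V1 = V + dt * (dV1 + iext)
    u1 = u + dt * du1
    w1 = w + dt * dw1
    dV2, du2, dw2 = reaction_rates(V1, u1, w1, ups, p)
    V += 0.5 * dt * (dV1 + dV2 + 2.0 * iext)
    u += 0.5 * dt * (du1 + du2)
    w += 0.5 * dt * (dw1 + dw2)


try:
    import math

    from numba import njit

    HAVE_NUMBA = True

    @njit(cache=True)
    def _heun_numba(V, u, w, ups, iext, dt, k, c1, c2, c3, a, A, B, e10, e2,
                    g0_, gam0, gam1, alpha, th_u, uM, ew0, dw0):  # pragma: no cover
        n = V.size
        Vf = V.reshape(n)
        uf = u.reshape(n)
        wf = w.reshape(n)
        pf = ups.reshape(n)
        ef = iext.reshape(n)
        for i in range(n):
            v0 = Vf[i]; u0 = uf[i]; w0 = wf[i]; up = pf[i]; ie = ef[i]
            x = v0 - B; xa = x / A
            ru = (uM - u0) / uM; su = ru * ru
            g = (gam0 + gam1 * u0) * 0.5 * (1.0 - math.tanh(alpha * (u0 - th_u))) + g0_
            dV1 = -g * k * (c1 * x * (a - xa) * (1.0 - xa)
                            + c2 * u0 * x + c3 * w0 * x * su) + ie
            s = xa - u0
            e = (g * e10 if up else e10) if s >= 0.0 else e2
            du1 = k * e * s
            dw1 = k * g * ew0 * (xa - (dw0 / max(su, 1e-30)) * w0)
            v1 = v0 + dt * dV1; u1 = u0 + dt * du1; w1 = w0 + dt * dw1
            x = v1 - B; xa = x / A
            ru = (uM - u1) / uM; su = ru * ru
            g = (gam0 + gam1 * u1) * 0.5 * (1.0 - math.tanh(alpha * (u1 - th_u))) + g0_
            dV2 = -g * k * (c1 * x * (a - xa) * (1.0 - xa)
                            + c2 * u1 * x + c3 * w1 * x * su) + ie
            s = xa - u1
            e = (g * e10 if up else e10) if s >= 0.0 else e2
            du2 = k * e * s
            dw2 = k * g * ew0 * (xa - (dw0 / max(su, 1e-30)) * w1)
            Vf[i] = v0 + 0.5 * dt * (dV1 + dV2)
            uf[i] = u0 + 0.5 * dt * (du1 + du2)
            wf[i] = w0 + 0.5 * dt * (dw1 + dw2)

    def heun_reaction_inplace(V, u, w, ups, iext, dt, p: ModelParameters) -> None:
        """Advance (V, u, w) in place by one Heun reaction substep of size dt."""
        _heun_numba(V, u, w, np.ascontiguousarray(ups), iext, dt, *param_tuple(p))

except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def heun_reaction_inplace(V, u, w, ups, iext, dt, p: ModelParameters) -> None:
        """Advance (V, u, w) in place by one Heun reaction substep of size dt."""
        _heun_numpy(V, u, w, ups, iext, dt, p)
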