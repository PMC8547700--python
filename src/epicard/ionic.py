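"""Right-hand side of the three-variable epicardial ionic model.

The total transmembrane current is the sum of an excitatory (cubic,
FitzHugh-Nagumo-like), a recovery and a transient-outward contribution,

    I_ion = g * k * (I_exc + I_rec + I_to),

modulated by a voltage-independent shape factor ``g(u)`` that is large
during the upstroke and relaxes to ``g0`` late in the action potential.
State variables: membrane potential ``V`` (mV), recovery variable ``u``
and transient-outward gate ``w`` (both dimensionless).  Rest is
``(B, 0, 0)`` and is an exact fixed point.

All functions accept scalars or numpy arrays and are free of side
effects; the integrators in :mod:`epicard.cell` and :mod:`epicard.tissue`
call :func:`reaction_rates` point-wise on whole grids.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

__all__ = [
    "ModelRegimeError",
    "excitatory_current",
    "recovery_current",
    "s_u_factor",
    "transient_outward_current",
    "shape_factor",
    "recovery_rate",
    "w_rate_and_asymptote",
    "derivatives",
    "reaction_rates",
]

# Floor used when dividing by s_u in the w equation; u stays well below
# u_M in every simulated regime, so the floor is never active in practice.
_SU_FLOOR = 1e-30


class ModelRegimeError(RuntimeError):
    """The state left the regime the model is defined on (e.g. u > u_M)."""


def excitatory_current(V, p: ModelParameters):
    """Cubic excitatory current; negative (inward) for a*A+B < V < A+B."""
    x = np.asarray(V, dtype=float) - p.B
    return p.c1 * x * (p.a - x / p.A) * (1.0 - x / p.A)


def recovery_current(V, u, p: ModelParameters):
    """Recovery (repolarizing) current c2*u*(V - B)."""
    return p.c2 * np.asarray(u, dtype=float) * (np.asarray(V, dtype=float) - p.B)


def s_u_factor(u, p: ModelParameters, *, on_violation: str = "raise"):
    """Availability factor ((u_M - u)/u_M)^2, in [0, 1] for u in [0, u_M].

    ``u > u_M`` means the state left the regime the model is defined on.
    ``on_violation`` selects the response: ``"raise"`` (default) or
    ``"clamp"`` (clamp the factor to 0).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u > p.u_M):
        if on_violation == "raise":
            raise ModelRegimeError(
                f"recovery variable exceeded u_M={p.u_M}: max u = {np.max(u)}"
            )
        if on_violation != "clamp":
            raise ValueError("on_violation must be 'raise' or 'clamp'")
    r = (p.u_M - u) / p.u_M
    return np.square(np.maximum(r, 0.0))


def transient_outward_current(V, u, w, p: ModelParameters):
    """Transient outward current c3*w*(V - B)*s_u; carves the phase-1 notch."""
    return (
        p.c3
        * np.asarray(w, dtype=float)
        * (np.asarray(V, dtype=float) - p.B)
        * s_u_factor(u, p)
    )


def shape_factor(u, p: ModelParameters):
    """Sigmoidal shape factor g(u) >= g0.

    High (about gamma0 + g0) for u well below theta_u, decaying to g0 for
    u well above it; the same value multiplies the total current, the
    upstroke-gated plateau rate and the w rate within one evaluation.
    """
    u = np.asarray(u, dtype=float)
    return (p.gamma0 + p.gamma1 * u) * 0.5 * (
        1.0 - np.tanh(p.alpha * (u - p.theta_u))
    ) + p.g0


def recovery_rate(V, u, is_upstroke, p: ModelParameters):
    """Two-rate constant e of the u equation.

    The branch is selected by the sign of du/dt, which (since k*e > 0)
    equals the sign of s = (V - B)/A - u: s >= 0 selects e1, s < 0
    selects e2.  During the upstroke e1 is boosted by the shape factor,
    e1 = g(u)*e10, so that the balance between excitatory and recovery
    currents is preserved while g is large.
    """
    V = np.asarray(V, dtype=float)
    u = np.asarray(u, dtype=float)
    s = (V - p.B) / p.A - u
    e1 = np.where(is_upstroke, shape_factor(u, p) * p.e10, p.e10)
    return np.where(s >= 0.0, e1, p.e2)


def w_rate_and_asymptote(u, p: ModelParameters):
    """Rate e_w = g(u)*ew0 and asymptote divisor d_w = dw0 / s_u of the w equation.

    The division by the availability factor makes d_w grow as u grows, so
    the w asymptote ((V - B)/A)/d_w shrinks during refractoriness and the
    notch vanishes at short diastolic intervals.  At s_u = 0 the divisor
    is infinite and the asymptote is taken as exactly 0 (no division by
    zero is performed on the asymptote itself).
    """
    e_w = shape_factor(u, p) * p.ew0
    su = s_u_factor(u, p)
    with np.errstate(divide="ignore"):
        d_w = np.where(su > 0.0, p.dw0 / np.maximum(su, _SU_FLOOR), np.inf)
    return e_w, d_w


def derivatives(state, is_upstroke, p: ModelParameters, I_ext=0.0):
    """Time derivatives (dV/dt [mV/s], du/dt [1/s], dw/dt [1/s]).

    ``state`` is the (V, u, w) triple; ``I_ext`` is an external current
    in mV/s (depolarizing positive).  ``is_upstroke`` is the
    previous-step upstroke flag (see :class:`epicard.cell.UpstrokeContext`).
    """
    V, u, w = state
    dV, du, dw = reaction_rates(
        np.asarray(V, float), np.asarray(u, float), np.asarray(w, float),
        is_upstroke, p,
    )
    return dV + I_ext, du, dw


def reaction_rates(V, u, w, is_upstroke, p: ModelParameters):
    """Vectorized reaction rates without the external current.

    This is the single code path used by the 0D and tissue integrators,
    so a cable with D = 0 reproduces the single-cell trajectory exactly.
    """
    x = V - p.B
    xa = x / p.A
    su = np.square((p.u_M - u) / p.u_M)
    g = (p.gamma0 + p.gamma1 * u) * 0.5 * (
        1.0 - np.tanh(p.alpha * (u - p.theta_u))
    ) + p.g0

    i_exc = p.c1 * x * (p.a - xa) * (1.0 - xa)
    i_rec = p.c2 * u * x
    i_to = p.c3 * w * x * su
    dV = -g * p.k * (i_exc + i_rec + i_to)

    s = xa - u
    e1 = np.where(is_upstroke, g * p.e10, p.e10)
    e = np.where(s >= 0.0, e1, p.e2)
    du = p.k * e * s

    e_w = g * p.ew0
    dw = p.k * e_w * (xa - (p.dw0 / np.maximum(su, _SU_FLOOR)) * w)
    return dV, du, dw
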