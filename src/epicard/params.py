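"""Model parameters of the three-variable epicardial ionic model.

The model has 17 named constants plus the monodomain diffusion
coefficient ``D``.  The defaults are the published epicardial parameter
set; all simulations in this package use them unless a modified set is
supplied explicitly or via a configuration file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = ["ModelParameters", "PARAM_NAMES"]

#: Canonical ordering of the parameter keys in serialized files.
PARAM_NAMES = (
    "k", "c1", "c2", "c3", "a", "A", "B", "e10", "e2",
    "gamma0", "gamma1", "alpha", "theta_u", "g0", "u_M",
    "ew0", "dw0", "D",
)


@dataclass(frozen=True)
class ModelParameters:
    """The constants of the epicardial model.

    Attributes
    ----------
    k : float
        Global rate scale (1/s); sets the timescale of all three state
        equations.
    c1, c2, c3 : float
        Gains of the excitatory, recovery and transient-outward current
        terms (dimensionless).
    a : float
        Activation threshold as a fraction of the amplitude; the
        excitatory current becomes regenerative above ``a*A + B``.
    A : float
        Action-potential amplitude scale (mV).
    B : float
        Resting membrane potential (mV).
    e10, e2 : float
        Recovery-variable rate constants: ``e10`` governs the plateau
        (du/dt >= 0 branch), ``e2`` the refractory decay (du/dt < 0).
    gamma0, gamma1, alpha, theta_u, g0 : float
        Constants of the sigmoidal shape factor ``g(u)`` that boosts the
        dynamics during the upstroke and relaxes to ``g0`` late in the
        action potential.
    u_M : float
        Ceiling of the recovery variable used in the quadratic
        availability factor ``s_u``; ``u`` must stay below it.
    ew0 : float
        Base rate constant of the transient-outward gate ``w``.
    dw0 : float
        Asymptote constant of ``w``; larger values mean a weaker notch.
    D : float
        Monodomain diffusion coefficient (cm^2/s).
    """

    k: float = 1000.0
    c1: float = 2.6
    c2: float = 1.0
    c3: float = 0.5
    a: float = 0.18
    A: float = 135.0
    B: float = -85.0
    e10: float = 0.0059
    e2: float = 0.015
    gamma0: float = 8.0
    gamma1: float = 20.0
    alpha: float = 15.0
    theta_u: float = 0.2
    g0: float = 0.1
    u_M: float = 0.58
    ew0: float = 0.04
    dw0: float = 0.6
    D: float = 1.171

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if not 0.0 < self.a < 1.0:
            raise ValueError("a must lie in (0, 1)")
        if self.u_M <= 0:
            raise ValueError("u_M must be positive")
        for name in ("e10", "e2", "ew0", "dw0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.D < 0:
            # D = 0 is allowed: it decouples the tissue solvers into
            # independent cells (used to cross-check the integrators)
            raise ValueError("D must be non-negative")

    @property
    def excitation_threshold(self) -> float:
        """Voltage above which the excitatory current is inward (mV): a*A + B."""
        return self.a * self.A + self.B

    @property
    def resting_state(self) -> tuple[float, float, float]:
        """The (V, u, w) fixed point of the unstimulated dynamics."""
        return (self.B, 0.0, 0.0)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    # -- flat key=value serialization -------------------------------------

    def to_file(self, path: Union[str, Path]) -> None:
        """Write the parameter set as flat ``key = value`` lines."""
        lines = [f"{name} = {getattr(self, name)!r}" for name in PARAM_NAMES]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ModelParameters":
        """Read a parameter set written by :meth:`to_file`.

        Unknown keys raise; missing keys keep their defaults.
        """
        values: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in PARAM_NAMES:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            values[key] = float(val)
        return cls(**values)
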