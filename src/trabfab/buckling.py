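"""Torsional buckling of a thin-walled cylindrical tube.

Closed-form relations for the critical shear stress and critical torque of
a thin-walled tube in torsion:

    D      = E t^3 / (12 (1 - nu^2))          flexural stiffness per unit
                                              circumference
    tau_cr = k pi^2 D / (l^2 t)               critical shear stress
    tau    = T / (2 t A)  =  2 T / (pi d^2 t) shear stress from torque
                                              (general / circular section)
    T_cr   = K pi^3 d^2 t^3 / (2 l^2)         critical torque,
                                              K = k E / (12 (1 - nu^2))

All quantities are SI (Pa, m, N m).  ``k`` is an empirical constant of the
material/boundary conditions; the chain of the first three relations for a
circular tube reproduces the T_cr expression exactly when K is derived from
(k, E, nu).  Validity requires t << d (thin wall); the formulas themselves
do not enforce it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TorsionTube",
    "flexural_stiffness",
    "critical_shear",
    "shear_from_torque",
    "shear_from_torque_general",
    "critical_torque",
    "lumped_constant",
]


def _positive(**kwargs):
    for name, v in kwargs.items():
        if not np.all(np.asarray(v) > 0):
            raise ValueError(f"{name} must be > 0")


def flexural_stiffness(E: float, t: float, nu: float) -> float:
    """D = E t^3 / (12 (1 - nu^2)), in N m."""
    _positive(E=E, t=t)
    if not -1.0 < nu < 0.5:
        raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
    return E * t**3 / (12.0 * (1.0 - nu**2))


def critical_shear(k: float, D: float, l: float, t: float) -> float:
    """tau_crit = k pi^2 D / (l^2 t), in Pa."""
    _positive(k=k, D=D, l=l, t=t)
    return k * np.pi**2 * D / (l**2 * t)


def shear_from_torque(T: float, d: float, t: float) -> float:
    """Circular thin-walled section: tau = 2 T / (pi d^2 t)."""
    _positive(T=T, d=d, t=t)
    return 2.0 * T / (np.pi * d**2 * t)


def shear_from_torque_general(T: float, t: float, A: float) -> float:
    """General thin-walled closed section: tau = T / (2 t A), with A the
    area enclosed by the section."""
    _positive(T=T, t=t, A=A)
    return T / (2.0 * t * A)


def lumped_constant(k: float, E: float, nu: float) -> float:
    """K = k E / (12 (1 - nu^2)): the material constant of the critical
    torque expression, derived from the critical-shear chain."""
    _positive(k=k, E=E)
    if not -1.0 < nu < 0.5:
        raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
    return k * E / (12.0 * (1.0 - nu**2))


def critical_torque(K: float, d: float, t: float, l: float) -> float:
    """T_crit = K pi^3 d^2 t^3 / (2 l^2), in N m."""
    _positive(K=K, d=d, t=t, l=l)
    return K * np.pi**3 * d**2 * t**3 / (2.0 * l**2)


@dataclass
class TorsionTube:
    """Thin-walled-tube parameters; derived buckling quantities as methods.

    ``K`` may be supplied directly or is derived from (k, E, nu).  Geometry
    in metres, moduli in Pa.  The thin-wall assumption (t much smaller than
    d) is the model's validity condition, not an enforced constraint.
    """

    E: float
    nu: float
    t: float
    l: float
    d: float
    k: float = 1.0
    K: float | None = None

    def __post_init__(self):
        _positive(E=self.E, t=self.t, l=self.l, d=self.d, k=self.k)
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
        if self.K is None:
            self.K = lumped_constant(self.k, self.E, self.nu)

    @property
    def D(self) -> float:
        return flexural_stiffness(self.E, self.t, self.nu)

    @property
    def area(self) -> float:
        return np.pi * self.d**2 / 4.0

    def tau_crit(self) -> float:
        return critical_shear(self.k, self.D, self.l, self.t)

    def T_crit(self) -> float:
        return critical_torque(self.K, self.d, self.t, self.l)

    def tau(self, T: float) -> float:
        return shear_from_torque(T, self.d, self.t)
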