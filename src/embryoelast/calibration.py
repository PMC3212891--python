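"""Micropipette force calibration from viscous drag.

The pipette tip is modelled as a slender cylinder (immersion depth L,
radius R) dragged transversely through a viscous oil at low Reynolds
number.  Measuring the tip deflection x at known drag forces yields the
pipette's force constant k = |F| / x, which converts tip deflection into
applied force during an experiment.

The transverse Stokes drag on a slender cylinder is implemented as

    F = 4 pi eta L v / (ln(2 L / R) + C)

with a configurable end-correction constant C (default 0.5).  Different
slender-body treatments place slightly different constants next to the
logarithm; C is therefore an explicit, documented parameter of this
package rather than a claim about any particular reference, and the
choice only shifts forces by a few percent for typical L/R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CalibrationRecord",
    "drag_force_cylinder",
    "fit_force_constant",
    "force_from_deflection",
    "DEFAULT_LOG_CONSTANT",
]

#: default end-correction constant C in ln(2L/R) + C
DEFAULT_LOG_CONSTANT = 0.5


def drag_force_cylinder(
    L_um: float,
    R_um: float,
    v_m_per_s: float,
    eta_pa_s: float,
    log_constant: float = DEFAULT_LOG_CONSTANT,
) -> float:
    """Transverse low-Reynolds drag force (N) on a slender cylinder.

    Parameters are the immersed length L (um), cylinder radius R (um),
    relative fluid velocity v (m/s, perpendicular to the axis) and dynamic
    viscosity eta (Pa s).  The force is linear in eta and v and, up to the
    logarithmic factor, in L.
    """
    if not (L_um > R_um > 0):
        raise ValueError(f"need L > R > 0, got L={L_um} um, R={R_um} um")
    if v_m_per_s < 0:
        raise ValueError("velocity must be non-negative")
    if not eta_pa_s > 0:
        raise ValueError("viscosity must be positive")
    L = L_um * 1e-6
    denom = np.log(2.0 * L_um / R_um) + log_constant
    if denom <= 0:
        raise ValueError("log denominator non-positive; L/R too small")
    return 4.0 * np.pi * eta_pa_s * L * v_m_per_s / denom


def force_from_deflection(k_n_per_m: float, x_um) -> np.ndarray | float:
    """Force (N) from tip deflection x (um) given force constant k (N/m).

    The force acts along the deflection direction; this returns |F| = k x
    for scalar or array x.
    """
    if not k_n_per_m > 0:
        raise ValueError("force constant must be positive")
    return k_n_per_m * np.asarray(x_um, dtype=float) * 1e-6


def fit_force_constant(
    deflections_um: Sequence[float], forces_n: Sequence[float]
) -> Tuple[float, float]:
    """Zero-intercept least-squares slope of force vs deflection.

    Returns ``(k, k_se)`` in N/m.  The regression is forced through the
    origin because zero deflection must mean zero force.
    """
    x = np.asarray(deflections_um, dtype=float) * 1e-6  # m
    f = np.asarray(forces_n, dtype=float)
    if x.size != f.size:
        raise ValueError("deflections and forces must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 calibration points")
    sxx = float(np.sum(x * x))
    if sxx == 0 or np.ptp(x) == 0:
        raise ValueError("deflections are degenerate (all equal); cannot fit slope")
    k = float(np.sum(f * x) / sxx)
    resid = f - k * x
    dof = max(x.size - 1, 1)
    k_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return k, k_se


@dataclass
class CalibrationRecord:
    """One pipette calibration: geometry, fluid, raw data and fitted k.

    ``velocities`` in m/s and ``deflections`` in um are paired
    observations; :meth:`calibrate` computes per-point drag forces and the
    zero-intercept force constant.
    """

    cylinder_length_um: float
    cylinder_radius_um: float
    fluid_viscosity_pa_s: float
    velocities: Sequence[float] = field(default_factory=list)
    deflections_um: Sequence[float] = field(default_factory=list)
    log_constant: float = DEFAULT_LOG_CONSTANT
    force_constant: Optional[float] = None
    force_constant_se: Optional[float] = None

    def __post_init__(self):
        if not (self.cylinder_length_um > self.cylinder_radius_um > 0):
            raise ValueError("need cylinder length > radius > 0")
        if not self.fluid_viscosity_pa_s > 0:
            raise ValueError("viscosity must be positive")
        if len(self.velocities) != len(self.deflections_um):
            raise ValueError("velocities and deflections must have equal length")

    def drag_forces(self) -> np.ndarray:
        """Drag force (N) for each recorded velocity."""
        return np.array([
            drag_force_cylinder(
                self.cylinder_length_um,
                self.cylinder_radius_um,
                v,
                self.fluid_viscosity_pa_s,
                self.log_constant,
            )
            for v in self.velocities
        ])

    def calibrate(self) -> Tuple[float, float]:
        """Fit and store the force constant; returns (k, k_se) in N/m."""
        k, se = fit_force_constant(self.deflections_um, self.drag_forces())
        self.force_constant = k
        self.force_constant_se = se
        return k, se

    def to_dict(self) -> dict:
        return {
            "cylinder_length_um": self.cylinder_length_um,
            "cylinder_radius_um": self.cylinder_radius_um,
            "fluid_viscosity_pa_s": self.fluid_viscosity_pa_s,
            "velocities_m_per_s": list(map(float, self.velocities)),
            "deflections_um": list(map(float, self.deflections_um)),
            "log_constant": self.log_constant,
            "force_constant_n_per_m": self.force_constant,
            "force_constant_se_n_per_m": self.force_constant_se,
        }
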