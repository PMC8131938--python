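"""Flight-mechanics power curve and characteristic speeds.

Mechanical power in flapping flight is modelled as the classical
three-component sum

    P(V) = P_ind(V) + P_par(V) + P_pro,

with induced power P_ind = k (m g)^2 / (2 rho V S_d) over the wing disc
S_d = pi b^2 / 4, parasite power P_par = 1/2 rho V^3 S_b C_Db with the body
frontal area from the allometric rule S_b = a m^b_exp, and a profile power
taken as a fixed multiple (profile constant / aspect ratio) of the absolute
minimum of the two variable terms.  The characteristic speeds follow from
the curve: the minimum power speed Vmp minimizes P(V); the maximum range
speed Vmr minimizes P(V)/V, i.e. the energy per unit distance (the tangent
to the curve from the origin), so Vmp < Vmr always.

The constants (induced power factor 1.2, profile power constant 8.4, body
frontal area 0.00813 m^0.666, body drag coefficient 0.2) are the standard
flight-mechanics defaults and are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import Morphology


@dataclass(frozen=True)
class PowerCurveConfig:
    air_density: float = 1.225               # kg/m^3, sea-level ISA
    gravity: float = 9.80665                 # m/s^2
    body_drag_coefficient: float = 0.2
    induced_power_factor: float = 1.2
    profile_power_constant: float = 8.4
    body_frontal_area_coeff: float = 0.00813
    body_frontal_area_exp: float = 0.666

    def __post_init__(self):
        for name in ("air_density", "gravity", "body_drag_coefficient",
                     "induced_power_factor", "profile_power_constant",
                     "body_frontal_area_coeff", "body_frontal_area_exp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def wing_loading(mass: float, wing_area: float) -> float:
    """Body mass over wing area, kg/m^2."""
    if mass <= 0 or wing_area <= 0:
        raise ValueError("mass and wing area must be positive")
    return mass / wing_area


def _two_term_coefficients(morph: Morphology, cfg: PowerCurveConfig):
    """(a, b) of the variable part a V^3 + b / V."""
    s_disc = np.pi * morph.wingspan**2 / 4.0
    s_body = cfg.body_frontal_area_coeff * morph.mass**cfg.body_frontal_area_exp
    a = 0.5 * cfg.air_density * s_body * cfg.body_drag_coefficient
    b = cfg.induced_power_factor * (morph.mass * cfg.gravity) ** 2 / (
        2.0 * cfg.air_density * s_disc
    )
    return a, b


def mechanical_power(v, morph: Morphology, cfg: PowerCurveConfig | None = None):
    """Mechanical power (W) at airspeed v (m/s); vectorized."""
    cfg = cfg or PowerCurveConfig()
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("airspeed must be positive")
    a, b = _two_term_coefficients(morph, cfg)
    # minimum of the two variable terms, (b/3a)^(1/4), is closed-form
    v_star = (b / (3.0 * a)) ** 0.25
    p_absmin = a * v_star**3 + b / v_star
    p_pro = cfg.profile_power_constant / morph.aspect_ratio * p_absmin
    p = a * v**3 + b / v + p_pro
    return float(p) if p.ndim == 0 else p


@dataclass
class PowerCurve:
    """Power curve for one bird, with its characteristic speeds."""

    morphology: Morphology
    config: PowerCurveConfig

    def power(self, v):
        return mechanical_power(v, self.morphology, self.config)

    @property
    def vmp(self) -> float:
        """Minimum power speed (m/s): argmin of P(V)."""
        res = minimize_scalar(self.power, bounds=(0.05, 200.0), method="bounded",
                              options={"xatol": 1e-4})
        if not res.success or not 0.05 + 1e-3 < res.x < 200.0 - 1e-3:
            raise ValueError("no interior minimum of the power curve")
        return float(res.x)

    @property
    def vmr(self) -> float:
        """Maximum range speed (m/s): argmin of P(V)/V (tangent from origin)."""
        res = minimize_scalar(lambda v: self.power(v) / v, bounds=(0.05, 200.0),
                              method="bounded", options={"xatol": 1e-4})
        if not res.success or not 0.05 + 1e-3 < res.x < 200.0 - 1e-3:
            raise ValueError("no interior minimum of P(V)/V")
        return float(res.x)

    def table(self, v_grid=None):
        """(V, P) pairs for export."""
        import pandas as pd

        v = np.arange(2.0, 30.01, 0.25) if v_grid is None else np.asarray(v_grid)
        return pd.DataFrame({"airspeed": v, "power": self.power(v)})


def power_curve(morph: Morphology, cfg: PowerCurveConfig | None = None) -> PowerCurve:
    return PowerCurve(morph, cfg or PowerCurveConfig())
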