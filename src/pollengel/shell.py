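"""Hyperelastic inflation of the exine shell with aperture opening.

The sporopollenin exine is modeled as a thin incompressible Gent membrane
of reference radius R0 and thickness t_e.  For an equibiaxial stretch
lambda the inflation pressure of a Gent balloon is

    P(lambda) = 2 mu_e (t_e/R0) (lambda^-1 - lambda^-7)
                * Jm / (Jm - (2 lambda^2 + lambda^-4 - 3))

The Gent limit Jm encodes finite chain extensibility: P diverges as the
first strain invariant approaches Jm + 3, which defines the maximum
swelling ratio lambda_max.  (A neo-Hookean balloon instead has a pressure
limit point and no finite lambda_max, which is why Gent is used here.)

The three apertures act as soft spots: below the opening ratio
lambda_open the particle deforms mostly by hinging the aperture flaps
outward, which costs little energy.  This phase is represented by a scalar
pressure knockdown f_open < 1 applied to the membrane law, blended
smoothly to 1 at lambda_open so the pressure curve is continuous and
monotone.

The strain energy density per reference volume is W(lambda) =
integral_1^lambda P(s) * 3 s^2 ds (since V/V0 = lambda^3), evaluated by
adaptive quadrature.

Units: radii/thicknesses in um, moduli and pressures in kPa, W in kJ/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "ExineShell",
    "InflationState",
    "exine_inflation_pressure",
    "strain_energy_density",
    "critical_swelling_ratios",
    "phase_of",
]


@dataclass
class ExineShell:
    """Geometry and Gent material parameters of the exine membrane."""

    R0: float = 17.5            # reference outer radius, um
    t_e: float = 0.6            # exine thickness, um
    mu_e: float = 5333.3        # shear modulus, kPa (E_e = 3 mu_e)
    Jm: float = 1.5             # Gent extensibility limit
    aperture_fraction: float = 0.2
    f_open: float = 0.3         # pressure knockdown while apertures open
    lambda_open: float = 1.08   # ratio at which apertures are fully open
    blend_width: float = 0.02   # smooth-blend width below lambda_open

    def __post_init__(self) -> None:
        for name in ("R0", "t_e", "mu_e", "Jm", "f_open", "lambda_open",
                     "blend_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.f_open <= 1.0):
            raise ValueError("f_open must lie in (0, 1]")
        if not (0.0 <= self.aperture_fraction < 1.0):
            raise ValueError("aperture_fraction must lie in [0, 1)")
        if self.lambda_open <= 1.0:
            raise ValueError("lambda_open must exceed 1")


@dataclass
class InflationState:
    lambda_: float
    pressure: float
    W: float
    phase: str  # aperture_opening | stretching | locked


def _gent_invariant_excess(lam: float) -> float:
    """I1 - 3 for an equibiaxial membrane stretch lambda."""
    return 2.0 * lam**2 + lam**-4 - 3.0


def _aperture_factor(lam: float, shell: ExineShell) -> float:
    """Pressure knockdown: f_open deep in the aperture phase, 1 beyond.

    Smoothstep blend over [lambda_open - blend_width, lambda_open] keeps
    the pressure curve continuous and monotone.
    """
    lo = shell.lambda_open - shell.blend_width
    if lam <= lo:
        return shell.f_open
    if lam >= shell.lambda_open:
        return 1.0
    u = (lam - lo) / shell.blend_width
    return shell.f_open + (1.0 - shell.f_open) * u * u * (3.0 - 2.0 * u)


def phase_of(lam: float, shell: ExineShell) -> str:
    lam_max = critical_swelling_ratios(shell)[2]
    if lam >= lam_max:
        return "locked"
    return "aperture_opening" if lam < shell.lambda_open else "stretching"


def exine_inflation_pressure(lambda_, shell: ExineShell):
    """Inflation pressure P_e,inflation(lambda) in kPa.  Vectorized.

    Raises if lambda >= lambda_max (Gent locking) or lambda < 1.
    """
    lam = np.asarray(lambda_, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    if np.any(lam < 1.0):
        raise ValueError("inflation requires lambda >= 1")
    lam_max = critical_swelling_ratios(shell)[2]
    if np.any(lam >= lam_max):
        raise ValueError(f"lambda >= lambda_max = {lam_max:.6f} "
                         "(Gent locking)")
    excess = 2.0 * lam**2 + lam**-4 - 3.0
    base = (2.0 * shell.mu_e * (shell.t_e / shell.R0)
            * (lam**-1 - lam**-7) * shell.Jm / (shell.Jm - excess))
    fac = np.array([_aperture_factor(v, shell) for v in lam])
    out = base * fac
    return float(out[0]) if scalar else out


def strain_energy_density(lambda_: float, shell: ExineShell,
                          rtol: float = 1e-8) -> float:
    """Strain energy density W(lambda) in kJ/m^3 by adaptive quadrature.

    W = integral_1^lambda P(s) dV/V0 with V/V0 = s^3, i.e. the pressure
    work per unit reference volume done inflating the particle.
    """
    if lambda_ < 1.0:
        raise ValueError("lambda must be >= 1")
    if lambda_ == 1.0:
        return 0.0
    brk = [p for p in (shell.lambda_open - shell.blend_width,
                       shell.lambda_open) if 1.0 < p < lambda_]
    val, _ = quad(lambda s: exine_inflation_pressure(s, shell) * 3.0 * s**2,
                  1.0, lambda_, epsrel=rtol, epsabs=0.0, limit=200,
                  points=brk or None)
    return float(val)


def critical_swelling_ratios(shell: ExineShell
                             ) -> tuple[float, float, float]:
    """(lambda_0, lambda_open, lambda_max) for the shell.

    lambda_0 = 1 by definition (reference state); lambda_open is the
    configured aperture-opening ratio; lambda_max is the Gent locking
    stretch, the positive root of 2 lambda^2 + lambda^-4 - 3 = Jm.
    """
    f = lambda lam: _gent_invariant_excess(lam) - shell.Jm
    hi = 1.5
    while f(hi) < 0:
        hi *= 2.0
    lam_max = brentq(f, 1.0 + 1e-12, hi, xtol=1e-10, rtol=8.9e-16)
    return 1.0, shell.lambda_open, float(lam_max)


def inflation_state(lambda_: float, shell: ExineShell) -> InflationState:
    """Bundle pressure, strain energy and phase label at one ratio."""
    return InflationState(
        lambda_=lambda_,
        pressure=exine_inflation_pressure(lambda_, shell),
        W=strain_energy_density(lambda_, shell),
        phase=phase_of(lambda_, shell),
    )
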