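"""Swelling pressure of the intine polyelectrolyte gel.

De-esterified pectin (pectate) carries carboxyl groups whose ionization is
set by pH; the resulting fixed charge drives Donnan partitioning of mobile
ions between the gel and the bath, and the excess interior ion content
produces an osmotic driving pressure.  The total swelling pressure at
linear swelling ratio lambda is the sum of three terms:

    P_i,swelling(lambda) = pi_ion + pi_mix + pi_elastic

* pi_ion  — ideal van 't Hoff pressure RT * sum(c_in - c_bath) from the
  Donnan partition against the (electroneutral) bath;
* pi_mix  — Flory-Huggins mixing pressure -(RT/V_m) [ln(1-phi) + phi +
  chi phi^2] with polymer volume fraction phi = phi0 / lambda^3;
* pi_elastic — Gaussian affine network term -G_i_eff (lambda - 1/lambda).

Divalent (and trivalent) cations chelate pairs of carboxylates ("egg-box"
binding), which simultaneously neutralizes fixed charge and stiffens the
network; EDTA sequesters those cations 1:1 and reverses both effects.

Concentrations are in mM (= mol/m^3), pressures in kPa, temperature in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R_GAS",
    "IonSpecies",
    "IonicEnvironment",
    "IntineGel",
    "SwellingPressureBreakdown",
    "ionization_fraction",
    "donnan_partition",
    "ionic_osmotic_pressure",
    "mixing_pressure",
    "elastic_pressure",
    "divalent_binding",
    "intine_swelling_pressure",
    "free_swelling_ratio",
    "default_gel",
    "environment",
]

R_GAS = 8.31446261815324  # J / (mol K)

#: Molar volume of the solvent (water), m^3/mol, used in the mixing term.
V_M_WATER = 1.8e-5

# Stoichiometry of the salts used in the study's ion-response experiments.
_SALTS = {
    "KCl": (("K+", 1, 1), ("Cl-", -1, 1)),
    "NaCl": (("Na+", 1, 1), ("Cl-", -1, 1)),
    "MgCl2": (("Mg2+", 2, 1), ("Cl-", -1, 2)),
    "CaCl2": (("Ca2+", 2, 1), ("Cl-", -1, 2)),
    "SrCl2": (("Sr2+", 2, 1), ("Cl-", -1, 2)),
    "Fe(NO3)3": (("Fe3+", 3, 1), ("NO3-", -1, 3)),
}


@dataclass(frozen=True)
class IonSpecies:
    name: str
    z: int
    c_mM: float


@dataclass
class IonicEnvironment:
    """Bath composition: pH, mobile ions, chelator dose, temperature.

    The ion list must be electroneutral; a monovalent counter-ion is added
    automatically if the listed species leave a residual charge.  H+/OH-
    act only through carboxyl ionization, not as osmotic species.
    """

    pH: float
    ions: list[IonSpecies] = field(default_factory=list)
    chelator_mM: float = 0.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pH <= 14.0):
            raise ValueError("pH must lie in [0, 14]")
        if self.chelator_mM < 0:
            raise ValueError("chelator concentration must be nonnegative")
        if any(s.c_mM < 0 for s in self.ions):
            raise ValueError("ion concentrations must be nonnegative")
        # merge duplicate species (e.g. Cl- contributed by several salts)
        merged: dict[tuple[str, int], float] = {}
        for s in self.ions:
            merged[(s.name, s.z)] = merged.get((s.name, s.z), 0.0) + s.c_mM
        self.ions = [IonSpecies(n, z, c) for (n, z), c in merged.items()]
        resid = sum(s.z * s.c_mM for s in self.ions)
        strength = sum(abs(s.z) * s.c_mM for s in self.ions)
        if abs(resid) > 1e-9 * max(strength, 1.0):
            name = "X-" if resid > 0 else "X+"
            self.ions = list(self.ions) + [
                IonSpecies(name, -1 if resid > 0 else 1, abs(resid))]

    @property
    def multivalent_mM(self) -> float:
        """Total concentration of cations with valence >= 2."""
        return sum(s.c_mM for s in self.ions if s.z >= 2)

    def free_multivalent_mM(self) -> float:
        """Multivalent cations remaining after 1:1 chelation by EDTA."""
        return max(0.0, self.multivalent_mM - self.chelator_mM)

    def active_ions(self) -> list[IonSpecies]:
        """Osmotically active species after chelation.

        Chelated multivalent cations form a neutral, membrane-inert
        complex with EDTA and take an equivalent charge of counter-anions
        out of the active pool, so a chelator dose matching the
        multivalent load restores the pre-salt bath exactly.
        """
        multi = self.multivalent_mM
        bound = min(multi, self.chelator_mM)
        if bound <= 0 or multi <= 0:
            return [s for s in self.ions if s.c_mM > 0]
        frac_free = 1.0 - bound / multi
        removed_charge = sum(s.z * s.c_mM * (1.0 - frac_free)
                             for s in self.ions if s.z >= 2)
        anion_charge = sum(-s.z * s.c_mM for s in self.ions if s.z < 0)
        anion_scale = (max(0.0, 1.0 - removed_charge / anion_charge)
                       if anion_charge > 0 else 1.0)
        out = []
        for s in self.ions:
            c = s.c_mM * (frac_free if s.z >= 2
                          else anion_scale if s.z < 0 else 1.0)
            if c > 0:
                out.append(IonSpecies(s.name, s.z, c))
        return out


def environment(pH: float = 7.0, *, temperature: float = 298.0,
                chelator_mM: float = 0.0, **salts_mM: float
                ) -> IonicEnvironment:
    """Build a bath from salt formulas, e.g. environment(7, KCl=10, CaCl2=100)."""
    ions: list[IonSpecies] = []
    for salt, c in salts_mM.items():
        if salt not in _SALTS:
            raise KeyError(f"unknown salt {salt!r}; known: {sorted(_SALTS)}")
        for name, z, mult in _SALTS[salt]:
            ions.append(IonSpecies(name, z, mult * c))
    return IonicEnvironment(pH=pH, ions=ions, chelator_mM=chelator_mM,
                            temperature=temperature)


@dataclass
class IntineGel:
    """Material parameters of the intine gel at its reference (dry) state.

    c_coo_total : carboxyl site concentration at reference, mM.
    pKa         : carboxyl pKa (galacturonate, default 3.5).
    phi0        : polymer volume fraction at reference.
    chi         : Flory mixing parameter.
    G_i         : network shear modulus entering pi_elastic, kPa.
    E_i_MPa     : indentation-scale Young's modulus of the intine layer,
                  MPa — the denominator of M_E/I.  Distinct from G_i: the
                  AFM probes the composite cellulose/pectin wall, while
                  G_i is the much softer osmotic network elasticity.
    ca_binding_K     : Langmuir association constant for multivalent
                       binding, 1/mM.
    stiffening_factor: maximum modulus multiplication at full occupancy.
    """

    c_coo_total: float = 30.0
    pKa: float = 3.5
    phi0: float = 0.05
    chi: float = 0.45
    G_i: float = 20.0
    E_i_MPa: float = 10.0
    ca_binding_K: float = 0.05
    stiffening_factor: float = 11.6

    def __post_init__(self) -> None:
        if not (0.0 < self.phi0 < 1.0):
            raise ValueError("phi0 must lie in (0, 1)")
        for name in ("c_coo_total", "G_i", "E_i_MPa", "ca_binding_K",
                     "stiffening_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SwellingPressureBreakdown:
    lambda_: float
    pi_ion: float
    pi_mix: float
    pi_elastic: float
    total: float
    donnan_potential: float


def ionization_fraction(pH: float, pKa: float) -> float:
    """Fraction of carboxyl groups deprotonated (Henderson-Hasselbalch)."""
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def donnan_partition(c_fixed: float, env: IonicEnvironment
                     ) -> tuple[dict[str, float], float]:
    """Ideal Donnan partition of bath ions against a fixed charge.

    Solves sum_j z_j c_j^bath exp(-z_j y) + c_fixed = 0 for the reduced
    potential y = F psi / RT; interior concentrations follow Boltzmann,
    c_j^in = c_j^bath exp(-z_j y).  ``c_fixed`` is signed (negative for
    carboxylate).  Chelated multivalent salt is osmotically inert and is
    excluded from the partition.  Returns ({name: c_in}, y).
    """
    ions = env.active_ions()
    if not ions:
        if abs(c_fixed) > 0:
            raise ValueError("fixed charge cannot be neutralized: bath has "
                             "no mobile ions")
        return {}, 0.0

    def residual(y: float) -> float:
        return sum(s.z * s.c_mM * np.exp(-s.z * y) for s in ions) + c_fixed

    if c_fixed == 0.0:
        y = 0.0
    else:
        # residual is strictly decreasing in y; expand a bracket around 0
        lo, hi = -1.0, 1.0
        for _ in range(200):
            if residual(lo) > 0 >= residual(hi):
                break
            lo *= 2.0
            hi *= 2.0
        else:
            raise ValueError(f"cannot bracket Donnan potential; residual(0)="
                             f"{residual(0.0):.3e}")
        y = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        # polish to the stated residual tolerance
        if abs(residual(y)) > 1e-12 * sum(abs(s.z) * s.c_mM for s in ions):
            raise ValueError("Donnan root did not converge")
    internal = {s.name: s.c_mM * float(np.exp(-s.z * y)) for s in ions}
    return internal, float(y)


def ionic_osmotic_pressure(internal: dict[str, float],
                           env: IonicEnvironment) -> float:
    """Ideal van 't Hoff osmotic pressure RT * sum(c_in - c_bath), kPa."""
    bath = {s.name: s.c_mM for s in env.active_ions()}
    excess = sum(internal.get(n, 0.0) - c for n, c in bath.items())
    return R_GAS * env.temperature * excess * 1e-3  # mM*J/mol = Pa -> kPa


def mixing_pressure(lambda_: float, phi0: float, chi: float,
                    T: float = 298.0, V_m: float = V_M_WATER) -> float:
    """Flory-Huggins mixing pressure at swelling ratio lambda, kPa."""
    phi = phi0 / lambda_**3
    if not (0.0 < phi < 1.0):
        raise ValueError(f"polymer fraction phi={phi:.3g} outside (0, 1)")
    val = -(R_GAS * T / V_m) * (np.log1p(-phi) + phi + chi * phi**2)
    return float(val) * 1e-3


def elastic_pressure(lambda_: float, G_i_effective: float) -> float:
    """Gaussian network restoring pressure -G (lambda - 1/lambda), kPa."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    return -G_i_effective * (lambda_ - 1.0 / lambda_)


def divalent_binding(env: IonicEnvironment, gel: IntineGel
                     ) -> tuple[float, float, float]:
    """Langmuir occupancy of carboxylate sites by multivalent cations.

    EDTA removes multivalent cations 1:1 before binding.  Occupancy theta
    stiffens the network, G_eff = G_i (1 + s*theta), and neutralizes fixed
    charge by the factor (1 - theta).

    Returns (theta, G_i_effective, charge_factor).
    """
    c_free = env.free_multivalent_mM()
    theta = gel.ca_binding_K * c_free / (1.0 + gel.ca_binding_K * c_free)
    g_eff = gel.G_i * (1.0 + gel.stiffening_factor * theta)
    return theta, g_eff, 1.0 - theta


def effective_intine_modulus_MPa(env: IonicEnvironment, gel: IntineGel
                                 ) -> float:
    """Indentation-scale intine modulus after cation stiffening, MPa."""
    theta, _, _ = divalent_binding(env, gel)
    return gel.E_i_MPa * (1.0 + gel.stiffening_factor * theta)


def intine_swelling_pressure(lambda_: float, gel: IntineGel,
                             env: IonicEnvironment
                             ) -> SwellingPressureBreakdown:
    """Total intine swelling pressure and its breakdown at ratio lambda.

    The fixed charge is the ionized, unbound carboxylate concentration
    diluted by the volume change: c_fixed = -alpha c_coo (1-theta)/lambda^3.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    alpha = ionization_fraction(env.pH, gel.pKa)
    theta, g_eff, charge_factor = divalent_binding(env, gel)
    c_fixed = -alpha * gel.c_coo_total * charge_factor / lambda_**3
    internal, y = donnan_partition(c_fixed, env)
    p_ion = ionic_osmotic_pressure(internal, env)
    p_mix = mixing_pressure(lambda_, gel.phi0, gel.chi, env.temperature)
    p_el = elastic_pressure(lambda_, g_eff)
    return SwellingPressureBreakdown(
        lambda_=lambda_, pi_ion=p_ion, pi_mix=p_mix, pi_elastic=p_el,
        total=p_ion + p_mix + p_el, donnan_potential=y)


def free_swelling_ratio(gel: IntineGel, env: IonicEnvironment,
                        lambda_max: float = 6.0) -> float:
    """Swelling ratio of the unconstrained gel (total pressure = 0).

    Returns 1.0 when the gel has no net driving pressure at lambda = 1.
    """
    def total(lam: float) -> float:
        return intine_swelling_pressure(lam, gel, env).total

    if total(1.0) <= 0.0:
        return 1.0
    hi = lambda_max
    while total(hi) > 0.0:
        hi *= 1.5
        if hi > 1e3:
            raise ValueError("free swelling does not equilibrate")
    return float(brentq(total, 1.0, hi, xtol=1e-12, rtol=8.9e-16))


def default_gel(**overrides) -> IntineGel:
    """Default intine parameterization used throughout the analyses."""
    return IntineGel(**overrides)
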