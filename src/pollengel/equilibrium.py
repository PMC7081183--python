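"""Pressure-balance equilibrium of the bilayer pollen microgel.

The intine gel and the exine shell are bonded, so both share a single
linear swelling ratio lambda.  Equilibrium is the ratio at which the
intine's swelling pressure equals the pressure needed to inflate the
exine:

    P_i,swelling(lambda_eq) = P_e,inflation(lambda_eq)

P_i is strictly decreasing in lambda (charge dilution, mixing dilution,
network recoil) while P_e is strictly increasing up to Gent locking, so
the balance point is unique; the solver verifies the monotone bracket
rather than assuming it.  When there is no net driving pressure at
lambda = 1 the particle stays at its reference size, lambda_eq = 1.

Sweeping the exine/intine modulus ratio M_E/I at fixed intine reproduces
the regime structure: a stiff exine (M_E/I > 2) acts as a rigid boundary
(lambda_eq ~ 1, "constrained"); below 2 the equilibrium climbs steeply
toward the locking stretch ("steep_swelling"); with multivalent-cation
stiffening of the intine the effective ratio drops below 1 and the
particle sits below its reference-environment size ("de_swelling").

Stimulus sequences (pH steps, cation/EDTA additions) are propagated with
a first-order relaxation envelope: within each segment lambda relaxes
exponentially toward that segment's equilibrium with a swelling or
de-swelling time constant (de-swelling is the faster of the two).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .gel import (IntineGel, IonicEnvironment, divalent_binding,
                  effective_intine_modulus_MPa, intine_swelling_pressure)
from .shell import ExineShell, critical_swelling_ratios, \
    exine_inflation_pressure

__all__ = [
    "EquilibriumResult",
    "EquilibriumCurve",
    "StimulusTrajectory",
    "NonMonotoneBalanceError",
    "shell_for_ratio",
    "solve_balance",
    "solve_equilibrium",
    "sweep_modulus_ratio",
    "classify_regime",
    "stimulus_trajectory",
]

#: Residual tolerance on the pressure balance, kPa.
BALANCE_TOL_KPA = 1e-6


class NonMonotoneBalanceError(RuntimeError):
    """The net driving pressure g(lambda) = P_i - P_e is not decreasing.

    Carries a diagnostic (lambda, g) table for inspection.
    """

    def __init__(self, msg: str, lam: np.ndarray, g: np.ndarray):
        super().__init__(msg)
        self.diagnostic = np.column_stack([lam, g])


@dataclass
class EquilibriumResult:
    lambda_eq: float
    diameter_um: float
    P_balance: float
    regime: str
    converged: bool
    residual: float


@dataclass
class EquilibriumCurve:
    M_EI: np.ndarray
    lambda_eq: np.ndarray
    regime: list[str]


@dataclass
class StimulusTrajectory:
    time_s: np.ndarray
    lambda_t: np.ndarray
    segment_index: np.ndarray
    lambda_eq_per_segment: np.ndarray
    tau_swell: float
    tau_deswell: float


def shell_for_ratio(M_EI: float, gel: IntineGel,
                    template: ExineShell | None = None) -> ExineShell:
    """Exine shell realizing a modulus ratio M_E/I against a given intine.

    The exine shear modulus is mu_e = M_E/I * E_i / 3 (incompressible,
    E = 3 mu), with the intine's indentation-scale modulus E_i in MPa and
    mu_e in kPa.  Geometry and Gent parameters come from the template.
    """
    if M_EI <= 0:
        raise ValueError("modulus ratio must be positive")
    template = template or ExineShell()
    mu_e_kPa = M_EI * gel.E_i_MPa / 3.0 * 1e3
    return replace(template, mu_e=mu_e_kPa)


def solve_balance(p_intine: Callable[[float], float],
                  p_exine: Callable[[float], float],
                  lambda_max: float, *, n_check: int = 64
                  ) -> tuple[float, float]:
    """Root of g(lambda) = p_intine - p_exine on [1, lambda_max).

    Verifies on a coarse grid that g is non-increasing (unique balance
    point); returns (lambda_eq, residual).  If g(1) <= 0 the reference
    state is the equilibrium and (1.0, 0.0) is returned exactly.
    """
    def g(lam: float) -> float:
        return p_intine(lam) - p_exine(lam)

    # a driving pressure below the balance tolerance is no driving pressure
    if g(1.0) <= BALANCE_TOL_KPA:
        return 1.0, 0.0
    hi = lambda_max - 1e-9 * max(1.0, lambda_max)
    lam_grid = np.linspace(1.0, hi, n_check)
    g_grid = np.array([g(v) for v in lam_grid])
    dg = np.diff(g_grid)
    tol = 1e-9 * max(1.0, float(np.max(np.abs(g_grid))))
    if np.any(dg > tol):
        raise NonMonotoneBalanceError(
            "net driving pressure is not monotone decreasing in lambda; "
            "check gel/shell parameters", lam_grid, g_grid)
    if g_grid[-1] > 0.0:
        # driving pressure still positive at locking: equilibrium pinned
        # arbitrarily close to lambda_max by the Gent divergence
        lam = brentq(g, lam_grid[-1], lambda_max - 1e-13 * lambda_max,
                     xtol=1e-13, rtol=8.9e-16, maxiter=200)
    else:
        lam = brentq(g, 1.0, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return float(lam), float(g(lam))


def solve_equilibrium(gel: IntineGel, shell: ExineShell,
                      env: IonicEnvironment, *,
                      reference_lambda: float | None = None
                      ) -> EquilibriumResult:
    """Equilibrium swelling ratio where P_i,swelling = P_e,inflation.

    Multivalent binding (stiffening + charge neutralization) is applied
    inside the intine pressure; a single lambda is shared by both layers.
    ``reference_lambda`` (equilibrium in the reference environment, pH 7
    no multivalent salt) is only used for the regime label.
    """
    lam_max = critical_swelling_ratios(shell)[2]

    def p_i(lam: float) -> float:
        return intine_swelling_pressure(lam, gel, env).total

    def p_e(lam: float) -> float:
        return exine_inflation_pressure(lam, shell)

    lam_eq, resid = solve_balance(p_i, p_e, lam_max)
    converged = abs(resid) <= BALANCE_TOL_KPA
    m_ei_eff = (3.0 * shell.mu_e * 1e-3) / effective_intine_modulus_MPa(env, gel)
    ref = reference_lambda if reference_lambda is not None else lam_eq
    regime = classify_regime(m_ei_eff, lam_eq, ref)
    return EquilibriumResult(
        lambda_eq=lam_eq,
        diameter_um=2.0 * shell.R0 * lam_eq,
        P_balance=p_e(lam_eq) if lam_eq > 1.0 else 0.0,
        regime=regime,
        converged=converged,
        residual=resid,
    )


def classify_regime(M_EI: float, lambda_eq: float,
                    reference_lambda: float) -> str:
    """Label the swelling regime from the (effective) modulus ratio.

    constrained for M_E/I > 2; steep_swelling for 1 <= M_E/I <= 2;
    de_swelling for M_E/I < 1 when the equilibrium sits below the
    reference.  Boundary ties resolve toward the larger-ratio class.
    """
    if not (np.isfinite(M_EI) and np.isfinite(lambda_eq)):
        raise ValueError("inputs must be finite")
    if M_EI > 2.0:
        return "constrained"
    if M_EI >= 1.0:
        return "steep_swelling"
    return "de_swelling" if lambda_eq < reference_lambda else "steep_swelling"


def sweep_modulus_ratio(gel: IntineGel, shell_template: ExineShell,
                        env: IonicEnvironment,
                        ratios: Sequence[float] | np.ndarray, *,
                        reference_env: IonicEnvironment | None = None
                        ) -> EquilibriumCurve:
    """Equilibrium swelling ratio across a grid of modulus ratios M_E/I.

    Each grid point rescales the exine shear modulus at fixed intine; the
    resulting lambda_eq is non-increasing in M_E/I.  ``reference_env``
    (default pH 7, 10 mM KCl) anchors the de-swelling label.
    """
    from .gel import environment
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("modulus ratios must be positive")
    ref_env = reference_env or environment(7.0, KCl=10.0,
                                           temperature=env.temperature)
    lams = np.empty(ratios.size)
    regimes: list[str] = []
    for i, r in enumerate(ratios):
        shell = shell_for_ratio(r, gel, shell_template)
        ref = solve_equilibrium(gel, shell, ref_env).lambda_eq
        res = solve_equilibrium(gel, shell, env, reference_lambda=ref)
        lams[i] = res.lambda_eq
        regimes.append(res.regime)
    return EquilibriumCurve(M_EI=ratios, lambda_eq=lams, regime=regimes)


def stimulus_trajectory(gel: IntineGel, shell: ExineShell,
                        env_sequence: Sequence[tuple[IonicEnvironment, float]],
                        *, tau_swell: float = 3.0, tau_deswell: float = 1.0,
                        dt: float = 0.05, lambda_start: float | None = None
                        ) -> StimulusTrajectory:
    """lambda(t) under a sequence of (environment, duration_s) segments.

    Within each segment lambda relaxes exponentially toward that
    segment's equilibrium ratio, with the swelling time constant when
    rising and the (faster) de-swelling constant when falling; the
    underlying equilibria are state-free, so completed stimulus cycles
    return lambda to its starting value.
    """
    if not env_sequence:
        raise ValueError("environment sequence must be nonempty")
    if tau_swell <= 0 or tau_deswell <= 0:
        raise ValueError("relaxation times must be positive")
    times: list[np.ndarray] = []
    lams: list[np.ndarray] = []
    seg_idx: list[np.ndarray] = []
    lam_eqs = np.array([solve_equilibrium(gel, shell, e).lambda_eq
                        for e, _ in env_sequence])
    lam = lambda_start if lambda_start is not None else lam_eqs[0]
    t0 = 0.0
    for i, (_, dur) in enumerate(env_sequence):
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        n = max(int(np.ceil(dur / dt)) + 1, 2)
        t = np.linspace(0.0, dur, n)
        tau = tau_swell if lam_eqs[i] >= lam else tau_deswell
        traj = lam_eqs[i] + (lam - lam_eqs[i]) * np.exp(-t / tau)
        times.append(t0 + t)
        lams.append(traj)
        seg_idx.append(np.full(n, i))
        lam = float(traj[-1])
        t0 += dur
    return StimulusTrajectory(
        time_s=np.concatenate(times),
        lambda_t=np.concatenate(lams),
        segment_index=np.concatenate(seg_idx),
        lambda_eq_per_segment=lam_eqs,
        tau_swell=tau_swell,
        tau_deswell=tau_deswell,
    )
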