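"""Seeded synthetic-data generators with ground truth.

Every pipeline input can be generated here: Hertzian AFM approach curves
with instrument noise and a contact-point offset, flow-imaging style
frames of disc particles, size populations mimicking the ~35 um (dry)
to ~43 um (swollen) shift of processed pollen, and stimulus schedules
(pH cycles, cation-then-chelator additions).  All generators are pure
functions of their arguments including the seed, and each returns the
generating truth alongside the data so recovery tests never re-derive
hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian

from .afm import ForceCurve, hertz_force
from .gel import IonicEnvironment, environment

__all__ = [
    "gen_force_curve",
    "gen_particle_images",
    "gen_dipa_population",
    "gen_stimulus_sequence",
]

#: Instrument cap on the loading force, uN.
MAX_LOAD_UN = 4.8


@dataclass
class ForceCurveTruth:
    E_MPa: float
    nu: float
    r_tip_nm: float
    k_N_per_m: float
    contact_index: int
    z_contact_nm: float
    delta_max_nm: float


def gen_force_curve(E_MPa: float, *, nu: float = 0.5, r_tip_nm: float = 5.0,
                    k_N_per_m: float = 42.0, contact_offset_nm: float = 200.0,
                    delta_max_nm: float = 60.0, n_baseline: int = 200,
                    n_contact: int = 300, noise_sigma_nm: float = 0.0,
                    max_force_uN: float = MAX_LOAD_UN,
                    label: str = "", condition: str = "", seed: int = 0
                    ) -> tuple[ForceCurve, ForceCurveTruth]:
    """Forward-generate a Hertzian approach curve.

    The baseline spans [0, contact_offset_nm) in z; beyond contact the
    indentation depth ramps linearly to ``delta_max_nm`` and the piezo
    position follows z = delta + d + z_contact with cantilever deflection
    d = F/k.  Depths are truncated where the Hertz force would exceed the
    ``max_force_uN`` instrument cap.  Gaussian deflection noise of s.d.
    ``noise_sigma_nm`` is added throughout.
    """
    if E_MPa <= 0 or r_tip_nm <= 0 or k_N_per_m <= 0:
        raise ValueError("material and probe parameters must be positive")
    if noise_sigma_nm < 0:
        raise ValueError("noise sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    # enforce the instrument load cap by truncating the depth ramp
    f_at_max = hertz_force(delta_max_nm, E_MPa, nu, r_tip_nm)
    if f_at_max > max_force_uN:
        delta_max_nm = float(
            (max_force_uN / f_at_max) ** (2.0 / 3.0) * delta_max_nm)
    delta = np.linspace(0.0, delta_max_nm, n_contact)
    force = hertz_force(delta, E_MPa, nu, r_tip_nm)      # uN
    d_contact = force / k_N_per_m * 1.0e3                # nm
    z_contact_seg = delta + d_contact + contact_offset_nm

    z_base = np.linspace(0.0, contact_offset_nm, n_baseline, endpoint=False)
    z = np.concatenate([z_base, z_contact_seg])
    d = np.concatenate([np.zeros(n_baseline), d_contact])
    if noise_sigma_nm > 0:
        d = d + rng.normal(0.0, noise_sigma_nm, size=d.size)
    curve = ForceCurve(z=z, d=d, k=k_N_per_m, r_tip=r_tip_nm,
                       label=label, condition=condition)
    truth = ForceCurveTruth(E_MPa=E_MPa, nu=nu, r_tip_nm=r_tip_nm,
                            k_N_per_m=k_N_per_m, contact_index=n_baseline,
                            z_contact_nm=contact_offset_nm,
                            delta_max_nm=delta_max_nm)
    return curve, truth


@dataclass
class SceneTruth:
    centers: np.ndarray      # (n, 2) row/col px
    diameters_px: np.ndarray
    um_per_px: float


def gen_particle_images(n: int, diameters_px, *, shape=(512, 512),
                        um_per_px: float = 1.0, blur_sigma: float = 1.0,
                        noise_sigma: float = 0.0, margin: int = 4,
                        max_tries: int = 10000, seed: int = 0
                        ) -> tuple[np.ndarray, SceneTruth]:
    """Render non-overlapping bright discs on a dark frame.

    ``diameters_px`` is a scalar or length-n sequence.  Disc centers are
    drawn by rejection sampling (overlap and border exclusion); exceeding
    ``max_tries`` raises with a suggestion to enlarge the frame.  The
    frame is float in [0, 1] after Gaussian blur and additive noise.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    diam = np.broadcast_to(np.asarray(diameters_px, dtype=float), (n,)).copy()
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    centers: list[tuple[float, float]] = []
    for i in range(n):
        r = diam[i] / 2.0
        if 2 * r + 2 * margin > min(shape):
            raise ValueError("particle does not fit in the frame")
        placed = False
        for _ in range(max_tries):
            row = rng.uniform(r + margin, shape[0] - r - margin)
            col = rng.uniform(r + margin, shape[1] - r - margin)
            ok = all((row - cr) ** 2 + (col - cc) ** 2
                     > (r + diam[j] / 2.0 + margin) ** 2
                     for j, (cr, cc) in enumerate(centers))
            if ok:
                centers.append((row, col))
                rr, cc = draw_disk((row, col), r, shape=shape)
                img[rr, cc] = 1.0
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place all particles without "
                               "overlap; use a larger frame or fewer/"
                               "smaller particles")
    if blur_sigma > 0:
        img = gaussian(img, sigma=blur_sigma, preserve_range=True)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = SceneTruth(centers=np.array(centers).reshape(-1, 2),
                       diameters_px=diam, um_per_px=um_per_px)
    return img, truth


def gen_dipa_population(mean_um: float, sd_um: float, n: int,
                        seed: int = 0) -> np.ndarray:
    """Truncated-normal (at zero) sample of n particle diameters in um."""
    if mean_um <= 0 or sd_um < 0 or n < 1:
        raise ValueError("require mean > 0, sd >= 0, n >= 1")
    if sd_um == 0:
        return np.full(n, mean_um)
    a = (0.0 - mean_um) / sd_um
    rng = np.random.default_rng(seed)
    return truncnorm.rvs(a, np.inf, loc=mean_um, scale=sd_um, size=n,
                         random_state=rng)


def gen_stimulus_sequence(kind: str, *, levels=None,
                          segment_duration_s: float = 30.0,
                          background_KCl_mM: float = 10.0,
                          edta_mM: float = 10.0, ca_mM: float = 100.0
                          ) -> list[tuple[IonicEnvironment, float]]:
    """Environment schedules for the two stimulus protocols.

    ``pH_cycle`` steps the bath pH (default 2 -> 12 -> 2) at constant
    background salt; ``cation_edta`` holds pH 7 and adds CaCl2 (default
    100 mM) then EDTA (default 10 mM) on top of the calcium.  Custom
    ``levels`` override the defaults: pH values for pH_cycle, or
    (ca_mM, edta_mM) pairs for cation_edta.
    """
    if kind == "pH_cycle":
        phs = list(levels) if levels is not None else [2.0, 12.0, 2.0]
        if not phs:
            raise ValueError("empty stimulus levels")
        return [(environment(ph, KCl=background_KCl_mM), segment_duration_s)
                for ph in phs]
    if kind == "cation_edta":
        steps = (list(levels) if levels is not None
                 else [(0.0, 0.0), (ca_mM, 0.0), (ca_mM, edta_mM)])
        if not steps:
            raise ValueError("empty stimulus levels")
        out = []
        for ca, edta in steps:
            env = environment(7.0, KCl=background_KCl_mM, CaCl2=ca,
                              chelator_mM=edta)
            out.append((env, segment_duration_s))
        return out
    raise ValueError(f"unknown stimulus kind {kind!r}")
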