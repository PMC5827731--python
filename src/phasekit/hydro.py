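"""Hydrodynamics: PFG-NMR diffusion fits, Stokes–Einstein radii, and AUC algebra.

Pulsed-field-gradient NMR measures translational diffusion through the
Stejskal–Tanner attenuation of the signal with gradient strength g:

    ln(I/I0) = −D · ϒ² g² δ² (Δ − δ/3)

with ϒ the ¹H gyromagnetic ratio, δ the gradient duration and Δ the diffusion
delay.  :func:`fit_diffusion` fits all replicates as a single group by linear
least squares through the origin (the equation has no intercept); a
free-intercept diagnostic mode reports the deviation instead.  The diffusion
coefficient converts to a hydrodynamic radius via Stokes–Einstein,
R_H = kT/(6πηD).  When gradients are recorded as percentages of an unknown
amplifier maximum, :func:`calibrate_gradient` solves for the maximum gradient
strength that makes a reference sample of known R_H come out right.

For sedimentation-velocity AUC, only the algebraic size-and-shape relations
are provided: f = M(1 − v̄ρ)/(N_A·s) and f₀ = 6πη·R₀ with R₀ the radius of
the compact sphere of the same anhydrous mass, giving the frictional ratio
f/f₀.  No Lamm-equation inversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants

__all__ = [
    "GAMMA_1H",
    "DEFAULT_CONDITIONS",
    "DiffusionDecay",
    "DiffusionFit",
    "HydroConditions",
    "SedimentationSpecies",
    "fit_diffusion",
    "stokes_einstein",
    "stokes_einstein_d",
    "calibrate_gradient",
    "frictional_ratio",
    "stejskal_tanner_attenuation",
]

#: ¹H gyromagnetic ratio, rad s⁻¹ T⁻¹.
GAMMA_1H = 2.675222e8

_K_B = constants.Boltzmann
_N_A = constants.Avogadro
_SVEDBERG = 1e-13  # s


@dataclass(frozen=True)
class HydroConditions:
    """Temperature and solvent viscosity for hydrodynamic conversions.

    Defaults are 25 °C water (298.15 K, 8.9e-4 Pa·s).
    """

    temperature_k: float = 298.15
    viscosity_pa_s: float = 8.9e-4

    def __post_init__(self) -> None:
        if self.temperature_k <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("temperature and viscosity must be positive")


DEFAULT_CONDITIONS = HydroConditions()


@dataclass(frozen=True)
class DiffusionDecay:
    """A Stejskal–Tanner decay series (replicates concatenated).

    ``gradients`` is in T/m, or as fractions of ``g_max`` when given in
    percent (use :meth:`from_percent`).  ``intensity`` and ``i0`` are signal
    amplitudes; δ and Δ in seconds.
    """

    gradients_t_per_m: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)
    i0: float
    delta_s: float  # gradient duration δ
    big_delta_s: float  # diffusion delay Δ
    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        g = np.asarray(self.gradients_t_per_m, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if g.shape != y.shape or g.ndim != 1:
            raise ValueError("gradients and intensities must be 1-D arrays of equal length")
        if np.any(g < 0):
            raise ValueError("gradient strengths must be >= 0")
        if np.any(y <= 0) or self.i0 <= 0:
            raise ValueError("intensities must be positive")
        if not (0 < self.delta_s < self.big_delta_s):
            raise ValueError("need 0 < δ < Δ")
        object.__setattr__(self, "gradients_t_per_m", g)
        object.__setattr__(self, "intensity", y)

    @classmethod
    def from_percent(
        cls,
        percent: np.ndarray,
        g_max_t_per_m: float,
        intensity: np.ndarray,
        i0: float,
        delta_s: float,
        big_delta_s: float,
        gamma: float = GAMMA_1H,
    ) -> "DiffusionDecay":
        return cls(
            gradients_t_per_m=np.asarray(percent, dtype=float) / 100.0 * g_max_t_per_m,
            intensity=intensity, i0=i0, delta_s=delta_s, big_delta_s=big_delta_s, gamma=gamma,
        )

    def b_values(self) -> np.ndarray:
        """Stejskal–Tanner b factors ϒ²g²δ²(Δ − δ/3), s/m²."""
        return (
            self.gamma**2
            * self.gradients_t_per_m**2
            * self.delta_s**2
            * (self.big_delta_s - self.delta_s / 3.0)
        )


def stejskal_tanner_attenuation(
    d_m2_per_s: float,
    gradients_t_per_m: np.ndarray,
    delta_s: float,
    big_delta_s: float,
    gamma: float = GAMMA_1H,
) -> np.ndarray:
    """Forward model I/I0 = exp(−D·ϒ²g²δ²(Δ − δ/3))."""
    g = np.asarray(gradients_t_per_m, dtype=float)
    b = gamma**2 * g**2 * delta_s**2 * (big_delta_s - delta_s / 3.0)
    return np.exp(-d_m2_per_s * b)


@dataclass(frozen=True)
class DiffusionFit:
    d_m2_per_s: float
    d_stderr: float
    residuals: np.ndarray = field(repr=False)
    intercept: float | None = None  # only in the free-intercept diagnostic mode
    flagged: bool = False  # negative D or non-monotone decay beyond noise


def fit_diffusion(decay: DiffusionDecay, free_intercept: bool = False) -> DiffusionFit:
    """Group fit of ln(I/I0) vs b = ϒ²g²δ²(Δ − δ/3) through the origin.

    All points (replicates included) enter one least-squares fit; the slope
    is −D and its standard error comes from the grouped residuals.  With
    ``free_intercept=True`` an intercept is also fit as a diagnostic for
    normalization errors; the Stejskal–Tanner model itself has none.
    """
    if np.unique(decay.gradients_t_per_m).size < 3:
        raise ValueError("need >= 3 distinct gradient strengths")
    b = decay.b_values()
    y = np.log(decay.intensity / decay.i0)
    n = y.size
    if free_intercept:
        x_mat = np.column_stack([b, np.ones_like(b)])
        coef, *_ = np.linalg.lstsq(x_mat, y, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        resid = y - x_mat @ coef
        dof = max(n - 2, 1)
        cov = np.linalg.inv(x_mat.T @ x_mat) * np.sum(resid**2) / dof
        stderr = float(np.sqrt(cov[0, 0]))
    else:
        slope = float(np.sum(b * y) / np.sum(b * b))
        intercept = None
        resid = y - slope * b
        dof = max(n - 1, 1)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / np.sum(b * b)))

    d = -slope
    flagged = d < 0
    # non-monotone decay beyond noise: mean intensity should not rise with g
    order = np.argsort(decay.gradients_t_per_m)
    ys = y[order]
    if n >= 4 and np.any(np.diff(ys) > 3.0 * max(np.std(resid), 1e-15)):
        flagged = True
    return DiffusionFit(
        d_m2_per_s=d, d_stderr=stderr, residuals=resid, intercept=intercept, flagged=flagged
    )


def stokes_einstein(d_m2_per_s: float, cond: HydroConditions = DEFAULT_CONDITIONS) -> float:
    """Hydrodynamic radius R_H = kT/(6πηD), in metres."""
    if d_m2_per_s <= 0:
        raise ValueError("D must be positive")
    return _K_B * cond.temperature_k / (6.0 * np.pi * cond.viscosity_pa_s * d_m2_per_s)


def stokes_einstein_d(rh_m: float, cond: HydroConditions = DEFAULT_CONDITIONS) -> float:
    """Inverse relation: D = kT/(6πηR_H)."""
    if rh_m <= 0:
        raise ValueError("R_H must be positive")
    return _K_B * cond.temperature_k / (6.0 * np.pi * cond.viscosity_pa_s * rh_m)


def calibrate_gradient(
    percent: np.ndarray,
    intensity: np.ndarray,
    i0: float,
    delta_s: float,
    big_delta_s: float,
    reference_rh_m: float,
    cond: HydroConditions = DEFAULT_CONDITIONS,
    gamma: float = GAMMA_1H,
) -> float:
    """Solve for the 100% gradient strength from a reference of known R_H.

    The decay is recorded at gradient fractions of an unknown maximum g_max.
    Fitting ln(I/I0) against b'(g_max=1) = ϒ²(frac·1)²δ²(Δ−δ/3) gives a slope
    −D·g_max²; requiring the diffusion coefficient to equal the
    Stokes–Einstein value for ``reference_rh_m`` yields
    g_max = sqrt(D_apparent/D_reference).
    """
    frac = np.asarray(percent, dtype=float) / 100.0
    y = np.log(np.asarray(intensity, dtype=float) / i0)
    if np.unique(frac).size < 3:
        raise ValueError("need >= 3 distinct gradient fractions")
    b_unit = gamma**2 * frac**2 * delta_s**2 * (big_delta_s - delta_s / 3.0)
    slope = float(np.sum(b_unit * y) / np.sum(b_unit * b_unit))  # = −D·g_max²
    if slope >= 0:
        raise ValueError("degenerate decay: no attenuation with gradient strength")
    d_ref = stokes_einstein_d(reference_rh_m, cond)
    return float(np.sqrt(-slope / d_ref))


@dataclass(frozen=True)
class SedimentationSpecies:
    """A sedimenting species: coefficient s (Svedberg), molar mass M (Da), v̄, ρ."""

    s_svedberg: float
    molar_mass_da: float
    vbar_ml_per_g: float = 0.73
    solvent_density_g_per_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.s_svedberg <= 0 or self.molar_mass_da <= 0:
            raise ValueError("s and M must be positive")
        if 1.0 - self.vbar_ml_per_g * self.solvent_density_g_per_ml <= 0:
            raise ValueError("non-sedimenting: buoyancy factor (1 − v̄ρ) <= 0")


def frictional_ratio(
    species: SedimentationSpecies, cond: HydroConditions = DEFAULT_CONDITIONS
) -> float:
    """Frictional ratio f/f₀ from (s, M, v̄, ρ) and solvent conditions.

    f = M(1 − v̄ρ)/(N_A·s);  f₀ = 6πη·R₀,  R₀ = (3Mv̄/(4πN_A))^(1/3).
    Units: M in g/mol, v̄ in mL/g, ρ in g/mL, s in Svedberg (10⁻¹³ s); the
    sphere radius works in cm with η converted to poise (1 Pa·s = 10 P).
    """
    m = species.molar_mass_da  # g/mol
    buoy = 1.0 - species.vbar_ml_per_g * species.solvent_density_g_per_ml
    s = species.s_svedberg * _SVEDBERG
    f = m * buoy / (_N_A * s)  # g/s (cgs friction)
    r0_cm = (3.0 * m * species.vbar_ml_per_g / (4.0 * np.pi * _N_A)) ** (1.0 / 3.0)
    eta_poise = cond.viscosity_pa_s * 10.0
    f0 = 6.0 * np.pi * eta_poise * r0_cm
    return float(f / f0)


def sedimentation_coefficient(
    molar_mass_da: float,
    ff0: float,
    vbar_ml_per_g: float = 0.73,
    solvent_density_g_per_ml: float = 1.0,
    cond: HydroConditions = DEFAULT_CONDITIONS,
) -> float:
    """Forward relation: s (Svedberg) for a species of mass M and shape f/f₀."""
    if ff0 < 1.0:
        raise ValueError("f/f0 must be >= 1")
    buoy = 1.0 - vbar_ml_per_g * solvent_density_g_per_ml
    if buoy <= 0:
        raise ValueError("non-sedimenting: buoyancy factor (1 − v̄ρ) <= 0")
    r0_cm = (3.0 * molar_mass_da * vbar_ml_per_g / (4.0 * np.pi * _N_A)) ** (1.0 / 3.0)
    f = ff0 * 6.0 * np.pi * cond.viscosity_pa_s * 10.0 * r0_cm
    s = molar_mass_da * buoy / (_N_A * f)
    return s / _SVEDBERG
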