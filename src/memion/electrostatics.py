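"""Measurement model for boundary-potential experiments on planar bilayers.

Four pieces fit together:

* **Gouy-Chapman/Grahame**: the diffuse-layer surface potential psi0 of a
  charged plane in a 1:1 electrolyte,
  ``psi0 = (2RT/F) asinh(sigma / sqrt(8 eps0 epsr R T c))``.
* **Self-consistent Langmuir adsorption**: a charged surfactant adsorbs
  with a Langmuir isotherm whose subsurface concentration carries the
  Boltzmann factor of the surface potential it itself creates; the fixed
  point gives the boundary-potential change vs bulk concentration.
* **Inner-field compensation (IFC)**: membrane capacitance vs applied
  voltage is a parabola (electrostriction); its minimum sits at the
  intramembrane potential Phi_in.
* **Nonactin conductance**: a change in the electrostatic barrier for the
  monovalent-cation carrier changes conductance by a Boltzmann factor,
  ``dPhi_b = (RT/F) ln(G0/G)`` (positive adsorbed charge raises the
  barrier and lowers G).

Units: concentrations mol/L (bulk salt) and umol/L (surfactant), charge
densities e/nm^2, potentials mV, temperature K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import constants
from scipy.optimize import least_squares

from .errors import FitError, NumericalError, RangeError

R = constants.R                     # J/(mol K)
F = constants.value("Faraday constant")   # C/mol
EPS0 = constants.epsilon_0          # F/m
E_CHARGE = constants.e              # C

#: e/nm^2 -> C/m^2
_SIGMA_SI = E_CHARGE / 1e-18


@dataclass
class ElectrolyteConditions:
    salt_concentration: float = 0.020      # mol/L, 1:1 electrolyte
    temperature: float = 295.0             # K
    relative_permittivity: float = 80.0
    ion_valence: int = 1

    def __post_init__(self) -> None:
        if self.salt_concentration <= 0 or self.temperature <= 0:
            raise ValueError("concentration and temperature must be positive")


@dataclass
class AdsorptionParams:
    binding_constant: float            # K, 1/M
    max_site_density: float            # Gamma_max, molecules/nm^2
    surfactant_valence: int            # +1 cationic, -1 anionic

    def __post_init__(self) -> None:
        if self.binding_constant <= 0 or self.max_site_density <= 0:
            raise ValueError("K and Gamma_max must be positive")
        if self.surfactant_valence not in (-1, 1):
            raise ValueError("surfactant valence must be +/-1")


@dataclass
class BoundaryPotentialCurve:
    concentrations_uM: np.ndarray
    delta_phi_mV: np.ndarray
    method: str = "MODEL"              # IFC | NONACTIN | MODEL

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.delta_phi_mV = np.asarray(self.delta_phi_mV, dtype=float)
        if np.any(np.diff(self.concentrations_uM) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.delta_phi_mV)):
            raise ValueError("potentials must be finite")


@dataclass
class IFCScan:
    applied_voltage_mV: np.ndarray
    capacitance: np.ndarray            # arbitrary units
    c0: Optional[float] = None         # capacitance at zero inner field
    alpha: Optional[float] = None      # 1/mV^2 electrostriction coefficient
    phi_in_estimate: Optional[float] = None

    def __post_init__(self) -> None:
        self.applied_voltage_mV = np.asarray(self.applied_voltage_mV, dtype=float)
        self.capacitance = np.asarray(self.capacitance, dtype=float)
        if np.any(self.capacitance <= 0):
            raise ValueError("capacitance must be positive")


# ---------------------------------------------------------------------------
# Gouy-Chapman / Grahame
# ---------------------------------------------------------------------------

def _grahame_prefactors(cond: ElectrolyteConditions):
    rt = R * cond.temperature
    c_si = cond.salt_concentration * 1000.0                 # mol/m^3
    denom = np.sqrt(8.0 * EPS0 * cond.relative_permittivity * rt * c_si)
    return 2.0 * rt / F, denom                              # (V), (C/m^2)


def grahame_psi(sigma: float, cond: ElectrolyteConditions) -> float:
    """Surface potential psi0 (mV) of charge density sigma (e/nm^2)."""
    sigma = np.asarray(sigma, dtype=float)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("sigma must be finite")
    pref, denom = _grahame_prefactors(cond)
    psi_v = pref * np.arcsinh(sigma * _SIGMA_SI / denom)
    return psi_v * 1000.0


def grahame_sigma(psi_mV: float, cond: ElectrolyteConditions) -> float:
    """Inverse of :func:`grahame_psi`: sigma (e/nm^2) from psi0 (mV)."""
    pref, denom = _grahame_prefactors(cond)
    sigma_si = denom * np.sinh(np.asarray(psi_mV, dtype=float) / 1000.0 / pref)
    return sigma_si / _SIGMA_SI


def debye_huckel_psi(sigma: float, cond: ElectrolyteConditions) -> float:
    """Linearised (small-sigma) surface potential, sigma/(eps0 epsr kappa), mV."""
    rt = R * cond.temperature
    c_si = cond.salt_concentration * 1000.0
    kappa = np.sqrt(2.0 * F ** 2 * c_si / (EPS0 * cond.relative_permittivity * rt))
    psi_v = np.asarray(sigma, dtype=float) * _SIGMA_SI / (
        EPS0 * cond.relative_permittivity * kappa
    )
    return psi_v * 1000.0


# ---------------------------------------------------------------------------
# Self-consistent Langmuir adsorption
# ---------------------------------------------------------------------------

def _solve_psi(
    c_molar: float,
    params: AdsorptionParams,
    cond: ElectrolyteConditions,
    feedback: bool,
    tol_mV: float = 1e-6,
    max_iter: int = 10_000,
) -> float:
    """Fixed point of psi = Grahame(z * Gamma(c * exp(-z F psi / RT)))."""
    z = params.surfactant_valence
    rt_f_mV = R * cond.temperature / F * 1000.0

    def step(psi_mV: float) -> float:
        if feedback:
            c_s = c_molar * np.exp(-z * psi_mV / rt_f_mV)
        else:
            c_s = c_molar
        gamma = params.max_site_density * params.binding_constant * c_s / (
            1.0 + params.binding_constant * c_s
        )
        return grahame_psi(z * gamma, cond)

    psi = 0.0
    damping = 1.0
    resid = np.inf
    for _ in range(max_iter):
        target = step(psi)
        new_resid = abs(target - psi)
        if new_resid < tol_mV:
            return target
        if new_resid > resid:           # oscillation: damp harder
            damping *= 0.5
        resid = new_resid
        psi = psi + damping * (target - psi)
    raise NumericalError(
        f"adsorption fixed point did not converge in {max_iter} iterations "
        f"(last residual {resid:.3g} mV)"
    )


def adsorption_curve(
    params: AdsorptionParams,
    cond: ElectrolyteConditions,
    concentrations_uM: Sequence[float],
    feedback: bool = True,
) -> BoundaryPotentialCurve:
    """Model boundary-potential change vs bulk surfactant concentration.

    With ``feedback=True`` (default) the subsurface concentration carries
    the Boltzmann factor of the self-generated surface potential; with
    ``feedback=False`` the naive Langmuir + Grahame composition is used.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    phi = np.array(
        [_solve_psi(c * 1e-6, params, cond, feedback) for c in conc]
    )
    return BoundaryPotentialCurve(
        concentrations_uM=conc, delta_phi_mV=phi, method="MODEL"
    )


@dataclass
class AdsorptionFit:
    params: Optional[AdsorptionParams]
    residual_norm: float
    converged: bool
    identifiable: bool
    message: str = ""


def fit_adsorption(
    curve: BoundaryPotentialCurve,
    cond: ElectrolyteConditions,
    valence: int,
    feedback: bool = True,
) -> AdsorptionFit:
    """Least-squares fit of (K, Gamma_max) to a boundary-potential curve.

    Optimises in log-parameters for positivity.  A flat curve (spread of
    |dPhi| below 1 mV) is flagged unidentifiable and no fit is attempted.
    """
    conc = curve.concentrations_uM
    phi = curve.delta_phi_mV
    if len(conc) < 4:
        raise FitError("need at least 4 points to fit (K, Gamma_max)")
    if float(np.ptp(np.abs(phi))) < 1.0 and float(np.max(np.abs(phi))) < 1.0:
        return AdsorptionFit(
            params=None, residual_norm=float(np.linalg.norm(phi)),
            converged=False, identifiable=False,
            message="flat curve: (K, Gamma_max) unidentifiable",
        )

    # initial guess: Gamma_max from the largest potential, K from mid-range c
    sigma_guess = abs(float(grahame_sigma(np.max(np.abs(phi)), cond)))
    gamma0 = max(sigma_guess, 1e-4)
    k0 = 1.0 / (np.median(conc) * 1e-6)

    def residuals(x):
        k, gmax = np.exp(x)
        p = AdsorptionParams(
            binding_constant=k, max_site_density=gmax, surfactant_valence=valence
        )
        model = adsorption_curve(p, cond, conc, feedback=feedback).delta_phi_mV
        return model - phi

    result = least_squares(
        residuals, x0=np.log([k0, gamma0]), method="lm", xtol=1e-12, ftol=1e-12
    )
    k_hat, gmax_hat = np.exp(result.x)
    return AdsorptionFit(
        params=AdsorptionParams(
            binding_constant=float(k_hat),
            max_site_density=float(gmax_hat),
            surfactant_valence=valence,
        ),
        residual_norm=float(np.linalg.norm(result.fun)),
        converged=bool(result.success),
        identifiable=True,
        message=result.message,
    )


# ---------------------------------------------------------------------------
# Inner field compensation
# ---------------------------------------------------------------------------

@dataclass
class PhiInEstimate:
    phi_in_mV: float
    stderr_mV: float
    c0: float
    alpha: float


def estimate_phi_in(scan: IFCScan) -> PhiInEstimate:
    """Locate the capacitance minimum of an IFC voltage scan.

    Fits ``C(U) = C0 (1 + alpha (U - Phi_in)^2)`` — a quadratic in U — and
    returns the vertex with its standard error (delta method on the
    polynomial covariance).  The minimum must lie inside the scanned range.
    """
    u = scan.applied_voltage_mV
    c = scan.capacitance
    if len(u) < 5:
        raise RangeError("need at least 5 scan points bracketing the minimum")
    coef, cov = np.polyfit(u, c, 2, cov=True)
    a, b, c0_term = coef
    if a <= 0:
        raise RangeError("capacitance scan has no minimum (non-convex fit)")
    phi_in = -b / (2.0 * a)
    if not (u.min() <= phi_in <= u.max()):
        raise RangeError(
            f"capacitance minimum at {phi_in:.1f} mV lies outside the scanned "
            f"range [{u.min():.1f}, {u.max():.1f}] mV"
        )
    # delta method: d(phi)/d(a,b) = (b/(2a^2), -1/(2a))
    grad = np.array([b / (2.0 * a ** 2), -1.0 / (2.0 * a), 0.0])
    var = float(grad @ cov @ grad)
    c_min = c0_term - b ** 2 / (4.0 * a)
    alpha = a / c_min if c_min > 0 else float("nan")
    scan.c0 = float(c_min)
    scan.alpha = float(alpha)
    scan.phi_in_estimate = float(phi_in)
    return PhiInEstimate(
        phi_in_mV=float(phi_in),
        stderr_mV=float(np.sqrt(max(var, 0.0))),
        c0=float(c_min),
        alpha=float(alpha),
    )


# ---------------------------------------------------------------------------
# Nonactin conductance
# ---------------------------------------------------------------------------

def nonactin_delta_phi(G: float, G0: float, T: float = 295.0) -> float:
    """Boundary-potential change (mV) from nonactin conductance ratio.

    Monovalent-cation carrier convention: positively charged adsorbates
    raise the barrier and lower the conductance, so
    ``dPhi_b = (RT/F) ln(G0 / G)``.
    """
    G = np.asarray(G, dtype=float)
    G0 = np.asarray(G0, dtype=float)
    if np.any(G <= 0) or np.any(G0 <= 0):
        raise ValueError("conductances must be positive")
    return float(R * T / F * 1000.0 * np.log(G0 / G))
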