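"""Model fits for domain-boundary kinetics and line-tension temperature scaling.

Two models are fitted here.  The first is the mono-exponential growth of the
total phase-boundary contour length after actin filaments adhere to an
already phase-separated membrane,

    L(t) = L_final * (1 - exp(-(t - t0) / tau)),

with the lag time ``t0`` held fixed (default 1 min, the time at which the
first domain deformations become visible) so that exactly two parameters
(L_final, tau) are free.

The second is the temperature dependence of the final contour-length change.
The line tension gamma between the liquid-ordered (Lo) and liquid-disordered
(Ld) phases falls approximately linearly with temperature,
gamma ~ gamma0 * (TC - T) / TC, where TC is the critical temperature at
which it extrapolates to zero.  If actin binding deposits a
temperature-independent boundary energy E = gamma * L, the final contour
length follows

    L(T) = A * TC / (TC - T),        A = E / gamma0,

where the single amplitude A is the contour-length change extrapolated to
T = 0 degC.  The temperature scale is Celsius throughout: the model is
anchored at T = 0 degC (where L = A) with TC = 37 degC, the miscibility
transition temperature of the 1:2:1 DOPC:DPPC:cholesterol mixture.

A small desk calculation is also provided: the ratio of the inter-phase
lipid transfer energy to the boundary-elongation energy, which compares the
energetic cost for a single saturated lipid to cross the phase boundary with
the cost of lengthening the boundary by one lipid diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "KineticFit",
    "LineTensionFit",
    "EnergyRatioInputs",
    "monoexponential",
    "fit_monoexponential",
    "line_tension_model",
    "fit_line_tension",
    "energy_ratio",
    "BOLTZMANN_J_PER_K",
]

#: Boltzmann constant in J/K (exact, SI 2019).
BOLTZMANN_J_PER_K = 1.380649e-23


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from every start."""


@dataclass(frozen=True)
class KineticFit:
    """Result of a mono-exponential contour-growth fit."""

    L_final: float  # um
    tau: float  # min
    t0: float  # min, fixed input
    L_final_stderr: float
    tau_stderr: float
    residual_rms: float  # um
    tau_at_bound: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        return monoexponential(np.asarray(t, dtype=float), self.L_final, self.tau, self.t0)


@dataclass(frozen=True)
class LineTensionFit:
    """Result of fitting L(T) = A * TC / (TC - T)."""

    A: float  # um, contour-length change extrapolated to T = 0 degC (= E/gamma0)
    A_stderr: float
    TC: float  # degC, fixed input
    temperatures: tuple = field(default=())
    residuals: tuple = field(default=())  # um, observed - predicted
    weighted: bool = False

    def predict(self, T: np.ndarray) -> np.ndarray:
        return line_tension_model(np.asarray(T, dtype=float), self.A, self.TC)


@dataclass(frozen=True)
class EnergyRatioInputs:
    """Physical inputs for the transfer-vs-elongation energy comparison.

    line_tension_pN
        Lo/Ld line tension in pN (order 1 pN for DOPC:DPPC:cholesterol).
    elongation_nm
        Boundary elongation per transferred lipid, in nm (~one lipid diameter).
    transfer_energy_kBT
        Free energy to move one saturated lipid between phases, in kB*T units.
    temperature_K
        Absolute temperature at which kB*T is evaluated (room temperature
        of the contraction experiments, ~24 degC = 297.15 K).
    """

    line_tension_pN: float = 1.0
    elongation_nm: float = 1.0
    transfer_energy_kBT: float = 1.5
    temperature_K: float = 297.15

    def __post_init__(self):
        for name in ("line_tension_pN", "elongation_nm", "transfer_energy_kBT", "temperature_K"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def monoexponential(t, L_final, tau, t0=1.0):
    """Saturating growth L_final * (1 - exp(-(t - t0)/tau)); 0 for t < t0."""
    t = np.asarray(t, dtype=float)
    return L_final * -np.expm1(-np.clip(t - t0, 0.0, None) / tau)


def line_tension_model(T, A, TC=37.0):
    """Final contour-length change L(T) = A * TC / (TC - T), Celsius scale."""
    T = np.asarray(T, dtype=float)
    return A * TC / (TC - T)


def _initial_guess(t, L, t0):
    """Closed-form initialization: plateau from the max, tau from a
    log-linear regression of log(1 - L/L0) on the early rising points."""
    L0 = float(np.max(L)) * 1.05
    frac = 1.0 - L / L0
    good = (frac > 0.05) & (t > t0)
    if good.sum() >= 2:
        slope = np.polyfit(t[good] - t0, np.log(frac[good]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else np.ptp(t) / 3.0
    else:
        tau0 = np.ptp(t) / 3.0
    tau0 = float(np.clip(tau0, 1e-3, 10 * max(np.ptp(t), 1.0)))
    return max(L0, 1e-9), tau0


def fit_monoexponential(times_min, lengths_um, t0: float = 1.0) -> KineticFit:
    """Least-squares fit of the two free parameters (L_final, tau).

    Deterministic multi-start Levenberg-Marquardt/TRF: the closed-form
    initialization is perturbed by factors {0.5, 1, 2} on each parameter and
    the best converged optimum is kept, which makes the fit reproducible and
    robust to shallow local minima on noisy series.

    Parameters
    ----------
    times_min, lengths_um
        Time points (min) and total contour-length change (um).
    t0
        Fixed lag time in minutes.

    Returns
    -------
    KineticFit with parameter standard errors from the covariance at the
    optimum and the RMS of the residuals.
    """
    t = np.asarray(times_min, dtype=float)
    L = np.asarray(lengths_um, dtype=float)
    if t.ndim != 1 or t.shape != L.shape:
        raise ValueError("times and lengths must be 1-D arrays of equal length")
    if t.size < 3:
        raise ValueError("need at least 3 data points to fit 2 parameters")
    if np.any(t < t0):
        raise ValueError(f"all time points must be >= t0 = {t0}")
    order = np.argsort(t)
    t, L = t[order], L[order]

    L0, tau0 = _initial_guess(t, L, t0)
    bounds = ([1e-12, 1e-6], [np.inf, np.inf])
    best = None
    diagnostics = []
    for fL in (1.0, 0.5, 2.0):
        for ftau in (1.0, 0.5, 2.0):
            try:
                popt, pcov = optimize.curve_fit(
                    lambda tt, Lf, tau: monoexponential(tt, Lf, tau, t0),
                    t, L, p0=[L0 * fL, tau0 * ftau], bounds=bounds, maxfev=20000,
                )
            except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
                diagnostics.append(str(exc))
                continue
            ssr = float(np.sum((L - monoexponential(t, *popt, t0)) ** 2))
            if best is None or ssr < best[0] - 1e-12:
                best = (ssr, popt, pcov)
    if best is None:
        raise FitError("mono-exponential fit did not converge from any start: "
                       + "; ".join(diagnostics))
    ssr, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    tau_at_bound = bool(popt[1] <= 2e-6)
    return KineticFit(
        L_final=float(popt[0]),
        tau=float(popt[1]),
        t0=float(t0),
        L_final_stderr=float(perr[0]),
        tau_stderr=float(perr[1]),
        residual_rms=float(np.sqrt(ssr / t.size)),
        tau_at_bound=tau_at_bound,
    )


def fit_line_tension(temperatures_C, lengths_um, TC: float = 37.0,
                     weights=None) -> LineTensionFit:
    """Fit the single amplitude A in L(T) = A * TC / (TC - T).

    The model is linear in A, so the unweighted least-squares solution is
    closed form: A = sum(L_i f_i) / sum(f_i^2) with f_i = TC / (TC - T_i).
    An optional inverse-variance weighted mode is available by passing
    per-point weights.

    Parameters
    ----------
    temperatures_C
        Temperatures in degC; every value must be strictly below TC.
    lengths_um
        Final contour-length changes (um) at those temperatures.
    TC
        Critical temperature in degC at which line tension extrapolates to
        zero (default 37, the miscibility temperature of the mixture).
    weights
        Optional nonnegative per-point weights (e.g. 1/sigma^2).

    Returns
    -------
    LineTensionFit with the amplitude A = E/gamma0 (um), its standard error
    from the fit covariance, and per-point residuals.
    """
    T = np.atleast_1d(np.asarray(temperatures_C, dtype=float))
    L = np.atleast_1d(np.asarray(lengths_um, dtype=float))
    if T.shape != L.shape:
        raise ValueError("temperatures and lengths must have equal length")
    if T.size < 1:
        raise ValueError("need at least one (T, L) point")
    if np.any(T >= TC):
        bad = T[T >= TC]
        raise ValueError(f"all temperatures must be < TC = {TC} degC; got {bad.tolist()}")
    f = TC / (TC - T)
    if weights is None:
        w = np.ones_like(f)
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        weighted = True
    denom = float(np.sum(w * f * f))
    A = float(np.sum(w * L * f) / denom)
    resid = L - A * f
    # Standard error from the linear-model covariance; with a single point
    # the residual variance is undefined and the error is reported as 0.
    dof = T.size - 1
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    A_stderr = float(np.sqrt(sigma2 / denom))
    return LineTensionFit(
        A=A, A_stderr=A_stderr, TC=float(TC),
        temperatures=tuple(T.tolist()), residuals=tuple(resid.tolist()),
        weighted=weighted,
    )


def energy_ratio(inputs: EnergyRatioInputs = EnergyRatioInputs()) -> float:
    """Transfer energy over boundary-elongation energy, dimensionless.

    The elongation energy is line_tension * elongation (1 pN * 1 nm =
    1e-21 J), expressed in kB*T at the given temperature, and the ratio is
    transfer_energy / elongation_energy.  With the default inputs (1 pN,
    1 nm, 1.5 kB*T, 297.15 K) the transfer of one DPPC between phases costs
    roughly six times the boundary-elongation energy.
    """
    kBT_J = BOLTZMANN_J_PER_K * inputs.temperature_K
    elongation_J = inputs.line_tension_pN * 1e-12 * inputs.elongation_nm * 1e-9
    return inputs.transfer_energy_kBT * kBT_J / elongation_J
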