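"""Closed-form compartmental concentration models for DCE-MRI kinetics.

The systemic circulation of a gadolinium contrast agent delivered as a
zero-order infusion is described by a linear two-compartment model: arterial
blood (compartment 1, volume ``V1``) exchanges with a peripheral compartment
(rates ``k12``/``k21``) and is cleared with rate ``k10``.  The arterial
concentration ``C1(t)`` is a bi-exponential function of time whose exponents
``lambda1 >= lambda2 > 0`` are the eigenvalues of the exchange system.

Tissue is modelled with the extended Tofts model: the extravascular
extracellular space (EES, compartment 3) is driven one-way by the arterial
curve with fractional rate ``k30`` (``k30 = Ktrans / ve``), and the total
tissue concentration mixes the EES and plasma curves with fractional volumes
``ve`` and ``vb``::

    C_tissue(t) = ve * Ce(t) + vb * Cp(t),    Cp(t) ~ C1(t)

All closed forms are validated against :func:`ode_reference_solution`, an
independent numerical integration of the underlying ODE system.

Units: time in minutes, rates in 1/min, concentrations in mM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    CoincidentRateError,
    DimensionError,
    InvalidInfusionWindowError,
    ModelError,
    OracleFailureError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AifParams",
    "TissueParams",
    "as_time_grid",
    "elapsed_infusion_time",
    "system_eigenvalues",
    "aif_concentration",
    "ees_concentration",
    "tissue_concentration",
    "batch_tissue_concentration",
    "sse_objective",
    "ode_reference_solution",
]

#: relative tolerance below which two exponential rates count as coincident
COINCIDENCE_RTOL = 1e-8
#: relative nudge applied to resolve a near-coincident rate
COINCIDENCE_NUDGE = 1e-6


def as_time_grid(times) -> np.ndarray:
    """Validate and return an acquisition time grid (minutes).

    Requires at least two strictly increasing, non-negative time points.
    """
    t = np.asarray(times, dtype=float).ravel()
    if t.size < 2:
        raise ModelError(f"time grid needs at least 2 points, got {t.size}")
    if not np.all(np.isfinite(t)):
        raise ModelError("time grid contains non-finite values")
    if t[0] < 0:
        raise ModelError("time grid must be non-negative")
    if not np.all(np.diff(t) > 0):
        raise ModelError("time points must be strictly increasing")
    return t


@dataclass(frozen=True)
class AifParams:
    """Systemic two-compartment parameters driving the arterial input function.

    Parameters
    ----------
    r0_over_v1 : float
        Zero-order infusion rate over central volume, treated as a single
        parameter (mM/min).
    k10, k12, k21 : float
        Fractional clearances (1/min); ``k10`` is elimination, ``k12``/``k21``
        exchange with the peripheral compartment.  ``k12`` may be zero
        (decoupled system).
    t0, t1 : float
        Infusion start/end on the acquisition clock (min); fixed protocol
        inputs, not fitted.
    tlag : float
        Delay between the infusion clock and contrast arrival at the
        observation site (min).
    """

    r0_over_v1: float
    k10: float
    k12: float
    k21: float
    t0: float
    t1: float
    tlag: float = 0.0

    def __post_init__(self):
        if self.r0_over_v1 < 0:
            raise ModelError("r0_over_v1 must be non-negative")
        if self.k10 <= 0 or self.k21 <= 0 or self.k12 < 0:
            raise ModelError("rates must satisfy k10 > 0, k21 > 0, k12 >= 0")
        if not self.t1 > self.t0:
            raise InvalidInfusionWindowError(
                f"infusion end t1={self.t1} must exceed start t0={self.t0}"
            )
        if self.t0 < 0 or self.tlag < 0:
            raise ModelError("t0 and tlag must be non-negative")

    @property
    def eigenvalues(self) -> tuple[float, float]:
        """System eigenvalues (lambda1, lambda2), nudged away from coincidence."""
        k10, k12, k21 = _resolved_rates(self.k10, self.k12, self.k21)
        return system_eigenvalues(k10, k12, k21)


@dataclass(frozen=True)
class TissueParams:
    """Per-voxel extended Tofts parameters.

    ``ve`` and ``vb`` are unitless fractional volumes, ``k30`` (1/min) is the
    EES equilibration rate and ``tlag`` (min) the voxel-specific bolus arrival
    delay.  ``ktrans = k30 * ve`` is derived.
    """

    ve: float
    k30: float
    vb: float
    tlag: float = 0.0

    def __post_init__(self):
        if not 0 < self.ve < 1:
            raise ModelError("ve must lie strictly between 0 and 1")
        if not 0 <= self.vb < 1:
            raise ModelError("vb must lie in [0, 1)")
        if self.k30 <= 0:
            raise ModelError("k30 must be positive")
        if self.tlag < 0:
            raise ModelError("tlag must be non-negative")

    @property
    def ktrans(self) -> float:
        """Volume transfer coefficient Ktrans = k30 * ve (1/min)."""
        return self.k30 * self.ve


def elapsed_infusion_time(t, t0: float, t1: float, tlag: float = 0.0):
    """Apparent elapsed infusion time ``tau``.

    ``tau = 0`` for ``t <= t0 + tlag``; ``tau = t - t0 - tlag`` during the
    infusion; ``tau = t1 - t0`` after ``t1 + tlag``.  Accepts scalars or
    arrays.
    """
    if not t1 > t0:
        raise InvalidInfusionWindowError(f"t1={t1} must exceed t0={t0}")
    if tlag < 0:
        raise ModelError("tlag must be non-negative")
    return np.clip(np.asarray(t, dtype=float) - t0 - tlag, 0.0, t1 - t0)


def system_eigenvalues(k10: float, k12: float, k21: float) -> tuple[float, float]:
    """Eigenvalues of the two-compartment exchange system.

    ``lambda_{1,2} = (k10+k12+k21 +/- sqrt((k10+k12+k21)^2 - 4 k10 k21)) / 2``
    with ``lambda1 >= lambda2 > 0``; Vieta: their sum is ``k10+k12+k21`` and
    their product ``k10*k21``.

    Raises
    ------
    CoincidentRateError
        If the discriminant is non-positive or the eigenvalues coincide
        within relative tolerance (the closed forms only cover distinct
        exponents).
    """
    if k10 <= 0 or k21 <= 0 or k12 < 0:
        raise ModelError("rates must satisfy k10 > 0, k21 > 0, k12 >= 0")
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    if disc <= 0 or math.sqrt(disc) < COINCIDENCE_RTOL * s:
        raise CoincidentRateError(
            f"eigenvalues coincide for rates ({k10}, {k12}, {k21})"
        )
    root = math.sqrt(disc)
    return 0.5 * (s + root), 0.5 * (s - root)


def _resolved_rates(k10: float, k12: float, k21: float) -> tuple[float, float, float]:
    """Nudge ``k10`` when the eigenvalues would coincide (measure-zero case)."""
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    if disc <= 0 or math.sqrt(max(disc, 0.0)) < COINCIDENCE_RTOL * s:
        k10 = k10 * (1.0 + COINCIDENCE_NUDGE)
        logger.warning(
            "near-coincident eigenvalues; nudging k10 to %.12g", k10
        )
    return k10, k12, k21


def _separate_k30(k30, lam1: float, lam2: float):
    """Nudge ``k30`` away from either eigenvalue.  Works on scalars or arrays."""
    tol = COINCIDENCE_RTOL * (lam1 + lam2)
    k30 = np.asarray(k30, dtype=float)
    close = (np.abs(k30 - lam1) < tol) | (np.abs(k30 - lam2) < tol)
    if np.any(close):
        logger.warning("k30 within tolerance of an eigenvalue; nudging")
        k30 = np.where(close, k30 * (1.0 + COINCIDENCE_NUDGE), k30)
    return k30 if k30.ndim else float(k30)


def _c1_terms(tau, tshift, lam1, lam2, k21, r0v1):
    """Bi-exponential arterial solution, written exactly as the printed form.

    The ``(1 - e^{lambda tau})`` factor vanishes identically before contrast
    arrival (tau = 0), which enforces causality without branching.
    """
    e1 = (
        (1.0 - np.exp(lam1 * tau))
        * (k21 - lam1)
        * np.exp(-lam1 * tshift)
        / (-lam1 * (lam2 - lam1))
    )
    e2 = (
        (1.0 - np.exp(lam2 * tau))
        * (k21 - lam2)
        * np.exp(-lam2 * tshift)
        / (-lam2 * (lam1 - lam2))
    )
    return r0v1 * (e1 + e2)


def _c3_terms(tau, tshift, lam1, lam2, k30, k21, r0v1):
    """Tri-exponential EES solution driven one-way by the arterial curve."""
    e1 = (
        (1.0 - np.exp(lam1 * tau))
        * (k21 - lam1)
        * np.exp(-lam1 * tshift)
        / (-lam1 * (lam2 - lam1) * (k30 - lam1))
    )
    e2 = (
        (1.0 - np.exp(lam2 * tau))
        * (k21 - lam2)
        * np.exp(-lam2 * tshift)
        / (-lam2 * (lam1 - lam2) * (k30 - lam2))
    )
    e3 = (
        (1.0 - np.exp(k30 * tau))
        * (k21 - k30)
        * np.exp(-k30 * tshift)
        / (-k30 * (lam1 - k30) * (lam2 - k30))
    )
    return k30 * r0v1 * (e1 + e2 + e3)


def aif_concentration(times, p: AifParams) -> np.ndarray:
    """Arterial (plasma) concentration-time course ``C1(t)`` in mM."""
    t = as_time_grid(times)
    k10, k12, k21 = _resolved_rates(p.k10, p.k12, p.k21)
    lam1, lam2 = system_eigenvalues(k10, k12, k21)
    tau = elapsed_infusion_time(t, p.t0, p.t1, p.tlag)
    tshift = t - p.t0 - p.tlag
    return _c1_terms(tau, tshift, lam1, lam2, k21, p.r0_over_v1)


def ees_concentration(times, p: AifParams, k30: float) -> np.ndarray:
    """EES concentration-time course ``Ce(t) = C3(t)`` in mM.

    Satisfies ``dC3/dt = k30 * (C1(t) - C3(t))`` (back-transfer into blood is
    ignored when defining ``C1``).  ``k30`` is nudged slightly if it falls
    within tolerance of either system eigenvalue.
    """
    if k30 <= 0:
        raise ModelError("k30 must be positive")
    t = as_time_grid(times)
    k10, k12, k21 = _resolved_rates(p.k10, p.k12, p.k21)
    lam1, lam2 = system_eigenvalues(k10, k12, k21)
    k30 = _separate_k30(k30, lam1, lam2)
    tau = elapsed_infusion_time(t, p.t0, p.t1, p.tlag)
    tshift = t - p.t0 - p.tlag
    return _c3_terms(tau, tshift, lam1, lam2, k30, k21, p.r0_over_v1)


def tissue_concentration(times, aif: AifParams, tp: TissueParams) -> np.ndarray:
    """Extended Tofts tissue concentration ``ve*Ce(t) + vb*C1(t)`` in mM.

    The voxel-specific ``tp.tlag`` replaces the systemic lag in both the EES
    and plasma terms, shifting the whole input curve to model local bolus
    arrival delay.
    """
    shifted = replace(aif, tlag=tp.tlag)
    c3 = ees_concentration(times, shifted, tp.k30)
    c1 = aif_concentration(times, shifted)
    return tp.ve * c3 + tp.vb * c1


def batch_tissue_concentration(times, aif: AifParams, ve, k30, vb, tlag) -> np.ndarray:
    """Vectorised extended Tofts model for a batch of voxels.

    ``ve, k30, vb, tlag`` are length-B arrays; returns a ``(B, n_f)`` array.
    Elementwise arithmetic is identical to :func:`tissue_concentration`, so a
    single-voxel batch reproduces the scalar path bit for bit.
    """
    t = as_time_grid(times)
    ve = np.atleast_1d(np.asarray(ve, dtype=float))
    k30 = np.atleast_1d(np.asarray(k30, dtype=float))
    vb = np.atleast_1d(np.asarray(vb, dtype=float))
    tlag = np.atleast_1d(np.asarray(tlag, dtype=float))
    k10, k12, k21 = _resolved_rates(aif.k10, aif.k12, aif.k21)
    lam1, lam2 = system_eigenvalues(k10, k12, k21)
    k30 = _separate_k30(k30, lam1, lam2)[:, None]
    tshift = t[None, :] - aif.t0 - tlag[:, None]
    tau = np.clip(tshift, 0.0, aif.t1 - aif.t0)
    c1 = _c1_terms(tau, tshift, lam1, lam2, k21, aif.r0_over_v1)
    c3 = _c3_terms(tau, tshift, lam1, lam2, k30, k21, aif.r0_over_v1)
    return ve[:, None] * c3 + vb[:, None] * c1


def sse_objective(observed, predicted) -> float:
    """Least-squares objective: sum of squared residuals (mM^2)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DimensionError(
            f"observed shape {obs.shape} != predicted shape {pred.shape}"
        )
    r = obs - pred
    return float(np.sum(r * r))


def ode_reference_solution(times, p: AifParams, k30: float):
    """Numerically integrated (C1, C3) series — the validation oracle.

    Integrates the compartment ODE system directly (zero-order input
    ``r0_over_v1`` on ``[t0+tlag, t1+tlag]``, exchange ``k12``/``k21``,
    elimination ``k10``, one-way EES driving ``k30``) with tight tolerances,
    piecewise across the input discontinuities.  Independent of the closed
    forms above by construction.
    """
    t = as_time_grid(times)
    tmax = float(t[-1])
    b0 = p.t0 + p.tlag
    b1 = p.t1 + p.tlag
    ksum = p.k10 + p.k12

    def rhs_for(inp):
        def rhs(_t, y):
            c1, a2, c3 = y
            return (
                inp - ksum * c1 + p.k21 * a2,
                p.k12 * c1 - p.k21 * a2,
                k30 * (c1 - c3),
            )

        return rhs

    out = np.zeros((t.size, 3))
    y = np.zeros(3)
    segments = (
        (0.0, min(b0, tmax), 0.0),
        (min(b0, tmax), min(b1, tmax), p.r0_over_v1),
        (min(b1, tmax), tmax, 0.0),
    )
    for a, b, inp in segments:
        if b <= a:
            continue
        inside = (t > a) & (t <= b)
        t_eval = np.unique(np.append(t[inside], b))
        sol = solve_ivp(
            rhs_for(inp),
            (a, b),
            y,
            t_eval=t_eval,
            method="DOP853",
            rtol=1e-11,
            atol=1e-13,
        )
        if not sol.success:
            raise OracleFailureError(sol.message)
        if np.any(inside):
            # map requested times onto the (unique, sorted) evaluation grid
            pos = np.searchsorted(sol.t, t[inside])
            out[inside] = sol.y[:, pos].T
        y = sol.y[:, -1]
    return out[:, 0], out[:, 2]
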