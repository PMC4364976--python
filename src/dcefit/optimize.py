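"""Bound-constrained Nelder-Mead simplex minimisation, serial and batched.

Box constraints are enforced by an arcsine change of variables rather than
clipping: ``xu = arcsin(2(x - lb)/(ub - lb) - 1)`` maps the box onto an
unconstrained space, and the inverse sine map returns any real vector to the
interior of the box.  The simplex evolves entirely in the unconstrained
space.

Two variants are provided:

* :func:`nelder_mead_serial` — the classic branching algorithm with
  conditional termination, used for the arterial fit and as the reference in
  agreement checks.
* :func:`nelder_mead_batched` — a branch-free, fixed-iteration variant that
  advances many independent problems in lockstep.  All accept/reject
  decisions are evaluated as boolean masks and blended arithmetically, so
  control flow is identical for every problem — the structure that maps onto
  array/GPU backends.  Given the same initial simplex, it reproduces the
  serial vertex sequence exactly.

:func:`two_stage_minimize` chains two batched stages with convergence
culling: problems whose final simplex has collapsed after the first (short)
stage are frozen, and only the remainder is re-minimised from a fresh
simplex seeded at their stage-1 best estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import OutOfBoundsError

logger = logging.getLogger(__name__)

__all__ = [
    "Bounds",
    "FitOutcome",
    "BatchFitResult",
    "to_unconstrained",
    "to_constrained",
    "initial_simplex",
    "nelder_mead_serial",
    "nelder_mead_batched",
    "two_stage_minimize",
]

# classic Nelder-Mead coefficients: reflection, expansion, contraction, shrink
RHO = 1.0
CHI = 2.0
GAMMA = 0.5
SIGMA = 0.5

# simplex seeding: perturb each coordinate by 5% of its value, or by this
# absolute step when the coordinate is zero (the widely used recipe)
NONZERO_STEP_FRACTION = 0.05
ZERO_COORD_STEP = 0.00025

_BOUNDARY_CLAMP = 1e-12


@dataclass(frozen=True)
class Bounds:
    """Elementwise finite box constraints ``lb < ub`` in natural units."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self):
        lb = np.asarray(self.lb, dtype=float).ravel()
        ub = np.asarray(self.ub, dtype=float).ravel()
        if lb.shape != ub.shape:
            raise ValueError("lb and ub must have the same length")
        if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
            raise ValueError("bounds must be finite")
        if not np.all(ub > lb):
            raise ValueError("ub must exceed lb elementwise")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def n(self) -> int:
        return self.lb.size

    @property
    def span(self) -> np.ndarray:
        return self.ub - self.lb

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lb + self.ub)


@dataclass
class FitOutcome:
    """Result of one minimisation: best point (natural units), value, status."""

    x_best: np.ndarray
    f_best: float
    converged: bool
    iters_used: int


@dataclass
class BatchFitResult:
    """Results of a batch of simultaneous minimisations.

    ``first_converged_iter[b]`` is the first iteration index at which problem
    ``b`` met the convergence criterion (only populated when a monitor is
    requested; ``-1`` means never met).
    """

    x_best: np.ndarray
    f_best: np.ndarray
    converged: np.ndarray
    iters_used: int
    first_converged_iter: Optional[np.ndarray] = None
    stage2_ran: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.f_best.size


def to_unconstrained(x, b: Bounds) -> np.ndarray:
    """Map natural-unit ``x`` in ``[lb, ub]`` to the unconstrained space.

    Boundary values are clamped inward by ``1e-12 * (ub - lb)`` so the sine
    map retains a usable local slope; values outside the box raise.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < b.lb) or np.any(x > b.ub):
        raise OutOfBoundsError("x outside [lb, ub]")
    eps = _BOUNDARY_CLAMP * b.span
    xc = np.clip(x, b.lb + eps, b.ub - eps)
    return np.arcsin(2.0 * (xc - b.lb) / b.span - 1.0)


def to_constrained(xu, b: Bounds) -> np.ndarray:
    """Inverse sine map; lands inside ``[lb, ub]`` for any real input."""
    xu = np.asarray(xu, dtype=float)
    return b.lb + b.span * (np.sin(xu) + 1.0) / 2.0


def initial_simplex(xu0: np.ndarray) -> np.ndarray:
    """Seed simplex around ``xu0`` in the unconstrained space, shape (n+1, n)."""
    xu0 = np.asarray(xu0, dtype=float).ravel()
    n = xu0.size
    V = np.tile(xu0, (n + 1, 1))
    for i in range(n):
        step = NONZERO_STEP_FRACTION * xu0[i] if xu0[i] != 0.0 else ZERO_COORD_STEP
        V[i + 1, i] += step
    return V


def _batch_initial_simplices(XU0: np.ndarray) -> np.ndarray:
    B, n = XU0.shape
    V = np.repeat(XU0[:, None, :], n + 1, axis=1)
    steps = np.where(
        XU0 != 0.0, NONZERO_STEP_FRACTION * XU0, ZERO_COORD_STEP
    )
    idx = np.arange(n)
    V[:, idx + 1, idx] += steps
    return V


def _spreads(V: np.ndarray, F: np.ndarray):
    """Function and vertex spreads of sorted simplices (batched or single)."""
    f_spread = F[..., -1] - F[..., 0]
    v_spread = np.max(np.abs(V - V[..., 0:1, :]), axis=(-2, -1))
    return f_spread, v_spread


def _converged(V: np.ndarray, F: np.ndarray, tol: float):
    """Both function spread and vertex spread below ``tol``."""
    f_spread, v_spread = _spreads(V, F)
    return (f_spread < tol) & (v_spread < tol)


def _sanitize(vals):
    """Replace non-finite objective values by +inf so they are never selected."""
    vals = np.asarray(vals, dtype=float)
    bad = ~np.isfinite(vals)
    if np.any(bad):
        logger.debug("non-finite objective value(s) replaced by +inf")
        vals = np.where(bad, np.inf, vals)
    return vals


def nelder_mead_serial(
    objective: Callable[[np.ndarray], float],
    x0,
    b: Bounds,
    max_iter: int = 300,
    tol: float = 1e-5,
    init_simplex: Optional[np.ndarray] = None,
    trace: Optional[list] = None,
) -> FitOutcome:
    """Classic Nelder-Mead with conditional termination, in the sine-mapped space.

    Terminates when both the function spread ``max_i |f_i - f_best|`` and the
    vertex spread (max coordinate deviation from the best vertex, measured in
    the unconstrained space) fall below ``tol``, or after ``max_iter``
    iterations.  ``trace``, if given a list, collects the sorted
    ``(vertices, fvals)`` at the start of every iteration.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = b.n

    def g(xu):
        return float(_sanitize(objective(to_constrained(xu, b))))

    if init_simplex is not None:
        V = np.array(init_simplex, dtype=float, copy=True)
    else:
        V = initial_simplex(to_unconstrained(np.asarray(x0, dtype=float), b))
    F = np.array([g(v) for v in V])

    converged = False
    iters_used = max_iter
    for it in range(max_iter):
        order = np.argsort(F, kind="stable")
        V, F = V[order], F[order]
        if trace is not None:
            trace.append((V.copy(), F.copy()))
        if bool(_converged(V, F, tol)):
            converged = True
            iters_used = it
            break
        cen = V[:n].mean(axis=0)
        d = cen - V[n]
        xr = cen + RHO * d
        fr = g(xr)
        if fr < F[0]:
            xe = cen + CHI * RHO * d
            fe = g(xe)
            if fe < fr:
                V[n], F[n] = xe, fe
            else:
                V[n], F[n] = xr, fr
        elif fr < F[n - 1]:
            V[n], F[n] = xr, fr
        elif fr < F[n]:
            xoc = cen + GAMMA * RHO * d
            foc = g(xoc)
            if foc <= fr:
                V[n], F[n] = xoc, foc
            else:
                _shrink_serial(V, F, g)
        else:
            xic = cen - GAMMA * d
            fic = g(xic)
            if fic < F[n]:
                V[n], F[n] = xic, fic
            else:
                _shrink_serial(V, F, g)

    order = np.argsort(F, kind="stable")
    V, F = V[order], F[order]
    if not converged:
        converged = bool(_converged(V, F, tol))
    return FitOutcome(
        x_best=to_constrained(V[0], b),
        f_best=float(F[0]),
        converged=converged,
        iters_used=iters_used,
    )


def _shrink_serial(V, F, g):
    best = V[0].copy()
    for i in range(1, V.shape[0]):
        V[i] = best + SIGMA * (V[i] - best)
        F[i] = g(V[i])


def nelder_mead_batched(
    objective_batch: Callable[[np.ndarray], np.ndarray],
    X0: np.ndarray,
    b: Bounds,
    n_iter: int,
    tol: float = 1e-5,
    init_simplices: Optional[np.ndarray] = None,
    monitor: bool = False,
    trace: Optional[list] = None,
) -> BatchFitResult:
    """Branch-free Nelder-Mead: exactly ``n_iter`` lockstep iterations on B problems.

    ``objective_batch`` maps a ``(B, n)`` natural-unit array to ``(B,)``
    values, evaluating every problem at its own point in one call.  Each
    iteration computes the reflection, expansion, both contractions and the
    shrink candidates for *all* problems, then blends the accepted update via
    boolean masks — no data-dependent control flow.  The per-problem
    convergence flag is evaluated on the final simplex only; with
    ``monitor=True`` the criterion is additionally *measured* (never acted
    on) each iteration, recording when each problem first satisfies it.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X0 = np.asarray(X0, dtype=float)
    B, n = X0.shape
    if n != b.n:
        raise ValueError("X0 width does not match bounds dimension")

    def g(XU):
        return _sanitize(objective_batch(to_constrained(XU, b)))

    if init_simplices is not None:
        V = np.array(init_simplices, dtype=float, copy=True)
    else:
        V = _batch_initial_simplices(to_unconstrained(X0, b))
    F = np.stack([g(V[:, i, :]) for i in range(n + 1)], axis=1)

    first_conv = np.full(B, -1, dtype=int) if monitor else None
    for it in range(n_iter):
        order = np.argsort(F, axis=1, kind="stable")
        V = np.take_along_axis(V, order[:, :, None], axis=1)
        F = np.take_along_axis(F, order, axis=1)
        if trace is not None:
            trace.append((V.copy(), F.copy()))
        if monitor:
            conv = _converged(V, F, tol)
            first_conv = np.where((first_conv < 0) & conv, it, first_conv)

        cen = V[:, :n, :].mean(axis=1)
        d = cen - V[:, n, :]
        xr = cen + RHO * d
        xe = cen + CHI * RHO * d
        xoc = cen + GAMMA * RHO * d
        xic = cen - GAMMA * d
        fr = g(xr)
        fe = g(xe)
        foc = g(xoc)
        fic = g(xic)

        f0, fsw, fw = F[:, 0], F[:, n - 1], F[:, n]
        better_best = fr < f0
        m_exp = better_best & (fe < fr)
        m_ref = (better_best & ~(fe < fr)) | (~better_best & (fr < fsw))
        m_oc = ~better_best & ~(fr < fsw) & (fr < fw) & (foc <= fr)
        m_ic = ~better_best & ~(fr < fsw) & ~(fr < fw) & (fic < fw)
        m_shr = ~(m_exp | m_ref | m_oc | m_ic)

        conds = [m_exp[:, None], m_ref[:, None], m_oc[:, None], m_ic[:, None]]
        cand = np.select(conds, [xe, xr, xoc, xic], default=0.0)
        cand = cand + np.where(m_shr[:, None], V[:, n, :], 0.0)
        fcand = np.select([m_exp, m_ref, m_oc, m_ic], [fe, fr, foc, fic], default=0.0)
        fcand = fcand + np.where(m_shr, fw, 0.0)

        # shrink candidates from the pre-update sorted simplex
        best = V[:, 0:1, :]
        Vs = best + SIGMA * (V[:, 1:, :] - best)
        Fs = np.stack([g(Vs[:, i, :]) for i in range(n)], axis=1)

        V = V.copy()
        F = F.copy()
        V[:, n, :] = cand
        F[:, n] = fcand
        V[:, 1:, :] = np.where(m_shr[:, None, None], Vs, V[:, 1:, :])
        F[:, 1:] = np.where(m_shr[:, None], Fs, F[:, 1:])

    order = np.argsort(F, axis=1, kind="stable")
    V = np.take_along_axis(V, order[:, :, None], axis=1)
    F = np.take_along_axis(F, order, axis=1)
    conv = _converged(V, F, tol)
    if monitor:
        first_conv = np.where((first_conv < 0) & conv, n_iter, first_conv)
    return BatchFitResult(
        x_best=to_constrained(V[:, 0, :], b),
        f_best=F[:, 0].copy(),
        converged=conv,
        iters_used=n_iter,
        first_converged_iter=first_conv,
    )


def two_stage_minimize(
    objective_batch: Callable[[np.ndarray, np.ndarray], np.ndarray],
    X0: np.ndarray,
    b: Bounds,
    iters: Sequence[int] = (150, 200),
    tol: float = 1e-5,
    monitor: bool = False,
) -> BatchFitResult:
    """Two-stage batched minimisation with convergence culling.

    Stage 1 runs the batched optimizer on all problems for ``iters[0]``
    iterations; problems whose final simplex satisfies the convergence
    criterion are frozen (their results pass through untouched).  Stage 2
    re-minimises only the remainder for ``iters[1]`` iterations from fresh
    simplices seeded at the stage-1 best estimates.  If stage 2 fails to
    improve a problem (possible only through the boundary clamp of the
    re-seeding round trip), the stage-1 result is kept.

    ``objective_batch(X, indices)`` must evaluate problems ``indices`` (into
    the original batch) at the rows of ``X``.
    """
    X0 = np.asarray(X0, dtype=float)
    B = X0.shape[0]
    idx_all = np.arange(B)
    r1 = nelder_mead_batched(
        lambda X: objective_batch(X, idx_all), X0, b, int(iters[0]), tol,
        monitor=monitor,
    )
    unconv = ~r1.converged
    stage2_ran = unconv.copy()
    logger.info(
        "stage 1: %d/%d problems converged after %d iterations",
        int(np.sum(r1.converged)), B, int(iters[0]),
    )
    if not np.any(unconv):
        r1.stage2_ran = stage2_ran
        return r1
    idx2 = idx_all[unconv]
    r2 = nelder_mead_batched(
        lambda X: objective_batch(X, idx2),
        r1.x_best[unconv],
        b,
        int(iters[1]),
        tol,
    )
    x_best = r1.x_best.copy()
    f_best = r1.f_best.copy()
    converged = r1.converged.copy()
    improved = r2.f_best <= r1.f_best[unconv]
    sel = idx2[improved]
    x_best[sel] = r2.x_best[improved]
    f_best[sel] = r2.f_best[improved]
    converged[idx2] = r2.converged
    logger.info(
        "stage 2: %d/%d re-minimised problems converged after %d iterations",
        int(np.sum(r2.converged)), idx2.size, int(iters[1]),
    )
    return BatchFitResult(
        x_best=x_best,
        f_best=f_best,
        converged=converged,
        iters_used=int(iters[0]) + int(iters[1]),
        first_converged_iter=r1.first_converged_iter,
        stage2_ran=stage2_ran,
    )
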