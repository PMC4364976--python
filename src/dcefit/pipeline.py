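"""The four-step voxel-wise analysis: arterial fit, exclusion, tissue fit, maps.

Given one DCE-MRI slice (time grid, arterial concentration series ``Cv``,
tissue concentration grid ``CT`` and an ROI mask), the pipeline

1. fits the systemic two-compartment arterial model to ``Cv`` with the
   serial Nelder-Mead (300 iterations, tolerance 1e-5);
2. screens tissue voxels, excluding those with missing values, only
   negative values, or values exceeding a multiple of the fitted arterial
   peak;
3. fits the extended Tofts model (``ve, k30, vb, tlag``) to every kept voxel
   with the batched two-stage optimizer; and
4. derives ``Ktrans = k30 * ve`` maps and median ROI summaries.

Excluded voxels carry NaN sentinels in every parameter map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional

import numpy as np

from . import models
from .exceptions import (
    DegenerateArterialDataError,
    DimensionError,
    EmptyBatchError,
    EmptyMapError,
    EmptyRoiError,
    UndefinedBaselineError,
)
from .models import AifParams, as_time_grid, batch_tissue_concentration
from .optimize import (
    Bounds,
    FitOutcome,
    nelder_mead_serial,
    two_stage_minimize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SliceData",
    "ExclusionReason",
    "ExclusionMask",
    "FitMaps",
    "RoiSummary",
    "TissueFitConfig",
    "fit_arterial",
    "exclusion_mask",
    "fit_tissue",
    "fit_tissue_serial",
    "roi_summary",
    "percent_change",
    "clip_for_display",
]

#: sentinel written into parameter maps at excluded voxels
SENTINEL = np.nan

#: order of the fitted arterial parameters in the optimisation vector
AIF_PARAM_NAMES = ("r0_over_v1", "k10", "k12", "k21", "tlag")
#: order of the fitted tissue parameters in the optimisation vector
TISSUE_PARAM_NAMES = ("ve", "k30", "vb", "tlag")


@dataclass(frozen=True)
class SliceData:
    """One slice of DCE-MRI data: the unit of pipeline work.

    ``time``: (n_f,) minutes; ``cv``: (n_f,) arterial mM; ``ct``:
    (nx, ny, n_f) tissue mM; ``roi``: (nx, ny) boolean tumor mask.
    """

    time: np.ndarray
    cv: np.ndarray
    ct: np.ndarray
    roi: np.ndarray

    def __post_init__(self):
        t = as_time_grid(self.time)
        cv = np.asarray(self.cv, dtype=float).ravel()
        ct = np.asarray(self.ct, dtype=float)
        roi = np.asarray(self.roi, dtype=bool)
        if cv.size != t.size:
            raise DimensionError(
                f"cv length {cv.size} != time length {t.size} (frame axis)"
            )
        if ct.ndim != 3:
            raise DimensionError(f"ct must be 3-D (nx, ny, n_f), got {ct.ndim}-D")
        if ct.shape[2] != t.size:
            raise DimensionError(
                f"ct frame axis {ct.shape[2]} != time length {t.size}"
            )
        if roi.shape != ct.shape[:2]:
            raise DimensionError(
                f"roi shape {roi.shape} != ct spatial shape {ct.shape[:2]}"
            )
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "cv", cv)
        object.__setattr__(self, "ct", ct)
        object.__setattr__(self, "roi", roi)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ct.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.time.size


class ExclusionReason(IntEnum):
    NONE = 0
    MISSING = 1
    ALL_NEGATIVE = 2
    OVER_THRESHOLD = 3


@dataclass(frozen=True)
class ExclusionMask:
    """Per-voxel exclusion flags with reason codes (reporting precedence:
    missing > all_negative > over_threshold)."""

    excluded: np.ndarray
    reason: np.ndarray

    def __post_init__(self):
        excluded = np.asarray(self.excluded, dtype=bool)
        reason = np.asarray(self.reason, dtype=np.uint8)
        if excluded.shape != reason.shape:
            raise DimensionError("excluded and reason shapes differ")
        if not np.array_equal(excluded, reason != ExclusionReason.NONE):
            raise ValueError("reason codes inconsistent with excluded flags")
        object.__setattr__(self, "excluded", excluded)
        object.__setattr__(self, "reason", reason)

    @property
    def n_excluded(self) -> int:
        return int(np.sum(self.excluded))


@dataclass
class FitMaps:
    """Per-voxel parameter and diagnostic maps from the tissue fit.

    Excluded voxels carry NaN in every parameter map and ``converged=False``.
    ``ktrans = k30 * ve`` holds exactly wherever defined.
    """

    ve: np.ndarray
    k30: np.ndarray
    vb: np.ndarray
    tlag: np.ndarray
    ktrans: np.ndarray
    sse: np.ndarray
    converged: np.ndarray
    exclusion: ExclusionMask
    first_converged_iter: Optional[np.ndarray] = None

    def map_names(self) -> tuple[str, ...]:
        return ("ve", "k30", "vb", "tlag", "ktrans", "sse")


@dataclass(frozen=True)
class RoiSummary:
    """Median tumor parameters over non-excluded ROI voxels."""

    median_ve: float
    median_ktrans: float
    n_voxels: int


@dataclass(frozen=True)
class TissueFitConfig:
    """Settings for the batched tissue fit (bounds in natural units)."""

    bounds: Bounds = field(
        default_factory=lambda: Bounds(
            lb=np.array([1e-3, 1e-3, 0.0, 0.0]),
            ub=np.array([1.0, 10.0, 1.0, 2.0]),
        )
    )
    # literature-plausible tumor starting point (ve, k30, vb, tlag); a start
    # with non-zero arcsine coordinates keeps the seeded simplex responsive
    x0: Optional[np.ndarray] = field(
        default_factory=lambda: np.array([0.2, 0.5, 0.05, 0.1])
    )
    stage_iters: tuple[int, int] = (150, 200)
    tol: float = 1e-5
    monitor: bool = False

    def initial_estimate(self) -> np.ndarray:
        if self.x0 is not None:
            return np.asarray(self.x0, dtype=float)
        return self.bounds.midpoint()


def fit_arterial(
    time,
    cv,
    init: AifParams,
    b: Bounds,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> tuple[AifParams, FitOutcome]:
    """Fit the arterial model to the measured blood curve.

    Minimises the least-squares objective over ``(r0_over_v1, k10, k12, k21,
    tlag)`` with ``t0``/``t1`` fixed from ``init`` (protocol inputs), using
    the serial Nelder-Mead started at ``init``.
    """
    t = as_time_grid(time)
    cv = np.asarray(cv, dtype=float).ravel()
    if cv.size != t.size:
        raise DimensionError(f"cv length {cv.size} != time length {t.size}")
    if not np.all(np.isfinite(cv)) or np.all(cv == 0):
        raise DegenerateArterialDataError(
            "arterial series is all-zero or contains non-finite values"
        )
    if b.n != 5:
        raise ValueError("arterial bounds must cover 5 parameters")

    def objective(x):
        p = replace(
            init,
            r0_over_v1=x[0], k10=x[1], k12=x[2], k21=x[3], tlag=x[4],
        )
        return models.sse_objective(cv, models.aif_concentration(t, p))

    x0 = np.array([init.r0_over_v1, init.k10, init.k12, init.k21, init.tlag])
    outcome = nelder_mead_serial(objective, x0, b, max_iter=max_iter, tol=tol)
    fitted = replace(
        init,
        r0_over_v1=outcome.x_best[0],
        k10=outcome.x_best[1],
        k12=outcome.x_best[2],
        k21=outcome.x_best[3],
        tlag=outcome.x_best[4],
    )
    logger.info(
        "arterial fit: sse=%.3e, converged=%s after %d iterations",
        outcome.f_best, outcome.converged, outcome.iters_used,
    )
    return fitted, outcome


def exclusion_mask(
    ct, aif_fit: AifParams, time, factor: float = 2.0
) -> ExclusionMask:
    """Screen tissue voxels before fitting.

    A voxel is excluded if any frame is missing/non-finite, if *all* frames
    are negative, or if any frame exceeds ``factor`` times the peak of the
    fitted arterial curve (tissue concentrations physically cannot greatly
    exceed the arterial peak).  Reason codes follow that precedence.
    """
    t = as_time_grid(time)
    ct = np.asarray(ct, dtype=float)
    finite = np.isfinite(ct)
    missing = ~finite.all(axis=2)
    all_negative = (np.where(finite, ct, 0.0) < 0).all(axis=2)
    peak = float(np.max(models.aif_concentration(t, aif_fit)))
    over = (np.where(finite, ct, -np.inf) > factor * peak).any(axis=2)
    reason = np.select(
        [missing, all_negative, over],
        [
            ExclusionReason.MISSING,
            ExclusionReason.ALL_NEGATIVE,
            ExclusionReason.OVER_THRESHOLD,
        ],
        default=ExclusionReason.NONE,
    ).astype(np.uint8)
    mask = ExclusionMask(excluded=reason != 0, reason=reason)
    logger.info(
        "exclusion: %d/%d voxels removed (threshold %.3g mM)",
        mask.n_excluded, ct.shape[0] * ct.shape[1], factor * peak,
    )
    return mask


def _kept_observations(data: SliceData, mask: ExclusionMask):
    keep = ~mask.excluded
    idx = np.flatnonzero(keep.ravel())
    if idx.size == 0:
        raise EmptyBatchError("all voxels excluded; nothing to fit")
    n_f = data.n_frames
    cobs = data.ct.reshape(-1, n_f)[idx]
    return idx, cobs


def make_tissue_objective(data: SliceData, aif_fit: AifParams, cobs: np.ndarray):
    """Batched least-squares objective for the kept-voxel observations.

    Returns ``f(X, indices)`` evaluating rows of ``X`` (columns ``ve, k30,
    vb, tlag``) against the corresponding rows of ``cobs``.
    """

    def objective_batch(X, indices):
        pred = batch_tissue_concentration(
            data.time, aif_fit, X[:, 0], X[:, 1], X[:, 2], X[:, 3]
        )
        r = cobs[indices] - pred
        return np.sum(r * r, axis=1)

    return objective_batch


def _empty_maps(shape, mask: ExclusionMask) -> FitMaps:
    full = lambda: np.full(shape, SENTINEL)
    return FitMaps(
        ve=full(), k30=full(), vb=full(), tlag=full(), ktrans=full(),
        sse=full(), converged=np.zeros(shape, dtype=bool), exclusion=mask,
    )


def fit_tissue(
    data: SliceData,
    aif_fit: AifParams,
    mask: ExclusionMask,
    cfg: TissueFitConfig = TissueFitConfig(),
) -> FitMaps:
    """Fit the extended Tofts model to every non-excluded voxel (batched).

    All kept voxels are flattened into one batch and minimised in lockstep by
    the two-stage branch-free Nelder-Mead.  Returns parameter maps with NaN
    sentinels at excluded voxels and ``ktrans = k30 * ve`` derived per voxel.
    """
    idx, cobs = _kept_observations(data, mask)
    objective_batch = make_tissue_objective(data, aif_fit, cobs)
    X0 = np.tile(cfg.initial_estimate(), (idx.size, 1))
    res = two_stage_minimize(
        objective_batch, X0, cfg.bounds,
        iters=cfg.stage_iters, tol=cfg.tol, monitor=cfg.monitor,
    )
    maps = _empty_maps(data.shape, mask)
    flat = {name: maps.__dict__[name].ravel() for name in maps.map_names()}
    for j, name in enumerate(TISSUE_PARAM_NAMES):
        flat[name][idx] = res.x_best[:, j]
    flat["ktrans"][idx] = res.x_best[:, 1] * res.x_best[:, 0]
    flat["sse"][idx] = res.f_best
    conv = maps.converged.ravel()
    conv[idx] = res.converged
    if cfg.monitor and res.first_converged_iter is not None:
        fci = np.full(data.shape, SENTINEL).ravel()
        fci[idx] = np.where(
            res.first_converged_iter < 0, np.nan, res.first_converged_iter
        )
        maps.first_converged_iter = fci.reshape(data.shape)
    logger.info(
        "tissue fit: %d voxels, %.1f%% converged",
        idx.size, 100.0 * np.mean(res.converged),
    )
    return maps


def fit_tissue_serial(
    data: SliceData,
    aif_fit: AifParams,
    mask: ExclusionMask,
    cfg: TissueFitConfig = TissueFitConfig(),
    max_iter: Optional[int] = None,
) -> FitMaps:
    """Per-voxel serial reference fit (conditional-termination Nelder-Mead).

    Runs the classic branching optimizer voxel by voxel with the same
    objective, bounds and initial estimate as :func:`fit_tissue`, with
    ``max_iter`` defaulting to the combined two-stage budget.  Used to verify
    that the lockstep batched variant does not alter the estimates.
    """
    idx, cobs = _kept_observations(data, mask)
    objective_batch = make_tissue_objective(data, aif_fit, cobs)
    if max_iter is None:
        max_iter = int(cfg.stage_iters[0]) + int(cfg.stage_iters[1])
    x0 = cfg.initial_estimate()
    maps = _empty_maps(data.shape, mask)
    flat = {name: maps.__dict__[name].ravel() for name in maps.map_names()}
    conv = maps.converged.ravel()
    one = np.empty((1,), dtype=int)
    for j, voxel in enumerate(idx):
        one[0] = j
        outcome = nelder_mead_serial(
            lambda x: float(objective_batch(x[None, :], one)[0]),
            x0, cfg.bounds, max_iter=max_iter, tol=cfg.tol,
        )
        for k, name in enumerate(TISSUE_PARAM_NAMES):
            flat[name][voxel] = outcome.x_best[k]
        flat["ktrans"][voxel] = outcome.x_best[1] * outcome.x_best[0]
        flat["sse"][voxel] = outcome.f_best
        conv[voxel] = outcome.converged
    return maps


def roi_summary(maps: FitMaps, roi) -> RoiSummary:
    """Median ``ve`` and ``Ktrans`` over non-excluded ROI voxels."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != maps.ve.shape:
        raise DimensionError("roi shape does not match parameter maps")
    sel = roi & ~maps.exclusion.excluded & np.isfinite(maps.ve)
    n = int(np.sum(sel))
    if n == 0:
        raise EmptyRoiError("ROI contains no non-excluded voxels")
    return RoiSummary(
        median_ve=float(np.median(maps.ve[sel])),
        median_ktrans=float(np.median(maps.ktrans[sel])),
        n_voxels=n,
    )


def percent_change(pre: float, post: float) -> float:
    """Percent change from a pre-treatment to a post-treatment value."""
    if pre == 0:
        raise UndefinedBaselineError("percent change undefined for pre == 0")
    return 100.0 * (post - pre) / pre


def clip_for_display(map_, low_pct: float = 0.0, high_pct: float = 99.0):
    """Clamp extreme outliers to percentile values for heat-map display.

    Percentiles are computed over the finite (non-sentinel) entries; NaN
    sentinels are preserved in the output.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    m = np.asarray(map_, dtype=float)
    finite = np.isfinite(m)
    if not np.any(finite):
        raise EmptyMapError("map contains no finite values")
    lo, hi = np.percentile(m[finite], [low_pct, high_pct])
    out = m.copy()
    out[finite] = np.clip(m[finite], lo, hi)
    return out
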