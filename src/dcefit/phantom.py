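"""Digital reference phantom: synthetic slices with known ground truth.

The generator emulates the per-slice data layout the pipeline consumes
(time grid, arterial series, tissue grid, ROI mask) from a known arterial
parameter set and per-voxel tissue truth fields, adds independent Gaussian
concentration noise, and can deliberately corrupt voxels to exercise each
exclusion rule.  Every pipeline stage is therefore testable against exact
ground truth without any external data.

Noise is additive Gaussian on concentration (the generator operates
downstream of signal-to-concentration conversion); each voxel's noise stream
is seeded from ``(seed, voxel index)`` so neither corruption nor evaluation
order can change the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ModelError
from .models import AifParams, aif_concentration, batch_tissue_concentration
from .pipeline import (
    ExclusionMask,
    ExclusionReason,
    FitMaps,
    SliceData,
)

logger = logging.getLogger(__name__)

__all__ = ["FieldSpec", "PhantomSpec", "default_phantom", "make_phantom"]

#: seed of the stock phantom
DEFAULT_SEED = 20150318


@dataclass(frozen=True)
class FieldSpec:
    """Spatial pattern for one truth parameter.

    ``kind`` is ``constant`` (value ``vmin``), ``gradient`` (linear ramp
    ``vmin -> vmax`` along ``axis`` in {'x', 'y', 'diag', 'radial'}), or
    ``blobs`` (``vmin`` background with ``n_blobs`` smooth Gaussian bumps
    reaching toward ``vmax``, placed by the phantom seed).
    """

    kind: str
    vmin: float
    vmax: Optional[float] = None
    axis: str = "x"
    n_blobs: int = 3

    def __post_init__(self):
        if self.kind not in ("constant", "gradient", "blobs"):
            raise ModelError(f"unknown field kind {self.kind!r}")
        if self.kind != "constant" and self.vmax is None:
            raise ModelError(f"{self.kind} field needs vmax")

    def render(self, nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full((nx, ny), float(self.vmin))
        lo, hi = float(self.vmin), float(self.vmax)
        xx, yy = np.meshgrid(
            np.linspace(0.0, 1.0, nx), np.linspace(0.0, 1.0, ny), indexing="ij"
        )
        if self.kind == "gradient":
            ramp = {
                "x": xx,
                "y": yy,
                "diag": (xx + yy) / 2.0,
                "radial": np.hypot(xx - 0.5, yy - 0.5) / np.hypot(0.5, 0.5),
            }[self.axis]
            return lo + (hi - lo) * ramp
        f = np.zeros((nx, ny))
        for _ in range(self.n_blobs):
            cx, cy = rng.uniform(0.2, 0.8, 2)
            w = rng.uniform(0.08, 0.2)
            f += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * w * w))
        f /= max(f.max(), 1e-12)
        return lo + (hi - lo) * f


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic slice with ground truth."""

    nx: int = 64
    ny: int = 64
    n_f: int = 40
    duration_min: float = 8.0
    aif: AifParams = field(
        default_factory=lambda: AifParams(
            r0_over_v1=12.0, k10=0.6, k12=0.4, k21=0.2,
            t0=0.2, t1=0.7, tlag=0.05,
        )
    )
    ve: FieldSpec = field(
        default_factory=lambda: FieldSpec("gradient", 0.05, 0.45, axis="radial")
    )
    k30: FieldSpec = field(
        default_factory=lambda: FieldSpec("gradient", 0.1, 2.0, axis="x")
    )
    vb: FieldSpec = field(
        default_factory=lambda: FieldSpec("gradient", 0.0, 0.1, axis="y")
    )
    tlag: FieldSpec = field(
        default_factory=lambda: FieldSpec("gradient", 0.0, 0.3, axis="diag")
    )
    roi_center: tuple[float, float] = (40.0, 40.0)
    roi_radius: float = 10.0
    noise_sd: float = 0.02
    seed: int = DEFAULT_SEED
    n_missing: int = 0
    n_all_negative: int = 0
    n_over_threshold: int = 0

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or self.n_f < 2:
            raise ModelError("phantom grid must be at least 1x1 with 2 frames")
        if self.noise_sd < 0:
            raise ModelError("noise_sd must be non-negative")
        n_corrupt = self.n_missing + self.n_all_negative + self.n_over_threshold
        if n_corrupt > self.nx * self.ny:
            raise ModelError("more corrupted voxels requested than exist")

    def times(self) -> np.ndarray:
        """Acquisition grid: n_f uniformly spaced frames ending at duration."""
        dt = self.duration_min / self.n_f
        return dt * np.arange(1, self.n_f + 1)

    def roi_mask(self) -> np.ndarray:
        xx, yy = np.meshgrid(
            np.arange(self.nx), np.arange(self.ny), indexing="ij"
        )
        cx, cy = self.roi_center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.roi_radius**2


def default_phantom() -> PhantomSpec:
    """The stock 64x64 phantom: 40 frames over 8 min, disc ROI, noise 0.02 mM.

    Truth ranges span physiologically plausible tumor/brain values
    (``ve`` 0.05-0.45, ``k30`` 0.1-2 /min, ``vb`` 0-0.1, ``tlag`` 0-0.3 min).
    """
    return PhantomSpec()


def _truth_fields(spec: PhantomSpec) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    return {
        name: getattr(spec, name).render(spec.nx, spec.ny, rng)
        for name in ("ve", "k30", "vb", "tlag")
    }


def make_phantom(spec: PhantomSpec) -> tuple[SliceData, FitMaps]:
    """Generate a synthetic slice and the ground-truth maps that made it.

    The arterial series is the closed-form model plus noise; each voxel's
    tissue series is the extended Tofts model at that voxel's truth
    parameters plus independent noise.  Corrupted voxels (counts from the
    spec) are overwritten to trip, respectively, the missing / all-negative /
    over-threshold exclusion rules, and are marked excluded in the returned
    truth maps.
    """
    t = spec.times()
    fields = _truth_fields(spec)
    n_vox = spec.nx * spec.ny

    cv_clean = aif_concentration(t, spec.aif)
    ct_clean = batch_tissue_concentration(
        t,
        spec.aif,
        fields["ve"].ravel(),
        fields["k30"].ravel(),
        fields["vb"].ravel(),
        fields["tlag"].ravel(),
    )

    ct = ct_clean.copy()
    if spec.noise_sd > 0:
        for v in range(n_vox):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, v]))
            ct[v] += rng.normal(0.0, spec.noise_sd, spec.n_f)
        rng_cv = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
        cv = cv_clean + rng_cv.normal(0.0, spec.noise_sd, spec.n_f)
    else:
        cv = cv_clean.copy()

    # corruption: disjoint voxel sets chosen by a dedicated stream
    reason = np.zeros(n_vox, dtype=np.uint8)
    n_corrupt = spec.n_missing + spec.n_all_negative + spec.n_over_threshold
    if n_corrupt:
        rng_c = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
        chosen = rng_c.choice(n_vox, size=n_corrupt, replace=False)
        peak = float(np.max(cv_clean))
        k = 0
        for v in chosen[: spec.n_missing]:
            ct[v, rng_c.integers(spec.n_f)] = np.nan
            reason[v] = ExclusionReason.MISSING
        k += spec.n_missing
        for v in chosen[k : k + spec.n_all_negative]:
            ct[v] = -rng_c.uniform(0.01, 0.1, spec.n_f)
            reason[v] = ExclusionReason.ALL_NEGATIVE
        k += spec.n_all_negative
        for v in chosen[k:]:
            ct[v, rng_c.integers(spec.n_f)] = 10.0 * peak
            reason[v] = ExclusionReason.OVER_THRESHOLD

    shape = (spec.nx, spec.ny)
    excl = ExclusionMask(
        excluded=(reason != 0).reshape(shape), reason=reason.reshape(shape)
    )
    sentinel = lambda a: np.where(excl.excluded, np.nan, a)
    truth = FitMaps(
        ve=sentinel(fields["ve"]),
        k30=sentinel(fields["k30"]),
        vb=sentinel(fields["vb"]),
        tlag=sentinel(fields["tlag"]),
        ktrans=sentinel(fields["k30"] * fields["ve"]),
        sse=np.where(excl.excluded, np.nan, 0.0),
        converged=~excl.excluded,
        exclusion=excl,
    )
    data = SliceData(
        time=t,
        cv=cv,
        ct=ct.reshape(spec.nx, spec.ny, spec.n_f),
        roi=spec.roi_mask(),
    )
    logger.info(
        "phantom: %dx%d grid, %d frames, noise %.3g mM, %d corrupted voxels",
        spec.nx, spec.ny, spec.n_f, spec.noise_sd, n_corrupt,
    )
    return data, truth
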