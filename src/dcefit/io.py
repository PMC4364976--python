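"""Readers and writers for the pipeline's on-disk formats.

Grids and parameter maps travel as NIfTI-1 (4-D ``nx x ny x 1 x n_f`` or
3-D stacks for the tissue series, 2-D images for maps and masks); the time
and arterial series as two-column delimited text (``time_min,
concentration_mM``); the ROI summary as CSV; and the run manifest as JSON.
NaN is the sentinel for excluded voxels in every on-disk map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DimensionError
from .pipeline import ExclusionMask, FitMaps, RoiSummary, SliceData

logger = logging.getLogger(__name__)

__all__ = [
    "read_slice",
    "read_series",
    "write_series",
    "write_grid",
    "read_grid",
    "write_maps",
    "read_maps",
    "write_manifest",
]

_AFFINE = np.eye(4)


def write_grid(path, array) -> None:
    """Write an array as float64 NIfTI-1 (identity affine)."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), _AFFINE)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_grid(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def write_series(path, time, values, value_name: str = "concentration_mM") -> None:
    """Write a two-column delimited text series (time in minutes)."""
    pd.DataFrame({"time_min": np.asarray(time, float).ravel(),
                  value_name: np.asarray(values, float).ravel()}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column delimited text series (comma or whitespace).

    An optional single header line is skipped.  Parsing goes through
    ``np.loadtxt``, which round-trips float64 text exactly.
    """
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    try:
        float(first.split("," if delimiter else None)[0])
        skip = 0
    except ValueError:
        skip = 1
    arr = np.atleast_2d(np.loadtxt(path, delimiter=delimiter, skiprows=skip))
    if arr.shape[1] < 2:
        raise DimensionError(f"{path}: expected two columns (time, value)")
    return arr[:, 0].copy(), arr[:, 1].copy()


def read_slice(
    ct_path, roi_path, cv_path, time_in_seconds: bool = False
) -> SliceData:
    """Assemble a :class:`SliceData` from on-disk inputs.

    ``ct`` may be a 4-D NIfTI (nx, ny, 1, n_f) or a 3-D stack (nx, ny, n_f);
    ``roi`` a 2-D NIfTI treated as boolean; ``cv`` a two-column text file.
    With ``time_in_seconds`` the time column is converted to minutes.
    """
    ct = read_grid(ct_path)
    if ct.ndim == 4:
        if ct.shape[2] != 1:
            raise DimensionError(
                f"4-D ct must have a singleton third axis, got {ct.shape}"
            )
        ct = ct[:, :, 0, :]
    elif ct.ndim != 3:
        raise DimensionError(f"ct must be 3-D or 4-D, got {ct.ndim}-D")
    roi = read_grid(roi_path)
    if roi.ndim != 2:
        raise DimensionError(f"roi must be 2-D, got {roi.ndim}-D")
    time, cv = read_series(cv_path)
    if time_in_seconds:
        time = time / 60.0
    if cv.size != ct.shape[2]:
        raise DimensionError(
            f"cv length {cv.size} != ct frame axis {ct.shape[2]}"
        )
    return SliceData(time=time, cv=cv, ct=ct, roi=roi != 0)


def _versions() -> dict:
    import matplotlib
    import scipy

    from . import __version__

    return {
        "dcefit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nib.__version__,
        "pandas": pd.__version__,
        "matplotlib": matplotlib.__version__,
    }


def write_maps(
    maps: FitMaps,
    summary: RoiSummary | None,
    out_dir,
    config: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """Write parameter maps, the ROI summary and a JSON run manifest.

    Returns the manifest dict.  One NIfTI per map (NaN sentinels), the
    exclusion reason codes, convergence flags, a CSV summary, and
    ``manifest.json`` embedding the configuration and software versions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in maps.map_names():
        p = out / f"{name}.nii.gz"
        write_grid(p, getattr(maps, name))
        files[name] = p.name
    write_grid(out / "converged.nii.gz", maps.converged.astype(np.float64))
    write_grid(
        out / "exclusion_reason.nii.gz",
        maps.exclusion.reason.astype(np.float64),
    )
    files["converged"] = "converged.nii.gz"
    files["exclusion_reason"] = "exclusion_reason.nii.gz"
    summary_dict = None
    if summary is not None:
        summary_dict = asdict(summary)
        pd.DataFrame([summary_dict]).to_csv(out / "roi_summary.csv", index=False)
        files["roi_summary"] = "roi_summary.csv"
    manifest = {
        "config": config or {},
        "versions": _versions(),
        "files": files,
        "n_excluded": maps.exclusion.n_excluded,
        "roi_summary": summary_dict,
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("wrote %d maps + manifest to %s", len(files), out)
    return manifest


def read_maps(out_dir) -> FitMaps:
    """Read back a directory written by :func:`write_maps`."""
    out = Path(out_dir)
    arrays = {
        name: read_grid(out / f"{name}.nii.gz")
        for name in ("ve", "k30", "vb", "tlag", "ktrans", "sse")
    }
    converged = read_grid(out / "converged.nii.gz").astype(bool)
    reason = read_grid(out / "exclusion_reason.nii.gz").astype(np.uint8)
    mask = ExclusionMask(excluded=reason != 0, reason=reason)
    return FitMaps(converged=converged, exclusion=mask, **arrays)


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))
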