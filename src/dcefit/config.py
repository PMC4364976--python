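"""Run configuration: every knob that influences a pipeline run, fully defaulted.

The configuration round-trips through YAML and is echoed verbatim into the
run manifest so any run can be reproduced from its outputs alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .models import AifParams
from .optimize import Bounds
from .pipeline import TissueFitConfig

__all__ = ["RunConfig"]

_AIF_PARAMS = ("r0_over_v1", "k10", "k12", "k21", "tlag")
_TISSUE_PARAMS = ("ve", "k30", "vb", "tlag")


def _default_aif_init() -> dict:
    # literature-plausible systemic Gd-DTPA kinetics for a short infusion
    return {
        "r0_over_v1": 10.0, "k10": 0.5, "k12": 0.3, "k21": 0.15, "tlag": 0.1,
    }


def _default_aif_bounds() -> dict:
    return {
        "r0_over_v1": [0.5, 50.0],
        "k10": [0.05, 3.0],
        "k12": [0.01, 3.0],
        "k21": [0.01, 3.0],
        "tlag": [0.0, 1.0],
    }


def _default_tissue_bounds() -> dict:
    return {
        "ve": [1e-3, 1.0],
        "k30": [1e-3, 10.0],
        "vb": [0.0, 1.0],
        "tlag": [0.0, 2.0],
    }


@dataclass(frozen=True)
class RunConfig:
    """All settings for one slice analysis.

    ``t0``/``t1`` (min) are the infusion window from the injection protocol;
    they are fixed inputs, never fitted.  ``time_in_seconds`` converts the
    input time column (and ``t0``/``t1``) from seconds to minutes on read.
    """

    t0: float = 0.2
    t1: float = 0.7
    aif_init: dict = field(default_factory=_default_aif_init)
    aif_bounds: dict = field(default_factory=_default_aif_bounds)
    aif_max_iter: int = 300
    tissue_bounds: dict = field(default_factory=_default_tissue_bounds)
    tissue_init: dict | None = None  # None -> library default start
    stage_iters: tuple[int, int] = (150, 200)
    tol: float = 1e-5
    exclusion_factor: float = 2.0
    clip_percentiles: tuple[float, float] = (0.0, 99.0)
    monitor: bool = False
    seed: int = 0
    time_in_seconds: bool = False

    # ---- materialised objects -------------------------------------------

    def aif_init_params(self) -> AifParams:
        return AifParams(t0=self.t0, t1=self.t1, **self.aif_init)

    def aif_bounds_obj(self) -> Bounds:
        lb = [self.aif_bounds[k][0] for k in _AIF_PARAMS]
        ub = [self.aif_bounds[k][1] for k in _AIF_PARAMS]
        return Bounds(np.array(lb), np.array(ub))

    def tissue_fit_config(self) -> TissueFitConfig:
        lb = [self.tissue_bounds[k][0] for k in _TISSUE_PARAMS]
        ub = [self.tissue_bounds[k][1] for k in _TISSUE_PARAMS]
        kwargs = {}
        if self.tissue_init is not None:
            kwargs["x0"] = np.array([self.tissue_init[k] for k in _TISSUE_PARAMS])
        return TissueFitConfig(
            bounds=Bounds(np.array(lb), np.array(ub)),
            stage_iters=tuple(self.stage_iters),
            tol=self.tol,
            monitor=self.monitor,
            **kwargs,
        )

    # ---- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_iters"] = list(self.stage_iters)
        d["clip_percentiles"] = list(self.clip_percentiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stage_iters" in d:
            d["stage_iters"] = tuple(d["stage_iters"])
        if "clip_percentiles" in d:
            d["clip_percentiles"] = tuple(d["clip_percentiles"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
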