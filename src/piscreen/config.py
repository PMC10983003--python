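"""Runtime configuration (TOML) for batch screening."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .excited import LC_INTERCEPT, LC_SLOPE
from .model import DEFAULT_DAMPING, DEFAULT_MAX_ITER, DEFAULT_TOL


@dataclass
class ScreenConfig:
    """Settings for the screening pipeline.

    Loaded from a TOML file with sections [scf], [overlap], [correction],
    [classification] and [parameters]; every key is optional.
    """

    scf_tol: float = DEFAULT_TOL
    scf_max_iter: int = DEFAULT_MAX_ITER
    scf_damping: float = DEFAULT_DAMPING
    overlap_method: str = "exact"          # "exact" | "spline"
    lc_slope: float = LC_SLOPE
    lc_intercept: float = LC_INTERCEPT
    classification_level: str = "cis_dsp"  # gap level used for inverted/normal
    apply_linear_correction: bool = False
    threshold: float = 0.0                 # inverted iff gap < threshold
    cutoff_scale: float = 1.15
    table_path: str | None = None          # alternative valence-state table
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "ScreenConfig":
        data = tomllib.loads(Path(path).read_text())
        cfg = cls()
        scf = data.get("scf", {})
        cfg.scf_tol = float(scf.get("tol", cfg.scf_tol))
        cfg.scf_max_iter = int(scf.get("max_iter", cfg.scf_max_iter))
        cfg.scf_damping = float(scf.get("damping", cfg.scf_damping))
        cfg.overlap_method = data.get("overlap", {}).get(
            "method", cfg.overlap_method)
        corr = data.get("correction", {})
        cfg.lc_slope = float(corr.get("slope", cfg.lc_slope))
        cfg.lc_intercept = float(corr.get("intercept", cfg.lc_intercept))
        cls_ = data.get("classification", {})
        cfg.classification_level = cls_.get("level", cfg.classification_level)
        cfg.apply_linear_correction = bool(
            cls_.get("linear_correction", cfg.apply_linear_correction))
        cfg.threshold = float(cls_.get("threshold", cfg.threshold))
        par = data.get("parameters", {})
        cfg.cutoff_scale = float(par.get("cutoff_scale", cfg.cutoff_scale))
        cfg.table_path = par.get("table_path", cfg.table_path)
        cfg.extra = data
        return cfg
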