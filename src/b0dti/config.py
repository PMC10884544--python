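"""Run configuration: a flat YAML-dialect key-value file, fully validated.

Every pipeline run is derivable from the echoed effective configuration
plus the seed alone; unknown keys are rejected so typos cannot silently
fall back to defaults, and the seed is mandatory.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "load_config"]

_DEFAULTS: dict = {
    "seed": None,  # mandatory
    # scheme: either file paths or the built-in default scheme
    "bval_path": None,
    "bvec_path": None,
    "te_path": None,
    "te_list": [54.0, 75.0, 100.0, 130.0],
    "b_shells": [750.0, 1500.0],
    "n_dirs": 30,
    "n_b0": 3,
    # tissue defaults (stick+zeppelin, rates in 1/s, diffusivities um^2/ms)
    "f": 0.4,
    "d_ia_par": 2.6,
    "d_ea_par": 2.0,
    "d_ea_perp": 0.4,
    "r2_ia": 12.0,
    "r2_ea_iso": 17.4,
    "r2_ea_aniso": 2.4,
    "intra_relaxation": "constant",  # or "dipolar"
    "kappa": "inf",
    # grids
    "f_list": [0.1, 0.3, 0.5, 0.7, 0.9],
    "conditions": ["analytic", "noisy", "dispersed"],
    "n_repeats": 1000,
    "theta_step": 1.0,
    "grid_kappa": 16.0,
    # cohort
    "n_subjects": 2,
    "n_tracts": 5,
    "n_segments_per_tract": 10,
    "n_voxels_per_segment": 8,
    "tilt_angle": 18.0,
    "tissue_jitter": 0.05,
    "segment_scatter_deg": 5.0,
    "snr": 100.0,
    # analysis switches
    "bin_width": 1.0,
    "min_bins": 10,
    "trim_fraction": 0.2,
    "trim_each_end": False,
    "min_voxels": 4,
}

_FRACTIONS = ("f", "tissue_jitter", "trim_fraction")


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted run configuration."""

    values: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError as err:
            raise AttributeError(name) from err

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.values, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def echo(self) -> str:
        """Effective configuration as YAML; re-validating it is idempotent."""
        return yaml.safe_dump(self.values, sort_keys=True)


def validate_config(raw: dict | str) -> RunConfig:
    """Validate a raw config mapping (or YAML text) into a RunConfig.

    Applies documented defaults, rejects unknown keys, requires a seed, and
    range-checks fractions and sizes.  Units are fixed by convention:
    b in s/mm^2, diffusivities in um^2/ms, TE in ms, rates in 1/s.
    """
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a key-value mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    if cfg["seed"] is None:
        raise ValueError("config must set a seed")
    cfg["seed"] = int(cfg["seed"])
    for key in _FRACTIONS:
        v = float(cfg[key])
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{key} = {v} out of range [0, 1]")
        cfg[key] = v
    for key in ("n_subjects", "n_tracts", "n_segments_per_tract",
                "n_voxels_per_segment", "n_dirs", "n_b0", "n_repeats",
                "min_bins", "min_voxels"):
        v = int(cfg[key])
        if v < 1:
            raise ValueError(f"{key} must be a positive integer, got {v}")
        cfg[key] = v
    for key in ("d_ia_par", "d_ea_par", "d_ea_perp", "r2_ia", "r2_ea_iso",
                "r2_ea_aniso", "snr", "bin_width", "theta_step", "grid_kappa"):
        v = float(cfg[key])
        if v < 0:
            raise ValueError(f"{key} must be >= 0, got {v}")
        cfg[key] = v
    if not 0.0 <= float(cfg["tilt_angle"]) < 90.0:
        raise ValueError("tilt_angle must lie in [0, 90)")
    cfg["tilt_angle"] = float(cfg["tilt_angle"])
    cfg["kappa"] = float(cfg["kappa"])
    if cfg["intra_relaxation"] not in ("constant", "dipolar"):
        raise ValueError("intra_relaxation must be 'constant' or 'dipolar'")
    for key in ("bval_path", "bvec_path", "te_path"):
        if cfg[key] is not None and not Path(cfg[key]).exists():
            raise ValueError(f"{key}: file {cfg[key]} not found")
    paths = [cfg[k] is not None for k in ("bval_path", "bvec_path", "te_path")]
    if any(paths) and not all(paths):
        raise ValueError("bval_path, bvec_path and te_path must be given together")
    cfg["te_list"] = [float(v) for v in cfg["te_list"]]
    cfg["b_shells"] = [float(v) for v in cfg["b_shells"]]
    cfg["f_list"] = [float(v) for v in cfg["f_list"]]
    for f in cfg["f_list"]:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"f_list entry {f} out of range [0, 1]")
    cfg["conditions"] = [str(c) for c in cfg["conditions"]]
    for c in cfg["conditions"]:
        if c not in ("analytic", "noisy", "dispersed"):
            raise ValueError(f"unknown condition {c!r}")
    cfg["trim_each_end"] = bool(cfg["trim_each_end"])
    return RunConfig(values=cfg)


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())
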