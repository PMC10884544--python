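"""Synthetic cohort generation: a stand-in for a tiltable-coil study.

Emulates a white-matter tractometry study in which the same subjects are
scanned twice, in a default (0 degree) and a tilted head orientation
(default 18 degrees about the left-right scanner axis), to vary the fibre
angle to B0 without changing the anatomy.  Only single-fibre-population
voxels are generated, organised subject > tract > along-tract segment >
voxel; voxels within a segment share a tract-level fibre direction up to a
small angular scatter so that segment means are meaningful, and per-voxel
tissue parameters are jittered around the reference stick+zeppelin values
to mimic micro-anatomical variability.

Head re-orientation rotates the anatomy (fibre orientations); B0 and the
diffusion-gradient directions remain fixed in the scanner frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import TissueParams, RelaxationModel, signal_no_dispersion, signal_with_dispersion
from .noise import NoiseSpec, add_rician
from .scheme import AcquisitionScheme

__all__ = [
    "CohortConfig",
    "sample_orientations",
    "apply_head_tilt",
    "rotation_matrix",
    "build_cohort",
    "generate_cohort_signals",
    "TISSUE_COLUMNS",
]

TISSUE_COLUMNS = [
    "f",
    "d_ia_par",
    "d_ea_par",
    "d_ea_perp",
    "r2_ia",
    "r2_ea_iso",
    "r2_ea_aniso",
]


@dataclass(frozen=True)
class CohortConfig:
    """Sizes, geometry and variability of the synthetic cohort.

    ``tissue_jitter`` is a per-parameter coefficient of variation for
    multiplicative truncated-Gaussian jitter around the reference tissue
    values; ``segment_scatter_deg`` is the angular scatter of voxel fibre
    orientations about their tract direction.  ``snr`` is defined on the
    b=0, TE=0 signal.
    """

    n_subjects: int = 2
    n_tracts: int = 5
    n_segments_per_tract: int = 10
    n_voxels_per_segment: int = 8
    tilt_angle: float = 18.0
    tilt_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    theta_sampling: str = "uniform_sphere"
    theta_histogram: tuple[tuple[float, float, float], ...] | None = None
    tissue_jitter: float = 0.05
    segment_scatter_deg: float = 5.0
    snr: float = 100.0
    kappa: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_tracts", "n_segments_per_tract", "n_voxels_per_segment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.tilt_angle < 90.0:
            raise ValueError("tilt_angle must lie in [0, 90)")
        if self.tissue_jitter < 0 or self.segment_scatter_deg < 0:
            raise ValueError("jitter and scatter must be >= 0")
        if self.theta_sampling not in ("uniform_sphere", "custom_histogram"):
            raise ValueError(f"unknown theta_sampling {self.theta_sampling!r}")
        ax = np.asarray(self.tilt_axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-8:
            raise ValueError("tilt_axis must be a unit vector")


def sample_orientations(
    n: int, mode: str = "uniform_sphere", seed: int = 0, histogram=None
) -> np.ndarray:
    """Draw n unit fibre orientations.

    ``uniform_sphere`` samples isotropically, so after folding the angle to
    B0 (+z) its density is proportional to sin(theta) on [0, 90] degrees.
    ``custom_histogram`` draws theta from user-supplied (lo_deg, hi_deg,
    weight) bins (uniform within each bin) and the azimuth uniformly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "uniform_sphere":
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    if mode == "custom_histogram":
        if not histogram:
            raise ValueError("custom_histogram mode needs a non-empty histogram")
        hist = np.asarray(histogram, dtype=float)
        w = hist[:, 2]
        if np.all(w <= 0):
            raise ValueError("histogram weights must not all be zero")
        bins = rng.choice(len(hist), size=n, p=w / w.sum())
        theta = np.radians(rng.uniform(hist[bins, 0], hist[bins, 1]))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
    raise ValueError(f"unknown orientation sampling mode {mode!r}")


def rotation_matrix(angle_deg: float, axis) -> np.ndarray:
    """Rotation by angle_deg about a unit axis (Rodrigues form)."""
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    a = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1.0 - np.cos(a)) * (K @ K)


def apply_head_tilt(orientations, angle_deg: float, axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Rotate fibre orientations by the head tilt.

    The head (and with it every fibre) rotates about the given scanner-frame
    axis; B0 and the gradient directions do not move.
    """
    R = rotation_matrix(angle_deg, axis)
    out = np.atleast_2d(np.asarray(orientations, dtype=float)) @ R.T
    return out if np.asarray(orientations).ndim == 2 else out[0]


def _scatter_about(direction: np.ndarray, n: int, scatter_deg: float,
                   rng: np.random.Generator) -> np.ndarray:
    """n unit vectors scattered about `direction` with ~scatter_deg spread."""
    if scatter_deg == 0:
        return np.tile(direction, (n, 1))
    # tangent-plane Gaussian scatter, renormalised
    t = np.radians(scatter_deg)
    helper = np.array([1.0, 0.0, 0.0]) if abs(direction[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    offs = rng.normal(0.0, t, size=(n, 2))
    v = direction + offs[:, :1] * e1 + offs[:, 1:] * e2
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _jitter(values: np.ndarray, cv: float, rng: np.random.Generator,
            lo: float = 0.0, hi: float = np.inf) -> np.ndarray:
    """Multiplicative truncated-Gaussian jitter with coefficient of variation cv."""
    if cv == 0:
        return values.copy()
    factors = rng.normal(1.0, cv, size=values.shape)
    factors = np.clip(factors, 1.0 - 3.0 * cv, 1.0 + 3.0 * cv)
    return np.clip(values * factors, lo, hi)


def build_cohort(config: CohortConfig, tissue: TissueParams | None = None) -> pd.DataFrame:
    """Generate the voxel table of the synthetic cohort.

    One row per voxel with ids (subject, tract, segment, voxel), the fibre
    orientation in the default head position (scanner frame, unit vector)
    and the jittered tissue parameters.  Deterministic given
    ``config.seed``.
    """
    tissue = tissue or TissueParams()
    rng = np.random.default_rng(config.seed)
    rows = []
    for subj in range(config.n_subjects):
        tract_dirs = sample_orientations(
            config.n_tracts,
            config.theta_sampling,
            seed=int(rng.integers(2**31)),
            histogram=config.theta_histogram,
        )
        for tract in range(config.n_tracts):
            for seg in range(config.n_segments_per_tract):
                # segments drift slightly along the tract
                seg_dir = _scatter_about(tract_dirs[tract], 1, config.segment_scatter_deg / 2, rng)[0]
                vox_dirs = _scatter_about(
                    seg_dir, config.n_voxels_per_segment, config.segment_scatter_deg, rng
                )
                for vox in range(config.n_voxels_per_segment):
                    rows.append(
                        (subj, tract, seg, vox, *vox_dirs[vox])
                    )
    df = pd.DataFrame(
        rows, columns=["subject", "tract", "segment", "voxel", "nx", "ny", "nz"]
    )
    nvox = len(df)
    cv = config.tissue_jitter
    df["f"] = _jitter(np.full(nvox, tissue.f), cv, rng, 0.0, 1.0)
    df["d_ia_par"] = _jitter(np.full(nvox, tissue.d_ia_par), cv, rng)
    df["d_ea_par"] = _jitter(np.full(nvox, tissue.d_ea_par), cv, rng)
    df["d_ea_perp"] = _jitter(np.full(nvox, tissue.d_ea_perp), cv, rng,
                              hi=float(df["d_ea_par"].min()))
    # keep the zeppelin prolate voxel-wise
    df["d_ea_perp"] = np.minimum(df["d_ea_perp"], df["d_ea_par"])
    df["r2_ia"] = _jitter(np.full(nvox, tissue.relax_intra.r2_iso), cv, rng)
    df["r2_ea_iso"] = _jitter(np.full(nvox, tissue.relax_extra.r2_iso), cv, rng)
    df["r2_ea_aniso"] = _jitter(np.full(nvox, tissue.relax_extra.r2_aniso), cv, rng)
    df["is_sfp"] = True
    return df


def _voxel_tissue(row, kappa: float, extra_kind: str = "sin4") -> TissueParams:
    return TissueParams(
        f=row.f,
        d_ia_par=row.d_ia_par,
        d_ia_perp=0.0,
        d_ea_par=row.d_ea_par,
        d_ea_perp=min(row.d_ea_perp, row.d_ea_par),
        relax_intra=RelaxationModel("constant", row.r2_ia, 0.0),
        relax_extra=RelaxationModel(extra_kind, row.r2_ea_iso, row.r2_ea_aniso),
        n=(row.nx, row.ny, row.nz),
        kappa=kappa,
    )


def generate_cohort_signals(
    cohort: pd.DataFrame,
    scheme: AcquisitionScheme,
    config: CohortConfig,
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Simulate the diffusion-relaxation signals of every cohort voxel in
    both head orientations.

    Returns a long table with one row per voxel x head orientation,
    carrying the orientation actually seen by the scanner, the true fibre
    angle to B0, and the (optionally Rician-noisy) signal vector for every
    scheme measurement in wide columns ``s0 .. s{M-1}``.
    """
    if noise is None:
        noise = NoiseSpec(snr=config.snr, seed=config.seed + 1)
    rng = noise.rng()
    b0 = np.asarray(scheme.b0_direction)
    R = rotation_matrix(config.tilt_angle, config.tilt_axis)
    out_rows = []
    sig_blocks = []
    for _, row in cohort.iterrows():
        n_default = np.array([row.nx, row.ny, row.nz])
        for orient, n_vec in (("default", n_default), ("tilted", R @ n_default)):
            tissue = _voxel_tissue(row, config.kappa).with_(n=tuple(n_vec))
            if np.isfinite(config.kappa):
                s = signal_with_dispersion(scheme.b, scheme.g, scheme.te, tissue, b0)
            else:
                s = signal_no_dispersion(scheme.b, scheme.g, scheme.te, tissue, b0)
            s = add_rician(s, noise.sigma, rng)
            theta_true = float(np.degrees(np.arccos(min(abs(n_vec @ b0), 1.0))))
            out_rows.append(
                (int(row.subject), int(row.tract), int(row.segment), int(row.voxel),
                 orient, theta_true)
            )
            sig_blocks.append(s)
    meta = pd.DataFrame(
        out_rows,
        columns=["subject", "tract", "segment", "voxel", "orientation", "theta_true"],
    )
    sig = pd.DataFrame(
        np.vstack(sig_blocks), columns=[f"s{i}" for i in range(len(scheme))]
    )
    return pd.concat([meta, sig], axis=1)
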