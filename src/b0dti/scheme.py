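"""Acquisition schemes: per-measurement (b, g, TE) plus pulse timing.

Schemes are read and written in the FSL dialect: a ``bval`` file with one
whitespace-separated row of b-values (s/mm^2), a ``bvec`` file with three
rows of x/y/z gradient components in the scanner frame, and a sidecar text
column of echo times (ms), one per measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AcquisitionScheme", "read_scheme", "write_scheme", "default_scheme", "shell_directions"]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion-relaxation acquisition: arrays of b (s/mm^2), unit gradient
    directions (scanner frame) and echo times (ms), with pulse timings
    Delta (time between diffusion gradients) and delta (gradient duration).

    b = 0 rows may carry a zero gradient vector; every echo time must offer
    at least 7 non-collinear nonzero-b measurements plus a b = 0 measurement
    so that a diffusion tensor is estimable per TE.
    """

    b: np.ndarray
    g: np.ndarray
    te: np.ndarray
    delta_big: float = 22.0
    delta_small: float = 8.0
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float).ravel()
        g = np.asarray(self.g, dtype=float).reshape(-1, 3)
        te = np.asarray(self.te, dtype=float).ravel()
        if not (len(b) == len(g) == len(te)):
            raise ValueError(
                f"measurement counts differ: {len(b)} b-values, {len(g)} gradients, {len(te)} echo times"
            )
        if np.any(b < 0):
            raise ValueError("b-values must be >= 0")
        if np.any(te < 0):
            raise ValueError("echo times must be >= 0")
        norms = np.linalg.norm(g, axis=1)
        dwi = b > 0
        bad = dwi & (np.abs(norms - 1.0) > 1e-8)
        if np.any(bad):
            raise ValueError(f"non-unit gradient at rows {np.flatnonzero(bad).tolist()}")
        b0d = np.asarray(self.b0_direction, dtype=float)
        if abs(np.linalg.norm(b0d) - 1.0) > 1e-8:
            raise ValueError("b0_direction must be a unit vector")
        for te_val in np.unique(te):
            sel = te == te_val
            if np.count_nonzero(sel & dwi) < 7 or np.count_nonzero(sel & ~dwi) < 1:
                raise ValueError(
                    f"TE={te_val} needs >= 7 diffusion-weighted and >= 1 b=0 measurements"
                )
            gd = g[sel & dwi]
            outer = np.column_stack(
                [gd[:, 0] ** 2, gd[:, 1] ** 2, gd[:, 2] ** 2,
                 gd[:, 0] * gd[:, 1], gd[:, 0] * gd[:, 2], gd[:, 1] * gd[:, 2]]
            )
            if np.linalg.matrix_rank(outer) < 6:
                raise ValueError(
                    f"TE={te_val}: diffusion directions are collinear/degenerate; "
                    "a tensor is not estimable"
                )
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "b0_direction", tuple(b0d))

    def __len__(self) -> int:
        return len(self.b)

    @property
    def te_values(self) -> np.ndarray:
        return np.unique(self.te)

    def subset_te(self, te_value: float) -> "AcquisitionScheme":
        """Rows acquired at a single echo time (tensors are fitted per TE)."""
        sel = self.te == te_value
        if not np.any(sel):
            raise ValueError(f"no measurements at TE={te_value}")
        return AcquisitionScheme(
            self.b[sel], self.g[sel], self.te[sel],
            self.delta_big, self.delta_small, self.b0_direction,
        )


def shell_directions(n: int, seed: int = 0) -> np.ndarray:
    """n roughly uniform unit vectors on the hemisphere.

    A golden-spiral seed polished by a few electrostatic-repulsion steps on
    antipodally symmetrised charges; deterministic for a given (n, seed).
    """
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * (i + seed)
    z = i / n  # hemisphere
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    for _ in range(60):
        # antipodal pairs repel: force from both q and -q
        d1 = pts[:, None, :] - pts[None, :, :]
        d2 = pts[:, None, :] + pts[None, :, :]
        r1 = np.linalg.norm(d1, axis=-1) + np.eye(n)
        r2 = np.linalg.norm(d2, axis=-1)
        force = (d1 / r1[..., None] ** 3).sum(axis=1) + (d2 / r2[..., None] ** 3).sum(axis=1)
        pts = pts + 0.003 * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[pts[:, 2] < 0] *= -1.0
    return pts


def default_scheme(
    te_list=(54.0, 75.0, 100.0, 130.0),
    b_shells=(750.0, 1500.0),
    n_dirs: int = 30,
    n_b0: int = 3,
    delta_big: float = 22.0,
    delta_small: float = 8.0,
) -> AcquisitionScheme:
    """Multi-TE two-shell scheme: per TE, ``n_b0`` b=0 rows plus ``n_dirs``
    directions on each shell, directions shared across TEs (fixed in the
    scanner frame)."""
    dirs = shell_directions(n_dirs)
    b_rows, g_rows, te_rows = [], [], []
    for te in te_list:
        b_rows.extend([0.0] * n_b0)
        g_rows.extend([[0.0, 0.0, 0.0]] * n_b0)
        te_rows.extend([te] * n_b0)
        for b in b_shells:
            b_rows.extend([b] * n_dirs)
            g_rows.extend(dirs.tolist())
            te_rows.extend([te] * n_dirs)
    return AcquisitionScheme(
        np.array(b_rows), np.array(g_rows), np.array(te_rows), delta_big, delta_small
    )


def read_scheme(
    bval_path, bvec_path, te_path, delta_big: float = 22.0, delta_small: float = 8.0
) -> AcquisitionScheme:
    """Read an FSL-dialect bval/bvec pair plus a TE sidecar column.

    Gradient norms within 1% of unity are renormalised; larger deviations
    on diffusion-weighted rows are rejected.  b = 0 rows accept zero
    vectors.
    """
    b = np.loadtxt(bval_path, dtype=float).ravel()
    g = np.loadtxt(bvec_path, dtype=float)
    te = np.loadtxt(te_path, dtype=float).ravel()
    if g.ndim != 2 or 3 not in g.shape:
        raise ValueError(f"bvec file {bvec_path} must hold a 3xN or Nx3 array")
    if g.shape[0] == 3 and g.shape[1] != 3:
        g = g.T
    elif g.shape == (3, 3):
        g = g.T  # FSL convention: rows are components
    if g.shape[0] != b.size:
        raise ValueError(
            f"bvec row count {g.shape[0]} does not match bval count {b.size}"
        )
    if te.size != b.size:
        raise ValueError(f"TE count {te.size} does not match bval count {b.size}")
    if np.any(b < 0):
        raise ValueError("bval: negative b-value")
    norms = np.linalg.norm(g, axis=1)
    dwi = b > 0
    off = np.abs(norms - 1.0)
    bad = dwi & (off > 0.01)
    if np.any(bad):
        raise ValueError(
            f"bvec: gradient norm deviates >1% from unity at rows {np.flatnonzero(bad).tolist()}"
        )
    fix = dwi & (off > 0)
    g = g.copy()
    g[fix] /= norms[fix, None]
    return AcquisitionScheme(b, g, te, delta_big, delta_small)


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path, te_path) -> None:
    """Write the FSL-dialect bval/bvec pair and the TE sidecar."""
    Path(bval_path).write_text(" ".join(f"{v:.6g}" for v in scheme.b) + "\n")
    rows = [" ".join(f"{v:.17g}" for v in scheme.g[:, i]) for i in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")
    Path(te_path).write_text("\n".join(f"{v:.6g}" for v in scheme.te) + "\n")
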