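"""Diffusion-tensor estimation by iterative weighted linear least squares.

The log-signal of a mono-exponential tensor model is linear in the seven
parameters (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz):

    ln S_i = ln S0 - sum_jk b_i g_ij g_ik D_jk.

Ordinary least squares on log-signals is biased because log-transformed
noise is heteroscedastic with variance ~ sigma^2 / S_i^2; IWLLS corrects
this by weighting each row with the squared model-predicted signal and
iterating until the parameters settle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import AcquisitionScheme

__all__ = [
    "DTFitResult",
    "DiffusionTensorModel",
    "fit_dt_iwlls",
    "fibre_angle_to_b0",
    "design_matrix",
]

_TENSOR_COLS = ["dxx", "dyy", "dzz", "dxy", "dxz", "dyz"]


def design_matrix(b: np.ndarray, g: np.ndarray) -> np.ndarray:
    """B-matrix design for the 7-parameter log-linear tensor model.

    Columns: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    with b rescaled by 1e-3 so the fitted tensor is in um^2/ms for b in
    s/mm^2.
    """
    b = np.asarray(b, dtype=float) * 1e-3
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fibre_angle_to_b0(e1, b0_dir) -> float:
    """Folded angle (degrees, [0, 90]) between the principal eigenvector and B0."""
    e1 = np.asarray(e1, dtype=float)
    b0 = np.asarray(b0_dir, dtype=float)
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(b0)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length vector")
    c = abs(float(e1 @ b0)) / (n1 * n2)
    return float(np.degrees(np.arccos(min(c, 1.0))))


@dataclass(frozen=True)
class DTFitResult:
    """Fitted diffusion tensor at one echo time.

    Carries the symmetric tensor (um^2/ms), its eigenstructure sorted
    l1 >= l2 >= l3, the scalar measures MD = mean(eigs), AD = l1,
    RD = (l2+l3)/2, FA, and the folded fibre angle theta to B0 from the
    principal eigenvector.
    """

    s0: float
    tensor: np.ndarray
    eigenvalues: np.ndarray
    e1: np.ndarray
    md: float
    ad: float
    rd: float
    fa: float
    theta: float
    converged: bool
    n_iter: int
    negative_eigenvalues: bool
    n_clipped: int

    def summary(self) -> str:
        lines = [
            "Diffusion tensor fit (IWLLS)",
            f"  S0        : {self.s0:.6g}",
            f"  eigenvalues (um^2/ms): {self.eigenvalues[0]:.4f}, "
            f"{self.eigenvalues[1]:.4f}, {self.eigenvalues[2]:.4f}",
            f"  MD / AD / RD: {self.md:.4f} / {self.ad:.4f} / {self.rd:.4f} um^2/ms",
            f"  FA        : {self.fa:.4f}",
            f"  theta(B0) : {self.theta:.2f} deg",
            f"  converged : {self.converged} ({self.n_iter} iterations)"
            + ("  [negative eigenvalues]" if self.negative_eigenvalues else ""),
        ]
        return "\n".join(lines)


def _iwlls_batch(
    X: np.ndarray, signals: np.ndarray, max_iter: int = 10, rtol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IWLLS over a batch of voxels.

    signals: (V, M) positive. Returns (beta (V,7), converged (V,), n_iter (V,),
    n_clipped (V,)).
    """
    V, M = signals.shape
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design: directions are collinear")
    s0_guess = np.maximum(signals.max(axis=1), 1e-300)
    floor = 1e-10 * s0_guess[:, None]
    clipped = signals < floor
    s = np.maximum(signals, floor)
    y = np.log(s)
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # OLS init, (V, 7)
    converged = np.zeros(V, dtype=bool)
    n_iter = np.zeros(V, dtype=int)
    active = np.ones(V, dtype=bool)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        w = np.exp(X @ beta[idx].T).T  # predicted signals, (v, M)
        w2 = w**2
        # weighted normal equations per voxel: (X' W X) beta = X' W y
        Xw = X[None, :, :] * w2[:, :, None]  # (v, M, 7)
        A = np.einsum("vmi,mj->vij", Xw, X)
        rhs = np.einsum("vmi,vm->vi", Xw, y[idx])
        new = np.linalg.solve(A, rhs[..., None])[..., 0]
        # relative change against the parameter-vector scale (componentwise
        # ratios blow up on exact zeros, e.g. off-diagonals of diagonal tensors)
        scale = np.maximum(np.max(np.abs(beta[idx]), axis=1), 1e-12)
        delta = np.max(np.abs(new - beta[idx]), axis=1) / scale
        beta[idx] = new
        n_iter[idx] = it
        done = delta < rtol
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, converged, n_iter, clipped.sum(axis=1)


def _eig_measures(beta: np.ndarray) -> dict[str, np.ndarray]:
    """Eigen-decomposition and scalar measures for a batch of beta (V, 7)."""
    V = beta.shape[0]
    D = np.empty((V, 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[:, ::-1]
    e1 = evecs[:, :, ::-1][:, :, 0]
    md = evals.mean(axis=1)
    ad = evals[:, 0]
    rd = 0.5 * (evals[:, 1] + evals[:, 2])
    lbar = md[:, None]
    ss = np.sum(evals**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum((evals - lbar) ** 2, axis=1) / ss)
    fa = np.where(ss == 0, 0.0, np.clip(fa, 0.0, 1.0))
    return {
        "s0": np.exp(beta[:, 0]),
        "tensor": D,
        "evals": evals,
        "e1": e1,
        "md": md,
        "ad": ad,
        "rd": rd,
        "fa": fa,
    }


class DiffusionTensorModel:
    """Log-linear diffusion tensor model for signals at one echo time.

    Parameters
    ----------
    scheme : AcquisitionScheme
        Must contain a single echo time (use ``scheme.subset_te``); needs
        at least 7 diffusion-weighted measurements spanning 6 non-collinear
        directions plus a b = 0 row.
    signals : array, (M,) or (V, M)
        Measured signals; a 2-d array fits V voxels in one vectorised pass.

    ``fit()`` runs IWLLS: OLS on log-signals to initialise, then weighted
    least squares with weights equal to the squared model-predicted
    signals, iterated to a relative parameter tolerance of 1e-6 (max 10
    iterations).  Nonpositive signals are clipped to 1e-10 x S0 before the
    log; the count of clipped samples is reported.  No positivity
    constraint is imposed on the tensor: negative eigenvalues are flagged,
    not repaired.
    """

    def __init__(self, scheme: AcquisitionScheme, signals):
        if len(scheme.te_values) != 1:
            raise ValueError(
                "DiffusionTensorModel fits one echo time at a time; "
                "use scheme.subset_te() to split a multi-TE scheme"
            )
        signals = np.asarray(signals, dtype=float)
        self._single = signals.ndim == 1
        self.signals = np.atleast_2d(signals)
        if self.signals.shape[1] != len(scheme):
            raise ValueError(
                f"signal count {self.signals.shape[1]} does not match scheme length {len(scheme)}"
            )
        self.scheme = scheme
        self.design = design_matrix(scheme.b, scheme.g)

    def fit(self, max_iter: int = 10, rtol: float = 1e-6):
        beta, conv, n_iter, n_clip = _iwlls_batch(
            self.design, self.signals, max_iter=max_iter, rtol=rtol
        )
        m = _eig_measures(beta)
        b0 = np.asarray(self.scheme.b0_direction)
        results = []
        for v in range(beta.shape[0]):
            results.append(
                DTFitResult(
                    s0=float(m["s0"][v]),
                    tensor=m["tensor"][v],
                    eigenvalues=m["evals"][v],
                    e1=m["e1"][v],
                    md=float(m["md"][v]),
                    ad=float(m["ad"][v]),
                    rd=float(m["rd"][v]),
                    fa=float(m["fa"][v]),
                    theta=fibre_angle_to_b0(m["e1"][v], b0),
                    converged=bool(conv[v]),
                    n_iter=int(n_iter[v]),
                    negative_eigenvalues=bool(m["evals"][v, 2] < 0),
                    n_clipped=int(n_clip[v]),
                )
            )
        return results[0] if self._single else results

    def fit_arrays(self, max_iter: int = 10, rtol: float = 1e-6) -> dict[str, np.ndarray]:
        """Batched fit returning plain arrays (fast path for pipelines)."""
        beta, conv, n_iter, n_clip = _iwlls_batch(
            self.design, self.signals, max_iter=max_iter, rtol=rtol
        )
        m = _eig_measures(beta)
        b0 = np.asarray(self.scheme.b0_direction)
        cos = np.abs(m["e1"] @ b0)
        m["theta"] = np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))
        m["converged"] = conv
        m["n_iter"] = n_iter
        m["n_clipped"] = n_clip
        return m


def fit_dt_iwlls(scheme: AcquisitionScheme, signals) -> DTFitResult:
    """Fit a diffusion tensor to one voxel's signals at a single TE."""
    return DiffusionTensorModel(scheme, np.asarray(signals, dtype=float)).fit()
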