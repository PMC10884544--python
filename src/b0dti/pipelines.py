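"""The three study pipelines.

* ``run_simulation_grid`` — anisotropy of MD/AD/RD/FA over a grid of
  axonal fractions and echo times, in three conditions: noiseless
  analytic curves, Rician-noisy tensor fits, and Watson-dispersed noisy
  tensor fits.
* ``run_pooled_analysis`` — pool every single-fibre voxel from all
  subjects and both head orientations, then quantify each measure's
  theta-dependence per TE by 1-degree binning + weighted smoothing spline
  and by the sin^4 representation.
* ``run_tractometry`` — compare the same anatomical segments across the
  two head orientations: segment-mean changes of each measure regressed
  through the origin on the segment-mean change of sin^4(theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anisotropy import (
    Sin4AnisotropyModel,
    SplineAnisotropyModel,
    aic_least_squares,
    fit_sin4,
)
from .cohort import CohortConfig, rotation_matrix
from .forward import (
    TissueParams,
    analytic_dt_measures,
    signal_no_dispersion,
    signal_with_dispersion,
)
from .noise import NoiseSpec, add_rician
from .scheme import AcquisitionScheme, default_scheme
from .tensor import DiffusionTensorModel

__all__ = [
    "run_simulation_grid",
    "fit_cohort_tensors",
    "run_pooled_analysis",
    "run_tractometry",
    "MEASURES",
]

MEASURES = ("md", "ad", "rd", "fa")

_F_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
_TE_GRID = (54.0, 75.0, 100.0, 130.0)


def _orientation_for_theta(theta_deg: np.ndarray, phi: np.ndarray) -> np.ndarray:
    t = np.radians(theta_deg)
    return np.column_stack(
        [np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), np.cos(t)]
    )


def _simulate_cell_fits(
    tissue: TissueParams,
    scheme_te: AcquisitionScheme,
    n_repeats: int,
    snr: float,
    rng: np.random.Generator,
    dispersed: bool,
    kappa: float,
) -> tuple[np.ndarray, dict]:
    """Simulate n_repeats voxels spanning theta in [0, 90] and fit tensors."""
    theta = np.linspace(0.0, 90.0, n_repeats)
    # random azimuths: a fixed azimuth per theta would turn the direction-set-
    # dependent estimation bias into a systematic pseudo-trend in theta
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_repeats)
    dirs = _orientation_for_theta(theta, phi)
    b0 = np.asarray(scheme_te.b0_direction)
    signals = np.empty((n_repeats, len(scheme_te)))
    for i in range(n_repeats):
        t = tissue.with_(n=tuple(dirs[i]), kappa=kappa if dispersed else np.inf)
        if dispersed:
            signals[i] = signal_with_dispersion(
                scheme_te.b, scheme_te.g, scheme_te.te, t, b0
            )
        else:
            signals[i] = signal_no_dispersion(
                scheme_te.b, scheme_te.g, scheme_te.te, t, b0
            )
    if np.isfinite(snr):
        sigma = 1.0 / snr  # SNR defined on the b=0, TE=0 signal (=1, normalised)
        e1 = rng.normal(0.0, sigma, size=signals.shape)
        e2 = rng.normal(0.0, sigma, size=signals.shape)
        signals = np.sqrt((signals + e1) ** 2 + e2**2)
    fits = DiffusionTensorModel(scheme_te, signals).fit_arrays()
    return theta, fits


def run_simulation_grid(
    f_list=_F_GRID,
    te_list=_TE_GRID,
    conditions=("analytic", "noisy", "dispersed"),
    tissue: TissueParams | None = None,
    scheme: AcquisitionScheme | None = None,
    snr: float = 100.0,
    kappa: float = 16.0,
    n_repeats: int = 1000,
    theta_step: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Anisotropy B of each tensor measure over the (f, TE) grid.

    For every grid cell and condition the measure-versus-theta relation is
    built (analytically on a ``theta_step``-degree grid, or from simulated
    noisy tensor fits of ``n_repeats`` voxels with theta spread over
    [0, 90]), the sin^4 representation is fitted, and its coefficient B and
    model-selection verdict are recorded.  One row per condition x measure
    x TE x f.
    """
    tissue = tissue or TissueParams()
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        if cond not in ("analytic", "noisy", "dispersed"):
            raise ValueError(f"unknown condition {cond!r}")
        for f in f_list:
            tis = tissue.with_(f=f)
            for te in te_list:
                if cond == "analytic":
                    theta = np.arange(0.0, 90.0 + theta_step / 2, theta_step)
                    vals = {m: np.empty_like(theta) for m in MEASURES}
                    for i, th in enumerate(theta):
                        meas = analytic_dt_measures(te, th, tis)
                        for m in MEASURES:
                            vals[m][i] = getattr(meas, m)
                    theta_fit = theta
                else:
                    if scheme is None:
                        scheme = default_scheme(te_list=tuple(te_list))
                    sch = scheme.subset_te(te)
                    theta_fit, fits = _simulate_cell_fits(
                        tis,
                        sch,
                        n_repeats,
                        snr,
                        rng,
                        dispersed=(cond == "dispersed"),
                        kappa=kappa,
                    )
                    theta_fit = fits["theta"]  # fitted angle, as in the estimation chain
                    vals = {m: fits[m] for m in MEASURES}
                for m in MEASURES:
                    res = fit_sin4(theta_fit, vals[m])
                    rows.append(
                        dict(
                            condition=cond,
                            measure=m,
                            te=te,
                            f=f,
                            a_hat=res.a_hat,
                            b_hat=res.b_hat,
                            b_ci_lo=res.b_ci85[0],
                            b_ci_hi=res.b_ci85[1],
                            aic_iso=res.aic_iso,
                            aic_aniso=res.aic_aniso,
                            delta_aic=res.delta_aic,
                            selected=res.selected,
                            seed=seed,
                        )
                    )
    return pd.DataFrame(rows)


def fit_cohort_tensors(signals: pd.DataFrame, scheme: AcquisitionScheme) -> pd.DataFrame:
    """Fit per-TE diffusion tensors for every cohort voxel x orientation.

    ``signals`` is the wide table from ``generate_cohort_signals``.
    Returns a tidy table with one row per voxel x orientation x TE carrying
    MD/AD/RD/FA (um^2/ms), the fitted fibre angle theta (degrees) and fit
    flags.
    """
    id_cols = ["subject", "tract", "segment", "voxel", "orientation"]
    sig = signals[[c for c in signals.columns if c.startswith("s") and c[1:].isdigit()]]
    sig = sig.to_numpy()
    out = []
    for te in scheme.te_values:
        sel = scheme.te == te
        sch = scheme.subset_te(te)
        fits = DiffusionTensorModel(sch, sig[:, sel]).fit_arrays()
        block = signals[id_cols].copy()
        block["te"] = te
        for m in MEASURES:
            block[m] = fits[m]
        block["theta"] = fits["theta"]
        block["converged"] = fits["converged"]
        block["negative_eigenvalues"] = fits["evals"][:, 2] < 0
        out.append(block)
    return pd.concat(out, ignore_index=True)


def run_pooled_analysis(
    fits: pd.DataFrame, width: float = 1.0, min_bins: int = 10
) -> pd.DataFrame:
    """Pooled single-fibre-voxel analysis per measure x TE.

    All voxels from all subjects and both head orientations are pooled.
    Each measure's theta-dependence is quantified two ways: binning in
    ``width``-degree subsets followed by a count-weighted smoothing spline
    (signed magnitude + variance contribution), and the sin^4
    representation on the unbinned voxel values (A, B, selection).
    """
    rows = []
    for te, g in fits.groupby("te"):
        for m in MEASURES:
            theta = g["theta"].to_numpy()
            vals = g[m].to_numpy()
            row = dict(te=te, measure=m, n_voxels=len(g))
            try:
                spl = SplineAnisotropyModel(theta, vals, width=width, min_bins=min_bins).fit()
                row.update(
                    magnitude=spl.magnitude,
                    variance_contribution=spl.variance_contribution,
                    std_iso=spl.std_iso,
                    std_aniso=spl.std_aniso,
                    n_bins=len(spl.bin_centers),
                )
            except ValueError as err:
                row.update(magnitude=np.nan, variance_contribution=np.nan,
                           n_bins=np.nan, error=str(err))
            try:
                res = fit_sin4(theta, vals)
                row.update(
                    a_hat=res.a_hat,
                    b_hat=res.b_hat,
                    b_ci_lo=res.b_ci85[0],
                    b_ci_hi=res.b_ci85[1],
                    delta_aic=res.delta_aic,
                    selected=res.selected,
                )
            except (ValueError, np.linalg.LinAlgError) as err:
                row.update(a_hat=np.nan, b_hat=np.nan, b_ci_lo=np.nan,
                           b_ci_hi=np.nan, delta_aic=np.nan,
                           selected="degenerate", error=str(err))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TractometryFit:
    """Origin-constrained fit d(measure) = B * d(sin^4 theta) across segments."""

    b_hat: float
    b_se: float
    aic_iso: float
    aic_aniso: float
    star: bool
    std_change: float
    n_segments: int


def _origin_fit(x: np.ndarray, y: np.ndarray) -> TractometryFit:
    sxx = float(x @ x)
    if sxx <= 0:
        raise np.linalg.LinAlgError("degenerate regressor: no spread in d(sin^4 theta)")
    b = float(x @ y) / sxx
    resid = y - b * x
    n = len(y)
    rss = float(resid @ resid)
    rss_iso = float(y @ y)  # isotropic assumption: B = 0
    aic_aniso = aic_least_squares(rss, n, 1)
    aic_iso = aic_least_squares(rss_iso, n, 0)
    dof = max(n - 1, 1)
    se = np.sqrt(rss / dof / sxx)
    std_y = float(np.std(y))
    std_change = (std_y - float(np.std(resid))) / std_y if std_y > 0 else np.nan
    return TractometryFit(
        b_hat=b,
        b_se=float(se),
        aic_iso=aic_iso,
        aic_aniso=aic_aniso,
        star=bool(aic_iso - aic_aniso > 2.0),
        std_change=std_change,
        n_segments=n,
    )


def run_tractometry(
    fits: pd.DataFrame,
    trim_fraction: float = 0.2,
    min_voxels: int = 4,
    trim_each_end: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment-wise comparison of default versus tilted head orientation.

    Segment means over single-fibre voxels are formed per orientation for
    each measure and for sin^4(theta); the outer-most ``trim_fraction`` of
    segments per tract (half from each end, or ``trim_fraction`` from each
    end when ``trim_each_end``) and segments with fewer than ``min_voxels``
    voxels are excluded.  For every measure x TE the change across
    orientations is fitted through the origin,
    d(measure) = B * d(sin^4 theta), with an AIC comparison against B = 0.

    Returns ``(summary, segments)``: one summary row per measure x TE and
    the surviving per-segment difference table.
    """
    df = fits.copy()
    df["sin4"] = np.sin(np.radians(df["theta"])) ** 4
    key = ["subject", "tract", "segment", "te"]
    seg = (
        df.groupby(key + ["orientation"])
        .agg(**{m: (m, "mean") for m in MEASURES},
             sin4=("sin4", "mean"), n_voxels=("sin4", "size"))
        .reset_index()
    )
    wide = seg.pivot_table(index=key, columns="orientation").reset_index()
    wide.columns = ["_".join(c).rstrip("_") if c[1] else c[0] for c in wide.columns]
    need = [f"{c}_{o}" for c in ("sin4", "n_voxels") for o in ("default", "tilted")]
    missing = [c for c in need if c not in wide.columns]
    if missing:
        raise ValueError("tractometry needs both head orientations for every segment")
    # voxel-count exclusion: "3 or fewer voxels" are dropped
    keep = (wide["n_voxels_default"] >= min_voxels) & (wide["n_voxels_tilted"] >= min_voxels)
    wide = wide[keep]
    # end-segment trim per tract
    n_seg = int(df["segment"].max()) + 1
    cut = trim_fraction if trim_each_end else trim_fraction / 2.0
    lo, hi = np.floor(n_seg * cut), np.ceil(n_seg * (1.0 - cut)) - 1
    wide = wide[(wide["segment"] >= lo) & (wide["segment"] <= hi)]
    if len(wide) == 0:
        raise ValueError("no segments survive the exclusion rules")
    segments = wide[key].copy()
    segments["d_sin4"] = wide["sin4_default"].to_numpy() - wide["sin4_tilted"].to_numpy()
    for m in MEASURES:
        segments[f"d_{m}"] = wide[f"{m}_default"].to_numpy() - wide[f"{m}_tilted"].to_numpy()
    rows = []
    for te, g in segments.groupby("te"):
        x = g["d_sin4"].to_numpy()
        for m in MEASURES:
            y = g[f"d_{m}"].to_numpy()
            row = dict(te=te, measure=m)
            try:
                fit = _origin_fit(x, y)
                row.update(
                    b_hat=fit.b_hat, b_se=fit.b_se, aic_iso=fit.aic_iso,
                    aic_aniso=fit.aic_aniso, star=fit.star,
                    std_change=fit.std_change, n_segments=fit.n_segments,
                    degenerate=False,
                )
            except np.linalg.LinAlgError:
                row.update(b_hat=np.nan, b_se=np.nan, aic_iso=np.nan,
                           aic_aniso=np.nan, star=False, std_change=np.nan,
                           n_segments=len(g), degenerate=True)
            rows.append(row)
    return pd.DataFrame(rows), segments
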