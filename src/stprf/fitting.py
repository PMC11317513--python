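"""Model fitting: OLS, split-half cross-validation, grid fits, retinotopy.

All variance-explained quantities are reported in percent so that
cross-validated R-squared, adjusted R-squared, split-half reliability (the
noise ceiling) and the voxel-inclusion thresholds live on one scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .hemodynamics import causal_convolve, double_gamma_hrf
from .stimulus import GridSpec, RetinotopyStimulus, SquareLayout

__all__ = [
    "FitResult",
    "fit_ols",
    "crossval_fit",
    "gridfit_cst_exponent",
    "split_half_reliability",
    "select_voxels",
    "CSSRetinoFit",
    "RetinoSearchSpec",
    "fit_css_retinotopy",
    "normalize_prediction",
    "CST_EXPONENT_GRID",
]

CST_EXPONENT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 1.0001, 0.05), 2))


@dataclass
class FitResult:
    """Cross-validated fit of one voxel.

    ``betas`` holds the offset followed by the regressor weights (one weight
    for single-predictor models; sustained and transient weights for the
    two-channel model).  Percent scale for the R-squared family.
    """

    betas: np.ndarray
    cv_r2: float
    adj_cv_r2: float
    best_cst_n: float | None = None
    noise_ceiling: float | None = None
    flags: tuple[str, ...] = ()


def _design(predictors: np.ndarray) -> np.ndarray:
    predictors = np.asarray(predictors, dtype=np.float64)
    if predictors.ndim == 1:
        predictors = predictors[:, None]
    return np.column_stack([np.ones(predictors.shape[0]), predictors])


def normalize_prediction(pred: np.ndarray) -> np.ndarray:
    """Scale a predicted time series (or each column) to a maximum of 1."""
    pred = np.asarray(pred, dtype=np.float64)
    if pred.ndim == 1:
        m = pred.max()
        return pred / m if m > 0 else pred.copy()
    out = pred.copy()
    for j in range(out.shape[1]):
        m = out[:, j].max()
        if m > 0:
            out[:, j] = out[:, j] / m
    return out


def fit_ols(predictors: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Ordinary-least-squares betas, intercept first.

    A column of ones is prepended to capture the response offset.  Rank
    deficiency is flagged with a warning and resolved by the minimum-norm
    (pseudo-inverse) solution.
    """
    X = _design(predictors)
    y = np.asarray(data, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("predictors and data have different lengths")
    betas, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design; minimum-norm solution used", stacklevel=2)
    return betas


def _r2_percent(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 100.0 * (1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot)


def crossval_fit(
    pred_halves: Sequence[np.ndarray],
    data_halves: Sequence[np.ndarray],
) -> FitResult:
    """Split-half cross-validated fit.

    Betas are estimated on one half and applied, fixed, to score the other
    half (and vice versa); betas and R-squared values are averaged across the
    two directions.  The adjusted variant penalizes for the number of time
    points and regressors.  Constant (zero-variance) test data yields NaN
    with a flag.
    """
    if len(pred_halves) != 2 or len(data_halves) != 2:
        raise ValueError("exactly two halves are required")
    betas_acc, r2s, adj = [], [], []
    flags: list[str] = []
    for train, test in ((0, 1), (1, 0)):
        b = fit_ols(pred_halves[train], data_halves[train])
        Xt = _design(pred_halves[test])
        yhat = Xt @ b
        y = np.asarray(data_halves[test], dtype=np.float64)
        r2 = _r2_percent(y, yhat)
        if np.isnan(r2):
            flags.append("constant_test_half")
        n, p = Xt.shape[0], Xt.shape[1] - 1
        adj.append(100.0 - (100.0 - r2) * (n - 1) / (n - p - 1))
        r2s.append(r2)
        betas_acc.append(b)
    return FitResult(
        betas=np.mean(betas_acc, axis=0),
        cv_r2=float(np.mean(r2s)),
        adj_cv_r2=float(np.mean(adj)),
        flags=tuple(flags),
    )


def gridfit_cst_exponent(
    pred_halves_by_n: Mapping[float, Sequence[np.ndarray]],
    data_halves: Sequence[np.ndarray],
) -> tuple[float, FitResult, dict[float, float]]:
    """Grid fit of the spatiotemporal compressive exponent.

    ``pred_halves_by_n`` maps each candidate exponent to its two predicted
    halves (each an (n_tr, 2) sustained/transient array).  Returns the
    exponent with the highest cross-validated R-squared (ties broken toward
    the smallest exponent), its fit, and the full score table.
    """
    scores: dict[float, float] = {}
    fits: dict[float, FitResult] = {}
    for n in sorted(pred_halves_by_n):
        fit = crossval_fit(pred_halves_by_n[n], data_halves)
        fits[n] = fit
        scores[n] = fit.cv_r2
    finite = {n: s for n, s in scores.items() if np.isfinite(s)}
    if not finite:
        raise ValueError("all exponent candidates produced undefined scores")
    best = min(finite, key=lambda n: (-finite[n], n))
    result = fits[best]
    result.best_cst_n = best
    return best, result, scores


def split_half_reliability(run_series: np.ndarray) -> float:
    """Split-half reliability in percent.

    Runs (rows) are split into odd and even halves and averaged within each
    half; one half then serves as the predictor for the other under the same
    cross-validated variance-explained measure as the model fits (scale and
    offset fitted on the training direction, fixed for scoring), averaged
    over both directions.  Serves as the noise ceiling and as the >= 10 %
    inclusion filter; ~100 for duplicated runs, ~0 for pure noise.
    """
    runs = np.asarray(run_series, dtype=np.float64)
    if runs.ndim != 2 or runs.shape[0] < 2:
        raise ValueError("need at least two runs (rows)")
    odd = runs[0::2].mean(axis=0)
    even = runs[1::2].mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return crossval_fit((odd, even), (even, odd)).cv_r2


def select_voxels(
    params: pd.DataFrame,
    layout_box: tuple[float, float] = (0.59, 9.41),
    min_retino_r2: float = 20.0,
    min_reliability: float = 10.0,
    max_tau_ms: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the voxel-inclusion filters.

    Keeps voxels with retinotopy R-squared >= ``min_retino_r2``, pRF center
    inside the per-quadrant stimulus bounding box (|x| and |y| within
    ``layout_box`` with matching signs, i.e. on the stimulated diagonal),
    split-half reliability >= ``min_reliability``, and, when a ``tau_ms``
    column is present, time constants <= ``max_tau_ms``.

    Returns the kept rows and an exclusion table with one reason code per
    dropped voxel.
    """
    required = {"x0", "y0"}
    missing = required - set(params.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    lo, hi = layout_box
    reasons = []
    keep = np.ones(len(params), dtype=bool)
    for i, row in enumerate(params.itertuples(index=False)):
        why = None
        if "retino_r2" in params.columns and row.retino_r2 < min_retino_r2:
            why = "retino_r2_below_threshold"
        elif not (
            lo <= abs(row.x0) <= hi
            and lo <= abs(row.y0) <= hi
            and np.sign(row.x0) == np.sign(row.y0)
        ):
            why = "center_outside_stimulus_box"
        elif "reliability" in params.columns and row.reliability < min_reliability:
            why = "reliability_below_threshold"
        elif "tau_ms" in params.columns and getattr(row, "tau_ms") > max_tau_ms:
            why = "tau_above_limit"
        if why is not None:
            keep[i] = False
            reasons.append({"index": params.index[i], "reason": why})
    return params[keep].copy(), pd.DataFrame(reasons, columns=["index", "reason"])


# ---------------------------------------------------------------------------
# retinotopy (compressive spatial) fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSSRetinoFit:
    x0: float
    y0: float
    sigma: float
    css_n: float
    r2: float
    responsive: bool = True


@dataclass(frozen=True)
class RetinoSearchSpec:
    """Two-stage search grids for the compressive-spatial retinotopy fit."""

    center_step_deg: float = 1.0
    sigmas: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    exponents: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 1.0)
    pixel_deg: float = 0.5
    refine: bool = True
    min_r2_responsive: float = 5.0


def _frame_hrf(stim: RetinotopyStimulus) -> np.ndarray:
    """Canonical HRF sampled at the bar-frame interval."""
    params_dt_ms = stim.design.step_dur_s * 1000.0
    from .hemodynamics import HRFParams

    return double_gamma_hrf(HRFParams(dt_ms=params_dt_ms))


def css_retinotopy_prediction(
    stim: RetinotopyStimulus,
    grid: GridSpec,
    movie_flat: np.ndarray,
    x0: float,
    y0: float,
    sigma: float,
    css_n: float,
    hrf_frame: np.ndarray,
) -> np.ndarray:
    """Predicted bar-run BOLD (frame resolution) for one candidate pRF."""
    xs, ys = grid.xs, grid.ys
    gx = np.exp(-((xs - x0) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y0) ** 2) / (2 * sigma**2))
    g = np.outer(gy, gx).ravel()
    s = g.sum()
    if s > 0:
        g = g / s
    drive = movie_flat @ g
    return causal_convolve(drive**css_n, hrf_frame)


def fit_css_retinotopy(
    stim: RetinotopyStimulus,
    voxel_series: np.ndarray,
    search: RetinoSearchSpec = RetinoSearchSpec(),
) -> CSSRetinoFit:
    """Two-stage compressive-spatial pRF fit on the bar protocol.

    Stage 1 is an exhaustive grid over pRF centers (a lattice inside the
    aperture), sizes, and exponents, scored by OLS variance explained at the
    frame resolution.  Stage 2 refines the best grid point with a
    derivative-free local search over (x0, y0, log sigma, exponent).
    """
    y = np.asarray(voxel_series, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("voxel series contains non-finite values")
    if y.size != stim.n_frames:
        raise ValueError("series length must equal the number of bar frames")

    R = stim.design.radius_deg
    grid = GridSpec(-R, R, -R, R, search.pixel_deg)
    movie = stim.rasterize(grid).astype(np.float64)
    movie_flat = movie.reshape(-1, stim.n_frames).T  # (frames, pixels)
    hrf_frame = _frame_hrf(stim)

    # stage 1: vectorized coarse grid
    xs = np.arange(-R + 1.0, R, search.center_step_deg)
    centers = [(x, yy) for x in xs for yy in xs if x**2 + yy**2 <= R**2]
    gx_all = grid.xs
    gy_all = grid.ys
    best = (-np.inf, None)
    y_c = y - y.mean()
    ss_tot = float(np.sum(y_c**2))
    if ss_tot == 0:
        return CSSRetinoFit(0.0, 0.0, 1.0, 1.0, float("nan"), responsive=False)

    for sigma in search.sigmas:
        gbank = []
        for (cx, cy) in centers:
            gxv = np.exp(-((gx_all - cx) ** 2) / (2 * sigma**2))
            gyv = np.exp(-((gy_all - cy) ** 2) / (2 * sigma**2))
            g = np.outer(gyv, gxv).ravel()
            s = g.sum()
            gbank.append(g / s if s > 0 else g)
        G = np.asarray(gbank).T  # (pixels, centers)
        drives = movie_flat @ G  # (frames, centers)
        for n in search.exponents:
            resp = drives**n
            pred = np.apply_along_axis(causal_convolve, 0, resp, hrf_frame)
            pc = pred - pred.mean(axis=0)
            denom = np.einsum("ij,ij->j", pc, pc)
            num = pc.T @ y_c
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(denom > 0, num**2 / (denom * ss_tot), -np.inf)
            j = int(np.argmax(r2))
            if r2[j] > best[0]:
                best = (float(r2[j]), (centers[j][0], centers[j][1], sigma, n))

    r2_coarse, (x0, y0, sigma, css_n) = best
    r2_pct = 100.0 * r2_coarse

    if search.refine:

        def negloss(theta: np.ndarray) -> float:
            tx, ty, lsig, tn = theta
            sig = float(np.exp(lsig))
            nn = float(np.clip(tn, 0.01, 1.0))
            pred = css_retinotopy_prediction(
                stim, grid, movie_flat, tx, ty, sig, nn, hrf_frame
            )
            pc = pred - pred.mean()
            denom = float(pc @ pc)
            if denom <= 0:
                return 1.0
            return 1.0 - float(pc @ y_c) ** 2 / (denom * ss_tot)

        res = optimize.minimize(
            negloss,
            x0=np.array([x0, y0, np.log(sigma), css_n]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 800},
        )
        if res.fun <= 1.0 - r2_coarse + 1e-12:
            x0, y0 = float(res.x[0]), float(res.x[1])
            sigma = float(np.exp(res.x[2]))
            css_n = float(np.clip(res.x[3], 0.01, 1.0))
            r2_pct = 100.0 * (1.0 - float(res.fun))

    responsive = r2_pct >= search.min_r2_responsive
    return CSSRetinoFit(x0, y0, sigma, css_n, r2_pct, responsive=responsive)
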