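"""Simultaneous-suppression quantification.

The analysis proceeds in three steps: (1) segment each (concatenated) run
into 23-TR block windows spanning 4 s before block onset to 11 s after block
offset and average them per condition; (2) summarize each voxel-condition
into one amplitude by averaging a 9-TR window around the response peak,
whose start (4 s or 5 s after block onset) is chosen per visual area and
condition from the grand-mean window's cumulative sum; (3) regress each
voxel's simultaneous amplitude on its sequential amplitude per condition
pair with a linear mixed model whose slopes quantify suppression (slope 1 =
none; smaller = stronger), with random intercepts and slopes per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .stimulus import Block, BlockSchedule, Condition, PAIR_LABELS

__all__ = [
    "WINDOW_PRE_TR",
    "WINDOW_LEN_TR",
    "BlockWindow",
    "segment_blocks",
    "average_condition_windows",
    "choose_peak_start",
    "condition_amplitudes",
    "build_suppression_table",
    "LMMResult",
    "fit_suppression_lmm",
    "compare_lmm_variants",
    "BootstrapSummary",
    "bootstrap_param_summary",
]

WINDOW_PRE_TR = 4
WINDOW_LEN_TR = 23
PEAK_WINDOW_LEN_TR = 9


@dataclass(frozen=True)
class BlockWindow:
    condition_label: str
    pair_label: str
    seq_type: str
    window: np.ndarray  # (23,)


def segment_blocks(
    run_series: np.ndarray,
    schedule: BlockSchedule | Sequence[Block],
    tr_s: float = 1.0,
    onset_offset_s: float = 0.0,
) -> list[BlockWindow]:
    """Cut a TR-resolution series into one 23-sample window per block.

    Windows run from 4 s before block onset to 18 s after (23 TRs at 1 s).
    ``onset_offset_s`` shifts all block onsets, e.g. when the series is a
    concatenation of runs.
    """
    series = np.asarray(run_series, dtype=np.float64)
    blocks = schedule.blocks if isinstance(schedule, BlockSchedule) else tuple(schedule)
    out = []
    for b in blocks:
        start = int(round((b.onset_s + onset_offset_s) / tr_s)) - WINDOW_PRE_TR
        stop = start + WINDOW_LEN_TR
        if start < 0 or stop > series.size:
            raise ValueError(
                f"block window [{start}, {stop}) exceeds run bounds (n={series.size})"
            )
        out.append(
            BlockWindow(
                condition_label=b.condition.label,
                pair_label=b.condition.pair_label,
                seq_type=b.condition.seq_type,
                window=series[start:stop].copy(),
            )
        )
    return out


def average_condition_windows(
    block_windows: Iterable[BlockWindow],
) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    """Per condition label: (mean window, SEM across repeats, n repeats)."""
    grouped: dict[str, list[np.ndarray]] = {}
    for bw in block_windows:
        grouped.setdefault(bw.condition_label, []).append(bw.window)
    out = {}
    for label, wins in grouped.items():
        arr = np.asarray(wins)
        n = arr.shape[0]
        sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
        out[label] = (arr.mean(axis=0), sem, n)
    return out


def choose_peak_start(grand_mean_window: np.ndarray) -> int:
    """Start (4 or 5 s after block onset) of the 9-TR amplitude window.

    The grand-mean window is re-baselined to the mean of the 4 pre-onset
    TRs and clipped at zero; the start is the first post-onset TR at which
    the cumulative sum exceeds 10 % of its total, mapped to the nearer of
    4 s and 5 s.  A non-positive grand mean falls back to 4 s with a warning.
    """
    w = np.asarray(grand_mean_window, dtype=np.float64)
    if w.size != WINDOW_LEN_TR:
        raise ValueError(f"expected a {WINDOW_LEN_TR}-TR window, got {w.size}")
    baseline = w[:WINDOW_PRE_TR].mean()
    resp = np.clip(w[WINDOW_PRE_TR:] - baseline, 0.0, None)
    total = resp.sum()
    if total <= 0:
        warnings.warn("non-positive grand-mean window; defaulting to a 4-s start", stacklevel=2)
        return 4
    cum = np.cumsum(resp)
    t_star = int(np.argmax(cum > 0.10 * total))  # seconds after onset
    return 4 if t_star <= 4 else 5


def _amplitude(window: np.ndarray, start_s: int) -> float:
    i0 = WINDOW_PRE_TR + start_s
    return float(np.asarray(window)[i0 : i0 + PEAK_WINDOW_LEN_TR].mean())


def condition_amplitudes(
    windows_by_voxel: Mapping[object, Mapping[str, np.ndarray]],
    voxel_area: Mapping[object, str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], int]]:
    """Summarize per-voxel condition windows into one amplitude each.

    ``windows_by_voxel`` maps voxel id -> condition label -> mean 23-TR
    window.  The 9-TR averaging window start is chosen per (area, condition)
    from the grand mean across the area's voxels and applied to every voxel
    of the area.  Returns a long table (voxel, area, condition, amplitude)
    and the chosen starts.
    """
    if voxel_area is None:
        voxel_area = {v: "all" for v in windows_by_voxel}
    # grand means per (area, condition)
    acc: dict[tuple[str, str], list[np.ndarray]] = {}
    for vox, conds in windows_by_voxel.items():
        area = voxel_area[vox]
        for label, win in conds.items():
            acc.setdefault((area, label), []).append(np.asarray(win))
    starts = {
        key: choose_peak_start(np.mean(wins, axis=0)) for key, wins in acc.items()
    }
    rows = []
    for vox, conds in windows_by_voxel.items():
        area = voxel_area[vox]
        for label, win in conds.items():
            rows.append(
                {
                    "voxel": vox,
                    "area": area,
                    "condition": label,
                    "amplitude": _amplitude(win, starts[(area, label)]),
                }
            )
    return pd.DataFrame(rows), starts


def build_suppression_table(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-condition amplitudes into matched SEQ/SIM pairs.

    Input columns: voxel, area, condition (e.g. ``SEQ-long-small``),
    amplitude, and optionally participant.  Output rows: one per voxel and
    condition pair with ``seq_ampl`` and ``sim_ampl`` columns.
    """
    df = amplitudes.copy()
    parts = df["condition"].str.split("-", expand=True)
    df["seq_type"] = parts[0]
    df["pair"] = parts[1] + "-" + parts[2]
    index_cols = [c for c in ("participant", "area", "voxel") if c in df.columns]
    wide = df.pivot_table(
        index=index_cols + ["pair"], columns="seq_type", values="amplitude"
    ).reset_index()
    wide = wide.rename(columns={"SEQ": "seq_ampl", "SIM": "sim_ampl"})
    if "seq_ampl" not in wide.columns or "sim_ampl" not in wide.columns:
        raise ValueError("unpaired SEQ/SIM amplitudes in the table")
    missing = wide["seq_ampl"].isna() | wide["sim_ampl"].isna()
    if missing.any():
        raise ValueError("unpaired SEQ/SIM amplitudes in the table")
    return wide


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Per-condition suppression slopes with participant-level random effects."""

    slopes: dict[str, float]
    slope_se: dict[str, float]
    slope_ci95: dict[str, tuple[float, float]]
    intercepts: dict[str, float]
    participant_slopes: pd.DataFrame  # participant x pair
    r2: float
    loglik: float
    aic: float
    bic: float
    df_model: int
    converged: bool
    flags: tuple[str, ...] = ()


def _prepare_lmm_frame(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    df = table.copy()
    required = {"participant", "pair", "seq_ampl", "sim_ampl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"suppression table missing columns: {sorted(missing)}")
    if df["participant"].nunique() < 2:
        raise ValueError("the mixed model requires at least two participants")
    pairs = sorted(df["pair"].unique())
    for p in pairs:
        tag = p.replace("-", "_")
        df[f"d_{tag}"] = (df["pair"] == p).astype(float)
        df[f"s_{tag}"] = df[f"d_{tag}"] * df["seq_ampl"]
    return df, pairs


def fit_suppression_lmm(
    table: pd.DataFrame,
    structure: str = "diagonal",
    maxiter: int = 200,
) -> LMMResult:
    """Fit the suppression mixed model by maximum likelihood.

    Fixed effects: one intercept and one slope of SIM on SEQ amplitude per
    condition pair (cell-means coding of the condition interaction).
    Random effects: per-participant intercept and slope per condition pair.
    ``structure`` selects the random-effects covariance: ``"diagonal"``
    (independent variance components, the stable default) or ``"full"``
    (unstructured covariance over the eight participant effects).  If the
    full fit fails or is singular it falls back to diagonal with a flag.
    """
    df, pairs = _prepare_lmm_frame(table)
    tags = [p.replace("-", "_") for p in pairs]
    fixed = (
        "sim_ampl ~ 0 + "
        + " + ".join(f"d_{t}" for t in tags)
        + " + "
        + " + ".join(f"s_{t}" for t in tags)
    )
    flags: list[str] = []

    def _fit(struct: str):
        if struct == "full":
            re_formula = "0 + " + " + ".join(
                [f"d_{t}" for t in tags] + [f"s_{t}" for t in tags]
            )
            model = smf.mixedlm(fixed, df, groups=df["participant"], re_formula=re_formula)
        else:
            vc = {f"ri_{t}": f"0 + d_{t}" for t in tags}
            vc.update({f"rs_{t}": f"0 + s_{t}" for t in tags})
            model = smf.mixedlm(
                fixed, df, groups=df["participant"], vc_formula=vc, re_formula="0"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=False, maxiter=maxiter)

    result = None
    if structure == "full":
        try:
            result = _fit("full")
            cov = result.cov_re.to_numpy()
            if not np.all(np.linalg.eigvalsh(cov) > 1e-10):
                flags.append("singular_full_covariance_refit_diagonal")
                result = None
        except Exception:
            flags.append("full_fit_failed_refit_diagonal")
            result = None
    if result is None:
        result = _fit("diagonal")

    fe = result.fe_params
    with warnings.catch_warnings():
        # near-singular covariances can produce NaN standard errors for some
        # simulated datasets; reported as-is rather than raised
        warnings.simplefilter("ignore", RuntimeWarning)
        se = result.bse_fe
    # CI95 on a t reference with participants-1 df: slope uncertainty is
    # dominated by the between-participant variance, and the normal quantile
    # under-covers at the small participant counts typical here
    tcrit = float(sps.t.ppf(0.975, max(df["participant"].nunique() - 1, 1)))
    slopes, slope_se, slope_ci, intercepts = {}, {}, {}, {}
    for p, t in zip(pairs, tags):
        b = float(fe[f"s_{t}"])
        s = float(se[f"s_{t}"])
        slopes[p] = b
        slope_se[p] = s
        slope_ci[p] = (b - tcrit * s, b + tcrit * s)
        intercepts[p] = float(fe[f"d_{t}"])

    # participant-level slopes: fixed slope + that participant's random slope
    re_rows = []
    for participant, effects in result.random_effects.items():
        row: dict[str, object] = {"participant": participant}
        for p, t in zip(pairs, tags):
            delta = 0.0
            for name, value in effects.items():
                if f"s_{t}" in str(name):
                    delta = float(np.atleast_1d(value)[0])
                    break
            row[p] = slopes[p] + delta
        re_rows.append(row)
    participant_slopes = pd.DataFrame(re_rows).set_index("participant")

    resid = df["sim_ampl"].to_numpy() - np.asarray(result.fittedvalues)
    ss_tot = float(np.sum((df["sim_ampl"] - df["sim_ampl"].mean()) ** 2))
    r2 = 100.0 * (1.0 - float(np.sum(resid**2)) / ss_tot) if ss_tot > 0 else float("nan")

    k = result.params.size + 1  # fixed + random-covariance params + residual var
    llf = float(result.llf)
    return LMMResult(
        slopes=slopes,
        slope_se=slope_se,
        slope_ci95=slope_ci,
        intercepts=intercepts,
        participant_slopes=participant_slopes,
        r2=r2,
        loglik=llf,
        aic=float(-2 * llf + 2 * k),
        bic=float(-2 * llf + np.log(len(df)) * k),
        df_model=int(k),
        converged=bool(getattr(result, "converged", True)),
        flags=tuple(flags),
    )


def compare_lmm_variants(table: pd.DataFrame) -> pd.DataFrame:
    """Fit the main mixed model and three simpler alternatives.

    Variants: (main) per-pair fixed slopes with per-participant random
    intercept and slope per pair; (i) a single fixed slope with a random
    participant intercept; (ii) per-pair fixed slopes with a single random
    participant intercept; (iii) per-pair fixed slopes with a random
    participant intercept per pair.  Reports log-likelihood, AIC, BIC, and
    model degrees of freedom per variant (non-convergence is reported, not
    raised).
    """
    df, pairs = _prepare_lmm_frame(table)
    tags = [p.replace("-", "_") for p in pairs]
    fixed_inter = (
        "sim_ampl ~ 0 + "
        + " + ".join(f"d_{t}" for t in tags)
        + " + "
        + " + ".join(f"s_{t}" for t in tags)
    )
    specs = {
        "main": dict(
            fixed=fixed_inter,
            vc={f"ri_{t}": f"0 + d_{t}" for t in tags}
            | {f"rs_{t}": f"0 + s_{t}" for t in tags},
            re="0",
        ),
        "single_slope_random_intercept": dict(
            fixed="sim_ampl ~ 1 + seq_ampl", vc=None, re="1"
        ),
        "interaction_single_intercept": dict(fixed=fixed_inter, vc=None, re="1"),
        "interaction_intercept_per_condition": dict(
            fixed=fixed_inter, vc={f"ri_{t}": f"0 + d_{t}" for t in tags}, re="0"
        ),
    }
    rows = []
    for name, spec in specs.items():
        try:
            if spec["vc"] is None:
                model = smf.mixedlm(
                    spec["fixed"], df, groups=df["participant"], re_formula=spec["re"]
                )
            else:
                model = smf.mixedlm(
                    spec["fixed"],
                    df,
                    groups=df["participant"],
                    vc_formula=spec["vc"],
                    re_formula=spec["re"],
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, maxiter=200)
            k = res.params.size + 1  # + residual variance
            llf = float(res.llf)
            rows.append(
                {
                    "variant": name,
                    "loglik": llf,
                    "df": int(k),
                    "aic": float(-2 * llf + 2 * k),
                    "bic": float(-2 * llf + np.log(len(df)) * k),
                    "converged": bool(getattr(res, "converged", True)),
                }
            )
        except Exception as exc:  # report, do not raise
            rows.append(
                {
                    "variant": name,
                    "loglik": float("nan"),
                    "df": -1,
                    "aic": float("nan"),
                    "bic": float("nan"),
                    "converged": False,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapSummary:
    statistic: str
    point: float
    boot_mean: float
    boot_sem: float
    n_boot: int


def bootstrap_param_summary(
    values: np.ndarray,
    n_boot: int = 1000,
    statistic: str = "median",
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap (with replacement) summary of a parameter sample.

    ``statistic`` is ``"median"`` (sizes, exponents, time constants) or
    ``"mean"`` (channel beta weights).  Resampling happens within the given
    sample, mirroring per-participant, per-area resampling.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("empty sample")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    fn = np.median if statistic == "median" else np.mean
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boots = fn(vals[idx], axis=1)
    return BootstrapSummary(
        statistic=statistic,
        point=float(fn(vals)),
        boot_mean=float(boots.mean()),
        boot_sem=float(boots.std(ddof=1)) if n_boot > 1 else 0.0,
        n_boot=n_boot,
    )
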