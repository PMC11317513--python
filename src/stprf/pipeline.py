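"""End-to-end orchestration, configuration and table I/O.

The canonical interchange formats are long-format TSV tables plus JSON
sidecars; a 4-D NIfTI volume with a binary mask and a parameter sidecar is
supported as an optional ingestion path.  A pipeline run persists every
intermediate table and a manifest (config hash, package version, seeds) that
fully determines the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import prf_models as pm
from .fitting import (
    CST_EXPONENT_GRID,
    FitResult,
    crossval_fit,
    gridfit_cst_exponent,
    normalize_prediction,
    select_voxels,
    split_half_reliability,
)
from .hemodynamics import HRFParams, double_gamma_hrf, neural_to_bold
from .stimulus import RunDesign
from .suppression import (
    average_condition_windows,
    build_suppression_table,
    condition_amplitudes,
    fit_suppression_lmm,
    segment_blocks,
)
from .synthetic import AreaProfile, sample_population, simulate_dataset, SimulatedDataset

logger = logging.getLogger("stprf")

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "ResultsBundle",
    "run_pipeline",
    "write_results",
    "read_voxel_table",
    "write_voxel_table",
    "read_nifti_dataset",
    "dataset_amplitudes",
    "predict_voxel_bold",
    "fit_voxel_model",
]

VOXEL_TABLE_COLUMNS = ("participant", "voxel", "run", "t", "value")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    seed: int = 0
    participants: int = 3
    models: tuple[str, ...] = ("lss", "css", "cst")
    target_reliability: float = 0.8
    n_repeats: int = 4
    lmm_structure: str = "diagonal"
    profiles: tuple[AreaProfile, ...] = ()
    design: RunDesign | None = None
    hrf: HRFParams = field(default_factory=HRFParams)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        known = {"lss", "css", "cst", "dog", "dnst"}
        bad = set(self.models) - known
        if bad:
            raise ConfigError(f"unknown models {sorted(bad)}; known: {sorted(known)}")
        if not 0 < self.target_reliability <= 1:
            raise ConfigError("target_reliability must be in (0, 1]")
        if self.participants < 1:
            raise ConfigError("participants must be >= 1")
        if self.design is None:
            self.design = RunDesign(seed=self.seed)
        if not self.profiles:
            self.profiles = (
                AreaProfile(
                    name="V1like",
                    model="lss",
                    n_voxels=30,
                    sigma_range=(0.5, 1.5),
                ),
                AreaProfile(
                    name="TOlike",
                    model="cst",
                    n_voxels=30,
                    sigma_range=(4.0, 8.0),
                    exponent_range=(0.2, 0.4),
                ),
            )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        try:
            profiles = tuple(
                AreaProfile(**{**p, **{k: tuple(v) for k, v in p.items() if isinstance(v, list)}})
                for p in raw.pop("profiles", [])
            )
            design_raw = raw.pop("design", None)
            design = RunDesign(**design_raw) if design_raw else None
            hrf_raw = raw.pop("hrf", None)
            hrf = HRFParams(**hrf_raw) if hrf_raw else HRFParams()
            if "models" in raw:
                raw["models"] = tuple(raw["models"])
            return cls(profiles=profiles, design=design, hrf=hrf, **raw)
        except TypeError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, Mapping):
            raise ConfigError("configuration root must be a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    fit_tables: dict[str, pd.DataFrame]
    amplitudes: pd.DataFrame
    suppression_table: pd.DataFrame
    lmm_results: dict[str, object]
    manifest: dict

    def lmm_slope_table(self) -> pd.DataFrame:
        rows = []
        for area, res in self.lmm_results.items():
            for pair, slope in res.slopes.items():
                rows.append(
                    {
                        "area": area,
                        "pair": pair,
                        "slope": slope,
                        "se": res.slope_se[pair],
                        "ci95_lo": res.slope_ci95[pair][0],
                        "ci95_hi": res.slope_ci95[pair][1],
                        "intercept": res.intercepts[pair],
                        "r2": res.r2,
                        "loglik": res.loglik,
                        "aic": res.aic,
                        "bic": res.bic,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-voxel prediction helpers
# ---------------------------------------------------------------------------

def predict_voxel_bold(
    model: str,
    row: Mapping,
    sequences: Sequence,
    hrf_kernel: np.ndarray,
    tr_s: float = 1.0,
    kernels: pm.TemporalKernels | None = None,
    cst_n: float | None = None,
) -> np.ndarray:
    """Concatenated-run BOLD prediction for one voxel under one model.

    Returns (n_tr,) for single-channel models and (n_tr, 2) for the
    two-channel spatiotemporal model.  Spatial parameters come from the
    voxel's parameter row (``x0``, ``y0``, ``sigma``, ``exponent``); the
    spatiotemporal exponent may be overridden with ``cst_n`` (grid fitting).
    """
    prf = pm.SpatialPRF(float(row["x0"]), float(row["y0"]), float(row["sigma"]))
    per_run = []
    for seq in sequences:
        if model == "lss":
            per_run.append(neural_to_bold(pm.predict_lss(prf, seq), hrf_kernel, tr_s=tr_s))
        elif model == "css":
            n = float(row.get("css_n", row.get("exponent", 1.0)))
            per_run.append(
                neural_to_bold(
                    pm.predict_css(pm.CSSParams(prf, n), seq), hrf_kernel, tr_s=tr_s
                )
            )
        elif model == "cst":
            n = cst_n if cst_n is not None else float(row.get("exponent", 0.5))
            ch = pm.predict_cst(pm.CSTParams(prf, cst_n=n), seq, kernels=kernels)
            sus = neural_to_bold(ch.sustained, hrf_kernel, tr_s=tr_s)
            tra = neural_to_bold(ch.transient, hrf_kernel, tr_s=tr_s)
            per_run.append(np.column_stack([sus, tra]))
        elif model == "dog":
            params = pm.DoGParams(prf, surround_scale=float(row.get("surround_scale", 7.4)))
            per_run.append(
                neural_to_bold(pm.predict_dog(params, seq), hrf_kernel, tr_s=tr_s)
            )
        elif model == "dnst":
            params = pm.DNSTParams(
                prf,
                tau1_ms=float(row.get("tau1_ms", 50.0)),
                tau2_ms=float(row.get("tau2_ms", 100.0)),
                sigma_dn=float(row.get("sigma_dn", 0.1)),
                n_dn=float(row.get("n_dn", 2.0)),
            )
            per_run.append(
                neural_to_bold(pm.predict_dnst(params, seq), hrf_kernel, tr_s=tr_s)
            )
        else:
            raise ValueError(f"unknown model {model!r}")
    return np.concatenate(per_run, axis=0)


def fit_voxel_model(
    model: str,
    row: Mapping,
    dataset: SimulatedDataset,
    data_halves: tuple[np.ndarray, np.ndarray],
    hrf_kernel: np.ndarray,
    kernels: pm.TemporalKernels,
    reliability: float,
) -> FitResult:
    if model == "cst":
        preds = {}
        for n in CST_EXPONENT_GRID:
            pred = predict_voxel_bold(
                "cst", row, dataset.sequences, hrf_kernel, dataset.tr_s, kernels, cst_n=n
            )
            pred = normalize_prediction(pred)
            preds[n] = (pred, pred)
        best, fit, _ = gridfit_cst_exponent(preds, data_halves)
        fit.noise_ceiling = reliability
        return fit
    pred = predict_voxel_bold(model, row, dataset.sequences, hrf_kernel, dataset.tr_s, kernels)
    pred = normalize_prediction(pred)
    fit = crossval_fit((pred, pred), data_halves)
    fit.noise_ceiling = reliability
    return fit


def dataset_amplitudes(dataset: SimulatedDataset) -> tuple[pd.DataFrame, dict]:
    """Segment a simulated dataset and summarize per-condition amplitudes."""
    blocks = dataset.concatenated_blocks()
    mean_series = dataset.mean_series()
    windows_by_voxel: dict[str, dict[str, np.ndarray]] = {}
    voxel_area: dict[str, str] = {}
    for i, rec in enumerate(dataset.ground_truth):
        wins = segment_blocks(mean_series[i], blocks, tr_s=dataset.tr_s)
        cond_means = average_condition_windows(wins)
        windows_by_voxel[rec.voxel] = {c: m for c, (m, _, _) in cond_means.items()}
        voxel_area[rec.voxel] = rec.area
    amp, starts = condition_amplitudes(windows_by_voxel, voxel_area)
    participant = {rec.voxel: rec.participant for rec in dataset.ground_truth}
    amp["participant"] = amp["voxel"].map(participant)
    return amp, starts


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run stimulus generation, simulation, fitting and suppression analysis.

    All eight conditions are predicted jointly per voxel from the two-run
    stimulus sequence; fits use split-half cross-validation; the suppression
    mixed model is fit per area.  Stage failures raise with a stage tag.
    """
    logger.info("pipeline start (seed=%s, digest=%s)", config.seed, config.digest())
    design = config.design
    records = []
    for p in range(config.participants):
        pid = f"S{p + 1}"
        for profile in config.profiles:
            records.extend(
                sample_population(profile, seed=config.seed + p, participant=pid)
            )
    dataset = simulate_dataset(
        records,
        design,
        hrf=config.hrf,
        target_reliability=config.target_reliability,
        n_repeats=config.n_repeats,
        seed=config.seed,
    )

    odd, even = dataset.split_halves()
    reliabilities = np.array(
        [split_half_reliability(dataset.series[i]) for i in range(len(records))]
    )
    params = dataset.params.copy()
    params["reliability"] = reliabilities
    params["retino_r2"] = 100.0  # ground-truth parameters: by construction reliable
    kept, exclusions = select_voxels(params)
    logger.info("voxel selection kept %d / %d", len(kept), len(params))

    hrf_kernel = double_gamma_hrf(config.hrf)
    kernels = pm.make_temporal_irfs()
    fit_tables: dict[str, pd.DataFrame] = {}
    for model in config.models:
        rows = []
        for idx in kept.index:
            row = params.loc[idx]
            i = params.index.get_loc(idx)
            halves = (odd[i], even[i])
            try:
                fit = fit_voxel_model(
                    model, row, dataset, halves, hrf_kernel, kernels, reliabilities[i]
                )
            except Exception as exc:
                raise RuntimeError(f"[fitting:{model}] voxel {row['voxel']}: {exc}") from exc
            rows.append(
                {
                    "voxel": row["voxel"],
                    "participant": row["participant"],
                    "area": row["area"],
                    "model": model,
                    "cv_r2": fit.cv_r2,
                    "adj_cv_r2": fit.adj_cv_r2,
                    "noise_ceiling": fit.noise_ceiling,
                    "best_cst_n": fit.best_cst_n,
                    **{f"beta{j}": b for j, b in enumerate(fit.betas)},
                }
            )
        fit_tables[model] = pd.DataFrame(rows)

    if len(kept) == 0:
        logger.warning("no voxels survived selection; returning empty bundle")
        empty = pd.DataFrame()
        manifest = _manifest(config, exclusions, n_voxels=0)
        return ResultsBundle(fit_tables, empty, empty, {}, manifest)

    kept_voxels = set(kept["voxel"])
    amplitudes, starts = dataset_amplitudes(dataset)
    amplitudes = amplitudes[amplitudes["voxel"].isin(kept_voxels)]
    table = build_suppression_table(amplitudes)
    lmm_results = {}
    for area, sub_table in table.groupby("area"):
        try:
            lmm_results[area] = fit_suppression_lmm(sub_table, structure=config.lmm_structure)
        except Exception as exc:
            raise RuntimeError(f"[suppression] area {area}: {exc}") from exc

    manifest = _manifest(config, exclusions, n_voxels=len(kept))
    manifest["peak_window_starts"] = {f"{a}|{c}": s for (a, c), s in starts.items()}
    return ResultsBundle(fit_tables, amplitudes, table, lmm_results, manifest)


def _manifest(config: PipelineConfig, exclusions: pd.DataFrame, n_voxels: int) -> dict:
    return {
        "stprf_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_voxels": n_voxels,
        "n_excluded": int(len(exclusions)),
        "exclusion_reasons": exclusions["reason"].value_counts().to_dict()
        if len(exclusions)
        else {},
    }


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def write_voxel_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(VOXEL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"voxel table missing columns: {sorted(missing)}")
    df.to_csv(path, sep="\t", index=False)


def read_voxel_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format voxel table, reporting malformed rows by line number."""
    df = pd.read_csv(path, sep="\t")
    missing = set(VOXEL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s): {sorted(missing)}")
    bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()].tolist()
    if bad:
        lines = [i + 2 for i in bad[:10]]  # +2: header + 1-indexing
        raise ValueError(f"{path}: non-numeric 'value' at line(s) {lines}")
    df["value"] = df["value"].astype(float)
    return df


def read_nifti_dataset(
    nii_path: str | Path, mask_path: str | Path, sidecar: str | Path
) -> pd.DataFrame:
    """Ingest a 4-D NIfTI + binary mask + TSV sidecar into the long format.

    The sidecar must have one row per in-mask voxel (in C order of the mask's
    True entries) with at least a ``voxel`` column; ``participant`` and
    ``run`` default to single values when absent.
    """
    import nibabel as nib

    img = np.asarray(nib.load(str(nii_path)).dataobj, dtype=np.float64)
    mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    if img.ndim != 4:
        raise ValueError("expected a 4-D NIfTI volume")
    if mask.shape != img.shape[:3]:
        raise ValueError("mask shape does not match volume")
    side = pd.read_csv(sidecar, sep="\t")
    series = img[mask]  # (n_voxels, n_t)
    if len(side) != series.shape[0]:
        raise ValueError("sidecar rows do not match in-mask voxel count")
    rows = []
    for i, meta in enumerate(side.itertuples(index=False)):
        vox = getattr(meta, "voxel", f"vox{i:05d}")
        participant = getattr(meta, "participant", "S1")
        run = getattr(meta, "run", 0)
        for t, value in enumerate(series[i]):
            rows.append(
                {
                    "participant": participant,
                    "voxel": vox,
                    "run": run,
                    "t": t,
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows, columns=list(VOXEL_TABLE_COLUMNS))


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> Path:
    """Persist all bundle tables as TSV plus a JSON manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for model, df in bundle.fit_tables.items():
        df.to_csv(out / f"fits_{model}.tsv", sep="\t", index=False)
    bundle.amplitudes.to_csv(out / "amplitudes.tsv", sep="\t", index=False)
    bundle.suppression_table.to_csv(out / "suppression_table.tsv", sep="\t", index=False)
    slopes = bundle.lmm_slope_table()
    slopes.to_csv(out / "lmm_slopes.tsv", sep="\t", index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return manifest_path
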