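"""Synthetic voxel populations and noisy BOLD datasets.

Ground-truth voxel populations are sampled from area profiles (center, size,
exponent and channel-weight distributions), pushed through a chosen encoding
model and the canonical HRF, and corrupted with seeded Gaussian noise whose
standard deviation is calibrated in closed form to a target split-half
reliability.  Everything is deterministic given (profile, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import prf_models as pm
from .hemodynamics import HRFParams, double_gamma_hrf, neural_to_bold
from .stimulus import (
    BlockSchedule,
    RunDesign,
    SquareLayout,
    StimulusSequence,
    build_square_layout,
    generate_seqsim_pair,
)

__all__ = [
    "AreaProfile",
    "GroundTruthRecord",
    "SimulatedDataset",
    "sample_population",
    "noiseless_bold",
    "calibrate_noise_sd",
    "simulate_dataset",
    "simulate_suppression_table",
]


@dataclass(frozen=True)
class AreaProfile:
    """Statistical profile of one synthetic visual area.

    Centers are drawn uniformly within the quadrant stimulus box (the
    bounding box of the big-square layout) unless ``center_square`` pins
    them inside one square of the small layout with a 3-sigma margin, which
    yields pRFs overlapping exactly one square.  ``sigma_range`` is the
    effective (linear-equivalent) size range, roughly 1 deg for an early-area
    profile up to ~7.8 deg for the largest late-area profile.
    """

    name: str
    model: str  # "lss" | "css" | "cst"
    n_voxels: int
    sigma_range: tuple[float, float]
    exponent_range: tuple[float, float] = (1.0, 1.0)
    gain_range: tuple[float, float] = (0.5, 2.0)
    beta_ratio_range: tuple[float, float] = (1.0, 1.0)  # beta_t / beta_s for cst
    quadrant_center: tuple[float, float] = (5.0, 5.0)
    center_square: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("lss", "css", "cst"):
            raise ValueError(f"unknown generating model {self.model!r}")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        for rng_ in (self.sigma_range, self.exponent_range, self.gain_range):
            if rng_[0] > rng_[1] or rng_[0] <= 0:
                raise ValueError(f"bad range {rng_}")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Everything needed to regenerate one voxel's noiseless series bit-exactly."""

    voxel: str
    participant: str
    area: str
    model: str
    x0: float
    y0: float
    sigma: float
    exponent: float
    beta_s: float
    beta_t: float
    gain: float


def _center_box(profile: AreaProfile) -> tuple[float, float, float, float]:
    if profile.center_square is None:
        box = build_square_layout(4.0, quadrant_center=profile.quadrant_center).bounding_box
        return box.x_min, box.x_max, box.y_min, box.y_max
    sq = build_square_layout(2.0, quadrant_center=profile.quadrant_center).squares[
        profile.center_square
    ]
    margin = 3.0 * profile.sigma_range[1]
    if sq.width <= 2 * margin:
        raise ValueError("sigma too large to keep 3-sigma margin inside one square")
    return sq.x_min + margin, sq.x_max - margin, sq.y_min + margin, sq.y_max - margin


def sample_population(
    profile: AreaProfile, seed: int, participant: str = "P1"
) -> list[GroundTruthRecord]:
    """Draw ``n_voxels`` ground-truth records; reproducible per seed."""
    rng = np.random.default_rng(
        [seed, zlib.crc32(f"{profile.name}/{participant}".encode()), 0]
    )
    x_lo, x_hi, y_lo, y_hi = _center_box(profile)
    records = []
    for i in range(profile.n_voxels):
        sigma = float(rng.uniform(*profile.sigma_range))
        expo = float(rng.uniform(*profile.exponent_range))
        gain = float(rng.uniform(*profile.gain_range))
        ratio = float(rng.uniform(*profile.beta_ratio_range))
        records.append(
            GroundTruthRecord(
                voxel=f"{participant}-{profile.name}-{i:04d}",
                participant=participant,
                area=profile.name,
                model=profile.model,
                x0=float(rng.uniform(x_lo, x_hi)),
                y0=float(rng.uniform(y_lo, y_hi)),
                sigma=sigma,
                exponent=expo,
                beta_s=gain,
                beta_t=gain * ratio,
                gain=gain,
            )
        )
    return records


def noiseless_bold(
    record: GroundTruthRecord,
    sequences: Sequence[StimulusSequence],
    hrf_kernel: np.ndarray,
    tr_s: float = 1.0,
    kernels: pm.TemporalKernels | None = None,
) -> np.ndarray:
    """Noiseless per-run BOLD, shape (n_runs, n_tr), scaled by the record's betas."""
    prf = pm.SpatialPRF(record.x0, record.y0, record.sigma)
    rows = []
    for seq in sequences:
        if record.model == "lss":
            neural = record.gain * pm.predict_lss(prf, seq)
            rows.append(neural_to_bold(neural, hrf_kernel, tr_s=tr_s))
        elif record.model == "css":
            neural = record.gain * pm.predict_css(pm.CSSParams(prf, record.exponent), seq)
            rows.append(neural_to_bold(neural, hrf_kernel, tr_s=tr_s))
        else:  # cst
            ch = pm.predict_cst(
                pm.CSTParams(prf, cst_n=record.exponent), seq, kernels=kernels
            )
            bold = record.beta_s * neural_to_bold(
                ch.sustained, hrf_kernel, tr_s=tr_s
            ) + record.beta_t * neural_to_bold(ch.transient, hrf_kernel, tr_s=tr_s)
            rows.append(bold)
    return np.asarray(rows)


def calibrate_noise_sd(
    signal: np.ndarray, target_reliability: float, runs_per_half: int
) -> float:
    """Per-TR, per-run noise SD achieving an expected split-half reliability.

    The reliability measure regresses one half-average onto the other with
    betas fixed across directions; with half-averaged noise variance v and
    q = v / var_signal its expectation is ``1 / (1 + q)^2``.  Solving for the
    target rho gives ``v = var_signal * (rho**-0.5 - 1)`` and the per-run SD
    is ``sqrt(v * runs_per_half)``.
    """
    if not 0 < target_reliability <= 1:
        raise ValueError("target reliability must be in (0, 1]")
    var_s = float(np.var(np.asarray(signal, dtype=np.float64)))
    v = var_s * (target_reliability**-0.5 - 1.0)
    return float(np.sqrt(v * runs_per_half))


@dataclass
class SimulatedDataset:
    """Noisy synthetic dataset with run/split structure.

    ``series`` has shape (n_voxels, n_repeats, n_tr) where each repeat is
    the concatenation of the two unique runs.  Split halves are odd/even
    repeats averaged within each half.
    """

    params: pd.DataFrame
    ground_truth: list[GroundTruthRecord]
    series: np.ndarray
    schedules: tuple[BlockSchedule, BlockSchedule]
    sequences: tuple[StimulusSequence, StimulusSequence]
    tr_s: float
    target_reliability: float

    @property
    def n_repeats(self) -> int:
        return self.series.shape[1]

    def split_halves(self) -> tuple[np.ndarray, np.ndarray]:
        odd = self.series[:, 0::2].mean(axis=1)
        even = self.series[:, 1::2].mean(axis=1)
        return odd, even

    def mean_series(self) -> np.ndarray:
        return self.series.mean(axis=1)

    def concatenated_blocks(self) -> list:
        """Blocks of both unique runs with the second run's onsets offset."""
        from .stimulus import Block

        offset = self.schedules[0].run_dur_s
        blocks = list(self.schedules[0].blocks)
        for b in self.schedules[1].blocks:
            blocks.append(
                Block(
                    condition=b.condition,
                    onset_s=b.onset_s + offset,
                    offset_s=b.offset_s + offset,
                    events=b.events,
                )
            )
        return blocks


def simulate_dataset(
    records: Sequence[GroundTruthRecord],
    design: RunDesign,
    hrf: HRFParams = HRFParams(),
    target_reliability: float = 0.8,
    n_repeats: int = 4,
    seed: int = 0,
) -> SimulatedDataset:
    """Forward-simulate a noisy dataset from ground-truth records.

    Each repeat concatenates the design's two unique runs; independent
    Gaussian noise is added per TR and per repeat, calibrated per voxel to
    the target split-half reliability (percent-signal-change units are
    whatever scale the record gains imply).
    """
    if n_repeats % 2 != 0:
        raise ValueError("n_repeats must be even for split-half analysis")
    (seq0, sch0), (seq1, sch1) = generate_seqsim_pair(design)
    hrf_kernel = double_gamma_hrf(hrf)
    kernels = pm.make_temporal_irfs()
    rng = np.random.default_rng([seed, 91])

    all_series = []
    rows = []
    for rec in records:
        runs = noiseless_bold(rec, (seq0, seq1), hrf_kernel, design.tr_s, kernels)
        concat = np.concatenate([runs[0], runs[1]])
        if target_reliability < 1.0:
            sd = calibrate_noise_sd(concat, target_reliability, n_repeats // 2)
        else:
            sd = 0.0
        reps = np.tile(concat, (n_repeats, 1))
        if sd > 0:
            reps = reps + rng.normal(0.0, sd, size=reps.shape)
        all_series.append(reps)
        row = asdict(rec)
        row["noise_sd"] = sd
        rows.append(row)
    params = pd.DataFrame(rows)
    return SimulatedDataset(
        params=params,
        ground_truth=list(records),
        series=np.asarray(all_series),
        schedules=(sch0, sch1),
        sequences=(seq0, seq1),
        tr_s=design.tr_s,
        target_reliability=target_reliability,
    )


def simulate_suppression_table(
    slopes: Mapping[str, float],
    n_participants: int = 10,
    n_voxels: int = 60,
    participant_slope_sd: float = 0.1,
    participant_intercept_sd: float = 0.02,
    noise_sd: float = 0.05,
    seq_ampl_range: tuple[float, float] = (0.2, 2.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a suppression table directly from the mixed-model generative form.

    For each participant, the per-pair slope is the fixed slope plus a
    Gaussian participant effect; SIM amplitudes are slope * SEQ + intercept
    + residual noise.  Used for mixed-model recovery tests.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        pid = f"S{p + 1}"
        p_slope = {k: v + rng.normal(0, participant_slope_sd) for k, v in slopes.items()}
        p_int = {k: rng.normal(0, participant_intercept_sd) for k in slopes}
        for v in range(n_voxels):
            seq = rng.uniform(*seq_ampl_range)
            for pair, slope in p_slope.items():
                rows.append(
                    {
                        "participant": pid,
                        "area": "synthetic",
                        "voxel": f"{pid}-v{v:03d}",
                        "pair": pair,
                        "seq_ampl": seq,
                        "sim_ampl": slope * seq + p_int[pair] + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
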