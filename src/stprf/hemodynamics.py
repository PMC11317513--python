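"""Neural-to-BOLD conversion: canonical double-gamma HRF and TR downsampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .prf_models import causal_convolve

__all__ = ["HRFParams", "double_gamma_hrf", "neural_to_bold"]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds).

    Defaults are the widely used canonical values: 6-s peak delay, 16-s
    undershoot delay, unit dispersions, 1:6 undershoot ratio, 32-s support.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if min(self.peak_delay_s, self.undershoot_delay_s) <= 0:
            raise ValueError("HRF delays must be positive")
        if self.duration_s < 32.0:
            raise ValueError("HRF kernel support must be at least 32 s")


def double_gamma_hrf(params: HRFParams = HRFParams()) -> np.ndarray:
    """Sampled double-gamma kernel, peak normalized to 1.

    Value 0 at t = 0; a single positive peak followed by a single negative
    undershoot.
    """
    dt_s = params.dt_ms / 1000.0
    t = np.arange(0.0, params.duration_s, dt_s)
    peak = stats.gamma.pdf(
        t, a=params.peak_delay_s / params.peak_dispersion_s, scale=params.peak_dispersion_s
    )
    under = stats.gamma.pdf(
        t,
        a=params.undershoot_delay_s / params.undershoot_dispersion_s,
        scale=params.undershoot_dispersion_s,
    )
    kernel = peak - params.undershoot_ratio * under
    return kernel / kernel.max()


def neural_to_bold(
    neural: np.ndarray,
    hrf_kernel: np.ndarray,
    tr_s: float = 1.0,
    dt_ms: float = 1.0,
    normalize: bool = False,
) -> np.ndarray:
    """Convolve a neural time series with the HRF and average within TR bins.

    The convolution is causal with a zero-padded start (runs begin with a
    blank); downsampling is a box-car mean over each TR bin, which conserves
    the run mean.  With ``normalize`` the output maximum is scaled to 1.
    """
    neural = np.asarray(neural, dtype=np.float64)
    samples_per_tr = int(round(tr_s * 1000.0 / dt_ms))
    if neural.size < samples_per_tr:
        raise ValueError("run shorter than one TR")
    conv = causal_convolve(neural, hrf_kernel)
    n_tr = neural.size // samples_per_tr
    bold = conv[: n_tr * samples_per_tr].reshape(n_tr, samples_per_tr).mean(axis=1)
    if normalize and bold.max() > 0:
        bold = bold / bold.max()
    return bold
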