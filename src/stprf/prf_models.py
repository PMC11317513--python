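"""Population-receptive-field encoding models.

Five encoding models map a binarized stimulus sequence to a
millisecond-resolution neural response:

* LSS  -- linear spatial summation: unit-volume 2-D Gaussian, linear in time;
* CSS  -- compressive spatial summation: LSS drive followed by a static
  power law with exponent in [0.01, 1];
* CST  -- compressive spatiotemporal summation: the LSS drive is filtered by
  a sustained and by on/off-transient neural impulse-response functions,
  half-wave rectified per channel, and compressed by a shared power law with
  exponent in [0.1, 1]; on- and off-transient channels are summed;
* DoG  -- difference of Gaussians: a unit-volume center Gaussian minus a
  unit-volume surround Gaussian scaled in size, linear in time;
* DN-ST -- delayed divisive normalization: the drive is filtered by a gamma
  impulse response and divisively normalized by a semi-saturation constant
  plus an exponentially-decaying low-pass copy of itself.

Because stimuli are unions of axis-aligned rectangles, the spatial stage of
every model is evaluated in closed form as a product of 1-D Gaussian
integrals; no pixel grid is involved except in test oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal, stats
from scipy.special import ndtr

from .stimulus import Rect, StimulusSequence

__all__ = [
    "SpatialPRF",
    "CSSParams",
    "TemporalIRFParams",
    "TemporalKernels",
    "CSTParams",
    "CSTChannels",
    "DoGParams",
    "DNSTParams",
    "DOG_SURROUND_SCALE",
    "SUSTAINED_IRF_DEFAULT",
    "TRANSIENT_SECOND_IRF_DEFAULT",
    "rect_overlap",
    "spatial_drive",
    "predict_lss",
    "predict_css",
    "make_temporal_irfs",
    "predict_cst",
    "predict_dog",
    "predict_dnst",
    "effective_sigma",
    "causal_convolve",
]

# Center-to-surround size ratios per visual area (from published
# center-surround fits; constant within an area).
DOG_SURROUND_SCALE: Mapping[str, float] = {
    "V1": 7.4,
    "V2": 6.8,
    "V3": 7.3,
    "hV4": 5.8,
}


@dataclass(frozen=True)
class SpatialPRF:
    """Circular 2-D Gaussian pRF with unit volume."""

    x0: float
    y0: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def effective_sigma(sigma: float, css_n: float) -> float:
    """Linear-model-equivalent pRF size ``sigma / sqrt(css_n)``.

    Compressive spatial fits trade off sigma against the exponent; dividing
    by the square root of the exponent recovers the standard deviation a
    linear model would estimate.  Used to build LSS/CST/DoG/DN-ST pRFs from
    compressive retinotopy fits.
    """
    if not 0 < css_n:
        raise ValueError("css_n must be positive")
    return sigma / math.sqrt(css_n)


@dataclass(frozen=True)
class CSSParams:
    spatial: SpatialPRF
    css_n: float

    def __post_init__(self) -> None:
        if not 0.01 <= self.css_n <= 1.0:
            raise ValueError(f"css_n must be in [0.01, 1], got {self.css_n}")


@dataclass(frozen=True)
class TemporalIRFParams:
    """Gamma-function IRF: ((t/(k*tau))^(n-1) exp(-t/(k*tau))) / (k*tau*(n-1)!).

    Peak at t = (n - 1) * kappa * tau ms.
    """

    kappa: float
    tau_ms: float
    n: int

    def __post_init__(self) -> None:
        if self.tau_ms <= 0 or self.kappa <= 0:
            raise ValueError("kappa and tau_ms must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def peak_ms(self) -> float:
        return (self.n - 1) * self.kappa * self.tau_ms

    def pdf(self, t_ms: np.ndarray) -> np.ndarray:
        scale = self.kappa * self.tau_ms
        return stats.gamma.pdf(t_ms, a=self.n, scale=scale)

    def support_ms(self, tail: float = 1e-8) -> float:
        return float(stats.gamma.ppf(1 - tail, a=self.n, scale=self.kappa * self.tau_ms))


# Defaults reproduce a sustained IRF peaking at ~40 ms and a biphasic
# on-transient IRF; the transient is the sustained gamma minus a slightly
# slower gamma.
SUSTAINED_IRF_DEFAULT = TemporalIRFParams(kappa=1.0, tau_ms=4.93, n=9)
TRANSIENT_SECOND_IRF_DEFAULT = TemporalIRFParams(kappa=1.33, tau_ms=4.93, n=10)


@dataclass(frozen=True)
class TemporalKernels:
    """Sampled sustained / on-transient / off-transient kernels.

    The sustained kernel sums to 1; each transient kernel sums to 0 with
    positive and negative lobes of equal mass; the off-transient is the
    negated on-transient.
    """

    sustained: np.ndarray
    on_transient: np.ndarray
    off_transient: np.ndarray
    dt_ms: float


def make_temporal_irfs(
    sustained: TemporalIRFParams = SUSTAINED_IRF_DEFAULT,
    second_gamma: TemporalIRFParams = TRANSIENT_SECOND_IRF_DEFAULT,
    dt_ms: float = 1.0,
) -> TemporalKernels:
    if dt_ms > 1.0:
        raise ValueError("dt_ms must be <= 1 ms for millisecond-resolution IRFs")
    support = max(sustained.support_ms(), second_gamma.support_ms())
    n = int(math.ceil(support / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    sus = sustained.pdf(t)
    sus = sus / sus.sum()
    sec = second_gamma.pdf(t)
    sec = sec / sec.sum()
    diff = sus - sec
    pos = np.clip(diff, 0.0, None)
    neg = np.clip(-diff, 0.0, None)
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("transient IRF is not biphasic; check gamma parameters")
    # balance the lobes so the transient kernel has zero net area
    on = pos - neg * (pos.sum() / neg.sum())
    return TemporalKernels(sustained=sus, on_transient=on, off_transient=-on, dt_ms=dt_ms)


@dataclass(frozen=True)
class CSTParams:
    spatial: SpatialPRF
    cst_n: float
    sustained_irf: TemporalIRFParams = SUSTAINED_IRF_DEFAULT
    second_gamma_irf: TemporalIRFParams = TRANSIENT_SECOND_IRF_DEFAULT
    beta_s: float = 1.0
    beta_t: float = 1.0

    def __post_init__(self) -> None:
        if not 0.1 <= self.cst_n <= 1.0:
            raise ValueError(f"cst_n must be in [0.1, 1], got {self.cst_n}")


@dataclass(frozen=True)
class CSTChannels:
    """Sustained and combined-transient neural responses (beta weighting deferred)."""

    sustained: np.ndarray
    transient: np.ndarray


@dataclass(frozen=True)
class DoGParams:
    center: SpatialPRF
    surround_scale: float

    def __post_init__(self) -> None:
        if self.surround_scale <= 1:
            raise ValueError("surround_scale must exceed 1")

    @classmethod
    def for_area(cls, center: SpatialPRF, area: str) -> "DoGParams":
        try:
            return cls(center=center, surround_scale=DOG_SURROUND_SCALE[area])
        except KeyError as exc:
            raise KeyError(
                f"no surround scale tabulated for area {area!r}; "
                f"known areas: {sorted(DOG_SURROUND_SCALE)}"
            ) from exc


@dataclass(frozen=True)
class DNSTParams:
    spatial: SpatialPRF
    tau1_ms: float = 50.0
    tau2_ms: float = 100.0
    sigma_dn: float = 0.1
    n_dn: float = 2.0

    def __post_init__(self) -> None:
        if min(self.tau1_ms, self.tau2_ms) <= 0 or self.sigma_dn < 0 or self.n_dn <= 0:
            raise ValueError("DN-ST parameters must be positive")
        if self.tau1_ms > 1000:
            raise ValueError("tau1_ms above 1000 ms is outside the accepted range")


# ---------------------------------------------------------------------------
# spatial stage (closed form)
# ---------------------------------------------------------------------------

def _interval_mass(a: float, b: float, mu: float, sigma: float) -> float:
    inv = 1.0 / sigma
    return float(ndtr((b - mu) * inv) - ndtr((a - mu) * inv))


def rect_overlap(prf: SpatialPRF, rect: Rect) -> float:
    """Fraction of the unit-volume Gaussian pRF falling inside ``rect``.

    Separable product of 1-D Gaussian interval integrals; always in [0, 1].
    A zero-area rectangle contributes 0 (with a warning).
    """
    if rect.area == 0:
        warnings.warn(f"zero-area rectangle {rect.label or rect.key}", stacklevel=2)
        return 0.0
    return _interval_mass(rect.x_min, rect.x_max, prf.x0, prf.sigma) * _interval_mass(
        rect.y_min, rect.y_max, prf.y0, prf.sigma
    )


def spatial_drive(prf: SpatialPRF, sequence: StimulusSequence) -> np.ndarray:
    """Millisecond-resolution spatial pRF drive.

    At each millisecond the drive is the sum of Gaussian-rectangle overlaps
    of the rectangles active at that time; it is piecewise constant between
    events.  This is exactly the LSS neural prediction.
    """
    out = np.zeros(sequence.duration_ms, dtype=np.float64)
    cache: dict[tuple[float, float, float, float], float] = {}
    for rect, on, off in sequence.events:
        w = cache.get(rect.key)
        if w is None:
            w = rect_overlap(prf, rect)
            cache[rect.key] = w
        if w:
            out[on:off] += w
    return out


def predict_lss(prf: SpatialPRF, sequence: StimulusSequence) -> np.ndarray:
    """Linear spatial summation prediction (identical to the spatial drive)."""
    return spatial_drive(prf, sequence)


def predict_css(params: CSSParams, sequence: StimulusSequence) -> np.ndarray:
    drive = spatial_drive(params.spatial, sequence)
    return drive**params.css_n


# ---------------------------------------------------------------------------
# temporal stages
# ---------------------------------------------------------------------------

# FFT cache for repeated convolutions with the same kernel (HRF, IRFs):
# keyed by kernel bytes and padded length, bounded to avoid growth.
_KERNEL_FFT_CACHE: dict[tuple[int, int], np.ndarray] = {}


def causal_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution truncated to the length of ``x`` (zero-padded start).

    Kernel FFTs are cached, which makes repeated convolutions of long runs
    with the same HRF or IRF substantially cheaper.
    """
    from scipy import fft as sfft

    x = np.asarray(x, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    nfull = x.size + kernel.size - 1
    nfft = sfft.next_fast_len(nfull)
    key = (hash(kernel.tobytes()), nfft)
    kf = _KERNEL_FFT_CACHE.get(key)
    if kf is None:
        if len(_KERNEL_FFT_CACHE) > 32:
            _KERNEL_FFT_CACHE.clear()
        kf = sfft.rfft(kernel, nfft)
        _KERNEL_FFT_CACHE[key] = kf
    out = sfft.irfft(sfft.rfft(x, nfft) * kf, nfft)
    return out[: x.size]


def predict_cst(
    params: CSTParams,
    sequence: StimulusSequence,
    kernels: TemporalKernels | None = None,
) -> CSTChannels:
    """Compressive spatiotemporal prediction.

    Per channel: convolve the spatial drive with the channel IRF, half-wave
    rectify, raise to ``cst_n``; the on- and off-transient channels are then
    summed into a single transient channel.  Channel beta weights are applied
    at the fitting stage, not here.
    """
    if kernels is None:
        kernels = make_temporal_irfs(params.sustained_irf, params.second_gamma_irf)
    drive = spatial_drive(params.spatial, sequence)
    n = params.cst_n

    def _channel(kernel: np.ndarray) -> np.ndarray:
        x = causal_convolve(drive, kernel)
        # suppress FFT noise in silent periods: the fractional exponent would
        # otherwise amplify ~1e-13 residuals into visible spurious output
        floor = 1e-10 * np.abs(x).max() if x.size else 0.0
        x = np.where(x > floor, x, 0.0)
        return x**n

    sus = _channel(kernels.sustained)
    on = _channel(kernels.on_transient)
    off = _channel(kernels.off_transient)
    return CSTChannels(sustained=sus, transient=on + off)


def predict_dog(
    params: DoGParams,
    sequence: StimulusSequence,
    grid_spec=None,
) -> np.ndarray:
    """Difference-of-Gaussians prediction: center drive minus surround drive.

    Both Gaussians have unit volume (fully balanced surround), so a stimulus
    covering the whole field drives the model to ~0.  Linear in time; output
    may be negative.  ``grid_spec`` is accepted for interface parity but the
    evaluation is closed-form for rectangle stimuli.
    """
    center = spatial_drive(params.center, sequence)
    surround_prf = SpatialPRF(
        params.center.x0, params.center.y0, params.center.sigma * params.surround_scale
    )
    surround = spatial_drive(surround_prf, sequence)
    return center - surround


def predict_dnst(
    params: DNSTParams, sequence: StimulusSequence, dt_ms: float = 1.0
) -> np.ndarray:
    """Delayed-normalization spatiotemporal prediction.

    r(t) is the spatial drive filtered by a gamma IRF ``t * exp(-t / tau1)``;
    the output is ``|r|^n / (sigma_dn^n + (|r| * exp(-t / tau2))^n)`` where
    ``*`` is causal convolution.  Both filters are normalized to unit sum so
    ``sigma_dn`` is comparable across time constants and the steady-state
    output of a step input has the closed form ``d^n / (sigma_dn^n + d^n)``.
    A 0/0 at zero drive and zero semi-saturation is defined as 0.
    """
    if dt_ms > 1.0:
        raise ValueError("dt_ms must be <= 1 ms")
    drive = spatial_drive(params.spatial, sequence)

    t1_support = -params.tau1_ms * math.log(1e-12) + 10 * params.tau1_ms
    t = np.arange(0.0, t1_support, dt_ms)
    irf1 = t * np.exp(-t / params.tau1_ms)
    irf1 /= irf1.sum()
    t2 = np.arange(0.0, -params.tau2_ms * math.log(1e-12), dt_ms)
    irf2 = np.exp(-t2 / params.tau2_ms)
    irf2 /= irf2.sum()

    r = np.abs(causal_convolve(drive, irf1))
    num = r**params.n_dn
    den = params.sigma_dn**params.n_dn + causal_convolve(r, irf2) ** params.n_dn
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out
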