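"""Per-channel signal feature bank and the 1044-value segment descriptor.

Channel-group plan
------------------
The extractor assembles exactly 1044 values per segment:

* 16 EMG channels x 46 features (time, frequency and entropy banks) = 736
* 12 accelerometer/gyroscope channels x 17 features = 204
*  8 orientation-quaternion channels x 13 features = 104

Low-rate IMU channels only get estimators that are stable at ~20 samples.
Feature names are registered as ``device.channel.feature`` and are stable
across runs.

Degenerate-input policy: once a segment has passed the minimum-duration
gate, no feature raises — quantities undefined on constant or too-short
input return the documented sentinel 0 (a debug message is logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _dwt

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "InsufficientDataError",
    "mav",
    "rms",
    "zcr",
    "wamp",
    "amplitude_shape_features",
    "hjorth",
    "fractal_features",
    "spectral_features",
    "wavelet_energy",
    "ar_features",
    "entropy_features",
    "feature_names",
    "extract_feature_vector",
    "extract_feature_table",
    "EMG_FEATURES",
    "MOTION_FEATURES",
    "ORIENTATION_FEATURES",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """A channel is too short for the requested feature set."""


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the feature bank."""

    wamp_threshold: float = 10.0
    ar_orders: tuple[int, ...] = (1, 2, 4, 8)
    wavelet: str = "db4"
    wavelet_levels: int = 4
    higuchi_kmax: int = 8
    hist_bins: int = 64
    svd_embed_dim: int = 10
    inactive_threshold: float = 3.0

    def __post_init__(self) -> None:
        if tuple(self.ar_orders) != (1, 2, 4, 8):
            raise ValueError("ar_orders must be exactly (1, 2, 4, 8)")
        for name in ("wamp_threshold", "wavelet_levels", "higuchi_kmax", "hist_bins", "svd_embed_dim", "inactive_threshold"):
            if getattr(self, name) <= 0 and name != "wamp_threshold":
                raise ValueError(f"{name} must be positive")
        if self.wamp_threshold < 0:
            raise ValueError("wamp_threshold must be >= 0")


@dataclass
class FeatureVector:
    """1044 finite values with a stable name registry."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _asarray(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    return a


def _fin(v: float) -> float:
    if not math.isfinite(v):
        logger.debug("non-finite feature value replaced by sentinel 0")
        return 0.0
    return float(v)


# ---------------------------------------------------------------------------
# time-domain primitives


def mav(x) -> float:
    """Mean absolute value: (1/N) * sum |x_n|."""
    x = _asarray(x)
    if len(x) < 1:
        raise ValueError("mav requires at least one sample")
    return float(np.mean(np.abs(x)))


def rms(x) -> float:
    """Root mean square: sqrt((1/N) * sum x_n^2)."""
    x = _asarray(x)
    if len(x) < 1:
        raise ValueError("rms requires at least one sample")
    return float(np.sqrt(np.mean(x**2)))


def zcr(x) -> float:
    """Sign-change rate: (1/(N-1)) * #{i : x_i * x_{i+1} < 0}.

    A zero sample gives a zero product and therefore counts as no crossing.
    """
    x = _asarray(x)
    if len(x) < 2:
        raise ValueError("zcr requires at least two samples")
    return float(np.count_nonzero(x[:-1] * x[1:] < 0) / (len(x) - 1))


def wamp(x, threshold: float) -> int:
    """Willison amplitude: #{i : |x_{i+1} - x_i| > threshold}."""
    x = _asarray(x)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(x) < 2:
        return 0
    return int(np.count_nonzero(np.abs(np.diff(x)) > threshold))


def amplitude_shape_features(x, fs: float = 1.0, inactive_threshold: float = 3.0) -> dict[str, float]:
    """Amplitude/shape descriptors (IEMG, Teager energy, slope, ...).

    ``slope`` is the least-squares line slope in units per second,
    ``std`` is the population standard deviation, ``skewness`` the plain
    moment estimator and ``kurtosis`` excess kurtosis; minima/maxima count
    strict local extrema.
    """
    x = _asarray(x)
    n = len(x)
    if n < 3:
        raise ValueError("amplitude_shape_features requires at least 3 samples")
    d1 = np.diff(x)
    t = np.arange(n) / fs
    tc = t - t.mean()
    denom = float(np.sum(tc**2))
    slope = float(np.sum(tc * (x - x.mean())) / denom) if denom > 0 else 0.0
    m2 = float(np.mean((x - x.mean()) ** 2))
    if m2 > 0:
        m3 = float(np.mean((x - x.mean()) ** 3))
        m4 = float(np.mean((x - x.mean()) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    interior = x[1:-1]
    minima = int(np.count_nonzero((interior < x[:-2]) & (interior < x[2:])))
    maxima = int(np.count_nonzero((interior > x[:-2]) & (interior > x[2:])))
    tk = x[1:-1] ** 2 - x[:-2] * x[2:]
    d2 = np.diff(d1)
    return {
        "iemg": float(np.sum(np.abs(x))),
        "nonlinear_energy": float(np.mean(tk)),
        "slope": slope,
        "line_length": float(np.sum(np.abs(d1))),
        "std": float(np.sqrt(m2)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "minima": float(minima),
        "maxima": float(maxima),
        "skewness": _fin(skew),
        "kurtosis": _fin(kurt),
        "zc_d1": zcr(d1) if len(d1) >= 2 else 0.0,
        "zc_d2": zcr(d2) if len(d2) >= 2 else 0.0,
        "inactive": float(np.count_nonzero(np.abs(x) < inactive_threshold)),
    }


def hjorth(x) -> tuple[float, float, float]:
    """Hjorth (activity, mobility, complexity); constant input -> (0, 0, 0)."""
    x = _asarray(x)
    if len(x) < 3:
        return (0.0, 0.0, 0.0)
    var0 = float(np.var(x))
    if var0 <= 0:
        return (0.0, 0.0, 0.0)
    d1 = np.diff(x)
    var1 = float(np.var(d1))
    mobility = math.sqrt(var1 / var0)
    if var1 <= 0:
        return (var0, mobility, 0.0)
    d2 = np.diff(d1)
    var2 = float(np.var(d2)) if len(d2) else 0.0
    mobility_d = math.sqrt(var2 / var1)
    complexity = mobility_d / mobility if mobility > 0 else 0.0
    return (var0, mobility, _fin(complexity))


# ---------------------------------------------------------------------------
# fractal / scaling descriptors


def _higuchi_fd(x: np.ndarray, kmax: int) -> float:
    n = len(x)
    ks, ls = [], []
    for k in range(1, kmax + 1):
        lk = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (len(idx) - 1) / k
            lk.append(dist * norm / k)
        if lk:
            mean_lk = float(np.mean(lk))
            if mean_lk > 0:
                ks.append(math.log(1.0 / k))
                ls.append(math.log(mean_lk))
    if len(ks) < 2:
        return 0.0
    return float(np.polyfit(ks, ls, 1)[0])


def _petrosian_fd(x: np.ndarray) -> float:
    n = len(x)
    d = np.diff(x)
    nz = d[d != 0]
    n_delta = int(np.count_nonzero(nz[:-1] * nz[1:] < 0)) if len(nz) > 1 else 0
    log_n = math.log10(n)
    denom = log_n + math.log10(n / (n + 0.4 * n_delta))
    if denom == 0:
        return 0.0
    return log_n / denom


def _dfa_alpha(x: np.ndarray) -> float:
    n = len(x)
    profile = np.cumsum(x - np.mean(x))
    max_box = n // 4
    if max_box < 4:
        return 0.0
    sizes = np.unique(np.round(np.exp(np.linspace(math.log(4), math.log(max_box), 10))).astype(int))
    sizes = sizes[sizes >= 4]
    logs, logf = [], []
    for s in sizes:
        n_boxes = n // s
        if n_boxes < 1:
            continue
        segs = profile[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        tc = t - t.mean()
        denom = np.sum(tc**2)
        slopes = segs @ tc / denom
        intercepts = segs.mean(axis=1)
        resid = segs - (intercepts[:, None] + slopes[:, None] * tc[None, :])
        f = math.sqrt(float(np.mean(resid**2)))
        if f > 0:
            logs.append(math.log(s))
            logf.append(math.log(f))
    if len(logs) < 2:
        return 0.0
    return float(np.polyfit(logs, logf, 1)[0])


def _expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expected rescaled range of white noise at window n."""
    from scipy.special import gammaln

    if n <= 340:
        front = math.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / math.sqrt(math.pi)
    else:
        front = 1.0 / math.sqrt(n * math.pi / 2.0)
    tail = sum(math.sqrt((n - i) / i) for i in range(1, n))
    return ((n - 0.5) / n) * front * tail


def _hurst_rs(x: np.ndarray) -> float:
    """Rescaled-range Hurst with the Anis-Lloyd-Peters small-sample correction."""
    n = len(x)
    max_w = n // 2
    if max_w < 8:
        return 0.0
    sizes = np.unique(np.round(np.exp(np.linspace(math.log(8), math.log(max_w), 8))).astype(int))
    logs, logrs = [], []
    for s in sizes:
        n_chunks = n // s
        if n_chunks < 1:
            continue
        vals = []
        for c in range(n_chunks):
            chunk = x[c * s : (c + 1) * s]
            dev = np.cumsum(chunk - chunk.mean())
            r = float(dev.max() - dev.min())
            sd = float(chunk.std())
            if sd > 0:
                vals.append(r / sd)
        if vals:
            m = float(np.mean(vals)) - _expected_rs(s) + math.sqrt(math.pi * s / 2.0)
            if m > 0:
                logs.append(math.log(s))
                logrs.append(math.log(m))
    if len(logs) < 2:
        return 0.0
    return float(np.polyfit(logs, logrs, 1)[0])


def fractal_features(x, kmax: int = 8) -> tuple[float, float, float, float]:
    """(Higuchi FD, Petrosian FD, DFA alpha, Hurst exponent).

    Constant input returns all-zero sentinels; fewer than 20 samples is an
    error because none of the estimators is meaningful there.
    """
    x = _asarray(x)
    if len(x) < 20:
        raise InsufficientDataError("fractal features require at least 20 samples")
    if float(np.ptp(x)) == 0.0:
        return (0.0, 0.0, 0.0, 0.0)
    return (
        _fin(_higuchi_fd(x, kmax)),
        _fin(_petrosian_fd(x)),
        _fin(_dfa_alpha(x)),
        _fin(_hurst_rs(x)),
    )


# ---------------------------------------------------------------------------
# spectral descriptors


def _periodogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT amplitude and power, unnormalized (|X|, |X|^2)."""
    X = np.fft.rfft(x)
    amp = np.abs(X)
    return amp, amp**2


def spectral_features(x, fs: float) -> dict[str, float]:
    """DFT-derived descriptors on the one-sided periodogram.

    "Modified" median/mean frequency use the amplitude spectrum |X(f)|
    instead of power.  An all-zero signal returns all-zero sentinels.
    """
    x = _asarray(x)
    if len(x) < 1:
        raise ValueError("spectral_features requires a nonempty signal")
    if fs <= 0:
        raise ValueError("fs must be positive")
    amp, power = _periodogram(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    total_p = float(np.sum(power))
    names = [
        "peak_freq",
        "median_freq",
        "mod_median_freq",
        "mod_mean_freq",
        "iw_mean_freq",
        "iw_bandwidth",
        "total_spectrum",
        "mean_power",
    ]
    if total_p <= 0:
        return {k: 0.0 for k in names}
    total_a = float(np.sum(amp))
    cum_p = np.cumsum(power)
    cum_a = np.cumsum(amp)
    median_freq = float(freqs[np.searchsorted(cum_p, total_p / 2.0)])
    mod_median_freq = float(freqs[np.searchsorted(cum_a, total_a / 2.0)])
    iw_mean = float(np.sum(freqs * power) / total_p)
    return {
        "peak_freq": float(freqs[int(np.argmax(power))]),
        "median_freq": median_freq,
        "mod_median_freq": mod_median_freq,
        "mod_mean_freq": float(np.sum(freqs * amp) / total_a),
        "iw_mean_freq": iw_mean,
        "iw_bandwidth": float(np.sqrt(np.sum((freqs - iw_mean) ** 2 * power) / total_p)),
        "total_spectrum": total_p,
        "mean_power": total_p / len(power),
    }


def wavelet_energy(x, wavelet: str = "db4", levels: int = 4) -> float:
    """Total squared detail-coefficient energy of the discrete decomposition.

    Inputs shorter than ``2**levels`` are decomposed at the maximum feasible
    depth.
    """
    x = _asarray(x)
    if len(x) < 2:
        return 0.0
    _, details = _dwt.wavedec(x, wavelet=wavelet, levels=levels)
    return float(sum(np.sum(d**2) for d in details))


# ---------------------------------------------------------------------------
# autoregressive descriptors


def _levinson(r: np.ndarray, order: int) -> tuple[np.ndarray, float, list[tuple[np.ndarray, float]]]:
    """Levinson-Durbin on autocovariance ``r[0..order]``.

    Returns (coefficients a_1..a_p of x[n] = sum a_i x[n-i] + e, final error
    variance, and the (coeffs, error) at every intermediate order).
    """
    a = np.zeros(0)
    err = float(r[0])
    history: list[tuple[np.ndarray, float]] = []
    for m in range(1, order + 1):
        if err <= 1e-300:
            # degenerate: freeze, remaining orders inherit current fit
            history.append((a.copy(), 0.0))
            for _ in range(m + 1, order + 1):
                history.append((a.copy(), 0.0))
            return a, 0.0, history
        acc = r[m] - float(np.dot(a, r[m - 1 : 0 : -1])) if m > 1 else float(r[1])
        k = acc / err
        new_a = np.empty(m)
        new_a[: m - 1] = a - k * a[::-1]
        new_a[m - 1] = k
        a = new_a
        err = err * (1.0 - k * k)
        history.append((a.copy(), max(err, 0.0)))
    return a, max(err, 0.0), history


def ar_features(x, orders: Sequence[int] = (1, 2, 4, 8)) -> dict[str, float]:
    """First AR coefficient and final prediction-error variance per order.

    Fits via Levinson-Durbin on the biased autocorrelation; a (near-)constant
    signal yields all-zero sentinels.
    """
    x = _asarray(x)
    max_order = max(orders)
    if len(x) <= 2 * max_order:
        raise InsufficientDataError(f"ar_features requires more than {2 * max_order} samples")
    n = len(x)
    r = np.array([float(np.dot(x[: n - k], x[k:])) / n for k in range(max_order + 1)])
    out: dict[str, float] = {}
    if r[0] <= 1e-300 or float(np.ptp(x)) == 0.0:
        for p in orders:
            out[f"ar_coef_{p}"] = 0.0
            out[f"ar_err_{p}"] = 0.0
        return out
    _, _, history = _levinson(r, max_order)
    for p in orders:
        coeffs, err = history[p - 1]
        out[f"ar_coef_{p}"] = _fin(coeffs[0]) if len(coeffs) else 0.0
        out[f"ar_err_{p}"] = _fin(err)
    return out


# ---------------------------------------------------------------------------
# entropy descriptors


def _shannon_from_probs(p: np.ndarray) -> float:
    p = p[p > 0]
    if len(p) == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def entropy_features(
    x,
    fs: float,
    config: Optional[FeatureConfig] = None,
    hist_range: Optional[tuple[float, float]] = None,
) -> tuple[float, float, float, float]:
    """(Shannon, spectral, SVD, Fisher) information measures.

    Shannon uses a fixed-width amplitude histogram (``hist_range`` defaults
    to the observed min/max), natural log, empty bins skipped.  Spectral
    entropy is normalized by log(#bins) into [0, 1].  SVD entropy and Fisher
    information act on the normalized singular values of the delay-embedding
    matrix (delay 1).  Constant input returns all zeros.
    """
    config = config or FeatureConfig()
    x = _asarray(x)
    if len(x) < config.svd_embed_dim + 1:
        raise InsufficientDataError(
            f"entropy features require at least {config.svd_embed_dim + 1} samples"
        )
    if float(np.ptp(x)) == 0.0:
        return (0.0, 0.0, 0.0, 0.0)

    lo, hi = hist_range if hist_range is not None else (float(np.min(x)), float(np.max(x)))
    if hi <= lo:
        shannon = 0.0
    else:
        counts, _ = np.histogram(x, bins=config.hist_bins, range=(lo, hi))
        shannon = _shannon_from_probs(counts / len(x))

    _, power = _periodogram(x)
    total_p = float(np.sum(power))
    if total_p <= 0 or len(power) < 2:
        spectral = 0.0
    else:
        spectral = _shannon_from_probs(power / total_p) / math.log(len(power))

    d = config.svd_embed_dim
    emb = np.lib.stride_tricks.sliding_window_view(x, d)
    s = np.linalg.svd(emb, compute_uv=False)
    s_norm = s / np.sum(s)
    svd_entropy = _shannon_from_probs(s_norm)
    fisher = 0.0
    for i in range(len(s_norm) - 1):
        if s_norm[i] > 1e-15:
            fisher += (s_norm[i + 1] - s_norm[i]) ** 2 / s_norm[i]
    return (_fin(shannon), _fin(spectral), _fin(svd_entropy), _fin(fisher))


# ---------------------------------------------------------------------------
# the 1044-value segment descriptor

EMG_FEATURES: tuple[str, ...] = (
    # time domain
    "mav",
    "iemg",
    "higuchi_fd",
    "petrosian_fd",
    "dfa_alpha",
    "nonlinear_energy",
    "slope",
    "line_length",
    "wamp",
    "std",
    "min",
    "max",
    "hurst",
    "minima",
    "maxima",
    "skewness",
    "kurtosis",
    "zc",
    "zc_d1",
    "zc_d2",
    "rms",
    "inactive",
    "mobility",
    "activity",
    "complexity",
    # frequency domain
    "peak_freq",
    "median_freq",
    "mod_median_freq",
    "mod_mean_freq",
    "iw_mean_freq",
    "iw_bandwidth",
    "total_spectrum",
    "mean_power",
    "wavelet_energy",
    "ar_coef_1",
    "ar_err_1",
    "ar_coef_2",
    "ar_err_2",
    "ar_coef_4",
    "ar_err_4",
    "ar_coef_8",
    "ar_err_8",
    # entropy based
    "shannon",
    "spectral_entropy",
    "svd_entropy",
    "fisher_info",
)

MOTION_FEATURES: tuple[str, ...] = (
    "mav",
    "rms",
    "min",
    "max",
    "std",
    "skewness",
    "kurtosis",
    "zc",
    "wamp",
    "line_length",
    "slope",
    "mobility",
    "activity",
    "complexity",
    "peak_freq",
    "median_freq",
    "shannon",
)

ORIENTATION_FEATURES: tuple[str, ...] = (
    "mav",
    "rms",
    "min",
    "max",
    "std",
    "skewness",
    "kurtosis",
    "zc",
    "line_length",
    "slope",
    "mobility",
    "activity",
    "complexity",
)

_DEVICES = ("left", "right")
_EMG_CHANNELS = tuple(f"emg{c}" for c in range(8))
_MOTION_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")
_ORIENT_CHANNELS = ("quat_w", "quat_x", "quat_y", "quat_z")

MIN_EMG_SAMPLES = 80  # 0.4 s at 200 Hz
MIN_IMU_SAMPLES = 20  # 0.4 s at 50 Hz


def feature_names() -> list[str]:
    """The stable 1044-entry ``device.channel.feature`` registry."""
    names: list[str] = []
    for dev in _DEVICES:
        for ch in _EMG_CHANNELS:
            names.extend(f"{dev}.{ch}.{f}" for f in EMG_FEATURES)
    for dev in _DEVICES:
        for ch in _MOTION_CHANNELS:
            names.extend(f"{dev}.{ch}.{f}" for f in MOTION_FEATURES)
    for dev in _DEVICES:
        for ch in _ORIENT_CHANNELS:
            names.extend(f"{dev}.{ch}.{f}" for f in ORIENTATION_FEATURES)
    return names


def _basic_stats(x: np.ndarray, fs: float, config: FeatureConfig) -> dict[str, float]:
    shape = amplitude_shape_features(x, fs=fs, inactive_threshold=config.inactive_threshold)
    act, mob, comp = hjorth(x)
    return {
        "mav": mav(x),
        "rms": rms(x),
        "min": shape["min"],
        "max": shape["max"],
        "std": shape["std"],
        "skewness": shape["skewness"],
        "kurtosis": shape["kurtosis"],
        "zc": zcr(x),
        "line_length": shape["line_length"],
        "slope": shape["slope"],
        "mobility": mob,
        "activity": act,
        "complexity": comp,
        **shape,
    }


def _emg_channel_features(x: np.ndarray, fs: float, config: FeatureConfig) -> dict[str, float]:
    out = _basic_stats(x, fs, config)
    out["wamp"] = float(wamp(x, config.wamp_threshold))
    hig, pet, dfa, hurst = fractal_features(x, kmax=config.higuchi_kmax)
    out.update({"higuchi_fd": hig, "petrosian_fd": pet, "dfa_alpha": dfa, "hurst": hurst})
    out.update(spectral_features(x, fs))
    out["wavelet_energy"] = wavelet_energy(x, config.wavelet, config.wavelet_levels)
    out.update(ar_features(x, config.ar_orders))
    sh, sp, sv, fi = entropy_features(x, fs, config, hist_range=(-127.0, 128.0))
    out.update({"shannon": sh, "spectral_entropy": sp, "svd_entropy": sv, "fisher_info": fi})
    return out


def _motion_channel_features(x: np.ndarray, fs: float, config: FeatureConfig) -> dict[str, float]:
    out = _basic_stats(x, fs, config)
    out["wamp"] = float(wamp(x, config.wamp_threshold))
    out.update(spectral_features(x, fs))
    try:
        sh, _, _, _ = entropy_features(x, fs, config)
    except InsufficientDataError:
        sh = 0.0
    out["shannon"] = sh
    return out


def _orientation_channel_features(x: np.ndarray, fs: float, config: FeatureConfig) -> dict[str, float]:
    return _basic_stats(x, fs, config)


def extract_feature_vector(segment, config: Optional[FeatureConfig] = None) -> FeatureVector:
    """Assemble the 1044-value descriptor for one segment or recording.

    ``segment`` is anything exposing ``channel_arrays()`` with the standard
    two-armband channel layout (a :class:`~armsign.segmentation.Segment` or
    a :class:`~armsign.synth.TwoArmRecording`).
    """
    config = config or FeatureConfig()
    channels = segment.channel_arrays()
    for (dev, ch), (fs, x) in channels.items():
        needed = MIN_EMG_SAMPLES if ch.startswith("emg") else MIN_IMU_SAMPLES
        if len(x) < needed:
            raise InsufficientDataError(
                f"channel {dev}.{ch} has {len(x)} samples; needs >= {needed}"
            )
    values: list[float] = []
    for dev in _DEVICES:
        for ch in _EMG_CHANNELS:
            fs, x = channels[(dev, ch)]
            feats = _emg_channel_features(x, fs, config)
            values.extend(_fin(feats[f]) for f in EMG_FEATURES)
    for dev in _DEVICES:
        for ch in _MOTION_CHANNELS:
            fs, x = channels[(dev, ch)]
            feats = _motion_channel_features(x, fs, config)
            values.extend(_fin(feats[f]) for f in MOTION_FEATURES)
    for dev in _DEVICES:
        for ch in _ORIENT_CHANNELS:
            fs, x = channels[(dev, ch)]
            feats = _orientation_channel_features(x, fs, config)
            values.extend(_fin(feats[f]) for f in ORIENTATION_FEATURES)
    return FeatureVector(np.array(values), feature_names())


def extract_feature_table(dataset, config: Optional[FeatureConfig] = None):
    """Featurize every recording of a dataset into its ``features`` table."""
    from .dataset import FeatureTable

    config = config or FeatureConfig()
    rows = []
    labels = []
    for rec in dataset.recordings:
        rows.append(extract_feature_vector(rec, config).values)
        labels.append(rec.label)
    dataset.features = FeatureTable(feature_names(), np.vstack(rows), labels)
    return dataset.features
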