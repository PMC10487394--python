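"""HRV metric battery for 4-minute NN segments.

Three domains, 27 metrics total, using the naming conventions common to HRV
analysis toolkits so downstream tables can be assembled by metric name:

* time domain (16): mean_nni, median_nni, range_nni, sdnn, sdsd, rmssd,
  nni_50, pnni_50, nni_20, pnni_20, cvsd, cvnni, mean_hr, max_hr, min_hr,
  std_hr
* frequency domain (7): vlf, lf, hf, total_power, lf_hf_ratio, lfnu, hfnu,
  from a Welch periodogram of the cubic-spline-resampled tachogram
* non-linear (4): csi, cvi, modified_csi (Poincare-plot descriptors) and
  sampen (sample entropy)

Standard-deviation convention is population (ddof=0) throughout, switchable
per config. Undefined ratios (e.g. hf == 0) propagate as NaN, never +/-inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .preprocess import NNSeries, Segment

__all__ = [
    "SpectralConfig",
    "SampleEntropyConfig",
    "TIME_DOMAIN_METRICS",
    "FREQUENCY_DOMAIN_METRICS",
    "NONLINEAR_METRICS",
    "ALL_METRICS",
    "METRIC_DOMAIN",
    "time_domain",
    "interpolate_and_psd",
    "frequency_domain",
    "poincare",
    "sample_entropy",
    "compute_record",
]

TIME_DOMAIN_METRICS = (
    "mean_nni", "sdnn", "sdsd", "nni_50", "pnni_50", "nni_20", "pnni_20",
    "rmssd", "median_nni", "range_nni", "cvsd", "cvnni", "mean_hr",
    "max_hr", "min_hr", "std_hr",
)
FREQUENCY_DOMAIN_METRICS = (
    "lf", "hf", "lf_hf_ratio", "lfnu", "hfnu", "total_power", "vlf",
)
NONLINEAR_METRICS = ("csi", "cvi", "modified_csi", "sampen")
ALL_METRICS = TIME_DOMAIN_METRICS + FREQUENCY_DOMAIN_METRICS + NONLINEAR_METRICS

METRIC_DOMAIN = {
    **{m: "time" for m in TIME_DOMAIN_METRICS},
    **{m: "frequency" for m in FREQUENCY_DOMAIN_METRICS},
    **{m: "non-linear" for m in NONLINEAR_METRICS},
}


@dataclass(frozen=True)
class SpectralConfig:
    """Tachogram resampling and Welch-periodogram parameters.

    Band edges follow the short-term HRV convention: VLF 0.003-0.04 Hz,
    LF 0.04-0.15 Hz, HF 0.15-0.40 Hz. The tachogram is resampled at 4 Hz
    (well above twice the HF upper edge) by cubic spline, mean-removed, and
    analysed with 120-s Hann Welch segments at 50% overlap — two full
    segments plus one overlap inside a 4-min window.
    """

    resample_hz: float = 4.0
    interpolation: str = "cubic"
    vlf_band: tuple[float, float] = (0.003, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    welch_segment_s: float = 120.0
    welch_overlap: float = 0.5
    window_name: str = "hann"

    def __post_init__(self) -> None:
        bands = (self.vlf_band, self.lf_band, self.hf_band)
        edges = [e for b in bands for e in b]
        if any(b[0] >= b[1] for b in bands) or sorted(edges) != edges:
            raise ValueError("bands must be increasing and non-overlapping")
        if self.resample_hz <= 2 * self.hf_band[1]:
            raise ValueError("resample_hz must exceed twice the HF upper edge")


@dataclass(frozen=True)
class SampleEntropyConfig:
    """Embedding dimension m and tolerance r as a fraction of the series sd."""

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1 or self.r <= 0:
            raise ValueError("need m >= 1 and r > 0")


def _std(x: np.ndarray, ddof: int) -> float:
    return float(np.std(x, ddof=ddof))


def time_domain(nn, ddof: int = 0) -> dict:
    """The 16 time-domain metrics from the NN intervals alone.

    pnni_50 / pnni_20 are percentages of the N-1 successive differences;
    heart-rate statistics come from the instantaneous rate 60000/NN.
    """
    rr = np.asarray(nn.rr if hasattr(nn, "rr") else nn, dtype=float)
    if len(rr) < 2:
        raise ValueError("need at least 2 intervals")
    diff = np.diff(rr)
    hr = 60_000.0 / rr
    mean_nni = float(np.mean(rr))
    sdnn = _std(rr, ddof)
    rmssd = float(np.sqrt(np.mean(diff**2)))
    nni_50 = int(np.sum(np.abs(diff) > 50))
    nni_20 = int(np.sum(np.abs(diff) > 20))
    return {
        "mean_nni": mean_nni,
        "median_nni": float(np.median(rr)),
        "range_nni": float(rr.max() - rr.min()),
        "sdnn": sdnn,
        "sdsd": _std(diff, ddof),
        "rmssd": rmssd,
        "nni_50": nni_50,
        "pnni_50": 100.0 * nni_50 / len(diff),
        "nni_20": nni_20,
        "pnni_20": 100.0 * nni_20 / len(diff),
        "cvsd": rmssd / mean_nni,
        "cvnni": sdnn / mean_nni,
        "mean_hr": float(np.mean(hr)),
        "max_hr": float(np.max(hr)),
        "min_hr": float(np.min(hr)),
        "std_hr": _std(hr, ddof),
    }


def interpolate_and_psd(nn, cfg: SpectralConfig = SpectralConfig()):
    """Evenly resampled tachogram -> Welch power spectral density.

    The NN series (interval value at each beat time) is interpolated onto a
    uniform grid at cfg.resample_hz, the mean removed, and a Welch PSD taken
    with the configured segment length, overlap and window. Returns
    (frequencies Hz, density ms^2/Hz).
    """
    bt = np.asarray(nn.beat_time, dtype=float) / 1000.0  # s
    rr = np.asarray(nn.rr, dtype=float)
    if len(rr) < 4:
        raise ValueError("too few beats for spectral analysis")
    duration = bt[-1] - bt[0]
    if duration < cfg.welch_segment_s:
        raise ValueError("segment shorter than one Welch segment")
    fs = cfg.resample_hz
    t_grid = np.arange(bt[0], bt[-1], 1.0 / fs)
    if cfg.interpolation == "cubic":
        x = CubicSpline(bt, rr)(t_grid)
    elif cfg.interpolation == "linear":
        x = np.interp(t_grid, bt, rr)
    else:
        raise ValueError(f"unknown interpolation {cfg.interpolation!r}")
    x = x - x.mean()
    nperseg = int(round(cfg.welch_segment_s * fs))
    noverlap = int(round(nperseg * cfg.welch_overlap))
    freqs, psd = signal.welch(
        x, fs=fs, window=cfg.window_name, nperseg=min(nperseg, len(x)),
        noverlap=noverlap, detrend="constant", scaling="density",
    )
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def frequency_domain(psd_pair, cfg: SpectralConfig = SpectralConfig()) -> dict:
    """Band powers by trapezoidal integration plus the derived ratios."""
    freqs, psd = psd_pair
    vlf = _band_power(freqs, psd, cfg.vlf_band)
    lf = _band_power(freqs, psd, cfg.lf_band)
    hf = _band_power(freqs, psd, cfg.hf_band)
    tot = vlf + lf + hf
    if lf + hf > 0:
        lfnu = 100.0 * lf / (lf + hf)
        hfnu = 100.0 * hf / (lf + hf)
    else:
        lfnu = hfnu = math.nan
    ratio = lf / hf if hf > 0 else math.nan
    return {
        "vlf": vlf, "lf": lf, "hf": hf, "total_power": tot,
        "lf_hf_ratio": ratio, "lfnu": lfnu, "hfnu": hfnu,
    }


def poincare(nn, ddof: int = 0) -> dict:
    """Poincare-plot descriptors of the lag-1 return map.

    sd1/sd2 are the dispersions transverse/longitudinal to the identity
    line; the cardiac sympathetic index csi = L/T with T = 4*sd1, L = 4*sd2,
    the cardiac vagal index cvi = log10(L*T), and modified_csi = L^2/T.
    Degenerate axes (constant series) yield NaN ratios.
    """
    rr = np.asarray(nn.rr if hasattr(nn, "rr") else nn, dtype=float)
    if len(rr) < 3:
        raise ValueError("need at least 3 intervals")
    diff = np.diff(rr)
    var_d = np.var(diff, ddof=ddof)
    sd1 = math.sqrt(var_d / 2.0)
    sd2_sq = 2.0 * np.var(rr, ddof=ddof) - var_d / 2.0
    sd2 = math.sqrt(max(sd2_sq, 0.0))
    T, L = 4.0 * sd1, 4.0 * sd2
    csi = L / T if T > 0 else math.nan
    cvi = math.log10(L * T) if L * T > 0 else math.nan
    mcsi = L * L / T if T > 0 else math.nan
    return {"sd1": sd1, "sd2": sd2, "T": T, "L": L,
            "csi": csi, "cvi": cvi, "modified_csi": mcsi}


def sample_entropy(nn, cfg: SampleEntropyConfig = SampleEntropyConfig(),
                   ddof: int = 0) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev tolerance r * sd.

    B counts template pairs of length m, A pairs of length m+1, both over
    the N-m templates that admit an (m+1)-extension; self-matches excluded.
    NaN when either count is zero or the series has no variance.
    """
    x = np.asarray(nn.rr if hasattr(nn, "rr") else nn, dtype=float)
    m = cfg.m
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short for sample entropy")
    sd = np.std(x, ddof=ddof)
    if sd == 0:
        return math.nan
    r = cfg.r * sd
    # embed: templates of length m+1 (their m-prefixes are the m-templates)
    n_t = n - m  # number of templates admitting an extension
    idx = np.arange(n_t)[:, None] + np.arange(m + 1)[None, :]
    emb = x[idx]  # (n_t, m+1)
    # pairwise Chebyshev distances on prefixes and full templates
    d_m = np.max(np.abs(emb[:, None, :m] - emb[None, :, :m]), axis=-1)
    d_m1 = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
    iu = np.triu_indices(n_t, k=1)
    b = int(np.sum(d_m[iu] <= r))
    a = int(np.sum(d_m1[iu] <= r))
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def compute_record(
    segment: Segment,
    spectral: SpectralConfig = SpectralConfig(),
    sampen_cfg: SampleEntropyConfig = SampleEntropyConfig(),
    ddof: int = 0,
) -> dict:
    """Full 27-metric record for one analysis segment."""
    nn = segment.nn
    rec = time_domain(nn, ddof=ddof)
    rec.update(frequency_domain(interpolate_and_psd(nn, spectral), spectral))
    pc = poincare(nn, ddof=ddof)
    rec.update({k: pc[k] for k in ("csi", "cvi", "modified_csi")})
    rec["sampen"] = sample_entropy(nn, sampen_cfg, ddof=ddof)
    return {k: rec[k] for k in ALL_METRICS}
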