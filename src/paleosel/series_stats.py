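"""Abundance-structure statistics for stratigraphic count series.

Implements the species-level temporal-structure predictors: mean
abundance over positive samples, the averaged local variation
coefficient CV̄, the rescaled-range Hurst exponent, the Lomb-periodogram
spectral exponent ν, adjusted abundance-distribution skewness G(a), and
a windowed Taylor's-law power fit σ²(a) = c·āᵇ.

Statistics that are undefined for a given species (too few samples,
zero variance) return NaN so the species drops out of any model that
needs that predictor — mirroring complete-case culling downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from paleosel.core_data import AbundanceSeries, SpeciesRecord, longest_series


@dataclass(frozen=True)
class PowerSpectrum:
    """A one-sided power spectrum on a fixed frequency grid.

    Frequencies are in cycles per meter (depth is the time axis),
    strictly increasing and positive; powers are the classical
    variance-normalized Lomb periodogram ordinates.
    """

    frequencies: np.ndarray
    powers: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        p = np.asarray(self.powers, float)
        if f.shape != p.shape:
            raise ValueError("frequencies and powers must have the same shape")
        if len(f) and (np.any(np.diff(f) <= 0) or f[0] <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(p < 0):
            raise ValueError("powers must be non-negative")


@dataclass(frozen=True)
class TaylorFit:
    """Power-law fit of windowed variance against windowed mean."""

    prefactor: float
    exponent: float
    r: float
    p: float
    n: int


def positive_counts(record: SpeciesRecord) -> np.ndarray:
    """All positive counts pooled over the species' cores."""
    vals = [v for s in record.series for v in s.values if v > 0]
    return np.asarray(vals, dtype=float)


def mean_abundance(record: SpeciesRecord) -> float:
    """Mean element count per sample, pooled over cores, zeros omitted.

    Zero samples inside a species' range record non-detection, not
    abundance, so the average is taken over positive samples only.
    """
    pos = positive_counts(record)
    if len(pos) == 0:
        raise ValueError(f"{record.species_id!r}: no positive counts")
    return float(pos.mean())


def local_cv2(a: float, b: float) -> float:
    """Two-sample local variation coefficient: sample sd / mean.

    Both counts must be positive (the pair comes from two nearby,
    non-zero samples).  Uses the n−1 standard deviation, so
    CV2(a, b) = |a − b| / (√2 · mean).
    """
    if a <= 0 or b <= 0:
        raise ValueError("local CV2 requires two positive counts")
    mean = (a + b) / 2.0
    sd = abs(a - b) / math.sqrt(2.0)
    return sd / mean


def averaged_cv(record: SpeciesRecord) -> float:
    """Averaged variation coefficient CV̄ over all local pairs.

    Within each core the positive samples form a subsequence (zeros are
    skipped when pairing "nearby non-zero" samples); every consecutive
    pair contributes one CV2.  CV̄ is the grand mean of all pairs over
    all cores, which factors out both absolute abundance (CV is
    scale-free) and series length (each pair spans the same short
    interval).  NaN when no core yields a pair.
    """
    cvs: list[float] = []
    for s in record.series:
        pos = [v for v in s.values if v > 0]
        cvs.extend(local_cv2(a, b) for a, b in zip(pos, pos[1:]))
    if not cvs:
        return math.nan
    return float(np.mean(cvs))


def hurst_exponent(series: AbundanceSeries) -> float:
    """Rescaled-range Hurst exponent of a count series.

    RS = (1/S_T)·[max_k Σ_{j≤k}(a_j − ā) − min_k Σ_{j≤k}(a_j − ā)]
    with S_T the maximum-likelihood (n-denominator) standard deviation,
    then H = ln(RS)/ln(T) with T the series length in samples.  Zeros
    are kept: omitting them would erase the long-term variation the
    statistic measures.  NaN for constant series or T < 3.
    """
    a = np.asarray(series.values, dtype=float)
    t = len(a)
    if t < 3:
        return math.nan
    s_t = a.std(ddof=0)
    if s_t == 0:
        return math.nan
    cums = np.cumsum(a - a.mean())
    rs = (cums.max() - cums.min()) / s_t
    return float(math.log(rs) / math.log(t))


def lomb_periodogram(series: AbundanceSeries, oversample: int = 1) -> PowerSpectrum:
    """Classical variance-normalized Lomb periodogram against depth.

    Suited to stratigraphic series with uneven sampling intervals.  The
    frequency grid runs from 1/span to the pseudo-Nyquist frequency
    n/(2·span) in steps of 1/(oversample·span), where span is the total
    depth extent; powers are the Lomb ordinates divided by the sample
    variance (ddof=1), so a pure sinusoid of amplitude A peaks near
    n·A²/(4σ²).  Requires ≥4 samples and a non-constant series.
    """
    a = np.asarray(series.values, dtype=float)
    n = len(a)
    if n < 4:
        raise ValueError("Lomb periodogram requires at least 4 samples")
    if np.ptp(a) == 0:
        raise ValueError("constant series has no spectrum")
    # depth increases downhole; use elapsed "time" from the oldest sample
    t = series.depths[0] - np.asarray(series.depths, dtype=float)
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("series must span a positive depth interval")
    k = np.arange(1, (n * oversample) // 2 + 1)
    freqs = k / (oversample * span)  # cycles per meter
    ang = 2.0 * math.pi * freqs
    raw = signal.lombscargle(t, a - a.mean(), ang)
    power = raw / a.var(ddof=1)
    return PowerSpectrum(frequencies=freqs, powers=power)


def spectral_exponent(spectrum: PowerSpectrum) -> float:
    """Scaling exponent ν: minus the OLS slope of log power on log frequency.

    A constant 1 is added to frequencies and powers before taking
    natural logs, to avoid exaggerating the effect of logarithms on
    small values; this makes ν depend on the frequency units, which are
    fixed to cycles per meter.  Higher ν means redder (more
    autocorrelated) abundance dynamics.
    """
    f = np.asarray(spectrum.frequencies, float)
    p = np.asarray(spectrum.powers, float)
    if len(f) < 2:
        raise ValueError("need at least 2 spectrum points")
    x = np.log(f + 1.0)
    y = np.log(p + 1.0)
    if np.ptp(x) == 0:
        raise ValueError("degenerate spectrum: all frequencies equal")
    slope, _ = np.polyfit(x, y, 1)
    return float(-slope)


def abundance_skewness(record: SpeciesRecord, adjusted: bool = True) -> float:
    """Skewness G(a) of the pooled positive-count distribution.

    Adjusted Fisher–Pearson estimator G1 = g1·√(n(n−1))/(n−2) by
    default (``adjusted=False`` gives plain g1).  NaN when fewer than 3
    positive counts or zero variance.
    """
    pos = positive_counts(record)
    return _skewness(pos, adjusted=adjusted)


def _skewness(x: np.ndarray, adjusted: bool = True) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return math.nan
    return float(stats.skew(x, bias=not adjusted))


def spectral_exponent_for(record: SpeciesRecord, oversample: int = 1) -> float:
    """ν of the species' longest first-to-last-appearance series, or NaN."""
    series = longest_series(record)
    try:
        return spectral_exponent(lomb_periodogram(series, oversample=oversample))
    except ValueError:
        return math.nan


def taylor_fit(series: AbundanceSeries, window: int = 3) -> TaylorFit:
    """Windowed Taylor's-law fit σ²(a) = c·āᵇ on one series.

    Slides a window of `window` consecutive positive samples (stride 1
    over the positive subsequence, zeros excluded), computes each
    window's sample mean and variance, and fits OLS of ln variance on
    ln mean over windows with positive variance.  Returns prefactor
    c = exp(intercept), exponent b = slope, plus Pearson r and its
    two-sided p on the log-log pairs.
    """
    pos = np.asarray([v for v in series.values if v > 0], dtype=float)
    if len(pos) < window + 1:
        raise ValueError(f"need at least {window + 1} positive samples")
    means, variances = [], []
    for i in range(len(pos) - window + 1):
        w = pos[i : i + window]
        v = w.var(ddof=1)
        if v > 0:
            means.append(w.mean())
            variances.append(v)
    if len(means) < 3:
        raise ValueError("fewer than 3 usable (variance>0) windows")
    x = np.log(np.asarray(means))
    y = np.log(np.asarray(variances))
    if np.ptp(x) == 0:
        raise ValueError("zero spread in window means")
    slope, intercept = np.polyfit(x, y, 1)
    r, p = stats.pearsonr(x, y)
    return TaylorFit(
        prefactor=float(math.exp(intercept)),
        exponent=float(slope),
        r=float(r),
        p=float(p),
        n=len(x),
    )
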