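"""Per-component outcome measures of postural control.

Four variables are computed per trial and principal movement:

* ``SaEn_PP`` — sample entropy of the detrended principal position,
  the irregularity of the sway along that component;
* ``SaEn_PA`` — sample entropy of the principal acceleration, the
  irregularity of the neuromuscular control signal;
* ``N`` — number of acceleration zero crossings, read as the number of
  corrective interventions of the control system ("control tightness");
* ``sigma`` — standard deviation of the time between zero crossings,
  the timing variability of those interventions.

Sample entropy uses a delayed embedding (lag ``tau`` samples, not
series subsampling) with embedding dimension ``m`` and tolerance
``r = r_coeff * SD`` of the series as passed in.  Both PP and PA are
low-pass filtered (zero-phase 6th-order Butterworth, 7 Hz) before any
measure is taken; PP is additionally detrended by subtracting a
501-sample (~4 s at 120 Hz) centered moving average whose edge values
are held at the nearest fully-defined average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .pma import PMTimeSeries

__all__ = [
    "EntropyParams",
    "UndefinedMeasureError",
    "moving_average_detrend",
    "butterworth_lowpass",
    "power_fraction",
    "sample_entropy",
    "zero_crossings",
    "intercrossing_sd",
    "compute_measures_table",
]


class UndefinedMeasureError(ValueError):
    """Raised when a measure is undefined for the given series (e.g. r = 0)."""


@dataclass
class EntropyParams:
    """Sample-entropy parameters: m=2, r=0.2*SD, lag 12 samples (100 ms at 120 Hz)."""

    m: int = 2
    r_coeff: float = 0.2
    tau: int = 12
    rate_hz: float = 120.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1 or self.r_coeff <= 0:
            raise ValueError("require m >= 1, tau >= 1, r_coeff > 0")

    @property
    def lag_ms(self) -> float:
        return 1000.0 * self.tau / self.rate_hz


def moving_average_detrend(x: np.ndarray, window: int = 501) -> np.ndarray:
    """Subtract a centered moving average; edges use the nearest defined value.

    The centered ``window``-sample average exists for interior samples
    only; for the first and last ``(window-1)//2`` samples the
    subtracted trend is held constant at the first/last fully-defined
    average (so slow drifts are removed without inventing edge trends).
    """
    x = np.asarray(x, float)
    if window % 2 == 0:
        raise ValueError("detrend window must be odd (centered average)")
    if x.size <= window:
        raise ValueError(f"series of length {x.size} too short for window {window}")
    if window == 1:
        return np.zeros_like(x)
    h = (window - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    ma_core = (csum[window:] - csum[:-window]) / window  # length n - window + 1
    trend = np.concatenate([
        np.full(h, ma_core[0]), ma_core, np.full(h, ma_core[-1]),
    ])
    return x - trend


def butterworth_lowpass(
    x: np.ndarray, cutoff_hz: float = 7.0, order: int = 6, rate_hz: float = 120.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """6th-order Butterworth low-pass, zero-phase (forward-backward) by default.

    Zero-phase application keeps crossing times and entropy templates
    unshifted at the cost of squaring the magnitude response; a
    single-pass variant is available via ``zero_phase=False``.
    """
    if not 0 < cutoff_hz < rate_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rate_hz / 2} Hz)")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    x = np.asarray(x, float)
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def power_fraction(x: np.ndarray, rate_hz: float, f_limit_hz: float) -> float:
    """Fraction of (non-DC) spectral power below ``f_limit_hz``."""
    x = np.asarray(x, float)
    if x.size < 256:
        raise ValueError("need at least 256 samples for a stable spectrum")
    f, p = sps.periodogram(x, fs=rate_hz)
    nz = f > 0
    total = p[nz].sum()
    if total == 0:
        return 0.0
    return float(p[nz & (f < f_limit_hz)].sum() / total)


try:  # numba accelerates the O(N^2) pair counting ~100x when available
    from numba import njit

    @njit(cache=True)
    def _count_pairs_jit(emb: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
        n = emb.shape[0]
        b = 0
        a = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                ok = True
                for k in range(m):
                    if abs(emb[i, k] - emb[j, k]) > r:
                        ok = False
                        break
                if ok:
                    b += 1
                    if abs(emb[i, m] - emb[j, m]) <= r:
                        a += 1
        return b, a

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _pair_count_within(emb: np.ndarray, m: int, r: float, chunk: int = 256) -> tuple[int, int]:
    """Counts of template pairs (i<j) within Chebyshev tolerance r.

    ``emb`` is the (N, m+1) delayed-embedding matrix; returns (B, A):
    matches over the first m coordinates and over all m+1, both on the
    same index range with self-matches excluded.
    """
    if _HAVE_NUMBA:
        emb = np.ascontiguousarray(emb, dtype=np.float64)
        b, a = _count_pairs_jit(emb, m, r)
        return int(b), int(a)
    n = emb.shape[0]
    tot_m = 0
    tot_m1 = 0
    for i0 in range(0, n, chunk):
        block = emb[i0 : i0 + chunk]
        d = np.abs(block[:, None, :] - emb[None, :, :])
        dm = d[:, :, :m].max(axis=2)
        dm1 = np.maximum(dm, d[:, :, m])
        tot_m += int((dm <= r).sum())
        tot_m1 += int((dm1 <= r).sum())
    # full-matrix counts include self (distance 0) and both orders
    return (tot_m - n) // 2, (tot_m1 - n) // 2


def sample_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Sample entropy with delayed embedding: -ln(A/B).

    Templates ``u_i = [x(i), x(i+tau), ..., x(i+(d-1)tau)]`` are formed
    for ``d = m`` and ``d = m+1`` over the common index range; ``B`` and
    ``A`` count pairs (i<j) whose Chebyshev distance is at most
    ``r = r_coeff * SD(x)``.  Higher values mean a less regular series.
    Returns ``+inf`` (with a warning) when no (m+1)-matches exist;
    raises :class:`UndefinedMeasureError` for a constant series.
    """
    params = params or EntropyParams()
    x = np.asarray(x, float)
    m, tau = params.m, params.tau
    n = x.size
    if n < (m + 1) * tau + 10:
        raise ValueError(f"series of length {n} too short for m={m}, tau={tau}")
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise UndefinedMeasureError("sample entropy undefined: series is constant (r = 0)")
    r = params.r_coeff * sd

    n_templates = n - m * tau  # common range: indices valid for the (m+1)-dim template
    emb = np.column_stack([x[j * tau : j * tau + n_templates] for j in range(m + 1)])
    B, A = _pair_count_within(emb, m, r)
    if B == 0:
        # cannot happen for non-constant series of admissible length with m>=1
        raise UndefinedMeasureError("sample entropy undefined: no m-matches")
    if A == 0:
        warnings.warn("sample entropy: no (m+1)-matches; returning +inf sentinel",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(-np.log(A / B))


def _filled_signs(x: np.ndarray) -> np.ndarray:
    """Sign sequence with zeros replaced by the preceding nonzero sign
    (leading zeros take the following sign); empty if the series is all zero."""
    s = np.sign(np.asarray(x, float)).astype(int)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.zeros(0, int)
    idx = np.arange(s.size)
    last = np.maximum.accumulate(np.where(s != 0, idx, -1))
    filled = np.where(last >= 0, s[np.clip(last, 0, None)], s[nz[0]])
    return filled


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes between consecutive samples.

    Exact zeros inherit the preceding nonzero sign (leading zeros the
    following one), so a run of zeros contributes at most one crossing.
    """
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    filled = _filled_signs(x)
    if filled.size == 0:
        warnings.warn("zero_crossings: all-zero series", RuntimeWarning, stacklevel=2)
        return 0
    return int(np.sum(filled[1:] != filled[:-1]))


def crossing_times(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Times (s) of the sample after each sign change."""
    filled = _filled_signs(np.asarray(x, float))
    if filled.size == 0:
        return np.zeros(0)
    idx = np.flatnonzero(filled[1:] != filled[:-1]) + 1
    return idx / rate_hz


def intercrossing_sd(x: np.ndarray, rate_hz: float) -> float:
    """SD (n-1 denominator) of the time between successive zero crossings.

    Returns NaN (undefined-measure sentinel) with fewer than 3 crossings.
    """
    times = crossing_times(x, rate_hz)
    if times.size < 3:
        warnings.warn("intercrossing_sd: fewer than 3 crossings; undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.std(np.diff(times), ddof=1))


def compute_measures_table(
    pm_series: list[PMTimeSeries],
    retained: np.ndarray,
    params: EntropyParams | None = None,
    cutoff_hz: float = 7.0,
    filter_order: int = 6,
    detrend_window: int = 501,
    filter_pa: bool = True,
) -> pd.DataFrame:
    """Compute all four measures per trial x retained PM (tidy long table).

    Processing order: PP is low-pass filtered then detrended before its
    entropy; PA is derived from the unfiltered PP, then low-pass
    filtered before its entropy, crossing count and crossing-timing SD
    (``filter_pa=False`` computes N/sigma on raw PA instead).  Undefined
    measures propagate as NaN/inf sentinels without aborting the table.
    """
    params = params or EntropyParams(rate_hz=pm_series[0].rate_hz if pm_series else 120.0)
    rows = []
    retained = np.asarray(retained, int)
    for ts in pm_series:
        for j, pm_idx in enumerate(retained):
            pp = ts.pp[:, j]
            pa = ts.pa[:, j]
            pp_f = butterworth_lowpass(pp, cutoff_hz, filter_order, ts.rate_hz)
            pp_d = moving_average_detrend(pp_f, detrend_window)
            pa_f = butterworth_lowpass(pa, cutoff_hz, filter_order, ts.rate_hz) if filter_pa else pa
            row = {
                "subject_id": ts.subject_id,
                "group": ts.group,
                "condition": ts.condition,
                "pm": int(pm_idx) + 1,
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                try:
                    row["saen_pp"] = sample_entropy(pp_d, params)
                except UndefinedMeasureError:
                    row["saen_pp"] = float("nan")
                try:
                    row["saen_pa"] = sample_entropy(pa_f, params)
                except UndefinedMeasureError:
                    row["saen_pa"] = float("nan")
                row["n_crossings"] = zero_crossings(pa_f)
                row["sigma_s"] = intercrossing_sd(pa_f, ts.rate_hz)
            rows.append(row)
    return pd.DataFrame(rows)
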