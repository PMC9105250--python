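"""The 22-feature canonical time-series characteristics catalogue.

Hand-crafted featurization of each (window, channel) pair with the 22
canonical features distilled by Lubba et al. from the hctsa library:
distribution modes, extreme-event timing, linear/nonlinear autocorrelation
summaries, automutual information, successive-difference statistics,
detrended-fluctuation and rescaled-range scaling proportions, symbolic
transition-matrix and motif entropies, spectral summaries, and a spline-based
periodicity measure.

All features are computed on the z-scored window (the catalogue is defined on
z-scored series).  Features that are undefined on a degenerate window
(constant values, too-short series) return NaN; :func:`featurize` imputes
those by the baseline-set median of the same feature and logs a warning.

A hard minimum window length of 15 samples is enforced: several catalogue
features are undefined on shorter windows, so requests below the minimum are
refused rather than silently padded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

from .preprocess import ValidationError, WindowTensor

logger = logging.getLogger(__name__)

#: Number of catalogue features per channel.
N_FEATURES = 22

#: Shortest window (samples) on which the full catalogue is defined.
MIN_WINDOW = 15


class UndefinedFeatureError(ValidationError):
    """Raised when the catalogue is requested on a too-short series."""


# ---------------------------------------------------------------------------
# small shared helpers

def _zscore(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - x.mean()) / sd


def _acf(y: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Autocorrelation (biased, FFT-based), acf[0] = 1."""
    n = len(y)
    if max_lag is None:
        max_lag = n - 1
    yc = y - y.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(yc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[: max_lag + 1]
    if acov[0] == 0:
        return np.full(max_lag + 1, np.nan)
    return acov / acov[0]


def _first_zero_ac(y: np.ndarray, max_lag: int | None = None) -> int:
    """First lag at which the autocorrelation is <= 0 (capped at max_lag)."""
    n = len(y)
    cap = (n - 1) if max_lag is None else min(max_lag, n - 1)
    ac = _acf(y, cap)
    for tau in range(1, cap + 1):
        if not np.isfinite(ac[tau]) or ac[tau] <= 0:
            return tau
    return cap


def _quantile_ml(x: np.ndarray, q: float) -> float:
    """Quantile with (k-0.5)/n plotting positions (hctsa convention)."""
    xs = np.sort(x)
    n = len(xs)
    pos = (np.arange(1, n + 1) - 0.5) / n
    return float(np.interp(q, pos, xs))


def _coarse_grain_quantile(y: np.ndarray, n_groups: int = 3) -> np.ndarray:
    """Symbolize into equiprobable groups 0..n_groups-1."""
    th = [_quantile_ml(y, (k + 1) / n_groups) for k in range(n_groups - 1)]
    return np.digitize(y, th)


def _longest_run(b: np.ndarray, value: int) -> int:
    best = cur = 0
    for v in b:
        cur = cur + 1 if v == value else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# the 22 features (each takes the z-scored window)

def _histogram_mode(y: np.ndarray, n_bins: int) -> float:
    counts, edges = np.histogram(y, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mx = counts.max()
    return float(centers[counts == mx].mean())


def f_histogram_mode_5(y):
    """Mode of the z-scored distribution on a 5-bin histogram."""
    return _histogram_mode(y, 5)


def f_histogram_mode_10(y):
    """Mode of the z-scored distribution on a 10-bin histogram."""
    return _histogram_mode(y, 10)


def f_first_1e_ac_crossing(y):
    """First 1/e crossing of the autocorrelation function (interpolated)."""
    n = len(y)
    thresh = 1.0 / np.e
    ac = _acf(y)
    for i in range(1, n):
        if not np.isfinite(ac[i]):
            return np.nan
        if ac[i] < thresh:
            return float(i - 1 + (ac[i - 1] - thresh) / (ac[i - 1] - ac[i]))
    return float(n)


def f_first_min_ac(y):
    """Lag of the first local minimum of the autocorrelation function."""
    n = len(y)
    ac = _acf(y)
    for i in range(1, n - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            return float(i)
    return float(n)


def f_histogram_ami_even_2_5(y):
    """Automutual information at lag 2, 5 even bins over the value range."""
    tau, n_bins = 2, 5
    if len(y) <= tau + 1:
        return np.nan
    lo, hi = y.min() - 0.1, y.max() + 0.1
    edges = np.linspace(lo, hi, n_bins + 1)
    a, b = y[:-tau], y[tau:]
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    joint /= joint.sum()
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] /
                                           np.outer(pa, pb)[nz])))


def f_trev_1_num(y):
    """Time-reversibility statistic: mean cubed successive difference."""
    d = np.diff(y)
    return float(np.mean(d ** 3))


def f_pnn40(y):
    """Proportion of successive differences exceeding 0.04 (z-scored sd)."""
    d = np.abs(np.diff(y))
    return float(np.mean(d > 0.04))


def f_binary_mean_longstretch1(y):
    """Longest run of consecutive values above the mean."""
    return float(_longest_run((y > y.mean()).astype(int), 1))


def f_transition_matrix_3ac_sumdiagcov(y):
    """Trace of the covariance of the 3-letter symbol transition matrix.

    The series is down-sampled at the first zero-crossing of its
    autocorrelation, symbolized into three equiprobable letters, and the
    3x3 transition matrix's column covariance trace is returned.
    """
    tau = _first_zero_ac(y)
    yd = y[::tau]
    if len(yd) < 4 or np.unique(yd).size < 3:
        return np.nan
    sym = _coarse_grain_quantile(yd, 3)
    T = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        T[a, b] += 1
    T /= T.sum()
    return float(np.trace(np.cov(T, rowvar=False, ddof=1)))


def f_periodicity_wang(y):
    """Spline-detrended autocorrelation periodicity (threshold 0.01).

    Detrend with a least-squares cubic spline (one interior knot), then find
    the first autocorrelation peak that exceeds its preceding trough by at
    least 0.01 and is positive; return its lag, or 0 if none.
    """
    n = len(y)
    th = 0.01
    x = np.arange(n, dtype=float)
    try:
        spl = LSQUnivariateSpline(x, y, t=[(n - 1) / 2.0], k=3)
        ydt = y - spl(x)
    except Exception:
        return np.nan
    sd = ydt.std()
    if sd == 0:
        return 0.0
    ydt = (ydt - ydt.mean()) / sd
    max_tau = n // 3
    ac = _acf(ydt, max_tau)
    troughs, peaks = [], []
    for i in range(1, max_tau):
        if i + 1 > max_tau:
            break
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            troughs.append(i)
        elif ac[i] > ac[i - 1] and ac[i] > ac[i + 1]:
            peaks.append(i)
    for p in peaks:
        prior = [t for t in troughs if t < p]
        if not prior:
            continue
        t = prior[-1]
        if ac[p] - ac[t] >= th and ac[p] > 0:
            return float(p)
    return 0.0


def f_embed2_dist_expfit_meandiff(y):
    """Goodness of exponential fit to successive 2-d embedding distances.

    Embed at lag tau (first AC zero-crossing, capped at n/10), take the
    Euclidean distances between successive embedded points, fit an
    exponential by maximum likelihood, and return the mean absolute
    difference between the empirical density histogram and the fitted pdf.
    """
    n = len(y)
    tau = min(_first_zero_ac(y), max(n // 10, 1))
    m = n - tau
    if m < 3:
        return np.nan
    a, b = y[:m], y[tau:tau + m]
    d = np.hypot(np.diff(a), np.diff(b))
    lam = d.mean()
    if lam == 0:
        return np.nan
    n_bins = int(np.ceil(np.sqrt(len(d))))
    counts, edges = np.histogram(d, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = np.exp(-centers / lam) / lam
    return float(np.mean(np.abs(counts - pdf)))


def f_ami_gaussian_first_min(y):
    """First minimum of the Gaussian automutual information (lags 1..40)."""
    n = len(y)
    max_lag = min(40, n // 2)
    if max_lag < 1:
        return np.nan
    ami = np.empty(max_lag)
    for k, tau in enumerate(range(1, max_lag + 1)):
        r = np.corrcoef(y[:-tau], y[tau:])[0, 1]
        r2 = min(r * r, 1 - 1e-12)
        ami[k] = -0.5 * np.log(1.0 - r2)
    for k in range(1, max_lag - 1):
        if ami[k] < ami[k - 1] and ami[k] < ami[k + 1]:
            return float(k + 1)
    return float(max_lag)


def f_localsimple_mean1_tauresrat(y):
    """AC zero-crossing ratio of last-value-forecast residuals vs the series."""
    res = np.diff(y)
    if res.std() == 0:
        return np.nan
    return float(_first_zero_ac(res) / _first_zero_ac(y))


def _outlier_include_mdrmd(y: np.ndarray) -> float:
    n = len(y)
    if y.max() <= 0:
        return np.nan
    inc = 0.01
    thresholds = np.arange(0, y.max(), inc)
    med_rel, frac = [], []
    for thr in thresholds:
        times = np.nonzero(y >= thr)[0] + 1
        frac.append(len(times) / n)
        med_rel.append(np.median(times) / (n / 2) - 1 if len(times) else np.nan)
    med_rel = np.asarray(med_rel)
    frac = np.asarray(frac)
    keep = frac >= 0.02                     # diverse-enough extreme events
    if not keep.any():
        return np.nan
    last = np.nonzero(keep)[0].max()
    return float(np.median(med_rel[: last + 1]))


def f_outlier_include_p_mdrmd(y):
    """Median location drift of increasingly extreme positive events."""
    return _outlier_include_mdrmd(y)


def f_outlier_include_n_mdrmd(y):
    """Median location drift of increasingly extreme negative events."""
    return _outlier_include_mdrmd(-y)


def _rect_psd(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-segment rectangular-window power spectrum over [0, pi] rad."""
    n = len(y)
    nfft = int(2 ** np.ceil(np.log2(n)))
    f = np.fft.rfft(y - y.mean(), nfft)
    p = (np.abs(f) ** 2) / (2.0 * np.pi * n)
    w = 2.0 * np.pi * np.arange(len(p)) / nfft
    return w, p


def f_welch_area_5_1(y):
    """Total spectral power in the lowest fifth of frequencies."""
    w, p = _rect_psd(y)
    dw = w[1] - w[0]
    return float(np.sum(p[: len(p) // 5]) * dw)


def f_welch_centroid(y):
    """Spectral centroid: frequency splitting the power in half (rad)."""
    w, p = _rect_psd(y)
    dw = w[1] - w[0]
    cs = np.cumsum(p) * dw
    if cs[-1] == 0:
        return np.nan
    idx = np.searchsorted(cs, cs[-1] / 2.0)
    return float(w[min(idx, len(w) - 1)])


def f_binary_diff_longstretch0(y):
    """Longest run of successive decreases."""
    b = (np.diff(y) >= 0).astype(int)
    return float(_longest_run(b, 0))


def f_motif_three_quantile_hh(y):
    """Shannon entropy of successive letter pairs, 3-letter equiprobable."""
    if np.unique(y).size < 3:
        return np.nan
    sym = _coarse_grain_quantile(y, 3)
    joint = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        joint[a, b] += 1
    joint /= joint.sum()
    nz = joint > 0
    return float(-np.sum(joint[nz] * np.log(joint[nz])))


def _fluct_anal_prop_r1(y: np.ndarray, lag: int, how: str) -> float:
    """Two-regime scaling split of log fluctuation vs log timescale.

    Computes the fluctuation function F(tau) of the lag-subsampled cumulative
    sum over ~50 log-spaced timescales (linear detrending per segment;
    ``how`` = 'dfa' uses residual rms, 'rsrange' the residual range), fits
    two straight lines to (log tau, log F) with every admissible split point,
    and returns the proportion of timescales assigned to the first regime at
    the best split.
    """
    x = np.cumsum(y[::lag])
    n = len(x)
    if n < 20:
        return np.nan
    taus = np.unique(np.floor(np.logspace(np.log10(5), np.log10(n / 2), 50))
                     .astype(int))
    taus = taus[(taus >= 5) & (taus <= n // 2)]
    ntt = len(taus)
    # at least 2 points per regime; widen toward 6 when scales allow
    min_points = min(6, max(2, ntt // 3))
    if ntt < 2 * min_points:
        return np.nan
    F = np.empty(ntt)
    for k, tau in enumerate(taus):
        nb = n // tau
        seg = x[: nb * tau].reshape(nb, tau)
        t = np.arange(tau, dtype=float)
        tm = t - t.mean()
        denom = (tm ** 2).sum()
        slope = (seg - seg.mean(axis=1, keepdims=True)) @ tm / denom
        resid = (seg - seg.mean(axis=1, keepdims=True)
                 - slope[:, None] * tm[None, :])
        if how == "rsrange":
            v = resid.max(axis=1) - resid.min(axis=1)
            F[k] = np.sqrt(np.mean(v ** 2))
        elif how == "dfa":
            F[k] = np.sqrt(np.mean(resid ** 2))
        else:  # pragma: no cover
            raise ValueError(how)
    if np.any(F <= 0):
        return np.nan
    lt, lf = np.log(taus.astype(float)), np.log(F)

    def _sse(xs, ys):
        xm, ym = xs.mean(), ys.mean()
        denom = ((xs - xm) ** 2).sum()
        b = ((xs - xm) * (ys - ym)).sum() / denom if denom > 0 else 0.0
        r = ys - (ym + b * (xs - xm))
        return (r ** 2).sum()

    best_sse, best_i = np.inf, min_points
    for i in range(min_points, ntt - min_points + 1):
        s = _sse(lt[:i], lf[:i]) / i + _sse(lt[i:], lf[i:]) / (ntt - i)
        if s < best_sse:
            best_sse, best_i = s, i
    return float(best_i / ntt)


def f_rs_range_fit_prop_r1(y):
    """Proportion of slow timescales in the first rescaled-range regime."""
    return _fluct_anal_prop_r1(y, lag=2, how="rsrange")


def f_dfa_prop_r1(y):
    """Proportion of slow timescales in the first DFA scaling regime."""
    return _fluct_anal_prop_r1(y, lag=2, how="dfa")


def f_localsimple_mean3_stderr(y):
    """Std of residuals from a rolling 3-sample-mean forecast."""
    n = len(y)
    train = 3
    if n <= train + 1:
        return np.nan
    fc = np.convolve(y, np.ones(train) / train, mode="valid")[:-1]
    res = y[train:] - fc
    return float(res.std(ddof=1))


#: Catalogue in canonical order: (name, function).
CATALOGUE: tuple[tuple[str, object], ...] = (
    ("DN_HistogramMode_5", f_histogram_mode_5),
    ("DN_HistogramMode_10", f_histogram_mode_10),
    ("CO_f1ecac", f_first_1e_ac_crossing),
    ("CO_FirstMin_ac", f_first_min_ac),
    ("CO_HistogramAMI_even_2_5", f_histogram_ami_even_2_5),
    ("CO_trev_1_num", f_trev_1_num),
    ("MD_hrv_classic_pnn40", f_pnn40),
    ("SB_BinaryStats_mean_longstretch1", f_binary_mean_longstretch1),
    ("SB_TransitionMatrix_3ac_sumdiagcov", f_transition_matrix_3ac_sumdiagcov),
    ("PD_PeriodicityWang_th0_01", f_periodicity_wang),
    ("CO_Embed2_Dist_tau_d_expfit_meandiff", f_embed2_dist_expfit_meandiff),
    ("IN_AutoMutualInfoStats_40_gaussian_fmmi", f_ami_gaussian_first_min),
    ("FC_LocalSimple_mean1_tauresrat", f_localsimple_mean1_tauresrat),
    ("DN_OutlierInclude_p_001_mdrmd", f_outlier_include_p_mdrmd),
    ("DN_OutlierInclude_n_001_mdrmd", f_outlier_include_n_mdrmd),
    ("SP_Summaries_welch_rect_area_5_1", f_welch_area_5_1),
    ("SB_BinaryStats_diff_longstretch0", f_binary_diff_longstretch0),
    ("SB_MotifThree_quantile_hh", f_motif_three_quantile_hh),
    ("SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1", f_rs_range_fit_prop_r1),
    ("SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1", f_dfa_prop_r1),
    ("SP_Summaries_welch_rect_centroid", f_welch_centroid),
    ("FC_LocalSimple_mean3_stderr", f_localsimple_mean3_stderr),
)

FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _ in CATALOGUE)


def catch22_vector(series: np.ndarray) -> np.ndarray:
    """Compute the 22 catalogue features of a univariate window.

    The window is z-scored first.  Raises :class:`UndefinedFeatureError` for
    series shorter than :data:`MIN_WINDOW` samples; degenerate windows
    (constant values) yield NaNs for the features undefined on them.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("catch22_vector expects a 1-d series")
    if len(x) < MIN_WINDOW:
        raise UndefinedFeatureError(
            f"series of length {len(x)} is shorter than the {MIN_WINDOW}-sample "
            "minimum on which the full catalogue is defined")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    y = _zscore(x)
    if y is None:
        return np.full(N_FEATURES, np.nan)
    out = np.empty(N_FEATURES)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, (_, fn) in enumerate(CATALOGUE):
            try:
                out[k] = fn(y)
            except (FloatingPointError, ValueError, ZeroDivisionError):
                out[k] = np.nan
    return out


@dataclass
class FeatureMatrix:
    """Per-window handcrafted features (one row per window, 22*nC columns)."""

    values: np.ndarray
    columns: tuple[str, ...]
    labels: pd.DataFrame
    medians: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValidationError("column names must match value columns")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))


def featurize(tensor: WindowTensor,
              impute_medians: np.ndarray | None = None) -> FeatureMatrix:
    """Apply the catalogue per channel per window of a window tensor.

    Output shape is (n_windows, 22 * nC) with columns named
    ``<channel>__<feature>``.  NaNs from degenerate windows are imputed by
    the per-column median — computed from this tensor when
    ``impute_medians`` is None (the baseline call), otherwise taken from the
    supplied baseline medians (the stimulation call), so the imputation is
    causal.
    """
    if tensor.cW < MIN_WINDOW:
        raise UndefinedFeatureError(
            f"window duration {tensor.cW} s is below the {MIN_WINDOW}-s minimum: "
            "part of the catalogue is undefined on shorter windows")
    n = len(tensor.values)
    nC = tensor.n_channels
    values = np.empty((n, N_FEATURES * nC))
    for i in range(n):
        win = tensor.unflatten(i)
        for c in range(nC):
            values[i, c * N_FEATURES:(c + 1) * N_FEATURES] = \
                catch22_vector(win[c])
    columns = tuple(f"{ch}__{feat}" for ch in tensor.channels
                    for feat in FEATURE_NAMES)
    if impute_medians is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            medians = np.nanmedian(values, axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
    else:
        medians = np.asarray(impute_medians, dtype=float)
        if medians.shape != (values.shape[1],):
            raise ValidationError("impute_medians has the wrong shape")
    nan_mask = ~np.isfinite(values)
    if nan_mask.any():
        bad_cols = {columns[j] for j in np.unique(np.nonzero(nan_mask)[1])}
        logger.warning("imputing %d undefined feature values by median "
                       "(columns: %s)", int(nan_mask.sum()),
                       ", ".join(sorted(bad_cols)))
        values[nan_mask] = np.broadcast_to(medians, values.shape)[nan_mask]
    return FeatureMatrix(values=values, columns=columns,
                         labels=tensor.labels.copy(), medians=medians)
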