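"""Agreement and coherence statistics for BP estimates.

Covers the full evaluation battery: Pearson r / ME / MAE / SD with
Bland-Altman 95% limits of agreement (ME +- 1.96 SD), baseline-offset-removed
correlation, mean BP, wavelet-coherence magnitude-squared coherence (MSC)
between estimated and reference MBP with a shuffle-bootstrap z-score null,
directional concordance rates, and error histograms with empirical coverage.

The wavelet coherence follows the standard construction: continuous wavelet
transforms with an analytic Morlet (omega0 = 6), cross-spectrum smoothed in
time (scale-proportional Gaussian) and across scales (boxcar), and

    MSC = |S(Wxy / s)|^2 / ( S(|Wx|^2 / s) * S(|Wy|^2 / s) )

which is bounded in [0, 1] and exactly 1 for self-coherence. The cone of
influence (edge-effect region) is masked before summarising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementStats",
    "CoherenceResult",
    "BootstrapResult",
    "compute_mbp",
    "agreement",
    "baseline_offset_correlation",
    "wavelet_coherence",
    "bootstrap_msc",
    "msc_improvement",
    "concordance_rate",
    "error_histogram",
]

MORLET_OMEGA0 = 6.0
# pywt's complex Morlet 'cmorB-C' is exp(2*pi*i*C*t) * exp(-t^2/B); B=2,
# C=omega0/(2*pi) reproduces the classic Morlet with omega0 = 6.
_CMOR = f"cmor2.0-{MORLET_OMEGA0 / (2 * math.pi):.6f}"
# Fourier period of a Morlet at scale s: lambda = 4*pi*s / (w0 + sqrt(2+w0^2))
_FOURIER_FACTOR = 4 * math.pi / (MORLET_OMEGA0 + math.sqrt(2 + MORLET_OMEGA0**2))
_DJ = 1.0 / 12.0  # scale resolution, octaves
BOOTSTRAP_ITERATIONS = 100
Z_CRITICAL = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Pearson r, error moments and Bland-Altman limits of agreement."""

    r: float
    me: float  # mmHg, mean(est - ref)
    mae: float  # mmHg
    sd: float  # mmHg, sample SD (n-1) of est - ref
    loa_low: float  # me - 1.96*sd
    loa_high: float  # me + 1.96*sd
    n: int

    def rounded(self) -> dict:
        """Values at reporting precision: 1 decimal (mmHg), 2 decimals (r)."""
        return {
            "r": round(self.r, 2) if np.isfinite(self.r) else float("nan"),
            "me": round(self.me, 1),
            "mae": round(self.mae, 1),
            "sd": round(self.sd, 1),
            "loa_low": round(self.loa_low, 1),
            "loa_high": round(self.loa_high, 1),
            "n": self.n,
        }


@dataclass(frozen=True)
class CoherenceResult:
    """Time x scale magnitude-squared coherence map with summaries."""

    msc_map: np.ndarray  # (n_scales, n_times), NaN inside the cone of influence
    phase_map: np.ndarray  # radians
    periods: np.ndarray  # seconds per scale row
    times: np.ndarray  # seconds per column
    avg_max_msc: float  # time-mean of the per-column maximum MSC
    significant_mask: np.ndarray | None = None


@dataclass(frozen=True)
class BootstrapResult:
    """Shuffle-null calibration of the average maximum MSC."""

    observed: float
    null_values: np.ndarray
    z: float
    significant: bool


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------


def compute_mbp(sbp, dbp):
    """Mean blood pressure, MBP = DBP + (SBP - DBP)/3."""
    sbp = np.asarray(sbp, float)
    dbp = np.asarray(dbp, float)
    if np.any(sbp < dbp):
        raise ValueError("sbp must be >= dbp")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def agreement(est, ref) -> AgreementStats:
    """Estimate-vs-reference agreement: r, ME, MAE, SD and 95% LoA."""
    est = np.asarray(est, float)
    ref = np.asarray(ref, float)
    if len(est) != len(ref):
        raise ValueError("est and ref must be aligned")
    if len(est) < 3:
        raise ValueError("need at least 3 paired values")
    err = est - ref
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    sd = float(np.std(err, ddof=1))
    if np.std(est) == 0 or np.std(ref) == 0:
        logger.warning("zero-variance series: Pearson r undefined")
        r = float("nan")
    else:
        r = float(pearsonr(est, ref)[0])
    return AgreementStats(
        r=r,
        me=me,
        mae=mae,
        sd=sd,
        loa_low=me - Z_CRITICAL * sd,
        loa_high=me + Z_CRITICAL * sd,
        n=len(est),
    )


def baseline_offset_correlation(est, ref, baseline_est, baseline_ref) -> float:
    """Pearson r after removing per-subject baseline offsets.

    ``baseline_est`` / ``baseline_ref`` are aligned per-sample baseline values
    (each subject's baseline broadcast over their windows); samples with a
    missing (NaN) baseline are excluded with a warning. Returns NaN when the
    offset-removed deviations are degenerate.
    """
    est, ref = np.asarray(est, float), np.asarray(ref, float)
    b_est, b_ref = np.asarray(baseline_est, float), np.asarray(baseline_ref, float)
    ok = np.isfinite(b_est) & np.isfinite(b_ref) & np.isfinite(est) & np.isfinite(ref)
    if not ok.all():
        logger.warning("%d samples without baseline excluded", int((~ok).sum()))
    de = est[ok] - b_est[ok]
    dr = ref[ok] - b_ref[ok]
    if len(de) < 3 or np.std(de) == 0 or np.std(dr) == 0:
        logger.warning("degenerate offset-removed series: r undefined")
        return float("nan")
    return float(pearsonr(de, dr)[0])


def msc_improvement(msc_a: float, msc_b: float) -> int:
    """Relative MSC improvement of model a over model b, percent (rounded)."""
    if msc_b <= 0:
        raise ValueError("reference MSC must be positive")
    return int(round(100.0 * (msc_a - msc_b) / msc_b))


def concordance_rate(feature, ref_bp) -> float:
    """Fraction of consecutive steps in which the feature moves with BP.

    Ties (a zero step in either series) are excluded from the denominator;
    all-tie input yields NaN with a warning.
    """
    f = np.diff(np.asarray(feature, float))
    r = np.diff(np.asarray(ref_bp, float))
    if len(f) != len(r):
        raise ValueError("series must be aligned")
    if len(f) < 2:
        raise ValueError("need at least 3 samples")
    nz = (f != 0) & (r != 0)
    if not nz.any():
        logger.warning("all steps tied: concordance undefined")
        return float("nan")
    return float(np.mean(np.sign(f[nz]) == np.sign(r[nz])))


def error_histogram(errors, bins: int = 20) -> dict:
    """Histogram of estimation errors plus coverage within ME +- 1.96 SD."""
    err = np.asarray(errors, float)
    if len(err) < 20:
        raise ValueError("need at least 20 errors")
    counts, edges = np.histogram(err, bins=bins)
    me = float(np.mean(err))
    sd = float(np.std(err, ddof=1))
    if sd == 0:
        coverage = 1.0  # degenerate: every error equals the mean
    else:
        lo, hi = me - Z_CRITICAL * sd, me + Z_CRITICAL * sd
        coverage = float(np.mean((err >= lo) & (err <= hi)))
    return {"counts": counts, "edges": edges, "me": me, "sd": sd, "coverage": coverage}


# ---------------------------------------------------------------------------
# Wavelet coherence
# ---------------------------------------------------------------------------


def _cwt(x: np.ndarray, scales_samples: np.ndarray, dt: float) -> np.ndarray:
    coef, _ = pywt.cwt(x, scales_samples, _CMOR, sampling_period=dt, method="fft")
    return coef


def _smooth(field: np.ndarray, scales_samples: np.ndarray) -> np.ndarray:
    """Time smoothing (Gaussian, width ~ scale) then scale smoothing (boxcar)."""
    out = np.empty_like(field)
    for k, s in enumerate(scales_samples):
        sigma = max(s / 2.0, 0.5)  # samples; half-scale Gaussian in time
        out[k] = gaussian_filter1d(field[k].real, sigma, mode="nearest")
        if np.iscomplexobj(field):
            out[k] = out[k] + 1j * gaussian_filter1d(field[k].imag, sigma, mode="nearest")
    width = max(1, int(round(0.6 / _DJ)))  # 0.6 octaves across scales
    if np.iscomplexobj(field):
        out = uniform_filter1d(out.real, width, axis=0, mode="nearest") + 1j * uniform_filter1d(
            out.imag, width, axis=0, mode="nearest"
        )
    else:
        out = uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


def wavelet_coherence(x, y, dt: float, n_surrogates: int = 0, seed: int = 0) -> CoherenceResult:
    """Magnitude-squared wavelet coherence between two uniform series.

    ``dt`` is the sampling step in seconds (e.g. 5 s for windowed MBP).
    Periods span 4*dt up to a third of the record, 12 voices per octave.
    ``n_surrogates`` > 0 additionally estimates a pointwise 95% significance
    mask against AR(1) surrogates (off by default).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if n < 64:
        raise ValueError("need at least 64 samples for wavelet coherence")
    x = (x - x.mean()) / (x.std() or 1.0)
    y = (y - y.mean()) / (y.std() or 1.0)

    min_period = 4.0 * dt
    max_period = n * dt / 3.0
    if max_period <= min_period:
        raise ValueError("series too short for the smallest resolvable scale")
    n_scales = int(np.floor(np.log2(max_period / min_period) / _DJ)) + 1
    periods = min_period * 2.0 ** (_DJ * np.arange(n_scales))
    # pywt scale (in samples) for center frequency C: period = s*dt/C
    c = MORLET_OMEGA0 / (2 * math.pi)
    scales_samples = periods * c / dt

    wx = _cwt(x, scales_samples, dt)
    wy = _cwt(y, scales_samples, dt)
    inv_s = (1.0 / scales_samples)[:, None]
    s_xx = _smooth(np.abs(wx) ** 2 * inv_s, scales_samples)
    s_yy = _smooth(np.abs(wy) ** 2 * inv_s, scales_samples)
    s_xy = _smooth(wx * np.conj(wy) * inv_s, scales_samples)
    denom = s_xx * s_yy
    denom[denom <= 0] = np.finfo(float).tiny
    msc = np.abs(s_xy) ** 2 / denom
    msc = np.clip(msc, 0.0, 1.0)
    phase = np.angle(s_xy)

    # cone of influence: e-folding time sqrt(2) * s, scale s = period / fourier_factor
    times = np.arange(n) * dt
    coi_width = math.sqrt(2.0) * periods / _FOURIER_FACTOR  # seconds
    msc_masked = msc.copy()
    for k in range(n_scales):
        edge = (times < coi_width[k]) | (times > times[-1] - coi_width[k])
        msc_masked[k, edge] = np.nan

    col_max = np.nanmax(
        np.where(np.isfinite(msc_masked), msc_masked, -np.inf), axis=0
    )
    valid_cols = np.isfinite(col_max) & (col_max > -np.inf)
    avg_max = float(np.mean(col_max[valid_cols])) if valid_cols.any() else float("nan")

    sig_mask = None
    if n_surrogates > 0:
        sig_mask = _significance_mask(x, y, msc, scales_samples, dt, n_surrogates, seed)

    return CoherenceResult(
        msc_map=msc_masked,
        phase_map=phase,
        periods=periods,
        times=times,
        avg_max_msc=avg_max,
        significant_mask=sig_mask,
    )


def _ar1_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    if np.std(x) == 0:
        return x.copy()
    r1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    r1 = np.clip(r1, -0.99, 0.99)
    eps = rng.standard_normal(n) * np.std(x) * math.sqrt(1 - r1**2)
    out = np.empty(n)
    out[0] = x[0]
    for i in range(1, n):
        out[i] = r1 * out[i - 1] + eps[i]
    return out


def _significance_mask(x, y, msc, scales_samples, dt, n_surrogates, seed):
    rng = np.random.default_rng(seed)
    inv_s = (1.0 / scales_samples)[:, None]
    maxima = np.zeros_like(msc)
    samples = []
    for _ in range(n_surrogates):
        xs = _ar1_surrogate(x, rng)
        ys = _ar1_surrogate(y, rng)
        wx = _cwt(xs, scales_samples, dt)
        wy = _cwt(ys, scales_samples, dt)
        s_xx = _smooth(np.abs(wx) ** 2 * inv_s, scales_samples)
        s_yy = _smooth(np.abs(wy) ** 2 * inv_s, scales_samples)
        s_xy = _smooth(wx * np.conj(wy) * inv_s, scales_samples)
        denom = s_xx * s_yy
        denom[denom <= 0] = np.finfo(float).tiny
        samples.append(np.abs(s_xy) ** 2 / denom)
    thresh = np.quantile(np.stack(samples), 0.95, axis=0)
    return msc > thresh


def bootstrap_msc(x, y, iterations: int = BOOTSTRAP_ITERATIONS, seed: int = 0, dt: float = 5.0) -> BootstrapResult:
    """Shuffle-null test of the average maximum MSC.

    The estimate series ``x`` is randomly permuted ``iterations`` times
    (destroying its temporal structure) and the average maximum MSC against
    ``y`` recomputed each time; z = (observed - mean_null) / sd_null, with
    significance declared at z > 1.96.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    observed = wavelet_coherence(x, y, dt).avg_max_msc
    null_values = np.empty(iterations)
    for i in range(iterations):
        null_values[i] = wavelet_coherence(rng.permutation(x), y, dt).avg_max_msc
    sd = float(np.std(null_values, ddof=1))
    if sd == 0:
        raise ValueError("degenerate null distribution (sd = 0): z undefined")
    z = float((observed - float(np.mean(null_values))) / sd)
    return BootstrapResult(
        observed=observed, null_values=null_values, z=z, significant=z > Z_CRITICAL
    )
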