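"""Windowed hemodynamic feature extraction from processed pad signals.

For each analysis window the seven regression inputs are derived:

* mean dC  — window average of the chest <0.5 Hz band relative to the
  recording's resting baseline (intrathoracic-volume surrogate, pF);
* PTT      — chest-BCG-to-leg-pulse transit delay by windowed normalised
  cross-correlation, cross-checked against per-beat J-to-peak pairing (s);
* PWV      — pad spacing / PTT (m/s);
* HR       — 60 / mean J-J interval (bpm);
* LF HRV   — 0.004-0.15 Hz power of the beat-interval series via
  Lomb-Scargle (ms^2);
* I-J      — median interval from the I trough to the J peak (s);

plus subject age and baseline cuff BP supplied as metadata downstream.

Two windowing modes mirror the two reference devices: 40 s disjoint windows
around intermittent cuff cycles, and 10 s windows sliding in 5 s steps for
continuous beat-to-beat references.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .sigproc import ProcessedSignals

logger = logging.getLogger(__name__)

__all__ = [
    "BeatAnnotations",
    "FeatureWindow",
    "iter_windows",
    "detect_beats",
    "compute_ptt",
    "compute_pwv",
    "compute_hr_hrv",
    "compute_mean_dc",
    "extract_features",
    "features_to_frame",
]

WINDOW_INTERMITTENT = 40.0  # s
WINDOW_CONTINUOUS = 10.0  # s
STEP_CONTINUOUS = 5.0  # s
PTT_LAG_BOUNDS = (0.05, 0.40)  # s, physiological chest-to-popliteal range
LF_BAND = (0.004, 0.15)  # Hz
HRV_TOTAL_BAND = (0.004, 0.4)  # Hz, denominator band for the variance split
ENVELOPE_SMOOTH = 0.1  # s moving average on the analytic-signal magnitude
PROMINENCE_FACTOR = 0.3  # x median envelope amplitude
DISTANCE_FACTOR = 0.4  # x running median beat interval
IJ_SEARCH = 0.15  # s window before each J peak for the I trough
XCORR_BEAT_TOL = 0.05  # s max disagreement between the two PTT readings
MAX_INVALID_FRACTION = 0.2  # windows with more invalid samples are dropped
HR_RANGE = (30.0, 180.0)  # bpm


@dataclass(frozen=True)
class BeatAnnotations:
    """Detected beat landmarks, all in seconds from recording start."""

    j_peaks: np.ndarray
    i_troughs: np.ndarray
    leg_peaks: np.ndarray


@dataclass
class FeatureWindow:
    """Feature vector for one analysis window; NaN marks missing values."""

    t_start: float
    t_end: float
    mean_dc: float = np.nan  # pF
    ptt: float = np.nan  # s
    pwv: float = np.nan  # m/s
    hr: float = np.nan  # bpm
    lf_hrv: float = np.nan  # ms^2
    ij_interval: float = np.nan  # s
    valid: bool = False
    ref_sbp: float = np.nan  # mmHg, window-averaged reference
    ref_dbp: float = np.nan  # mmHg


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def iter_windows(
    duration: float, mode: str = "continuous", anchors=None
) -> list[tuple[float, float]]:
    """Half-open analysis windows [t, t+W) covering a recording.

    ``continuous``: 10 s windows every 5 s — (0, 10), (5, 15), (10, 20), ...
    for every start k*5 with k*5 + 10 <= duration.
    ``intermittent``: disjoint 40 s windows, anchored at the supplied cuff
    cycle start times or tiled from 0 when no anchors are given.
    """
    if mode == "continuous":
        width, step = WINDOW_CONTINUOUS, STEP_CONTINUOUS
        if duration < width:
            logger.warning("duration %.1f s shorter than one %g s window", duration, width)
            return []
        n = int(np.floor((duration - width) / step)) + 1
        return [(k * step, k * step + width) for k in range(n)]
    if mode == "intermittent":
        width = WINDOW_INTERMITTENT
        if duration < width:
            logger.warning("duration %.1f s shorter than one %g s window", duration, width)
            return []
        if anchors is None:
            anchors = np.arange(0.0, duration - width + 1e-9, width)
        return [(float(a), float(a) + width) for a in anchors if a + width <= duration + 1e-9]
    raise ValueError(f"unknown windowing mode {mode!r}")


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------


def _envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """Analytic-signal magnitude smoothed by a 0.1 s moving average."""
    clean = np.nan_to_num(x, nan=0.0)
    env = np.abs(sps.hilbert(clean))
    w = max(1, int(round(ENVELOPE_SMOOTH * fs)))
    kernel = np.ones(w) / w
    return sps.convolve(env, kernel, mode="same")


def _find_peaks_pass(x, weighted, env, fs, interval_s):
    interval_s = float(np.clip(interval_s, 60.0 / HR_RANGE[1], 60.0 / HR_RANGE[0]))
    distance = max(1, int(round(DISTANCE_FACTOR * interval_s * fs)))
    # typical beat amplitude from the upper envelope tail; the height floor is
    # applied in linear signal units so a half-amplitude beat still passes
    amp = float(np.percentile(env, 95))
    peaks, _ = sps.find_peaks(weighted, distance=distance)
    return peaks[x[peaks] >= PROMINENCE_FACTOR * amp]


def detect_beats(
    bcg: np.ndarray,
    leg: np.ndarray | None,
    sample_rate: float,
    hr_prior: float = 60.0,
) -> BeatAnnotations:
    """Locate chest J peaks, their preceding I troughs and leg pulse peaks.

    The band-passed signal is weighted by its smoothed Hilbert envelope to
    sharpen amplitude maxima; peaks are then selected with a minimum distance
    of 0.4x the running median beat interval (seeded at 60/hr_prior) and a
    prominence floor of 0.3x the median envelope amplitude. Two passes refine
    the distance constraint from the detected intervals. The I trough is the
    most prominent minimum within 0.15 s before each J peak.
    """
    fs = sample_rate
    if len(bcg) < 5 * fs:
        raise ValueError("need at least 5 s of signal for beat detection")

    def detect_train(x: np.ndarray) -> np.ndarray:
        xc = np.nan_to_num(x, nan=0.0)
        env = _envelope(x, fs)
        weighted = xc * env
        peaks = _find_peaks_pass(xc, weighted, env, fs, 60.0 / hr_prior)
        if len(peaks) >= 3:
            med_int = float(np.median(np.diff(peaks))) / fs
            peaks = _find_peaks_pass(xc, weighted, env, fs, med_int)
        return peaks / fs

    j_peaks = detect_train(bcg)
    leg_peaks = detect_train(leg) if leg is not None and len(leg) else np.array([])

    i_troughs = []
    neg = -np.nan_to_num(bcg, nan=0.0)
    for tj in j_peaks:
        i1 = int(round(tj * fs))
        i0 = max(0, i1 - int(round(IJ_SEARCH * fs)))
        if i1 - i0 < 3:
            continue
        seg = neg[i0:i1]
        cand, props = sps.find_peaks(seg, prominence=0.0)
        if len(cand):
            best = cand[np.argmax(props["prominences"])]
        else:
            best = int(np.argmin(bcg[i0:i1]))
        i_troughs.append((i0 + best) / fs)
    return BeatAnnotations(
        j_peaks=np.asarray(j_peaks),
        i_troughs=np.asarray(i_troughs),
        leg_peaks=np.asarray(leg_peaks),
    )


# ---------------------------------------------------------------------------
# PTT / PWV
# ---------------------------------------------------------------------------


def _beat_paired_ptt(annotations: BeatAnnotations) -> float:
    """Median (leg peak - nearest preceding J peak) delay, NaN if none pair."""
    j = annotations.j_peaks
    deltas = []
    for tl in annotations.leg_peaks:
        prior = j[j < tl]
        if len(prior):
            d = tl - prior[-1]
            if PTT_LAG_BOUNDS[0] <= d <= PTT_LAG_BOUNDS[1]:
                deltas.append(d)
    return float(np.median(deltas)) if deltas else np.nan


def compute_ptt(
    chest_bcg: np.ndarray,
    leg: np.ndarray,
    annotations: BeatAnnotations,
    sample_rate: float,
    lag_bounds: tuple[float, float] = PTT_LAG_BOUNDS,
) -> float:
    """Pulse transit time for one window, seconds; NaN when ambiguous.

    Normalised cross-correlation between the chest BCG and the leg signal,
    maximised over physiological lags and refined by parabolic interpolation;
    the result must agree within 0.05 s with the median per-beat J-to-leg-peak
    delay, otherwise the window is rejected (NaN).
    """
    if len(annotations.j_peaks) < 3:
        return np.nan
    fs = sample_rate
    x = np.nan_to_num(np.asarray(chest_bcg, float), nan=0.0)
    y = np.nan_to_num(np.asarray(leg, float), nan=0.0)
    x = x - x.mean()
    y = y - y.mean()
    if x.std() == 0 or y.std() == 0:
        return np.nan
    corr = sps.correlate(y, x, mode="full")
    lags = sps.correlation_lags(len(y), len(x), mode="full")
    sel = (lags >= int(np.floor(lag_bounds[0] * fs))) & (
        lags <= int(np.ceil(lag_bounds[1] * fs))
    )
    if not sel.any():
        return np.nan
    corr_sel = corr[sel]
    lags_sel = lags[sel]
    k = int(np.argmax(corr_sel))
    if k == 0 or k == len(corr_sel) - 1:
        return np.nan  # peak on a bound: ambiguous lag
    # parabolic refinement around the discrete argmax
    c0, c1, c2 = corr_sel[k - 1], corr_sel[k], corr_sel[k + 1]
    denom = c0 - 2 * c1 + c2
    frac = 0.5 * (c0 - c2) / denom if denom != 0 else 0.0
    ptt = (lags_sel[k] + frac) / fs

    beat_ptt = _beat_paired_ptt(annotations)
    if np.isnan(beat_ptt) or abs(ptt - beat_ptt) > XCORR_BEAT_TOL:
        return np.nan
    return float(ptt)


def compute_pwv(ptt: float, pad_spacing: float) -> float:
    """Pulse wave velocity = pad spacing / PTT, m/s."""
    if not ptt > 0:
        raise ValueError("ptt must be positive")
    return pad_spacing / ptt


# ---------------------------------------------------------------------------
# HR and LF HRV
# ---------------------------------------------------------------------------


def compute_hr_hrv(j_peaks: np.ndarray) -> tuple[float, float]:
    """Heart rate (bpm) and LF-band heart-rate variability power (ms^2).

    HR is 60 over the mean successive J-J interval. LF HRV distributes the
    beat-interval variance (ms^2) over a dense Lomb-Scargle spectrum of the
    unevenly sampled interval series and integrates the 0.004-0.15 Hz band,
    so a pure sinusoidal interval modulation of amplitude A ms yields ~A^2/2.
    Requires >= 3 beats; LF HRV additionally needs >= 30 s of beats (NaN
    otherwise, to be carried from an enclosing longer window).
    """
    j = np.asarray(j_peaks, float)
    if len(j) < 3:
        return np.nan, np.nan
    intervals = np.diff(j)
    hr = 60.0 / float(np.mean(intervals))
    if j[-1] - j[0] < 30.0:
        return hr, np.nan
    t_mid = 0.5 * (j[1:] + j[:-1])
    y = intervals * 1000.0  # ms
    var = float(np.var(y))
    if var == 0:
        return hr, 0.0
    yc = y - y.mean()
    freqs = np.linspace(HRV_TOTAL_BAND[0], HRV_TOTAL_BAND[1], 400)
    pgram = sps.lombscargle(t_mid, yc, 2 * np.pi * freqs)
    total = pgram.sum()
    if total == 0:
        return hr, 0.0
    in_lf = (freqs >= LF_BAND[0]) & (freqs <= LF_BAND[1])
    lf_power = var * float(pgram[in_lf].sum() / total)
    return hr, lf_power


# ---------------------------------------------------------------------------
# mean dC
# ---------------------------------------------------------------------------


def compute_mean_dc(
    lowfreq_chest: np.ndarray,
    window: tuple[float, float],
    sample_rate: float,
    baseline: float | None = None,
) -> float:
    """Window average of the chest <0.5 Hz band, as a delta from rest (pF).

    The resting baseline is the median of the first 10 s of the recording
    unless supplied explicitly.
    """
    fs = sample_rate
    if baseline is None:
        head = lowfreq_chest[: int(10 * fs)]
        head = head[np.isfinite(head)]
        if len(head) == 0:
            return np.nan
        baseline = float(np.median(head))
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    seg = lowfreq_chest[i0:i1]
    seg = seg[np.isfinite(seg)]
    if len(seg) == 0:
        return np.nan
    return float(np.mean(seg)) - baseline


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def _window_slice(arr: np.ndarray, t0: float, t1: float, fs: float) -> np.ndarray:
    return arr[int(round(t0 * fs)) : int(round(t1 * fs))]


def extract_features(
    proc_chest: ProcessedSignals,
    proc_leg: ProcessedSignals | None,
    meta: dict | None = None,
    mode: str = "continuous",
    anchors=None,
    ref_bp: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    hr_prior: float = 60.0,
) -> list[FeatureWindow]:
    """Per-window feature extraction over a whole recording.

    ``ref_bp`` is an optional (times, sbp, dbp) triple of reference BP
    samples; values falling in each window are averaged into ``ref_sbp`` /
    ``ref_dbp``. Windows overlapping more than 20% invalid samples, or
    failing any sub-step, are emitted with ``valid=False``. A missing or
    empty leg signal degrades gracefully: chest-only features are still
    populated, but PTT/PWV stay NaN and every window is invalid.
    """
    fs = proc_chest.sample_rate
    duration = len(proc_chest.bcg) / fs
    windows = iter_windows(duration, mode=mode, anchors=anchors)
    pad_spacing = proc_chest.pad_spacing
    baseline_head = proc_chest.lowfreq[: int(10 * fs)]
    baseline_head = baseline_head[np.isfinite(baseline_head)]
    baseline = float(np.median(baseline_head)) if len(baseline_head) else np.nan

    leg_ok = proc_leg is not None and len(proc_leg.bcg) > 0

    # LF HRV needs >=30 s of beats; for short continuous windows it is
    # carried from the full-recording beat series.
    global_lf = np.nan
    if duration >= 30.0:
        try:
            ann_full = detect_beats(
                proc_chest.bcg, None, fs, hr_prior=hr_prior
            )
            _, global_lf = compute_hr_hrv(ann_full.j_peaks)
        except ValueError:
            pass

    out: list[FeatureWindow] = []
    for t0, t1 in windows:
        fw = FeatureWindow(t_start=t0, t_end=t1)
        if ref_bp is not None:
            t_ref, sbp_ref, dbp_ref = ref_bp
            inw = (np.asarray(t_ref) >= t0) & (np.asarray(t_ref) < t1)
            if inw.any():
                fw.ref_sbp = float(np.mean(np.asarray(sbp_ref)[inw]))
                fw.ref_dbp = float(np.mean(np.asarray(dbp_ref)[inw]))

        mask_c = _window_slice(proc_chest.valid_mask, t0, t1, fs)
        invalid_frac = 1.0 - float(np.mean(mask_c)) if len(mask_c) else 1.0
        if leg_ok:
            mask_l = _window_slice(proc_leg.valid_mask, t0, t1, fs)
            invalid_frac = max(invalid_frac, 1.0 - float(np.mean(mask_l)) if len(mask_l) else 1.0)

        bcg_w = _window_slice(proc_chest.bcg, t0, t1, fs)
        leg_w = _window_slice(proc_leg.bcg, t0, t1, fs) if leg_ok else None
        fw.mean_dc = compute_mean_dc(proc_chest.lowfreq, (t0, t1), fs, baseline=baseline)

        try:
            ann = detect_beats(bcg_w, leg_w, fs, hr_prior=hr_prior)
        except ValueError:
            out.append(fw)
            continue
        hr, lf = compute_hr_hrv(ann.j_peaks)
        fw.hr = hr
        fw.lf_hrv = lf if np.isfinite(lf) else global_lf
        if len(ann.i_troughs) and len(ann.j_peaks) >= 3:
            ij = []
            for ti in ann.i_troughs:
                after = ann.j_peaks[ann.j_peaks > ti]
                if len(after):
                    ij.append(after[0] - ti)
            if ij:
                fw.ij_interval = float(np.median(ij))

        if leg_w is not None:
            ptt = compute_ptt(bcg_w, leg_w, ann, fs)
            if np.isfinite(ptt):
                fw.ptt = ptt
                fw.pwv = compute_pwv(ptt, pad_spacing)

        fw.valid = (
            invalid_frac <= MAX_INVALID_FRACTION
            and np.isfinite(fw.ptt)
            and np.isfinite(fw.hr)
            and HR_RANGE[0] <= fw.hr <= HR_RANGE[1]
            and PTT_LAG_BOUNDS[0] <= fw.ptt <= PTT_LAG_BOUNDS[1]
            and np.isfinite(fw.mean_dc)
        )
        out.append(fw)
    return out


def features_to_frame(features: list[FeatureWindow]):
    """Feature windows as a pandas DataFrame (one row per window)."""
    import pandas as pd

    cols = [
        "t_start",
        "t_end",
        "mean_dc",
        "ptt",
        "pwv",
        "hr",
        "lf_hrv",
        "ij_interval",
        "valid",
        "ref_sbp",
        "ref_dbp",
    ]
    return pd.DataFrame([{c: getattr(f, c) for c in cols} for f in features])
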