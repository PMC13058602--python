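"""Preprocessing of raw SEC pad signals.

Pipeline: wavelet + Savitzky-Golay denoising per channel, zero-phase band
separation into the BCG band (1-10 Hz) and the intrathoracic-volume band
(<0.5 Hz), motion-artifact rejection (body-shift steps >0.5 pF and windows
of low inter-sensor correlation), channel fusion by masked averaging, and an
in-band/out-of-band spectral SNR.

All filters are applied forward-backward (zero phase): pulse transit time is
a timing measurement, so group delay must not shift beat landmarks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SensorRecording",
    "ProcessedSignals",
    "denoise",
    "split_bands",
    "reject_artifacts",
    "fuse_channels",
    "compute_snr",
    "process_pair",
]

BCG_BAND = (1.0, 10.0)  # Hz, cardiac-vibration band
LOWFREQ_EDGE = 0.5  # Hz, intrathoracic-volume band upper edge
STEP_THRESHOLD = 0.5  # pF, body-shift rejection rule
CORR_THRESHOLD = 0.5  # minimum mean pairwise inter-channel correlation
ARTIFACT_WINDOW = 1.0  # s, span for both artifact criteria
SG_WINDOW = 15  # samples
SG_ORDER = 4
WAVELET = "db4"
WAVELET_LEVEL = 2


@dataclass(frozen=True)
class SensorRecording:
    """Multi-channel capacitance time series (pF) from one pad."""

    signal: np.ndarray  # (channels, samples)
    sample_rate: float  # Hz
    pad_id: str  # "chest" or "leg"
    pad_spacing: float  # meters, shared with the paired pad

    def __post_init__(self) -> None:
        sig = np.atleast_2d(np.asarray(self.signal, float))
        object.__setattr__(self, "signal", sig)
        if sig.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if not np.all(np.isfinite(sig)):
            raise ValueError("recording contains non-finite samples")
        if self.sample_rate <= 20:
            raise ValueError("sample_rate must exceed 20 Hz")
        if self.pad_id not in ("chest", "leg"):
            raise ValueError("pad_id must be 'chest' or 'leg'")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class ProcessedSignals:
    """Fused band-separated signals for one pad with a validity mask."""

    bcg: np.ndarray  # fused 1-10 Hz band, pF (NaN where invalid)
    lowfreq: np.ndarray  # fused <0.5 Hz band, pF (NaN where invalid)
    valid_mask: np.ndarray  # per-sample bool
    sample_rate: float
    pad_spacing: float = np.nan

    def __post_init__(self) -> None:
        if not (len(self.bcg) == len(self.lowfreq) == len(self.valid_mask)):
            raise ValueError("bcg, lowfreq and valid_mask must have equal length")


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------


def _wavelet_denoise(x: np.ndarray) -> np.ndarray:
    """db4 decomposition to level 2, soft universal threshold on details."""
    coeffs = pywt.wavedec(x, WAVELET, level=WAVELET_LEVEL)
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1 - np.median(d1))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]]
    out = pywt.waverec(coeffs, WAVELET)
    return out[: len(x)]


def denoise(recording: SensorRecording) -> SensorRecording:
    """Per-channel wavelet (db4, level 2, soft universal threshold) then
    Savitzky-Golay smoothing (order 4, 15-sample window). Length preserved."""
    if recording.n_samples < SG_WINDOW:
        raise ValueError(
            f"signal too short for the {SG_WINDOW}-sample Savitzky-Golay window"
        )
    out = np.empty_like(recording.signal)
    for c in range(recording.n_channels):
        x = _wavelet_denoise(recording.signal[c])
        out[c] = sps.savgol_filter(x, SG_WINDOW, SG_ORDER)
    return SensorRecording(
        signal=out,
        sample_rate=recording.sample_rate,
        pad_id=recording.pad_id,
        pad_spacing=recording.pad_spacing,
    )


# ---------------------------------------------------------------------------
# Band separation
# ---------------------------------------------------------------------------


def split_bands(recording: SensorRecording) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase 1-10 Hz band-pass (BCG) and <0.5 Hz low-pass (volume).

    Order-4 Butterworth, applied forward-backward per channel. Returns
    (bcg_channels, lowfreq_channels), each (channels, samples).
    """
    fs = recording.sample_rate
    if fs <= 2.2 * BCG_BAND[1]:
        raise ValueError("sample_rate puts the 10 Hz band edge too close to Nyquist")
    sos_bp = sps.butter(4, BCG_BAND, btype="bandpass", fs=fs, output="sos")
    sos_lp = sps.butter(4, LOWFREQ_EDGE, btype="low", fs=fs, output="sos")
    bcg = sps.sosfiltfilt(sos_bp, recording.signal, axis=1)
    # finite-length filtering leaves a tiny DC residue; the band excludes DC
    bcg = bcg - bcg.mean(axis=1, keepdims=True)
    low = sps.sosfiltfilt(sos_lp, recording.signal, axis=1)
    return bcg, low


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------


def _sliding_range(x: np.ndarray, w: int) -> np.ndarray:
    """max - min over a centred sliding window of w samples, per sample."""
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    return maximum_filter1d(x, w, mode="nearest") - minimum_filter1d(x, w, mode="nearest")


def reject_artifacts(
    recording: SensorRecording,
    step_threshold: float = STEP_THRESHOLD,
    corr_threshold: float = CORR_THRESHOLD,
    window: float = ARTIFACT_WINDOW,
    prior_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample validity mask.

    A sample is invalid when (a) any channel changes by more than
    ``step_threshold`` pF across a ``window``-second span (body shift), or
    (b) the mean pairwise inter-channel Pearson correlation in its window
    falls below ``corr_threshold`` (loss of contact / phase misalignment).
    Invalid spans are dilated by one window on each side. With a single
    channel, criterion (b) is skipped with a warning. Samples already
    invalid in ``prior_mask`` are ignored when computing the statistics, so
    the operation is idempotent.
    """
    sig = recording.signal
    fs = recording.sample_rate
    w = max(2, int(round(window * fs)))
    n = sig.shape[1]
    invalid = np.zeros(n, bool)
    prior_invalid = (
        ~np.asarray(prior_mask, bool) if prior_mask is not None else np.zeros(n, bool)
    )

    work = sig.copy()
    if prior_invalid.any():
        # hold previously rejected spans at their boundary value so old
        # artifacts do not re-trigger the detector
        idx = np.arange(n)
        good = ~prior_invalid
        if not good.any():
            return np.zeros(n, bool)
        for c in range(work.shape[0]):
            work[c, prior_invalid] = np.interp(
                idx[prior_invalid], idx[good], work[c, good]
            )

    # (a) step criterion: sliding range per channel, on a 0.3 s median-filtered
    # baseline so that cardiac vibrations and pulse lobes (~0.1 s wide) do not
    # masquerade as body shifts while genuine steps pass through unattenuated
    from scipy.ndimage import median_filter

    k = max(3, int(round(0.3 * fs)) | 1)
    for c in range(work.shape[0]):
        base = median_filter(work[c], size=k, mode="nearest")
        invalid |= _sliding_range(base, w) > step_threshold

    # (b) windowed inter-channel correlation
    if sig.shape[0] >= 2:
        n_win = n // w
        for k in range(n_win):
            seg = work[:, k * w : (k + 1) * w]
            segc = seg - seg.mean(axis=1, keepdims=True)
            sd = segc.std(axis=1)
            active = sd > 1e-12  # flat channels carry no phase information
            if active.sum() < 2:
                continue
            norm = segc[active] / sd[active, None]
            cmat = norm @ norm.T / seg.shape[1]
            iu = np.triu_indices(int(active.sum()), k=1)
            if np.mean(cmat[iu]) < corr_threshold:
                invalid[k * w : (k + 1) * w] = True
    else:
        logger.warning("single-channel recording: inter-sensor correlation check skipped")

    # dilate invalid spans by one window on each side
    if invalid.any():
        invalid = sps.convolve(invalid.astype(int), np.ones(2 * w + 1, int), mode="same") > 0
    return ~(invalid | prior_invalid)


# ---------------------------------------------------------------------------
# Fusion and SNR
# ---------------------------------------------------------------------------


def fuse_channels(channels: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Average equal-length channels sample-wise; invalid samples become NaN.

    Per-channel NaNs (e.g. a dead channel) are excluded from the mean of the
    remaining channels.
    """
    channels = np.atleast_2d(np.asarray(channels, float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        fused = np.nanmean(channels, axis=0)
    if valid_mask is not None:
        fused = fused.copy()
        fused[~np.asarray(valid_mask, bool)] = np.nan
    if not np.isfinite(fused).any():
        raise ValueError("no valid samples to fuse")
    return fused


def compute_snr(recording: SensorRecording) -> float:
    """In-band over out-of-band spectral power ratio.

    Power in the physiological bands [0, 0.5] Hz and [1, 10] Hz divided by
    the power everywhere else up to Nyquist, DC bin excluded, averaged over
    channels.
    """
    fs = recording.sample_rate
    if recording.duration < 10.0:
        raise ValueError("need at least 10 s of signal for a stable SNR estimate")
    x = recording.signal - recording.signal.mean(axis=1, keepdims=True)
    freqs = np.fft.rfftfreq(x.shape[1], 1.0 / fs)
    power = np.abs(np.fft.rfft(x, axis=1)) ** 2
    power[:, 0] = 0.0  # DC excluded
    in_band = ((freqs > 0) & (freqs <= LOWFREQ_EDGE)) | (
        (freqs >= BCG_BAND[0]) & (freqs <= BCG_BAND[1])
    )
    p_in = power[:, in_band].sum(axis=1)
    p_out = power[:, ~in_band].sum(axis=1)
    p_out[p_out == 0] = np.finfo(float).tiny
    return float(np.mean(p_in / p_out))


# ---------------------------------------------------------------------------
# Convenience: full preprocessing of one pad
# ---------------------------------------------------------------------------


def process_recording(recording: SensorRecording, **artifact_kw) -> ProcessedSignals:
    """denoise -> split_bands -> reject_artifacts -> fuse, for one pad."""
    den = denoise(recording)
    bcg_ch, low_ch = split_bands(den)
    mask = reject_artifacts(den, **artifact_kw)
    bcg = fuse_channels(bcg_ch, mask)
    low = fuse_channels(low_ch, mask)
    return ProcessedSignals(
        bcg=bcg,
        lowfreq=low,
        valid_mask=mask,
        sample_rate=recording.sample_rate,
        pad_spacing=recording.pad_spacing,
    )


def process_pair(chest: SensorRecording, leg: SensorRecording, **artifact_kw):
    """Preprocess the chest/leg pair; returns (ProcessedSignals, ProcessedSignals)."""
    return process_recording(chest, **artifact_kw), process_recording(leg, **artifact_kw)
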