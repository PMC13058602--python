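"""Forward simulator for capacitive sensing-pad (SEC) recordings.

Generates paired chest/leg single-electrode-capacitance signals with known
ground truth so the whole processing chain (denoising, band separation, beat
detection, PTT, BP regression, agreement statistics) can be exercised and
validated without access to human recordings.

Physical picture
----------------
A subject lies supine on two sensing pads. The chest pad capacitance carries

* a slow (<0.5 Hz) component proportional to intrathoracic blood volume,
  modelled here as a low-pass-filtered linear function of mean arterial
  pressure (MAP) plus a respiratory sinusoid;
* a ballistocardiogram (BCG) beat train in the 1-10 Hz band, one damped
  I-J-K complex per heart beat, with the I trough leading the dominant
  J peak by ~40 ms;
* white sensor noise and occasional body-shift steps (>0.5 pF artifacts).

The leg pad sees a single-lobed arterial pulse per beat, delayed relative to
the chest J peak by the pulse transit time (PTT). PTT is tied to BP through
an inverse-square-root law in MAP (Moens-Korteweg-flavoured) plus a slowly
varying vasomotor-tone jitter, so part of the BP information travels only
through the volume (mean dC) channel and part only through timing.

Every random draw goes through one seeded ``numpy.random.Generator``; the
same seed yields bit-identical recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .sigproc import SensorRecording

__all__ = [
    "CircuitParams",
    "BPTrajectory",
    "SimConfig",
    "GroundTruth",
    "make_bp_trajectory",
    "bp_to_ptt",
    "synthesize_recordings",
    "simulate_subject",
]

# Fixed maneuver durations (seconds), mirroring the supine test protocol:
# Valsalva strains of 20 s and sustained isometric handgrip of 30 s, each
# followed by a 1 min rest.
MANEUVER_DURATIONS = {"valsalva": 20.0, "handgrip": 30.0, "rest": 60.0}
DEFAULT_PROTOCOL = ("valsalva", "rest", "valsalva", "rest", "handgrip", "rest")

#: physiological clamp for pulse transit time, chest-to-popliteal (seconds)
PTT_BOUNDS = (0.05, 0.40)

# BCG beat morphology: Gaussian lobes (amplitude factor, center offset from
# the J peak in seconds, width in seconds). I and K troughs are symmetric
# about J so that cross-correlation against the symmetric leg pulse lobe
# peaks at the true transit lag.
_BCG_LOBES = ((-0.45, -0.040, 0.018), (1.00, 0.000, 0.020), (-0.45, 0.040, 0.018))
_LEG_LOBE_WIDTH = 0.030  # seconds
IJ_INTERVAL = 0.040  # seconds, I trough to J peak


@dataclass(frozen=True)
class CircuitParams:
    """Gains of the three serially coupled capacitance sources.

    ``c_cpc`` is the static electrode capacitance (pF), ``c_pressure_gain``
    scales mechanical vibration (BCG / pulse) into pF and ``c_eps_gain``
    scales relative blood-volume change into pF.
    """

    c_cpc: float = 50.0
    c_pressure_gain: float = 1.0
    c_eps_gain: float = 1.0

    def __post_init__(self) -> None:
        if not (self.c_cpc > 0 and self.c_pressure_gain > 0 and self.c_eps_gain > 0):
            raise ValueError("all circuit parameters must be strictly positive")


@dataclass(frozen=True)
class BPTrajectory:
    """Ground-truth SBP/DBP time courses with labelled maneuver intervals."""

    times: np.ndarray  # seconds, strictly increasing
    sbp: np.ndarray  # mmHg
    dbp: np.ndarray  # mmHg
    maneuver_marks: tuple  # (label, t_start, t_end) triples

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if np.any(self.sbp <= self.dbp):
            raise ValueError("sbp must exceed dbp at every sample")
        for name, arr in (("sbp", self.sbp), ("dbp", self.dbp)):
            if np.any(arr < 40) or np.any(arr > 250):
                raise ValueError(f"{name} outside the physiological range [40, 250] mmHg")

    @property
    def map(self) -> np.ndarray:
        """Mean arterial pressure, DBP + (SBP - DBP)/3."""
        return self.dbp + (self.sbp - self.dbp) / 3.0


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs for one subject run.

    Amplitude units are pF, times seconds, rates Hz unless noted.
    """

    seed: int = 0
    sample_rate: float = 100.0  # Hz; 10x the upper BCG band edge
    duration: float = 300.0
    hr_baseline: float = 62.0  # bpm
    pad_spacing: float = 1.0  # meters, chest pad to leg pad
    noise_sd: float = 0.018  # pF white sensor noise, per channel
    artifact_rate: float = 0.0  # body-shift steps per minute
    artifact_amplitude: float = 0.8  # pF step size (>0.5 pF rejection rule)
    ptt_coupling: tuple[float, float] = (1.932, 0.0)  # (a, b): PTT = a/sqrt(MAP)+b
    volume_coupling: float = 0.02  # pF per mmHg of MAP for the slow component
    resp_rate: float = 0.2  # Hz respiratory modulation
    resp_amplitude: float = 0.15  # pF
    bcg_amplitude: float = 0.30  # pF J-peak size (chest)
    leg_pulse_amplitude: float = 0.25  # pF
    leg_slow_ratio: float = 0.25  # leg slow component relative to chest
    ptt_tone_sd: float = 0.008  # s, slow vasomotor-tone jitter on PTT (AR(1))
    hr_lf_amplitude: float = 3.0  # bpm, 0.1 Hz autonomic HR modulation
    hr_map_gain: float = 0.15  # bpm per mmHg of MAP deviation
    sbp_baseline: float = 120.0  # mmHg
    dbp_baseline: float = 80.0  # mmHg
    age: float = 41.0  # years (subject metadata for the regression model)
    baseline_lead: float = 30.0  # s of quiet baseline before the first maneuver
    maneuvers: tuple[str, ...] = DEFAULT_PROTOCOL
    circuit: CircuitParams = field(default_factory=CircuitParams)

    def __post_init__(self) -> None:
        if self.sample_rate < 50:
            raise ValueError("sample_rate must be >= 50 Hz (BCG band extends to 10 Hz)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0 or self.artifact_rate < 0:
            raise ValueError("noise_sd and artifact_rate must be non-negative")
        if self.artifact_amplitude <= 0:
            raise ValueError("artifact_amplitude must be positive")
        unknown = set(self.maneuvers) - set(MANEUVER_DURATIONS)
        if unknown:
            raise ValueError(f"unknown maneuver labels: {sorted(unknown)}")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities recorded by the simulator for recovery tests."""

    beat_times: np.ndarray  # s, chest J-peak times, strictly increasing
    true_ptt: np.ndarray  # s per beat, within PTT_BOUNDS
    true_hr: np.ndarray  # bpm per continuous (10 s / 5 s) window
    true_mean_dc: np.ndarray  # pF per continuous window
    windows: np.ndarray  # (n_windows, 2) window bounds in s
    bp: BPTrajectory
    components: dict  # named clean signal components (pre-gain, per pad)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        lo, hi = PTT_BOUNDS
        if np.any(self.true_ptt < lo) or np.any(self.true_ptt > hi):
            raise ValueError("true_ptt outside physiological bounds")


# ---------------------------------------------------------------------------
# BP trajectory
# ---------------------------------------------------------------------------

_TRAJ_DT = 0.1  # s grid for the trajectory
_RELAX_TAU = 15.0  # s exponential relaxation during rests
_VALSALVA_DIP = 15.0  # mmHg SBP dip during strain
_VALSALVA_OVERSHOOT = 18.0  # mmHg SBP overshoot on release
_HANDGRIP_RISE = 25.0  # mmHg SBP rise over the 30 s grip
_DBP_FRACTION = 0.5  # DBP follows SBP perturbations at half amplitude


def make_bp_trajectory(config: SimConfig) -> BPTrajectory:
    """Piecewise-smooth SBP/DBP time course for the maneuver protocol.

    A flat baseline lead-in is followed by the configured maneuver sequence:
    Valsalva strains produce a dip-then-overshoot transient, handgrip a linear
    ramp, and rests an exponential relaxation back to baseline. With an empty
    ``maneuvers`` tuple the trajectory is flat at the configured baselines.
    """
    needed = config.baseline_lead + sum(MANEUVER_DURATIONS[m] for m in config.maneuvers)
    if config.maneuvers and config.duration < needed:
        raise ValueError(
            f"duration {config.duration:.0f} s too short for the requested maneuvers "
            f"({needed:.0f} s needed)"
        )

    n = int(round(config.duration / _TRAJ_DT)) + 1
    times = np.arange(n) * _TRAJ_DT
    delta = np.zeros(n)  # SBP deviation from baseline
    marks = []

    segments = [("baseline", config.baseline_lead)]
    segments += [(m, MANEUVER_DURATIONS[m]) for m in config.maneuvers]

    t0 = 0.0
    v = 0.0  # current SBP deviation carried across segments
    for label, seg_len in segments:
        t1 = min(t0 + seg_len, config.duration)
        sel = (times >= t0) & (times <= t1)
        tau = times[sel] - t0
        if label in ("baseline", "rest"):
            delta[sel] = v * np.exp(-tau / _RELAX_TAU)
        elif label == "valsalva":
            u = tau / seg_len
            shape = -_VALSALVA_DIP * np.exp(-(((u - 0.35) / 0.15) ** 2) / 2.0)
            shape += _VALSALVA_OVERSHOOT * np.exp(-(((u - 0.92) / 0.10) ** 2) / 2.0)
            delta[sel] = v * np.exp(-tau / _RELAX_TAU) + shape
        elif label == "handgrip":
            delta[sel] = v + _HANDGRIP_RISE * tau / seg_len
        if label != "baseline":
            marks.append((label, t0, t1))
        if sel.any():
            v = delta[sel][-1]
        t0 = t1
    # tail beyond the protocol relaxes back to baseline
    sel = times > t0
    if sel.any():
        delta[sel] = v * np.exp(-(times[sel] - t0) / _RELAX_TAU)

    sbp = config.sbp_baseline + delta
    dbp = config.dbp_baseline + _DBP_FRACTION * delta
    return BPTrajectory(times=times, sbp=sbp, dbp=dbp, maneuver_marks=tuple(marks))


# ---------------------------------------------------------------------------
# PTT <-> BP coupling
# ---------------------------------------------------------------------------


def bp_to_ptt(sbp, dbp, coupling: tuple[float, float] = (1.932, 0.0)):
    """Map BP to pulse transit time: PTT = a / sqrt(MAP) + b.

    MAP = DBP + (SBP - DBP)/3. The law is strictly decreasing in MAP (stiffer,
    more pressurised arteries transmit the pulse faster); the output is
    clamped to the physiological range 0.05-0.40 s.
    """
    sbp = np.asarray(sbp, float)
    dbp = np.asarray(dbp, float)
    if np.any(sbp <= dbp):
        raise ValueError("sbp must exceed dbp")
    if np.any(dbp < 40) or np.any(sbp > 250):
        raise ValueError("BP outside physiological range [40, 250] mmHg")
    a, b = coupling
    map_ = dbp + (sbp - dbp) / 3.0
    ptt = a / np.sqrt(map_) + b
    return np.clip(ptt, *PTT_BOUNDS)


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------


def _gauss_train(t: np.ndarray, centers: np.ndarray, lobes, fs: float) -> np.ndarray:
    """Sum of Gaussian lobes placed at each center time (vectorised locally)."""
    out = np.zeros_like(t)
    half = 0.35  # s support half-width per beat
    n = len(t)
    for c in centers:
        i0 = max(0, int((c - half) * fs))
        i1 = min(n, int((c + half) * fs) + 1)
        tt = t[i0:i1] - c
        for amp, off, width in lobes:
            out[i0:i1] += amp * np.exp(-(((tt - off) / width) ** 2) / 2.0)
    return out


def _beat_times(config: SimConfig, map_t: np.ndarray, t: np.ndarray, rng) -> np.ndarray:
    """Integrate the instantaneous heart rate to beat (J-peak) times."""
    phase = rng.uniform(0, 2 * math.pi)
    hr = (
        config.hr_baseline
        + config.hr_map_gain * (map_t - map_t[0])
        + config.hr_lf_amplitude * np.sin(2 * math.pi * 0.1 * t + phase)
    )
    hr = np.clip(hr, 30.0, 180.0)
    cum = np.cumsum(hr / 60.0) / config.sample_rate  # beats elapsed
    n_beats = int(np.floor(cum[-1]))
    # first beat a little after the start so the I trough is in-range
    targets = np.arange(1, n_beats + 1) - 0.5
    targets = targets[targets < cum[-1]]
    return np.interp(targets, cum, t)


def synthesize_recordings(
    config: SimConfig, bp: BPTrajectory
) -> tuple[SensorRecording, SensorRecording, GroundTruth]:
    """Generate chest and leg 4-channel recordings plus ground truth.

    Chest channels share a clean signal (volume drift + respiration + BCG
    train) scaled by per-channel gains, with independent white noise and
    optional body-shift step artifacts. Leg channels carry the delayed pulse
    train plus a smaller slow component. All latent quantities (beat times,
    per-beat PTT, per-window HR and mean dC, the clean components) are
    returned for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    map_t = np.interp(t, bp.times, bp.map)

    # --- slow intrathoracic-volume component (strictly <0.5 Hz) ---
    drift = config.volume_coupling * (map_t - map_t[0])
    sos = sps.butter(4, 0.4, btype="low", fs=fs, output="sos")
    drift = sps.sosfiltfilt(sos, drift)
    resp_phase = rng.uniform(0, 2 * math.pi)
    resp = config.resp_amplitude * np.sin(2 * math.pi * config.resp_rate * t + resp_phase)
    chest_slow = config.circuit.c_eps_gain * (drift + resp)
    leg_slow = config.leg_slow_ratio * chest_slow

    # --- beat train and transit times ---
    beats = _beat_times(config, map_t, t, rng)
    map_at_beats = np.interp(beats, t, map_t)
    sbp_at_beats = np.interp(beats, bp.times, bp.sbp)
    dbp_at_beats = np.interp(beats, bp.times, bp.dbp)
    ptt = np.asarray(bp_to_ptt(sbp_at_beats, dbp_at_beats, config.ptt_coupling))
    if config.ptt_tone_sd > 0:
        # slow AR(1) vasomotor-tone jitter, correlation time ~30 s
        rr = np.diff(beats, prepend=beats[0])
        rho = np.exp(-np.maximum(rr, 1e-3) / 30.0)
        tone = np.zeros(len(beats))
        eps = rng.standard_normal(len(beats))
        for k in range(len(beats)):
            prev = tone[k - 1] if k else 0.0
            tone[k] = rho[k] * prev + config.ptt_tone_sd * math.sqrt(1 - rho[k] ** 2) * eps[k]
        ptt = ptt + tone
    ptt = np.clip(ptt, *PTT_BOUNDS)

    chest_bcg = config.circuit.c_pressure_gain * config.bcg_amplitude * _gauss_train(
        t, beats, _BCG_LOBES, fs
    )
    leg_pulse = config.circuit.c_pressure_gain * config.leg_pulse_amplitude * _gauss_train(
        t, beats + ptt, ((1.0, 0.0, _LEG_LOBE_WIDTH),), fs
    )

    # --- per-channel assembly ---
    def make_pad(clean: np.ndarray, pad_id: str) -> np.ndarray:
        gains = rng.uniform(0.8, 1.2, size=4)
        sig = gains[:, None] * clean[None, :] + config.circuit.c_cpc
        if config.noise_sd > 0:
            sig = sig + rng.normal(0.0, config.noise_sd, size=sig.shape)
        return sig

    chest_sig = make_pad(chest_slow + chest_bcg, "chest")
    leg_sig = make_pad(leg_slow + leg_pulse, "leg")

    # --- body-shift step artifacts ---
    n_art = rng.poisson(config.artifact_rate * config.duration / 60.0)
    for _ in range(n_art):
        pad = chest_sig if rng.random() < 0.5 else leg_sig
        ch = rng.integers(0, 4)
        idx = rng.integers(int(1 * fs), n - 1)
        pad[ch, idx:] += rng.choice([-1.0, 1.0]) * config.artifact_amplitude

    # --- windowed ground truth (continuous 10 s / 5 s windows) ---
    from .features import iter_windows  # local import to avoid a cycle at import time

    windows = iter_windows(config.duration, mode="continuous")
    true_hr = np.full(len(windows), np.nan)
    true_dc = np.full(len(windows), np.nan)
    base_dc = np.median(chest_slow[: int(10 * fs)]) if n >= int(10 * fs) else np.median(chest_slow)
    for k, (t0, t1) in enumerate(windows):
        inb = (beats >= t0) & (beats < t1)
        if inb.sum() >= 3:
            true_hr[k] = 60.0 / np.mean(np.diff(beats[inb]))
        seg = chest_slow[int(t0 * fs) : int(t1 * fs)]
        true_dc[k] = np.mean(seg) - base_dc

    truth = GroundTruth(
        beat_times=beats,
        true_ptt=ptt,
        true_hr=true_hr,
        true_mean_dc=true_dc,
        windows=np.asarray(windows, float),
        bp=bp,
        components={
            "chest_slow": chest_slow,
            "chest_bcg": chest_bcg,
            "leg_slow": leg_slow,
            "leg_pulse": leg_pulse,
        },
    )
    chest = SensorRecording(
        signal=chest_sig, sample_rate=fs, pad_id="chest", pad_spacing=config.pad_spacing
    )
    leg = SensorRecording(
        signal=leg_sig, sample_rate=fs, pad_id="leg", pad_spacing=config.pad_spacing
    )
    return chest, leg, truth


def simulate_subject(config: SimConfig):
    """Convenience wrapper: trajectory + synthesis in one call."""
    bp = make_bp_trajectory(config)
    return synthesize_recordings(config, bp)
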