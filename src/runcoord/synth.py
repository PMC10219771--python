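"""Synthetic running sessions with known ground truth.

The generator emulates treadmill running at a fixed cadence: each leg's
shank angular velocity has one dominant positive peak at mid-swing and
negative dips at heel strike and toe-off; the right leg runs in antiphase
(half-cycle delay). EMG channels are band-limited Gaussian carriers
amplitude-modulated by phase-locked Gaussian activation bursts with
configurable cycle-to-cycle amplitude/timing jitter and inter-limb
asymmetry. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError
from .gait import STANCE, SWING
from .signal_io import ChannelKind, ChannelMeta, Recording, SampledSignal, Side

_EMG_CARRIER_BAND_HZ = (20.0, 450.0)

#: Gyro morphology (deg/s and fractions of the cycle period).
_GYRO_PEAK_AMPL = 250.0
_GYRO_HS_DIP = 100.0
_GYRO_TO_DIP = 90.0
_GYRO_PEAK_WIDTH_FRAC = 0.06
_GYRO_DIP_WIDTH_FRAC = 0.03
_GYRO_NOISE_SD = 4.0


@dataclass(frozen=True)
class ActivationTemplate:
    """One muscle's activation burst, in normalized phase time."""

    phase: str                 # "stance" or "swing"
    center_frac: float         # burst center within the phase, [0, 1]
    width_frac: float          # Gaussian sigma as a fraction of phase duration
    amplitude_mv: float

    def __post_init__(self) -> None:
        if self.phase not in (STANCE, SWING):
            raise ParameterError(f"unknown phase {self.phase!r}")
        if not 0.0 <= self.center_frac <= 1.0:
            raise ParameterError("center_frac must lie in [0, 1]")
        if self.width_frac <= 0 or self.amplitude_mv < 0:
            raise ParameterError("width_frac must be > 0 and amplitude_mv >= 0")


#: Plausibility defaults: knee extensors burst in stance, gastrocnemii in
#: late stance, tibialis anterior around heel strike, hamstrings late swing.
DEFAULT_TEMPLATES: dict[str, ActivationTemplate] = {
    # burst centers stay >= 2.5 sigma from the phase edges so that tail
    # leakage into the adjacent phase is negligible against the noise floor
    "rectus_femoris": ActivationTemplate(STANCE, 0.30, 0.12, 0.80),
    "vastus_lateralis": ActivationTemplate(STANCE, 0.35, 0.13, 0.90),
    "vastus_medialis": ActivationTemplate(STANCE, 0.40, 0.14, 0.85),
    "tibialis_anterior": ActivationTemplate(SWING, 0.70, 0.12, 0.60),
    "biceps_femoris": ActivationTemplate(SWING, 0.65, 0.13, 0.70),
    "gastrocnemius_medialis": ActivationTemplate(STANCE, 0.55, 0.15, 0.90),
    "gastrocnemius_lateralis": ActivationTemplate(STANCE, 0.60, 0.15, 0.80),
}


@dataclass(frozen=True)
class SimulationConfig:
    speed_kmh: float = 10.0
    cadence_hz: float = 1.25          # cycles per second per leg
    duration_s: float = 30.0
    stance_fraction: float = 0.35
    emg_rate_hz: float = 2000.0
    gyro_rate_hz: float = 148.0
    muscles: dict[str, ActivationTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    sigma_amp: float = 0.0            # multiplicative amplitude jitter SD
    sigma_time: float = 0.0           # burst-center jitter SD (phase fraction)
    asymmetry_rho: float = 0.0        # right amplitudes scaled by (1 - rho)
    hum_amplitude_mv: float = 0.0     # 50 Hz mains contamination
    dc_offset_mv: float = 0.0
    noise_floor_mv: float = 0.02      # baseline envelope so energy never vanishes
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cadence_hz, self.duration_s, self.emg_rate_hz, self.gyro_rate_hz) <= 0:
            raise ParameterError("rates, cadence and duration must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ParameterError("stance_fraction must lie in (0, 1)")
        if not 0 <= self.asymmetry_rho <= 1:
            raise ParameterError("asymmetry_rho must lie in [0, 1]")
        if self.sigma_amp < 0 or self.sigma_time < 0:
            raise ParameterError("jitter SDs must be >= 0")

    @property
    def period_s(self) -> float:
        return 1.0 / self.cadence_hz


@dataclass
class GroundTruth:
    """Event times and realized burst parameters the signals were built from."""

    swing_peaks_s: dict[Side, np.ndarray] = field(default_factory=dict)
    heel_strikes_s: dict[Side, np.ndarray] = field(default_factory=dict)
    toe_offs_s: dict[Side, np.ndarray] = field(default_factory=dict)
    burst_amplitudes: dict[tuple[str, Side], np.ndarray] = field(default_factory=dict)
    burst_centers_s: dict[tuple[str, Side], np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "events": {
                side.value: {
                    "swing_peaks_s": self.swing_peaks_s[side].tolist(),
                    "heel_strikes_s": self.heel_strikes_s[side].tolist(),
                    "toe_offs_s": self.toe_offs_s[side].tolist(),
                }
                for side in self.swing_peaks_s
            },
            "bursts": {
                f"{muscle}/{side.value}": {
                    "amplitudes_mv": self.burst_amplitudes[(muscle, side)].tolist(),
                    "centers_s": self.burst_centers_s[(muscle, side)].tolist(),
                }
                for (muscle, side) in self.burst_amplitudes
            },
        }


_SIDE_IDX = {Side.LEFT: 0, Side.RIGHT: 1}


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *stream])


def event_times(cfg: SimulationConfig, side: Side) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic swing-peak / heel-strike / toe-off times for one leg.

    Left swing peaks at 0.3 s + k/cadence; the right leg is delayed by half
    a cycle. Heel strike and toe-off frame the stance interval, centred
    between consecutive swing peaks.
    """
    p = cfg.period_s
    offset = 0.3 + (0.5 * p if side is Side.RIGHT else 0.0)
    n = int(np.floor((cfg.duration_s - offset - 0.3) / p)) + 1
    if n < 2:
        raise ParameterError("duration too short for two swing peaks")
    peaks = offset + p * np.arange(n)
    half_swing = 0.5 * (1.0 - cfg.stance_fraction) * p
    heel = peaks[:-1] + half_swing
    toe = heel + cfg.stance_fraction * p
    return peaks, heel, toe


def simulate_gyro(cfg: SimulationConfig, side: Side) -> SampledSignal:
    """Mediolateral shank angular velocity for one leg (deg/s)."""
    peaks, heel, toe = event_times(cfg, side)
    p = cfg.period_s
    t = np.arange(int(round(cfg.duration_s * cfg.gyro_rate_hz))) / cfg.gyro_rate_hz
    x = np.zeros_like(t)
    for c, ampl, width in (
        (peaks, _GYRO_PEAK_AMPL, _GYRO_PEAK_WIDTH_FRAC * p),
        (heel, -_GYRO_HS_DIP, _GYRO_DIP_WIDTH_FRAC * p),
        (toe, -_GYRO_TO_DIP, _GYRO_DIP_WIDTH_FRAC * p),
    ):
        for tc in c:
            x += ampl * np.exp(-0.5 * ((t - tc) / width) ** 2)
    x += _rng(cfg, 1, _SIDE_IDX[side]).normal(0.0, _GYRO_NOISE_SD, size=t.shape)
    return SampledSignal(x, cfg.gyro_rate_hz, 0.0)


def _bandlimited_carrier(rng: np.random.Generator, n: int, rate_hz: float) -> np.ndarray:
    """Band-limited unit-power noise carrier.

    The local RMS (10 ms Gaussian window) is pinned to one so a burst's
    energy is set by the activation envelope rather than by the carrier's
    chi-square fluctuations; without this the cycle-to-cycle energy spread
    of a jitter-free simulation would swamp the stability index.
    """
    white = rng.standard_normal(n)
    lo, hi = _EMG_CARRIER_BAND_HZ
    hi = min(hi, 0.45 * rate_hz)
    sos = butter(4, (lo, hi), btype="bandpass", fs=rate_hz, output="sos")
    carrier = sosfiltfilt(sos, white)
    # mains-free carrier: hum is modelled as a separate additive term, and
    # any random content near 50 Hz would re-emerge as cycle-to-cycle energy
    # jitter when the analysis notch rings through burst edges. The stop
    # band is wider than the notch so that amplitude-modulation sidebands
    # (envelope bandwidth of a few Hz) cannot refill it.
    sos_stop = butter(4, (42.0, 58.0), btype="bandstop", fs=rate_hz, output="sos")
    carrier = sosfiltfilt(sos_stop, carrier)
    carrier /= float(np.sqrt(np.mean(carrier**2)))
    local_rms = np.sqrt(gaussian_filter1d(carrier**2, 0.010 * rate_hz) + 1e-12)
    return carrier / local_rms


def _phase_interval(
    k: int,
    template: ActivationTemplate,
    peaks: np.ndarray,
    heel: np.ndarray,
    toe: np.ndarray,
) -> tuple[float, float] | None:
    """Interval of cycle k's stance or swing; swing spans toe-off to the next
    heel strike."""
    if template.phase == STANCE:
        return float(heel[k]), float(toe[k])
    if k + 1 < len(heel):
        return float(toe[k]), float(heel[k + 1])
    return None


def simulate_emg(
    cfg: SimulationConfig, muscle: str, side: Side, gt: GroundTruth
) -> SampledSignal:
    """One muscle's surface EMG (mV), modulated by per-cycle bursts.

    Per-cycle realized amplitudes and centers are appended to ``gt``.
    """
    template = cfg.muscles[muscle]
    peaks = gt.swing_peaks_s[side]
    heel = gt.heel_strikes_s[side]
    toe = gt.toe_offs_s[side]

    muscle_idx = list(cfg.muscles).index(muscle)
    rng = _rng(cfg, 2, _SIDE_IDX[side], muscle_idx)
    n = int(round(cfg.duration_s * cfg.emg_rate_hz))
    t = np.arange(n) / cfg.emg_rate_hz
    carrier = _bandlimited_carrier(rng, n, cfg.emg_rate_hz)

    scale = (1.0 - cfg.asymmetry_rho) if side is Side.RIGHT else 1.0
    envelope = np.full(n, cfg.noise_floor_mv)
    amplitudes, centers = [], []
    for k in range(len(heel)):
        interval = _phase_interval(k, template, peaks, heel, toe)
        if interval is None:
            continue
        start, end = interval
        dur = end - start
        a = template.amplitude_mv * (1.0 + rng.normal(0.0, cfg.sigma_amp)) if cfg.sigma_amp else template.amplitude_mv
        a = max(a, 0.05 * template.amplitude_mv) * scale
        center = start + template.center_frac * dur
        if cfg.sigma_time:
            center += rng.normal(0.0, cfg.sigma_time) * dur
        width = template.width_frac * dur
        burst = a * np.exp(-0.5 * ((t - center) / width) ** 2)
        # activation stays inside its phase: zero support outside the
        # interval, so adjacent phases see only the noise floor
        burst[(t < start) | (t >= end)] = 0.0
        envelope += burst
        amplitudes.append(a)
        centers.append(center)
    gt.burst_amplitudes[(muscle, side)] = np.array(amplitudes)
    gt.burst_centers_s[(muscle, side)] = np.array(centers)

    x = envelope * carrier
    if cfg.hum_amplitude_mv:
        x = x + cfg.hum_amplitude_mv * np.sin(2 * np.pi * 50.0 * t)
    if cfg.dc_offset_mv:
        x = x + cfg.dc_offset_mv
    return SampledSignal(x, cfg.emg_rate_hz, 0.0)


def simulate_session(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Full session: per-side 3-axis gyro plus one EMG channel per muscle."""
    gt = GroundTruth()
    channels: dict[ChannelMeta, SampledSignal] = {}
    for side in (Side.LEFT, Side.RIGHT):
        peaks, heel, toe = event_times(cfg, side)
        gt.swing_peaks_s[side] = peaks
        gt.heel_strikes_s[side] = heel
        gt.toe_offs_s[side] = toe

        gx = simulate_gyro(cfg, side)
        tag = side.value[0]
        rng = _rng(cfg, 3, _SIDE_IDX[side])
        channels[
            ChannelMeta(f"gyro_x_{tag}", ChannelKind.GYRO_X, side, "tibialis_anterior")
        ] = gx
        # off-axis channels: attenuated waveform plus independent noise
        for kind, gain, stream in ((ChannelKind.GYRO_Y, 0.2, 0), (ChannelKind.GYRO_Z, 0.05, 1)):
            noisy = gain * gx.samples + rng.normal(0.0, _GYRO_NOISE_SD, size=len(gx))
            channels[
                ChannelMeta(f"{kind.value}_{tag}", kind, side, "tibialis_anterior")
            ] = SampledSignal(noisy, cfg.gyro_rate_hz, 0.0)

        for muscle in cfg.muscles:
            channels[ChannelMeta(f"emg_{muscle}_{tag}", ChannelKind.EMG, side, muscle)] = (
                simulate_emg(cfg, muscle, side, gt)
            )

    rec = Recording(
        channels,
        label=f"synthetic_seed{cfg.seed}",
        speed_kmh=cfg.speed_kmh,
    )
    return rec, gt


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gt.to_dict(), indent=2))
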