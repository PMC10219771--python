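"""EMG preprocessing: high-pass filtering of motion artifacts and notch
rejection of mains interference."""

from __future__ import annotations

from dataclasses import dataclass

from scipy.signal import butter, filtfilt, iirnotch, lfilter, sosfilt, sosfiltfilt

from .errors import ParameterError
from .signal_io import ChannelKind, Recording, SampledSignal


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing parameters.

    Defaults: 4th-order 10 Hz Butterworth high-pass and a Q=30 notch at
    50 Hz, both applied forward-backward (zero-phase) so that burst timing
    stays aligned with the gyro-derived cycle boundaries.
    """

    highpass_cutoff_hz: float = 10.0
    highpass_order: int = 4
    notch_freq_hz: float = 50.0
    notch_q: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.highpass_cutoff_hz <= 0 or self.notch_freq_hz <= 0:
            raise ParameterError("filter frequencies must be positive")
        if self.highpass_order < 1:
            raise ParameterError("highpass_order must be >= 1")


def _check_nyquist(freq_hz: float, rate_hz: float, what: str) -> None:
    if freq_hz >= rate_hz / 2:
        raise ParameterError(
            f"{what} ({freq_hz} Hz) must be below Nyquist ({rate_hz / 2} Hz)"
        )


def highpass(x: SampledSignal, spec: FilterSpec = FilterSpec()) -> SampledSignal:
    """Butterworth high-pass; removes DC and low-frequency motion artifacts."""
    _check_nyquist(spec.highpass_cutoff_hz, x.rate_hz, "high-pass cutoff")
    sos = butter(
        spec.highpass_order,
        spec.highpass_cutoff_hz,
        btype="highpass",
        fs=x.rate_hz,
        output="sos",
    )
    if spec.zero_phase:
        y = sosfiltfilt(sos, x.samples)
    else:
        y = sosfilt(sos, x.samples)
    return SampledSignal(y, x.rate_hz, x.t0_s)


def notch(x: SampledSignal, spec: FilterSpec = FilterSpec()) -> SampledSignal:
    """IIR notch at the mains frequency."""
    _check_nyquist(spec.notch_freq_hz, x.rate_hz, "notch frequency")
    b, a = iirnotch(spec.notch_freq_hz, spec.notch_q, fs=x.rate_hz)
    if spec.zero_phase:
        y = filtfilt(b, a, x.samples)
    else:
        y = lfilter(b, a, x.samples)
    return SampledSignal(y, x.rate_hz, x.t0_s)


def preprocess(x: SampledSignal, spec: FilterSpec = FilterSpec()) -> SampledSignal:
    return notch(highpass(x, spec), spec)


def preprocess_emg(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Apply notch(highpass(.)) to every EMG channel; gyro channels pass
    through untouched."""
    channels = {}
    for meta, sig in rec:
        channels[meta] = preprocess(sig, spec) if meta.kind is ChannelKind.EMG else sig
    return Recording(channels, label=rec.label, speed_kmh=rec.speed_kmh)
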