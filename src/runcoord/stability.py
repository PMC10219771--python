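"""Amplitude and spatiotemporal stability of muscle EMG profiles.

Per muscle, phase and cycle the shortest window holding at least 90% of the
phase's EMG energy is located. Cycle-to-cycle means and population standard
deviations of (a) the window energy and (b) the window/phase duration ratio
yield two stability coefficients k = (1 - sigma/mean) * 100, clamped below
at zero. The integral coefficient K_EMG averages (k_E + k_dt)/2 over all
muscle x phase combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, ParameterError
from .gait import CyclePartition
from .signal_io import Recording, SampledSignal, Side
from .symmetry import energy_signal


@dataclass
class LocalizationWindow:
    """Shortest contiguous interval within a phase holding at least the
    target fraction of the phase's energy (earliest such window on ties)."""

    phase: int
    cycle: int
    start_s: float
    end_s: float
    energy: float          # E_{f,T}: energy inside the window
    phase_energy: float    # E_f: total energy of the phase
    phase_duration_s: float
    window_n: int = 0      # window length in samples
    phase_n: int = 0       # phase length in samples
    degenerate: bool = False  # silent phase (zero energy): excluded downstream

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_ratio(self) -> float:
        """Window duration over phase duration (dimensionless, in [0, 1]).

        Computed from sample counts so bit-identical cycles yield exactly
        identical ratios regardless of float round-off in the boundaries.
        """
        if self.phase_n:
            return min(self.window_n / self.phase_n, 1.0)
        return min(self.duration_s / self.phase_duration_s, 1.0)


@dataclass
class PhaseStabilityStats:
    """Cycle-to-cycle statistics of one muscle x phase combination."""

    muscle: str
    side: Side
    phase: int
    phase_name: str
    energies: np.ndarray          # E_{f,T}^i per cycle
    duration_ratios: np.ndarray   # dt_f^i per cycle
    mean_energy: float = 0.0
    mean_ratio: float = 0.0
    sd_energy: float = 0.0
    sd_ratio: float = 0.0
    k_energy: float | None = None
    k_ratio: float | None = None
    excluded: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.energies)


@dataclass
class StabilityReport:
    k_emg_pct: float
    n_cycles: int
    n_muscles: int
    n_phases: int
    per_phase: list[PhaseStabilityStats] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "K_EMG_pct": self.k_emg_pct,
            "n_cycles": self.n_cycles,
            "per_phase": [
                {
                    "muscle": s.muscle,
                    "side": s.side.value,
                    "phase": s.phase,
                    "phase_name": s.phase_name,
                    "k_E": s.k_energy,
                    "k_dt": s.k_ratio,
                    "mean_E": s.mean_energy,
                    "sd_E": s.sd_energy,
                    "mean_dt": s.mean_ratio,
                    "sd_dt": s.sd_ratio,
                    "excluded": s.excluded,
                }
                for s in self.per_phase
            ],
        }


def shortest_energy_window(values: np.ndarray, fraction: float = 0.9) -> tuple[int, int]:
    """Index range [i, j) of the shortest contiguous window whose sum is at
    least ``fraction`` of the total; earliest window on ties. O(n) two-pointer
    sweep over the cumulative sum (values must be non-negative)."""
    v = np.asarray(values, dtype=np.float64)
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    total = float(v.sum())
    if total <= 0:
        raise ValueError("zero total energy")
    target = fraction * total
    # tolerate float round-off so the uniform case picks ceil(f*n) samples
    tol = 1e-12 * total
    best_len = len(v) + 1
    best = (0, len(v))
    acc = 0.0
    i = 0
    for j in range(len(v)):
        acc += v[j]
        while acc - v[i] >= target - tol:
            acc -= v[i]
            i += 1
        if acc >= target - tol:
            length = j - i + 1
            if length < best_len:  # strict: keeps the earliest on ties
                best_len = length
                best = (i, j + 1)
    return best


def localization_window(
    e: SampledSignal,
    phase_start_s: float,
    phase_end_s: float,
    fraction: float = 0.9,
    phase: int = 0,
    cycle: int = 0,
) -> LocalizationWindow:
    """Locate the muscle-effort window of one phase on an energy signal."""
    if phase_end_s <= phase_start_s:
        raise ParameterError("empty phase interval")
    seg = e.slice_time(phase_start_s, phase_end_s)
    if len(seg) == 0:
        raise ParameterError("phase interval contains no samples")
    total = float(seg.samples.sum())
    duration = phase_end_s - phase_start_s
    if total <= 0:
        return LocalizationWindow(
            phase=phase, cycle=cycle,
            start_s=phase_start_s, end_s=phase_end_s,
            energy=0.0, phase_energy=0.0,
            phase_duration_s=duration,
            window_n=len(seg), phase_n=len(seg),
            degenerate=True,
        )
    i, j = shortest_energy_window(seg.samples, fraction)
    return LocalizationWindow(
        phase=phase, cycle=cycle,
        start_s=seg.t0_s + i / seg.rate_hz,
        end_s=seg.t0_s + j / seg.rate_hz,
        energy=float(seg.samples[i:j].sum()),
        phase_energy=total,
        phase_duration_s=duration,
        window_n=j - i, phase_n=len(seg),
    )


def phase_stats(
    windows: list[LocalizationWindow],
    durations: list[float] | None = None,
    muscle: str = "",
    side: Side = Side.LEFT,
    phase: int = 0,
    phase_name: str = "",
) -> PhaseStabilityStats:
    """Means and population standard deviations (denominator N) of window
    energy and duration ratio across N >= 2 cycles."""
    if durations is not None and len(durations) != len(windows):
        raise ParameterError("windows and durations must cover the same cycles")
    if len(windows) < 2:
        raise InsufficientDataError(f"need >= 2 cycles, got {len(windows)}")
    energies = np.array([w.energy for w in windows])
    if durations is None:
        ratios = np.array([w.duration_ratio for w in windows])
    else:
        ratios = np.array(
            [w.duration_s / t for w, t in zip(windows, durations)]
        )
    def _population_sd(v: np.ndarray) -> float:
        # exact zero for a constant sequence: np.std can return ~1 ulp
        # when the computed mean of identical values rounds
        return 0.0 if np.ptp(v) == 0 else float(v.std())

    stats = PhaseStabilityStats(
        muscle=muscle, side=side, phase=phase, phase_name=phase_name,
        energies=energies, duration_ratios=ratios,
        mean_energy=float(energies.mean()),
        mean_ratio=float(ratios.mean()),
        sd_energy=_population_sd(energies),  # population form (ddof=0)
        sd_ratio=_population_sd(ratios),
        excluded=any(w.degenerate for w in windows),
    )
    return stats


def stability_coefficients(stats: PhaseStabilityStats) -> PhaseStabilityStats:
    """k = (1 - sigma/mean) * 100, clamped below at 0 so coefficients stay
    inside the 0–100% range even when sigma exceeds the mean."""
    if stats.excluded:
        return stats
    if stats.mean_energy <= 0 or stats.mean_ratio <= 0:
        stats.excluded = True
        return stats
    stats.k_energy = max(0.0, (1.0 - stats.sd_energy / stats.mean_energy) * 100.0)
    stats.k_ratio = max(0.0, (1.0 - stats.sd_ratio / stats.mean_ratio) * 100.0)
    return stats


def integral_stability(
    all_stats: list[PhaseStabilityStats],
    n_muscles: int,
    n_phases: int,
    n_cycles: int = 0,
) -> StabilityReport:
    """K_EMG: mean of (k_E + k_dt)/2 over the included muscle x phase pairs.

    Degenerate (silent) phases are excluded from the average rather than
    counted as zero stability; they stay listed in the report with the
    ``excluded`` flag set.
    """
    included = [s for s in all_stats if not s.excluded]
    if not included:
        raise InsufficientDataError("all muscle/phase combinations excluded")
    pair_means = [(s.k_energy + s.k_ratio) / 2.0 for s in included]
    return StabilityReport(
        k_emg_pct=float(np.mean(pair_means)),
        n_cycles=n_cycles or (included[0].n_cycles if included else 0),
        n_muscles=n_muscles,
        n_phases=n_phases,
        per_phase=list(all_stats),
    )


def assess_stability(
    rec: Recording,
    part: CyclePartition,
    muscles: list[str] | None = None,
    n_cycles: int = 20,
    fraction: float = 0.9,
) -> StabilityReport:
    """Full stability pipeline for one leg of a preprocessed recording."""
    side = part.side
    if muscles is None:
        muscles = rec.emg_muscles(side)
    if not muscles:
        raise ConfigurationError(f"no EMG channels on side {side.value}")
    if len(part.cycles) < n_cycles:
        raise InsufficientDataError(
            f"partition has {len(part.cycles)} cycles, need {n_cycles}"
        )
    cycles = part.cycles[:n_cycles]
    n_phases = len(cycles[0].phases)

    all_stats: list[PhaseStabilityStats] = []
    for muscle in muscles:
        e = energy_signal(rec.emg(muscle, side))
        for f in range(n_phases):
            windows = [
                localization_window(
                    e,
                    c.phases[f].start_s,
                    c.phases[f].end_s,
                    fraction=fraction,
                    phase=c.phases[f].f,
                    cycle=c.i,
                )
                for c in cycles
            ]
            stats = phase_stats(
                windows,
                muscle=muscle,
                side=side,
                phase=cycles[0].phases[f].f,
                phase_name=cycles[0].phases[f].name,
            )
            all_stats.append(stability_coefficients(stats))
    return integral_stability(
        all_stats, n_muscles=len(muscles), n_phases=n_phases, n_cycles=n_cycles
    )
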