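"""End-to-end analysis: recording in, coordination report out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import emg, gait, report, stability, symmetry
from .errors import ConfigurationError
from .signal_io import ChannelKind, Recording, Side, align_timebases


@dataclass(frozen=True)
class AnalysisConfig:
    filter: emg.FilterSpec = emg.FilterSpec()
    n_cycles: int = 20
    muscles: tuple[str, ...] | None = None
    points_per_cycle: int = symmetry.DEFAULT_POINTS_PER_CYCLE
    period_range_s: tuple[float, float] = gait.DEFAULT_PERIOD_RANGE_S
    energy_fraction: float = 0.9
    pool_sides: bool = True   # average the two legs' K_EMG into one value

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "filter" in raw:
            kwargs["filter"] = emg.FilterSpec(**raw["filter"])
        for key in ("n_cycles", "points_per_cycle", "energy_fraction", "pool_sides"):
            if key in raw:
                kwargs[key] = raw[key]
        if "muscles" in raw and raw["muscles"] is not None:
            kwargs["muscles"] = tuple(raw["muscles"])
        if "period_range_s" in raw:
            kwargs["period_range_s"] = tuple(raw["period_range_s"])
        return cls(**kwargs)


def segment_sides(
    rec: Recording, cfg: AnalysisConfig
) -> dict[Side, gait.CyclePartition]:
    parts = {}
    for side in (Side.LEFT, Side.RIGHT):
        gyro = rec.gyro(side, ChannelKind.GYRO_X)
        parts[side] = gait.segment_gait(
            gyro,
            n_cycles=cfg.n_cycles,
            side=side,
            period_range_s=cfg.period_range_s,
        )
    return parts


def analyze_recording(
    rec: Recording, cfg: AnalysisConfig = AnalysisConfig(), meta: dict | None = None
) -> dict:
    """Run the full pipeline on one recording and return the merged report."""
    rec = align_timebases(rec)
    pre = emg.preprocess_emg(rec, cfg.filter)
    parts = segment_sides(pre, cfg)

    muscles = list(cfg.muscles) if cfg.muscles else None
    sym = symmetry.symmetry_coefficient(
        pre,
        parts[Side.LEFT],
        parts[Side.RIGHT],
        muscles=muscles,
        points_per_cycle=cfg.points_per_cycle,
    )

    stab_sides = []
    for side in (Side.LEFT, Side.RIGHT):
        if not pre.emg_muscles(side):
            continue
        stab_sides.append(
            stability.assess_stability(
                pre,
                parts[side],
                muscles=muscles,
                n_cycles=cfg.n_cycles,
                fraction=cfg.energy_fraction,
            )
        )
    if not stab_sides:
        raise ConfigurationError("no EMG channels to assess")
    if cfg.pool_sides and len(stab_sides) == 2:
        pooled = stability.StabilityReport(
            k_emg_pct=float(np.mean([s.k_emg_pct for s in stab_sides])),
            n_cycles=stab_sides[0].n_cycles,
            n_muscles=stab_sides[0].n_muscles,
            n_phases=stab_sides[0].n_phases,
            per_phase=[p for s in stab_sides for p in s.per_phase],
        )
    else:
        pooled = stab_sides[0]

    meta = dict(meta or {})
    meta.setdefault("label", rec.label)
    if rec.speed_kmh is not None:
        meta.setdefault("speed_kmh", rec.speed_kmh)
    return report.coordination_report(pooled, sym, meta)
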