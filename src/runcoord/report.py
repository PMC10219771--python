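"""Summary statistics and merged per-recording reports."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConsistencyError, InsufficientDataError
from .stability import StabilityReport
from .symmetry import SymmetryReport

__all__ = [
    "StageSummary",
    "summarise",
    "round_half_away",
    "coordination_report",
    "validate_report",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the study tables;
    Python's built-in round is banker's rounding). Uses decimal arithmetic
    so ties like 1.005 round up despite binary representation."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarise(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (denominator n - 1).

    Returns unrounded values; use :func:`round_half_away` for display.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise InsufficientDataError(f"need >= 2 values, got {v.size}")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class StageSummary:
    stage: str
    values: list[float]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return summarise(self.values)[0]

    @property
    def sd(self) -> float:
        return summarise(self.values)[1]

    def to_row(self) -> dict:
        return {
            "stage": self.stage,
            "n": self.n,
            "mean": round_half_away(self.mean),
            "sd": round_half_away(self.sd),
        }


#: Minimal structural schema of a coordination report. Each entry maps a
#: required key to the accepted types (None allowed where listed).
_REPORT_SCHEMA: dict[str, tuple] = {
    "label": (str,),
    "software": (str,),
    "version": (str,),
    "K_EMG_pct": (float, int, type(None)),
    "alpha_pct": (float, int, type(None)),
    "stability": (dict, type(None)),
    "symmetry": (dict, type(None)),
}


def validate_report(report: dict) -> dict:
    """Check a coordination report against the shipped structural schema."""
    for key, types in _REPORT_SCHEMA.items():
        if key not in report:
            raise ConsistencyError(f"report missing required key {key!r}")
        if not isinstance(report[key], types):
            raise ConsistencyError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected one of {[t.__name__ for t in types]}"
            )
    for key in ("K_EMG_pct", "alpha_pct"):
        val = report[key]
        if val is not None and not 0.0 <= float(val) <= 100.0:
            raise ConsistencyError(f"{key} = {val} outside [0, 100]")
    return report


def coordination_report(
    stab: StabilityReport | None,
    sym: SymmetryReport | None,
    meta: dict | None = None,
) -> dict:
    """Merge stability and symmetry results into one JSON-ready report."""
    from . import __version__

    meta = dict(meta or {})
    label_s = meta.get("stability_label")
    label_y = meta.get("symmetry_label")
    if label_s is not None and label_y is not None and label_s != label_y:
        raise ConsistencyError(
            f"reports come from different recordings: {label_s!r} vs {label_y!r}"
        )
    report = {
        "label": str(meta.get("label", label_s or label_y or "")),
        "software": "runcoord",
        "version": __version__,
        "K_EMG_pct": None if stab is None else stab.k_emg_pct,
        "alpha_pct": None if sym is None else sym.alpha_pct,
        "stability": None if stab is None else stab.to_dict(),
        "symmetry": None if sym is None else sym.to_dict(),
    }
    for key in ("speed_kmh", "seed", "config"):
        if key in meta:
            report[key] = meta[key]
    return validate_report(report)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def summary_table(summaries: list[StageSummary]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([s.to_row() for s in summaries])
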