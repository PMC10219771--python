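"""Published per-athlete reference values bundled for validation.

Thirteen professional runners completed an incremental treadmill protocol
(five 30 s stages, 8–12 km/hr). For each athlete the study reports the
integral EMG-profile stability coefficient K_EMG (%) per stage, and one
left/right muscular-effort symmetry coefficient alpha (%) averaged over
stages. These printed values are inputs for validating the summary
statistics; they are not recomputable from raw signals (none are deposited).
"""

from __future__ import annotations

#: K_EMG (%) per athlete (rows 1-13) for each load stage (km/hr).
STABILITY_BY_STAGE_PCT: dict[int, list[float]] = {
    8: [85.05, 83.16, 86.40, 86.13, 84.46, 82.61, 85.96, 85.65, 84.71, 70.80, 80.22, 84.82, 80.12],
    9: [79.20, 83.19, 86.67, 85.57, 81.22, 80.17, 84.51, 87.42, 87.97, 87.84, 87.06, 84.94, 82.07],
    10: [84.24, 83.63, 86.52, 85.31, 85.91, 84.06, 85.37, 84.39, 86.59, 82.03, 82.17, 82.46, 87.49],
    11: [86.75, 82.68, 87.79, 84.66, 82.81, 77.74, 86.32, 85.67, 79.67, 72.91, 87.17, 82.68, 81.70],
    12: [80.63, 85.77, 87.15, 82.77, 82.65, 82.46, 85.37, 81.25, 87.10, 86.13, 86.31, 84.53, 85.20],
}

#: Published per-stage "mean ± SD" of K_EMG (%), as printed.
STABILITY_STAGE_MEANS_PCT: dict[int, tuple[float, float]] = {
    8: (83.09, 4.23),
    9: (84.45, 3.02),
    10: (84.63, 1.76),
    11: (82.97, 4.26),
    12: (84.41, 2.21),
}

#: Symmetry coefficient alpha (%) per athlete, averaged over load stages.
SYMMETRY_ALPHA_PCT: list[float] = [
    77.04, 70.44, 64.49, 79.53, 81.87, 72.56, 84.05,
    83.29, 95.65, 88.79, 83.03, 85.73, 86.67,
]

#: Headline lower bounds quoted for the study cohort.
STABILITY_HEADLINE_MIN_PCT = 83.0
SYMMETRY_HEADLINE_MIN_PCT = 81.0
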