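"""Bundled example cohort data.

Per-volunteer summary statistics (mean ± SD per subject) from a
ten-volunteer breathing-feedback study, covering three scenarios each
for DIBH (breath-hold amplitude in mm, plateau drift in mm/s) and 4DCT
(breathing amplitude in mm, cycle duration in s):

* ``audio`` — audio feedback, no table movement
* ``visual`` — visual feedback, no table movement
* ``visual_table`` — visual feedback with table movement

Useful as realistic input for :func:`couchcorr.metrics.cohort_summary`
and :func:`couchcorr.metrics.compare_scenarios`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["volunteer_dibh", "volunteer_4dct", "SCENARIOS"]

SCENARIOS = ("audio", "visual", "visual_table")

# volunteer: (amplitude_mean, amplitude_sd, drift_mean, drift_sd) per scenario
_DIBH = {
    "audio": [
        (4.2, 0.7, -0.3, 0.1), (5.0, 1.2, -0.5, 0.1), (23.8, 1.3, -0.5, 0.4),
        (21.0, 0.8, -0.0, 0.3), (13.1, 0.2, -0.4, 0.1), (13.1, 2.8, -0.6, 0.1),
        (6.8, 0.8, -0.0, 0.1), (17.0, 0.7, -1.0, 0.1), (10.3, 0.6, -0.3, 0.2),
        (11.6, 1.6, -0.0, 0.1),
    ],
    "visual": [
        (10.9, 0.2, -0.2, 0.0), (10.5, 0.2, -0.2, 0.1), (16.7, 0.4, -0.0, 0.0),
        (12.7, 0.5, -0.5, 0.2), (12.1, 1.0, -0.2, 0.0), (11.1, 0.3, -0.2, 0.3),
        (10.3, 1.8, -0.4, 0.1), (10.9, 0.2, -0.2, 0.0), (4.8, 0.1, 0.0, 0.1),
        (9.5, 0.4, 0.1, 0.0),
    ],
    "visual_table": [
        (14.4, 0.4, -0.1, 0.2), (18.2, 0.1, -0.3, 0.2), (18.2, 0.7, -0.2, 0.2),
        (17.1, 0.2, -0.4, 0.0), (15.4, 0.7, -0.4, 0.0), (19.3, 0.7, -0.4, 0.4),
        (6.9, 0.2, 0.0, 0.1), (11.6, 0.2, -0.1, 0.2), (9.5, 0.7, -0.2, 0.6),
        (18.8, 0.3, 0.1, 0.1),
    ],
}

# volunteer: (amplitude_mean, amplitude_sd, duration_mean, duration_sd)
_FOURD = {
    "audio": [
        (14.4, 0.7, 4.4, 0.2), (8.1, 1.3, 3.0, 0.2), (41.0, 2.8, 4.5, 0.3),
        (11.7, 1.0, 5.7, 1.6), (8.2, 0.9, 4.1, 0.2), (12.1, 1.1, 5.3, 0.4),
        (14.7, 0.9, 7.9, 0.2), (14.4, 0.4, 5.6, 0.5), (20.6, 1.8, 4.8, 0.4),
        (16.9, 1.7, 9.7, 0.9),
    ],
    "visual": [
        (27.5, 3.0, 9.7, 1.8), (32.4, 1.8, 9.7, 0.7), (32.9, 1.3, 10.0, 0.3),
        (31.7, 2.5, 9.9, 0.7), (15.1, 7.6, 6.8, 3.0), (30.0, 2.1, 11.3, 1.9),
        (30.4, 2.3, 9.9, 0.0), (31.9, 2.5, 9.4, 2.2), (31.2, 2.3, 10.1, 1.7),
        (27.6, 2.4, 10.3, 1.0),
    ],
    "visual_table": [
        (30.2, 3.6, 8.4, 2.9), (30.7, 2.4, 9.9, 0.6), (33.6, 1.7, 10.0, 0.2),
        (30.5, 1.6, 9.9, 0.4), (25.2, 1.3, 9.9, 0.3), (29.0, 1.5, 9.9, 0.3),
        (29.9, 1.6, 10.0, 0.2), (26.1, 2.7, 9.3, 1.4), (30.8, 2.8, 9.8, 1.0),
        (35.4, 2.4, 10.3, 0.6),
    ],
}


def _frame(data: dict, cols: tuple[str, ...]) -> pd.DataFrame:
    rows = [
        (scenario, volunteer + 1, *values)
        for scenario, entries in data.items()
        for volunteer, values in enumerate(entries)
    ]
    return pd.DataFrame(rows, columns=("scenario", "volunteer", *cols))


def volunteer_dibh() -> pd.DataFrame:
    """DIBH per-volunteer statistics: amplitude (mm) and drift (mm/s)."""
    return _frame(
        _DIBH, ("amplitude_mean", "amplitude_sd", "drift_mean", "drift_sd")
    )


def volunteer_4dct() -> pd.DataFrame:
    """4DCT per-volunteer statistics: amplitude (mm) and cycle duration (s)."""
    return _frame(
        _FOURD, ("amplitude_mean", "amplitude_sd", "duration_mean", "duration_sd")
    )
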