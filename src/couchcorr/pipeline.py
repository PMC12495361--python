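"""End-to-end correction: pose streams -> table-motion-corrected trace.

Wires the geometry together: estimate the session camera pitch from the
table marker, project both markers onto the patient anterior-posterior
axis, resample the table stream onto the patient timestamps, and
subtract.  The result is a pair of breathing traces (corrected and
uncorrected) ready for the DIBH / 4DCT metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import correct_breathing, estimate_session_pitch, project_ap
from .streams import BreathingTrace, PoseStream, XrayEvent, pair_streams

__all__ = ["CorrectionResult", "correct_streams"]


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected and uncorrected AP breathing traces plus the pitch used."""

    corrected: BreathingTrace
    uncorrected: BreathingTrace
    theta: float  # rad, session camera pitch estimate
    n_dropped: int  # patient samples without a near-enough table frame

    def to_dict(self) -> dict:
        return {
            "theta_rad": self.theta,
            "n_samples": len(self.corrected),
            "n_dropped": self.n_dropped,
        }


def _flags_from_events(t: np.ndarray, events) -> np.ndarray:
    on = np.zeros(t.shape, dtype=bool)
    for ev in events or ():
        ev = ev if isinstance(ev, XrayEvent) else XrayEvent(*ev)
        on |= ev.contains(t)
    return on


def correct_streams(
    patient: PoseStream,
    table: PoseStream,
    max_gap: float = 0.2,
    theta: float | None = None,
    theta_window: float = 1.0,
    xray_events=None,
    label: str = "corrected",
) -> CorrectionResult:
    """Compute the table-motion-corrected breathing trace.

    Parameters
    ----------
    patient, table : PoseStream
        The two marker streams.
    max_gap : float
        Maximum patient-to-table frame gap (s) before a sample is dropped.
    theta : float, optional
        Camera pitch override (rad); by default the median per-frame
        pitch over the table marker's first ``theta_window`` seconds.
    xray_events : iterable of XrayEvent or (t_on, t_off), optional
        Beam-on intervals used to flag the output samples.
    """
    if theta is None:
        theta = estimate_session_pitch(table, window_s=theta_window)
    x_patient = project_ap(patient.translations, theta)
    x_table = project_ap(table.translations, theta)
    t, xb, xt = pair_streams(patient.t, x_patient, table.t, x_table, max_gap=max_gap)
    corrected = correct_breathing(xb, xt)
    flags = _flags_from_events(t, xray_events)
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else None
    return CorrectionResult(
        corrected=BreathingTrace(t, corrected, flags, label=label, sample_rate_hz=rate),
        uncorrected=BreathingTrace(
            t, xb, flags, label=f"{label}_uncorrected", sample_rate_hz=rate
        ),
        theta=float(theta),
        n_dropped=len(patient) - len(t),
    )
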