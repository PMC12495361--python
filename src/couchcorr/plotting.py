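"""Minimal matplotlib helpers for traces and feedback sessions."""

from __future__ import annotations

import numpy as np

from .feedback import SessionSummary
from .streams import BreathingTrace, extract_xray_events

__all__ = ["plot_trace", "plot_session"]

_STATE_COLORS = {"within": "tab:green", "edge": "gold", "outside": "tab:red"}


def plot_trace(trace: BreathingTrace, ax=None, shade_xray: bool = True, **kwargs):
    """Plot amplitude vs time, optionally shading beam-on intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.t, trace.amplitude, label=trace.label or None, **kwargs)
    if shade_xray:
        for ev in extract_xray_events(trace):
            ax.axvspan(ev.t_on, ev.t_off, color="0.85", zorder=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("AP amplitude (mm)")
    if trace.label:
        ax.legend()
    return ax


def plot_session(summary: SessionSummary, ax=None):
    """Plot a feedback replay: signal, window band, and state colors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.array([s.t for s in summary.states])
    amp = np.array([s.amplitude for s in summary.states])
    lo = np.array([s.window.lower for s in summary.states])
    hi = np.array([s.window.upper for s in summary.states])
    ax.fill_between(t, lo, hi, color="0.9", label="window")
    colors = [_STATE_COLORS[s.state] for s in summary.states]
    ax.scatter(t, amp, c=colors, s=4)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("AP amplitude (mm)")
    return ax
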