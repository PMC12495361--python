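"""Patient-facing breathing guidance: target waveform and window logic.

Regular-breathing guidance follows a cosine-power respiratory model,

    g(t) = A * (1 - cos(pi * t / T) ** k),        k even (default 6),

with phase origin at end-exhale: g(0) = 0 is the resting baseline,
g(T/2) = A the end-inhale peak, and A is the peak-to-trough amplitude.
The even exponent produces the long-exhale / short-inhale shape of
relaxed breathing.

Two display modes exist: a stationary (draggable) window for DIBH and a
window of fixed half-width riding the guidance waveform for 4DCT.  Each
sample is classified ``within`` / ``edge`` / ``outside`` (the display's
green / yellow / red); the core here is headless, rendering is a thin
layer elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .streams import BreathingTrace

__all__ = [
    "GuidanceParams",
    "BreathingWindow",
    "FeedbackState",
    "SessionSummary",
    "guidance_waveform",
    "static_window",
    "dynamic_window",
    "classify",
    "run_session",
]

STATES = ("outside", "edge", "within")


@dataclass(frozen=True)
class GuidanceParams:
    """Guidance waveform parameters.

    A : peak-to-trough amplitude, mm.  T : cycle duration, s.
    exponent : even cosine power >= 2.
    """

    A: float = 30.0
    T: float = 10.0
    exponent: int = 6

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ConfigError("guidance amplitude A must be > 0")
        if not self.T > 0:
            raise ConfigError("guidance cycle duration T must be > 0")
        if self.exponent < 2 or self.exponent % 2:
            raise ConfigError("exponent must be an even integer >= 2")


@dataclass(frozen=True)
class BreathingWindow:
    """Amplitude corridor [lower, upper] with a yellow edge margin."""

    lower: float
    upper: float
    mode: str = "static_dibh"  # or "dynamic_4dct"
    edge_margin: float = 0.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigError("window requires lower < upper")
        if not 0 <= self.edge_margin < (self.upper - self.lower) / 2:
            raise ConfigError("edge_margin must be < half the window width")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class FeedbackState:
    """Classification of one sample against its window."""

    t: float
    amplitude: float
    window: BreathingWindow = field(repr=False)
    state: str


@dataclass(frozen=True)
class SessionSummary:
    """Per-sample states plus time-fraction occupancy of each state."""

    states: tuple
    occupancy: dict

    @property
    def n(self) -> int:
        return len(self.states)


def guidance_waveform(t, params: GuidanceParams) -> float | np.ndarray:
    """Evaluate the guidance waveform g(t); T-periodic, range [0, A]."""
    t = np.asarray(t, dtype=float)
    g = params.A * (1.0 - np.cos(np.pi * t / params.T) ** params.exponent)
    return float(g) if g.ndim == 0 else g


def static_window(
    lower: float, upper: float, edge_margin_frac: float = 0.1
) -> BreathingWindow:
    """Stationary DIBH window; the yellow edge zone is a width fraction."""
    return BreathingWindow(
        lower, upper, mode="static_dibh",
        edge_margin=edge_margin_frac * (upper - lower),
    )


def dynamic_window(
    t: float,
    params: GuidanceParams,
    half_width: float,
    edge_margin_frac: float = 0.1,
) -> BreathingWindow:
    """Window of fixed half-width centered on g(t).

    Bounds may be negative near end-exhale; clipping for display is the
    presentation layer's business, not the classifier's.
    """
    if not half_width > 0:
        raise ConfigError("half_width must be > 0")
    center = guidance_waveform(float(t), params)
    return BreathingWindow(
        center - half_width, center + half_width, mode="dynamic_4dct",
        edge_margin=edge_margin_frac * 2 * half_width,
    )


def classify(amplitude: float, window: BreathingWindow) -> str:
    """Classify a sample: outside the bounds, at the edge, or within."""
    if amplitude < window.lower or amplitude > window.upper:
        return "outside"
    if (
        amplitude - window.lower <= window.edge_margin
        or window.upper - amplitude <= window.edge_margin
    ):
        return "edge"
    return "within"


def run_session(
    trace: BreathingTrace,
    window: BreathingWindow | None = None,
    guidance: GuidanceParams | None = None,
    half_width: float | None = None,
    edge_margin_frac: float = 0.1,
) -> SessionSummary:
    """Replay a trace against a static or dynamic window.

    Pass either ``window`` (static mode) or ``guidance`` plus
    ``half_width`` (dynamic mode).  Returns per-sample states and the
    fraction of samples spent in each state.
    """
    if (window is None) == (guidance is None):
        raise ConfigError("pass exactly one of window= or guidance=")
    if guidance is not None and half_width is None:
        raise ConfigError("dynamic mode needs half_width")
    states = []
    for i in range(len(trace)):
        w = (
            window
            if window is not None
            else dynamic_window(float(trace.t[i]), guidance, half_width, edge_margin_frac)
        )
        states.append(
            FeedbackState(
                t=float(trace.t[i]),
                amplitude=float(trace.amplitude[i]),
                window=w,
                state=classify(float(trace.amplitude[i]), w),
            )
        )
    n = max(len(states), 1)
    occupancy = {s: sum(fs.state == s for fs in states) / n for s in STATES}
    return SessionSummary(states=tuple(states), occupancy=occupancy)
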