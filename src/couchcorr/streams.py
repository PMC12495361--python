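"""Breathing-trace and pose-log containers, file I/O, pairing and alignment.

File formats (UTF-8, '.' decimal separator, units in the headers):

* Trace CSV — optional ``#`` metadata lines, then the header
  ``t_s,amplitude_mm,xray_on`` with the X-ray flag encoded 0/1.
* Pose log — optional ``#`` metadata lines, then
  ``t_s,marker_id,m11,...,m34``: the twelve row-major elements of the
  upper 3x4 of the homogeneous transform (rotation + translation, mm).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import AlignmentError, EmptyOverlapError, ParseError, ValidationError
from .geometry import Pose

__all__ = [
    "TraceSample",
    "BreathingTrace",
    "XrayEvent",
    "PoseStream",
    "read_trace",
    "write_trace",
    "read_pose_log",
    "write_pose_log",
    "pair_streams",
    "align_first_xray",
    "extract_xray_events",
]

TRACE_HEADER = "t_s,amplitude_mm,xray_on"
POSE_HEADER = "t_s,marker_id," + ",".join(
    f"m{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3, 4)
)


@dataclass(frozen=True)
class TraceSample:
    """One breathing-trace sample."""

    t: float
    amplitude: float
    xray_on: bool


@dataclass(frozen=True)
class XrayEvent:
    """One maximal beam-on interval [t_on, t_off)."""

    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValidationError("XrayEvent requires t_on < t_off")

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.t_on) & (t < self.t_off)


class BreathingTrace:
    """A 1-D breathing signal with per-sample X-ray flags.

    Array-backed: ``t`` (s, strictly increasing), ``amplitude`` (mm) and
    ``xray_on`` (bool), plus a free-text ``label`` and the nominal
    ``sample_rate_hz``.
    """

    def __init__(
        self,
        t,
        amplitude,
        xray_on=None,
        label: str = "",
        sample_rate_hz: float | None = None,
    ) -> None:
        self.t = np.asarray(t, dtype=float)
        self.amplitude = np.asarray(amplitude, dtype=float)
        if xray_on is None:
            xray_on = np.zeros(self.t.shape, dtype=bool)
        self.xray_on = np.asarray(xray_on, dtype=bool)
        self.label = label
        self.sample_rate_hz = sample_rate_hz
        if not (self.t.shape == self.amplitude.shape == self.xray_on.shape):
            raise ValidationError("t, amplitude and xray_on must share a shape")
        if self.t.ndim != 1:
            raise ValidationError("trace arrays must be 1-D")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.amplitude)):
            raise ValidationError("trace contains non-finite values")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("trace timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> TraceSample:
        return TraceSample(float(self.t[i]), float(self.amplitude[i]), bool(self.xray_on[i]))

    def __iter__(self) -> Iterator[TraceSample]:
        return (self[i] for i in range(len(self)))

    def shifted(self, dt: float) -> "BreathingTrace":
        """Copy with all timestamps shifted by ``dt`` seconds."""
        return BreathingTrace(
            self.t + dt, self.amplitude, self.xray_on, self.label, self.sample_rate_hz
        )

    @property
    def median_dt(self) -> float:
        if len(self.t) < 2:
            raise ValidationError("need >= 2 samples to infer a sample interval")
        return float(np.median(np.diff(self.t)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_s": self.t, "amplitude_mm": self.amplitude, "xray_on": self.xray_on}
        )

    def __repr__(self) -> str:
        return (
            f"BreathingTrace(n={len(self)}, label={self.label!r}, "
            f"span={self.t[0]:.2f}..{self.t[-1]:.2f} s)" if len(self)
            else f"BreathingTrace(n=0, label={self.label!r})"
        )


def _data_lines(path) -> Iterator[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line and not line.startswith("#"):
                yield lineno, line


def read_trace(path) -> BreathingTrace:
    """Read a breathing-trace CSV; see module docstring for the format."""
    path = Path(path)
    lines = _data_lines(path)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty file, expected header '{TRACE_HEADER}'")
    if header.replace(" ", "") != TRACE_HEADER:
        raise ParseError(f"{path}:{lineno}: expected header '{TRACE_HEADER}', got '{header}'")
    t, amp, xray = [], [], []
    for lineno, line in lines:
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        try:
            t.append(float(parts[0]))
            amp.append(float(parts[1]))
            flag = int(parts[2])
            if flag not in (0, 1):
                raise ValueError
            xray.append(bool(flag))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed row '{line}'")
    return BreathingTrace(t, amp, xray, label=path.stem)


def write_trace(trace: BreathingTrace, path, metadata: dict | None = None) -> None:
    """Write a trace CSV.

    Floats are serialised with ``%.17g`` so a write/read round trip is
    bit-exact.  ``metadata`` key/value pairs are written as ``#`` lines.
    """
    buf = io.StringIO()
    if trace.label:
        buf.write(f"# label={trace.label}\n")
    for k, v in (metadata or {}).items():
        buf.write(f"# {k}={v}\n")
    buf.write(TRACE_HEADER + "\n")
    for i in range(len(trace)):
        buf.write(
            f"{trace.t[i]:.17g},{trace.amplitude[i]:.17g},{int(trace.xray_on[i])}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


class PoseStream:
    """Array-backed sequence of poses for a single marker."""

    def __init__(self, t, matrices, marker_id: str) -> None:
        self.t = np.asarray(t, dtype=float)
        self.matrices = np.asarray(matrices, dtype=float)
        self.marker_id = marker_id
        if self.matrices.shape != (len(self.t), 4, 4):
            raise ValidationError("matrices must have shape (n, 4, 4)")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("pose timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def translations(self) -> np.ndarray:
        """(n, 3) global translations in mm."""
        return self.matrices[:, :3, 3]

    @property
    def rotations(self) -> np.ndarray:
        return self.matrices[:, :3, :3]

    def poses(self) -> Iterator[Pose]:
        """Iterate as validated :class:`~couchcorr.geometry.Pose` objects."""
        for i in range(len(self)):
            yield Pose(float(self.t[i]), self.marker_id, self.matrices[i])

    def __repr__(self) -> str:
        return f"PoseStream(marker={self.marker_id!r}, n={len(self)})"


def read_pose_log(path, marker_id: str | None = None) -> PoseStream:
    """Read a pose log, optionally filtering to one marker.

    A log may interleave several markers; the returned stream contains a
    single marker (the file's only one, or ``marker_id`` if given).
    """
    path = Path(path)
    lines = _data_lines(path)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty file, expected header '{POSE_HEADER}'")
    if header.replace(" ", "") != POSE_HEADER:
        raise ParseError(f"{path}:{lineno}: expected header '{POSE_HEADER}'")
    t, mats, markers = [], [], set()
    for lineno, line in lines:
        parts = line.split(",")
        if len(parts) != 14:
            raise ParseError(f"{path}:{lineno}: expected 14 fields, got {len(parts)}")
        mid = parts[1].strip()
        if marker_id is not None and mid != marker_id:
            continue
        try:
            ts = float(parts[0])
            vals = [float(x) for x in parts[2:]]
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed row '{line}'")
        M = np.eye(4)
        M[:3, :] = np.asarray(vals).reshape(3, 4)
        t.append(ts)
        mats.append(M)
        markers.add(mid)
    if marker_id is None:
        if len(markers) > 1:
            raise ParseError(
                f"{path}: multiple markers {sorted(markers)}; pass marker_id to select one"
            )
        marker_id = markers.pop() if markers else "unknown"
    return PoseStream(t, np.asarray(mats).reshape(-1, 4, 4), marker_id)


def write_pose_log(stream: PoseStream, path, metadata: dict | None = None) -> None:
    buf = io.StringIO()
    buf.write(f"# marker={stream.marker_id}\n")
    for k, v in (metadata or {}).items():
        buf.write(f"# {k}={v}\n")
    buf.write(POSE_HEADER + "\n")
    for i in range(len(stream)):
        vals = ",".join(f"{x:.17g}" for x in stream.matrices[i, :3, :].ravel())
        buf.write(f"{stream.t[i]:.17g},{stream.marker_id},{vals}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def pair_streams(
    patient_t,
    patient_x,
    table_t,
    table_x,
    max_gap: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample the table signal onto the patient timestamps.

    The table signal is linearly interpolated at each patient timestamp;
    patient samples whose nearest table frame is farther than ``max_gap``
    seconds are dropped (table-stream dropouts).

    Returns
    -------
    (t, x_patient, x_table) arrays on the retained patient timestamps.

    Raises
    ------
    EmptyOverlapError
        If the two time ranges are disjoint.
    """
    pt = np.asarray(patient_t, dtype=float)
    px = np.asarray(patient_x, dtype=float)
    tt = np.asarray(table_t, dtype=float)
    tx = np.asarray(table_x, dtype=float)
    if pt.size == 0 or tt.size == 0:
        raise ValidationError("pair_streams requires non-empty streams")
    if pt[-1] < tt[0] or tt[-1] < pt[0]:
        raise EmptyOverlapError(
            f"patient [{pt[0]:.3f}, {pt[-1]:.3f}] s and table "
            f"[{tt[0]:.3f}, {tt[-1]:.3f}] s do not overlap"
        )
    # distance from each patient timestamp to the nearest table frame
    idx = np.searchsorted(tt, pt)
    left = tt[np.clip(idx - 1, 0, len(tt) - 1)]
    right = tt[np.clip(idx, 0, len(tt) - 1)]
    nearest = np.minimum(np.abs(pt - left), np.abs(pt - right))
    keep = nearest <= max_gap
    xi = np.interp(pt[keep], tt, tx)
    return pt[keep], px[keep], xi


def _first_on_time(trace: BreathingTrace) -> float:
    on = np.flatnonzero(trace.xray_on)
    if on.size == 0:
        raise AlignmentError(
            f"trace {trace.label!r} has no X-ray-on sample to align to"
        )
    return float(trace.t[on[0]])


def align_first_xray(traces: Sequence[BreathingTrace]) -> list[BreathingTrace]:
    """Shift each trace so its first off->on transition sits at t = 0.

    A trace that starts already beam-on is aligned to its first sample.
    Amplitudes are untouched; the operation is idempotent.
    """
    return [tr.shifted(-_first_on_time(tr)) for tr in traces]


def extract_xray_events(trace: BreathingTrace) -> list[XrayEvent]:
    """Maximal beam-on runs of a trace as ordered, non-overlapping events.

    ``t_off`` is the timestamp of the first beam-off sample after a run,
    or the final timestamp if the run reaches the end of the trace.
    """
    flags = trace.xray_on.astype(int)
    if flags.size == 0 or not flags.any():
        return []
    d = np.diff(np.concatenate(([0], flags, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # index of first off sample (may be len)
    events = []
    for s, e in zip(starts, ends):
        t_on = float(trace.t[s])
        t_off = float(trace.t[e]) if e < len(trace.t) else float(trace.t[-1])
        if t_off > t_on:
            events.append(XrayEvent(t_on, t_off))
    return events
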