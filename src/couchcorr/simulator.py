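"""Synthetic dual-marker test bed: breathing, table sag/feed, camera, noise.

Stands in for the tracking hardware: it generates time-stamped 4x4 pose
streams for a patient marker and a table marker, plus a ground-truth
sidecar, for configurable scan scenarios.

Emulated physics
----------------
* Breathing patterns: sinusoid (peak-to-trough ``amplitude`` at
  ``frequency``), the cosine-power guidance waveform, and a DIBH
  sequence (free breathing interleaved with smooth-ramped rectangular
  holds of ``plateau_duration`` at ``amplitude``).
* Table sag: smooth monotone deflection from 0 to a load-scaled
  fraction of ``sag_max`` while the table travels — across the beam-on
  interval for helical scans, in stepwise ramps at each feed gap for
  axial 4DCT.  Load scaling is linear, 0.2 + 0.8 * load/104, so the
  three study loads (0, 52, 104 kg) map to 20 %, 60 % and 100 % of
  ``sag_max``.  Both markers ride the table, so the identical sag (and
  cranio-caudal feed) enters both pose streams.
* Camera geometry: patient-frame positions are embedded into the global
  frame through the inverse pitch rotation; marker orientations carry
  the pitch so the analysis side can re-extract it.
* Tracking noise: seeded isotropic Gaussian noise per global axis
  (``noise_rms`` mm per axis); optional constant ``latency`` on the
  table stream.
* X-ray events: one beam-on block for helical scans; repeating blocks
  separated by feed gaps for axial 4DCT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, ParseError
from .feedback import GuidanceParams, guidance_waveform
from .geometry import pitch_matrix
from .streams import BreathingTrace, PoseStream, XrayEvent, write_pose_log

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "breathing_pattern",
    "sag_profile",
    "xray_schedule",
    "simulate",
    "scenario_presets",
    "write_outputs",
    "read_ground_truth",
]

PATTERNS = ("sinusoid", "cos6", "dibh_sequence")
SCAN_MODES = ("helical_dibh", "axial_4dct")

#: DIBH sequence shape: smoothstep ramp time (s); lead-in and inter-hold
#: rest are 3 and 1 free-breathing periods so segments join at end-exhale.
DIBH_RAMP = 1.0
#: Axial 4DCT timing: beam-on block length and feed-gap length (s).
AXIAL_BLOCK_ON = 6.0
AXIAL_GAP = 2.0
AXIAL_LEAD_IN = 2.0
#: Helical table travel distance used for the cranio-caudal channel (mm).
HELICAL_TRAVEL = 100.0
#: Constant medial-lateral offset of the table marker (mm); exercises the
#: fact that only the AP projection enters the correction.
TABLE_MARKER_ML = 250.0


@dataclass(frozen=True)
class SimConfig:
    """Simulation scenario.

    Units: mm, s, Hz, kg, rad.  ``amplitude`` is peak-to-trough for the
    periodic patterns and the hold level for the DIBH sequence.
    ``sag_max`` is the full-load (104 kg) deflection endpoint, <= 0.
    """

    pattern: str = "sinusoid"
    amplitude: float = 20.0
    frequency: float = 0.2  # Hz; sinusoid and DIBH free breathing
    cycle_duration: float = 10.0  # s; cos6 guidance period T
    plateau_duration: float = 6.5
    n_plateaus: int = 3
    scan_mode: str = "axial_4dct"
    sag_max: float = -5.0
    load_kg: float = 104.0
    table_feed: float = 34.5  # mm per axial step
    pitch_theta: float = 0.35  # rad, camera pitch (~20 deg)
    noise_rms: float = 0.06  # mm per global axis
    latency: float = 0.0  # s, table stream only
    sample_rate: float = 50.0  # Hz
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigError(f"unknown pattern {self.pattern!r}; expected {PATTERNS}")
        if self.scan_mode not in SCAN_MODES:
            raise ConfigError(f"unknown scan_mode {self.scan_mode!r}")
        f = self.frequency if self.pattern != "cos6" else 1.0 / self.cycle_duration
        if not self.sample_rate > 2 * f:
            raise ConfigError("sample_rate must exceed twice the breathing frequency")
        if self.noise_rms < 0:
            raise ConfigError("noise_rms must be >= 0")
        if self.sag_max > 0:
            raise ConfigError("sag_max must be <= 0 (sag is a downward deflection)")
        if not (self.amplitude > 0 and self.duration > 0 and abs(self.pitch_theta) < np.pi / 2):
            raise ConfigError("invalid amplitude, duration or pitch_theta")

    @property
    def sag_scale(self) -> float:
        """Load-dependent fraction of sag_max: 0.2 + 0.8 * load/104, in [0, 1]."""
        return float(np.clip(0.2 + 0.8 * self.load_kg / 104.0, 0.0, 1.0))

    @property
    def breathing_period(self) -> float:
        return self.cycle_duration if self.pattern == "cos6" else 1.0 / self.frequency


@dataclass(frozen=True)
class GroundTruth:
    """Oracle channel of a simulation run."""

    t: np.ndarray = field(repr=False)
    breathing: np.ndarray = field(repr=False)  # true AP breathing, mm
    sag: np.ndarray = field(repr=False)  # true table sag, mm
    events: tuple  # XrayEvent beam-on intervals

    @property
    def xray_on(self) -> np.ndarray:
        on = np.zeros(self.t.shape, dtype=bool)
        for ev in self.events:
            on |= ev.contains(self.t)
        return on

    def breathing_trace(self, label: str = "truth") -> BreathingTrace:
        return BreathingTrace(self.t, self.breathing, self.xray_on, label=label)


@dataclass(frozen=True)
class SimResult:
    patient: PoseStream
    table: PoseStream
    truth: GroundTruth
    config: SimConfig


def _smoothstep(x) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _fb(t, config: SimConfig) -> np.ndarray:
    """Free breathing inside the DIBH sequence: half-amplitude sinusoid."""
    return (config.amplitude / 4.0) * (
        1.0 - np.cos(2 * np.pi * config.frequency * np.asarray(t, dtype=float))
    )


def _dibh_timeline(config: SimConfig) -> tuple[float, float, float]:
    """(lead_in, per-hold block length, rest) of the DIBH sequence, s."""
    period = 1.0 / config.frequency
    lead = 3.0 * period
    rest = period
    block = 2 * DIBH_RAMP + config.plateau_duration + rest
    return lead, block, rest


def breathing_pattern(t, config: SimConfig) -> np.ndarray:
    """True AP breathing displacement (mm) at times ``t``.

    * ``sinusoid``: (A/2)(1 - cos(2 pi f t)); peak-to-trough A, baseline 0.
    * ``cos6``: the guidance waveform with A and T = ``cycle_duration``.
    * ``dibh_sequence``: free breathing (peak-to-trough A/2) with
      ``n_plateaus`` holds at level A, smoothstep ramps of 1 s, lead-in
      of three breathing periods and one period of rest between holds;
      all joints fall at end-exhale so the signal is continuous.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    A = config.amplitude
    if config.pattern == "sinusoid":
        out = (A / 2.0) * (1.0 - np.cos(2 * np.pi * config.frequency * t))
    elif config.pattern == "cos6":
        out = guidance_waveform(t, GuidanceParams(A=A, T=config.cycle_duration))
        out = np.atleast_1d(out)
    else:
        lead, block, rest = _dibh_timeline(config)
        H, R = config.plateau_duration, DIBH_RAMP
        out = np.empty_like(t)
        tau = t - lead
        i = np.floor(tau / block)
        pre = t < lead
        post = i >= config.n_plateaus
        out[pre] = _fb(t[pre], config)
        out[post] = _fb(tau[post] - config.n_plateaus * block, config)
        mid = ~(pre | post)
        u = tau[mid] - i[mid] * block
        v = np.empty_like(u)
        up = u < R
        hold = (u >= R) & (u < R + H)
        down = (u >= R + H) & (u < 2 * R + H)
        restm = u >= 2 * R + H
        v[up] = A * _smoothstep(u[up] / R)
        v[hold] = A
        v[down] = A * _smoothstep(1.0 - (u[down] - R - H) / R)
        v[restm] = _fb(u[restm] - 2 * R - H, config)
        out[mid] = v
    return out


def xray_schedule(config: SimConfig) -> tuple:
    """Beam-on intervals for the scan mode.

    Helical: a single block (covering the DIBH hold sequence when the
    pattern is ``dibh_sequence``).  Axial 4DCT: repeating blocks of
    :data:`AXIAL_BLOCK_ON` s separated by :data:`AXIAL_GAP` s feed gaps.
    """
    if config.scan_mode == "helical_dibh":
        if config.pattern == "dibh_sequence":
            lead, block, rest = _dibh_timeline(config)
            t_on = lead
            t_off = lead + config.n_plateaus * block - rest
        else:
            t_on, t_off = AXIAL_LEAD_IN, config.duration - AXIAL_LEAD_IN
        return (XrayEvent(t_on, min(t_off, config.duration)),)
    events = []
    t_on = AXIAL_LEAD_IN
    while t_on + AXIAL_BLOCK_ON <= config.duration:
        events.append(XrayEvent(t_on, t_on + AXIAL_BLOCK_ON))
        t_on += AXIAL_BLOCK_ON + AXIAL_GAP
    if not events:
        raise ConfigError("duration too short for a single axial beam-on block")
    return tuple(events)


def _travel_progress(t, config: SimConfig) -> np.ndarray:
    """Normalised table-travel progress p(t) in [0, 1].

    Helical (or a single axial block): smoothstep across the beam-on
    interval.  Axial with B blocks: constant j/(B-1) during block j,
    smoothstep ramps across each feed gap.
    """
    t = np.asarray(t, dtype=float)
    events = xray_schedule(config)
    if len(events) == 1:
        ev = events[0]
        return _smoothstep((t - ev.t_on) / (ev.t_off - ev.t_on))
    B = len(events)
    p = np.zeros_like(t)
    for j, ev in enumerate(events):
        level = j / (B - 1)
        p = np.where(t >= ev.t_on, level, p)
        if j + 1 < B:
            nxt = events[j + 1]
            gap = (t - ev.t_off) / (nxt.t_on - ev.t_off)
            in_gap = (t >= ev.t_off) & (t < nxt.t_on)
            p = np.where(
                in_gap, level + (1.0 / (B - 1)) * _smoothstep(gap), p
            )
    return p


def sag_profile(t, config: SimConfig) -> np.ndarray:
    """True table sag (mm, <= 0) at times ``t``; 0 before table travel."""
    return config.sag_scale * config.sag_max * _travel_progress(t, config)


def _table_travel(t, config: SimConfig) -> np.ndarray:
    """Cranio-caudal table position (mm) at times ``t``."""
    events = xray_schedule(config)
    total = (
        HELICAL_TRAVEL
        if len(events) == 1
        else (len(events) - 1) * config.table_feed
    )
    return total * _travel_progress(t, config)


def simulate(config: SimConfig) -> SimResult:
    """Generate both marker pose streams plus the ground-truth channel.

    Patient AP truth is breathing + sag; table AP truth is sag alone;
    both markers share the cranio-caudal feed motion.  Patient-frame
    positions are mapped to the global frame by the transposed pitch
    rotation, marker orientations carry the pitch matrix itself, and
    seeded Gaussian noise of ``noise_rms`` mm is added per global axis
    independently for each marker.  ``latency`` delays the table
    stream's physical signal relative to its timestamps.
    """
    rate = config.sample_rate
    n = int(round(config.duration * rate))
    t = np.arange(n + 1) / rate
    events = xray_schedule(config)

    breathing = breathing_pattern(t, config)
    sag = sag_profile(t, config)
    cc = _table_travel(t, config)
    t_lagged = t - config.latency
    sag_table = sag_profile(t_lagged, config)
    cc_table = _table_travel(t_lagged, config)

    patient_frame = np.column_stack([breathing + sag, np.zeros_like(t), cc])
    table_frame = np.column_stack(
        [sag_table, np.full_like(t, TABLE_MARKER_ML), cc_table]
    )

    R = pitch_matrix(config.pitch_theta)
    rng = np.random.default_rng(config.seed)
    streams = {}
    for marker, frame in (("patient", patient_frame), ("table", table_frame)):
        global_xyz = frame @ R  # == (R.T @ frame.T).T
        if config.noise_rms > 0:
            global_xyz = global_xyz + rng.normal(0.0, config.noise_rms, frame.shape)
        mats = np.tile(np.eye(4), (len(t), 1, 1))
        mats[:, :3, :3] = R
        mats[:, :3, 3] = global_xyz
        streams[marker] = PoseStream(t, mats, marker)

    truth = GroundTruth(t=t, breathing=breathing, sag=sag, events=events)
    return SimResult(streams["patient"], streams["table"], truth, config)


def scenario_presets() -> dict[str, SimConfig]:
    """Named scenario configurations for the study conditions.

    Phantom scans: sinusoid 0.2 Hz / 20 mm for 4DCT, a DIBH sequence
    with 6.5 s holds for helical DIBH, each under three table loads
    (0 / 52 / 104 kg) with a -5 mm full-load sag endpoint.  Volunteer
    scenarios: audio-guided natural breathing versus cosine-power visual
    guidance (A = 30 mm, T = 10 s, 30 s runs for 4DCT), without and with
    table travel.
    """
    presets: dict[str, SimConfig] = {}
    for load in (0, 52, 104):
        presets[f"phantom_dibh_{load}kg"] = SimConfig(
            pattern="dibh_sequence", amplitude=20.0, frequency=0.2,
            plateau_duration=6.5, n_plateaus=3, scan_mode="helical_dibh",
            sag_max=-5.0, load_kg=load, duration=60.0,
        )
        presets[f"phantom_4dct_{load}kg"] = SimConfig(
            pattern="sinusoid", amplitude=20.0, frequency=0.2,
            scan_mode="axial_4dct", sag_max=-5.0, load_kg=load, duration=60.0,
        )
    # volunteer scenarios: sag endpoint ~-2 mm is a typical thorax-scan
    # deflection; scenarios without table movement set the endpoint to 0
    for name, cfg in {
        "volunteer_dibh_audio": dict(pattern="dibh_sequence", amplitude=13.0, sag_max=0.0),
        "volunteer_dibh_visual": dict(pattern="dibh_sequence", amplitude=15.0, sag_max=0.0),
        "volunteer_dibh_visual_table": dict(pattern="dibh_sequence", amplitude=15.0, sag_max=-2.0),
        "volunteer_4dct_audio": dict(
            pattern="sinusoid", amplitude=16.0, frequency=0.25, sag_max=0.0, duration=30.0
        ),
        "volunteer_4dct_visual": dict(
            pattern="cos6", amplitude=30.0, cycle_duration=10.0, sag_max=0.0, duration=30.0
        ),
        "volunteer_4dct_visual_table": dict(
            pattern="cos6", amplitude=30.0, cycle_duration=10.0, sag_max=-2.0, duration=30.0
        ),
    }.items():
        mode = "helical_dibh" if "dibh" in name else "axial_4dct"
        presets[name] = SimConfig(
            scan_mode=mode, load_kg=104.0, plateau_duration=6.5, n_plateaus=3,
            duration=cfg.pop("duration", 60.0), **cfg,
        )
    return presets


GROUND_TRUTH_HEADER = "t_s,breathing_mm,sag_mm,xray_on"


def write_outputs(result: SimResult, outdir, metadata: dict | None = None) -> dict:
    """Write pose logs and the ground-truth sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": result.config.seed, **(metadata or {})}
    paths = {
        "patient": outdir / "patient_poses.csv",
        "table": outdir / "table_poses.csv",
        "truth": outdir / "ground_truth.csv",
    }
    write_pose_log(result.patient, paths["patient"], metadata=meta)
    write_pose_log(result.table, paths["table"], metadata=meta)
    truth = result.truth
    xon = truth.xray_on
    lines = [f"# {k}={v}" for k, v in meta.items()]
    lines.append(GROUND_TRUTH_HEADER)
    for i in range(len(truth.t)):
        lines.append(
            f"{truth.t[i]:.17g},{truth.breathing[i]:.17g},"
            f"{truth.sag[i]:.17g},{int(xon[i])}"
        )
    paths["truth"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def read_ground_truth(path) -> GroundTruth:
    """Read a ground-truth sidecar written by :func:`write_outputs`."""
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        lines = [
            (no, ln.strip())
            for no, ln in enumerate(fh, start=1)
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines or lines[0][1].replace(" ", "") != GROUND_TRUTH_HEADER:
        raise ParseError(f"{path}: expected header '{GROUND_TRUTH_HEADER}'")
    for no, ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != 4:
            raise ParseError(f"{path}:{no}: expected 4 fields")
        try:
            rows.append((float(parts[0]), float(parts[1]), float(parts[2]), int(parts[3])))
        except ValueError:
            raise ParseError(f"{path}:{no}: malformed row '{ln}'")
    arr = np.asarray(rows, dtype=float)
    t, breathing, sag, xon = arr.T
    # reconstruct events from the flag column
    trace = BreathingTrace(t, breathing, xon.astype(bool))
    from .streams import extract_xray_events

    return GroundTruth(
        t=t, breathing=breathing, sag=sag, events=tuple(extract_xray_events(trace))
    )
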