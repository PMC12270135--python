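"""Synthetic data generators for every pipeline stage.

These generators produce inputs with the statistical structure the
analysis assumes — run-and-tumble tracks sampled at the camera frame rate
with localization noise, FRET step-response traces with baseline drift,
and noisy Hill dose-response tables — together with the exact ground
truth, so recovery can be quantified without any experimental data.

Track generation wraps the agent-based simulator: positions are sampled
at the frame rate, isotropic Gaussian localization noise is added, and
tracks are truncated to finite durations mimicking the residence of cells
in a microscope's field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fret import DoseResponse, FretTrace, StimulusEvent, hill_activity
from .response import ResponseModel
from .simulator import GradientChannel, SimConfig, SimulationResult, run_simulation
from .trackstats import Trajectory

__all__ = [
    "TrackGenSpec",
    "GroundTruth",
    "generate_tracks",
    "generate_fret_trace",
    "generate_dose_response",
]


@dataclass
class TrackGenSpec:
    """Specification of a synthetic tracking experiment.

    ``closed_ends=True`` (default) emulates tracking in a sealed chamber:
    every agent yields one track whose duration is drawn from an
    exponential distribution (mean ``duration_mean`` s) truncated to
    ``[duration_min, duration_max]``.  ``closed_ends=False`` emulates the
    open gradient channel: tracks are the residencies between entry and
    exit, as in the simulator.
    """

    model: ResponseModel
    n_tracks: int = 500
    frame_rate: float = 50.0
    noise_sigma: float = 0.35        # µm, isotropic localization noise
    channel: GradientChannel = field(default_factory=GradientChannel)
    closed_ends: bool = True
    run_speed: float = 25.0
    speed_std: float = 0.0
    tumble_time: float = 0.2
    rot_diffusion: float = 0.15
    duration_mean: float = 4.0
    duration_min: float = 1.0
    duration_max: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0 < self.duration_min <= self.duration_max:
            raise ValueError("invalid duration bounds")


@dataclass
class GroundTruth:
    """Frame-level truth emitted alongside a synthetic track ensemble.

    ``states[i]`` holds one boolean per frame *interval* of track ``i``
    (True = running during that interval), matching the dwell convention of
    the analysis: a track of n frames spans n - 1 intervals.
    """

    states: List[np.ndarray]
    tumbling_bias: np.ndarray        # per-track tumble-time fraction
    durations: np.ndarray            # s
    dy: np.ndarray                   # net y-displacement (noise-free), µm
    frame_rate: float

    @property
    def pooled_tumbling_bias(self) -> float:
        total = np.array([s.size for s in self.states], dtype=float)
        tumble = np.array([np.sum(~s) for s in self.states], dtype=float)
        return float(np.sum(tumble) / np.sum(total))

    @property
    def drift(self) -> float:
        """Duration-weighted mean y-velocity of the noise-free tracks."""
        return float(np.sum(self.dy) / np.sum(self.durations))

    def run_durations(self, min_frames: int = 5) -> np.ndarray:
        """True run durations (s) pooled over tracks, censored at track
        ends, keeping runs of at least ``min_frames`` frame intervals."""
        out = []
        for s in self.states:
            padded = np.concatenate([[False], s, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            starts, ends = edges[::2], edges[1::2]
            for a, b in zip(starts, ends):
                if b - a >= min_frames:
                    out.append((b - a) / self.frame_rate)
        return np.asarray(out)


def generate_tracks(spec: TrackGenSpec) -> Tuple[List[Trajectory], GroundTruth]:
    """Simulate, sample at the frame rate, add localization noise.

    Deterministic given ``spec.seed``.  Returns the noisy tracks (in the
    tracking-analysis input convention) and the exact ground truth.
    """
    f = spec.frame_rate
    dt = 1.0 / f
    rng = np.random.default_rng(spec.seed)
    if spec.closed_ends:
        raw = rng.exponential(spec.duration_mean, size=spec.n_tracks)
        durations = np.clip(raw, spec.duration_min, spec.duration_max)
        total = float(np.max(durations))
    else:
        durations = None
        total = spec.duration_max

    config = SimConfig(
        dt=dt, t_max=spec.duration_max, n_agents=spec.n_tracks,
        tumble_time=spec.tumble_time, rot_diffusion=spec.rot_diffusion,
        seed=int(rng.integers(0, 2 ** 31 - 1)), run_speed=spec.run_speed,
        speed_std=spec.speed_std, closed_ends=spec.closed_ends,
        record=True, total_time=total,
    )
    result = run_simulation(config, spec.model, spec.channel)

    tracks: List[Trajectory] = []
    states: List[np.ndarray] = []
    tb, durs, dys = [], [], []
    if spec.closed_ends:
        spans = [(i, 0, int(round(durations[i] * f))) for i in range(spec.n_tracks)]
    else:
        spans = [(int(a), int(s0), int(s1)) for a, s0, s1 in result.traj_table]

    tid = 0
    for agent, s0, s1 in spans:
        n = s1 - s0 + 1
        if n < 2:
            continue
        xy = result.positions[s0:s1 + 1, agent]
        noise = rng.normal(0.0, spec.noise_sigma, size=(n, 2)) if spec.noise_sigma > 0 else 0.0
        tracks.append(Trajectory(
            traj_id=tid, x=xy[:, 0] + (noise[:, 0] if spec.noise_sigma > 0 else 0.0),
            y=xy[:, 1] + (noise[:, 1] if spec.noise_sigma > 0 else 0.0),
            frame_rate=f, t0=s0 * dt))
        s = result.running_states[s0:s1, agent]
        states.append(s)
        tb.append(float(np.mean(~s)))
        durs.append((n - 1) * dt)
        dys.append(float(xy[-1, 1] - xy[0, 1]))
        tid += 1

    truth = GroundTruth(states=states, tumbling_bias=np.asarray(tb),
                        durations=np.asarray(durs), dy=np.asarray(dys),
                        frame_rate=f)
    return tracks, truth


# ---------------------------------------------------------------------------
# FRET generators


def generate_fret_trace(a0: float, k_d: float, h: float, rho: float,
                        stimuli: Sequence[Tuple[float, float, float]],
                        noise_sigma: float = 0.0, drift_slope: float = 0.0,
                        sample_rate: float = 1.0, t_end: Optional[float] = None,
                        calibration: bool = True, seed: int = 0):
    """Synthetic FRET recording for a strain with the given Hill response.

    ``stimuli`` is a sequence of ``(t_add, t_remove, concentration)``
    attractant steps.  The activity is piecewise constant (no short-term
    adaptation): ``A0`` unstimulated, ``A(L)`` while the attractant is
    present.  When ``calibration`` is set, a saturating-repellent step
    (A = 1) and a saturating attractant mix (A = 0) are appended, as used
    to calibrate the activity scale.  The activity maps onto a ratio
    ``r = c0 + 0.2 A`` (unstimulated ratio 1), multiplied by a linear
    drift ``1 + drift_slope * t`` with additive Gaussian noise.

    Returns ``(trace, truth)`` where ``truth`` records the activity
    timeline and the noise-free calibration levels on the corrected scale.
    """
    rng = np.random.default_rng(seed)
    events: List[StimulusEvent] = []
    segments: List[Tuple[float, float, float]] = []   # (t0, t1, activity)
    t_last = 0.0
    for t_add, t_remove, conc in stimuli:
        if t_remove <= t_add or t_add < t_last:
            raise ValueError("stimuli must be sorted and non-overlapping")
        events.append(StimulusEvent(t_add, "add", "MeAsp", conc))
        events.append(StimulusEvent(t_remove, "remove", "MeAsp", conc))
        segments.append((t_add, t_remove, float(hill_activity(conc, a0, k_d, h, rho))))
        t_last = t_remove
    if calibration:
        t_cal = t_last + 60.0
        events.append(StimulusEvent(t_cal, "add", "NiCl2", 300.0))
        events.append(StimulusEvent(t_cal + 60.0, "remove", "NiCl2", 300.0))
        segments.append((t_cal, t_cal + 60.0, 1.0))
        events.append(StimulusEvent(t_cal + 120.0, "add", "MeAsp+serine", 100.0))
        events.append(StimulusEvent(t_cal + 180.0, "remove", "MeAsp+serine", 100.0))
        segments.append((t_cal + 120.0, t_cal + 180.0, 0.0))
        t_last = t_cal + 180.0
    if t_end is None:
        t_end = t_last + 60.0

    time = np.arange(0.0, t_end, 1.0 / sample_rate)
    activity = np.full_like(time, a0)
    for t0, t1, a in segments:
        activity[(time >= t0) & (time < t1)] = a

    c1 = 0.2
    c0 = 1.0 - c1 * a0          # unstimulated ratio is 1
    ratio = (c0 + c1 * activity) * (1.0 + drift_slope * time)
    if noise_sigma > 0:
        ratio = ratio + rng.normal(0.0, noise_sigma, size=time.size)
    trace = FretTrace(time=time, ratio=np.maximum(ratio, 1e-6), events=events)
    truth = {
        "activity": activity,
        "activation_level": c0 + c1 * 1.0,     # corrected-scale ratio at A = 1
        "inactivation_level": c0 + c1 * 0.0,   # at A = 0
        "a0": a0, "k_d": k_d, "h": h, "rho": rho,
    }
    return trace, truth


def generate_dose_response(a0: float, k_d: float, h: float, rho: float,
                           doses: Sequence[float], noise_sigma: float = 0.0,
                           replicates: int = 1, seed: int = 0) -> List[DoseResponse]:
    """Noisy replicate dose-response tables from a Hill truth."""
    doses = np.asarray(list(doses), dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    clean = hill_activity(doses, a0, k_d, h, rho)
    out = []
    for _ in range(replicates):
        noisy = clean + (rng.normal(0.0, noise_sigma, doses.size)
                         if noise_sigma > 0 else 0.0)
        out.append(DoseResponse(conc=doses.copy(), activity=noisy))
    return out
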