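"""Trajectory analysis: swimmer filtering, run/tumble segmentation and
chemotaxis statistics.

The pipeline mirrors what particle-tracking analysis does to 2-D cell
trajectories recorded at high frame rate (default 50 frames/s):

1. discard tracks shorter than 1 s and separate swimmers from non-swimmers
   by a positional-variance-rate criterion (:func:`filter_swimmers`);
2. estimate a per-frame velocity by least-squares linear fits on a 10-frame
   sliding window (:func:`local_velocity`);
3. label each frame *run* or *tumble* by thresholding the local
   ballisticity — the ratio of the fitted speed to the step-displacement
   speed, which is 1 for straight constant-speed motion and drops at
   reorientations (:func:`segment_motility`);
4. summarise tumbling bias, run speed, chemotactic drift
   ``V_chem = sum_i V_i T_i / sum_i T_i`` and the up/down-gradient run-
   duration statistics (:func:`summarize_motility`, :func:`drift_and_bias`,
   :func:`run_direction_analysis`).

Localization noise comparable to the per-frame displacement inflates the
raw step displacement and would bias the ballisticity down; the
segmentation therefore estimates the noise variance from second
differences of the track and removes it from the step-displacement scale
(see :func:`estimate_noise_sigma2`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sp_stats

__all__ = [
    "Trajectory",
    "MotilityAnnotation",
    "Segment",
    "Segmentation",
    "SwimmerPartition",
    "MotilitySummary",
    "DriftEstimate",
    "RunDirectionSummary",
    "filter_swimmers",
    "local_velocity",
    "estimate_noise_sigma2",
    "segment_motility",
    "summarize_motility",
    "drift_and_bias",
    "run_direction_analysis",
    "spreading_bias",
    "spreading_bias_replicates",
    "analyze_ensemble",
]

#: median of a chi-squared(1) variate — converts a median of squared
#: Gaussian draws into a variance estimate
_CHI2_MEDIAN = 0.4549364231195728


@dataclass
class Trajectory:
    """Frame-indexed 2-D track of one cell (positions in µm)."""

    traj_id: Union[int, str]
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 50.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be matching 1-D arrays")
        if self.n_frames < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"non-finite coordinates in trajectory {self.traj_id}")

    @property
    def n_frames(self) -> int:
        return int(self.x.shape[0])

    @property
    def duration(self) -> float:
        """Track duration ``(n_frames - 1) / frame_rate`` in s."""
        return (self.n_frames - 1) / self.frame_rate

    def frame_dwell(self) -> np.ndarray:
        """Time attributed to each frame: ``1/f`` per frame except the last
        (a track of n frames spans n - 1 intervals)."""
        dwell = np.full(self.n_frames, 1.0 / self.frame_rate)
        dwell[-1] = 0.0
        return dwell


# ---------------------------------------------------------------------------
# swimmer filtering


@dataclass
class SwimmerPartition:
    swimmers: List[Trajectory]
    non_swimmers: List[Trajectory]
    discarded: List[Trajectory]


def diffusivity_statistic(traj: Trajectory) -> float:
    """Positional variance rate ``(<(x-<x>)^2> + <(y-<y>)^2>) / T`` (µm²/s)."""
    var = float(np.var(traj.x) + np.var(traj.y))
    return var / traj.duration


def filter_swimmers(trajectories: Sequence[Trajectory],
                    threshold: float = 0.61,
                    min_duration: float = 1.0) -> SwimmerPartition:
    """Partition tracks into swimmers, non-swimmers and discarded.

    Tracks shorter than ``min_duration`` (s) are discarded; the rest are
    swimmers iff their positional variance rate exceeds ``threshold``
    (µm²/s), a cutoff chosen just above the apparent diffusivity of
    non-motile cells.
    """
    part = SwimmerPartition([], [], [])
    for traj in trajectories:
        if traj.duration < min_duration:
            part.discarded.append(traj)
        elif diffusivity_statistic(traj) > threshold:
            part.swimmers.append(traj)
        else:
            part.non_swimmers.append(traj)
    return part


# ---------------------------------------------------------------------------
# local velocity


@dataclass
class MotilityAnnotation:
    """Per-frame fitted velocity and window step statistics for one track."""

    traj: Trajectory
    vx: np.ndarray            # fitted velocity components, µm/s
    vy: np.ndarray
    speed: np.ndarray         # |v|, µm/s
    mean_step: np.ndarray     # mean |step| over the window, µm
    msd_step: np.ndarray      # mean squared 1-frame step over the window, µm²
    msd_step2: np.ndarray     # mean squared 2-frame displacement, µm²
    window: int
    noise_sigma2: float       # estimated localization-noise variance, µm²

    @property
    def frame_rate(self) -> float:
        return self.traj.frame_rate


def estimate_noise_sigma2(x: np.ndarray, y: np.ndarray) -> float:
    """Localization-noise variance from second differences of the track.

    For smooth (locally linear) motion the second difference of the
    positions contains only noise, with variance ``6 sigma^2`` per axis; a
    median over frames and axes makes the estimate robust to the velocity
    jumps contributed by tumbles.
    """
    if x.shape[0] < 3:
        return 0.0
    d2 = np.concatenate([np.diff(x, 2), np.diff(y, 2)])
    return float(np.median(d2 ** 2) / (6.0 * _CHI2_MEDIAN))


def local_velocity(traj: Trajectory, window: int = 10) -> MotilityAnnotation:
    """Per-frame velocity from least-squares linear fits on a sliding window.

    The fit ``r(t') = r0(t) + v(t) (t' - t)`` runs over the ``window``
    consecutive frames approximately centred on each frame; frames closer
    than half a window to either end reuse the nearest full window.  The
    returned annotation also carries the mean and mean-squared
    frame-to-frame displacement over the same window.
    """
    n = traj.n_frames
    if n < window:
        raise ValueError(
            f"trajectory {traj.traj_id} shorter than the {window}-frame window")
    f = traj.frame_rate
    k = np.arange(window)
    c = (k - k.mean()) / np.sum((k - k.mean()) ** 2) * f  # LS slope weights

    xw = sliding_window_view(traj.x, window)
    yw = sliding_window_view(traj.y, window)
    slope_x = xw @ c
    slope_y = yw @ c

    step2 = np.diff(traj.x) ** 2 + np.diff(traj.y) ** 2
    step = np.sqrt(step2)
    lag2 = ((traj.x[2:] - traj.x[:-2]) ** 2 + (traj.y[2:] - traj.y[:-2]) ** 2)
    mean_step_w = sliding_window_view(step, window - 1).mean(axis=1)
    msd_step_w = sliding_window_view(step2, window - 1).mean(axis=1)
    msd_step2_w = sliding_window_view(lag2, window - 2).mean(axis=1)

    # frame -> window assignment: window [i-4, i+5] where it fits
    idx = np.clip(np.arange(n) - (window // 2 - 1), 0, n - window)
    vx = slope_x[idx]
    vy = slope_y[idx]
    return MotilityAnnotation(
        traj=traj, vx=vx, vy=vy, speed=np.hypot(vx, vy),
        mean_step=mean_step_w[idx], msd_step=msd_step_w[idx],
        msd_step2=msd_step2_w[idx], window=window,
        noise_sigma2=estimate_noise_sigma2(traj.x, traj.y),
    )


# ---------------------------------------------------------------------------
# run / tumble segmentation


@dataclass
class Segment:
    """A maximal stretch of identically labelled frames."""

    traj_id: Union[int, str]
    kind: str                 # "run" | "tumble"
    start: int                # first frame (inclusive)
    end: int                  # last frame (inclusive)
    n_frames: int
    duration: float           # dwell time, s
    dx: float                 # net displacement over the segment, µm
    dy: float

    @property
    def alpha(self) -> float:
        """Direction angle ``arccos(dy / |d|)`` in [0, pi]; NaN for zero
        net displacement."""
        norm = math.hypot(self.dx, self.dy)
        if norm == 0.0:
            return float("nan")
        return math.acos(max(-1.0, min(1.0, self.dy / norm)))


@dataclass
class Segmentation:
    """Per-frame labels and merged segments of one trajectory."""

    traj: Trajectory
    ballisticity: np.ndarray      # v_n per frame
    is_run: np.ndarray            # per-frame label
    segments: List[Segment]
    noise_sigma2_used: float
    speed: Optional[np.ndarray] = None   # fitted per-frame speed, µm/s

    @property
    def run_time(self) -> float:
        return float(np.sum(self.traj.frame_dwell()[self.is_run]))

    @property
    def tumble_time(self) -> float:
        return float(np.sum(self.traj.frame_dwell()[~self.is_run]))

    @property
    def tumbling_bias(self) -> float:
        tot = self.run_time + self.tumble_time
        if tot <= 0:
            raise ValueError("zero total time")
        return self.tumble_time / tot


def _step_scale(ann: MotilityAnnotation, sigma2: float) -> np.ndarray:
    """Estimate of the true (noise-free) per-frame step displacement.

    A localization error of variance ``sigma^2`` per coordinate adds
    ``4 sigma^2`` to the expected squared displacement at *every* lag (two
    coordinates, two frames), so the difference of the window-mean squared
    displacements at lag 2 and lag 1 cancels the noise term exactly:
    for locally linear motion ``(msd_2 - msd_1) / 3 = (v dt)^2``.  A floor
    of ``sigma^2 / 2`` keeps pure-noise (tumble) windows from collapsing
    to a zero denominator.  With ``sigma2 = 0`` the raw mean step
    displacement is used unchanged.
    """
    if sigma2 <= 0.0:
        return ann.mean_step
    dr2 = np.maximum((ann.msd_step2 - ann.msd_step) / 3.0, 0.5 * sigma2)
    return np.sqrt(dr2)


def segment_motility(ann: MotilityAnnotation, v_th: float = 0.785,
                     noise_sigma2: Union[str, float] = "auto",
                     label_smooth: int = 3) -> Segmentation:
    """Label frames run/tumble by thresholding the local ballisticity.

    ``v_n(t) = |v(t)| / (f * dr(t))`` compares the window-fitted speed with
    the step-displacement speed; it is 1 for ballistic motion and small
    during tumbles.  Frames with ``v_n >= v_th`` are runs.  ``noise_sigma2``
    selects the localization-noise variance used to correct ``dr``:
    ``"auto"`` (estimate from the track), a number (µm²), or 0 to disable
    the correction and use the raw mean step displacement.

    ``label_smooth`` (odd, in frames; 1 disables) despeckles the labels
    with a running majority vote, removing single-frame flickers that are
    below the resolution of the 10-frame velocity fit.
    """
    sigma2 = ann.noise_sigma2 if noise_sigma2 == "auto" else float(noise_sigma2)
    dr = _step_scale(ann, sigma2)
    f = ann.frame_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        vn = np.where(dr > 0, ann.speed / (f * dr), 0.0)
    is_run = vn >= v_th
    if label_smooth > 1:
        if label_smooth % 2 == 0:
            raise ValueError("label_smooth must be odd")
        from scipy.ndimage import median_filter
        is_run = median_filter(is_run.astype(np.int8), size=label_smooth,
                               mode="nearest").astype(bool)

    traj = ann.traj
    dwell = traj.frame_dwell()
    segments: List[Segment] = []
    n = traj.n_frames
    boundaries = np.flatnonzero(np.diff(is_run.astype(np.int8))) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries - 1, [n - 1]])
    for s, e in zip(starts, ends):
        segments.append(Segment(
            traj_id=traj.traj_id,
            kind="run" if is_run[s] else "tumble",
            start=int(s), end=int(e), n_frames=int(e - s + 1),
            duration=float(np.sum(dwell[s:e + 1])),
            dx=float(traj.x[e] - traj.x[s]),
            dy=float(traj.y[e] - traj.y[s]),
        ))
    return Segmentation(traj=traj, ballisticity=vn, is_run=is_run,
                        segments=segments, noise_sigma2_used=sigma2,
                        speed=ann.speed)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class MotilitySummary:
    """Pooled motility statistics over an ensemble of segmented tracks."""

    tumbling_bias: float              # pooled (times summed over all tracks)
    per_traj_bias: np.ndarray
    per_traj_duration: np.ndarray
    mean_run_speed: float             # µm/s, averaged over run frames
    n_trajectories: int


def summarize_motility(segmentations: Sequence[Segmentation]) -> MotilitySummary:
    """Pool tumbling bias and run speed over segmented trajectories.

    The pooled ("movie") bias sums run and tumble times over all
    trajectories, which equals the duration-weighted mean of the
    per-trajectory biases; the per-trajectory values (with durations as
    weights) are returned for distribution building.
    """
    if not segmentations:
        raise ValueError("no segmentations given")
    run_t = np.array([s.run_time for s in segmentations])
    tum_t = np.array([s.tumble_time for s in segmentations])
    tot = run_t + tum_t
    if np.sum(tot) <= 0:
        raise ValueError("zero total time")
    speed_sum = 0.0
    speed_w = 0.0
    for seg in segmentations:
        if seg.speed is None:
            continue
        w = seg.traj.frame_dwell()[seg.is_run]
        speed_sum += float(np.sum(seg.speed[seg.is_run] * w))
        speed_w += float(np.sum(w))
    mean_speed = speed_sum / speed_w if speed_w > 0 else float("nan")
    return MotilitySummary(
        tumbling_bias=float(np.sum(tum_t) / np.sum(tot)),
        per_traj_bias=tum_t / tot,
        per_traj_duration=tot,
        mean_run_speed=mean_speed,
        n_trajectories=len(segmentations),
    )


@dataclass
class DriftEstimate:
    v_chem: float           # µm/s, positive toward high concentration (+y)
    sem: float
    chemotaxis_bias: float  # v_chem / mean run speed (NaN if speed unknown)
    n_trajectories: int


def drift_and_bias(trajectories: Sequence[Trajectory],
                   mean_run_speed: Optional[float] = None) -> DriftEstimate:
    """Chemotactic drift ``V_chem = sum_i V_i T_i / sum_i T_i`` and bias.

    ``V_i`` is the trajectory-mean velocity along the gradient axis ``+y``
    (net y-displacement over duration) and ``T_i`` the track duration, so
    the estimator equals the total y-displacement over the total time.  The
    standard error uses the duration-weighted variance across trajectories
    with the effective sample size ``(sum T)^2 / sum T^2``.  The chemotaxis
    bias is the drift normalized by the mean run speed.
    """
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    t = np.array([traj.duration for traj in trajectories])
    dy = np.array([traj.y[-1] - traj.y[0] for traj in trajectories])
    v = dy / t
    tsum = float(np.sum(t))
    v_chem = float(np.sum(v * t) / tsum)
    var = float(np.sum(t * (v - v_chem) ** 2) / tsum)
    n_eff = tsum ** 2 / float(np.sum(t ** 2))
    sem = math.sqrt(var / n_eff) if len(trajectories) > 1 else float("nan")
    bias = v_chem / mean_run_speed if mean_run_speed else float("nan")
    return DriftEstimate(v_chem=v_chem, sem=sem, chemotaxis_bias=bias,
                         n_trajectories=len(trajectories))


# ---------------------------------------------------------------------------
# directional run analysis


@dataclass
class RunDirectionSummary:
    up_durations: np.ndarray
    down_durations: np.ndarray
    transverse_durations: np.ndarray
    n_zero_displacement: int

    @property
    def mean_up(self) -> float:
        return float(np.mean(self.up_durations)) if self.up_durations.size else float("nan")

    @property
    def mean_down(self) -> float:
        return float(np.mean(self.down_durations)) if self.down_durations.size else float("nan")

    @property
    def mean_all(self) -> float:
        alld = np.concatenate([self.up_durations, self.down_durations,
                               self.transverse_durations])
        return float(np.mean(alld)) if alld.size else float("nan")


def run_direction_analysis(segments: Sequence[Segment],
                           min_frames: int = 5) -> RunDirectionSummary:
    """Classify runs as up / down / transverse to the gradient.

    Runs shorter than ``min_frames`` frames are removed.  With ``alpha``
    the angle between the run's net displacement and ``+y``: ``alpha <
    pi/4`` is *up*, ``alpha > 3 pi/4`` is *down*, anything else (including
    the boundary values, strict inequalities) is *transverse*.  Zero-
    displacement runs are transverse by convention and counted.
    """
    up, down, trans = [], [], []
    n_zero = 0
    for seg in segments:
        if seg.kind != "run" or seg.n_frames < min_frames:
            continue
        alpha = seg.alpha
        if math.isnan(alpha):
            n_zero += 1
            trans.append(seg.duration)
        elif alpha < math.pi / 4.0:
            up.append(seg.duration)
        elif alpha > 3.0 * math.pi / 4.0:
            down.append(seg.duration)
        else:
            trans.append(seg.duration)
    return RunDirectionSummary(
        up_durations=np.asarray(up), down_durations=np.asarray(down),
        transverse_durations=np.asarray(trans), n_zero_displacement=n_zero)


# ---------------------------------------------------------------------------
# gradient-plate spreading bias


def spreading_bias(d_up: float, d_down: float) -> float:
    """Ratio of colony-edge distances up vs down the gradient."""
    if d_down <= 0 or d_up <= 0:
        raise ValueError("edge distances must be positive")
    return d_up / d_down


def spreading_bias_replicates(ratios: Sequence[float]):
    """Replicate mean ± SEM and a one-sided t-test against 1 (no bias).

    Returns ``(mean, sem, p_value)``; a zero-variance sample yields p = 1
    when the mean does not exceed 1 (no evidence of bias) and p = 0 when
    every replicate exceeds 1 identically.
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(np.mean(r))
    sem = float(np.std(r, ddof=1) / math.sqrt(r.size))
    if np.std(r, ddof=1) == 0.0:
        p = 0.0 if mean > 1.0 else 1.0
    else:
        p = float(sp_stats.ttest_1samp(r, 1.0, alternative="greater").pvalue)
    return mean, sem, p


# ---------------------------------------------------------------------------
# convenience pipeline


@dataclass
class EnsembleAnalysis:
    partition: SwimmerPartition
    annotations: List[MotilityAnnotation]
    segmentations: List[Segmentation]
    skipped_short: List[Trajectory]
    summary: MotilitySummary
    drift: DriftEstimate
    runs: List[Segment]
    run_directions: RunDirectionSummary


def analyze_ensemble(trajectories: Sequence[Trajectory], *,
                     swim_threshold: float = 0.61, min_duration: float = 1.0,
                     window: int = 10, v_th: float = 0.785,
                     noise_sigma2: Union[str, float] = "auto",
                     label_smooth: int = 3,
                     min_run_frames: int = 5) -> EnsembleAnalysis:
    """Full tracking analysis: filter, annotate, segment, summarise."""
    part = filter_swimmers(trajectories, swim_threshold, min_duration)
    annotations, segmentations, skipped = [], [], []
    for traj in part.swimmers:
        if traj.n_frames < window:
            skipped.append(traj)
            continue
        ann = local_velocity(traj, window)
        seg = segment_motility(ann, v_th, noise_sigma2, label_smooth)
        annotations.append(ann)
        segmentations.append(seg)
    if not segmentations:
        raise ValueError("no analyzable swimmer trajectories")
    summary = summarize_motility(segmentations)
    drift = drift_and_bias([s.traj for s in segmentations],
                           mean_run_speed=summary.mean_run_speed)
    runs = [seg for s in segmentations for seg in s.segments]
    directions = run_direction_analysis(runs, min_run_frames)
    return EnsembleAnalysis(
        partition=part, annotations=annotations, segmentations=segmentations,
        skipped_short=skipped, summary=summary, drift=drift, runs=runs,
        run_directions=directions)
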