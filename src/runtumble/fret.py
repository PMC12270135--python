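"""FRET ratio processing, kinase-activity calibration and Hill fitting.

A CheY-YFP / CheZ-CFP FRET pair reports chemotaxis-pathway (kinase)
activity as the YFP/CFP fluorescence ratio of an immobilized cell
population under flow.  Processing follows three steps:

1. :func:`normalize_ratio` removes the slow instrumental baseline drift
   (fitted on the unstimulated stretches of the recording) and scales the
   trace to its initial value;
2. :func:`kinase_activity` maps the corrected ratio linearly onto a
   relative activity scale using two calibration levels — full activation
   (A = 1, saturating repellent NiCl2) and full inactivation (A = 0,
   saturating attractant mix);
3. :func:`fit_hill` fits the dose dependence of the activity with
   ``A(L) = A0 (1 - L^H / (L^H + K_D^H))`` — the *wildtype* form — or with
   a residual fraction ``rho``, ``A(L) = A0 (1 - (1 - rho) L^H / (L^H +
   K_D^H))``, for strains whose activity is not fully inhibited at
   saturating attractant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .response import hill_inhibition

__all__ = [
    "StimulusEvent",
    "FretTrace",
    "DoseResponse",
    "HillFit",
    "normalize_ratio",
    "kinase_activity",
    "response_amplitudes",
    "fit_hill",
    "hill_activity",
]


@dataclass(frozen=True)
class StimulusEvent:
    """A stimulus annotation: compound added to or removed from the flow."""

    time: float            # s
    action: str            # "add" | "remove"
    compound: str
    concentration: float   # µM

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError("action must be 'add' or 'remove'")


@dataclass
class FretTrace:
    """YFP/CFP ratio time series with stimulus annotations."""

    time: np.ndarray
    ratio: np.ndarray
    events: List[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time.shape != self.ratio.shape or self.time.ndim != 1:
            raise ValueError("time and ratio must be matching 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.ratio <= 0):
            raise ValueError("ratios must be positive")
        self.events = sorted(self.events, key=lambda e: e.time)

    def unstimulated_mask(self) -> np.ndarray:
        """True where no compound is present (before the first addition and
        between a removal and the next addition)."""
        present = 0
        mask = np.ones_like(self.time, dtype=bool)
        t_prev = -math.inf
        for ev in self.events:
            if present > 0:
                mask &= ~((self.time >= t_prev) & (self.time < ev.time))
            t_prev = ev.time
            present += 1 if ev.action == "add" else -1
            present = max(present, 0)
        if present > 0:
            mask &= self.time < t_prev
        return mask


def normalize_ratio(trace: FretTrace, baseline_order: int = 1,
                    min_pre_points: int = 10) -> FretTrace:
    """Correct baseline drift and normalize to the start of the recording.

    A polynomial baseline (default linear) is fitted to the unstimulated
    stretches of the trace and divided out; the result is then scaled so
    that the first point equals 1.  Requires at least ``min_pre_points``
    samples before the first stimulus.
    """
    if not 0 <= baseline_order <= 2:
        raise ValueError("baseline_order must be 0, 1 or 2")
    mask = trace.unstimulated_mask()
    first_stim = trace.events[0].time if trace.events else math.inf
    n_pre = int(np.sum(trace.time < first_stim))
    if n_pre < min_pre_points:
        raise ValueError(
            f"need at least {min_pre_points} pre-stimulus points, got {n_pre}")
    if not mask.any():
        raise ValueError("no unstimulated segment to fit the baseline on")
    coef = np.polyfit(trace.time[mask], trace.ratio[mask], baseline_order)
    baseline = np.polyval(coef, trace.time)
    corrected = trace.ratio / baseline
    corrected = corrected / corrected[0]
    return FretTrace(time=trace.time.copy(), ratio=corrected,
                     events=list(trace.events))


def kinase_activity(ratio, activation_level: float, inactivation_level: float):
    """Map corrected YFP/CFP ratios onto the relative kinase-activity scale.

    ``A = (r - r_inact) / (r_act - r_inact)``: the calibration levels are
    the corrected ratios at full activation (A = 1, saturating repellent)
    and full inactivation (A = 0, saturating attractant).  The map is
    affine, so rescaling the ratio scale (and its calibration levels by the
    same factor) leaves the activity unchanged.
    """
    span = activation_level - inactivation_level
    if span == 0:
        raise ValueError("calibration levels are equal: zero dynamic range")
    return (np.asarray(ratio, dtype=float) - inactivation_level) / span


def response_amplitudes(trace: FretTrace, pre_points: int = 5,
                        post_window: float = 30.0) -> List[Tuple[StimulusEvent, float]]:
    """Initial ratio change elicited by each stimulus addition.

    For every "add" event: the baseline is the mean of ``pre_points``
    samples before the event, the response is the extremum (largest
    absolute deviation from that baseline) within ``post_window`` seconds
    after it, and the amplitude is the signed difference.
    """
    out: List[Tuple[StimulusEvent, float]] = []
    for ev in trace.events:
        if ev.action != "add":
            continue
        pre_idx = np.flatnonzero(trace.time < ev.time)
        if pre_idx.size < pre_points:
            raise ValueError(f"fewer than {pre_points} samples before t={ev.time}")
        base = float(np.mean(trace.ratio[pre_idx[-pre_points:]]))
        post = (trace.time >= ev.time) & (trace.time <= ev.time + post_window)
        if not post.any():
            raise ValueError(f"no samples within {post_window}s after t={ev.time}")
        dev = trace.ratio[post] - base
        out.append((ev, float(dev[np.argmax(np.abs(dev))])))
    return out


# ---------------------------------------------------------------------------
# dose-response fitting


@dataclass
class DoseResponse:
    """Relative kinase activity as a function of attractant concentration."""

    conc: np.ndarray     # µM, strictly increasing
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.conc.shape != self.activity.shape or self.conc.ndim != 1:
            raise ValueError("conc and activity must be matching 1-D arrays")
        if np.any(np.diff(self.conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")


def hill_activity(conc, a0: float, k_d: float, h: float, rho: float = 0.0):
    """``A(L) = A0 (1 - (1 - rho) L^H / (L^H + K_D^H))``.

    ``rho = 0`` gives the wildtype form; a positive ``rho`` leaves a
    residual activity ``A0 rho`` at saturating attractant.  ``A(0) = A0``
    exactly and ``A(K_D) = A0 (1 + rho) / 2``.
    """
    inhib = 1.0 - hill_inhibition(conc, k_d, h)  # L^H / (L^H + K_D^H)
    return a0 * (1.0 - (1.0 - rho) * inhib)


@dataclass
class HillFit:
    """Fitted dose-response parameters."""

    a0: float
    k_d: float
    h: float
    rho: float
    variant: str
    residuals: Optional[np.ndarray]
    converged: bool
    identifiable: bool
    message: str = ""

    def predict(self, conc):
        return hill_activity(conc, self.a0, self.k_d, self.h, self.rho)


def fit_hill(dose: DoseResponse, variant: str = "wildtype") -> HillFit:
    """Nonlinear least-squares Hill fit of a dose-response table.

    ``variant="wildtype"`` fixes ``rho = 0``; ``variant="residual"`` also
    fits the residual-activity fraction.  Needs at least 4 doses; data with
    no dose dependence are flagged unidentifiable.
    """
    if variant not in ("wildtype", "residual"):
        raise ValueError("variant must be 'wildtype' or 'residual'")
    n_params = 4 if variant == "residual" else 3
    if dose.conc.size < max(4, n_params):
        raise ValueError("need at least 4 doses for identifiability")
    act = dose.activity
    if np.ptp(act) < 1e-3:
        return HillFit(float(np.mean(act)), float("nan"), float("nan"),
                       0.0, variant, None, False, False,
                       "no dose dependence: K_D unidentifiable")

    a0_0 = float(np.max(act))
    pos = dose.conc[dose.conc > 0]
    k0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    rho0 = float(np.clip(np.min(act) / max(a0_0, 1e-9), 1e-3, 0.999))

    if variant == "wildtype":
        def curve(L, a0, kd, h):
            return hill_activity(L, a0, kd, h, 0.0)
        p0 = [a0_0, k0, 1.0]
        bounds = ([1e-9, 1e-9, 0.05], [10.0, 1e9, 20.0])
    else:
        def curve(L, a0, kd, h, rho):
            return hill_activity(L, a0, kd, h, rho)
        p0 = [a0_0, k0, 1.0, rho0]
        bounds = ([1e-9, 1e-9, 0.05, 0.0], [10.0, 1e9, 20.0, 1.0])

    try:
        popt, _ = optimize.curve_fit(curve, dose.conc, act, p0=p0,
                                     bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:
        return HillFit(float("nan"), float("nan"), float("nan"), float("nan"),
                       variant, None, False, True, str(exc))
    rho = float(popt[3]) if variant == "residual" else 0.0
    fit = HillFit(a0=float(popt[0]), k_d=float(popt[1]), h=float(popt[2]),
                  rho=rho, variant=variant, residuals=None, converged=True,
                  identifiable=True)
    fit.residuals = act - fit.predict(dose.conc)
    return fit
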