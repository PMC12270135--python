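"""Agent-based run-and-tumble simulation in a linear attractant gradient.

Cells are modelled as point agents in a finite 2-D channel: solid side
walls (specular reflection), open ends connected to infinite reservoirs
(an agent crossing an end is absorbed and a fresh agent is respawned at a
random end, conserving the population), and a linear attractant profile
along the channel axis ``+y``.

Motility is a two-state process.  A running agent advances at its run
speed along its heading, which diffuses rotationally; it switches to
tumbling as a Poisson process with rate ``lambda_RT = TB / (tau_T (1 -
TB))``, where ``TB`` is the tumbling bias prescribed by the response model
at the locally sensed concentration.  A tumbling agent does not move and
resumes running with rate ``1 / tau_T``, drawing a fresh uniform heading.
These rates make the stationary fraction of time spent tumbling exactly
``TB`` in a uniform environment, which is the quantity the response models
specify.

The population drift along the gradient is the duration-weighted mean of
the per-trajectory mean y-velocities, the same estimator applied to
experimental tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .response import (
    EPS_TB,
    Phenotype,
    PhenotypeTable,
    ResponseModel,
    effective_concentration,
    tumbling_bias_response,
    update_adaptation,
)

__all__ = [
    "GradientChannel",
    "SimConfig",
    "AgentState",
    "SimulationResult",
    "initialize_population",
    "step_agent",
    "run_simulation",
    "measure_drift",
    "weighted_drift",
]


@dataclass(frozen=True)
class GradientChannel:
    """Rectangular channel with a linear attractant profile along ``+y``.

    ``c(y) = c_low + (c_high - c_low) * y / length`` (µM), constant in x.
    ``length`` and ``width`` are in µm.
    """

    length: float = 2000.0
    width: float = 1000.0
    c_low: float = 0.0
    c_high: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("channel dimensions must be positive")
        if self.c_low < 0 or self.c_high < 0:
            raise ValueError("concentrations must be non-negative")

    def concentration(self, y):
        frac = np.clip(np.asarray(y, dtype=float) / self.length, 0.0, 1.0)
        return self.c_low + (self.c_high - self.c_low) * frac


@dataclass
class SimConfig:
    """Simulation parameters.

    Attributes
    ----------
    dt : integration time step (s); must satisfy ``dt <= tumble_time / 5``.
    t_max : maximum residence time of a single trajectory (s); trajectories
        still open after ``t_max`` are closed and a new one started in place.
    n_agents : number of concurrently active agents (the respawn rule keeps
        this constant, so at least ``n_agents`` trajectories are collected).
    tumble_time : mean tumble duration ``tau_T`` (s).
    rot_diffusion : rotational diffusion coefficient during runs (rad^2/s).
    tau_adapt : slow-adaptation time constant (s); ``inf`` disables it.
    run_speed, speed_std : run-speed distribution (µm/s); a positive
        ``speed_std`` samples per-cell speeds from a normal truncated at 0.
    adapt_init : "zero" starts agents unadapted (memory m = 0, appropriate
        for cells freshly introduced from an unstimulated culture); "local"
        starts them fully adapted to the concentration at their position.
    closed_ends : reflect at the channel ends instead of absorb/respawn
        (used for uniform-environment track generation).
    record : keep per-step positions and motility states (memory scales as
        ``n_agents * t_total / dt``; intended for moderate populations).
    total_time : total simulated time (s); defaults to ``t_max``.
    """

    dt: float = 0.02
    t_max: float = 60.0
    n_agents: int = 15_000
    tumble_time: float = 0.2
    rot_diffusion: float = 0.15
    tau_adapt: float = math.inf
    seed: int = 0
    run_speed: float = 25.0
    speed_std: float = 0.0
    adapt_init: str = "zero"
    closed_ends: bool = False
    record: bool = False
    total_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.tumble_time / 5.0 + 1e-12:
            raise ValueError("dt must not exceed tumble_time / 5")
        if self.n_agents < 1:
            raise ValueError("n_agents must be at least 1")
        if self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be positive (inf disables)")
        if self.adapt_init not in ("zero", "local"):
            raise ValueError("adapt_init must be 'zero' or 'local'")

    @property
    def adaptation_enabled(self) -> bool:
        return math.isfinite(self.tau_adapt)


@dataclass
class AgentState:
    """State of one simulated cell (scalar API)."""

    x: float
    y: float
    theta: float
    running: bool
    phenotype: Phenotype
    m: float = 0.0
    t: float = 0.0


# ---------------------------------------------------------------------------
# initialisation


def initialize_population(config: SimConfig, model: ResponseModel,
                          channel: GradientChannel,
                          rng: Optional[np.random.Generator] = None) -> List[AgentState]:
    """Draw the initial population: positions uniform over the channel,
    headings uniform on [0, 2pi), all agents running, phenotypes sampled
    once per agent.  Reproducible given ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_agents
    phen = model.sample_phenotypes(n, rng, speed=config.run_speed,
                                   speed_std=config.speed_std)
    x = rng.uniform(0.0, channel.width, n)
    y = rng.uniform(0.0, channel.length, n)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    if config.adaptation_enabled and config.adapt_init == "local":
        m = np.asarray(channel.concentration(y), dtype=float)
    else:
        m = np.zeros(n)
    return [
        AgentState(x=float(x[i]), y=float(y[i]), theta=float(theta[i]),
                   running=True, phenotype=phen.row(i), m=float(m[i]), t=0.0)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# scalar step (reference semantics; the engine below vectorises the same
# update over the whole population)


def step_agent(agent: AgentState, channel: GradientChannel, model: ResponseModel,
               dt: float, rng: np.random.Generator, *,
               tumble_time: float = 0.2, rot_diffusion: float = 0.15,
               tau_adapt: float = math.inf, adapt_init: str = "zero") -> AgentState:
    """Advance one agent by one time step and return its new state.

    Running agents move ballistically along their heading, rotate by a
    Gaussian angle of variance ``2 * rot_diffusion * dt`` and switch to
    tumbling with probability ``lambda_RT * dt``.  Tumbling agents stay put
    and switch to running with probability ``dt / tumble_time``, drawing a
    fresh uniform heading.  Side walls reflect; crossing an open end absorbs
    the agent and respawns a new one at a random end.
    """
    a = replace(agent)
    if a.running:
        a.x += a.phenotype.speed * dt * math.cos(a.theta)
        a.y += a.phenotype.speed * dt * math.sin(a.theta)
        if rot_diffusion > 0:
            a.theta += rng.normal(0.0, math.sqrt(2.0 * rot_diffusion * dt))
        # specular reflection on the side walls
        if a.x < 0.0:
            a.x, a.theta = -a.x, math.pi - a.theta
        elif a.x > channel.width:
            a.x, a.theta = 2.0 * channel.width - a.x, math.pi - a.theta
        if a.y < 0.0 or a.y > channel.length:
            return _respawn_scalar(a, channel, model, rng, tau_adapt, adapt_init,
                                   t=agent.t + dt)
    conc = float(channel.concentration(a.y))
    sensed = float(effective_concentration(conc, a.m)) if math.isfinite(tau_adapt) else conc
    tb = float(tumbling_bias_response(model, sensed, a.phenotype))
    if tb >= 1.0 - EPS_TB:
        raise ValueError("tumbling bias too close to 1: run->tumble rate undefined")
    if a.running:
        lam_rt = tb / (tumble_time * (1.0 - tb))
        if rng.uniform() < min(lam_rt * dt, 1.0):
            a.running = False
    else:
        if rng.uniform() < dt / tumble_time:
            a.running = True
            a.theta = rng.uniform(0.0, 2.0 * math.pi)
    if math.isfinite(tau_adapt):
        a.m = float(update_adaptation(a.m, conc, dt, tau_adapt))
    a.theta %= 2.0 * math.pi
    a.t = agent.t + dt
    return a


def _respawn_scalar(a: AgentState, channel: GradientChannel, model: ResponseModel,
                    rng: np.random.Generator, tau_adapt: float, adapt_init: str,
                    t: float) -> AgentState:
    bottom = rng.uniform() < 0.5
    y = 0.0 if bottom else channel.length
    x = rng.uniform(0.0, channel.width)
    theta = rng.uniform(0.0, math.pi) if bottom else rng.uniform(math.pi, 2.0 * math.pi)
    phen = model.sample_phenotypes(1, rng, speed=a.phenotype.speed).row(0)
    m = float(channel.concentration(y)) if (
        math.isfinite(tau_adapt) and adapt_init == "local") else 0.0
    return AgentState(x=x, y=y, theta=theta, running=True, phenotype=phen, m=m, t=t)


# ---------------------------------------------------------------------------
# results


@dataclass
class SimulationResult:
    """Trajectory ensemble summary produced by :func:`run_simulation`.

    ``dy``, ``duration`` and ``tumble_time`` are per-trajectory arrays (net
    y-displacement, residence time, time spent tumbling).  When the run was
    recorded, ``positions`` has shape ``(n_samples, n_agents, 2)``,
    ``running_states[k, i]`` is agent ``i``'s state during the interval
    ``[k dt, (k+1) dt)`` and ``traj_table`` maps trajectories to (agent,
    first sample, last sample) triples.
    """

    dy: np.ndarray
    duration: np.ndarray
    tumble_time: np.ndarray
    drift: float
    drift_sem: float
    config: SimConfig
    model_name: str
    gradient: tuple
    seed: int
    positions: Optional[np.ndarray] = None
    running_states: Optional[np.ndarray] = None
    traj_table: Optional[np.ndarray] = None
    phenotypes: Optional[PhenotypeTable] = None

    @property
    def n_trajectories(self) -> int:
        return int(self.dy.shape[0])

    @property
    def tumble_fraction(self) -> float:
        """Pooled fraction of time spent tumbling (duration-weighted)."""
        return float(np.sum(self.tumble_time) / np.sum(self.duration))

    @property
    def drift_per_trajectory(self) -> tuple:
        """Unweighted ensemble mean of the per-trajectory drift velocities.

        ``(mean of V_i, SEM)`` with ``V_i = dy_i / T_i``, each cell
        residency counted once.  This is the population-drift readout of
        the simulation study: the duration-weighted estimator measures the
        net particle flux, which vanishes in steady state for any motility
        model whose rates depend only on the current position (see the
        methods note), whereas the per-residency mean captures the real
        transport asymmetry — cells entering against the gradient stall in
        the high-tumbling region while cells riding up it exit cleanly.
        """
        v = self.dy / self.duration
        return float(np.mean(v)), float(np.std(v, ddof=1) / math.sqrt(v.size))

    def to_dataframe(self):
        """Recorded ensemble as a tidy trajectory table.

        Columns: traj_id, frame, t_s, x_um, y_um, state, phenotype_id.
        Requires ``record=True``.
        """
        import pandas as pd

        if self.positions is None:
            raise ValueError("simulation was not recorded; set record=True")
        frames = []
        dt = self.config.dt
        for tid, (agent, s0, s1) in enumerate(self.traj_table):
            n = s1 - s0 + 1
            if n < 2:
                continue
            state = np.empty(n, dtype=object)
            state[:-1] = np.where(self.running_states[s0:s1, agent], "run", "tumble")
            state[-1] = state[-2]  # final sample: no following interval
            frames.append(pd.DataFrame({
                "traj_id": tid,
                "frame": np.arange(n),
                "t_s": (s0 + np.arange(n)) * dt,
                "x_um": self.positions[s0:s1 + 1, agent, 0],
                "y_um": self.positions[s0:s1 + 1, agent, 1],
                "state": state,
                "phenotype_id": int(agent),
            }))
        return pd.concat(frames, ignore_index=True)


def weighted_drift(velocities: np.ndarray, durations: np.ndarray):
    """Duration-weighted mean drift and its standard error.

    ``V_chem = sum_i V_i T_i / sum_i T_i``.  The SEM uses the
    duration-weighted variance with the effective number of trajectories
    ``(sum T)^2 / sum T^2``.
    """
    v = np.asarray(velocities, dtype=float)
    t = np.asarray(durations, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 trajectories")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    wsum = float(np.sum(t))
    vchem = float(np.sum(v * t) / wsum)
    var = float(np.sum(t * (v - vchem) ** 2) / wsum)
    n_eff = wsum ** 2 / float(np.sum(t ** 2))
    sem = math.sqrt(var / n_eff)
    return vchem, sem


def measure_drift(dy: np.ndarray, durations: np.ndarray):
    """Drift from per-trajectory net y-displacements and residence times.

    With ``V_i = dy_i / T_i`` the duration-weighted mean reduces to the
    total displacement over the total time, ``sum dy_i / sum T_i``.
    """
    dy = np.asarray(dy, dtype=float)
    t = np.asarray(durations, dtype=float)
    return weighted_drift(dy / t, t)


# ---------------------------------------------------------------------------
# vectorised engine


def run_simulation(config: SimConfig, model: ResponseModel,
                   channel: GradientChannel) -> SimulationResult:
    """Simulate the population and return the trajectory ensemble.

    Each residency between entry into and exit from the channel (or
    ``t_max`` inside it) is one trajectory; the active-agent count is
    conserved throughout (absorption triggers respawn), so at least
    ``n_agents`` trajectories are collected.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_agents
    dt = config.dt
    total = config.total_time if config.total_time is not None else config.t_max
    n_steps = int(round(total / dt))
    adapt = config.adaptation_enabled

    phen = model.sample_phenotypes(n, rng, speed=config.run_speed,
                                   speed_std=config.speed_std)
    x = rng.uniform(0.0, channel.width, n)
    y = rng.uniform(0.0, channel.length, n)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    running = np.ones(n, dtype=bool)
    if adapt and config.adapt_init == "local":
        m = np.asarray(channel.concentration(y), dtype=float)
    else:
        m = np.zeros(n)

    # per-open-trajectory bookkeeping
    t_start = np.zeros(n)
    y_start = y.copy()
    tumble_acc = np.zeros(n)
    start_sample = np.zeros(n, dtype=np.int64)

    out_dy: list = []
    out_dur: list = []
    out_tumble: list = []
    out_table: list = []  # (agent, first sample, last sample)

    record = config.record
    if record:
        positions = np.empty((n_steps + 1, n, 2))
        positions[0, :, 0] = x
        positions[0, :, 1] = y
        states = np.empty((n_steps, n), dtype=bool)
    else:
        positions = states = None

    sqrt_rot = math.sqrt(2.0 * config.rot_diffusion * dt)
    p_tr = dt / config.tumble_time

    def close(mask: np.ndarray, t_end: float, end_sample: int,
              y_end: np.ndarray) -> None:
        dur = t_end - t_start[mask]
        keep = dur > 0
        idx = np.nonzero(mask)[0][keep]
        if idx.size == 0:
            return
        out_dy.append(y_end[mask][keep] - y_start[idx])
        out_dur.append(t_end - t_start[idx])
        out_tumble.append(tumble_acc[idx])
        if record:
            out_table.append(np.column_stack(
                [idx, start_sample[idx], np.full(idx.size, end_sample)]))

    for k in range(n_steps):
        t_now = k * dt
        was_running = running.copy()
        tumble_acc[~was_running] += dt
        if record:
            states[k] = was_running

        y_prev = y.copy()
        # ballistic advance of runners, then rotational diffusion
        step = np.where(was_running, phen.speed * dt, 0.0)
        x += step * np.cos(theta)
        y += step * np.sin(theta)
        if config.rot_diffusion > 0:
            dtheta = rng.normal(0.0, sqrt_rot, n)
            theta = np.where(was_running, theta + dtheta, theta)

        # specular reflection at the side walls
        left = x < 0.0
        right = x > channel.width
        if left.any() or right.any():
            x = np.where(left, -x, x)
            x = np.where(right, 2.0 * channel.width - x, x)
            flip = left | right
            theta = np.where(flip, math.pi - theta, theta)

        if config.closed_ends:
            low = y < 0.0
            high = y > channel.length
            if low.any() or high.any():
                y = np.where(low, -y, y)
                y = np.where(high, 2.0 * channel.length - y, y)
                theta = np.where(low | high, -theta, theta)
            absorbed = np.zeros(n, dtype=bool)
        else:
            absorbed = (y < 0.0) | (y > channel.length)
            if absorbed.any():
                # close at the last in-channel sample: the partial exit step
                # belongs to the reservoir, not to the trajectory
                close(absorbed, t_now, k, y_prev)
                n_out = int(absorbed.sum())
                bottom = rng.uniform(size=n_out) < 0.5
                y[absorbed] = np.where(bottom, 0.0, channel.length)
                x[absorbed] = rng.uniform(0.0, channel.width, n_out)
                theta[absorbed] = np.where(
                    bottom,
                    rng.uniform(0.0, math.pi, n_out),
                    rng.uniform(math.pi, 2.0 * math.pi, n_out),
                )
                running[absorbed] = True
                fresh = model.sample_phenotypes(n_out, rng, speed=config.run_speed,
                                                speed_std=config.speed_std)
                phen.tb0[absorbed] = fresh.tb0
                phen.k[absorbed] = fresh.k
                phen.rho[absorbed] = fresh.rho
                phen.speed[absorbed] = fresh.speed
                m[absorbed] = (channel.concentration(y[absorbed])
                               if adapt and config.adapt_init == "local" else 0.0)
                t_start[absorbed] = t_now + dt
                y_start[absorbed] = y[absorbed]
                tumble_acc[absorbed] = 0.0
                start_sample[absorbed] = k + 1

        eligible = ~absorbed
        conc = np.asarray(channel.concentration(y), dtype=float)
        sensed = effective_concentration(conc, m) if adapt else conc
        tb = np.clip(np.asarray(model.tumbling_bias(sensed, phen), dtype=float),
                     0.0, 1.0 - EPS_TB)
        lam_rt = tb / (config.tumble_time * (1.0 - tb))
        u = rng.uniform(size=n)
        to_tumble = was_running & eligible & (u < np.minimum(lam_rt * dt, 1.0))
        to_run = (~was_running) & eligible & (u < p_tr)
        running[to_tumble] = False
        if to_run.any():
            running[to_run] = True
            theta[to_run] = rng.uniform(0.0, 2.0 * math.pi, int(to_run.sum()))
        if adapt:
            m = np.where(eligible, update_adaptation(m, conc, dt, config.tau_adapt), m)

        # close trajectories that have been resident for t_max
        expired = (t_now + dt - t_start >= config.t_max - 1e-12) & eligible
        if expired.any():
            close(expired, t_now + dt, k + 1, y)
            t_start[expired] = t_now + dt
            y_start[expired] = y[expired]
            tumble_acc[expired] = 0.0
            start_sample[expired] = k + 1

        theta %= 2.0 * math.pi
        if record:
            positions[k + 1, :, 0] = x
            positions[k + 1, :, 1] = y

    still_open = t_start < total - 1e-12
    close(still_open, total, n_steps, y)

    dy = np.concatenate(out_dy) if out_dy else np.empty(0)
    dur = np.concatenate(out_dur) if out_dur else np.empty(0)
    tumble = np.concatenate(out_tumble) if out_tumble else np.empty(0)
    drift, sem = measure_drift(dy, dur)
    return SimulationResult(
        dy=dy, duration=dur, tumble_time=tumble, drift=drift, drift_sem=sem,
        config=config, model_name=model.name,
        gradient=(channel.c_low, channel.c_high), seed=config.seed,
        positions=positions, running_states=states,
        traj_table=(np.concatenate(out_table) if record and out_table else None),
        phenotypes=phen if record else None,
    )
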