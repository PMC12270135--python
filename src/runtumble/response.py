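"""Concentration -> tumbling-bias response models.

Adaptation-deficient (``cheR``-less) E. coli cannot perform temporal
comparisons; their tumbling bias (fraction of time spent tumbling) is
instead a direct, quasi-instantaneous function of the locally experienced
attractant concentration.  Two population models of this dependence are
implemented:

* :class:`HomogeneousResponse` — every cell follows the same declining Hill
  curve ``TB(L) = TB_inf + (TB0 - TB_inf) * K^H / (L^H + K^H)``, with a
  non-zero residual bias ``TB_inf`` at saturating attractant.

* :class:`HeterogeneousResponse` — each cell responds *sharply* (steep
  cell-level Hill exponent) but at its own sensitivity ``K_i`` drawn from a
  log-normal distribution, with a distributed basal bias ``TB0_i`` and a
  shared residual fraction ``rho``.  The population-mean response is then a
  shallow sigmoid even though individual cells are nearly switch-like.

The module also houses the hour-scale slow-adaptation update (a linear
relaxation of a concentration "memory" that is subtracted from the sensed
concentration) and fitting routines for both model kinds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "Phenotype",
    "PhenotypeTable",
    "BetaBasal",
    "EmpiricalBasal",
    "HomogeneousResponse",
    "HeterogeneousResponse",
    "TBResponseData",
    "ResponseFit",
    "tumbling_bias_response",
    "predict_population_tb",
    "population_mean_tb",
    "fit_response_model",
    "update_adaptation",
    "effective_concentration",
]

#: Phenotypes with tumbling bias above 1 - EPS_TB are rejected (the
#: run->tumble rate TB/(tau_T*(1-TB)) diverges at TB = 1).
EPS_TB = 1e-6


def hill_inhibition(conc, k: float, h: float):
    """Declining Hill factor ``K^H / (L^H + K^H)``, computed stably.

    Equals 1 at ``L = 0``, 1/2 at ``L = K`` (for any ``H``) and tends to 0 as
    ``L -> inf``.  Evaluated through a logistic in log-concentration so large
    exponents do not overflow.
    """
    conc = np.asarray(conc, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(conc)
        logk = np.log(k)
    # expit(-inf) = 0 handles L = 0 (factor 1) via the -log ratio below
    out = expit(np.asarray(h, dtype=float) * (logk - logc))
    return np.where(conc <= 0.0, 1.0, out)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class Phenotype:
    """Per-cell motility parameters.

    Attributes
    ----------
    tb0 : basal tumbling bias (fraction of time tumbling at zero attractant).
    k : sensitivity, the concentration (µM) at which the cell's response is
        half-saturated.
    rho : residual fraction — the tumbling bias retained at saturating
        attractant is ``rho * tb0``.
    speed : run speed in µm/s.
    """

    tb0: float
    k: float
    rho: float
    speed: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho * self.tb0 <= self.tb0 <= 1.0 - EPS_TB):
            raise ValueError(
                f"invalid phenotype biases tb0={self.tb0}, rho={self.rho}"
            )
        if self.k <= 0 or self.speed <= 0:
            raise ValueError("phenotype k and speed must be positive")


@dataclass
class PhenotypeTable:
    """Column-oriented phenotypes for a whole simulated population."""

    tb0: np.ndarray
    k: np.ndarray
    rho: np.ndarray
    speed: np.ndarray

    def __len__(self) -> int:
        return self.tb0.shape[0]

    def row(self, i: int) -> Phenotype:
        return Phenotype(
            float(self.tb0[i]), float(self.k[i]), float(self.rho[i]), float(self.speed[i])
        )


# ---------------------------------------------------------------------------
# basal-bias distributions (heterogeneous model)


@dataclass(frozen=True)
class BetaBasal:
    """Beta(a, b) distribution of basal tumbling bias on [0, 1]."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shape parameters must be positive")

    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.clip(rng.beta(self.a, self.b, size=n), 0.0, 1.0 - EPS_TB)

    def ppf(self, q) -> np.ndarray:
        return np.clip(stats.beta.ppf(q, self.a, self.b), 0.0, 1.0 - EPS_TB)


@dataclass(frozen=True)
class EmpiricalBasal:
    """Basal-bias distribution resampled from a measured tumbling-bias sample."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("empirical basal sample must be a non-empty 1-D array")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("basal biases must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0 - EPS_TB))

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.values, size=n, replace=True)

    def ppf(self, q) -> np.ndarray:
        return np.quantile(self.values, q)


BasalDistribution = Union[BetaBasal, EmpiricalBasal]


# ---------------------------------------------------------------------------
# response models


@dataclass(frozen=True)
class HomogeneousResponse:
    """Population-identical Hill response of tumbling bias to attractant.

    ``TB(L) = tb_inf + (tb0 - tb_inf) * k_r^h_r / (L^h_r + k_r^h_r)``
    """

    tb0: float
    tb_inf: float
    k_r: float
    h_r: float
    run_speed: float = 25.0

    name = "homogeneous"

    def __post_init__(self) -> None:
        if not (0.0 <= self.tb_inf <= self.tb0 <= 1.0 - EPS_TB):
            raise ValueError("require 0 <= tb_inf <= tb0 < 1")
        if self.k_r <= 0 or self.h_r <= 0:
            raise ValueError("k_r and h_r must be positive")

    def tumbling_bias(self, conc, phenotypes: Optional[PhenotypeTable] = None):
        tb = self.tb_inf + (self.tb0 - self.tb_inf) * hill_inhibition(
            conc, self.k_r, self.h_r
        )
        if phenotypes is not None:
            tb = np.broadcast_to(tb, np.broadcast_shapes(np.shape(tb), (len(phenotypes),))).copy()
        return tb

    def sample_phenotypes(self, n: int, rng: np.random.Generator,
                          speed: float | None = None,
                          speed_std: float = 0.0) -> PhenotypeTable:
        """Degenerate sampling: every cell carries the shared parameters."""
        v = self.run_speed if speed is None else speed
        speeds = _sample_speeds(n, v, speed_std, rng)
        rho = self.tb_inf / self.tb0 if self.tb0 > 0 else 0.0
        return PhenotypeTable(
            tb0=np.full(n, self.tb0),
            k=np.full(n, self.k_r),
            rho=np.full(n, rho),
            speed=speeds,
        )


@dataclass(frozen=True)
class HeterogeneousResponse:
    """Sharp per-cell responses at log-normally distributed sensitivities.

    Cell ``i`` responds as ``TB_i(L) = tb0_i * (rho + (1 - rho) *
    K_i^Hc / (L^Hc + K_i^Hc))`` with ``log K_i ~ N(mu_log_k, sigma_log_k^2)``
    and ``tb0_i`` drawn from ``basal``.  ``hill_cell`` is deliberately steep
    (default 10): individual cells are nearly switch-like, and the breadth of
    the population response comes from the spread of ``K_i``.
    """

    mu_log_k: float
    sigma_log_k: float
    rho: float
    basal: BasalDistribution
    hill_cell: float = 10.0
    run_speed: float = 25.0

    name = "heterogeneous"

    def __post_init__(self) -> None:
        if self.sigma_log_k <= 0:
            raise ValueError("sigma_log_k must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.hill_cell <= 0:
            raise ValueError("hill_cell must be positive")

    def tumbling_bias(self, conc, phenotypes: Optional[PhenotypeTable] = None):
        if phenotypes is None:
            raise ValueError(
                "heterogeneous response requires sampled phenotypes; "
                "call sample_phenotypes() first"
            )
        factor = self.rho + (1.0 - self.rho) * hill_inhibition(
            conc, phenotypes.k, self.hill_cell
        )
        return phenotypes.tb0 * factor

    def sample_phenotypes(self, n: int, rng: np.random.Generator,
                          speed: float | None = None,
                          speed_std: float = 0.0) -> PhenotypeTable:
        v = self.run_speed if speed is None else speed
        return PhenotypeTable(
            tb0=self.basal.sample(n, rng),
            k=np.exp(rng.normal(self.mu_log_k, self.sigma_log_k, size=n)),
            rho=np.full(n, self.rho),
            speed=_sample_speeds(n, v, speed_std, rng),
        )


ResponseModel = Union[HomogeneousResponse, HeterogeneousResponse]


def _sample_speeds(n: int, mean: float, std: float, rng: np.random.Generator) -> np.ndarray:
    if std <= 0:
        return np.full(n, float(mean))
    v = rng.normal(mean, std, size=n)
    # truncate at zero by resampling the (rare) non-positive draws
    bad = v <= 0
    while np.any(bad):
        v[bad] = rng.normal(mean, std, size=int(bad.sum()))
        bad = v <= 0
    return v


def tumbling_bias_response(model: ResponseModel, conc,
                           phenotype: Phenotype | PhenotypeTable | None = None):
    """Tumbling bias of ``model`` at concentration ``conc`` (µM).

    For the homogeneous model ``phenotype`` is ignored; for the heterogeneous
    model a :class:`Phenotype` (or table) is required.
    """
    if isinstance(phenotype, Phenotype):
        table = PhenotypeTable(
            tb0=np.array([phenotype.tb0]),
            k=np.array([phenotype.k]),
            rho=np.array([phenotype.rho]),
            speed=np.array([phenotype.speed]),
        )
        out = model.tumbling_bias(conc, table)
        return float(out[0]) if np.ndim(out) and out.shape == (1,) else out
    return model.tumbling_bias(conc, phenotype)


# ---------------------------------------------------------------------------
# population-level predictions


def predict_population_tb(model: HeterogeneousResponse, conc: float,
                          n_mc: int = 10_000,
                          rng: np.random.Generator | int | None = None):
    """Monte-Carlo population-mean tumbling bias and its sampled distribution.

    Returns ``(mean, samples)`` where ``samples`` is the per-cell tumbling
    bias of ``n_mc`` phenotypes drawn from the model at concentration
    ``conc``.  At ``conc = 0`` the distribution coincides with the basal-bias
    distribution.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000 for a stable estimate")
    rng = np.random.default_rng(rng)
    phen = model.sample_phenotypes(n_mc, rng)
    tb = model.tumbling_bias(conc, phen)
    return float(np.mean(tb)), tb


def population_mean_tb(model: ResponseModel, conc, n_quad: int = 80):
    """Population-mean tumbling bias by Gauss–Hermite quadrature.

    For the heterogeneous model the basal bias and the sensitivity are
    independent, so the mean factorises:
    ``E[TB] = E[tb0] * (rho + (1 - rho) * E_K[hill(conc, K)])``
    with the expectation over ``log K ~ N(mu, sigma^2)`` evaluated by
    Gauss–Hermite quadrature.  For the homogeneous model this is simply the
    Hill curve itself.
    """
    if isinstance(model, HomogeneousResponse):
        return model.tumbling_bias(conc)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    log_k = model.mu_log_k + model.sigma_log_k * nodes
    w = weights / math.sqrt(2.0 * math.pi)
    conc = np.asarray(conc, dtype=float)
    scalar = conc.ndim == 0
    conc2 = np.atleast_1d(conc)[:, None]
    hill = hill_inhibition(conc2, np.exp(log_k)[None, :], model.hill_cell)
    e_hill = hill @ w
    mean = model.basal.mean() * (model.rho + (1.0 - model.rho) * e_hill)
    return float(mean[0]) if scalar else mean


# ---------------------------------------------------------------------------
# measured tumbling-bias data and fitting


@dataclass
class TBResponseData:
    """Tumbling-bias measurements across attractant concentrations.

    Attributes
    ----------
    conc : strictly increasing concentrations (µM).
    mean_tb : per-concentration population-mean tumbling bias.
    samples : optional per-concentration arrays of per-trajectory tumbling
        biases (for distribution fitting).
    weights : optional per-concentration arrays of trajectory durations used
        to weight the samples.
    """

    conc: np.ndarray
    mean_tb: np.ndarray
    samples: Optional[dict] = None
    weights: Optional[dict] = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.mean_tb = np.asarray(self.mean_tb, dtype=float)
        if self.conc.ndim != 1 or self.conc.shape != self.mean_tb.shape:
            raise ValueError("conc and mean_tb must be matching 1-D arrays")
        if np.any(np.diff(self.conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any((self.mean_tb < 0) | (self.mean_tb > 1)):
            raise ValueError("tumbling biases must lie in [0, 1]")

    @classmethod
    def from_samples(cls, samples: dict, weights: Optional[dict] = None) -> "TBResponseData":
        """Build from ``{concentration: per-cell tumbling-bias array}``.

        Per-concentration means are duration-weighted when ``weights`` maps
        the same concentrations to duration arrays.
        """
        conc = np.array(sorted(samples))
        means = []
        for c in conc:
            v = np.asarray(samples[c], dtype=float)
            w = None if weights is None else np.asarray(weights[c], dtype=float)
            means.append(np.average(v, weights=w))
        return cls(conc=conc, mean_tb=np.array(means),
                   samples={float(c): np.asarray(samples[c], dtype=float) for c in conc},
                   weights=None if weights is None else
                   {float(c): np.asarray(weights[c], dtype=float) for c in conc})

    @classmethod
    def from_table(cls, df) -> "TBResponseData":
        """Build from a long table with columns conc_uM, tumbling_bias and
        (optionally) duration_s."""
        samples: dict = {}
        weights: dict = {}
        has_w = "duration_s" in df.columns
        for c, grp in df.groupby("conc_uM"):
            samples[float(c)] = grp["tumbling_bias"].to_numpy(dtype=float)
            if has_w:
                weights[float(c)] = grp["duration_s"].to_numpy(dtype=float)
        return cls.from_samples(samples, weights if has_w else None)


@dataclass
class ResponseFit:
    """Result of fitting a response model to tumbling-bias data."""

    model: Optional[ResponseModel]
    kind: str
    residuals: Optional[np.ndarray]
    converged: bool
    identifiable: bool
    message: str = ""
    objective: float = float("nan")


def _weighted_quantiles(values: np.ndarray, q: np.ndarray,
                        weights: Optional[np.ndarray]) -> np.ndarray:
    if weights is None:
        return np.quantile(values, q)
    order = np.argsort(values)
    v = values[order]
    w = np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= np.sum(w)
    return np.interp(q, cw, v)


_DECILES = np.arange(1, 10) / 10.0


def _fit_homogeneous(data: TBResponseData) -> ResponseFit:
    tb = data.mean_tb
    if np.ptp(tb) < 0.02:
        return ResponseFit(None, "homogeneous", None, False, False,
                           "no concentration dependence: K_r unidentifiable")

    def curve(L, tb0, tb_inf, k_r, h_r):
        return tb_inf + (tb0 - tb_inf) * hill_inhibition(L, k_r, h_r)

    pos = data.conc[data.conc > 0]
    k0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    p0 = [float(np.max(tb)), float(np.min(tb)), k0, 1.0]
    bounds = ([0.0, 0.0, 1e-9, 0.05], [1.0, 1.0, 1e9, 20.0])
    try:
        popt, _ = optimize.curve_fit(curve, data.conc, tb, p0=p0, bounds=bounds,
                                     maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        return ResponseFit(None, "homogeneous", None, False, True, str(exc))
    tb0, tb_inf, k_r, h_r = popt
    if tb_inf > tb0:  # enforce the declining orientation
        tb0, tb_inf = tb_inf, tb0
    model = HomogeneousResponse(tb0=float(tb0), tb_inf=float(tb_inf),
                                k_r=float(k_r), h_r=float(h_r))
    resid = tb - model.tumbling_bias(data.conc)
    return ResponseFit(model, "homogeneous", resid, True, True,
                       objective=float(np.sum(resid ** 2)))


def _fit_heterogeneous(data: TBResponseData, n_mc: int, seed: int,
                       hill_cell: float, maxiter: int) -> ResponseFit:
    if data.samples is None:
        raise ValueError("heterogeneous fitting needs per-concentration samples")
    if np.ptp(data.mean_tb) < 0.02:
        return ResponseFit(None, "heterogeneous", None, False, False,
                           "no concentration dependence: sensitivity unidentifiable")
    rng = np.random.default_rng(seed)
    # common random numbers: the same quantile draws at every objective
    # evaluation make the decile objective a smooth function of the
    # hyperparameters
    z = rng.standard_normal(n_mc)
    u = rng.uniform(0.0, 1.0, n_mc)

    concs = data.conc
    obs_dec = np.stack([
        _weighted_quantiles(data.samples[float(c)], _DECILES,
                            None if data.weights is None else data.weights[float(c)])
        for c in concs
    ])

    base = data.samples[float(concs[0])]
    m0, v0 = float(np.mean(base)), float(np.var(base))
    v0 = min(max(v0, 1e-4), m0 * (1 - m0) * 0.99)
    common = m0 * (1 - m0) / v0 - 1.0
    a0, b0 = max(m0 * common, 0.05), max((1 - m0) * common, 0.05)

    hi = data.samples[float(concs[-1])]
    rho0 = float(np.clip(np.mean(hi) / max(m0, 1e-6), 0.02, 0.9))
    pos = concs[concs > 0]
    mu0 = float(np.log(np.exp(np.mean(np.log(pos))))) if pos.size else 0.0

    def unpack(theta):
        mu, log_sig, logit_rho, log_a, log_b = theta
        return (mu, float(np.exp(log_sig)), float(expit(logit_rho)),
                float(np.exp(log_a)), float(np.exp(log_b)))

    def objective(theta):
        mu, sig, rho, a, b = unpack(theta)
        k = np.exp(mu + sig * z)
        tb0 = np.clip(stats.beta.ppf(u, a, b), 0.0, 1.0 - EPS_TB)
        sq = 0.0
        for i, c in enumerate(concs):
            tb = tb0 * (rho + (1 - rho) * hill_inhibition(c, k, hill_cell))
            pred = np.quantile(tb, _DECILES)
            sq += float(np.sum((pred - obs_dec[i]) ** 2))
        return sq

    theta0 = np.array([mu0, 0.0, float(np.log(rho0 / (1 - rho0))),
                       float(np.log(a0)), float(np.log(b0))])
    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-4,
                                     "fatol": 1e-8, "adaptive": True})
    mu, sig, rho, a, b = unpack(res.x)
    model = HeterogeneousResponse(mu_log_k=mu, sigma_log_k=sig, rho=rho,
                                  basal=BetaBasal(a, b), hill_cell=hill_cell)
    resid = data.mean_tb - population_mean_tb(model, concs)
    return ResponseFit(model, "heterogeneous", resid, bool(res.success) or
                       res.fun < objective(theta0), True, res.message,
                       objective=float(res.fun))


def fit_response_model(data: TBResponseData, kind: str = "homogeneous", *,
                       n_mc: int = 2000, seed: int = 0,
                       hill_cell: float = 10.0, maxiter: int = 4000) -> ResponseFit:
    """Fit a tumbling-bias response model to measured data.

    ``kind="homogeneous"`` performs nonlinear least squares of the Hill curve
    on the per-concentration mean biases (at least 4 concentrations).
    ``kind="heterogeneous"`` minimises the summed squared distance between
    the nine deciles of the predicted and observed per-concentration
    tumbling-bias distributions over the hyperparameters
    ``(mu_log_k, sigma_log_k, rho, a, b)``.

    Data with no concentration dependence are flagged unidentifiable rather
    than silently fitted.
    """
    if kind == "homogeneous":
        if data.conc.size < 4:
            raise ValueError("homogeneous fit needs at least 4 concentrations")
        return _fit_homogeneous(data)
    if kind == "heterogeneous":
        return _fit_heterogeneous(data, n_mc, seed, hill_cell, maxiter)
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# slow adaptation


def update_adaptation(m, conc, dt: float, tau_adapt: float):
    """One Euler step of the hour-scale adaptation memory.

    ``m' = m + dt * (L - m) / tau_adapt`` — a linear relaxation of the
    memory toward the local concentration, recovering exponential relaxation
    ``m(t) = L (1 - exp(-t/tau))`` in the ``dt -> 0`` limit.  An infinite
    ``tau_adapt`` disables adaptation (``m`` unchanged).
    """
    if tau_adapt <= 0:
        raise ValueError("tau_adapt must be positive (use inf to disable)")
    if math.isinf(tau_adapt):
        return m
    return m + dt * (np.asarray(conc, dtype=float) - m) / tau_adapt


def effective_concentration(conc, m):
    """Concentration actually sensed after subtracting the memory: ``max(L - m, 0)``."""
    return np.maximum(np.asarray(conc, dtype=float) - m, 0.0)
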