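"""Reference study conditions for an evolved, adaptation-deficient strain.

The package ships one canonical set of "R1-like" response parameters —
an evolved ``cheR`` deletion strain that tumbles without short-term
adaptation, responds to α-methyl-aspartate (MeAsp) with a declining
tumbling bias, and retains a residual bias at saturating attractant:

* :func:`r1_heterogeneous` — the heterogeneous-population truth: sharp
  per-cell responses (cell Hill exponent 10) at log-normally distributed
  sensitivities (median 100 µM, log-sd 1.2, reflecting a dose response
  shifted to somewhat higher concentrations than canonical wildtype MeAsp
  sensing), basal bias ~ Beta(2.5, 7.5) (mean 0.25, broad), shared
  residual fraction 0.15.

* :func:`r1_homogeneous` — the matched homogeneous model: a population
  Hill curve least-squares fitted to the heterogeneous population-mean
  response, so the two models agree on the mean tumbling bias at every
  concentration and differ only in their cell-to-cell structure.

* :func:`r1_tb_dataset` — a synthetic tumbling-bias measurement (per-cell
  samples at a panel of MeAsp concentrations) drawn from the
  heterogeneous truth, for fitting and recovery studies.

* :func:`r1_hill_truth` — the FRET dose-response truth of the residual
  variant (A0 = 1, K_D = 50 µM, H = 2, rho = 0.2).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .response import (
    BetaBasal,
    HeterogeneousResponse,
    HomogeneousResponse,
    TBResponseData,
    fit_response_model,
    population_mean_tb,
)

__all__ = [
    "r1_heterogeneous",
    "r1_homogeneous",
    "r1_tb_dataset",
    "r1_hill_truth",
    "R1_CONCENTRATIONS",
]

#: MeAsp panel (µM) used for the reference tumbling-bias measurement
R1_CONCENTRATIONS = (0.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)


def r1_heterogeneous(hill_cell: float = 10.0) -> HeterogeneousResponse:
    """The R1-like heterogeneous response truth.

    Basal bias ~ Beta(2.56, 5.44): mean 0.32 — the evolved strain tumbles
    more than its wildtype ancestor (~0.2) — with a broad spread.  The
    shared residual fraction 0.2 leaves a population-mean bias of ~0.064 at
    saturating MeAsp.  Sensitivities are log-normal with median 50 µM
    (log-sd 1.2), spanning roughly 5-500 µM for the central 95% of cells.
    """
    return HeterogeneousResponse(
        mu_log_k=math.log(50.0), sigma_log_k=1.2, rho=0.2,
        basal=BetaBasal(2.56, 5.44), hill_cell=hill_cell,
    )


@lru_cache(maxsize=None)
def _homogeneous_cached() -> HomogeneousResponse:
    het = r1_heterogeneous()
    conc = np.concatenate([[0.0], np.logspace(0, 4.5, 28)])
    mean_tb = np.asarray(population_mean_tb(het, conc))
    fit = fit_response_model(TBResponseData(conc=conc, mean_tb=mean_tb),
                             kind="homogeneous")
    if not fit.converged:
        raise RuntimeError("reference homogeneous fit failed")  # pragma: no cover
    return fit.model


def r1_homogeneous() -> HomogeneousResponse:
    """Homogeneous Hill model fitted to the heterogeneous population mean.

    Deterministic (quadrature means, no sampling), so the two reference
    models are matched in mean response by construction.
    """
    return _homogeneous_cached()


def r1_tb_dataset(n_per_conc: int = 500, seed: int = 0,
                  concentrations=R1_CONCENTRATIONS) -> TBResponseData:
    """Per-cell tumbling-bias samples drawn from the heterogeneous truth."""
    het = r1_heterogeneous()
    rng = np.random.default_rng(seed)
    samples = {}
    for c in concentrations:
        phen = het.sample_phenotypes(n_per_conc, rng)
        samples[float(c)] = np.asarray(het.tumbling_bias(c, phen))
    return TBResponseData.from_samples(samples)


def r1_hill_truth() -> dict:
    """FRET dose-response truth (residual variant) for recovery studies."""
    return {"a0": 1.0, "k_d": 50.0, "h": 2.0, "rho": 0.2}


def reference_dose_panel() -> np.ndarray:
    """8 log-spaced MeAsp doses (µM) spanning ~3 µM to 10 mM, bracketing
    the half-inhibitory concentration and reaching saturation."""
    return np.logspace(0.5, 4.0, 8)


def r1_drift_conditions() -> dict:
    """Gradient conditions of the simulated drift study: MeAsp source
    concentrations (µM) at the high end of the 2-mm channel."""
    return {"shallow": 100.0, "steep": 1000.0}
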