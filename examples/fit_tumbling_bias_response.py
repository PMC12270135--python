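"""Fit homogeneous and heterogeneous tumbling-bias response models.

Draws per-cell tumbling-bias samples at a panel of MeAsp concentrations
from the R1-like heterogeneous truth (sharp per-cell responses at
log-normally distributed sensitivities) and fits both model kinds, the
way measured dose-dependent tumbling data are analysed.
"""

import math

import runtumble as rt
from runtumble import reference

truth = reference.r1_heterogeneous()
data = reference.r1_tb_dataset(n_per_conc=500, seed=1)

hom = rt.fit_response_model(data, kind="homogeneous").model
print("homogeneous fit:   TB0=%.3f TB_inf=%.3f K_r=%.1f uM H_r=%.2f"
      % (hom.tb0, hom.tb_inf, hom.k_r, hom.h_r))

het_fit = rt.fit_response_model(data, kind="heterogeneous", seed=1)
het = het_fit.model
print("heterogeneous fit: median K=%.0f uM (truth %.0f), "
      "sigma_logK=%.2f (truth %.2f), rho=%.2f (truth %.2f)"
      % (math.exp(het.mu_log_k), math.exp(truth.mu_log_k),
         het.sigma_log_k, truth.sigma_log_k, het.rho, truth.rho))

# The homogeneous fit describes the population-mean response with a single
# shallow Hill curve; the heterogeneous fit explains the same means as a
# mixture of nearly switch-like cells with distributed sensitivities, and
# additionally reproduces the per-concentration tumbling-bias distributions.
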