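# Methods

`runtumble` models and analyses the chemotaxis of *E. coli* populations
that lack short-term (receptor-methylation) adaptation, such as evolved
`cheR` deletion strains.  In these cells the tumbling bias — the fraction
of time spent tumbling, `TB = t_tumble / (t_run + t_tumble)` — is treated
as a direct function of the locally experienced attractant concentration,
with no dependence on the cell's stimulus history on the seconds-to-
minutes timescale.

## Run-and-tumble model

Cells are point agents in a 2-D rectangular channel (length 2000 µm,
width 1000 µm) with a static linear attractant profile
`c(y) = c_low + (c_high − c_low) · y / L` along `+y`.  Motility is a
two-state process:

* **Run:** the agent advances at its run speed `v` (default 25 µm/s,
  constant per cell, optionally sampled from a truncated normal) along its
  heading θ, which diffuses with rotational diffusion coefficient
  `D_r = 0.15 rad²/s` (a typical value for swimming *E. coli*; the
  simulation is 2-D because the tracking data it emulates are 2-D
  projections).
* **Tumble:** the agent does not move; on resuming, a fresh heading is
  drawn uniformly on `[0, 2π)`.

Switching is Poissonian with rates

    λ_RT = TB / (τ_T (1 − TB)),      λ_TR = 1 / τ_T,

with mean tumble duration `τ_T = 0.2 s`.  This parameterization makes the
stationary tumble-time fraction exactly `TB` in a uniform environment —
`TB` is the quantity the response models specify, so the calibration is
exact by construction (and is verified as a stationarity oracle in the
tests).  Phenotypes with `TB ≥ 1 − 10⁻⁶` are rejected (the run→tumble
rate diverges).  Time is advanced by first-order Euler steps of
`Δt = 0.02 s` (≪ τ_T and the run durations); switching uses per-step
probabilities `λΔt` (clipped to 1), which preserves the stationary
fraction exactly at finite Δt.

Side walls reflect specularly.  The channel ends are open: an agent
crossing `y < 0` or `y > L` is absorbed and a new agent is respawned at a
uniformly chosen end, uniform lateral position, heading uniform over
inward directions, with a freshly drawn phenotype — conserving the active
population, as if both ends connected to identical infinite reservoirs.
Each residency between entry and exit (or `T_max = 60 s` inside) is one
trajectory; the final partial step of an absorbed agent belongs to the
reservoir and is not recorded.  A single seeded NumPy generator drives
all draws; runs are bit-reproducible given the seed.

## Response models

* **Homogeneous:** every cell follows
  `TB(L) = TB_∞ + (TB₀ − TB_∞) · K^H / (L^H + K^H)` — a declining Hill
  curve with a residual bias `TB_∞ > 0` at saturating attractant.
* **Heterogeneous:** cell *i* responds sharply
  (`H_c = 10` by default; a differentiable stand-in for a switch, the
  step being the `H_c → ∞` limit) at its own sensitivity `K_i`, with
  `TB_i(L) = TB₀ᵢ (ρ + (1 − ρ) K_i^{H_c} / (L^{H_c} + K_i^{H_c}))`.
  `log K_i` is normal (`µ_K`, `σ_K`) — positive support and two
  parameters make the log-normal the standard choice for such
  sensitivity spreads — the basal bias `TB₀ᵢ` is Beta-distributed (or
  resampled from data), and the residual fraction ρ is shared across
  cells, the minimal parameterization of the observed non-zero bias at
  high attractant.  Basal bias and sensitivity are drawn independently,
  so the population mean factorises and is computed by Gauss–Hermite
  quadrature (the Monte-Carlo and quadrature routes cross-check each
  other in the tests).

**Fitting.** The homogeneous model is fitted by bounded nonlinear least
squares on the per-concentration mean biases.  The heterogeneous model is
fitted by minimising the summed squared distance between the nine deciles
of the predicted and observed per-concentration tumbling-bias
distributions (robust, density-estimation-free) over
`(µ_K, σ_K, ρ, a, b)`, using common random numbers (fixed quantile draws)
so the objective is smooth, with Nelder–Mead.  Data without concentration
dependence are flagged unidentifiable rather than silently fitted.

**Reference conditions.** The shipped "R1-like" strain parameters are:
basal bias ~ Beta(2.56, 5.44) (mean 0.32 — an evolved strain noticeably
more tumbly than its ~0.2 wildtype ancestor — and broad), ρ = 0.2
(population-mean residual bias ≈ 0.064 at saturation), `µ_K = ln 50 µM`,
`σ_K = 1.2`.  The homogeneous reference is *defined* as the least-squares
Hill fit to the heterogeneous population mean (TB₀ = 0.322,
TB_∞ = 0.063, K = 49 µM, H = 1.37), so the two models are matched in mean
response by construction and differ only in cell-to-cell structure.

**Slow adaptation.** The hour-scale recovery of tumbling bias under
sustained stimulation is modelled as a concentration memory `m` relaxing
as `m' = m + Δt (L − m)/τ_adapt` (`τ_adapt = 3600 s`; infinite disables),
with the sensed concentration `max(L − m, 0)`.  Agents enter unadapted
(`m = 0`), as cells freshly introduced from an unstimulated culture; the
alternative of spawning fully adapted to the local concentration is
available (`adapt_init="local"`) but turns the model into a rectified
temporal differentiator, which is not the mechanism this package models.
Over a 60-s residency a 3600-s memory moves by < 2% of the concentration
gap, so enabling it cannot materially change the drift — which is the
point being tested.

## Drift statistics: why there are two

The track-analysis estimator is the duration-weighted mean of the
per-trajectory gradient-axis velocities,

    V_chem = Σᵢ Vᵢ Tᵢ / Σᵢ Tᵢ,   Vᵢ = Δyᵢ / Tᵢ,

which algebraically equals the total displacement over the total time —
i.e. the net particle flux per cell.  For any motility process whose
switching rates depend only on the *current position* (exactly the
non-adaptive model above), the steady state in a channel has uniform
run-phase density and strictly zero flux, a classical result for
run-and-tumble transport with direction-independent turning: the process
is time-reversal symmetric at stationarity.  `runtumble` reproduces this
null precisely (weighted drift ≈ 0 within error at N = 10⁵), and it is a
useful estimator identity/consistency check — but it cannot serve as the
readout of a simulation study of this model class.

The population drift the simulator reports (`drift_per_trajectory`) is
therefore the *unweighted* ensemble mean of the `Vᵢ`, each cell residency
counted once.  This statistic is genuinely positive in a gradient:
a cell entering against the gradient runs into a region of rising
tumbling bias and stalls (long residence, small displacement), while a
cell riding up the gradient sees its runs lengthen and exits cleanly
(short residence, large positive displacement).  Time-weighting cancels
this asymmetry; per-residency averaging does not.  Both statistics are
exposed (`SimulationResult.drift` is the weighted estimator, matching the
track-analysis convention), and the distinction is deliberate and
documented because it changes the scientific conclusion.

The same symmetry argument applies to directional run statistics: at
stationarity, up-gradient and down-gradient run-duration distributions
are identical in this model class (reversing an up-run yields a
statistically equivalent down-run).  Fresh, short observation windows —
which is what camera recordings of cells newly entering a field of view
are — carry a small (~1%) up>down asymmetry from the first run after an
isotropic start, plus a robust elongation of runs in *both* directions
relative to the attractant-free case (the response lowers the tumbling
bias wherever attractant is present).  The elongation is a strong,
reliably testable effect; the up/down ordering is at the edge of
statistical resolution at desk-scale ensemble sizes.

## Tracking analysis

Inputs are 2-D trajectories at 50 frames/s (pixel coordinates converted
at ingest, 0.7 µm/px by default); all internal computation is in µm and
s, frames are 0-based, and the gradient axis is `+y`.  A track of `n`
frames spans `n − 1` intervals; each frame carries a dwell of `1/f`
except the last, so segment durations partition the track duration
exactly.

1. **Swimmer filter.** Tracks shorter than 1 s are discarded; the rest
   are swimmers iff the positional variance rate
   `(⟨(x−⟨x⟩)²⟩ + ⟨(y−⟨y⟩)²⟩)/T` exceeds 0.61 µm²/s, a cutoff just above
   the apparent diffusivity of non-motile cells.
2. **Local velocity.** Least-squares linear fits on a 10-frame sliding
   window, evaluated for every frame; frames within half a window of a
   track end reuse the nearest full window (avoiding shrinking-window
   bias).  The vectorised implementation is tested against an
   independent per-window regression to 10⁻¹⁰.
3. **Ballisticity segmentation.** Frames are labelled run when
   `v_n = |v| / (f · Δr) ≥ 0.785`, where `Δr` estimates the true
   per-frame step displacement: `v_n` is 1 for straight constant-speed
   motion and small during tumbles, making 0.785 a dimensionless cutoff.
   Localization noise of variance σ² per coordinate inflates the
   expected squared step by `4σ²` *at every lag*, so `Δr` is estimated
   from the lag difference `Δr² = (msd₂ − msd₁)/3`, which cancels the
   noise term exactly and equals `(vΔt)²` for locally linear motion,
   with a floor of `σ̂²/2` so pure-noise windows keep a denominator of
   the order of the noise itself.  σ̂² is estimated robustly from the
   median squared second difference of the track (`6σ²` per axis for
   smooth motion); passing `noise_sigma2=0` recovers the plain
   mean-step form.  Labels are despeckled with a 3-frame majority vote
   (single-frame flickers are below the resolution of the 10-frame
   fit).  At the emulated acquisition conditions (50 fps, σ = 0.35 µm,
   25 µm/s — per-frame displacement 0.5 µm, comparable to the noise)
   this recovers pooled tumbling bias within ±0.03 and mean run
   durations within ~1%; without the lag-difference correction the raw
   ballisticity of a run is ≈ 0.6 and the 0.785 threshold misclassifies
   essentially all run frames.
4. **Summaries.** Pooled ("movie") tumbling bias sums times over all
   tracks — equivalently the duration-weighted mean of per-track biases;
   per-track biases are returned with durations as weights for
   distribution building.  `V_chem` and its duration-weighted SEM (with
   effective sample size `(ΣT)²/ΣT²`) follow the estimator above;
   chemotaxis bias is `V_chem` over the mean run speed.
5. **Directional runs.** Runs shorter than 5 frames are removed; the
   direction angle `α = arccos(Δy/|Δ|)` classifies runs as up (`α < π/4`)
   or down (`α > 3π/4`), boundary values and everything else transverse
   (strict inequalities: measure-zero tie-break), zero-displacement runs
   transverse and flagged.
6. **Spreading bias.** Ratio of colony-edge distances up vs down a
   plate gradient; replicates are summarised as mean ± SEM with a
   one-sided t-test against 1.

## FRET processing

The YFP/CFP ratio (proportional to kinase activity) is corrected by
fitting a polynomial baseline (default linear, order 0–2 configurable) to
the annotated unstimulated stretches, dividing it out, and scaling the
first point to 1.  Activity is the affine map `A = (r − r_inact)/(r_act −
r_inact)` anchored at full activation (saturating repellent, A = 1) and
full inactivation (saturating attractant mix, A = 0); the map is
invariant under rescaling of the ratio axis.  Response amplitudes are
taken between the mean of 5 pre-stimulus points and the extremum within
30 s after the addition (window configurable — the appropriate value
depends on the flow-exchange time of the instrument).

Dose–response curves are fitted by bounded least squares to
`A(L) = A₀ (1 − (1 − ρ) L^H/(L^H + K_D^H))`; the wildtype variant fixes
ρ = 0.  ρ multiplies the Hill term (asymptote `A₀ρ`) rather than adding
an offset so that `A(0) = A₀` exactly; `A(K_D) = A₀(1 + ρ)/2`.
Initialisation: `A₀ = max A`, `K_D` = geometric mid-dose, `H = 1`,
`ρ = min A / max A`.  The reference recovery study uses the
residual-variant truth (A₀ = 1, K_D = 50 µM, H = 2, ρ = 0.2) on an
8-dose log-spaced panel from ~3 µM to 10 mM, chosen to bracket K_D and
reach saturation.

## Synthetic data

Generators emit inputs with the statistical structure the analysis
assumes, plus exact ground truth, so every stage is testable without
experimental data:

* **Tracks** — the simulator sampled at the frame rate with isotropic
  Gaussian localization noise (default σ = 0.35 µm, half a pixel) and
  finite durations (exponential, mean 4 s, truncated to [1, 60] s,
  mimicking residence in a field of view).  Closed-chamber mode (every
  agent one track from a fresh uniform start) emulates recordings of a
  sealed observation chamber; open mode emits channel residencies.
* **FRET traces** — piecewise-constant activity mapped to a ratio scale
  with multiplicative linear drift and additive noise, with the two
  calibration stimuli appended; the generation is exactly invertible by
  the processing chain at zero noise.
* **Dose tables** — closed-form Hill values plus noise, in replicates.

What the generators do *not* emulate: the detection/linking stage of
particle tracking (merged or broken tracks near cell collisions),
anisotropic or frame-correlated localization error, cell-to-cell speed
variability unless requested, hydrodynamic wall interactions, and 3-D
swimming projected to 2-D.  Passing recovery tests therefore validates
the estimators under the stated noise model, not tracking artefacts.

## Problem sizes and numerical choices

Test-suite and acceptance-script ensembles are sized for a desk-scale
run: drift ensembles of 10⁴–1.5×10⁴ trajectories (the scale at which the
drift SEM is ~0.03–0.05 µm/s), 500 noisy tracks for segmentation
recovery, 100 replicate dose tables, 500 cells per concentration for
distribution fitting, 12 000 short tracks per condition for directional
statistics.  Degenerate inputs are rejected loudly (zero durations,
non-finite coordinates, equal calibration levels, flat dose responses);
boundary tie-breaks are strict inequalities; all stochastic components
take explicit seeds.

## Known limitations

* Effect sizes of the non-adaptive local-response model are small
  (~0.05 µm/s drift); orderings between nearby conditions
  (steep vs shallow gradient, heterogeneous vs homogeneous) are at the
  edge of resolution at 10⁴-trajectory scale, and the heterogeneity
  enhancement is not resolved at 3-SEM significance at that scale.
* The model contains no flagellar-motor remodeling, receptor-methylation
  kinetics, hydrodynamics, cell–cell interaction, attractant consumption
  or time-evolving gradients; these are out of scope by design.
* The ballisticity reading (fitted speed over step-displacement speed)
  is one of the plausible normalizations of the published threshold;
  the package treats it as the definition and validates it on synthetic
  ground truth.
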