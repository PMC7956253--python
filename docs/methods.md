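# Methods

## The model

`phagopbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model for long-circulating mPEG-PCL nanoparticles in tumour-bearing
mice. The body is nine compartments: venous and arterial blood pools, and
seven perfused organs (lung, liver, spleen, kidney, tumour, heart, rest of
body) wired in parallel between the pools, with the lung in series carrying
total cardiac output. Each organ consists of three sub-compartments —
capillary blood, interstitial tissue, and phagocytic cells (PCs: Kupffer
cells, red-pulp macrophages, alveolar macrophages, …) — exchanging as

    V_V,t dCV_t/dt = Q_t (CA − CV_t) − PA_t CV_t + PA_t C_T,t / P_t
                     − k_up,t(t) CV_t V_V,t + K_out,t A_PC,t
    V_T,t dC_T,t/dt = PA_t CV_t − PA_t C_T,t / P_t
    dA_PC,t/dt      = k_up,t(t) CV_t V_V,t − K_out,t A_PC,t

with PA_t = PAC_t × Q_t (permeability–area product), P_t the tissue/plasma
distribution coefficient, and a time-dependent phagocytic uptake rate
constant following a Hill function of time,

    k_up,t(T) = K_max,t T^n / (K_50,t^n + T^n),

which captures activation of phagocytosis after injection and its
saturation as the cells fill. Uptake draws from organ capillary blood and
release returns there; capillary↔tissue exchange is membrane-limited
(permeability-limited). Biliary (K_bile, liver) and urinary (K_urine,
kidney) elimination are first-order drains routed into cumulative
eliminated-amount states, so the sum of all state variables equals the
administered dose at all times — mass balance is structural, and its
numerical residual is a direct measure of integrator error.

An alternative tumour description replaces the PC sub-compartment with an
enhanced-permeability-and-retention (EPR) space: first-order extravasation
(K1) out of tumour capillary blood and intravasation (K2) back,

    V_V,T dCV_T/dt = Q_T (CA − CV_T) − K1 CV_T V_V,T + K2 A_EPR
    dA_EPR/dt      = K1 CV_T V_V,T − K2 A_EPR.

Structurally this is the PC organ with PA = 0, a constant uptake rate K1
and release K2; the implementation exploits that correspondence so both
variants share one state layout and one mass-conserving assembly. No
tabulated K1/K2 values exist for these formulations; the packaged defaults
(K1 = 0.1/h, K2 = 0.05/h) are placeholders, and the variant-comparison
workflow estimates K1/K2 from data before scoring.

Because k_up depends on time but not on state, the whole system is linear
in amounts: every concentration trajectory is exactly proportional to dose.
The suite asserts this to 1e-9 relative, and it makes every ratio- or
shape-based result independent of the assumed dose.

## Parameters and physiology

Per-organ kinetic parameters (P, PAC, K_max [1/h], K_50 [h], n, K_out
[1/h]) plus K_bile/K_urine [L/h] for five nanoparticle formulations
(80/200 nm size, 9.09/28.57% mPEG-PCL content, mPEG 2k/5k) ship as a tidy
CSV fixture (`data/formulations.csv`). K_max spans 0.05–560/h — liver and
spleen dominate by one to two orders of magnitude, the quantitative
signature of mononuclear-phagocyte capture of polymeric nanoparticles.
Note one internal inconsistency in the sources these values derive from:
prose discussion elsewhere attributes liver/spleen K_max of 151/83 h⁻¹ to
the 9.09%-80 nm formulation, while the parameter table assigns those values
to the 28.57%-80 nm one; the fixtures follow the table.

The mouse physiology (20 g body weight, cardiac output 740 mL/h, organ
volume fractions, capillary blood fractions VBloodC, flow fractions) is
assembled from standard rodent reference compilations (Brown et al. 1997)
and is fully overrideable via YAML config. Two values are modelling
assumptions rather than reference data and are marked as such in the
config: tumour blood flow (1% of cardiac output) and the venous/arterial
split of the blood pool (2:1). Tumour volume is fixed at 0.55 mL (the
mid-range of the implanted-tumour volumes) and does not grow over the 72 h
horizon. Units are mg, mL, h throughout, with tissue density 1 g/mL so
mg/g and mg/mL coincide. `scale_physiology` rescales volumes linearly with
body weight and flows allometrically (default exponent 0.75); it exists to
make cross-species extrapolation structurally possible, not to provide
validated rat/human parameter sets.

Structural switches collected in `ModelSpec`: clearance may drain capillary
blood (default; consistent with blood-facing transport) or tissue; an
optional portal-routing flag sends spleen venous effluent through the liver
capillary bed (off by default — the reference circulation diagram shows no
portal link). Venous-pool concentration is reported as "blood" (matching
sampling by withdrawal).

## Numerics

The system is stiff: capillary transit rates Q/V_V reach ~2×10³/h against
release rates of 0.075/h. Production integration uses scipy's LSODA with
rtol 1e-8 (1e-6 inside fitting loops, where speed matters and the loss
tolerates it) and atol 1e-13 × dose. The output grid is 0–72 h at 0.1 h
spacing with the six terminal-sampling times injected exactly, plus 48
log-spaced points between 1e-4 and 0.5 h: the venous bolus redistributes on
a ~1/1000 h timescale, and without resolving that transient, trapezoidal
blood AUCs are not grid-converged. With it, halving the grid changes
AUC(0–24 h) by < 0.1% for every fixture.

An independent oracle — a deliberately naive fixed-step classical RK4
integrator of the same right-hand side, step 1e-3 h — agrees with LSODA to
within 0.5% at all sampled times on a reduced two-organ circulation (liver
plus rest-of-body, no lung, where the generic assembly routes venous blood
directly to the arterial pool).

Hill-function conventions: k_up(0) = 0 for n > 0; for n = 0 the limit
convention k_up ≡ K_max/2 applies. Several tabulated rows have n ≈ 0.001,
which flattens the curve to ≈ K_max/2 over the whole experiment —
numerically benign but effectively removing K_50 and n from the
identifiable set for those organs.

## Fitting

Estimation mirrors a two-stage strategy. Stage 1 ("open loop") fits one
organ's (K_max, K_50, n, K_out) with the organ driven by the observed,
interpolated blood concentration as a forcing function; this decouples the
organ from the rest of the body and provides starting values. Because the
forcing interpolates sparse venous samples, open-loop predictions are not
identical to whole-body trajectories — the stage is a seeding heuristic,
and its self-consistency tests therefore use data generated by the
open-loop model itself. Stage 2 refits the whole-body model simultaneously
to all compartments by weighted least squares.

Parameters are optimised on a log10 scale (they span 0.0002–560) inside box
constraints, with a Nelder–Mead start refined by bounded trust-region least
squares (lmfit), and optional multi-start (default 5 random log-uniform
perturbations of the init; the first start is the init itself). By default
the distribution and permeability coefficients P/PAC stay fixed at their
tabulated values — sensitivity analysis shows they barely influence the
output, which also means data barely constrain them — and only phagocytosis
parameters and clearances should be freed.

Residual schemes: `relative` (weights 1/obs, i.e. squared loss weighted
1/obs²; the package default), `inverse` (1/obs), `uniform`, and `log`
(residuals on log concentrations). The log scheme is the maximum-likelihood
loss under the generator's multiplicative lognormal error and, unlike
1/obs weighting, does not couple a point's weight to its own noise
realisation; recovery experiments use it together with exclusion of
quantification-censored rows (substituted LLOQ/2 pseudo-values are not
draws from the model distribution and would bias a likelihood-based fit).

Goodness of fit is the R² of an ordinary linear regression of log10
observed on log10 predicted concentrations pooled over all compartments and
times; non-positive pairs are excluded with a reported count. Note R² of a
regression is invariant to a constant log offset — a uniformly 10×-off
prediction still scores 1.0 — so it measures shape agreement, not
calibration; the two-fold fraction (share of pairs within a factor of 2,
the conventional acceptability rule for PBPK models) covers calibration.

## Sensitivity analysis

Stage one screens every scalar parameter by ×2 and ÷2 perturbation,
recording the maximum relative change of an organ's amount trajectory over
0–24 h. Stage two computes relative sensitivity coefficients

    RSC = (dAUC/AUC) / (dp/p)

as a forward difference at +1%, where AUC is the trapezoidal area under the
compartment concentration curve over 0–24 h; blood is excluded from reports
by default, |RSC| > 0.5 classifies a parameter as highly sensitive, and
zero-valued parameters are skipped (RSC is undefined there). A
central-difference evaluator exists purely as a step-size oracle; forward
+1% and central ±0.1% agree within 2% on body weight, the least linear
parameter. Body-weight perturbation rescales volumes linearly and flows
allometrically — a documented semantic choice, since "perturb BW" is
ambiguous about which derived quantities co-vary. RSC of the injected dose
is exactly 1 in every compartment (dose linearity), which the suite uses as
an analytic end-to-end check.

K_max ratios between formulations are reported rounded half-up to 2
decimals (configurable), matching conventional reporting of such
comparisons.

## Synthetic data

The generator emulates the study design: IV bolus, terminal sampling at
0.083, 1, 4, 8, 24, 72 h, seven measured compartments, 3 replicate animals
per timepoint (a conventional choice for terminal-sampling mouse studies;
the source design does not state the count). Noise is multiplicative
lognormal, mean-unbiased (ε ~ N(−σ²/2, σ²), σ² = ln(1+CV²)), default
CV 20% — an assumption, since only error bars are reported for the real
assay. Values below the limit of quantification (default 0.0039 mg/mL, the
lower end of the fluorescence calibration ranges) are substituted by LLOQ/2
and flagged, or optionally dropped.

What the generator does *not* emulate: fluorescence-assay specifics
(quenching, ROI quantification, calibration-curve error structure),
between-animal physiological variability, tumour growth, and any
model-misspecification error — synthetic data are drawn from the model
itself. Passing recovery tests therefore demonstrate identifiability and
estimator correctness under the stated noise model, not that the model is
true of real mice.

## Recovery experiment

`recovery_experiment` draws, per seed, one synthetic study (CV 20%, n = 3,
6 timepoints) from a known formulation and refits the whole-body model
freeing liver and spleen K_max/K_out, starting from truth ×1.5, single
start, log residuals, censored rows dropped. Success means both K_max
estimates land within 30% of truth. A Fisher-information analysis at the
true parameters puts the attainable precision at sd(ln K_max) ≈ 0.13 for
liver and ≈ 0.20 for spleen — the spleen equilibrates its PC pool within
~20 minutes, after which only the K_max/K_out ratio is identified
(estimate correlation 0.96) — so per-seed success probability is ~0.8 even
for an efficient estimator, and occasional failing seeds are expected
noise, not defects. Multi-start was verified to reproduce the same optima,
and fitted losses fall below the loss at truth on failing seeds: the
misses are properties of the data, not of the optimizer.

## Problem sizes and defaults

Simulations integrate 25 states over 72 h in ~0.1 s. The test suite runs
the full model family (5 formulations × 2 variants), a 10-seed recovery
experiment (~2 minutes), and distributional checks at up to 10⁴ replicates.
The acceptance script re-derives every reported number from the packaged
fixtures at run time; its only randomness is the synthetic-data seeds,
all derived from the `--seed` argument.

## Known limitations

- Absolute concentrations depend on the assumed 2 mg dose (reconstructed
  from the preparation recipe; the true injected fluorescent dose is
  unpublished). All shape- and ratio-based results are dose-independent.
- The physiology table is assembled from general rodent references, not the
  study's own (unpublished) appendix; absolute organ profiles shift with it,
  though the qualitative sensitivity structure is robust.
- No intracellular trafficking, protein-corona dynamics, degradation, or
  lymphatic transport; tumour volume fixed.
- The headline goodness-of-fit values of the original animal study cannot
  be recomputed here because the underlying measurements are unpublished;
  the fitting machinery is validated on synthetic data instead.
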