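# Methods

## Scope and model structure

`mmae_pbpk` models the whole-body disposition of monomethyl auristatin E
(MMAE), the tubulin-binding payload of several approved antibody–drug
conjugates, after a single intravenous bolus in a tumor-bearing mouse. The
model is a physiologically based pharmacokinetic (PBPK) system of 80 ordinary
differential equations:

* a central blood pool split into plasma and blood cells;
* fifteen organs (lung, heart, kidney, brain, muscle, bone, skin, adipose,
  thymus, small and large intestine, spleen, pancreas, liver, and a lumped
  "other"/carcass compartment), each divided into plasma, blood-cell,
  endothelial, interstitial, and cellular sub-compartments;
* a cell-level tumor model with extracellular, intracellular-free, and
  tubulin-bound pools.

Organs are connected anatomically by regional blood flow: the lung receives
the whole cardiac output from the venous pool, all other organs receive
arterial blood from the lung, and the splanchnic organs (intestines, spleen,
pancreas) drain through the hepatic portal vein into the liver. Each regional
flow is split into plasma and blood-cell streams by the hematocrit.

Drug transfer processes, per tissue:

* **Fast exchange** between tissue plasma, endothelial, and interstitial
  spaces at a rate G x tissue plasma flow with G = 1000, which renders those
  spaces effectively in equilibrium with local plasma (driven by the unbound
  fraction fu_p on the way in).
* **Permeability-limited exchange** between plasma and blood cells (PS_BC)
  and between interstitial and cellular space (PS_i), with influx driven by
  fu_p·C and efflux by (fu_p/Kp)·C, so that the cellular:plasma concentration
  ratio approaches Kp at equilibrium. The unbound tissue fraction is
  fu_t = fu_p/Kp.
* **Hepatic elimination** CL_int x C_IS,liver from the liver interstitial
  space only (MMAE is cleared by hepatic metabolism and biliary excretion;
  renal elimination is minor and neglected).
* **Tumor exchange** via a Krogh-cylinder vascular term
  2·P·R_cap/R_krogh^2 and a surface-diffusion term 6·D/R_tumor^2, both
  driven by (C_plasma − C_extra/eps) and scaled by tumor volume on the
  plasma side; first-order cellular influx (k_in) and efflux (k_out); and
  second-order tubulin binding k_on·C_free·(C_tubulin − C_bound) −
  k_off·C_bound. k_on is derived from the tubulin dissociation constant
  (KD = 291 nM) and off-rate (0.545 1/h) as k_on = k_off/KD = 0.00187
  1/nM/h.

Everything except tubulin binding is linear in the state, so the right-hand
side is a constant matrix plus a two-entry bilinear correction, and the
Jacobian is analytic. With CL_int = 0 the system is exactly conservative;
mass-balance tests exploit this.

### Units and state conventions

Concentrations are nM, volumes mL, flows and clearances mL/h, time h,
amounts pmol (nM x mL). The molecular weight 717.98 g/mol converts ng/mL to
nM. The three tumor states are expressed per **total** tumor volume; this is
the one convention under which the amount-based plasma exchange term and the
concentration-based tumor equations conserve mass exactly, and it makes the
tumor homogenate observable simply C_extra + C_free + C_bound. The tumor is
a sphere of radius 0.7 cm (1.44 mL), constant over the one-week study.

### Krogh geometry

The capillary radius and intercapillary half-distance default to 8 µm and
75 µm (8e-4 / 7.5e-3 cm). Centimeter-scale values for these two lengths are
anatomically implausible and inconsistent with the Krogh-cylinder tumor
literature from which the exchange model derives; the micrometer scale
preserves the intended magnitude of the vascular exchange rate. Both lengths
are configurable.

## Physiology fixture

The physiological tables are not part of the published analysis and had to
be assembled: `data/mouse_28g.csv` holds volumes, sub-compartment volume
fractions, and regional whole-blood flows for a nominal 28 g mouse drawn
from standard rodent PBPK physiology, with a cardiac output of 676 mL/h
defined exactly as the sum of the regional flows (flow conservation holds by
construction). Hematocrit is 0.45.

Cellular volume fractions are the one quantity the reference data constrain:
the ratio of the apparent to the cellular-space-adjusted partition
coefficient of each observed tissue equals that tissue's cellular fraction
(e.g. lung 35.3/64.9 → 0.544). The default fixture uses those calibrated
fractions; `mouse_28g_literature.csv` ships generic rounded fractions as an
alternative, selected by passing its name to `load_physiology`. Endothelial
volume is fixed at 0.5% of each tissue; interstitial volume is the
remainder. Every downstream quantity that depends on the fixture
(simulated concentration scales, recovery experiments) is
fixture-sensitive; the package therefore validates itself by
simulate-and-refit self-consistency rather than by reproducing published
concentration values.

The tumor is not a fixture row: it has no sub-compartment split in this
model, and its geometry lives in `TumorParams`.

## Drug parameters

Defaults are the fitted/literature values: fu_p = 0.8, Kp_BC = 5.46,
PS_BC = 0.105 mL/h, CL_int = 137 mL/h, per-tissue adjusted Kp (lung 64.9,
heart 22.8, kidney 42.4, brain 0.53, muscle 1.51, bone 1.89, skin 2.87,
adipose 3.01, spleen 47.2, pancreas 2.93) and per-tissue PS (lung 2.47,
heart 1.47, kidney 14.2, brain 0.00825, muscle 3.16, bone 0.568, skin 0.681,
adipose 0.588, spleen 0.457, pancreas 0.0657, liver 49.2 mL/h). Unobserved
tissues (thymus, intestines) take the spleen's apparent Kp (27.1) adjusted
by their own cellular fraction; the carcass takes Kp = 1; their PS is the
muscle PS scaled by the tissue weight ratio. All are configurable.

The liver Kp defaults to 25.3, the value that additionally accounts for
CL_int (the apparent adjusted value, 3.80, understates partitioning in the
eliminating organ because elimination depresses the observed liver AUC).
The formula behind that accounting is not recoverable, so 25.3 is an input
constant, overridable to 3.80; the NCA pipeline reports the liver's apparent
Kp with an explanatory note rather than computing a correction.

Tumor defaults: P = 87.5 cm/h, D = 0.0104 cm²/h, eps = 0.44, k_in = 0.185
1/h, k_out = 0.046 1/h, C_tubulin = 2000 nM. k_in is dimensionally a
first-order rate (1/h); 0.185 is its estimated value.

## Numerical integration

The fast-exchange factor makes the system very stiff (plasma-endothelial
rates ~1e8 1/h); `simulate` uses LSODA with the analytic Jacobian, rtol 1e-8
and atol 1e-10 nM by default (BDF is available as a cross-check and agrees
to <1e-6 relative). The initial condition places the whole dose in central
plasma. Halving the tolerances changes observables by far less than 0.01%.
Likelihood evaluations during fitting use rtol 1e-6 / atol 1e-9, which
changes the objective in the sixth significant figure while tripling speed.

## Noncompartmental analysis

AUCs use the linear/log trapezoidal rule: linear on rising or flat segments
and wherever a concentration is zero, logarithmic on strictly declining
positive segments (exact for exponential decay between points). The terminal
slope is a log-linear regression of the last three positive points
(configurable); extrapolation adds C_last/lambda_z. Moment analysis gives
CL = dose/AUC_inf, MRT = AUMC_inf/AUC_inf, Vss = CL·MRT, t_half =
ln2/lambda_z; if no declining terminal phase exists the summary is flagged
partial. Partition coefficients are AUC ratios against plasma; adjusted Kp
divides by the cellular fraction. BLQ records are excluded from profiles
(means are taken over quantifiable replicates; time points with no
quantifiable replicate are dropped, leading, trailing, or embedded).

IVIVE follows CL_metabolic = CLint_vitro x scaling factor x liver weight
(µL/min converted to mL/h), with hepatocyte (10^6 cells/g) and microsomal
(mg protein/g) bases that must match their scaling factors; dividing by the
metabolic fraction of total elimination (default 0.4, the remainder mostly
biliary) gives whole-liver intrinsic clearance. PS values scale
allometrically with exponent 0.67.

## Synthetic studies

`generate_study` reproduces the biodistribution design: 0.1 mg/kg IV bolus
in a 28 g mouse (3900 pmol), destructive sampling at 5 min, 1, 6, 12, 24,
168 h, three animals per time point, with plasma, whole blood, eleven
tissues, and tumor measured per animal, LLOQ 0.2 ng/mL. Residual error is
drawn from Normal(Y, (sigma1 + sigma2·Y)^2) truncated at zero — the additive-
proportional variance model of the likelihood, taken literally; a log-normal
option exists. Defaults sigma1 = 0.01 nM and sigma2 = 0.10 are package
choices (the real study's residual magnitudes are unreported): 10%
proportional error is typical of LC-MS/MS tissue homogenate assays, and the
small additive floor keeps the variance model positive near the LLOQ.
BLQ values are retained but flagged. The generator emulates the design and
the assay error, not inter-animal physiological variability or tumor-size
variation — passing recovery tests therefore demonstrates estimator
self-consistency under the stated noise, not robustness to biological
heterogeneity.

## Maximum-likelihood estimation

Records are fitted individually, pooled across animals (the destructive
design yields one parameter set, not a population model). The objective is
the Gaussian −2 log-likelihood with variance (sigma1 + sigma2·Y)^2; BLQ
records are excluded and counted. sigma1 is fixed (0.01 nM) and sigma2
estimated by default. The estimated set mirrors the published analysis:
PS in blood cells and the eleven observed tissues plus liver, CL_int, and
k_in (14 parameters, plus sigma2).

Parameters are log-transformed and minimized with L-BFGS-B under generous
bounds (1e-6 to 1e5); the optimizer seed only jitters optional multi-start
restarts (single deterministic start by default). CV% uses the inverse of a
numerically differenced Hessian of −2LL at the optimum (covariance =
2·H^{-1}), with a 5% log-scale differencing step — large enough to sit above
the ODE-solver noise floor, small enough for local quadratic validity. The
SE of a log-parameter is directly the relative SE, so CV% = 100·SE_log
(delta method). A non-positive-definite or singular Hessian leaves the
affected CV% entries NaN. AIC = −2LL + 2k with k counting estimated variance
parameters.

The package's validation of the estimation layer is a simulate-and-refit
experiment (`recovery_experiment`): five independent synthetic studies at
the default (published) parameter values, each refitted from a 2x-perturbed
start. Five replicates keep the experiment within a few minutes on one CPU
while giving a stable median; the recovered medians for CL_int and
PS_kidney sit within a few percent of their generating values.

## Known limitations

* The physiology fixture is a stand-in; absolute simulated concentrations
  (and hence simulated AUCs and Kp values) depend on it and are not expected
  to reproduce published mouse data quantitatively.
* Single IV bolus only; no oral/subcutaneous routes, repeated dosing,
  enterohepatic recirculation, transporter kinetics, or tumor growth.
* Linear plasma protein binding and concentration-independent CL_int;
  tubulin binding is the only nonlinearity, and at the 0.1 mg/kg reference
  dose tubulin occupancy stays below ~1%, so the model operates in its
  near-linear regime.
* The naive-pooled likelihood understates between-animal variability; no
  mixed-effects machinery is provided.
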