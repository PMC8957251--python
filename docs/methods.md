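# Methods

## Model

`pbpksim` simulates a whole-body circulation of well-stirred, flow-limited
compartments. Each organ *i* obeys

    V_i dC_i/dt = F_i (C_in − C_i)

where `F_i` is the organ blood (or plasma) flow, `C_in` the inflowing
concentration, `C_i` the concentration of blood leaving the organ in
equilibrium with the tissue, and `V_i = V_blood,i + K_i · V_tissue,i` the
organ distribution volume set by the tissue/blood partition coefficient
`K_i`. Organs sit in parallel between artery and vein, except the portal
bed, whose effluent perfuses the liver, and the lung, which sits in series
(vein → lung → artery) and receives the whole cardiac output. Units are
minutes, liters, kilograms; blood density is 1 kg/l so weights double as
volumes.

The physiological parameter set (15 organ rows: weights, perfusions, lipid
fractions, extracellular-fluid fractions, interstitial/plasma albumin
ratios) describes a 70 kg, 20 % body-fat human and ships as a versioned
CSV (`pbpksim/data/standard_human.csv`); the loader validates columns and
row count, and nothing in the logic hard-codes the table. Adipose tissue
is two equal-weight depots with perfusions 0.074 and 0.01408 l/min/kg;
this heterogeneity is what produces the multi-day terminal phase of
lipophilic washout, and removing the slow depot shortens the terminal
time constant several-fold. The lung row carries the sentinel perfusion
−1.0 ("receives cardiac output"); bone (zero perfusion, zero lipid and
ECF fraction) is inert mass that counts toward body weight only.

### Partition prediction

Two solute classes admit a priori partitioning:

* **HLS (highly lipid-soluble)**, lipid/water partition `P ≥ ~100`:
  `K_i = (f_l,i P + (1 − f_l,i)) / (f_l,B P + (1 − f_l,B))`, saturating at
  `f_l,i / f_l,B`. The apparent blood lipid fraction `f_l,B` defaults to
  0.015; if a measured free plasma fraction is supplied it is converted to
  the equivalent `f_l,B = (1 − f_p)/(P f_p + 1 − f_p)` so the blood free
  fraction matches.
* **ECS (extracellular)**: the solute occupies plasma plus interstitium
  only, with interstitial/plasma partition `K_EC = f_p + (1 − f_p) K_alb`
  from the free plasma fraction `f_p` and the organ's interstitial/plasma
  albumin ratio. The interstitial volume is the ECF fraction times the
  organ volume. ECS dynamics run on plasma flows `F (1 − Hct)`; default
  hematocrit 0.45 (a config field).
* **Volatile** solutes use air-referenced coefficients: tissue/air
  capacity `(f_l k_fat/water + (1 − f_l)) k_water/air`, blood/air
  `k_blood/air`; states are partial pressures. A single alveolar gas store
  of volume `V_alv` (default 3 l) with continuous alveolar ventilation
  (default 5 l/min) is inserted between vein and lung:
  `V_alv dP_alv/dt = Vent (P_insp − P_alv) + CO·k_b/air (P_ven − P_alv)`,
  and arterial blood leaves at `P_alv`. Output is end-tidal (alveolar)
  partial pressure; dead space and breath cycling are ignored.

Per-organ capillary blood volume defaults to zero — the vein (4.29 l) and
artery (1.21 l) rows carry the blood — so `V_i = K_i × organ volume`
(HLS) or `K_EC,i ×` interstitial volume (ECS). The brain has no
interstitium, so for ECS solutes it is a pure pass-through.

### Capillary permeability limitation

For ECS solutes the single-pass extraction fraction
`fclr = (c_A − c_v)/(c_A − c_t)` may be < 1. A permeability-limited organ
takes up `fclr · F_P (C_A − C_t)` and returns the mixed effluent
`(1 − fclr) C_A + fclr C_t`; at `fclr = 1` this reduces exactly to the
flow-limited equations (verified trajectory-wise in the tests). `fclr`
relates to the permeability–surface-area product via the Crone–Renkin form
`fclr = 1 − exp(−f_p PS / F_plasma)`, so tight albumin binders
(`f_p → 0`) become capillary-limited even when the free molecule is
highly permeant. The user sets `fclr_muscle`; other tissues get
proportional values via a configurable ratio table whose neutral default
is 1.0 (the literature ratio set is not published in a reusable form).

### Clearance

Renal clearance is `fraction × kidney plasma flow` and removes
`Cl · C_arterial` from the kidney's vein-bound effluent: "fraction of
renal plasma cleared" describes extraction of the inflowing plasma, the
kidney venous concentration becomes `(1 − fraction) C_A` at quasi-steady
state, and the steady-state infusion identity
`C_arterial = rate / Cl` holds exactly (the package asserts it to 0.1 %).
Hepatic clearance is `fraction × (hepatic artery + portal) flow` acting on
the well-mixed liver concentration (extraction on the combined liver
outflow). Volatile solutes are cleared by expiration (`Vent · P_alv`),
plus optional hepatic metabolism.

### One-compartment comparison

When the metabolic time constant `T_Cl = V_ss / Cl` is long compared with
the slow-adipose equilibration constant `T_adipose = K_adipose/perfusion`,
the late kinetics collapse onto `C(t) = (D/V_ss) exp(−t/T_Cl)`.
`convergence_analysis` sets the hepatic fraction so the systemic
clearance matches each requested `T_Cl`, simulates a bolus, and reports
the maximum relative deviation `|C_1c − C_pbpk| / C_pbpk` over the window
`[10 T_adipose, 10 T_adipose + 2 T_Cl]`: ten time constants lets the
distribution transient decay to ~5·10⁻⁵, and two further `T_Cl` cover the
terminal phase to e⁻². "Good prediction" is operationalized as ≤ 10 %
late-time deviation (no numeric criterion exists in the source material
for the figure-level claim). For the reference lipophile
(`P = 2×10⁵`, `f_l,B = 0.0075`; `V_ss ≈ 1953 l`, `T_adipose ≈ 7571 min`)
the deviation falls from ~100 % at `T_Cl = 1.25 d` through ~66 % at
12.5 d to ~3.6 % at 125 d.

## Numerics

The assembled system is linear and time-invariant between dose events but
stiff (rate constants from ~0.5 min in the kidney to ~10⁴ min in slow
adipose), so it is integrated with `scipy.integrate.solve_ivp` BDF,
relative tolerance 1e-8 and absolute tolerance 1e-12 by default, with the
exact constant Jacobian supplied. Dose start/stop times are integration
breakpoints; boluses are state jumps of the vein compartment. Cumulative
cleared and dosed amounts are integrated as two augmented states, so mass
audits close to solver tolerance (≲ 1e-9 relative in practice). Solver
failure raises `SolverError` with the integrator diagnostic — never a
silent NaN. Mass conservation is also enforced structurally: with zero
clearance the capacity vector is a left null vector of the system matrix,
asserted in the tests to 1e-12.

An independent matrix-exponential propagation of the same state matrix
(`scipy.linalg.expm` stepping) serves as the oracle in the tests and the
acceptance report; it is never the simulation path. Terminal washout time
constants are computed from the least-negative eigenvalue of the
homogeneous system matrix and cross-checked against simulated tail
slopes.

The clearance fitter minimizes the sum of squared log-concentration
residuals over the single free fraction with bounded scalar minimization
(`minimize_scalar`, `xatol` 1e-9), which recovers a noise-free fraction to
~8 significant digits in ~15 model evaluations.

## Synthetic data generator

`synth_pk_data` simulates a scenario, samples the venous concentration at
the requested times, and multiplies by independent lognormal noise with
`sigma = sqrt(log(1 + CV²))`, so the multiplicative coefficient of
variation is exactly the nominal CV; the seed is an explicit argument
(no global state). It emulates assay scatter of a concentration–time
study but none of the structure of real residuals: no model
misspecification, no within-subject correlation, no inter-individual
variability, no sampling-time error, no limit of quantification. Passing
parameter-recovery tests therefore demonstrate identifiability and
estimator correctness under the stated noise model, not predictive
accuracy against real human data.

Scenario doses are round placeholders (1 unit bolus or infusion); the
system is linear, so every conclusion drawn from the fixtures rests on
ratios, shapes, time constants, and recovery — never on absolute
concentrations. The volatile fixture's partition set (blood/air 1.4,
water/air 0.61, fat/water 150) is an isoflurane-like synthetic
placeholder; only structural properties are asserted for it.

## Design choices in genuinely open territory

* **Body scaling** (`scale_body`) sets the two adipose weights equal so
  their lipid mass matches `fat_fraction × total_weight`, leaving every
  other organ (and blood volume) at template values. The organ-weight sum
  is deliberately not re-balanced against the requested total: the
  standard-human tissue parameters are assumed to extrapolate to the
  scaled subject. An error fires only when the implied adipose plus blood
  mass exceeds the total weight.
* **Renal clearance placement** (arterial-indexed, see above) was chosen
  over clearing at the kidney venous concentration because only the
  former preserves the analytic `C_ss = rate/Cl` identity and the
  conventional definition of clearance.
* **Maximum washout arithmetic**: with the measured blood lipid fraction
  0.005 and the slow-adipose perfusion 0.01408 l/min/kg the saturated
  washout time constant is 11364 min ≈ 7.9 days. Descriptions of "about
  11 days" for this bound circulate; the perfusion behind that rounding is
  not stated, so the package reports the computed 7.9 days and asserts
  nothing about 11.
* **Per-tissue `fclr` ratios** default to 1.0 (uniform) because the
  published ratio set is not available; the table is overridable.

## Problem sizes

The test suite and the acceptance report use: 600-min grids (121–601
points) for extracellular scenarios, a 50 000-min wash-in and 15 000-min
washout for the volatile fixture, convergence windows up to ~4.4×10⁵ min
for the `T_Cl` ladder, 20-sample synthetic datasets, and 50 seeds for the
noisy-recovery median. These sizes keep the whole suite under a minute on
one CPU while leaving every asserted margin wide (the convergence and
recovery checks pass with 2–3× headroom).

## Known limitations

No pH partitioning or ionization (weak acids/bases are exactly the class
the partition predictors cannot handle); no nonlinear or saturable
clearance, enterohepatic recycling, or oral absorption; no
diffusion-limited adipose exchange (relevant to the most extreme
lipophiles); no antecubital-vein sampling correction; no
ventilation/perfusion heterogeneity, second-gas or concentration effects
in the lung; no pediatric/allometric scaling beyond the fat-fraction
adjustment; no inter-individual variability sampling.
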