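# Model and methods

## Scope and state

`colicarb` integrates a kinetic ODE model of *E. coli* central carbon
metabolism on glucose/xylose mixtures. The state comprises

* 24 intracellular metabolites (mM): hexose/triose phosphates, PP-pathway
  intermediates, TCA/glyoxylate intermediates, intracellular xylose and
  xylulose, and the two mevalonate-pathway intermediates (acetoacetyl-CoA,
  HMG-CoA);
* 7 cofactor pool members (mM): ATP/ADP/AMP, NAD/NADH, NADP/NADPH;
* 4 extracellular species (g/l): glucose, xylose, acetate, mevalonate;
* biomass X (gDCW/l).

Each intracellular species obeys
`dc/dt = (production − consumption − anabolic drain)/V_cyto − μ·c`,
with the cytoplasmic volume `V_cyto = 2.47 ml/gDCW` converting specific
fluxes (mmol/gDCW/h) to concentration changes. Extracellular balances scale
uptake/secretion by biomass and molar mass; chemostat mode adds
`D·(feed − c)` to extracellular species and `−D·X` to biomass.

Cofactor pools are integrated **without** the growth-dilution term, so the
moiety totals ATP+ADP+AMP, NAD+NADH and NADP+NADPH are exact invariants of
the dynamics (verified to < 1e-6 relative drift in the test suite). AMP is
an inert pool member: no adenylate kinase is modeled.

## Rate laws and regulation

All reactions use Michaelis–Menten forms (reversible where the physiology
requires it: Pgi, Rpe, Rpi, the transketolase/transaldolase trio, and
fumarase) with the documented allosteric effectors:

* FBP activates pyruvate kinase (Hill, with a basal activity) and Ppc;
* NADPH inhibits G6PDH (squared term) and, weakly, 6PGDH and ICDH;
* G6P inhibits the PTS — a lumped proxy for G6P-triggered *ptsG*-mRNA
  destabilization — and, more weakly, the NPTS/glucokinase lump
  (glucokinase is product-inhibited);
* NADH inhibits PDH, αKGDH and MDH (respiratory redox control).

Transcription-factor control multiplies maximum rates:
`vmax = vmax' · Π f_i(TF_i)`, with `f = a + b·TF` for activation and
`f = a + b·(1 − TF)` for repression (per-edge constants in the regulation
table; capacities are calibrated so typical wild-type activities give
near-nominal rates). The TF activity functions are:

* **cAMP-Crp** — Hill function of the PEP/PYR ratio. Rationale: the PTS
  phosphorelay equilibrates fast, so EIIA~P (and hence adenylate cyclase
  activity and cAMP) tracks PEP/PYR. Activates the xylose operons, the
  non-PTS glucose transporters, citrate synthase, and Acs.
* **Cra** — repressed by FBP (Hill); represses *pykF*, activates the
  gluconeogenic/glyoxylate genes (Fbp, Pps, Pck, Icl).
* **ArcA** — Hill function of the NADH/NAD redox ratio; represses the TCA
  genes (CS, ICDH, αKGDH, SDH leg) and the respiratory chain. Anaerobic
  scenarios floor its activity at 0.9 and zero the electron-acceptor
  capacity of oxidative phosphorylation (mechanistic FNR control is out of
  scope). Overexpression is modeled purely as pinning the activity (the
  `MVA_dpgi_arcA` preset pins 0.95), with no promoter dynamics.
* **XylR** — saturating function of intracellular xylose. The xylose
  operons carry a basal (uninduced) expression of 15 % so induction can
  bootstrap from zero.

The xylose subsystem uses the explicit forms: transport with inducer
exclusion by unphosphorylated EIIA
(`v_XT = vmax'·f·[XYL]/(K_XYL + (1+[EIIA]/K_I)·[XYL])`), Michaelis–Menten
isomerase, and a two-substrate xylulokinase in xylulose and ATP. In the
assembled network the ABC transporter XT is additionally multiplied by an
ATP-availability factor `[ATP]/(K+[ATP])` so transport stalls when the
energy pool empties; the pure regulatory/substrate form is exposed
separately (`rate_xt`) and is the form whose closed-form limits the tests
check.

The EIIA phosphorylated fraction is a quasi-steady-state Hill function of
PEP/PYR (exponent 2); total EIIA (0.04 mM) is conserved.

## Growth and cofactor closure

Growth is linearly coupled to ATP production:
`μ = k_ATP · v_ATP · k_ACE/(k_ACE + [ACE])`, clamped at zero from below.
`v_ATP` is the signed sum over the substrate-level and oxidative
phosphorylation fluxes (OP + L_Emp + Pyk + PTACK + αKGDH − Glk − Pfk − Pps
− Pck − Acs − XT − Xyk). The OP term is `P/O_NADH · v_resp + P/O_FADH ·
v_SDH` with P/O yields 2 and 1 and a respiratory NADH-oxidation rate
saturable in NADH and ADP, repressed by ArcA, and zero anaerobically.

Two closures keep the cofactor pools in a physiological regime without
hiding the quantities the analysis reports:

* **ATP** — the lumped anabolic+maintenance demand is
  `k_drain·[ATP]·s + m·s` with `s = [ATP]/(K+[ATP])`. Making the demand a
  function of [ATP] rather than of μ avoids a circular closure (μ is itself
  defined by ATP production) and lets demand fall off faster than
  production at low energy charge, so transient dips recover instead of
  locking into a dead state.
* **NADPH** — the anabolic drain is `k_Anabolism · μ` (14.849 mmol/gDCW,
  the one literature-anchored constant), saturable in NADPH. A small
  soluble transhydrogenase flux (UdhA, NADPH + NAD → NADP + NADH) relieves
  NADPH *overflow*; it is engaged only at high NADPH (squared activation)
  and therefore never covers a deficit — NADPH shortfalls remain visible as
  negative availability in the productivity analysis, which is exactly the
  quantity the design scans report.

Anabolic precursor drains (G6P, F6P, GAP, PEP, PYR, AcCoA, αKG, OAA, R5P,
E4P) use classic biomass-composition coefficients (mmol/gDCW) scaled by μ,
each saturable in its precursor so an empty pool cannot be driven negative.

## Parameter provenance and calibration

The parameter file flags every entry `supplementary` (literature-printed;
currently only k_Anabolism = 14.849 mmol/gDCW) or `fallback` (this
package's own calibration). `k_ACE` is 5 g/l, reflecting the observation
that acetate above ~5 g/l inhibits growth; `k_ATP` is calibrated so the
wild type grows at ≈ 0.73 1/h on glucose. The fallback kinetic constants
were calibrated once, against qualitative physiology rather than any single
dataset:

* wild-type diauxie on glucose+xylose (< 5 % of xylose consumed before
  glucose depletion), with co-consumption in the Δpgi and ΔptsG knockouts;
* strong growth suppression of Δpgi on glucose (≈ 0.2 vs 0.73 1/h) driven
  by G6P accumulation (~50 mM) and NADPH inhibition of G6PDH, relieved by
  xylose addition;
* OPP-dominated NADPH production in Δpgi versus ICDH-dominated production
  in ΔptsG;
* chemostat growth on 4 g/l glucose feed up to D = 0.5 1/h, washout above;
* acetate overflow of a few tenths of a g/l per g/l glucose, reduced when
  the mevalonate pathway drains acetyl-CoA.

`validate-params` (CLI) audits the provenance flags; loading a parameter
file logs a prominent warning listing fallback entries.

## Numerics

* Stiff integration with `scipy.integrate.solve_ivp` (BDF; rtol 1e-8,
  atol 1e-10 defaults, scenario-configurable). Trajectories are reported on
  a dense-output grid (600 uniform points merged with the solver steps),
  which keeps the trapezoidal NADPH quadrature error well under 0.1 %.
* Batch runs stop at an event: both glucose and xylose below the depletion
  threshold (0.01 g/l). The cultivation time T is the event time, or the
  horizon if depletion is never reached. A zero-biomass batch returns a
  constant trajectory without integrating.
* Rate laws evaluate concentrations clamped at zero, so small solver
  undershoots cannot propagate; reported trajectories are clamped likewise.
* Chemostat steady states are found by integrating ~400 h and
  Newton-refining the endpoint on a conservation-reduced system (ADP, NAD,
  NADP and AMP eliminated through their moiety totals, which would
  otherwise make the Jacobian singular). Washout (biomass < 1e-4 gDCW/l) is
  reported as an outcome, not an error. At refined steady states every
  balance closes to ~1e-10 of the dominant term and |μ − D|/D < 1e-3.
* Design scans are deterministic; ties in `argmax` break toward the lower
  xylose content. The acceptance script scans at 5 % content resolution
  (21 points per strain), which resolves every optimum reported while
  keeping the full recomputation in the minutes range; the library default
  is 1 % steps.

## What the synthetic measured-flux fixture does and does not emulate

The flux-correlation utility compares a simulated flux vector with a
two-column (reaction, flux) table. Because no experimental flux dataset
ships with the package, the fixture generator perturbs a simulated
exponential-phase flux vector with seeded Gaussian noise (σ = 5 % of the
flux range) and writes it in the measured-table format. This exercises
name-matching, parsing and the correlation statistics; it does not emulate
the error structure of real 13C-MFA data (correlated errors,
reaction-dependent confidence intervals), so a high r against the fixture
validates the utility, not the model.

## Known limitations

* All rate laws are this package's own Michaelis–Menten parameterization;
  quantitative outputs (optimal xylose contents, peak productivities,
  improvement percentages) depend on that calibration and should be read as
  model-consistent magnitudes, not literature reproductions. The
  qualitative structure (diauxie dichotomy, interior Δpgi optimum, NADPH
  deficit signs, ArcA redesign gain) is robust in the test suite.
* In the mevalonate designs, ArcA overexpression raises the optimal xylose
  content relative to its own glucose-only case, but the direction of the
  shift between the Δpgi-MVA optimum and the ArcA redesign optimum is
  calibration-sensitive and is not asserted.
* Lumped reactions (L_Emp, PTACK, NPTS+Glk, SDH-Fum-MDH leg) report one
  flux for the whole lump; knockouts of a member gene disable the lump.
* No explicit CO2, oxygen, or osmotic constraints; carbon balance is not
  exactly closed (CO2-releasing steps discard the carbon).
* Transhydrogenase PntAB (NADH → NADPH) is deliberately absent so NADPH
  deficits stay visible; UdhA is present only as an overflow valve.
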