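# Methods

## The model

`hepaflux` simulates one hepatocyte's coupled glucose, acetaminophen (APAP)
and cysteine/glutathione metabolism, at a chosen position along the liver
sinusoid (periportal, intermediate or pericentral zone).  The network has
34 balanced metabolites and 47 reactions; three blood-side species
(glucose, lactate, cysteine) are boundary conditions held at scheduled
values, and APAP enters as a zero-order administration flux.

The biology the model is built to express:

* **Zonation.** Enzyme activities differ along the sinusoid.  Thirteen
  Vmax values are zone-dependent: glucose uptake (GLUT2), glucokinase,
  pyruvate kinase, fructose-2,6-bisphosphatase, aldolase,
  UTP-glucose-1-phosphate uridylyltransferase, CYP2E1 and UGT run higher
  pericentrally; fructose-1,6-bisphosphatase, cytosolic PEPCK, ER
  glucose-6-phosphatase, sulfotransferase and GSH synthesis run higher
  periportally.  All other parameters are zone-independent, so zonation is
  purely an activity (Vmax) pattern.
* **Glucose-drug crosstalk.** UDP-glucuronic acid (UDP-GA), the
  glucuronidation co-substrate, is made from glucose-1-phosphate via
  UDP-glucose.  Glycogen synthase competes for the same UDP-glucose pool,
  so the nutritional state (external glucose 4 mM fasting / 11 mM feeding)
  controls how much glucuronidation capacity the drug sees.
* **Hepatotoxicity readout.** CYP2E1 oxidises APAP to NAPQI, which is
  detoxified by GSH conjugation; when GSH runs low, NAPQI binds the free
  protein thiol pool and accumulates as protein adducts.

## Hybrid simulation scheme

Writing the network as `dx/dt = S v`, reactions are split into a
**dynamic** module (27 bottleneck reactions with explicit rate laws) and a
**static** module (20 fast reactions assumed at pseudo-steady state).
Species touched only by dynamic reactions (13 of them) form `x_d`; species
with at least one static reaction (21) form `x_s`.  With the blocks
`S_dd`, `S_sd`, `S_ss` of `S`, each integrator stage computes

    v_d  = rate laws(x, boundary)
    v_s  = -pinv(S_ss) @ S_sd @ v_d          (minimum-norm least squares)
    dx_d/dt = S_dd v_d
    dx_s/dt = S_sd v_d + S_ss v_s

The static balance `0 = S_sd v_d + S_ss v_s` is over-determined here
(21 equations, 20 unknowns, rank 19), so the least-squares residual is
generally non-zero.  That residual *is* the motion of `x_s`: it equals the
projection of `S_sd v_d` onto the left null space of `S_ss`.  In the
reference network that null space is spanned by two pool directions —

* the hexose-phosphate pool {G6P, F6P, G1P, G6P(ER)}, and
* the UDP-sugar pool {UDP-glucose, UDP-GA} —

so exactly these buffer pools evolve in time, with the imbalance shared
equally among pool members (the defining property of the pseudo-inverse
estimate), while every other static-module species stays at its
pseudo-steady value.  This is the mechanism behind the depletion
phenotypes: when gluconeogenic drain or glycogen-synthase demand exceeds
the uridylyltransferase supply, G1P, UDP-glucose and UDP-GA run down
together and glucuronidation collapses.

The pseudo-inverse is computed once per partition by SVD with a relative
singular-value cutoff (1e-10 x largest singular value); the per-step solve
is then a cached matrix-vector product.  Static flux estimates are
unconstrained in sign — a nominally irreversible fast reaction may carry a
negative least-squares flux, which is reported, not rejected.

## Integration and numerical choices

* Fixed-step explicit Runge-Kutta (RK4), default step 1e-3 h.  The fastest
  kinetic time scale in the reference model is NAPQI consumption
  (~1/200 h), comfortably inside the stability region; tests verify
  step-halving convergence on closed-form fixtures.
* Boundary-schedule breakpoints (feeding-to-fasting switches, end of the
  dosing window) are hit exactly: integration restarts at each breakpoint.
* Negative concentrations: transient integrator undershoot is clamped to 0
  after each step, and the cumulative clamped mass is reported in the
  result.  A *single-step* excursion below `-clamp_tolerance` (default
  0.05 mM) aborts the run.  The tolerance is deliberately a concentration
  scale, not machine epsilon: when a shared pool direction is exhausted,
  the equal-distribution rule keeps pushing a zeroed member slightly
  negative at a finite rate even though its own drains have stopped, and
  that overshoot is bounded by (rate x step / pool size), i.e. orders of
  magnitude below 0.05 mM in all supported protocols.  Anything larger
  indicates a genuine model error and should abort.
* Rate laws are compiled to closures grouped per reaction; the right-hand
  side is two small matrix products plus 27 scalar law evaluations.

## Rate laws and regulation

Units are mM and hours throughout.  The forms are mass action, irreversible
(multi-substrate) Michaelis-Menten, reversible Michaelis-Menten in the
convenience-kinetics shape, Hill, and zero-order (dosing only).  Allosteric
regulation is expressed as multiplicative Vmax factors
(`1 + a*M/(Ka+M)`, a Hill variant of the same, and `1/(1+M/Ki)`), which
keeps the zonation mechanism — per-zone Vmax overrides — orthogonal to
regulation.  The regulatory wiring of the glucose side:

* PFK1 activated, FBP1 inhibited by fructose-2,6-bisphosphate (the
  classical bifunctional-enzyme switch; PFK2/FBP2 set the F26BP level).
* Glycogen phosphorylase inhibited by intracellular glucose.
* Glycogen synthase activated by intracellular glucose through a
  switch-like Hill factor (n = 8, half point 8.57 mM).  This factor is the
  model's proxy for the insulin/glucagon signalling that is not modelled
  explicitly: it converts the fasting-to-feeding glucose step into a
  strong glycogen-synthesis response, which in turn drains the UDP-sugar
  pool in the feeding state.
* UTP-glucose-1-phosphate uridylyltransferase product-inhibited by
  UDP-glucose (Ki 1.04 mM), which stabilises the UDP pool at a finite
  level in every zone/state combination.
* GSH synthesis feedback-inhibited by GSH (Ki 3 mM).

## Parameter provenance and calibration

No kinetic parameter in the reference document is a literature transcript;
every parameter carries the provenance note `calibrated` in the document
metadata.  The calibration procedure, in order:

1. **Structure first.** Species/reaction inventory, module membership and
   the 13 zonated activities are fixed by the network design (counts
   34/47, 27/20, 13/21, 13) and never moved during calibration.
2. **Glucose side.** Vmax/Km values chosen so that the feeding state gives
   net glucose uptake and glycolysis (pericentral faster), the fasting
   state gives periportal gluconeogenesis and net glucose export, and the
   zonation orderings of the eight marker fluxes hold.
3. **UDP-sugar supply/demand.** The glycogen-synthase switch, the
   uridylyltransferase supply and the UGT co-substrate Km were fitted
   numerically (Nelder-Mead on the log-parameters, least squares against
   the four periportal contribution table rows) so that the fasting state
   keeps a UDP-GA reservoir while the feeding state runs it low.
4. **APAP routes and toxicity.** Pericentral route Vmax values, the GSH
   pool size/turnover and the NAPQI partitioning (GSH conjugation vs
   protein adduction) were fitted the same way against the four
   pericentral rows, with the adduct cells double-weighted because adduct
   formation is the hepatotoxicity readout.
5. **Presets.** The obese preset multiplies PEPCK and ER
   glucose-6-phosphatase Vmax by 1.5 (a literature direction and
   magnitude).  The infant preset's directions (glycogen synthase up,
   PEPCK and glycogen phosphorylase down) are established physiology; the
   default magnitudes (glycogen synthase x2.0, PEPCK x0.5, phosphorylase
   x0.3) are calibration knobs exposed in `PRESETS`, chosen so the infant
   pericentral feeding-overdose glucuronidation share lands on its
   reference value.

Contribution runs pre-equilibrate the drug-free model for 10 h at the
scenario's glucose level, then dose APAP at 0.5 or 6.0 mM/h for 30 min and
integrate the four elimination fluxes (trapezoid rule) over 5 h.
Percentages are reported to one decimal place.

## What the tests do and do not show

The toy-network generators provide independent oracles: linear mass-action
chains with matrix-exponential solutions, hand-solvable static splits, and
random over-determined static blocks checked against a normal-equation /
dense-SVD least-squares oracle.  These validate the *solver* and the
*integrator* exactly.

The reference liver model is validated semi-quantitatively: structural
counts, zonation orderings, transporter monotonicity, and contribution
tables under calibrated parameters.  Because the kinetic parameters are
calibrated to those same published summaries rather than measured, passing
tests demonstrate that the network structure plus the hybrid scheme *can*
reproduce the reported physiology — not that the parameter values are the
physiological ones.  Predictions outside the calibrated conditions
(other dose ranges, other zones' absolute fluxes) carry no quantitative
guarantee.

## Known quantitative gaps

Under the calibrated parameters the healthy-adult contribution table is
reproduced to within 2 percentage points per cell, but two perturbation
behaviours are only partially captured, and the corresponding tests are
expected to fail until the architecture changes:

* **Obese periportal-fasting glucuronidation collapse.**  Raising
  PEPCK/G6Pase by 50% should deplete G1P/UDP-glucose/UDP-GA completely and
  abolish glucuronidation in the fasting periportal zone while leaving all
  other scenarios untouched.  In this model the same perturbation only
  drains the UDP pool partially: with a large glycogen reservoir buffering
  the hexose-phosphate pool, the uridylyltransferase supply never collapses
  outright, and architectures that do collapse it (finite store, sharper
  G1P sensitivity) disturb the feeding-state scenarios that must stay
  unchanged.  The collapse appears to require a supply topology in which
  the gluconeogenic drain can exhaust an upstream buffer without touching
  the feeding-state operating point - a property the present single-pool
  least-squares coupling does not offer.
* **Infant pericentral overdose adducts.**  The infant preset reproduces
  the direction of every scenario and the glucuronidation share of the
  pericentral feeding overdose, but underestimates its protein-adduct
  share (about 11% vs 14%).  The model's pericentral oxidation load
  differs too little between fasting and feeding (the UDP-GA pool there is
  weakly state-dependent), so the GSH-depletion nonlinearity that amplifies
  adduct formation engages equally in both states; the adult
  fasting-overdose adduct cell pins the shared NAPQI-partitioning
  parameters and leaves no calibration headroom.

## Known limitations

* No sinusoidal blood flow between zones: each zone is simulated as an
  isolated hepatocyte against fixed blood-side boundary values.
* No oxygen/HIF or growth-factor regulation, no fatty-acid metabolism, no
  gene-expression layer.
* Cofactors (ATP/ADP, NAD(H), UTP) are not balanced; their effects are
  absorbed into effective rate constants.
* The static-module least-squares estimate distributes imbalance equally
  within a pool direction; species-specific buffering inside a pool is not
  represented.
* The insulin/glucagon axis is reduced to a glucose-dependent activity
  factor on glycogen synthase.
* Problem sizes in the test-suite runs (10 h equilibration windows, 2-4e-3
  h steps for qualitative suites) are chosen for fast, deterministic
  verification; the library defaults (1e-3 h, longer windows) are the
  reference configuration.
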