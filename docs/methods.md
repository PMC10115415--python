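# Methods

## The model

The package models the competition for the trimethylated histone H3 tail
(H3K4me3, label **H**) between the MLL1 PHD3-BRD reader module (**M**), the
peptidyl-prolyl isomerase Cyp33 (**C**), and a single-site RNA element
carrying a Cyp33 recognition motif (**R**).  Nine species interact through
six reversible mass-action reactions:

| reaction | Kd (μM) | origin |
|---|---|---|
| M + H ⇌ MH | 4 | ITC, intact PHD3-BRD reader |
| C + M ⇌ CM | 4.6 | ITC |
| CM + H ⇌ CMH | 70 | ITC, ternary with the α3 helix engaged |
| C + R ⇌ CR | 300 | NMR titration, single UAAUGU motif |
| R + H ⇌ RH | 30 | ITC |
| C + MH ⇌ CMH | 80.5 | derived (detailed balance) |

The species set deliberately excludes explicit cis/trans proline conformers
of the MLL1 linker and the isomerization step itself: the 4 μM M–H constant
describes the intact reader, and the Cyp33 binding steps implicitly include
any coupled isomerization.  RNA is one binding site, occupied exclusively by
either Cyp33 or the H3 tail (no C·R·H ternary), because the RNA-binding
surface of the Cyp33 RRM is occluded in the Cyp33–PHD3 complex and the
single-site assumption is the conservative choice for a repeat-motif RNA.

**Detailed balance.**  C, M and H can assemble into the ternary CMH along
two paths, forming a thermodynamic square.  Only three of its edges are
independent; the C+MH edge is therefore always *derived* as
Kd(C–M)·Kd(CM–H)/Kd(M–H) = 4.6·70/4 = 80.5 μM and can never be set directly
(attempting to override or scan it raises).  This guarantees that the product
of equilibrium constants around every closed cycle is exactly one, so the
ODE system has a true equilibrium with zero net flux in each reaction.

**Kinetics.**  Individual on-rates are not measured; every association is
assigned a common diffusion-limited on-rate of 10 μM⁻¹ s⁻¹ (10⁷ M⁻¹ s⁻¹)
and off-rates follow from koff = kon·Kd, spanning 0.046–3000 s⁻¹.  Units are
fixed package-wide: μM, seconds, μM⁻¹ s⁻¹.  Censored constants (the KRK
mutant's "Kd > 10 mM") are stored as flagged lower bounds and refuse kinetic
use.

**Equilibrium solver.**  Equilibria are computed algebraically, not by long
integration: each complex concentration is expressed through overall
association constants times free-monomer concentrations, and the free
concentrations are found by damped multiplicative fixed-point iteration on
the conservation equations (damping 0.5 in log space, cap 10⁵ iterations)
with a dense log-space root-finder fallback.  The solution is verified
against per-reaction net flux (< 1e-9 μM/s, referenced to the 100 μM working
scale because mass-action flux grows quadratically with concentration) and
against long-time stiff ODE integration (LSODA, rtol 1e-8, atol 1e-10 μM) in
the tests.  Species ordering is lexicographic so all matrices are
deterministic.

## The transcription pulse

The reference scenario starts at equilibrium with M = H = 100 μM (82% of the
H pool MLL1-bound).  At t = 5.6 min, zeroth-order synthesis of free R and
free C switches on together with first-order decay (kdeg = 0.005 s⁻¹) of the
*free* monomers; at t = 22 min synthesis stops and decay drains both species
again.  Synthesis rates are calibrated numerically (multiplicative
fixed-point on short simulations) so each pulsed species' total peaks at
100 μM at switch-off; decay restricted to free monomers means complexes
release their partners by mass action before removal, which leaves the
slowest relaxation mode — drainage of complexed Cyp33 — with a ~20 min
effective time constant.  The default horizon is therefore 120 min, by which
point the system has returned to the pre-trigger equilibrium to well under
1 μM per species.  Output resolution is 1 s with integrator restarts at
event times.

The H pool is partitioned into **active** = [MH] + [CMH] (reader-bound) and
**repressive** = [H] + [RH] (reader-free); the partition is exhaustive and
any unclassified H-containing species raises unless assigned.

At the four-component working point (all totals 100 μM) the repressive state
holds a slight majority (fraction 0.550).  Pulsing RNA alone (0.314) or
Cyp33 alone (0.402) leaves the active state dominant; the switch genuinely
requires both.  One robustness claim does **not** hold in this minimal
network: weakening the RNA–H3K4me3 affinity to 500 μM drops the repressive
fraction to 0.409, below one half (the share falls monotonically with that
Kd toward a floor of 0.387 where RNA acts only as a Cyp33 sink).  Retaining
dominance at 500 μM evidently requires ingredients beyond the nine-species
reconstruction — multivalent RNA avidity or explicit conformer states — for
which no measured rates are available, so the package reports the minimal
network's behavior rather than tuning unmeasured parameters to force the
claim.

## Assay layer

**Fast-exchange NMR titration.**  Under fast exchange the observed shift is
the population average δ_obs = δ_free + (δ_bound−δ_free)·f_bound with
f_bound from the exact 1:1 quadratic.  The fitter does nonlinear least
squares over (log Kd, δ_bound) with δ_free fixed, multi-started across Kd
decades 0.1–10⁵ μM; flat series (span below 3× a successive-difference noise
estimate) are flagged non-binding, and designs that never leave the linear
regime get a poorly-constrained flag.  Intermediate-exchange line broadening
is ignored, as licensed by the fast-exchange regime of the weak RNA
interactions.

**Combined CSP** uses the standard weighted Euclidean form
√(δH² + (0.2·δN)²); the 0.2 nitrogen weight is common practice and
configurable.

**ITC.**  Heats follow a sequential-injection single-site model with
displacement dilution: each injection of volume v dilutes prior cell
contents by (1 − v/V₀), totals are tracked per injection, and
q_i = V₀·ΔH·([PL]_i − [PL]_{i−1}(1−v/V₀)) in μcal.  The fitter recovers
(n, Kd, ΔH) by multi-start least squares; a Wiseman c-value n[cell]/Kd
outside [0.1, 10⁴] flags the Kd as low-confidence.  Baselines are assumed
pre-subtracted and the first injection can be discarded by flag.

**PPIase coupled assay.**  Progress curves of the chymotrypsin-coupled
isomerization assay are single exponentials A∞ − ΔA·e^(−k_obs t) with
k_obs = k₀ + TN·E/S₀.  The turnover number TN is operationalized as the
initial enzymatic velocity per enzyme at the assay substrate concentration
(default S₀ = 50 μM cis substrate, k₀ = 0.02 s⁻¹ thermal background), since
the assay's substrate concentration and Km are not part of the packaged
record; generator and fitter share this definition, which makes recovery
well-posed but means the absolute numbers should not be reinterpreted as
kcat.  Each curve is fit per-exponential; k_obs is then regressed on E/S₀
weighted by its standard error (slope = TN, intercept = k₀).  The slope is
invariant to arbitrary rescaling of the absorbance signal.

## Synthetic data

Generators produce each assay family from its forward model plus additive
Gaussian noise, seeded and bit-reproducible, with generator parameters
embedded in the object/file metadata so recovery tests never hard-code
truths.  Defaults emulate instrument-scale scatter: titration σ = 0.005 ppm,
ITC σ = 2% of the largest heat, PPIase σ = 1% of the signal amplitude.
Default designs: titrations at 100 μM protein with 0–8 ligand equivalents
(14 points; a widened 0–40 equivalent grid for millimolar binders), ITC with
20 × 2 μL injections into a 200 μL cell, enzyme grid 5–40 nM plus a blank
over 120 s progress curves.  Protein-observed titrations default to a
reporter amide proton moving 8.30 → 8.10 ppm, a typical strongly perturbed
resonance; the H3K4me3-peptide reporter (3.15 → 3.12 ppm) is used where that
titration is modeled.  What the generators do *not* emulate — baseline
drift, injection artifacts, exchange broadening, pipetting error in totals —
means recovery tests demonstrate correctness of the inference machinery at
realistic noise, not robustness to every experimental pathology.

## Numerical notes and limitations

* One published figure is internally tense: 200 μM single-motif RNA is
  described as leaving Cyp33 more than 50% bound, while the simple 1:1 model
  at Kd = 300 μM predicts ~40%; full-length Cyp33 may bind tighter than the
  RRM alone.  The package does not attempt to reconcile this.
* Mutant RNA constants (WLF, K83A, RK; KRK censored) ship in the parameter
  set for assay-recovery work; the default network always uses the wild-type
  value.
* Stochastic (Gillespie) simulation, spatial models, multivalent RNA
  avidity, temperature corrections and enthalpy/entropy decomposition are
  out of scope.
* Fitters use Levenberg–Marquardt refinement from the multi-start grid
  (xtol/ftol 1e-12); standard errors come from the linearized covariance at
  the optimum and are approximate for strongly non-linear posteriors (weak
  binders near the design edge).
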