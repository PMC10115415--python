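# cyp33switch

Quantitative model of the chromatin switch by which RNA-stimulated Cyp33
binding flips MLL1 target genes from an active to a repressive state — for
structural biologists and modelers who want to reason about the coupled
binding equilibria, and for assay analysts who want the underlying NMR, ITC
and PPIase computations as reusable, tested code.

## The science

The H3K4me3 mark (**H**) is read by the MLL1 PHD3-BRD module (**M**,
K_d = 4 μM).  The prolyl isomerase Cyp33 (**C**) binds MLL1 PHD3
(K_d = 4.6 μM) and weakens the reader's grip on the mark (ternary
CM + H ⇌ CMH, K_d = 70 μM); RNA bearing Cyp33's UAAUGU motif (**R**) binds
Cyp33 weakly (K_d = 300 μM per site) and can also accept the released H3
tail (R + H ⇌ RH, K_d = 30 μM).  These five measured constants, plus one
edge fixed by detailed balance
(K_d(C+MH) = 4.6·70/4 = 80.5 μM), define a nine-species mass-action network.
Given per-monomer totals **T**, the equilibrium solves

    [X] = β_X · ∏_m [m]^ν_mX ,   Σ_X ν_mX [X] = T_m ,

with overall association constants β from the K_d's; dynamics follow the
mass-action ODEs with diffusion-limited on-rates (10 μM⁻¹s⁻¹).  The H pool
is split into **active** ([MH]+[CMH], reader-bound) and **repressive**
([H]+[RH]) states.

The package also implements the assay computations that produced the
constants — fast-exchange NMR titrations (δ_obs population averaging),
combined [¹H,¹⁵N] CSP, sequential-injection ITC isotherms and the
chymotrypsin-coupled PPIase assay — together with seeded synthetic-data
generators, so every fitter is validated by parameter recovery end to end.
See `docs/methods.md` for the full model description.

## Worked example

```sh
$ cyp33switch equilibrate --totals M=100,H=100
...
active        81.9002 uM  (0.8190)
repressive    18.0998 uM  (0.1810)

$ cyp33switch equilibrate --totals M=100,H=100,C=100,R=100
...
active        45.0052 uM  (0.4501)
repressive    54.9948 uM  (0.5499)
```

With only reader and mark present, 82% of the H3K4me3 pool is MLL1-bound
(the 1:1 quadratic at 100 μM each, K_d 4 μM).  Adding Cyp33 and RNA at the
same concentration tips the balance: 55% of the mark is now reader-free —
the modeled repressive switch.  The time-resolved version (equilibrated
start, RNA transcription triggered at t = 5.6 min, switched off at 22 min,
each pulsed species peaking at 100 μM):

```sh
$ cyp33switch simulate --scenario pulse --out pulse.csv
$ cyp33switch simulate --scenario rna_only --out rna_only.csv
```

shows the same plateau (repressive 55.04 μM vs active 44.96 μM) and full
relaxation back to the starting equilibrium after switch-off, while the
single-component controls stay active-dominant (RNA-only: 68.6 μM active vs
31.4 μM repressive; Cyp33-only: 59.8 vs 40.2) — both RNA and Cyp33 are
required.  Assay-side:

```sh
$ cyp33switch --seed 1 gen titration --pair C-R --out wt.csv
$ cyp33switch fit titration wt.csv
          kd = 327.018 ± 30.5
 delta_bound = 8.09354 ± 0.00816
```

a synthetic wild-type Cyp33–RNA titration (truth 300 μM, σ = 0.005 ppm)
refit within its stated uncertainty.

The numbered scripts under `analysis/` run the same computations as a
narrative pipeline — equilibria, the pulse and its controls, the
RNA–H3K4me3 affinity sweep, and a recovery table for all packaged
constants — writing their tables to `results/`.

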