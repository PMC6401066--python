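# sas6flex

Quantitative analyses of how a flexible protein loop strengthens a weak
dimerisation interface, built around the *C. elegans* SAS-6 N-terminal
domain — the protein whose ring-shaped oligomers seed the 9-fold symmetric
cartwheel at the core of centrioles.

SAS-6 oligomerisation is driven by a strong coiled-coil (CC) interface and a
weak N-terminal (NN) interface (K_d on the 100 µM scale). A ~30-residue
disordered loop (K101–T131, between helix α2 and strand β5) transiently
contacts the structured core across the NN interface and stabilises the
dimer without ever folding — a "fuzzy" interaction. `sas6flex` implements
the analysis stages by which that claim is quantified, plus seeded synthetic
generators so every stage is testable offline:

| stage | module | statistic |
|---|---|---|
| NMR flexibility | `sas6flex.nmr` | secondary shifts Δδ(Cα/Cβ) vs random coil; hetNOE < 0.6 segmentation; intensity-vs-salt regression |
| contact dynamics | `sas6flex.contacts` | residue-pair contact occupancy (min heavy-atom distance < 3.5 Å) over trajectories |
| steered pulls | `sas6flex.pulling` | work-vs-distance W = ∫ k(λ−d) dλ, separation detection, ensemble comparison |
| self-association | `sas6flex.binding` | monomer–dimer isotherm fit: P = p_base + dp_max·f(C, K_d), f from 2M ⇌ D mass action |
| ring assembly | `sas6flex.ring` | isodesmic chain + ring-closure equilibrium: [A_j] = [A₁]ʲ/K_d^(j−1), [Ring] = γ[A₁]ⁿ/K_dⁿ |
| synthetic data | `sas6flex.synthetic` | seeded generators planting known ground truth for all of the above |

## Worked example

Fit a wild-type-like polarisation titration and ask what a 2-fold affinity
gain does to 9-ring assembly:

```python
from sas6flex import (DimerModelParams, fit_self_association, affinity_fold_change,
                      AssemblyParams, fold_change)
from sas6flex.synthetic import TitrationDesign, gen_titration

design = TitrationDesign.log_spaced(seed=1)          # 3 reps, 12 pts, 1–1000 µM, σ=2 mP
wt  = fit_self_association(gen_titration(DimerModelParams(100, 80, 60), design), n_boot=300)
var_design = TitrationDesign.log_spaced(seed=4)
var = fit_self_association(
    gen_titration(DimerModelParams(50, 80, 60), var_design, "S123E"), n_boot=300)

ratio, ci = affinity_fold_change(wt, var)
print(f"WT  K_d = {wt.kd:.1f} µM  (95% CI {wt.kd_ci[0]:.0f}–{wt.kd_ci[1]:.0f})")
print(f"var K_d = {var.kd:.1f} µM")
print(f"fold-change = {ratio:.2f}  (95% CI {ci[0]:.2f}–{ci[1]:.2f})")

ring = fold_change(AssemblyParams(kd_nn=100.0, c_total=1.0), kd_alt=50.0)
print(f"9-ring likelihood gain at 1 µM units: {ring['fold_change']:.0f}x")
```

prints

```
WT  K_d = 104.2 µM  (95% CI 80–133)
var K_d = 46.6 µM  (95% CI 38–59)
fold-change = 2.24  (95% CI 1.48–3.04)
9-ring likelihood gain at 1 µM units: 431x
```

The fitted affinities recover the planted 100 and 50 µM ground truths within
their confidence intervals; the ratio is the ~2-fold gain a single-residue
substitution in the loop can produce. Because a closed 9-ring carries nine
NN bonds, that 2-fold gain is amplified to a 10²–10²·⁷-fold increase in the
likelihood that a full ring assembles (512× in the dilute limit, less at
working concentrations) — small local changes in a disordered loop make an
effective switch for cartwheel formation.

A shell front end wraps the same stages
(`sas6flex gen-titration --out run1 --set seed=1`,
`sas6flex fit-dimer --out fit1 --input titration=run1/titration.csv`, …);
each run writes its outputs next to a `manifest.txt` echoing the effective
parameters and seeds.

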