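# Methods

This note documents the models implemented in `sas6flex`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter.

## Monomer–dimer self-association (`binding`)

The NN interface is modelled as ideal two-state self-association,
2M ⇌ D with K_d = [M]²/[D] on the protomer basis (total protomer
concentration C = [M] + 2[D]). The free monomer has the closed form
[M] = (−K_d + √(K_d² + 8 K_d C))/4, and the dimer fraction
f = (C − [M])/C satisfies f(K_d) = ½ exactly. The polarisation observable
is affine in f, P = p_base + dp_max·f; the fluorophore is assumed to be a
passive reporter of the dimer status of its carrier (the labelling scheme
is not modelled; no rotational-diffusion photophysics).

Fitting is weighted nonlinear least squares over (log₁₀K_d, p_base,
dp_max), jointly across replicates, weights 1/σ per point. K_d is
parameterised on a log scale for positivity and optimiser stability, with
an upper bound at 10× the largest concentration. Requirements: ≥ 5 distinct
concentrations; a span below one order of magnitude is recorded as a
warning. Confidence intervals are percentile bootstrap (default 1000
resamples, fixed seed), resampling points *within* each replicate to
respect the replicate structure of a three-experiment titration series.

Non-association is flagged, not fitted: a titration is reported
`associating=False` when (i) the fitted K_d reaches its upper bound,
(ii) the asymptotic 95% interval on dp_max includes zero, or (iii) the 95%
interval on log₁₀K_d is wider than one decade on each side. The third
criterion is this package's own addition: flat data with ~2 mP noise can
produce a nominally "significant" few-mP amplitude, but never a bounded
affinity, so the unbounded-K_d test is the reliable discriminator.

The fold-change between two conditions is K_d(weaker)/K_d(tighter), with an
interval from pairing the two bootstrap sample streams.

Under the default synthetic design (3 replicates × 12 log-spaced points,
1–1000 µM, σ = 2 mP, dp_max = 60 mP) the K_d estimator's sampling standard
deviation is ≈ 13% (the design does not reach saturation at 1000 µM for
K_d = 100 µM, so K_d and dp_max are correlated); the median relative error
across seeds is below 10%.

## NMR flexibility (`nmr`)

**Secondary shifts.** Δδ = δ_obs − δ_rc per residue for Cα and Cβ. The
bundled random-coil reference (`data/random_coil_shifts.csv`) is the
standard Wishart-style 20-residue Cα/Cβ table used by chemical-shift-index
practice; any other reference table can be passed explicitly. Glycine
carries no Cβ; missing observations propagate as missing.

**CSI-style classification.** Helix: Δδ(Cα) > +τCα; strand:
Δδ(Cα) < −τCα; a Cβ deviation pointing firmly the opposite way
(|Δδ(Cβ)| > τCβ with the contradicting sign) vetoes the call. Defaults
τCα = 0.7 ppm, τCβ = 1.0 ppm, minimum element length 4 — standard CSI
practice; the planted generator magnitudes (helix +3.0/−0.5, strand
−1.5/+2.0 ppm) sit comfortably beyond them. Structured runs shorter than
`min_len` are demoted to coil. No smoothing is applied before thresholding.

**hetNOE segmentation.** Residues with {¹H}-¹⁵N NOE ratio < 0.6 (strict)
are flexible; maximal runs are reported, with unmeasured gaps (prolines,
unassigned or overlapped resonances) of ≤ `max_gap` = 2 residues bridged so
a contiguous loop is not split by a missing assignment, and runs shorter
than `min_run` = 3 dropped. Measured rigid residues always terminate a run —
only genuinely unmeasured positions bridge. Segmentation is idempotent and
every flexible residue satisfies the threshold where measured. Ratios are
sanity-bounded to [−1.5, 1.2].

**Intensity trends.** Ordinary least squares of normalised resonance
intensity against salt concentration (≥ 3 points), reporting slope,
intercept, R² and residual SD; the closed-form two-parameter solution is
the test oracle.

## Contact occupancy (`contacts`)

Occupancy(a, b) = #frames with min-distance(a, b) < cutoff, divided by
n_frames. Defaults: cutoff 3.5 Å, heavy atoms only (the conservative
convention when a protocol does not state protons), strict `<` so a pair at
exactly the cutoff is *not* in contact. Per-residue marginals report the
fraction of frames a residue contacts *any* partner-group residue (the
quantity meaningful for "in contact for over half the time"), plus max and
mean pairwise occupancies. Replicate aggregation requires a shared cutoff
and residue universe and flags residues whose mean any-contact occupancy
exceeds 0.5.

No periodic-boundary imaging is applied; trajectories imported from
periodic MD engines must be pre-imaged. Occupancy is invariant to frame
order, symmetric under group swap, monotone in the cutoff, and chunked
evaluation is exact (integer frame counts).

## Steered-pull work (`pulling`)

Force: F(t) = k(λ(t) − d(t)) with λ the harmonic restraint centre and d the
collective variable, both in Å, k in kJ/mol per nm of extension (the
steered-MD convention); the Å→nm conversion lives in one constant. Work is
the trapezoidal integral of F over the *restraint-centre* displacement —
the external work done by the moving restraint, which is what pulling
engines report — not over d(t). The instantaneous harmonic spring energy is
deliberately excluded; with a stiff restraint the two conventions differ by
at most ½k(λ−d)², which is bounded and small. Negative force contributes
negative work; nothing is clipped.

Separation is the first frame opening a run of ≥ `persistence` = 10
zero-contact frames, guarding against transient fluctuations. Ensembles are
compared at the largest pulled distance common to all replicates: group
means, per-replicate final works, the fraction of cross-group pairs ordered
group1 > group2 (ties ½), and a two-sided Wilcoxon rank-sum test.

## Ring assembly (`ring`)

Nine coiled-coil dimer units ("units", taken as preformed) associate
head-to-head through identical NN bonds. The model is isodesmic chain
growth with one ring-closure step: [A_j] = [A₁]ʲ/K_d^(j−1) and
[Ring] = γ[A₁]ⁿ/K_dⁿ, statistical factors absorbed into the effective
ring-closure concentration γ (default 1000 µM, exposed). [A₁] is solved
from unit conservation by Brent root finding on log[A₁] over
[10⁻¹²·c_total, c_total]; the mass-balance residual is verified to 10⁻¹⁰
relative on every solve. Equilibrium only — the assembly claim is a
likelihood statement, not a kinetic one.

Ring likelihood = n[Ring]/c_total, the fraction of units sequestered in
closed rings. In the dilute limit it scales as K_d⁻ⁿ, so halving K_d gives
2⁹ = 512× for the 9-ring (2⁸ for the open 9-chain). The documented dilute
closed form truncates the chain series at dimers — [A₁] from the
monomer–dimer quadratic — which is solver-free and agrees with the full
solver to well under 1% for c_total ≤ K_d/100 (the naive power law in
c_total alone is off by the (a₁/c)⁹ chain correction, ≈ 1.8% already at
c_total = K_d/1000). At working concentrations of 0.1–10 µM units, halving
K_d from 100 to 50 µM raises the 9-ring likelihood by ≈ 145–500×,
approaching 512× from below as c_total → 0. The absolute likelihood is
sensitive to γ; the *fold-change* under an affinity change is nearly
γ-independent in the dilute regime, which is why fold-change is the robust
quantity. No ring stacking, no CC-interface equilibrium, no geometry.

## Synthetic generators (`synthetic`)

All generators are pure functions of their seed (fresh
`numpy.random.default_rng` per call; no global state).

* **Titrations** — model values plus i.i.d. Gaussian noise; replicate r of
  a design seeded s draws from seed s + r. Defaults: 3 replicates,
  12 log-spaced points 1–1000 µM, σ = 2 mP — a typical three-experiment FP
  series on a 100 µM-scale interaction.
* **hetNOE profiles** — rigid level 0.82, flexible level 0.35, Gaussian
  noise (default σ 0.05), clipped to [−0.5, 1.0]; a planted span such as
  101–131 in a 168-residue construct emulates a long disordered loop.
* **Shift profiles** — planted Δδ patterns per element span plus noise.
* **Bead-dimer trajectories** — one bead per residue, two chains 20 Å
  apart. Each loop residue carries an independent two-state Markov chain
  with stationary contact probability `p_on` and persistence `p_stay`
  (off→on probability p_on(1−p_stay)/(1−p_on), validated ≤ 1; the chain
  starts from its stationary distribution, so occupancy is unbiased at any
  length). Contact frames place the bead at half the cutoff from its
  designated partner; otherwise it sits on its chain, beyond twice the
  cutoff. The standard error of realised occupancy follows the
  autocorrelated-chain formula π(1−π)(1+ρ)/((1−ρ)n) with ρ = p_stay − p_on→on.
* **Pull traces** — 1-D overdamped Langevin particle (Euler–Maruyama) in a
  Gaussian adhesion well centred at the start separation, pulled by a
  harmonic restraint moving at constant velocity (defaults k = 1000
  kJ/mol/nm, v = 1 Å/ns, 20 ns → 20 Å pulled, matching a typical steered-MD
  protocol). Well depth 30 kJ/mol models the core interface;
  `extra_adhesion_depth` (0 for the loop-deletion analogue, 20 kJ/mol for
  the loop-bearing condition) adds the loop contribution. Friction
  γ = 100 kJ·ns/(mol·nm²) sets a friction-work baseline γvD ≈ 20 kJ/mol
  over the pull; stability requires dt < γ/k, enforced with the bound in
  the error message.
* **Intensity series** — straight line in [NaCl] plus noise, clipped at 0.

What the generators do **not** emulate: real NMR peak overlap and
assignment errors, chemical-exchange broadening lineshapes, all-atom
energetics and solvent (bead contacts are geometric, pulls are 1-D),
non-ideality and activity corrections in the titrations, and instrument
drift. Passing tests therefore demonstrate that the analysis stages recover
planted statistical structure of the stated form — not that real spectra or
trajectories would be free of systematic effects outside these models.

## Problem sizes and numerics

Default test and demonstration sizes: 5000-frame bead trajectories for
occupancy convergence (3-SE tolerance), 14 + 14 matched-seed pull
replicates per ensemble comparison, 2000-step Langevin integration per
pull, 200–1000 bootstrap resamples per titration fit, 10 seeds for
segmentation-recovery checks. The equilibrium solver uses machine-precision
Brent tolerances; work integration is trapezoidal (second-order in the
step); OLS agrees with the closed form to 10⁻¹⁰ relative. Degenerate
inputs — empty profiles, non-monotone time, overlapping spans, infeasible
Markov parameters, unstable time steps — are rejected with specific errors
rather than silently handled.
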