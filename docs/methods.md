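# Methods

`ramdpath` reproduces, at desk scale, the analysis workflow of a τRAMD
(random-acceleration molecular dynamics) ligand-unbinding study: driven
unbinding simulations structured as replicas × runs, classification of each
dissociation event into one of two egress pathways, bootstrap/chi-square
pathway statistics, residence-time estimation, and the structural
post-processing steps (side-chain torsions, contact series, TICA
free-energy profiles).  The all-atom receptor is replaced by an analytic
model landscape; everything downstream of the simulator operates exactly as
it would on real trajectories.

## The model landscape (`toy_system`)

A single ligand bead moves in a potential (kJ/mol, lengths in nm) composed
of:

* **Binding well** — inverted Gaussian, depth 30 (≈ 11.5 kBT at 313 K),
  width 0.35, centered at the origin.  Energy zero is the dissociated state,
  so the bound minimum sits at exactly −30.
* **Confining shell** — a Gaussian ridge in the radial coordinate at
  R = 1 nm (width 0.12, height 400) whose angular height dips along exactly
  two directions, the *external* and *internal* channel axes (105° apart,
  mirror images through the z = 0 plane).  The dip depth at each axis is the
  channel's **gate barrier**; the angular half-width (0.35 rad) is the
  channel width.
* **Septum** — a repulsive slab on the mirror plane with compact radial
  support (cosine switches, on between r = 1.0–1.3, off at 7.0–7.5).  It
  represents the receptor body that separates the two egress routes outside
  the binding site: without it the far field is empty space and a
  dissociating bead can drift from one route's far field into the other's,
  which would corrupt the final-frames classification.  Inside the binding
  site and far beyond the dissociation distance it is identically zero.
* **Tether (optional)** — a breakable harmonic anchor
  ½k(d−rest)²·S(d), with S a C1 cosine switch that turns the interaction
  off at `breakable_at`; it stands in for an ionic anchor interaction.
  Anchors are placed at their rest length from the bound pose so the bound
  state energy is unchanged.

All terms are analytic; forces are exact gradients (finite-difference
checked at 1e−5 relative tolerance).  A guard radius of 1e−9 nm around the
well center removes the (exponentially negligible, < 1e−12 kJ/mol/nm)
directional ambiguity of the shell term at r = 0.

### Gate calibration

Under the protocol's random force F = 376.56 kJ/mol/nm, a Gaussian gate of
height b and radial width 0.12 exerts a maximum restoring force
≈ 5.06·b.  Three calibrated heights are frozen in the archetypes:

| gate | height (kJ/mol) | max force vs F | behaviour |
|------|-----------------|----------------|-----------|
| easy | 10  | 51 ≪ 377   | crossed on first aligned attempt |
| slow | 70  | 354 ≈ 377  | crossed after repeated attempts (p ≈ 0.05–0.1 per attempt) |
| blocking | 500 | 2530 ≫ 377 | never crossed (residual tilted barrier ≫ kBT) |

The four archetypes encode the qualitative ligand classes: `agonist_like`
(external slow, internal blocking — single egress route), `cationic_like`
(external blocking, internal easy, plus a breakable tether toward the
internal side), `neutral_like` (two equal slow gates — both routes used),
`symmetric` (two equal easy gates, exact mirror symmetry; the null system
for the 50:50 checks).  `agonist_like` and `neutral_like` share the same
external gate, so their residence-time comparison isolates the effect of
the second (internal) route.

Mutant modifications apply to `neutral_like` only:
`remove_all_anchor_interactions` deletes the internal gate and any tether
(egress flips to ≥ 95 % internal); `remove_gate_bond` replaces the
hydrogen-bond gate (70) by a weaker compensating ionic gate (55) plus a
weak breakable tether — internal egress becomes easier but both routes stay
in play.  A tether alone cannot produce the mixed-exit phenotype in this
landscape: anchored inside it biases *attempts* toward its own side, and
anchored at the gate it is algebraically just another shell barrier, so the
residual-gate representation was chosen.

## Dynamics and the unbinding protocol (`ramd_engine`)

Overdamped (Brownian) dynamics replaces all-atom MD:

    x' = x + μ (F_landscape + F_random) dt + sqrt(2 μ kB T dt) ξ

with mobility μ = 0.01 nm²/(kJ/mol)/ps, T = 313 K, dt = 0.002 ps.  Only
egress geometry and relative kinetics are analysed, so no thermostat or
barostat machinery is modelled.  The mobility is chosen so a full
5 × 20-run protocol finishes in roughly one to two minutes on one CPU.

The random-acceleration protocol applies a constant-magnitude force
(9 kcal/mol/Å → 376.56 kJ/mol/nm) along a uniformly random unit vector and,
after every 50 fs evaluation window, re-draws the direction iff the
straight-line ligand displacement over that window fell below a threshold.
Dissociation is the first saved frame more than 6 nm from the reference
marker; runs hitting `max_time` are kept and flagged censored, never
dropped.

**Threshold calibration.**  The protocol's displacement threshold exists to
distinguish a stalled ligand from a moving one.  In Brownian dynamics at
313 K the thermal window displacement is √(6 μ kB T Δt_w) ≈ 0.09 nm while
the free drift is μFΔt_w ≈ 0.19 nm, so the discriminating value must sit
between them: the default is 0.08 nm (detects stalls on ~70 % of windows,
false re-draws in free flight ~2 %).  A threshold far below the thermal
displacement — meaningful for an inertial all-atom ligand — cannot separate
the two regimes here: stall detection would require
√(6 μ kB T Δt_w) < threshold and motion detection μFΔt_w > threshold
simultaneously, which at this force and window is only possible below
~19 K.  The threshold is an ordinary parameter; the protocol logic is
exercised in tests at several values, including 0.0025 nm.

The replica protocol equilibrates each replica with 10⁴ unperturbed
Langevin steps from the well center (a deliberately reduced stand-in for a
staged MD equilibration), then launches `n_runs` RAMD runs from that start.
Seeds derive from `(base_seed, replica, run)` through `SeedSequence`, so
every run is reproducible in isolation and results are independent of
execution order.

## Pathway classification (`path_classifier`)

A trajectory is assigned to the route whose representative marker it ends
up closest to: d_path = min over the final 10 frames of the minimum
ligand–marker distance; smallest d wins.  Two machine flags replace manual
curation: **ambiguous** when |d_ext − d_int| ≤ 0.5 nm (configurable; the
cases a human would inspect visually), **outlier** when both distances
exceed 10 nm.  Flagged trajectories are excluded from probabilities but
always counted and reported.  On simulated data the classifier is audited
against the recorded ground-truth exit channel (≥ 99 % agreement among
resolved runs).

Pathway probabilities are proportions over resolved trajectories; their
standard errors come from a flat bootstrap over trajectories (2000
resamples; a replica-stratified variant is available).  Preference against
a random 50:50 split uses the one-sample chi-square statistic with one
degree of freedom and no continuity correction — with integer splits of
100, (42, 58) gives p ≈ 0.110 and (71, 29) gives p ≈ 2.7 × 10⁻⁵.

## Residence times (`kinetics_stats`)

Per replica, the residence time is the interpolated 50th percentile of that
replica's dissociation times (the time by which half the runs have
dissociated); its uncertainty is the SD over 2000 bootstrap resamples.  The
bootstrap *mean* is deliberately not used as the point estimate: on
right-skewed samples it inflates the median by several percent at n = 20
(the plain interpolated median carries ≈ +3.7 % bias on exponential
samples at that size, the bootstrap mean about twice that).  Per ligand,
the summary is the mean and sample SD over replica estimates; censored runs
are excluded from estimates but counted, with a censored-as-max-time mode
for sensitivity checks.  Cross-ligand comparison uses classical one-way
fixed-effects ANOVA (scipy's implementation behind the module surface,
verified against a hand-rolled sums-of-squares oracle).

## Structural features (`structure_features`)

Signed torsions use the standard two-plane atan2 construction (verified
against an independent projection oracle and MDAnalysis; invariant under
rigid motion and under atom-order reversal, antisymmetric under
reflection).  Chi1 shifts between initial and final frames are circular
means wrapped to (−180°, 180°], with a configurable atom-name map so toy
beads work alongside real residues.  Contact series report per-frame
minimum heavy-atom distances plus boolean calls at package-convention
cutoffs (0.35 nm hydrogen-bond-like, 0.45 nm salt bridge) — raw distances
are always emitted because the calls are conventions.  The C-termini
distance is operationalized as the CA–CA distance between each chain's
highest-numbered resolved residue.

## TICA and free-energy profiles (`tica_fes`)

Features are all pairwise non-hydrogen atom distances between two
selections.  TICA uses the symmetrized (reversible) covariance estimator —
C0 from both window ends, Cτ symmetrized — and solves the generalized
eigenproblem Cτ v = λ C0 v with a 1e−10 relative floor on C0's spectrum
(near-duplicate distance features make C0 ill-conditioned).  Components are
C0-orthonormal; eigenvalues of closed-form processes are recovered to the
documented tolerances (i.i.d. → 0; AR(1) with φ = 0.9 → 0.9 ± 0.02;
symmetric two-state jump process → exp(−τ/t_r)).  Free-energy profiles are
−kB T ln(c/c_max) over occupied histogram bins (50 per dimension by
default), minimum at zero, empty bins NaN (unreachable, never 0); minima
detection masks bins with fewer than 5 counts.

## What the synthetic data does and does not show

The generator emulates the *structure* of the study's data: 5 × 20
replica-structured unbinding events per system, two spatially distinct
egress routes with ligand-class-dependent gating, censoring, and marker
beads for classification.  It does not emulate all-atom energetics,
protein flexibility, solvent, or absolute kinetics — gate heights are
behavioural calibrations, not fits to any receptor, and the toy's
picosecond dissociation times have no physical correspondence to the
nanosecond residence times of a real complex.  Passing tests therefore
demonstrate that the *analysis pipeline* (classification rule, statistics,
estimators, featurization) is correct and that the protocol logic behaves
as specified — not that the toy reproduces any particular receptor's
kinetics.  Quantities that depend only on the analysis (chi-square
p-values for given splits, estimator bias, oracle recoveries) transfer
directly; pathway percentages and residence-time ratios transfer only
qualitatively.

## Numerical choices and limitations

* Euler–Maruyama integration; stability requires μ·k_max·dt ≲ 1 — the
  steepest frozen landscape terms give ≈ 0.13, and the integrator raises on
  non-finite positions rather than propagating a blow-up.
* Problem sizes: 100 trajectories per protocol (the study's size), 2 ns
  time cap (the slowest archetype needs ≈ 0.3 ns on average; nothing is
  censored at the defaults), 2000 bootstrap resamples.
* Distances are non-periodic Euclidean throughout (the toy has no box);
  trajectories with implausibly large marker distances are flagged
  `outlier` rather than image-corrected.
* The classifier's ambiguity tolerance (0.5 nm) and outlier cutoff (10 nm)
  are conventions, reported with every output, not fitted values.
* PDB support covers fixed-column ATOM/HETATM records (first altloc kept);
  mmCIF, topologies and binary trajectory formats are out of scope.
* Censored-time handling in the force-monotonicity comparison counts
  censored runs at the time cap, which is conservative for a decreasing
  trend.
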