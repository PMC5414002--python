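# Methods

## Scope and model organisms

The package analyzes the two-state conformational behavior of FtsZ-type
cytomotive filament proteins — a closed conformation adopted by free
monomers and an open conformation adopted by subunits inside straight
protofilaments, distinguished by a rigid-body rotation of the
C-terminal domain (CTD) relative to the N-terminal domain (NTD) of
roughly 27° with an accompanying axial shift of the central helix H-7 —
and the kinetic consequences of treating that switch as
polymerization-associated.  All residue intervals use S. aureus FtsZ
author numbering (truncated construct 12–316).

## Superposition and domain motion

Residue correspondence is by global sequence alignment (Needleman–
Wunsch, BLOSUM62, affine gaps open 11 / extend 1; biotite's aligner).
These alignment parameters are conventional choices: for the
near-identical sequences this package compares, any reasonable scheme
yields the same pairs, and they are recorded in reports.  Superposition
is a weighted Kabsch fit with the reflection correction (determinant
+1 enforced), requiring ≥3 non-collinear paired Cα atoms.  Iterative
outlier rejection then repeats, up to a fixed number of cycles
(default 5): after each fit, pairs deviating by more than `cutoff`
(default 2.0) times the RMS deviation of the retained pairs are
dropped.  This rule is monotone — the reported RMSD never increases
from one cycle to the next — and with 0 cycles the all-vs-all matrix
is exactly symmetric.  Quoted pairwise RMSD comparisons use rejection
on; census matrices use rejection off so every sequence-matched
residue counts.  Both modes are exposed, since published pairwise
values do not always state which was used.

Interdomain rotation is measured in the fixed-domain frame: superpose
structure A onto B on the NTD interval (with rejection), Kabsch-fit
A's CTD (in that frame) onto B's CTD without rejection, and decompose
the residual rotation as angle = acos((trace−1)/2), axis = the
rotation's unit eigenvector, screw translation = the component of the
CTD-fit translation along the axis.  The axis sign is chosen to make
the screw component non-negative (for pure rotations, the first
significant axis component is made positive).  The measurement is
symmetric in argument order and invariant to rigid pre-transforms of
either input; tests verify both to 1e-6.

Domain intervals are supplied explicitly rather than detected
automatically: the FtsZ partition is well established, and automatic
dynamic-domain detection is out of scope.  The default NTD interval is
12–165; published alignments have used both 13–165 and 12–176, so a
wider-NTD preset (12–176) is also shipped and the interval is a plain
config field.  Open/closed classification thresholds at 15°, the
midpoint between the observed angle clusters near 0° and near 27°;
within ±3° of the threshold calls are sensitive to noise and the
census reports the raw angle alongside the label.

The H-7 register shift is not given its own metric; it surfaces in the
screw-translation component of the domain motion (a deliberate
simplification — a dedicated helix-register measure added little over
the screw decomposition on test geometries).

## Surface areas and filament geometry

SASA is Shrake–Rupley sphere sampling with a deterministic
golden-spiral (Fibonacci-lattice) point set — no RNG, so results are
bit-reproducible — at 960 points per atom by default (doubling the
count changes totals by <1%, and an isolated atom reproduces
4π(r+probe)² exactly up to the lattice quantization).  Van der Waals
radii are a fixed Chothia-style table keyed by element; unknown
elements fall back to 1.8 Å with a warning.  Probe radius 1.4 Å.
Hetero atoms (e.g. the interface nucleotide) are included in interface
calculations because they form part of the longitudinal contact.

Buried surface area of a subunit pair is ΔSASA = SASA(A) + SASA(B) −
SASA(AB).  Published interface areas come in two conventions; both are
implemented: `half_sum` (ΔSASA/2, the PISA-style "interface area",
the default) and `total`.  The convention is recorded in every report.
Contact residues are those losing >0.1 Å² on complexation.

Filaments are built by applying powers of one explicit rigid operator
to a subunit.  Space-group expansion is intentionally not implemented:
a protofilament neighbor needs one or two operators, which the user
supplies directly (see `data/pdb/README.md`), and full symmetry
machinery would be out of proportion.  The axial repeat of a lattice
pair is the screw component of the superposition transform between the
two sequence-identical chains (|t·axis| for a rotational operator, |t|
for a near-pure translation, with 0.5° as the pure-translation
threshold).

## Synthetic ground truth

The generator builds Cα-only chains: two quasi-uniform ball-shaped
point clouds ("NTD", "CTD") joined by a straight H-7-like segment,
numbered 12–165 / 169–195 / 196–316 to mirror the FtsZ presets, with a
small seeded jitter so different seeds give distinct globules.  The
subunit spans ~45 Å along z so that copies stacked at the default
44 Å repeat make head-to-tail contact.  Conformers apply an exactly
known CTD rotation about an axis through the H-7 centroid, an optional
H-7 translation, and isotropic Gaussian noise.  What this emulates is
the *measurement geometry* — rotations, repeats, interface burial —
not protein architecture: there are no side chains, no secondary
structure, no realistic packing, and interface tests use inflated
uniform radii (3.0 Å) so Cα chains make measurable contacts.  Passing
tests therefore demonstrate correctness of the measurements under
known ground truth, not fidelity on real coordinates; the
deposited-structure validation layer (user-fetched PDB entries) covers
the latter.

## Kinetic model

State: a set of filaments, each an ordered string of subunits
(minus→plus); subunit i carries one nucleotide (T or D) on its plus
face, forming interface i with subunit i+1 (tubulin-like geometry —
hydrolysis happens only at formed interfaces, where the catalytic loop
of the next subunit completes the composite active site; the plus-end
subunit's exposed nucleotide can exchange D→T but not hydrolyze).
Free monomers are closed; polymerized subunits open.  Units: energies
in kT, concentrations in a reference c0 = 1, rates scaled by k_on.

Rate table (c = free T-monomer concentration):

| reaction | rate | notes |
|---|---|---|
| association at an end | `k_on·c` (× `end_asymmetry` at one end) | asymmetry models the stereochemically distinct addition pathways; which end is fast is a label, not a biological prediction |
| end loss over interface X | `k_on·c0·exp(dG_X + dG_switch)` | departing subunit relaxes closed |
| internal breakage of X | `k_on·c0·exp(dG_X)` | new ends cannot switch |
| dimer nucleation | flux `(sum of end-association constants)·exp(-dG_switch)·c²` | two switches paid, one interface gained |
| annealing (off by default) | `k_on/V` per ordered filament pair | exact detailed-balance partner of breakage |
| hydrolysis | `k_hyd` per buried T | |
| exchange | `k_exch` per exposed D (free monomers and, by default, filament plus ends) | switchable |

Defaults (`SimParams`): k_on = 1, dG_T = −7, dG_D = −2, dG_switch = 2,
k_hyd = 0, k_exch = 10, end_asymmetry = 1.  These are not fitted to
any organism — no absolute rates are available for this reduced model —
but chosen so T interfaces are strong, D interfaces weak, exchange
fast relative to hydrolysis, and the switch penalty a few kT, the
qualitative regime of a treadmilling-competent nucleotide-driven
filament.  Free D monomers recharge to T before associating
(exchange is fast), so association draws on the T pool only.

The dimerization flux carries the statistical factor that makes the
`dG_switch = 0` limit *exactly* isodesmic (same equilibrium constant at
every step, dimer included): per-step association is a two-channel
reaction (a monomer can approach either face), so the dimer
association constant equals the summed end-association constants.
With this convention the closed-system stationary law, for k_hyd = 0
and breakage/annealing enabled as a reversible pair, is the ideal
aggregation ensemble

> π(m, {L}) ∝ (n!/m!) · σ^F · (K/V)^(#interfaces) / ∏ ν_L!

with K = exp(−dG − dG_switch), σ = exp(−dG_switch); a test verifies
this against the enumerated generator to 1e-12.  Two corollaries used
as oracles: the isodesmic mass fraction and geometric length
distribution, and the nucleation–elongation critical concentration
c_crit = c0·exp(dG_T + dG_switch).

Breakage without annealing (the default, matching the treadmilling
schema where fragments are transient) is an irreversible channel, so
equilibrium claims are only made for runs with annealing enabled;
treadmilling regimes use switch penalties large enough that breakage
is rare and the distinction is immaterial.

Simulation is the exact Gillespie direct method (no tau-leaping:
exactness is what the oracle tests check, and desk-scale performance
is adequate — ~10⁵ events/s).  Identical parameters and seed give
bit-identical event logs.  Subunit conservation in closed systems is
asserted at every step.  The small-system oracle enumerates states as
multisets of filament lengths (valid only for k_hyd = 0, where the
nucleotide state stays all-T) and solves πQ = 0 by least squares with
the normalization row appended.

### Observables

*Treadmilling velocity* of a filament is (net plus-end additions −
net minus-end additions)/2 per unit time — the drift speed of the
filament body at steady state — with a block-bootstrap confidence
interval (20 time blocks, 1000 resamples).  When breakage splits a
filament the larger fragment keeps the identity, so the bookkeeping
follows the dominant piece.  *Breakage vs end loss* compares events
per interface-time between internal and terminal D interfaces (a
dimer's single interface counts toward both end channels); the rate
construction forces the ratio to exp(−dG_switch) and the measurement
verifies it with a log-normal Poisson ratio interval.  *Mass curves*
average the polymerized fraction over the second half of equilibrated
closed-system runs, flag drift by comparing the third and fourth
quarters, and report time-to-half-plateau as the lag proxy; the onset
estimate is the free-monomer plateau c_total·(1 − mass fraction)
averaged over points above 20% polymer (the textbook critical-
concentration definition; a line-intercept fit was noticeably biased
low by curve rounding near the onset).

### Problem sizes

Tests and the acceptance script run at desk scale: closed systems of
150–160 subunits for equilibrium curves (finite-size deviations from
the infinite-volume closed forms are below the ~0.04 tolerance used),
n ≤ 8 for exact enumeration, seed filaments of 60–400 subunits and
simulated spans of 6–5000 time units for the kinetic regimes, 5000–
10⁴ draws for distributional checks.  These sizes give stable
statistics at interactive runtimes; all of them are ordinary function
arguments and scale up directly.

## Numerical choices and edge cases

* Kabsch requires ≥3 pairs and rejects collinear point sets (second
  singular value ≤ 1e-8 of the first).
* Altloc resolution: highest occupancy, ties toward 'A'; insertion
  codes are distinct residues ordered after the base number; residues
  missing a Cα are dropped from pairing (no interpolation).
* Rotation-angle extraction clamps (trace−1)/2 into [−1, 1]; the axis
  near 180° falls back to an eigen-decomposition of the symmetric part.
* `superpose` raises if rejection would leave fewer than 3 pairs.
* The SSA terminates cleanly with a reason when total propensity
  reaches zero (e.g. all rates zero) or an event cap is hit.
* Waiting-time and replicate checks derive independent streams with
  `numpy.random.SeedSequence` spawning.

## Known limitations

* The synthetic generator makes no attempt at protein-like geometry
  (see above); absolute synthetic BSA values are not comparable to
  real interfaces.
* The kinetic model is one-dimensional and well-mixed: no membrane
  attachment, no filament mechanics or curvature, no spatial
  diffusion, and no fitting of absolute rates to experimental data.
* Nucleation is strictly dimeric; larger critical nuclei are not
  modeled.
* Which structural end of the filament is the kinetic plus end is
  deliberately left undetermined; "plus" is a label for the face the
  asymmetry factor multiplies.
* Automatic (model-free) domain detection is not implemented; domain
  intervals are inputs.
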