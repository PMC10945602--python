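# Methods

## The model

`fibermc` samples chromatin fibers at nucleosome resolution with Metropolis
Monte Carlo. A fiber is a chain of rigid nucleosome cores connected by
linker-DNA bead runs (~9 bp per bead, rounded half-up with a one-bead
minimum), decorated with short histone-tail bead chains, optional
linker-histone (LH) bead chains at the dyad, and optional acetylation marks.
The potential energy is a sum of

- linker-DNA stretching, bending and twisting (`ES`, `EB`, `ET`) — a
  worm-like-chain bead model: harmonic bonds about a 3.0 nm equilibrium
  spacing, harmonic bending about collinearity (stiffness from a ~50 nm
  persistence length: `g = Lp·kBT/l0 ≈ 9.7 kcal/mol/rad²`), and a harmonic
  twist registry per linker;
- histone-tail and LH chain stretching and bending (`EtS`, `EtB`, `ElhS`,
  `ElhB`) — harmonic about template geometries anchored in the core body
  frame. Acetylated tails use the alternative *folded* template (shorter
  bonds) with all constants multiplied by 100, which makes them effectively
  rigid, compact, and poor at bridging nucleosomes;
- excluded volume (`EV`) — a purely repulsive shifted-truncated 12-6 form,
  zero at and beyond the contact distance (sum of per-species effective
  radii), continuous with continuous derivative at the cutoff;
- screened electrostatics (`EC`) — Debye–Hückel pair interactions between
  all non-bonded charged sites, shifted to zero at the nonbonded cutoff so
  pairs cross the cutoff continuously. Cores carry a configurable number of
  surface point charges (default 12) on a cylinder, which preserves
  anisotropic screened interactions without a full surface-charge
  optimization; linker beads carry a salt-screened net charge per ~9 bp;
  tails are weakly positive, LH beads strongly positive (a CTD-like
  charge);
- the TF restraint term (`E_TF`), described below.

Units are kcal/mol, nm, degrees, Kelvin; defaults are 293 K and 0.15 M
monovalent salt (Debye length 0.785 nm).

## Implicit TF (Myc:Max) bridging

A bivalent TF heterotetramer that bridges two DNA sites is modeled
implicitly as a harmonic restraint `E = k (l − l0)²` between two TF-bindable
linker beads, with `k = 20 kcal/mol/nm²` and rest length `l0 = 13 nm` (the
distance between the two DNA duplexes in the heterotetramer crystal
structure). Two bindable beads *engage* when they come within the 20 nm
capture radius while at least 30 linker beads apart along the fiber; an
engaged pair separating beyond 20 nm is *released*. Each bead holds at most
one restraint (one tetramer per site). When several pairings are possible
the closest pair engages first, ties broken by the lower bead index. The
restraint set is refreshed after every accepted move that displaces a
bindable bead relative to the others, and unconditionally every 1,000
steps. The restraint energy is part of the total energy used in the
Metropolis test; engagement and release themselves are rule-based events,
not Metropolis proposals (the restraint energy is small relative to the
system total, so this choice mainly affects kinetics, not the sampled
structures — it is flagged as a sensitivity, not a certainty).

## Sampling

Move set: a global pivot (rotate the shorter fiber end about a random axis
through a random backbone node), local translations of DNA and LH beads,
local translation/rotation of cores, and configurational-bias (Rosenbluth)
regrowth of tail chains with 8 trial directions per bead (bond lengths are
preserved; trial weights include the bend and nonbonded energies). A
tail-state swap operation moves a core's tails between the extended and
folded templates and is accepted on the local electrostatic energy change;
it is an equilibration/setup device, not part of the default move mix.
Spatial moves are accepted on the full energy change.

Move probabilities: pivots 20%; the remainder split across the local kinds
in proportion to element counts. Amplitudes (pivot 20°, core rotation 10°,
translations 0.5 nm) were tuned so that local moves accept at roughly
30–50% on relaxed fibers; pivot acceptance is necessarily lower in compact
states. Energy changes are evaluated incrementally (affected bonded terms
plus a moved-versus-static nonbonded cross sum in a compiled kernel); saved
frames recompute the full breakdown from scratch, so acceptance bookkeeping
cannot drift.

Replicas start from an ideal open two-start zigzag built by propagating the
core entry/exit geometry (DNA wraps 1.65 turns at 4.5 nm radius) with a
180° roll per step, perturbed by the replica's twist offset of 0, +12 or
−12 degrees; all DNA elastic terms are exactly zero in the start structure.
Seeds are one per replica; trajectories are bitwise reproducible for a
fixed seed. Frames are saved every 100,000 steps by default (configurable);
the start structure is stored as metadata, not counted as a frame. The
twist registry is carried per linker but no twist move is enabled by
default, so `ET` stays at its reference; twist variation enters through the
replica start structures.

## Observables

- **Fiber axis / packing ratio** — a cubic smoothing spline through the
  core centers (per-coordinate, smoothing parameter 4.0 — strong enough
  that the axis of an ideal zigzag runs between the two stacks, gentle
  enough to track smooth curvature to ~2%); the packing ratio is
  `11·NC/Fl` nucleosomes per 11 nm of axis length.
- **Sedimentation coefficient** — the Kirkwood-form
  `S20,w = ((S1−S0)ρ + S0)(1 + (R1/NC) Σ_{i≠j} 1/Rij)` with mononucleosome
  references `S0 = 11.1 S` (no LH), `S1 = 12 S` (with LH), nucleosome
  radius `R1 = 5.5 nm`, and the double sum over ordered pairs (so two cores
  at distance R contribute `2/R`).
- **Radius of gyration** — RMS core distance from the core centroid.
- **Contact maps** — two nucleosomes are in contact in a frame when any
  element of one (core, tails, or linker DNA) is within 2 nm
  surface-to-surface (center distance minus both excluded-volume radii) of
  any element of the other. Linker runs are split at their midpoint between
  the flanking cores (ties upstream). Per-frame indicators accumulate per
  replica; the ensemble map is the sum of single-replica maps. Raw counts
  are stored; frame-normalized frequencies are derived, never destructive.
  bp-resolution maps bin elements by their genomic midpoints.
- **Contact decay** — `I(k)`, the fraction of off-diagonal interaction mass
  at offset `|i−j| = k`, normalized to sum to 1.
- **Microdomains** — DBSCAN on the precomputed distance matrix
  `d = 1/frequency` (zero frequencies capped at 10× the largest finite
  distance so the matrix stays finite and the cap exceeds any plausible
  search radius). Reference radii for ensemble maps: eps 3 (62 bp fibers),
  2 (44 bp and life-like), 1.4 (26 bp), minpoints 5.
- **Promoter geometry** — per-frame alpha-shape volume of the promoter
  nucleosomes from (x, y, z) and area from the (x, y) projection (alpha
  100, a loose envelope), reported as ensemble mean ± SD. The alpha
  criterion keeps Delaunay simplices with circumradius ≤ alpha, matching
  the common alpha-radius convention.
- **Realized TF concentration** — per replica, the fraction of bindable
  beads engaged in a restraint averaged over frames; the ensemble value is
  the mean across replicas.
- **Convergence** — per-frame total energy, end-to-end distance,
  sedimentation coefficient and mean triplet angle at consecutive cores.

## Synthetic systems and what they do (not) show

The builders generate the study systems directly: uniform fibers
(26–80 bp linkers), life-like fibers drawn from the mESC linker-length
distribution (30/17/15/13/9/7/9% for 26/35/44/53/62/70/80 bp), the four
canonical TF binding patterns on 50-nucleosome fibers, TF concentration
marking (floor of the requested percentage, nested across concentrations
for a fixed seed), LH densities (floor rule; uniform, random or explicit
placement) and the four acetylation islands. The Eed-locus fixture tiles a
26,322 bp region with 129 nucleosomes at NRL 189 around seven NFRs (two
~350 bp, five ~200 bp), marks two ChIP-derived TF regions (region 1
overlapping the promoter-end nucleosomes) and places LHs at density 0.37
(or 0.8 for the somatic-cell variants). NFR bp positions and LH peak
positions are synthetic instances consistent with the published summary
statistics; coordinates are 0-based half-open (BED), converting the 1-based
genomic coordinates on ingest.

These systems reproduce the *mechanisms* — TF-position-dependent
population-level contact blocks, TF-driven compaction, LH-induced rigidity
that suppresses bridging on short linkers — not the calibrated absolute
observables of a fully parameterized mesoscale force field. Sequence-level
E-box recognition, explicit TF geometry, and solvent detail beyond
Debye–Hückel are out of scope, so quantitative packing ratios and
sedimentation values should be read as model-internal, not experimental,
predictions.

## Numerical choices

- Nonbonded cutoff: max(7 Debye lengths, largest contact diameter), 6.0 nm
  at defaults; both EC and EV are exactly zero at the cutoff.
- Bonded exclusions: directly bonded pairs and sites of the same rigid
  element are excluded from nonbonded sums; 1-3 pairs interact.
- Degenerate inputs raise: single-core fiber-axis requests, coincident
  cores in the sedimentation sum, all-zero maps in the decay normalization,
  coplanar/collinear vertex sets in alpha shapes.
- Desk-scale tail representation: 4 tail chains of 2 beads per core by
  default (configurable); this keeps the tail-mediated internucleosome
  attraction while holding the interaction-site count at roughly 26 sites
  per nucleosome.
- Test/verification problem sizes: the ensemble-level checks use
  25-nucleosome, 44 bp fibers with three 3-nucleosome TF regions (30 of 120
  linker beads bindable, an effective 25% concentration), 4 replicas of
  500,000 steps, pooling the final 250,000 steps; the LH comparison uses
  20-nucleosome 26 bp fibers at 50% marked beads, 3 replicas of 200,000
  steps. These sizes were chosen as the smallest at which the ensemble
  phenomena are unambiguous.

## Known limitations

- The simplified core charge model (12 surface sites, net −150e) preserves
  screened anisotropy but not the optimized surface potential of a
  calibrated mesoscale field; absolute compaction values differ from
  calibrated-force-field results.
- Twist is energetically present but not dynamically sampled by default.
- Pivot acceptance drops in strongly compacted states; sampling of deeply
  folded gene-scale fibers relies on the local move set and benefits from
  longer runs than the desk-scale defaults.
- The engagement rule is greedy nearest-first; other matchings (e.g.
  maximum-cardinality) would differ at high local densities of bindable
  beads.
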