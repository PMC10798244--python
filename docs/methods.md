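# Methods

## What the model is

`stepfold` asks a steric/kinetic question, not a thermodynamic one: can
a proposed 2D RNA–RNA interaction be *reached* in 3D by growing it a
base pair or two at a time? Everything in the package serves that
question; energies are in reduced units and make no claim of
thermodynamic realism.

### 2D layer

Structures are sets of base pairs over two chains with 1-based indices;
each residue pairs at most once; intramolecular pairs must enclose at
least a 3-nt hairpin loop (waived for 3D-derived annotations, which may
report sub-loop contacts). The canonical pair set is
{AU, UA, GC, CG, GU, UG}; non-canonical pairs found by geometric
annotation are kept in structures but excluded from exact-match
comparison and from the interaction metrics used at checkpoints.

Interaction metrics of a complex:

* `n_inter` — number of intermolecular pairs;
* `longest_perfect` — longest run of stacked pairs (i,j), (i+1,j−1);
* `with_loops` — pairs in the largest interaction *site*, where
  neighbouring pairs may be separated by at most `gap_limit` unpaired
  residues on each strand. `gap_limit` defaults to 4 — big enough to
  absorb bulges and small (≤4×4) interior loops inside one site, small
  enough not to merge independent contacts. The cut-off is this
  package's parameterisation; there is no field-standard value.

`bp_distance(a, b, region)` is the size of the symmetric difference of
the pair sets, optionally restricted to pairs touching a region. It is
a metric and is the 2D dissimilarity used everywhere in selection.

### Path generation

The maximal bulge-free extension grows a contiguous seed helix outward
one antiparallel position at a time while the facing residues form a
canonical pair. GU wobble counts by default (natural helices contain
GU; a flag restricts to Watson–Crick). Paths order the target pairs
left/right of the seed and emit one constraint structure per step under
the chosen scheme (alternating / symmetric / directional); symmetric
steps add one pair per side while both sides have room and taper to one
pair once a side is exhausted. At every step, intramolecular constraint
pairs with a residue inside the current interaction span widened by
`spacer` residues (default 2, per chain) are dropped — the spacer keeps
room for stems to open ahead of the zipper. Dropping frees the partner
rather than forcing it unpaired: constraints only ever pull together.

### 3D layer

One bead per nucleotide at a C3′-like position. Geometry defaults
(`GeometryParams`): bond 6.0 ± 0.75 Å, clash wall 4.0 Å, pairing
window [13, 16] Å, helix rise 2.8 Å, twist 32.7°, radius 9.0 Å. These
are package choices tuned for a one-bead model, not published
measurements. Two deliberate couplings:

* The ideal-helix partner phase (92.6°) puts the paired-bead distance
  at 13.01 Å, a hair above the annotation window floor. In an ideal
  helix no other bead is then an in-window candidate (near diagonal
  9.4 Å — below the window; far diagonal 16.2 Å and the 4-apart
  same-strand contact 19.8 Å — beyond or at the window edge and farther
  than the partner), so annotation recovers ideal helices exactly.
* The pipeline samples with a narrower *pull window* [13.5, 14.5] Å in
  the constraint wells: constrained pairs settle near the bottom of the
  annotation window, where they are the shortest candidate distances
  and greedy annotation reads the realised interaction in the intended
  register. The pull floor sits half an Ångström above the annotation
  floor so thermal excursions rarely drop a satisfied pair out of the
  window.

Annotation (3D→2D) collects candidate pairs — bead distance inside the
pairing window, same-chain separation ≥ 4 — and accepts them greedily by
ascending distance, skipping candidates whose residue already has a
partner. Deterministic; ties break toward smaller (chain, index). A
one-bead model cannot classify pair families (no Leontis–Westhof
edges); non-WC/GU identities are flagged by sequence only.

Superposition RMSD uses the Kabsch rotation with the determinant
correction — proper rotations only, since RNA is chiral.

### Sketching

`sketch_structure` builds a clash-free conformation for a 2D structure:
helices are placed as rigid ideal-geometry units with seeded random
orientations; a helix adjacent to one already-placed residue is anchored
at bond length; a helix pinned by *two* direct bonds (coaxial stacks,
kissing junctions) gets its translation from the intersection circle of
the two bond spheres. Unpaired segments between fixed endpoints start
as circular arcs with the segment's contour length (slack bulges
outward, as loops do) and are relaxed to bond length by iterative
projection; free tails are persistent self-avoiding walks. The whole
sketch is rejection-resampled until clash-free and until annotation
recovers every helix of ≥ 2 pairs (`require="helices"`) or equals the
structure's canonical pairs exactly (`require="exact"`, used for
pipeline starts). Deeply entangled pair sets can be genuinely
unembeddable; the sketcher reports failure after a bounded number of
attempts rather than forcing a geometry.

### Sampler

Metropolis Monte-Carlo over bead coordinates. Moves preserve bond
lengths exactly: crankshaft rotations of interior segments (biased
toward short segments — the local adjustments that remain acceptable in
a nearly-zipped duplex), end pivots with angles damped by segment
length, and rigid translation+rotation of chain B. Any proposal with a
clash is rejected before energy evaluation, so excluded volume is
exact, not just penalised.

Base energy = soft excluded volume (quadratic onset below 6 Å, weight
0.25) + worm-like-chain bending `bend_weight·(1 − cos φ)` per joint
(default 1.0, giving single-stranded segments a persistence of a few
beads). The bending term is load-bearing: without it the fully flexible
chains crumple and the 13–16 Å shell around the duplex fills with
spurious annotation candidates.

Constraint penalty: per required pair a flat-bottom quadratic on the
pairing window; a forced-unpaired position is penalised only while some
candidate sits inside its pairing window. Zero iff all constraints are
geometrically satisfied.

Seeds: one master seed; per-run seeds are `master + index·10007`
(mod 2³¹). Identical inputs and seed give bitwise-identical
trajectories. Frames are recorded every `max(1, n_step/200)` iterations
plus the final frame.

External tools can stand behind the same sampling contract through
`ExternalAdapter` (`simrna-like` distance-restraint dialect,
`fragment-assembly-like` dot-bracket dialect). A missing executable is
an explicit error; there is no silent fallback. Adapters are exercised
against a stub executable in the tests; no real external binary is
required anywhere.

### Selection and pipeline

Start clustering is agglomerative (average linkage) on the pairwise
superposition-RMSD matrix — a generic substitute for fragment-identity
clustering, which only exists inside a fragment-assembly tool.
Representatives are the lowest-energy members. `select_start` demands
an exact (canonical-only) annotation match with the initial structure;
`select_step` minimises the lexicographic key (interaction-region
bp-distance to the constraint, whole-complex bp-distance, energy,
step index, pool order). Level (ii) compares against the constraint
rather than the previous step's annotation: the constraint is the
declared hypothesis, the previous annotation is itself noisy.

The checkpoint compares annotated metrics of consecutive *selected*
frames, not constraint sizes — "the interaction did not expand" refers
to realised structure. `reached_target` tests that the annotated
canonical intermolecular pairs form a superset of the target, so extra
intramolecular pairs never block success. A run whose path ends without
reaching the target is recorded as `path_exhausted` (distinct from a
checkpoint stall, which the attrition statistics count identically).
`lookahead_steps` (default 0) exists for letting constraints run ahead
of realised structure; the default never does.

Pipeline sampling defaults (temperature 0.2, constraint weight 3.0,
max rotation 40°) are colder and stiffer than the bare sampler
defaults: each extension step only needs the local neighbourhood of the
previous selected frame, and the constraint term must dominate the
chain terms for the zipper to advance. The same settings are used for
every system — the exterior/kissing contrast emerges from geometry, not
from per-system tuning.

## Synthetic data and what passing tests mean

`make_exterior_system` (two unstructured chains, complementary central
window, flanks fixed non-complementary so the automatic target is the
window) and `make_kissing_system` (two stem–loop hairpins with fully
complementary loops, stem boundaries fixed non-pairing so the target
spans the loops) generate the two steric regimes at arbitrary sizes,
reproducibly from an RNG seed.

The packaged named scenarios reproduce the *architecture* of the
studied systems — chain lengths (54/47, 23/23, 50/41), stem and loop
sizes, the 3 bp CCG/GGC and 6 bp GUGCAC seeds, near-perfect antisense
complementarity — with synthetic sequences where the exact experimental
sequences are not part of this package (CopA/CopT, DsrA/rpoS; the HIV-1
DIS monomer is transcribed from its published structural description).
Every structural fact the acceptance checks measure holds by
construction of the architecture, not of the sequence identity.

What the synthetic systems do **not** emulate: real base-pair
thermodynamics (no stacking energies, no sequence-dependent stability),
tertiary contacts, ions, or kinetics on physical timescales. A passing
steric-contrast test shows that the one-bead model reproduces the
qualitative reachability difference between free-ended duplexes and
kissing hairpins at desk scale; it does not certify rates or lengths
for real molecules, and published run-percentage statistics obtained
with cluster-scale knowledge-based potentials are expressly not
reproduction targets for the built-in sampler.

## Numerical choices and degenerate inputs

* Problem sizes in the test suite are desk-scale by design: chains
  ≤ 60 nt, `n_step` ≤ 8000, ≤ 10 lineages per system; the integration
  contrast uses 20-nt systems and finishes in a few minutes.
* PDB round trips are exact to the fixed-format precision (10⁻³ Å).
* `n_step = 0` returns a single-frame trajectory; an empty interaction
  yields all-zero metrics; a pool smaller than `n_cluster` degrades to
  singleton clusters with a warning; explicit path files that violate
  nesting load with a warning (they are user hypotheses).
* Energy bookkeeping is never cached across frames: every recorded
  frame's energies re-derive from its coordinates to 10⁻⁹.

## Known limitations

* One bead per nucleotide cannot distinguish pair geometries, groove
  widths, or non-canonical families; annotation is purely metric.
* The greedy annotation can mis-register a sloppy duplex; the pull
  window mitigates but does not eliminate this, which is one reason a
  small fraction of easy (exterior) lineages still stall.
* The sketcher handles stems, kissing contacts and coaxial junctions,
  but arbitrarily entangled pair sets may be rejected as unbuildable.
* Sampling at a single temperature with local moves cannot cross large
  topological barriers (e.g. threading a chain through a loop); a stall
  therefore means "unreachable at this budget and temperature", which
  is the intended reading, not a proof of impossibility.
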