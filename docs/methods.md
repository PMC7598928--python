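# Methods

## Model

### Geometrized energy

Each candidate interaction between an atom of the fixed unit and an atom of
the mobile unit is a short-range Lennard-Jones pair potential discretized
into three intervals: distances below the hard-sphere contact (sum of van
der Waals radii, 1.2 Å per atom by default) are forbidden; distances inside
the well [lo, hi] contribute E_l; larger distances contribute E_h.  A
configuration with N_a of N wells active therefore has energy
E = N·E_h − N_a·(E_h − E_l) and, relative to the landscape constant
e^{−N·E_h/kT} (which cancels in every normalized quantity and is never
computed), Boltzmann weight w(N_a) = (e^{ΔE/k_B T})^{N_a}.  Defaults:
ΔE = 0.997 kJ/mol, T = 298.15 K (temperature is a free constant chosen so
the weight base rounds to 1.5; it is configurable), k_B = 0.0083145
kJ/(mol·K).  Well construction for planted fixtures: centred on the pair's
distance in the true pose with half-width 0.4 Å, never below the hard-sphere
contact.  One ΔE is shared by all wells; per-well overrides are accepted in
the system config.

### Active-constraint regions and the atlas

The assembly landscape of two rigid units is the 6-dimensional space of
relative poses (the fixed unit never moves).  Classifying every well at a
pose partitions the feasible poses into regions sharing an active-constraint
graph.  Constraint counting is generic: each independent active constraint
reduces the effective dimension by one, computed as 6 minus the numerical
rank of the distance-constraint Jacobian with respect to the pose at a
witness configuration (singular values below 1e−6 of the largest are
treated as zero; duplicate wells on one atom pair contribute a single row).
Regions form a DAG: a child has exactly one more active constraint than its
parent.  0-D regions (rank 6, hence ≥ 6 constraints) are the basin bottoms.

Two conventions reconcile interval-defined regions with equality-based
dimension bookkeeping:

* **classification** uses interval membership (endpoints count as active —
  ties resolve toward the more constrained child);
* **realization** pins active distances at well centres.

A region is labelled by its active set only; configurations where further
wells are active belong to the child region.

### Atlas construction

1. Every well seeds its 1-edge region via deterministic multistart
   realization of the single centre distance (24 octahedral-grid rotations
   with centroid-separated translations).
2. A region with effective dimension d ≥ 1 gets a Cayley chart: d non-well
   cross-unit atom pairs chosen greedily (lexicographic order, accepting a
   pair when it raises the Jacobian rank at the witness).  On very small
   units the rank saturates below 6 and the chart is simply shorter — the
   documented fallback.  Bounds per parameter come from triangle
   inequalities over shared-atom triples with the active centre distances,
   intersected with the steric lower bound.
3. The chart is swept by a breadth-first walk on a step lattice (0.5 Å)
   anchored at the witness: each node is realized by least squares
   warm-started from the neighbouring accepted pose, with a small seeded
   jitter (±0.2 step) against lattice artifacts, and expansion only
   continues from successfully realized nodes.  The walk is capped at 400
   samples per region by default.  A blind grid or uniform sweep of the
   chart's bounding box realizes almost nothing (the box is overwhelmingly
   inconsistent with the triangle inequalities), so the walk both matches
   the method's minimal-discarded-samples intent and is what makes desk-scale
   runs fast; 400 samples suffice for the structural quantities the package
   reports (region labels, bottoms, dedup counts at ε = 0.5 Å).
4. Realized poses whose active set strictly contains the region's edges
   register boundary (child) regions.  When a sample jumps several
   constraints at once, intermediate one-more-edge regions are inserted
   along the sorted edge chain with the same witness, so the stratification
   invariant (every region with < 5 effective dimensions has a parent with
   exactly one fewer edge) holds by construction.
5. 0-D regions are realized directly from all well centres with the full
   multistart set plus accumulated witnesses.
6. Configurations are deduplicated at ε = 0.5 Å in the similarity metric
   (Euclidean norm between mobile-atom coordinate vectors, atom order fixed
   by the input file — this makes dedup deterministic).  Regions that end
   with neither configurations nor realized descendants are dropped.

The realization solver is a Levenberg-Marquardt iteration directly on
(R, t) with multiplicative Rodrigues rotation updates, the exact analytic
Jacobian row [(y−t)×u, u] per distance residual, damping λ·(diag+1), and a
trust region of 0.5 rad / 2 Å per step.  Accepted solutions must meet every
target within 0.05 Å, are re-orthonormalized, steric-checked, and
ε-deduplicated.  Mirror-image poses are distinct configurations and kept
when feasible; nothing is quotiented.

The whole build is deterministic for a fixed seed and parameter set (region
processing order is sorted; per-region RNG streams are derived from the
seed and the region label).

### Basins and cruciality

Each 0-D region is a basin bottom.  A configuration in a region whose graph
is a subgraph of at least one bottom graph is assigned to the basin of its
nearest bottom configuration (ties to the lexicographically smallest bottom
label); configurations in regions that are no bottom's subgraph stay
unassigned.  ν_minima is the ε-deduplicated configuration count over the
union of 0-D regions.  ν_capsid weights each assigned configuration by
w(N_a) of its *own* region (the proximity-to-higher-region weighting is not
fully operational in the source description; this is our documented
resolution) and returns true-basin weight over all-basin weight.  The
basin-wide weighted sum is the primary definition; a `zero_dim_only` switch
computes the bottoms-only variant.  The true basin is the one whose bottom
holds the configuration nearest the true pose within ε; if none qualifies
the share is 0.

A knockout (one interaction, or all interactions of a residue) restricts
the atlas to regions disjoint from the knocked-out set — the atlas is never
re-sampled.  Bar-code conventions: 0/0 → 1 (irrelevant knockout);
x/0 → flagged undefined and the interface's prediction is aborted with a
diagnostic rather than guessed.  Cumulative bar-codes average component-wise
over an interface's assembly systems.  Display order is descending μ_capsid
(least crucial first, wild type first of all), ties by μ_minima then label.

### Capsid polyhedra and dual graphs

T = 1: monomers are flags (face, vertex) of the icosahedron — equivalently
the snub dodecahedron's vertices.  Contacts: the two within-face partners
(3-fold), the around-vertex ring partners (5-fold, pentamer), and one
chirally chosen trans partner across each icosahedron edge (2-fold; the
head-head convention under the outward counterclockwise face orientation).
This yields 60 vertices of degree 5, 150 edges, and exactly three edge
orbits (30/60/60) under the proper rotation group of order 60 — the full
icosahedral group is deliberately not used because protein capsids are
chiral.

T = 3: the Caspar-Klug (1,1) lattice is the pentakis dodecahedron — 60
triangular facets, 12 five-fold (P) and 20 six-fold (H) vertices.  Each
facet carries A at its P corner and B, C at its H corners (counterclockwise
from outside), so pentamers are all-A and hexamers alternate B/C.  The
systematic flag construction with the full T = 1 adjacency rules produces
*eight* edge orbits, because the hexamer ring contacts split by the
triangulation edge beneath them (icosahedral H–H vs pyramid P–H).  The
shipped template keeps seven orbit classes: the three quasi-3-fold contacts
A-B, A-C, B-C inside a facet, the A-A pentamer contact, the B-C hexamer
contact across H–H edges, the C-C dimer at the true 2-fold, and the A-B
dimer at the quasi-2-fold.  Both hallmark dimer contacts of BMV-like
capsids are retained; the within-hexamer contact across pyramid edges is
the class treated as sub-threshold.  With this template the
triangle-construction census over the seven representative edges evaluates
to 27 assembly systems, not the 31 the study reports; the per-type triangle
census of the original dual graph is unpublished, and no physically
plausible 7-orbit template we examined (dropping any one systematic class,
or swapping trans-pair chirality) reaches 31 (the attainable range is
21–29).  The discrepancy is reported as computed, never patched.

Interface types are computed as genuine edge orbits (the classifier is
never special-cased): the rotation group is generated numerically by
closure from a 5-fold and a 3-fold generator, acts on monomers through
equivariant representative points, and must preserve edges or the
construction fails loudly.  Connectivity pathways enumerate all subsets of
types (≤ 2^7) and keep those whose edge union is a connected, spanning,
minimal subgraph; "connected subgraph" is read as connected *and* spanning
all 60·T monomers.

Assembly systems per interface type: the lexicographically smallest edge of
the type is the representative; the monomer-monomer system is emitted once
and each considered triangle a-b-c adds the two dimer-monomer systems.  For
T = 1 one (lexicographically smallest) incident triangle is used — this
reproduces the reported census of 9, whereas using all incident triangles
would give 13 on any honest T = 1 dual graph (2-fold and 3-fold edges each
lie in two triangles).  For T = 3 all incident triangles are used.  The
policy is an explicit argument (`triangle_policy`), with the per-T defaults
above.

### Two-scale model

P_ι(r) = σ(a_ι μ_minima + b_ι μ_capsid + c_ι); pathway break probability
C_p = 1 − Π_{ι∈p}(1 − w_ι P_ι) with w_ι ∈ [0, 1] enforced by a logistic
reparametrization; capsid cruciality H(r) = Σ_p C_p.  Knockouts absent from
an interface type carry the neutral bar-code (1, 1).  The ranking loss is
implemented as L = Σ σ(H(r_j) − H(r_i)) over pairs in which r_i is the more
disruptive member — the form that is *minimal* when the required order
H(r_i) > H(r_j) holds.  Fitting is full-batch gradient descent with a fixed
step (default 0.05) and a 5000-iteration cap, analytic gradients, and the
init a = b = −1, c = 0, w = 0.5.  Training pairs from mutagenesis labels
follow the partial order disrupt > partial > non-disrupt (partials never
pair with each other); the default train split is 40% per virus, stratified
and seeded.  A first-prediction mode bypasses fitting entirely and ranks by
mean cumulative μ_capsid (ties by μ_minima), encoding the
equal-interface-importance assumption.

Evaluation offers (i) ranking concordance — the fraction of
(disrupt, non-disrupt) pairs ordered correctly, ties counting ½ — and
(ii) a 2-D linear-separability verdict on bar-code points, decided by a
unit-margin linear program (HiGHS); the geometric margin 2/‖(u,v)‖ is
reported, and a single represented class is trivially separable and
flagged.

## Synthetic data: what it emulates and what it does not

`make_planted_interface_system` packs 5–20 atoms per unit (minimum
separation 2.6 Å inside a 4 Å ball), places the mobile unit by bisection
along a random approach direction until the closest cross contact sits
0.55–0.9 Å above the hard-sphere floor, and centres wells on cross distances
at that pose.  Wells are picked nearest-first **subject to driving the
constraint Jacobian to rank 6** before free picks are allowed — without the
rank guard the six nearest pairs frequently share atoms and the "planted
minimum" degenerates into a 1-D motion curve.  With several planted minima
the wells are split evenly between poses, approach directions are kept
almost orthogonal, and rejection sampling enforces that each pose activates
exactly its own well group and that poses are separated by more than 3ε.
Generators are pure functions of their seed.

Planting guarantees each planted pose is a basin bottom; it does *not*
bound the total number of bottoms.  Distance-geometric combinations of the
designed centre distances routinely admit further genuine rigid solutions
(including mirror realizations), so ν_minima exceeds the number of planted
poses — tests assert that the planted poses appear among the bottoms and
that an independent multistart search finds no solution the atlas lacks,
not an exact bottom count.

`make_synthetic_capsid_dataset` draws per-type bar-codes with the two
components coupled (μ_capsid = 0.7·μ_minima + 0.3·uniform by default —
the components track each other closely in real atlases), scores them with
known parameters, labels by the median of the true score, and forms
training pairs either from the binary labels (the in-vitro setting) or from
the full true-score order (oracle supervision).  The packaged parameter-
recovery experiment uses the sharp-response instance a = b = −6, c = 6 with
pathway weights spread over [0.1, 0.95], 40 residues, full-order pairs, and
the default optimizer: an identifiable instance probing recovery rather
than identifiability limits.  With binary median-split supervision the
bounded sigmoid loss cannot constrain within-class order (its optimum
trades small-margin correct pairs for larger margins elsewhere), so
rank-correlation recovery claims are only meaningful under order-complete
supervision.

None of the fixtures emulate real VP fold geometry, solvent, electrostatics
or internal flexibility; units are abstract rigid bodies.  Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery — constraint counting, atlas stratification, restriction algebra,
ranking behaviour — not predictive accuracy on real capsid structures,
which requires full-atom inputs via the PDB reader.

## Problem sizes and determinism

Shipped defaults: ε = 0.5 Å, Cayley step 0.5 Å, realization tolerance
0.05 Å, 400 samples per region, 24 multistarts, rank tolerance 1e−6.  The
test suite atlases a 6-atom/6-well system (150 samples/region) and micro
systems of 1–2 atoms per unit for the exhaustive-oracle comparison (pose
grid at 0.5–0.8 Å with 24–120 quasi-uniform rotations from a Halton/
Shoemake sequence); the headline planted run uses 8 atoms/8 wells.  All
randomness flows from explicit integer seeds; rebuilding an atlas with the
same seed reproduces region labels, counts and configuration order exactly,
and the command line embeds version, seed and a config hash in every
artifact.

## Known limitations

* Two rigid bodies only; no simultaneous tri- or penta-body atlasing.
* Region size is measured by ε-dedup counting, not volume integration.
* The Cayley walk explores the chart component connected to its witnesses;
  disconnected components of the *same* active-constraint region are only
  reached through the multistart seeding.
* Atlas restriction (knockout) never re-atlases without the well, matching
  the method's definition; re-atlasing is available only as a test oracle.
* The T = 3 contact template is a documented 7-orbit choice (see above);
  orbit classification itself is exact.
* Mutagenesis validation at full-atom scale requires the real capsid
  structures as PDB input; the packaged experiments run on synthetic
  fixtures.
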