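# Methods

This note documents the models, algorithms and numerical choices behind
`mitocarrier`, in the spirit of a methods section: what each stage assumes,
which parameters matter, and what the synthetic validation does and does not
establish.

## The structural model

Mitochondrial ADP/ATP carriers are built from three homologous ~100-residue
domains arranged with approximate three-fold (pseudo-C3) symmetry about the
membrane normal. Each domain contributes an odd-numbered transmembrane helix,
a short matrix helix, and an even-numbered transmembrane helix. The carrier
alternates between a cytoplasmic-open (c) and a matrix-open (m) state; the
transition is described here, as in the structural literature, by splitting
each domain into two quasi-rigid pieces:

- the **core element** — the odd helix, matrix helix, linker and the
  N-terminal third of the even helix — which *rocks* as a rigid body by
  roughly 15° to open or close the matrix side; and
- the **gate element** — the even helix from its kink at the substrate-binding
  *contact point* (R88, G192, R287 in TtAac numbering) to the C-terminal
  end — which rotates toward the central axis to seal the cytoplasmic side.

The contact-point residue itself is assigned to the gate element: it is the
pivot of the even-helix kink and moves with the gate. Within each domain,
core and gate partition the domain span exactly (a tested invariant).

Closure of each side is maintained by a triplet of inter-domain salt bridges:
the matrix network (from the Px[DE]xx[KR] signature motifs on the odd
helices) and the cytoplasmic network (from the [YF][DE]xx[KR] motifs on the
even helices), the latter reinforced by tyrosine/arginine braces one helical
turn from the charged residues and by a hydrophobic plug (F97/F201/L295).

Two built-in annotations ship with the package: TtAac (domains 13–107,
116–211, 220–306) and ScAac2, derived from TtAac by the inter-species
residue correspondence (+8 in domain 1, +7 in domains 2 and 3, anchored on
published equivalences such as TtAac R100 = ScAac2 K108). The TtAac helix
*spans* are approximate: no per-helix boundaries are published, so defaults
were chosen consistent with the domain boundaries, the contact points, and
the helical fragments used to phase the structure. They are configuration
values, not code constants — override them via a topology JSON if better
assignments are available.

## Superposition and outlier rejection

Rigid superposition is the SVD (Kabsch) solution with reflection correction;
optimality is cross-checked in the tests against a dense SO(3) grid search
and against an independent library implementation. Element fits use backbone
atoms (N, CA, C, O).

Interactive alignment tools refine fits by cycles of rejection. The
emulation here is pinned and reproducible: after each fit, any residue whose
mean backbone deviation exceeds `cutoff_factor` (default 2.0) times the
current RMSD is removed and the fit repeated, stopping when nothing is
rejected, fewer than half the atoms would remain, or `max_cycles` (default
5) is reached. Rejection is per-residue, not per-atom. Only the elements
known to carry inhibitor-induced distortions (core element 2 and the H2
gate) use rejection by default; the others are plain least-squares, matching
the observation that they superpose well without it.

Sequence correspondence between homologous carriers uses global alignment
with BLOSUM62, gap open 10, gap extend 0.5, free end gaps. Percent identity
is identical pairs divided by alignment columns between the first and last
aligned pair (internal gap columns count; end gaps do not) — the denominator
matters at the ±1–2% level and is fixed here for reproducibility.

## Helix axes and kink angles

A kink angle is the angle between helix-axis directions fitted to the
`flank` residues (default 7, about two turns) on either side of a designated
break residue, which is excluded from both fits; straight helices score ~0°.

Axis directions are **not** taken from raw principal components: on a short
segment the helical radius and the phase of incomplete turns bias the first
PC by tens of degrees (a perfectly straight helix would measure as a ~23°
"kink" with 7-residue flanks). Instead each window of four consecutive
C-alphas yields a local direction from the cross product of successive
bond-difference vectors — exact for an ideal helix of any length — and the
windows are averaged. The reported fit quality is the variance fraction
explained for the turn-averaged trace. With this estimator the synthetic
recovery sweep (kinks of 10–90°) is exact to well under the 2° test
tolerance at zero noise.

The angle convention is deviation from collinearity: 0° means straight and
the value grows as the helix bends. Published kink angles are sometimes
quoted in the complementary convention (180° − angle, the inter-axis
angle); when comparing against literature values, check which convention a
source uses — the acceptance tests against the deposited structures
interpret the published H3 values (76°/43°) in the deviation convention
and would reveal a systematic complement-offset if the interpretation were
wrong.

## Pseudo-C3 axis and symmetrization

The public axis estimator fits the rigid transforms domain 1→2 and 2→3 on
symmetry-related C-alpha triples (obtained by pairwise global alignment of
the domain subsequences) and reports the mean rotation axis with per-pair
residuals |angle − 120°|.

Symmetrization keeps each domain internally rigid — the rigid-body limit of
the restraint-based approach it replaces — and iterates: propose a
three-fold generator from each cyclic inter-domain fit (rotation projected
to exactly 120° about its axis line); for each candidate, map the domains
into a common sector, build a template from the proposing pair, and refit
every domain rigidly; apply the candidate whose step moves the least total
C-alpha mass. The least-action selection is the important choice: averaging
all three mapped copies instead makes the *mean* configuration the fixed
point, so a single displaced domain drags the other two (and the axis) a
third of the way toward itself, and the displacement is never cleanly
removed. With the anchor-pair generator, a planted single-domain
displacement is corrected exactly (residual 0 against the original bundle;
only the displaced domain moves), the procedure is idempotent to machine
precision, and intra-domain geometry is preserved to < 1e-6 Å (all tested).
Convergence: max C-alpha step < 0.01 Å, at most 50 iterations; a
non-converged result is returned with `converged=False` rather than raised.
The documented restraint weight (2) is retained as metadata only — in the
rigid-body limit it has no free role.

Inter-domain linker atoms, which belong to no rigid piece, are placed by
per-atom linear blending between the flanking placements, weighted by
residue position. No loop rebuilding or energy minimization is performed;
the built models serve geometric analysis, not stereochemistry.

## Uninhibited state models

The uninhibited m-state is the symmetrized matrix-open structure. The
uninhibited c-state transplants the six elements of the matrix-open
structure onto the cytoplasmic-open template by independent backbone
superpositions (rejection only for core 2 and gate H2, as above), with
linkers blended. Building the c-state from the m-state's elements rather
than the reverse avoids propagating the inhibitor-induced H2/H3 distortions
of the cytoplasmic-open crystal form.

## Morphing and occlusion

Element-wise interpolation between states decomposes each element's A→B fit
into a rotation (constant-angular-velocity spherical interpolation) about
the moving element centroid and a linear centroid path, using the symmetric
form `x(s) = R_s[(1−s)(x_A−c_A) + s·R⁻¹(x_B−c_B)] + (1−s)c_A + s·c_B`.
Endpoint frames are the input coordinates verbatim; the midpoint of a pure
rotation carries exactly half the angle; and the morph is frame-wise
symmetric under A↔B exchange to 1e-9 Å (all tested invariants). Linker
atoms interpolate linearly.

Accessibility uses a probe-inflated grid flood fill: grid spacing 1.0 Å
(must not exceed the probe radius, 1.4 Å), vdW radii C 1.7 / N 1.55 /
O 1.52 / S 1.8 Å, 6 Å solvent margin. Free cells are flooded from the two
box faces along the membrane normal (taken as the pseudo-C3 axis; the
matrix side is the −axis face by default); a side is accessible when its
flood reaches a free cell within 4 Å of a binding-site atom, and a frame is
occluded when neither side is.

Two operational choices deserve note. First, an *implicit membrane*: inside
the central axial slab (70% of the structure's axial extent by default),
cells lying laterally outside the per-layer protein footprint are treated
as lipid and blocked. Without this the flood from one face simply wraps
around the outside of the protein and enters through the open far side, and
every state reads as open from both directions. The footprint model assumes
a roughly convex cross-section; deep lipid-facing grooves that truly
connect the two leaflets would be (incorrectly) sealed. Second, *gate
thickness* is the axial extent of the largest contiguous run of grid layers
in which no free cell within 8 Å of the axis is reachable from either face
— a symmetric reading of "the blocked span", since a one-sided definition
would count the solvent cavity itself as gate in an occluded state. The
thickness is an operationalization and is treated as approximate (band
checks only); in a fully occluded model it spans cap-plus-cavity and is not
comparable between implementations.

Clash counting (pairs of non-bonded atoms from different, non-adjacent
residues closer than 2.6 Å) is a morph diagnostic: element-wise morphs of
the synthetic bundle stay clash-free where whole-molecule interpolation
would tear the structure.

## Polar-interaction networks

Salt bridge: side-chain N of K/R/H within 4.0 Å of a side-chain carboxylate
O of D/E. Brace hydrogen bond: hydroxyl/amide side-chain O/N (Y, S, T, N, Q)
within 3.6 Å of a charged side-chain atom. Distances only — no hydrogens,
no angular criteria. Each residue pair is reported once at its
minimum-distance atom pair, with a salt bridge outranking a brace for the
same pair. Histidine is accepted as a donor (an inclusive default; no
carrier network position is His). Contacts are tagged intra-/inter-domain
from the domain spans, assigned to the matrix or cytoplasmic network by
residue-set membership (braces count toward the cytoplasmic network), and
listed residues whose side-chain atoms are missing from a model are reported
as unevaluable rather than silently dropped. Network comparison between
states is a set difference on residue pairs after mapping numbering through
the correspondence.

## The synthetic generator, and what the tests do and do not show

All quantitative behaviour is validated on generated structures with known
ground truth. The generator emulates exactly the features the analysis
consumes:

- ideal α-helices (rise 1.5 Å/residue, twist 100°/residue, C-alpha radius
  2.3 Å; N/CA/C placed on per-atom-type cylinders derived from ideal
  internal coordinates at φ=−63.5°, ψ=−41.5°; carbonyl O placed in the
  peptide plane anti to the following N, which keeps the O(i)···N(i+4)
  hydrogen bond at ~2.9 Å and the bundle clash-free at the 2.6 Å
  criterion);
- six-helix bundles with exact C3 placement (triplets at 0°/120°/240°,
  antiparallel within a domain, bundle radius 12 Å) and ground-truth
  topology;
- planted kinks (exact by construction), planted charged pseudo-atom pairs
  at specified distances (single side-chain atoms, e.g. NZ/OD1, on the
  inter-C-alpha line), rigid element perturbations with recorded global
  transforms, and seeded Gaussian coordinate noise;
- a two-state pair with the study's planted conditions: 15° core rocking,
  25° gate swing about the contact-point pivot, an H3 kink changing from
  76° to 43°, a three-pair cytoplasmic-style network formed in the m-like
  state only, and 75% sequence identity;
- a gated-pore fixture (barrel plus sliding caps) for occlusion logic with
  unambiguously known answers.

Everything is bit-reproducible under a fixed seed. The state pair uses
30-residue helices (60-residue domains) so that ≥50 symmetry triples survive
the planted sequence divergence; the analyses on it run in seconds.

What passing these tests shows: the estimators recover planted parameters at
stated tolerances, the algorithms satisfy their invariants, and the pipeline
is deterministic. What it does not show: behaviour on real side-chain
packing, crystallographic noise and missing atoms, non-ideal helix geometry,
or membrane proteins whose cross-section violates the convex-footprint
assumption. The published-value checks in the acceptance suite run whenever
the two deposited carrier structures are supplied locally (see
`tests/test_acceptance.py`); they are the bridge between the synthetic
validation and the real system.

## Degenerate inputs and tie-breaks

Collinear point sets are rejected by the superposition (second singular
value < 1e-12). Inter-domain transforms with rotation below 30° are treated
as degenerate for axis estimation. Altloc resolution keeps the
highest-occupancy copy, ties broken toward altloc "A". The identity
rotation reports angle 0 with a documented arbitrary axis (+z). Selection
output order is residue order then a fixed atom-name order, independent of
file order. Residue ranges are author-numbered and inclusive at both ends
throughout.
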