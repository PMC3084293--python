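# Methods

## Structure model and I/O

Coordinates are read with gemmi (PDB and mmCIF, auto-detected by
extension then by first record) into a minimal chain→residue→atom
hierarchy keyed by *author* residue numbering, since every residue
named in the neurexin literature (Trp1065, Pro1085, the Ca²⁺ ligands)
is an author number. Two policies are applied on read and are
deliberate simplifications:

- **Hydrogens are dropped.** All downstream geometry (SASA, clashes,
  superposition) is heavy-atom; a 2.3 Å crystal structure carries no
  hydrogens anyway.
- **Alternate conformers are reduced to one atom**: highest occupancy
  wins, ties go to the alphabetically first altloc. This keeps every
  geometric result single-valued and deterministic.

Residue categories (amino acid / water / ion / sugar / other) come
from a fixed table of three-letter codes: the 20 standard amino acids
plus MSE (which maps to `X` in extracted sequences), common waters,
monoatomic ions, and pyranose codes including NAG. Unknown codes fall
to `other` rather than guessing.

## Superposition

Kabsch's closed-form solution: SVD of the covariance of the centred
point sets, with the sign of the smallest singular vector flipped
whenever the unconstrained optimum would be a reflection, so det(R) is
always +1. The rotation angle is reported via the rotation-vector
magnitude, which equals acos((trace−1)/2) but keeps precision near 0°
and 180°. Degenerate inputs (fewer than three points, or collinear
points, where the rotation about the line is unconstrained) are
rejected rather than silently resolved.

Correspondences are built two ways:

- **numbering-based** — residues sharing author numbers after a
  caller-supplied offset (β-neurexin structures number the LNS6
  sequence from Gly84 where the α fragment has Gly1086, offset −1002);
- **sequence-seeded iterative alignment** for homologues with
  unrelated numbering: a global BLOSUM62 alignment (gap open −11,
  extend −1) seeds the pairing, then the loop superposes on current
  pairs, re-pairs mutually nearest Cα atoms within a prune cutoff
  (default 4.5 Å, ties to the lower residue number), and repeats to a
  fixed point (max 50 iterations). An iterate that would raise the
  RMSD without adding pairs terminates the loop and the previous
  iterate is returned, which is what makes the recorded RMSD history
  non-increasing under pruning. The exact published protocols behind
  numbers like "163 matched residues at 1.55 Å" are tool-internal, so
  agreement is asserted with tolerances (±0.3 Å, ±15 residues), not
  exactly.

Interface plasticity is the relative transform T_B ∘ T_A⁻¹ between two
placements of the same rigid body after both complexes are superposed
on the partner molecule; the rotation is its angle and the translation
is the Cα-centroid displacement. A screw decomposition would be an
alternative translation measure; centroid shift was chosen because it
is what a superposed figure shows directly.

## Solvent-accessible surface area

Shrake–Rupley: each atom's accessible sphere (r_vdw + r_probe) is
sampled with a deterministic golden-spiral point set (no RNG), and the
exposed fraction scales the analytic sphere area. Defaults: probe
1.4 Å, 960 points, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 /
Se 1.90 / Ca 1.97 Å. An atom whose element has no table entry is an
error naming the atom — a silent default radius would bias buried
areas invisibly.

Buried interface area is the two-sided measure
SASA(A) + SASA(B) − SASA(A∪B), computed over amino-acid heavy atoms
only; waters, ions and glycans are excluded throughout, and residues
forming the covalent inter-domain linkage (Gly1045–Pro1046 for the
LNS5–EGF3 junction) can be excluded from both the isolated and the
combined terms. Published buried-area figures depend on the radii set
and sampling of the original software, which are unrecorded, so
agreement on deposited entries is asserted at ±10%. The per-residue
breakdown sums exactly to the total by construction.

## Clash detection and hinge relief

A clash is a heavy-atom pair with centre distance below
r_i + r_j − tolerance, tolerance 0.4 Å by default (the conventional
severe-clash threshold; no criterion is stated with the published
model). Candidate pairs come from a KD-tree at the maximal contact
radius and are then tested exactly, so the result is identical to the
all-pairs computation (property-tested against it). Intra-chain pairs
within two residues of each other are never counted, and in hinge
scans mobile residues within two residues of the pivot are dropped —
both guards exist so the covalent linker cannot masquerade as a
clash.

The minimal relief rotation scans a deterministic grid: 200
Fibonacci-sphere axis directions through the pivot Cα × angles from
1° to 60° in 1° steps, returning the smallest angle any axis makes
clash-free. A published single-axis "rotated N° " description
under-determines the axis, so the package reports the minimum over
axes, which lower-bounds any specific choice. A clash-free input
reports 0°; if no grid point clears every clash the result carries the
minimal residual count instead of an angle. For a one-atom mobile set
the optimum is analytic (rotate in the pivot–atom–obstacle plane, away
from the obstacle; the law of cosines gives the angle), and the scan
is required to land within one grid step of that closed form.

## Metal coordination geometry

Inner-sphere ligands are all O/N atoms within a cutoff of the ion,
3.0 Å by default (typical Ca–O bonds run 2.3–2.6 Å), labelled by role:
backbone carbonyl O (atom name `O`), other protein O (side-chain),
water O, or other (e.g. protein N). Classification compares the unit
ligand directions against the ideal polyhedron with the same vertex
count — regular octahedron for six, pentagonal bipyramid for seven,
the two shapes relevant to LNS-domain Ca²⁺ sites; other counts report
`other`. Every vertex assignment (≤ 7! permutations) is tried and the
template optimally rotated onto the observations (Kabsch on unit
vectors); the score is the RMS angular deviation, making the result
exactly invariant under global rotation and ligand permutation.
Brute force was chosen over heuristic matching because exactness is
cheap at these sizes. No occupancy claims are made for any site.

## EGF signature scan

The register is the first six cysteines of the cleaned sequence
(gap characters and lowercase alignment insert-states are stripped
first); fewer than six is a flagged failure, not an exception, and
sequences with more than six use the first six. The signature position
is the residue four after the third cysteine, counting the cysteine
itself as zero — the convention validated against the structure-derived
anchor, where C3 at author position 1061 puts the signature at
Trp1065. Scan summaries report the signature fraction both over
sequences with a valid register and over all sequences, since a
database census could use either denominator.

## Synthetic study conditions

The generators produce the geometry of each problem with recorded
ground truth, not realistic proteins:

- **two-domain toy** — two blobs of single-carbon pseudo-residues
  (25 per domain, 7 Å radius, ≥3.2 Å spacing) at a controlled centroid
  separation; ground-truth buried area from a 10,000-point SASA
  evaluation of the same geometry.
- **clash scenes** — the one-atom case carries its closed-form relief
  angle; multi-atom cases carry an independent all-pairs, plain-numpy
  grid-search oracle on the same axis/angle grid.
- **metal shells** — water oxygens at 2.4 Å along template directions,
  each tilted by an angle drawn uniformly from [0, noise] about a
  random perpendicular axis; 5° noise is the robustness condition for
  the 100-draw classification check.
- **EGF sets** — fixed-length sequences with exactly six cysteines
  (≥5 apart so the signature position is unambiguous), an exact count
  of signature-positive sequences, optional five-cysteine decoys, and
  no stray C or W in the background alphabet.
- **docking scene** — a rigid helix core copied into the "complex"
  frame by a random rigid motion, an arm joined at a pivot residue,
  and a receptor blob placed against the arm; relief-angle oracle as
  above. Plasticity instances rotate the bound helix about an axis
  through its own centroid (so rotation and translation truths
  decouple exactly: pairwise values are |aᵢ−aⱼ| and |tᵢ−tⱼ|) before a
  random global scramble that the partner superposition must undo.
  The default instance spread (0–8° rotations, 0–2 Å translations)
  emulates the deviation range reported across deposited
  neurexin/neuroligin complexes.

All generators are pure functions of (seed, parameters) with one
`numpy` Generator stream each; repeated runs are byte-identical
through PDB round trips. What passing synthetic tests shows is that
the geometry engines are correct on controlled inputs; it does not
show anything about crystallographic error, alternate conformations,
or the radii conventions of other software — which is why
deposited-entry agreement carries the looser tolerances stated above.

## Problem sizes

Default sampling densities (960 SASA points, 200 hinge axes × 60
angles, 100-draw robustness checks, 1000-sequence oracle comparisons)
were chosen so each check is decisive while the full synthetic suite
and benchmark script complete in about a minute on one CPU; the dense
10,000-point SASA oracle is confined to the generators and tests that
cite it.

## Known limitations

- Deposited entries are not redistributed; the reference analyses and
  their tests require a one-time fetch (`analysis/01_fetch_reference.py`).
- The SASA radii table is by element, not atom type (no OXT/charged
  distinction); adequate at the ±10% level used for buried-area
  comparisons.
- Hinge relief treats the mobile segment as rigid — no side-chain
  repacking, no energetics; "relieved" means sterically clean at the
  stated tolerance.
- Coordination classification only scores the two templates it
  contrasts; 8-coordinate or square-antiprismatic sites report
  `other`.
- The iterative aligner seeds from a global sequence alignment;
  repeat proteins with severe register ambiguity could seed wrongly,
  though the prune/re-pair loop usually recovers.
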