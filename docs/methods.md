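# Methods

## The descriptor model

All descriptors in this package are purely geometric functions of atomic
coordinates; no energies or force-field terms enter anywhere. The unit of
analysis is one interfacial pocket of a homopentameric receptor ECD,
identified by its principal (+) and complementary (−) subunit. Pockets are
labelled a–e in ring order with principal subunit *i* and complementary
subunit *i*+1 (mod 5); a `ring_reversed` flag serves structures of opposite
handedness. Coordinates are in ångström throughout (nanometre trajectory
formats are converted on read).

### Interaction criteria

* Hydrogen bond: donor–acceptor heavy-atom distance ≤ 3.0 Å **and**
  donor–H–acceptor angle ≥ 135° (180° = linear). Donors are N/O heavy atoms
  with a bonded hydrogen; hydrogens are paired to their heavy atom by the
  PDB naming convention (HH1↔NH1, HG↔OG, HZ1↔NZ, …, within a 1.6 Å sanity
  cap) with a plain < 1.2 Å covalent-distance fallback. Acceptors are O
  atoms plus N atoms carrying no hydrogen: a protonated nitrogen (backbone
  amide, ammonium, guanidinium, amide ND2) is a donor only. Intra-residue
  pairs are excluded. The cutoffs live in `InteractionCriteria` and in the
  config file.
* Water bridge: one record per (residue, water) per frame when a single
  water hydrogen-bonds the ligand (either direction) and the residue in the
  same frame. Multiple simultaneous H-bond geometries through the same
  water still count once — the conservative reading of per-residue bridge
  multiplicity.
* Cation−π: ligand ammonium nitrogen (configurable) to aromatic ring
  centre ≤ 6.0 Å, with the angle between the best-fit ring normal (SVD of
  the centred ring atoms) and the centre→cation direction < 45° or > 135°.
  The ring centre is the unweighted centroid of the ring atoms.

Occurrence statistics: per (pocket, residue, kind), the percentage of
frames with at least one record; per (pocket, kind), the mean simultaneous
record count per frame ± s.d., counting multiple bonds with one residue and
treating frames without records as zero.

### Pocket cage and Loop C angle

The "atomic cage" is the convex hull (scipy `ConvexHull`) of the Cα atoms
of the 11 binding residues (7 principal: PHE115, GLU173, SER174, PHE175,
TYR218, THR220, PHE223; 4 complementary: PHE79, ARG81, LEU133, SER145),
rebuilt at every frame. Water occupancy counts water oxygens inside or on
the hull; points on a facet count as inside within a 10⁻⁹ Å half-space
tolerance, which keeps the integer count deterministic under floating-point
ties. The hull volume is reported raw, with no correction for the ligand's
excluded volume.

The Loop C orientation angle uses three Cα-pair centroids: apex C
(ASN219/THR220), hinge O (THR215/THR224) and complementary reference G
(ASN58/ARG81). The angle is taken **at the hinge** between rays O→C and
O→G — the loop pivots at its hinge — and the vertex is selectable
(`vertex="apex"/"hinge"/"reference"`) for sensitivity analysis.

### Assembly metrics

* Channel axis: eigenvector of the Cα inertia tensor whose eigenvalue is
  most separated from the other two (the unique moment of a ring-shaped
  assembly), sign-oriented from the restrained C-terminal tail centroid
  (residues 236–240) toward the overall Cα centroid. Parameter-free and
  stable for ring-like domains; a fixed axis can be substituted by the
  caller.
* RMSD: per-subunit backbone (N, Cα, C, O) deviation from the first frame
  after optimal (Kabsch) superposition.
* RMSF: per-residue Cα fluctuation after a two-pass fit — each frame's
  subunit backbone is superposed on the first frame to build the average
  structure, then on that average; the fluctuation is measured about the
  post-fit mean positions. Loop membership follows configurable
  residue-number ranges; exact loop termini are not published, so the
  shipped ranges bracket the residues named in the literature and are
  overridable.
* Contact maps: fraction of frames with Cα–Cα distance strictly below
  11 Å, principal × complementary subunit.
* Intrapocket/interpocket distances: binding-residue Cα centroids
  (unweighted — all Cα are carbons) projected per frame onto the plane
  orthogonal to the channel axis. Intrapocket: a pocket's principal-side to
  complementary-side centroid distance. Interpocket `x-y`: the
  complementary-side centroid of pocket x to the principal-side centroid of
  pocket y, the two centroids carried by their shared subunit. Distances
  are measured per frame and averaged; a `mean_positions=True` variant
  measures once between time-averaged centroids.
* Push–pull: for each consecutive-subunit triplet (i, i+1, i+2), the
  Cα–Cα distances SER174(+, Loop B′)→SER145(−, Loop E″) and
  LYS189(+, Loop F′)→SER145(−, Loop E″) and their Pearson correlation. A
  zero-variance series makes the correlation undefined (`None`), not an
  error of the pipeline. All five triplets are computed.

### Collective variables

Binding-site COM distance uses mass-weighted centroids. The solvation
coordination sums (1−(d/d₀)⁶)/(1−(d/d₀)¹⁰) over ligand-carbon ×
water-oxygen pairs with a hard 10 Å inclusion cutoff and d₀ = 2.5 Å; the
removable singularity at d = d₀ evaluates to 6/10. The hard cutoff leaves a
documented discontinuity of ≈ (d₀/10)⁴ ≈ 4·10⁻³ per pair at 10 Å, accepted
as part of the printed definition. Both ligand carbons of the glycine
zwitterion (Cα and the carboxylate carbon) enter the sum. Bias deposition,
well-tempered schedules and free-energy reconstruction are out of scope
(the reference protocol used a bias factor of 15, Gaussian widths
0.15 Å / 0.03 and height 1.2 kJ/mol in an external engine; recorded here
for context only).

## The synthetic pentamer generator

`pentapocket.synthetic` emits a C5 assembly of five minimal pseudo-subunit
scaffolds (72° rotations of one template) carrying every residue the
pipeline addresses, ligand particles (glycine-zwitterion-shaped) in a
configurable subset of pockets, cage waters with scheduled counts, and
exterior/parked waters. Chemical realism is deliberately absent: the
descriptors are geometric, so pseudo-residues with a handful of named atoms
give exact ground truth at desk scale.

Scripted conditions (defaults emulate the bound/empty pocket contrast of
the receptor):

| condition | bound pocket | empty pocket |
|---|---|---|
| cage waters | 1 (the bridge water) | 7 |
| Loop C angle | 24° ± 1° sinusoidal | 33° ± 2° |
| intrapocket distance | 11.6 Å (0.8 Å contraction) | 12.4 Å |
| ligand H-bond rates | ARG81 0.93, SER145 0.93, THR220 0.80, PHE175 0.50 | — |
| water-bridge rates | GLU173 0.75, SER174 0.70 | — |
| cation−π rates | PHE175 0.98, TYR218 0.40, PHE223 0.35, PHE79 0.05 | — |

Conserved intersubunit pair rates (all pockets): GLU119–ARG147 0.90,
LYS49–ASP96 0.70, ASN219–ASN58 0.60, THR220–ARG135 0.50, ASN219–LYS189
0.50. Push–pull: per-frame latent normals u, v drive Loop B′ and Loop F′
Cα displacements (amplitude 1.0 Å) with scripted coupling c ∈ [0, 1], so
the two monitored distances have population correlation exactly c. Thermal
noise is isotropic Gaussian with σ = 0.2 Å per coordinate by default. The
interpocket baseline lands at ≈ 16.5 Å via the default ring radius
(21.6 Å); intrapocket targets are met exactly by calibrated cluster shifts.

Design choices worth knowing:

* **Angle realization.** The scheduled Loop C angle is imposed by placing
  the ASN219 Cα so the apex-pair centroid meets the target given the
  current hinge and reference anchors; THR220 (a cage vertex) stays static.
  This decouples hull volume and intrapocket distance from the angle
  schedule, so each scripted quantity can be validated independently. Hull
  swelling is scripted separately via a `cage_scale` schedule (all 11
  vertices scale about their centroid, so volume scales exactly as s³).
* **Noise model.** Hydrogens ride their parent heavy atom (constrained X–H
  bonds, as in SHAKE/rigid-water MD), and scripted hydrogens reorient
  toward their partner atom after noise — emulating how a rigid water or
  hydroxyl keeps its donor geometry while a bond persists. At σ = 0 both
  rules are the identity. Without them, iid hydrogen noise breaks covalent
  pairing and bends donor angles at rates that misrepresent the scripted
  occurrence conditions.
* **Stream scoping.** Randomness is split into seed-scoped streams
  (waters, noise, events, push–pull), so changing one schedule never shifts
  another. Event streams are shared across the five pockets, which makes
  the C5-symmetry property exact at σ = 0 rather than merely statistical.
* **Ground-truth ledger.** Every scripted quantity (water counts, angles,
  per-frame hull volumes and intrapocket distances computed on the
  pre-noise geometry, Bernoulli event series, push–pull distances) is
  returned alongside the trajectory, and `ground_truth_ledger` regenerates
  it deterministically from (params, seed).

What the generator does **not** emulate: real protein geometry and
secondary structure, water structure and exchange, ligand flexibility,
periodic boundaries, and correlated slow modes beyond the scripted ones.
Passing tests therefore demonstrate that the descriptors measure what they
claim on geometry with known truth — not that the defaults reproduce any
particular experimental trajectory.

## Numerical choices

* Boundary waters count as inside the hull (tolerance above).
* Contact condition is strict `< 11 Å`; occurrence thresholds are `≥` for
  the H-bond angle and `≤` for distances, matching the printed criteria.
* Hull construction uses Qhull via scipy; degenerate (coplanar) cages raise
  a validation error rather than returning a zero volume.
* Superpositions use `scipy.spatial.transform.Rotation.align_vectors`
  (Kabsch); identity fits are zero to ~10⁻⁷ Å (solver tolerance).
* Zero-variance correlation inputs are rejected with a relative tolerance
  of 10⁻¹² on the standard deviation.
* The pipeline derives pocket occupancy from the ligand molecules actually
  present in the structure (each assigned to the nearest cage centroid),
  overriding the config pattern if they disagree.
* Determinism: identical inputs and seed give byte-identical CSV outputs;
  the manifest records a SHA-256 hash of the effective config.

## Problem sizes and limitations

The test suite and the acceptance script run the pipeline at 500 frames ×
~1700 atoms (the two-ligand synthetic model), where every stage completes
in well under a minute on one CPU; statistical recovery checks (occurrence
rates within 99% binomial intervals, a scripted 1 Å contraction within
three standard errors, push–pull ordering across coupling 0/0.5/1) use the
same scale. Known limitations: only pentamers are exercised (the code does
not hard-code n = 5 everywhere, but nothing else is tested); heteromeric
topologies, PBC imaging, grid-based pocket volumes and PCA-style analyses
are out of scope; and reproducing published trajectory averages requires
the corresponding deposited data, which this repository does not ship.
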