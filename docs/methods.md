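# Methods

## Overview

`voxattrib` implements an interpretability pipeline for voxel-based 3D
convolutional protein–ligand scorers: featurize a complex onto a 16-channel
pharmacophore grid, score it with a small differentiable 3D CNN, and explain
the score with Integrated Gradients (IG), both visually (Gaussian cube
export, top-region summaries, per-atom scores) and quantitatively
(complementary-channel reciprocity statistics).  A synthetic complex
generator makes every stage trainable and testable on one CPU with no
external data.

## Voxel featurization

Each atom carries eight boolean properties: hydrophobic, aromatic, H-bond
donor, H-bond acceptor, positive ionizable, negative ionizable, metal, and
heavy (the occupancy/excluded-volume property).  Protein and ligand are
rasterized separately, giving 16 channels on a cubic grid of 24 voxels per
side at 1.0 Å spacing, centered at the ligand's geometric center.  A flagged
atom deposits

    n(r) = 1 − exp(−(r_vdw / r)^12)

onto each voxel within a 5 Å cutoff (r = atom–voxel-center distance, r_vdw a
Bondi-style van der Waals radius), aggregated per voxel by maximum so values
stay in [0, 1].  n(r) saturates at 1 inside the vdW sphere and decays
steeply beyond ~1.3·r_vdw, so grids are close to binary; the information
distinguishing a 2.6 Å hydrogen-bond contact from a 1.4 Å steric clash lives
in the *extent* of the region where both protein and ligand channels are
simultaneously high, not in any single voxel's value.

Pharmacophore typing is deterministic and rule-based.  Ligands read from SDF
use RDKit connectivity and SMARTS patterns (carboxylate/phosphate/sulfonate
oxygens → negative ionizable, amine/guanidinium nitrogens → positive,
aromatic flags from perceived aromaticity, donors = N/O/S bearing hydrogens,
acceptors = N/O with a free lone pair).  Proteins use residue/atom-name
templates (Phe/Tyr/Trp/His ring atoms aromatic, Asp/Glu carboxylates
negative, Lys/Arg nitrogens positive, backbone and side-chain donor/acceptor
tables) plus distance-inferred connectivity; when explicit polar hydrogens
are present they override the donor templates.  Only heavy atoms and polar
hydrogens are retained from input structures; hydrogens never contribute to
occupancy, only to donor flagging of their parent.  Waters and non-protein
heteroatoms other than coordinated metal ions are dropped.

## Scorers

Three tasks share one architecture: a clash detector and a docking-pose
classifier (binary, the model's output is the pre-sigmoid logit) and a
pKd-like regression head.  The network is written directly in numpy with
exact manual backpropagation, because the attribution method needs
d(output)/d(input) at arbitrary interpolated inputs and training needs
weight gradients.

The architecture has two branches feeding one linear output unit:

- **Interaction-count branch.**  A pointwise (1³) stride-1 convolution at
  full grid resolution whose three units are *initialized* as coincidence
  detectors — each fires at voxels where protein-occupancy + ligand-occupancy
  (or the two donor/acceptor cross combinations) exceed a contact threshold —
  followed by a smooth rectifier and a global spatial sum.  This is a
  differentiable, trainable count of interaction voxels.  The initialization
  matters: stochastic gradient descent is extremely slow at discovering such
  narrow AND-gates from scratch (the gradient basin around the required
  ~−1.9 bias is tiny), but given the primed start it refines them readily.
  The corresponding output weights start at zero so that correlated counts
  cannot cancel each other at initialization.
- **Spatial branch.**  Two batch-normalized stride-2 3³ convolution blocks
  (16→16→32 feature maps, 24³→12³→6³) whose output maps are flattened into a
  32-unit dense layer.  Because the box is ligand-centered, absolute position
  in the grid is meaningful (e.g. how close the pocket wall sits on each
  side), so flattening is preferred over global pooling, which would erase
  exactly the spatial patterns these tasks need.

Activations are sharp softplus, `log(1+exp(4x))/4`, rather than ReLU.  This
choice is driven by the attribution method: a ReLU network is piecewise
linear, its path-integrand is piecewise constant, and the IG Riemann sum
then converges only at O(1/n) and non-monotonically; with smooth activations
the completeness gap falls at O(1/n²) and is far below 1% of the score
difference at the default 100 steps.  At sharpness 4 the training behavior
is indistinguishable from ReLU in our experiments.

Training: Adam (lr 2·10⁻³, batch 16), binary cross-entropy on the logit (or
squared error for regression), at most 30 epochs with early stopping on a
held-out 20% validation split (patience 4, minimum improvement 10⁻³), best
weights restored.  All initialization and the split derive from a single
integer seed; batch-norm uses running statistics at evaluation time, so
scoring and attribution are deterministic.

## Integrated Gradients

For scorer F, input grid x and baseline x′ (all-zero by default — the empty
box), the attribution of voxel i is

    IG_i = (x_i − x′_i) · (1/m) Σ_{k=1..m} ∂F/∂x_i (x′ + α_k (x − x′)),

a midpoint Riemann sum with α_k = (k−½)/m and m = 100 steps by default.
Attributions keep their sign (positive pushes the score up).  Classifiers
are attributed on the pre-sigmoid logit, so output saturation cannot zero
the gradients that the path integral is meant to recover.  Two extra forward
passes record the completeness gap |Σ IG_i − (F(x) − F(x′))|, the standard
quadrature-error diagnostic; it is stored on every attribution grid and
never dropped.  Attribution arithmetic is accumulated in float64 regardless
of grid dtype.

Summaries follow the scheme used for visual inspection: per channel, the
voxel with the largest |attribution| plus its in-bounds Chebyshev-radius-1
neighborhood (26-connectivity); globally, the channels owning the 5 largest
nonzero |attributions| (ties broken toward the lowest linear index,
channel-major).  Per-atom scores assign every nonzero-attribution voxel to
the nearest atom of the channel's entity that carries the channel's
property; the per-entity top atom is the score argmax.  A channel whose top
voxel has no property-matched atom within 3 Å is reported unassigned.  The
neighborhood radius and the voxel→atom rule are this package's own
definitions.

## Reciprocity analysis

For five complementary channel pairs (protein/ligand hydrophobic,
protein/ligand aromatic, protein acceptor + ligand donor, protein donor +
ligand acceptor, protein/ligand occupancy) the analysis records, per
complex, the Euclidean distance between the two per-channel
argmax-|attribution| voxel centers.  The random baseline draws one voxel per
channel uniformly among voxels whose *feature* value exceeds 0.75 —
guaranteeing an atom nearby — and records their distance; both draws come
from one seeded generator.  Distances vs baseline are compared with a
two-sided Mann–Whitney U test (exact enumeration with midrank ties for
min(n,m) ≤ 8, tie-corrected normal approximation otherwise), and the summed
|attribution| of the two top voxels is correlated (Pearson) with their
distance.  Pairs are reported individually without multiplicity correction.

The consistency study re-attributes a complex across rotated or slightly
perturbed (0.5 Å RMSD) input variants and counts how often the same atom is
the per-entity top atom; the random baseline is the expected modal count
under uniform atom choice, estimated by simulation from the same seed
stream.

## Synthetic complexes

The generator emulates, at desk scale, the ingredients the analyses need:

- **Pocket**: a spherical shell of pseudo-residue atoms (default 80 atoms at
  radius 8.0 ± 0.75 Å per complex, ±0.6 Å per atom) around a cavity.
  Composition ~70% hydrophobic carbon (20% of those aromatic), 15% donor
  nitrogen, 13% acceptor oxygen, 2% metal, with occasional ionizable flags.
- **Ligand**: a connected random-walk cluster of 12 heavy atoms (bond length
  1.5 Å, max branch degree 3) with elements C/N/O at 60/20/20%, rule-derived
  hydrophobic flags, a 3-atom aromatic patch, and donor/acceptor flags on
  N/O.  The ligand sits off-center in the cavity (uniform offset up to
  1.2 Å) — as real ligands do — which also prevents "wall asymmetry in the
  ligand-centered box" from becoming a degenerate class label for scorers.
- **Interactions**: 60% of flagged ligand atoms receive a pharmacophore-
  complementary protein partner placed 2.6–3.4 Å away (donor↔acceptor,
  aromatic↔aromatic, hydrophobic↔hydrophobic).
- **Poses**: crystal-like poses keep every protein–ligand heavy-atom
  distance ≥ 2.4 Å.  Clashed poses translate the ligand rigidly along a
  random direction until the minimum contact drops below 1.5 Å; directions
  that fail to reach the wall within 4 Å (threading a gap) are redrawn, so
  clashes stay docking-like rather than grossly displaced.  The two classes
  are disjoint by construction.  RMSD-controlled decoys apply a rigid
  rotation+translation whose magnitude is tuned by bisection to within 5% of
  the target (0.05 Å absolute for small targets); good poses sample targets
  in (0.5, 1.9) Å and bad poses in (4.3, 6.0) Å so that achieved RMSDs
  respect the ≤2 / ≥4 Å class definitions with the 2–4 Å band excluded as
  ambiguous.
- A synthetic pKd-like affinity label (fraction of ligand atoms with a
  complementary partner in contact range, mapped onto 2–12) supports the
  regression head.

All randomness flows from explicit integer seeds through numpy generators.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real protein geometry (secondary structure,
side-chain rotamers, covalent residue topology), chemically valid ligands,
water-mediated interactions, induced fit, and the property co-occurrence
statistics of real binding sites.  Results on this synthetic family
demonstrate that the pipeline's machinery (featurization → training →
attribution → reciprocity statistics) behaves as designed, not that any
particular real-world scorer has learned chemistry.

## Study protocol and problem sizes

The bundled analyses run at sizes chosen to complete in minutes on one CPU:
clash detector and pose classifier each train on 1000 grids (500 complexes
with one variant each, 80/20 split); the reciprocity study attributes 100
fresh clashed complexes with 100-step IG.  At these sizes the clash detector
reaches ≥0.97 held-out accuracy at ≥0.98 precision, the pose classifier
≥0.94 accuracy at ≥0.83 precision, the median protein/ligand occupancy
top-voxel distance is ≤3 Å (with a large mass exactly at 0), and the
Mann–Whitney p against the random baseline is far below 10⁻⁴ — the numbers
printed by `scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Argmax ties (top voxels, top atoms) break toward the lowest linear/atom
  index; determinism beats arbitrariness.
- A channel that is identically zero makes a pair distance undefined; the
  complex is excluded from that pair's distribution and logged, never
  silently zeroed.  Likewise a baseline channel with no voxel above 0.75.
- Precision with no positive predictions is reported as None, not 0.
- Cube files store lengths in Bohr (1 Å = 1.8897259886 Bohr), values in the
  standard z-fastest order, 7 significant digits (round-trips to ≥6).
- The kernel's r→0 limit is evaluated as exactly 1.
- Training aborts with a configuration echo if the loss becomes non-finite,
  and refuses single-class classification labels.

## Known limitations

- The numpy network is CPU-sized (two conv blocks, ~230k parameters); it is
  not a reproduction of any published scorer's architecture or capacity.
- Protein typing is template-based and will under-flag non-standard residues;
  unknown elements receive only the occupancy property (with a warning).
- Multi-model PDBs use the first model and first altloc; mmCIF is not
  supported; inputs are assumed protonated (no preparation is performed).
- Decoys are rigid-body only: no conformer generation, docking, or
  minimization.
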