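# Methods

## Coarse-grained representation

Every structure is reduced to one node per residue: the Cα atom for amino
acids and the phosphate P for nucleotides. All descriptors use uniform node
weights — with one node per residue, the residue-level "center of mass" is
the unweighted centroid, and mass-weighting is deliberately not offered.
Centroids, the radius of gyration

    Rg² = (1/N) Σ_k |R_k − R_com|²,

and inter-domain centroid distances are computed over the nodes actually
present; when a domain table names residues missing from a structure (e.g.
unresolved in a crystal), the domain silently shrinks and the resolution
report lists the missing residues. Residue numbering always follows the
source PDB (1-based, ranges inclusive), so domain definitions transfer
between conformers by residue identity, not by array index.

Superposition is Kabsch via SVD with the reflection corrected through the
sign of the determinant (the singular vector of the smallest singular value
is flipped). Node sets with fewer than three pairs or a near-collinear
configuration (second singular value ≤ 1e-9 of the first) are rejected: a
collinear set leaves one rotational degree of freedom undetermined.

Formal charges for counter-ion bookkeeping use a fixed table (Asp/Glu −1,
Lys/Arg +1, His 0) with protonation variants mapped onto their parents and
HIP/HSP = +1; N- and C-terminal charges cancel per chain; unknown residue
names count as neutral and are reported.

## Trajectory descriptors

RMSD profiles align every frame on the first retained frame (whole-molecule
or single-domain alignment) before measuring; an equilibration burn-in is
expressed in frames, with a converter from time given the recording
interval. Domain-wise RMSF aligns the frames on each domain alone so
inter-domain rearrangements cancel; the reference is the post-alignment
mean conformation refined once (align to frame 0 → average → re-align to
the mean → re-average). One refinement pass keeps the estimate
deterministic; further iterations change the result by far less than the
statistical noise of any realistic frame count. Histograms use a fixed bin
width (0.5 Å by default) rather than a fixed bin count so that
distributions from runs of different lengths remain directly comparable,
and are normalized to integrate to 1.

## Elastic network model

The anisotropic network Hessian uses a 13 Å cutoff and a uniform spring
constant γ = 1. Eigenvalues are therefore in relative units, which is all
the correlation and overlap analyses need — both are scale-free. For a
contacting pair the off-diagonal 3×3 superblock is −γ (d dᵀ)/|d|², diagonal
superblocks are negated row sums, so uniform translations cost exactly zero
energy. Mixed amino-acid/nucleotide networks use the same cutoff and γ for
every pair; the node kinds differ only in atom placement.

Slow modes: the n+6 smallest eigenpairs are computed (dense solver below
900 degrees of freedom, otherwise shift-invert Lanczos about σ = −1e-6,
where H − σI is positive definite so the factorization is safe). Zero modes
are those with |λ| below 1e-8 × the largest computed eigenvalue; a
connected network must produce exactly six, and any other count raises a
diagnostics error rather than silently continuing — a seventh near-zero
mode means the structure contains a genuine mechanism (see the generator
notes below). Disconnected networks are rejected with their component
sizes, which is the usual symptom of a too-small cutoff.

Cross-correlation maps follow the per-mode normalized dot product of node
displacement vectors; the multi-mode map weights per-mode maps by 1/λ_k and
normalizes by Σ 1/λ_k, implemented literally so the slowest modes dominate.
With a single mode the weighted map reduces exactly to the per-mode map.
Nodes with zero displacement norm in a mode get correlation 0 with a
warning.

Dynamic domains are read off the correlation map by correlation clustering:
agglomerative average linkage on the dissimilarity (1 − C)/2, cutting to k
groups. This is deterministic, permutation-equivariant, does not enforce
sequence contiguity (the core domain is genuinely non-contiguous), and
recovers precisely the block structure a reader would mark by eye. The
automatic choice between 2 and 3 groups picks the larger mean silhouette
score on the same dissimilarity.

Mode-directed deformation rescales the raw combination Σ c_k v_k so that
the root-mean-square node displacement equals the requested deformation
RMSD; zero modes can never leak in because a ModeSet contains only nonzero
eigenpairs.

## Docking and classification

A conformer is docked by Kabsch-superposing its binding-domain nodes onto
the anchor fragment, pairing nodes by residue-number intersection; the
transform is applied to the whole conformer and the merged complex is
screened with a k-d tree (exactly equivalent to the quadratic double loop).
Numerical choices, all configurable:

- clash threshold 4.0 Å between coarse-grained nodes (≈ heavy-atom
  van-der-Waals contact at Cα resolution);
- binding-domain contacts are never counted as clashes — that interface is
  the construction;
- "minor" head-domain clash: at most 5 clashing pairs;
- "close contact": clash-free head domain within 6 Å of the surface.

Classification is monotone by construction: any Arm2 clash dominates, then
head-domain clash count, then head proximity. Clashes in other regions do
not change the label (the label vocabulary describes head and Arm2
positioning), so adding clash pairs can never move a complex toward
`Extended`.

## Iterative conformer generation

Defaults follow the standard recipe: five slowest modes, 2 Å deformation
RMSD, 2 Å leader-clustering cutoff, two generations. The coefficient scheme
enumerates all sign/selection vectors in {−1, 0, +1}⁵ minus the zero vector
(242 children per parent), rescaled to the deformation RMSD — deterministic
and unbiased over mode directions; a seeded sampled-coefficient mode
(uniform directions on the 4-sphere) is available for cost control. Modes
are recomputed per parent, not per child. Children are pooled with their
parent before leader clustering so "the cluster containing the initial
structure" is identified exactly, then discarded; the leader (first member)
of each surviving cluster is relaxed and promoted. Clustering order is the
enumeration order, which makes the whole procedure bit-reproducible for a
fixed seed.

The relaxation backend is pluggable behind a small contract — no non-bonded
pair below the 3.0 Å hard core, virtual bonds within ±15 % of 3.8 Å, and at
most 1.5 Å RMSD of movement — checkable after every call; a child whose
relaxation violates the contract is discarded with a log entry. The default
backend is a deterministic steepest descent on a soft-sphere repulsion plus
virtual-bond springs, with stiff tethers restraining frozen (surface) node
sets; the final structure is capped at the 1.5 Å contract limit so
relaxation stays a local polish of the deformed geometry. Consequently
child–parent RMSD after relaxation lies in [drms − 1.5, drms + 1.5].

Overlap scoring superposes each conformer onto the root and takes the
absolute cosine between the resulting displacement vector and each root
mode; the report records the per-conformer maximum over the five slowest
modes and the count below a 0.7 threshold (conformations beyond the reach
of the initial modes alone).

## Synthetic generators: what they emulate, and why they look the way they do

The chain generator produces a ~400-residue three-domain bead chain
(defaults 110/126/97, mirroring the binding/core/head proportions) with
exact 3.8 Å virtual bonds, a 3.0 Å non-bonded clearance, compact
self-avoiding-walk domain blobs and short inter-domain bridges. Two
architectural features are not decoration but mechanical necessities,
discovered by measuring the slow modes of simpler candidates:

- **Re-entrant chain topology.** The chain runs binding → core → head →
  core → binding, so the core is non-contiguous in sequence (as in the real
  protein) and *every* hinge consists of two chain crossings. With a single
  thin crossing, a central-force network leaves near-free "gear" librations
  — a domain rotating about its own centroid rolls on its contact without
  first-order spring strain — and such modes carry essentially zero block
  structure in a correlation map. Two separated crossings pin a unique soft
  hinge axis.
- **Bent architecture.** Domain spheres sit on a V/U-shaped path (100°
  turns); for the two-domain toy the two arms hang from a common apex like
  tweezers (35° opening). Two collinear domains can only seesaw (a
  near-rigid-body rotation) or stretch (the stiffest relative motion), so
  their slowest internal mode is never anti-correlated translation; nearly
  parallel arms opening and closing about an apex move anti-parallel, which
  is what produces off-diagonal correlation blocks below −0.8.

Blob packing is dense enough (radius 2.2 n^⅓ + 1.5 Å) that the two chain
segments sharing the core sphere interdigitate into one rigid body; looser
packing lets them phase-separate into weakly coupled lobes with their own
spurious slow modes.

Pseudo-trajectories rigidly swing each non-core domain about the centroid
of its flanking linker beads with sinusoidal angles (anti-phase between
domains), scaled so the peak centroid displacement equals the requested
amplitude in Å, plus i.i.d. Gaussian node noise; an optional two-state
mixture folds the head by 60° in a fraction of frames to produce bimodal
descriptor histograms. Frames are descriptor fodder with known statistical
structure, not physical dynamics: linker geometry is not re-idealised per
frame, there are no solvent or force-field effects, and passing descriptor
tests therefore validates the estimators (alignment, averaging,
normalization, recovery of planted parameters), not any claim about real
trajectories.

The toy surface is a spherical-cap bead lattice (Fibonacci points, ~5 Å
spacing, 60 Å sphere radius) in two concentric layers 6 Å apart — a single
thin shell is bending-floppy and would contribute spurious slow modes to a
docked complex, whereas the cross-linked sandwich behaves like the rigid
body the large subunit effectively is at this resolution. The pole marks
the exit site and carries a single amino-acid reference node (chain L,
residue 102) for tunnel-distance descriptors. The anchor fragment is the
binding domain of the seed-matched chain posed tangentially so the full
chain extends radially outward; docking the unmodified chain therefore
reproduces an extended, clash-free pose, and a constructed semi-collapsed
conformer (body tilted about the binding-domain hinge until the head meets
the surface) reproduces a head-domain clash.

## Problem sizes

The validation suite and the acceptance script run entirely on synthetic
systems sized for interactive use: 376-node chains, ~780-node surface
layers (~1,150-node complexes), 2,000-frame noise-recovery trajectories,
and two ClustENM generations over a 132-node two-domain toy (242
enumerated children per parent). These sizes are far past the regime where
the estimators' asymptotics matter while keeping the full suite in the
low minutes on one core.

## Known limitations

- Eigenvalues (and hence mode "frequencies") are in relative units; only
  eigenvalue ratios and mode shapes are meaningful.
- The default relaxation backend polishes geometry (sterics and bond
  lengths); it is not an energy model, so conformer counts per generation
  are backend-dependent and only the procedure's contracts (cutoffs,
  reproducibility, bounds) are asserted.
- The correlation-clustering domain extractor targets 2–3 blocks in auto
  mode, matching the systems studied; richer decompositions require
  passing an explicit group count.
- PDB I/O is single-character chain IDs and standard ATOM records;
  mmCIF is out of scope.
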