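# tfdyn

Coarse-grained conformational dynamics of the bacterial chaperone trigger
factor (TF) and its complex with the large ribosomal subunit (50S), as a
tested, reusable pipeline.

TF is a ~432-residue, three-domain chaperone — ribosome-binding domain (BD,
residues 1–110), head domain with PPIase activity (HD, 150–246) and a
non-contiguous C-terminal core (CD, 111–149 and 247–432) carrying two
protruding arms (Arm1 304–346, Arm2 358–410) — that docks at the polypeptide
exit tunnel of the 50S subunit and cradles nascent chains as they emerge.
Its function hinges, literally, on large-scale inter-domain motions: opening
and closing of HD and BD relative to the core, and lateral sweeping of HD
over the ribosome surface. `tfdyn` implements the computational toolbox used
to characterise those motions:

- **Trajectory descriptors** — overall and domain-wise RMSD profiles,
  per-residue RMSF about the domain-aligned mean, radius-of-gyration and
  inter-domain distance series with fixed-width normalized histograms, and
  selection of representative conformers from a 2-D descriptor plane.
- **Elastic network model (ANM)** — one node per residue (Cα for amino
  acids, P for nucleotides), uniform springs within a 13 Å cutoff. Slow
  (global) modes come from the sparse Hessian eigenproblem; residue
  cross-correlations per mode
  `C_ij(k) = ΔR_i(k)·ΔR_j(k) / (|ΔR_i(k)||ΔR_j(k)|)` and their
  eigenvalue-weighted average `⟨C_ij⟩ = Σ_k C_ij(k)/λ_k / Σ_k 1/λ_k` expose
  the dynamic-domain decomposition, which is extracted by correlation
  clustering.
- **Docking by alignment** — a full-length conformer is placed on the 50S
  (or a toy surface) by Kabsch-superposing its binding domain onto an anchor
  fragment pre-positioned on the surface, then screened for steric clashes
  and classified (`Extended` → `Extended/HD close contact` → `HD minor
  clash` → `HD clash` → `Arm2 clash`).
- **ClustENM-style conformer generation** — iteratively deform along linear
  combinations of the five slowest modes at 2 Å deformation RMSD, leader-
  cluster at 2 Å RMSD, relax one representative per cluster, repeat for two
  generations; score each conformer by the overlap
  `|u_mode · v_conf| / (|u_mode||v_conf|)` with the root's slow modes.
- **Synthetic data** — seeded generators for multi-domain bead chains with
  hinge-dominated slow modes, pseudo-trajectories with known statistical
  structure, and an anchored toy surface, so the entire pipeline runs and is
  validated without any downloads.

## Worked example

```python
import numpy as np
from tfdyn import (ToySpec, make_hinge_structure, make_anchored_surface,
                   build_enm, slow_modes, cross_correlation, dynamic_domains,
                   dock_by_alignment)

spec = ToySpec(seed=1)                      # 110/126/97-residue chain
chain, domains = make_hinge_structure(spec)
modes = slow_modes(build_enm(chain, cutoff=13.0), n=10)
cmap = cross_correlation(modes, "weighted")
labels = dynamic_domains(cmap)
print(f"chain: {chain.n_nodes} residues, slowest eigenvalue {modes.eigenvalues[0]:.2e}")
print(f"dynamic domains (apo): {len(np.unique(labels))}")

anchored = make_anchored_surface(spec)
complex_model = dock_by_alignment(chain, anchored, domains)
d = complex_model.descriptors
print(f"docked pose: {complex_model.label!r}, "
      f"alignment RMSD {complex_model.alignment_rmsd:.2f} A")
print(f"Rg = {d['rg']:.1f} A, BD-Arm2 = {d['bd_arm2']:.1f} A, "
      f"HD-Arm1 = {d['hd_arm1']:.1f} A")
```

prints

```
chain: 376 residues, slowest eigenvalue 1.24e-05
dynamic domains (apo): 3
docked pose: 'Extended', alignment RMSD 0.00 A
Rg = 35.8 A, BD-Arm2 = 59.6 A, HD-Arm1 = 52.3 A
```

The free chain decomposes into its three dynamic domains (binding, core,
head), exactly as built by the generator. Docking the unmodified extended
chain onto the anchored surface reproduces the anchor pose (alignment
RMSD 0) without a single steric clash — the extended state is the
ribosome-compatible one — and the descriptor record (radius of gyration,
BD–Arm2 and HD–Arm1 centroid distances) characterises how open the docked
conformer is. Folding the head toward the binding side before docking
instead yields an `HD clash` label: compact, semi-collapsed states are
sterically incompatible with the surface.

The same stages are available from the shell:

```sh
tfdyn synth --seed 1 --out run/
tfdyn enm   --structure run/chain.pdb --out run/
tfdyn dock  --conformer run/chain.pdb --surface run/surface.pdb \
            --anchor run/anchor.pdb --domains run/domains.txt --out run/
tfdyn clustenm --structure run/chain.pdb --generations 2 --seed 1 --out run/
```

Each stage writes its outputs plus a JSON manifest (input hashes,
parameters, seed), so identical config + seed reproduces identical results.

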