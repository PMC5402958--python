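"""Iterative mode-directed conformer generation (ClustENM-style).

Each generation: recompute the elastic network of every parent, deform the
parent along linear combinations of its five slowest modes at a fixed
deformation RMSD, pool the children with the parent, leader-cluster the pool
by aligned RMSD, drop the cluster containing the parent, relax one
representative per surviving cluster, and promote the relaxed
representatives to parents of the next generation.  Two generations with a
2 Angstrom deformation and a 2 Angstrom cluster cutoff are the defaults.

Conformers are scored against the root's slow modes by the *overlap*

    overlap = | u_mode . v_conf | / (|u_mode| |v_conf|),

the absolute cosine between a mode vector and the superposed displacement
from the root to the conformer; 1 means the motion lies fully along the
mode, 0 means it is orthogonal to it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .enm import ModeSet, build_enm, deform_along, slow_modes
from .errors import UndefinedOverlapError
from .structures import Structure, coord_rmsd, kabsch, pairwise_rmsd

logger = logging.getLogger(__name__)

HARD_CORE_RADIUS = 3.0       # Angstrom; minimum non-bonded node separation
VIRTUAL_BOND_LENGTH = 3.8    # Angstrom; ideal CA-CA distance
BOND_TOLERANCE = 0.15        # fractional deviation allowed on virtual bonds
MAX_RELAX_SHIFT = 1.5        # Angstrom; max RMSD a relaxation may move


@dataclass
class ClustENMParams:
    """Generation-procedure parameters (defaults follow the standard recipe)."""

    n_modes: int = 5
    drms: float = 2.0            # deformation RMSD per child, Angstrom
    cluster_cutoff: float = 2.0  # leader-clustering RMSD cutoff, Angstrom
    generations: int = 2
    cutoff: float = 13.0         # elastic network cutoff, Angstrom
    coefficient_mode: str = "enumerate"   # "enumerate" | "sample"
    n_samples: int = 60          # children per parent in "sample" mode


@dataclass
class Conformer:
    """One node of a generation tree."""

    id: int
    generation: int
    parent_id: int | None
    structure: Structure
    cluster_id: int
    relaxed: bool
    rmsd_to_parent: float


@dataclass
class GenerationTree:
    """Root conformer plus per-generation relaxed representatives."""

    root: Structure
    params: ClustENMParams
    seed: int
    generations: list[list[Conformer]] = field(default_factory=list)

    def all_conformers(self) -> list[Conformer]:
        return [c for gen in self.generations for c in gen]

    @property
    def n_conformers(self) -> int:
        return sum(len(g) for g in self.generations)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "params": vars(self.params),
            "n_generations": len(self.generations),
            "n_conformers": self.n_conformers,
            "conformers": [
                {"id": c.id, "generation": c.generation,
                 "parent": c.parent_id, "cluster": c.cluster_id,
                 "rmsd_to_parent": round(c.rmsd_to_parent, 6)}
                for c in self.all_conformers()
            ],
        }


# ---------------------------------------------------------------------------
# Relaxation backend
# ---------------------------------------------------------------------------

def bonded_pairs(structure: Structure) -> np.ndarray:
    """Chain-neighbour node pairs (consecutive residue numbers, same chain)."""
    pairs = []
    for i in range(structure.n_nodes - 1):
        if (structure.chain_id[i] == structure.chain_id[i + 1]
                and structure.residue_number[i + 1] == structure.residue_number[i] + 1):
            pairs.append((i, i + 1))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def check_relaxation_contract(relaxed: Structure, original: Structure,
                              frozen: np.ndarray | None = None,
                              hard_core: float = HARD_CORE_RADIUS,
                              bond_length: float = VIRTUAL_BOND_LENGTH,
                              bond_tol: float = BOND_TOLERANCE,
                              max_shift: float = MAX_RELAX_SHIFT) -> list[str]:
    """Violations of the relaxation contract (empty list = compliant).

    The contract: no non-bonded pair closer than the hard-core radius,
    chain-neighbour distances within +-15% of the ideal virtual-bond length,
    and an (unaligned) RMSD to the input of at most 1.5 Angstrom.  Frozen
    (surface) nodes are exempt from the internal-geometry checks.
    """
    problems: list[str] = []
    mobile = np.ones(relaxed.n_nodes, dtype=bool)
    if frozen is not None and len(frozen):
        mobile[np.asarray(frozen, dtype=int)] = False
    bonds = bonded_pairs(relaxed)
    bond_set = {tuple(p) for p in bonds.tolist()}
    if bonds.size:
        keep = mobile[bonds[:, 0]] | mobile[bonds[:, 1]]
        blen = np.linalg.norm(relaxed.coords[bonds[keep, 0]]
                              - relaxed.coords[bonds[keep, 1]], axis=1)
        bad = np.abs(blen - bond_length) > bond_tol * bond_length
        if bad.any():
            problems.append(f"{int(bad.sum())} virtual bonds outside "
                            f"+-{bond_tol:.0%} of {bond_length} A")
    tree = cKDTree(relaxed.coords)
    for i, j in tree.query_pairs(hard_core):
        if (i, j) in bond_set or (j, i) in bond_set:
            continue
        if not (mobile[i] or mobile[j]):
            continue
        problems.append(f"hard-core violation: nodes {i},{j}")
        break
    shift = coord_rmsd(relaxed.coords, original.coords)
    if shift > max_shift + 1e-9:
        problems.append(f"relaxation moved {shift:.3f} A > {max_shift} A")
    return problems


class SoftSphereBackend:
    """Coarse-grained steepest-descent relaxation.

    Pseudo-potential: harmonic virtual-bond springs at 3.8 Angstrom plus a
    soft-sphere repulsion below the hard-core radius.  Frozen node sets
    (e.g. a large rigid surface) are restrained by stiff tethers to their
    input positions.  The final structure is capped to move at most 1.5
    Angstrom RMSD from the input, which keeps relaxation a local polish of
    the deformed geometry rather than a re-fold.

    Deterministic: no randomness is used.
    """

    def __init__(self, k_bond: float = 10.0, k_repulse: float = 10.0,
                 k_tether: float = 100.0, step: float = 0.01,
                 max_iter: int = 300,
                 hard_core: float = HARD_CORE_RADIUS,
                 bond_length: float = VIRTUAL_BOND_LENGTH):
        self.k_bond = k_bond
        self.k_repulse = k_repulse
        self.k_tether = k_tether
        self.step = step
        self.max_iter = max_iter
        self.hard_core = hard_core
        self.bond_length = bond_length

    def _forces(self, coords: np.ndarray, bonds: np.ndarray,
                ref: np.ndarray, frozen_mask: np.ndarray,
                bond_set: set) -> np.ndarray:
        f = np.zeros_like(coords)
        if bonds.size:
            d = coords[bonds[:, 1]] - coords[bonds[:, 0]]
            r = np.linalg.norm(d, axis=1)
            unit = d / r[:, None]
            pull = self.k_bond * (r - self.bond_length)
            np.add.at(f, bonds[:, 0], pull[:, None] * unit)
            np.add.at(f, bonds[:, 1], -pull[:, None] * unit)
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(self.hard_core):
            if (i, j) in bond_set:
                continue
            d = coords[j] - coords[i]
            r = float(np.linalg.norm(d))
            if r < 1e-9:
                continue
            push = self.k_repulse * (self.hard_core - r) * d / r
            f[i] -= push
            f[j] += push
        # stiff tethers hold frozen nodes at their reference positions
        f[frozen_mask] += self.k_tether * (ref[frozen_mask] - coords[frozen_mask])
        return f

    def relax(self, structure: Structure,
              frozen: np.ndarray | None = None) -> Structure:
        coords = structure.coords.copy()
        ref = structure.coords
        bonds = bonded_pairs(structure)
        bond_set = {tuple(sorted(p)) for p in bonds.tolist()}
        frozen_mask = np.zeros(structure.n_nodes, dtype=bool)
        if frozen is not None and len(frozen):
            frozen_mask[np.asarray(frozen, dtype=int)] = True
        for _ in range(self.max_iter):
            f = self._forces(coords, bonds, ref, frozen_mask, bond_set)
            fmax = np.max(np.linalg.norm(f, axis=1))
            if fmax < 1e-3:
                break
            coords = coords + min(self.step, 0.3 / fmax) * f
        # cap the total move at the contract limit
        shift = coord_rmsd(coords, ref)
        if shift > MAX_RELAX_SHIFT:
            coords = ref + (coords - ref) * (MAX_RELAX_SHIFT / shift) * 0.999
        return structure.with_coords(coords)


# ---------------------------------------------------------------------------
# Clustering and generation
# ---------------------------------------------------------------------------

def leader_cluster(conformers: Sequence[Structure], cutoff: float,
                   align: bool = True) -> np.ndarray:
    """Leader clustering in input order.

    The first conformer founds cluster 0; each subsequent conformer joins
    the first existing leader within *cutoff* RMSD (aligned by default),
    else founds a new cluster.  Every member is therefore within cutoff of
    its leader, and the assignment is deterministic in input order.
    """
    labels = np.full(len(conformers), -1, dtype=int)
    leaders: list[int] = []
    for i, conf in enumerate(conformers):
        for c, leader_idx in enumerate(leaders):
            if pairwise_rmsd(conformers[leader_idx], conf, align=align) <= cutoff:
                labels[i] = c
                break
        else:
            leaders.append(i)
            labels[i] = len(leaders) - 1
    return labels


def _coefficient_vectors(params: ClustENMParams,
                         rng: np.random.Generator) -> np.ndarray:
    if params.coefficient_mode == "enumerate":
        grid = np.array([c for c in itertools.product((-1, 0, 1),
                                                      repeat=params.n_modes)
                         if any(c)], dtype=float)
        return grid
    if params.coefficient_mode == "sample":
        v = rng.standard_normal((params.n_samples, params.n_modes))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    raise ValueError(f"unknown coefficient mode {params.coefficient_mode!r}")


def generate(root: Structure, params: ClustENMParams | None = None,
             backend: SoftSphereBackend | None = None, seed: int = 0,
             frozen: np.ndarray | None = None) -> GenerationTree:
    """Run the iterative deform / cluster / relax procedure.

    Per generation, modes are recomputed for every parent; the cluster
    containing the parent itself is discarded (the parent is prepended to
    the pool, so its cluster is the one holding index 0 of that pool); one
    representative (the leader) of each surviving cluster is relaxed and
    promoted.  A child whose relaxation violates the backend contract is
    discarded with a log entry.  With a fixed seed the run is
    bit-reproducible.
    """
    params = params or ClustENMParams()
    backend = backend or SoftSphereBackend()
    rng = np.random.default_rng(seed)
    tree = GenerationTree(root=root, params=params, seed=seed)
    parents: list[tuple[int, Structure]] = [(-1, root)]
    next_id = 0
    for gen in range(params.generations):
        new_reps: list[Conformer] = []
        for parent_id, parent in parents:
            modes = slow_modes(build_enm(parent, cutoff=params.cutoff),
                               n=params.n_modes)
            coeffs = _coefficient_vectors(params, rng)
            children = [deform_along(modes, c, params.drms) for c in coeffs]
            pool = [parent] + children
            labels = leader_cluster(pool, params.cluster_cutoff)
            parent_cluster = labels[0]
            for cluster in np.unique(labels):
                if cluster == parent_cluster:
                    continue
                leader_idx = int(np.flatnonzero(labels == cluster)[0])
                rep = pool[leader_idx]
                relaxed = backend.relax(rep, frozen=frozen)
                problems = check_relaxation_contract(relaxed, rep, frozen=frozen)
                if problems:
                    logger.warning("generation %d: discarding child of parent "
                                   "%d: %s", gen, parent_id, "; ".join(problems))
                    continue
                new_reps.append(Conformer(
                    id=next_id, generation=gen, parent_id=parent_id,
                    structure=relaxed, cluster_id=int(cluster), relaxed=True,
                    rmsd_to_parent=pairwise_rmsd(relaxed, parent, align=False)))
                next_id += 1
        tree.generations.append(new_reps)
        if not new_reps:
            logger.warning("generation %d produced no conformers; stopping", gen)
            break
        parents = [(c.id, c.structure) for c in new_reps]
    return tree


# ---------------------------------------------------------------------------
# Overlap scoring
# ---------------------------------------------------------------------------

def overlap(mode_vector: np.ndarray, displacement: np.ndarray) -> float:
    """Absolute cosine similarity between a mode and a displacement vector."""
    u = np.asarray(mode_vector, dtype=float).ravel()
    v = np.asarray(displacement, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedOverlapError("overlap undefined for zero-norm vector")
    return float(abs(u @ v) / (nu * nv))


def max_overlap_report(modes: ModeSet, tree: GenerationTree,
                       threshold: float = 0.7):
    """Per-conformer maximum overlap with the root's slow modes.

    Each conformer is first superposed onto the root; the displacement
    root -> conformer is then compared against each root mode and the
    maximum absolute cosine is reported, along with a count of conformers
    below *threshold* (conformations beyond the reach of the initial modes
    alone).

    Returns ``(DataFrame, summary_dict)``.
    """
    import pandas as pd

    root = tree.root
    rows = []
    for conf in tree.all_conformers():
        t = kabsch(conf.structure.coords, root.coords)
        v = (t.apply(conf.structure.coords) - root.coords).ravel()
        per_mode = [overlap(modes.eigenvectors[:, k], v)
                    for k in range(modes.n_modes)]
        rows.append({"conformer": conf.id, "generation": conf.generation,
                     "max_overlap": max(per_mode),
                     "best_mode": int(np.argmax(per_mode))})
    df = pd.DataFrame(rows)
    summary = {
        "n_conformers": len(df),
        "min": float(df["max_overlap"].min()) if len(df) else np.nan,
        "max": float(df["max_overlap"].max()) if len(df) else np.nan,
        "n_below_threshold": int((df["max_overlap"] < threshold).sum()) if len(df) else 0,
        "threshold": threshold,
    }
    return df, summary
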