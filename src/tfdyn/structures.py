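"""Coarse-grained structure representation, PDB I/O and rigid-body geometry.

A :class:`Structure` holds one node per residue: the C-alpha atom for amino
acids and the phosphate atom for nucleotides.  All geometric descriptors used
downstream (radius of gyration, inter-domain centroid distances, RMSD after
Kabsch superposition) operate on these nodes with uniform weights — with one
node per residue a uniform weight is the natural reading of a residue-level
"center of mass".

Distances are in Angstrom throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateAlignmentError,
    DomainLookupError,
    EmptyStructureError,
    TopologyError,
)

logger = logging.getLogger(__name__)

AMINO = "amino-acid"
NUCLEOTIDE = "nucleotide"

#: Formal side-chain charge at pH 7.  Protonation variants map onto the
#: behaviour of their parent residue, except HIP which is explicitly +1.
FORMAL_CHARGE: Mapping[str, int] = {
    "ASP": -1, "GLU": -1, "ASH": -1, "GLH": -1,
    "LYS": +1, "ARG": +1,
    "HIS": 0, "HID": 0, "HIE": 0, "HSD": 0, "HSE": 0,
    "HIP": +1, "HSP": +1,
}

_NEUTRAL = {
    "ALA", "ASN", "CYS", "GLN", "GLY", "ILE", "LEU", "MET", "PHE",
    "PRO", "SER", "THR", "TRP", "TYR", "VAL", "CYX", "CYM", "LYN",
}


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """One-node-per-residue coarse-grained structure.

    Parameters
    ----------
    coords
        (N, 3) float array of node positions in Angstrom.
    node_kind
        (N,) array of ``"amino-acid"`` or ``"nucleotide"`` tags.
    chain_id, residue_number, residue_name
        Per-node metadata copied from the source PDB (residue numbers are
        1-based as in the file).
    """

    coords: np.ndarray
    node_kind: np.ndarray
    chain_id: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.node_kind = np.asarray(self.node_kind, dtype="U12")
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype="U4")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyStructureError("structure must contain at least one node")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[0]
        for name, arr in (("node_kind", self.node_kind),
                          ("chain_id", self.chain_id),
                          ("residue_number", self.residue_number),
                          ("residue_name", self.residue_name)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        keys = list(zip(self.chain_id.tolist(), self.residue_number.tolist()))
        if len(set(keys)) != n:
            raise ValueError("(chain_id, residue_number) pairs must be unique")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure":
        return Structure(self.coords.copy(), self.node_kind.copy(),
                         self.chain_id.copy(), self.residue_number.copy(),
                         self.residue_name.copy())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology, new coordinates."""
        return Structure(np.asarray(coords, dtype=float), self.node_kind,
                         self.chain_id, self.residue_number, self.residue_name)

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(self.coords[idx], self.node_kind[idx],
                         self.chain_id[idx], self.residue_number[idx],
                         self.residue_name[idx])

    def index_of(self, chain: str, residue: int) -> int:
        hits = np.flatnonzero((self.chain_id == chain)
                              & (self.residue_number == residue))
        if hits.size == 0:
            raise DomainLookupError(f"residue {chain}:{residue} not in structure")
        return int(hits[0])

    def node_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chain_id.tolist(), self.residue_number.tolist()))

    def same_topology(self, other: "Structure") -> bool:
        return (self.n_nodes == other.n_nodes
                and bool(np.all(self.chain_id == other.chain_id))
                and bool(np.all(self.residue_number == other.residue_number)))


def concatenate(structures: Sequence[Structure]) -> Structure:
    """Merge structures into one; (chain, residue) keys must stay unique."""
    return Structure(
        np.concatenate([s.coords for s in structures]),
        np.concatenate([s.node_kind for s in structures]),
        np.concatenate([s.chain_id for s in structures]),
        np.concatenate([s.residue_number for s in structures]),
        np.concatenate([s.residue_name for s in structures]),
    )


@dataclass
class DomainMap:
    """Named residue-range sets, inclusive on both ends.

    A name maps to a list of ``(chain_id, start, end)`` entries; sets may be
    non-contiguous (the chaperone core domain is two ranges) and may overlap
    (the arms are sub-ranges of the core).
    """

    ranges: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def names(self) -> list[str]:
        return list(self.ranges)

    def add(self, name: str, chain: str, start: int, end: int) -> None:
        if end < start:
            raise ValueError(f"range end {end} < start {start} for {name!r}")
        self.ranges.setdefault(name, []).append((chain, int(start), int(end)))

    def resolve(self, structure: Structure, name: str,
                report_missing: bool = True) -> np.ndarray:
        """Node indices of *name* in *structure*, in structure order.

        Residues named by the map but absent from the structure (e.g. not
        resolved in the crystal) silently shrink the domain; they are logged
        so the shrinkage is visible.
        """
        if name not in self.ranges:
            raise DomainLookupError(f"unknown domain name {name!r}")
        mask = np.zeros(structure.n_nodes, dtype=bool)
        missing: list[tuple[str, int]] = []
        for chain, start, end in self.ranges[name]:
            sel = ((structure.chain_id == chain)
                   & (structure.residue_number >= start)
                   & (structure.residue_number <= end))
            mask |= sel
            if report_missing:
                present = set(structure.residue_number[structure.chain_id == chain].tolist())
                missing.extend((chain, r) for r in range(start, end + 1)
                               if r not in present)
        if missing:
            logger.warning("domain %r: %d residues in map but not in structure",
                           name, len(missing))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise DomainLookupError(f"domain {name!r} resolves to no nodes")
        return idx

    def missing_residues(self, structure: Structure) -> dict[str, list[tuple[str, int]]]:
        """Resolution report: for each name, mapped residues absent from *structure*."""
        out: dict[str, list[tuple[str, int]]] = {}
        for name, entries in self.ranges.items():
            missing = []
            for chain, start, end in entries:
                present = set(structure.residue_number[structure.chain_id == chain].tolist())
                missing.extend((chain, r) for r in range(start, end + 1)
                               if r not in present)
            if missing:
                out[name] = missing
        return out

    def covered_residues(self, names: Iterable[str]) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for name in names:
            for chain, start, end in self.ranges[name]:
                out.update((chain, r) for r in range(start, end + 1))
        return out

    # -- plain-text config format: one "name chain start end" per line -----
    @classmethod
    def from_file(cls, path: str | Path) -> "DomainMap":
        dm = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'name chain start end'")
            dm.add(parts[0], parts[1], int(parts[2]), int(parts[3]))
        return dm

    def to_file(self, path: str | Path) -> None:
        lines = [f"{name} {chain} {start} {end}"
                 for name, entries in self.ranges.items()
                 for chain, start, end in entries]
        Path(path).write_text("\n".join(lines) + "\n")


def tf_domain_map(chain: str = "A") -> DomainMap:
    """Domain boundaries of E. coli trigger factor (432 residues).

    BD is the N-terminal ribosome-binding domain, HD the PPIase head domain,
    and CD the C-terminal core made of two non-contiguous ranges carrying the
    two protruding arms.
    """
    dm = DomainMap()
    dm.add("BD", chain, 1, 110)
    dm.add("CD", chain, 111, 149)
    dm.add("CD", chain, 247, 432)
    dm.add("HD", chain, 150, 246)
    dm.add("Arm1", chain, 304, 346)
    dm.add("Arm2", chain, 358, 410)
    return dm


@dataclass
class Transform:
    """Proper rigid-body transform: ``x -> x @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length-3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.with_coords(self.apply(structure.coords))

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)

    def compose(self, other: "Transform") -> "Transform":
        """Transform equivalent to applying *other* first, then *self*."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

_NUCLEOTIDE_NAMES = {
    "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "I", "DI",
}


def _is_nucleotide(res_name: str) -> bool:
    return res_name.strip() in _NUCLEOTIDE_NAMES


def _atom_array_to_structure(atoms, cg: bool = True) -> Structure:
    """Reduce a biotite AtomArray to one node per residue (CA or P)."""
    import biotite.structure as struc

    names = atoms.res_name
    is_nt = np.array([_is_nucleotide(rn) for rn in names])
    if cg:
        keep = ((~atoms.hetero) & (
            ((atoms.atom_name == "CA") & ~is_nt)
            | ((atoms.atom_name == "P") & is_nt)))
    else:
        keep = ~atoms.hetero
    atoms = atoms[keep]
    is_nt = is_nt[keep]
    if atoms.array_length() == 0:
        raise EmptyStructureError("no coarse-grained nodes retained from PDB")
    # drop duplicate representative atoms per residue (should not happen
    # after altloc resolution, but be safe) and report dropped residues
    seen: set[tuple[str, int]] = set()
    order = []
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        if key not in seen:
            seen.add(key)
            order.append(i)
    atoms = atoms[np.asarray(order, dtype=int)]
    is_nt = is_nt[np.asarray(order, dtype=int)]
    kind = np.where(is_nt, NUCLEOTIDE, AMINO)
    return Structure(atoms.coord.astype(float), kind, atoms.chain_id.astype("U4"),
                     atoms.res_id.astype(int), atoms.res_name.astype("U4"))


def _resolve_altloc(atoms):
    """Keep, per atom site, the highest-occupancy altloc (ties: lexicographic)."""
    import numpy as _np

    altloc = getattr(atoms, "altloc_id", None)
    if altloc is None:
        return atoms
    occ = atoms.occupancy if "occupancy" in atoms.get_annotation_categories() \
        else _np.ones(atoms.array_length())
    best: dict[tuple, int] = {}
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.ins_code[i]), str(atoms.atom_name[i]))
        j = best.get(key)
        if j is None:
            best[key] = i
            continue
        better = (occ[i] > occ[j]
                  or (occ[i] == occ[j] and str(altloc[i]) < str(altloc[j])))
        if better:
            best[key] = i
    idx = _np.asarray(sorted(best.values()), dtype=int)
    return atoms[idx]


def read_pdb(path: str | Path, chain_filter: set[str] | None = None,
             cg: bool = True, model: int = 1) -> Structure:
    """Read one model of a PDB file as a coarse-grained :class:`Structure`.

    Altloc conflicts are resolved to the highest occupancy (ties broken by
    the lexicographically first altloc id); residues lacking the
    representative atom (CA / P) are dropped and logged.
    """
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=model, altloc="all",
                                   extra_fields=["occupancy"])
    atoms = _resolve_altloc(atoms)
    if chain_filter is not None:
        atoms = atoms[np.isin(atoms.chain_id, list(chain_filter))]
    n_res_before = len({(str(c), int(r)) for c, r in
                        zip(atoms.chain_id, atoms.res_id)}) if atoms.array_length() else 0
    structure = _atom_array_to_structure(atoms, cg=cg)
    if cg and structure.n_nodes < n_res_before:
        logger.info("read_pdb: dropped %d residues lacking a CA/P node",
                    n_res_before - structure.n_nodes)
    return structure


def read_pdb_models(path: str | Path, chain_filter: set[str] | None = None,
                    cg: bool = True) -> list[Structure]:
    """Read every MODEL of a (multi-model) PDB file."""
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    return [read_pdb(path, chain_filter=chain_filter, cg=cg, model=m)
            for m in range(1, n_models + 1)]


def _structure_to_atom_array(structure: Structure):
    import biotite.structure as struc

    n = structure.n_nodes
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.chain_id = structure.chain_id
    atoms.res_id = structure.residue_number
    atoms.res_name = structure.residue_name
    is_nt = structure.node_kind == NUCLEOTIDE
    atoms.atom_name = np.where(is_nt, "P", "CA")
    atoms.element = np.where(is_nt, "P", "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def write_pdb(structure: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write a structure (or a sequence of frames as MODEL blocks) to PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile()
    if isinstance(structure, Structure):
        pdb_file.set_structure(_structure_to_atom_array(structure))
    else:
        frames = list(structure)
        if not frames:
            raise EmptyStructureError("no frames to write")
        arrays = [_structure_to_atom_array(s) for s in frames]
        stack = struc.stack(arrays)
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Scalar geometry
# ---------------------------------------------------------------------------

def radius_of_gyration(structure: Structure) -> float:
    """Root-mean-square node distance from the unweighted centroid (Angstrom)."""
    centered = structure.coords - structure.coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def centroid_distance(structure: Structure, domains: DomainMap,
                      a: str, b: str) -> float:
    """Distance between the unweighted node centroids of two named sets."""
    ca = structure.coords[domains.resolve(structure, a, report_missing=False)].mean(axis=0)
    cb = structure.coords[domains.resolve(structure, b, report_missing=False)].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Transform:
    """Least-squares proper rotation + translation mapping mobile onto reference.

    Reflections are corrected by flipping the sign of the singular vector
    belonging to the smallest singular value.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise DegenerateAlignmentError("need >= 3 paired nodes for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc
    # collinearity check: a rank-<2 point set leaves a rotation dof undetermined
    sv = np.linalg.svd(m, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateAlignmentError("paired nodes are (near-)collinear")
    h = m.T @ r
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return Transform(rot, rc - rot @ mc)


def superpose(mobile: Structure, reference: Structure,
              domains: DomainMap | None = None,
              selection: str | None = None) -> tuple[Transform, float]:
    """Kabsch-superpose *mobile* onto *reference* over a named selection.

    Nodes are paired by (chain, residue number) identity within the selection
    (the whole structure when *selection* is None).  Returns the transform and
    the RMSD over the paired nodes after applying it.
    """
    if selection is not None:
        if domains is None:
            raise DomainLookupError("selection given but no DomainMap")
        mob_idx = domains.resolve(mobile, selection, report_missing=False)
        ref_idx = domains.resolve(reference, selection, report_missing=False)
    else:
        mob_idx = np.arange(mobile.n_nodes)
        ref_idx = np.arange(reference.n_nodes)
    mob_keys = {(str(mobile.chain_id[i]), int(mobile.residue_number[i])): i
                for i in mob_idx}
    pairs = [(mob_keys[(str(reference.chain_id[j]), int(reference.residue_number[j]))], j)
             for j in ref_idx
             if (str(reference.chain_id[j]), int(reference.residue_number[j])) in mob_keys]
    if len(pairs) < 3:
        raise DegenerateAlignmentError(
            f"only {len(pairs)} paired nodes in selection {selection!r}")
    mi = np.asarray([p[0] for p in pairs])
    ri = np.asarray([p[1] for p in pairs])
    transform = kabsch(mobile.coords[mi], reference.coords[ri])
    moved = transform.apply(mobile.coords[mi])
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference.coords[ri]) ** 2, axis=1))))
    return transform, rmsd


def coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unaligned) RMSD between two matched coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_rmsd(a: Structure, b: Structure, align: bool = True) -> float:
    """RMSD between two conformers of the same topology.

    With ``align=True`` the optimal superposition is applied first, so the
    value is the metric used for conformer clustering.
    """
    if not a.same_topology(b):
        raise TopologyError("structures do not share a topology")
    if align:
        t = kabsch(a.coords, b.coords)
        return coord_rmsd(t.apply(a.coords), b.coords)
    return coord_rmsd(a.coords, b.coords)


# ---------------------------------------------------------------------------
# Charge bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class IonReport:
    """Counter-ions needed to neutralize the net formal charge at pH 7."""

    count: int
    net_charge: int
    ion: str                     # "Na+" or "Cl-" (or "" when neutral)
    unknown_residues: list[str]

    def __int__(self) -> int:
        return self.count


def neutralizing_ion_count(structure: Structure) -> IonReport:
    """Monovalent counter-ions required to neutralize the amino-acid chain.

    Net formal charge = (#Arg + #Lys) - (#Asp + #Glu) with His neutral;
    N- and C-terminal charges cancel per chain.  Non-standard residue names
    are counted as neutral and listed in the report.
    """
    net = 0
    unknown: list[str] = []
    for kind, name in zip(structure.node_kind, structure.residue_name):
        if kind != AMINO:
            continue
        name = name.strip().upper()
        if name in FORMAL_CHARGE:
            net += FORMAL_CHARGE[name]
        elif name not in _NEUTRAL:
            unknown.append(name)
    if unknown:
        logger.warning("neutralizing_ion_count: %d nodes with non-standard "
                       "residue names counted as neutral: %s",
                       len(unknown), sorted(set(unknown)))
    ion = "" if net == 0 else ("Na+" if net < 0 else "Cl-")
    return IonReport(count=abs(net), net_charge=net, ion=ion,
                     unknown_residues=unknown)
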