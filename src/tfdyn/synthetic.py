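"""Synthetic multi-domain structures, pseudo-trajectories and a toy surface.

Everything the pipeline consumes can be generated here, seeded and in
memory: a ~400-residue three-domain bead chain with flexible linkers whose
slow modes are hinge-dominated (emulating the chaperone's binding / core /
head architecture), pseudo-trajectories with domain-scale anti-correlated
motion plus thermal noise, and a large rigid hemispherical bead surface
carrying a binding-domain-sized anchor fragment for docking tests.

Two architectural features of the real chaperone are reproduced because
they are mechanically essential, not decorative:

* the molecule is bent (V/U-shaped), so no domain can spin freely about a
  common axis through all centroids;
* the core domain is non-contiguous in sequence -- the chain runs
  binding domain -> core -> head -> core -- so the head domain is anchored
  by two chain crossings.  Two crossings define a single soft hinge axis;
  with only one crossing a central-force elastic network leaves near-free
  "gear" rotations of the domain about its own centroid, which carry no
  block structure in a cross-correlation map.

All generators are pure functions of (spec, seed).  Chains use an exact
3.8 Angstrom virtual bond and keep every non-bonded pair at least
3.0 Angstrom apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .docking import AnchorComplex
from .errors import GenerationError
from .structures import AMINO, NUCLEOTIDE, DomainMap, Structure
from .traj import Trajectory

logger = logging.getLogger(__name__)

BOND = 3.8          # Angstrom, virtual CA-CA bond
MIN_SEP = 3.0       # Angstrom, non-bonded clearance
_ZHAT = np.array([0.0, 0.0, 1.0])


@dataclass
class ToySpec:
    """Specification for synthetic chains, trajectories and surfaces.

    The default chain mirrors the proportions of the real chaperone:
    binding (110), core (126, split in sequence around the head) and head
    (97) domains, with two arm sub-ranges labelled inside the core.
    Trajectory fields: frames, inter-domain motion amplitude (Angstrom,
    measured at the moving domain's centroid), per-node Gaussian noise
    sigma (Angstrom) and an optional two-state mixture (fraction of frames
    in a semi-collapsed state, for bimodal descriptor histograms).
    """

    n_domains: int = 3
    domain_sizes: tuple[int, ...] = (110, 126, 97)
    domain_names: tuple[str, ...] = ("BD", "CD", "HD")
    linker_length: int = 8         # beads per inter-domain bridge (nominal)
    bend_angle: float = 100.0      # degrees turned between domain spheres
    apex_angle: float = 35.0       # arm opening of the two-domain tweezer
    arm_fraction: float = 0.3      # of the core tail, labelled Arm1/Arm2
    seed: int = 0
    chain_id: str = "A"
    # trajectory spec
    n_frames: int = 200
    amplitude: float = 5.0         # Angstrom at domain centroid
    noise_sigma: float = 0.3       # Angstrom per node per axis
    oscillation_period: int = 50   # frames
    collapsed_fraction: float = 0.0
    # surface spec
    surface_radius: float = 60.0   # sphere radius, Angstrom
    surface_spacing: float = 5.0   # bead lattice spacing, Angstrom
    cap_height: float = 25.0       # height of the spherical cap, Angstrom

    def __post_init__(self) -> None:
        if self.n_domains < 1 or any(s < 1 for s in self.domain_sizes):
            raise ValueError("counts must be positive")
        if len(self.domain_sizes) != self.n_domains:
            raise ValueError("domain_sizes length must equal n_domains")
        if len(self.domain_names) != self.n_domains:
            raise ValueError("domain_names length must equal n_domains")


def _domain_radius(n: int) -> float:
    # compact random packing of n beads with 3 A clearance; dense enough
    # that chain segments sharing a sphere interdigitate into one rigid body
    return 2.2 * n ** (1 / 3) + 1.5


def _unit(v: np.ndarray, rng=None) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _rot_z(angle: float) -> np.ndarray:
    return _rotation_about(_ZHAT, angle)


def _clearance_ok(placed: list[np.ndarray], cand: np.ndarray,
                  skip_last: bool) -> bool:
    """cand keeps >= MIN_SEP from every placed bead (except its bonded
    predecessor, the last placed bead, when skip_last)."""
    if not placed:
        return True
    arr = np.asarray(placed[:-1] if skip_last else placed)
    if arr.size == 0:
        return True
    return bool(np.min(np.linalg.norm(arr - cand, axis=1)) >= MIN_SEP + 0.05)


def _grow_blob(rng: np.random.Generator, start: np.ndarray, center: np.ndarray,
               radius: float, n: int, placed: list[np.ndarray],
               bonded_prev: bool, exit_point: np.ndarray | None) -> list[np.ndarray]:
    """Self-avoiding walk of *n* beads inside a sphere, starting at *start*.

    The last few beads are pulled toward *exit_point* (when given) so the
    chain leaves the blob on the side where the next bridge departs.
    """
    if not _clearance_ok(placed, start, skip_last=bonded_prev):
        raise GenerationError("blob start bead clashes")
    blob = [start]
    tries_left = 8000
    while len(blob) < n:
        pos = blob[-1]
        near_exit = exit_point is not None and len(blob) >= n - 4
        goal = exit_point if near_exit else center
        ok = False
        for _ in range(80):
            tries_left -= 1
            if tries_left <= 0:
                raise GenerationError("blob packing did not converge")
            pull = (goal - pos) / max(radius, 1e-9)
            direction = rng.standard_normal(3) + (1.5 if near_exit else 0.8) * pull
            direction /= np.linalg.norm(direction)
            cand = pos + BOND * direction
            if np.linalg.norm(cand - center) > radius:
                continue
            if not _clearance_ok(placed + blob, cand, skip_last=True):
                continue
            blob.append(cand)
            ok = True
            break
        if not ok:
            if len(blob) > 1:
                blob.pop()        # backtrack one bead and retry
            else:
                raise GenerationError("blob packing stuck at first bead")
    return blob


def _walk_bridge(rng: np.random.Generator, placed: list[np.ndarray],
                 target_center: np.ndarray, target_radius: float,
                 entry_point: np.ndarray, max_beads: int,
                 waypoint: np.ndarray | None = None) -> tuple[list[np.ndarray], np.ndarray]:
    """Near-straight bridge from the last placed bead toward an entry point.

    Beads step one bond at a time toward the entry point (via an optional
    waypoint, e.g. the tweezer apex) with a little jitter; the walk ends as
    soon as the next step would land inside the target sphere (that landing
    bead belongs to the next domain segment, not to the bridge).
    """
    bridge: list[np.ndarray] = []
    pos = placed[-1]
    via = waypoint
    for _ in range(max_beads):
        if via is not None and np.linalg.norm(pos - via) < BOND * 1.2:
            via = None
        goal = via if via is not None else entry_point
        stepped = False
        for _try in range(40):
            direction = _unit(_unit(goal - pos) + rng.standard_normal(3) * 0.25)
            cand = pos + BOND * direction
            if _clearance_ok(placed + bridge, cand, skip_last=True):
                stepped = True
                break
        if not stepped:
            raise GenerationError("bridge step blocked")
        if via is None and np.linalg.norm(cand - target_center) <= 0.85 * target_radius:
            return bridge, cand          # cand = landing bead of next segment
        bridge.append(cand)
        pos = cand
    raise GenerationError("bridge did not reach the target sphere")


def _chain_plan(spec: ToySpec) -> tuple[list[tuple[int, int]], list[int]]:
    """Segment plan: list of (sphere index, n beads) along the chain.

    For three domains the chain re-enters the core sphere after the head
    (binding -> core -> head -> core), mirroring the real non-contiguous
    core; for two domains the first named domain is split around the
    second.  Returns the plan and the total bead count per sphere.
    """
    sizes = spec.domain_sizes
    if spec.n_domains == 1:
        plan = [(0, sizes[0])]
    elif spec.n_domains == 2:
        half = sizes[0] // 2
        plan = [(0, sizes[0] - half), (1, sizes[1]), (0, half)]
    elif spec.n_domains == 3:
        first = max(10, int(round(sizes[1] * 0.2)))
        bd_half = sizes[0] // 2
        plan = [(0, sizes[0] - bd_half), (1, first), (2, sizes[2]),
                (1, sizes[1] - first), (0, bd_half)]
    else:
        plan = [(i, sizes[i]) for i in range(spec.n_domains)]
    n_spheres = max(s for s, _ in plan) + 1
    totals = [sum(n for s, n in plan if s == i) for i in range(n_spheres)]
    return plan, totals


def make_hinge_structure(spec: ToySpec) -> tuple[Structure, DomainMap]:
    """Compact domain blobs joined by short bridges, exact 3.8 A bonds.

    Domain spheres are laid out on a bent (V/U-shaped) path; sphere
    surfaces sit just beyond the usual 13 A elastic-network cutoff, so
    domains couple only through the bridge beads at the elbows.  The head
    domain (and, for two-domain toys, the second domain) is anchored by
    two bridges, which pins a unique hinge axis and makes the slowest
    network modes anti-correlated domain counter-swings.  Deterministic
    per seed.
    """
    plan, totals = _chain_plan(spec)
    radii = [_domain_radius(n) for n in totals]
    n_spheres = len(totals)
    apex = None
    if spec.n_domains == 2:
        # tweezer layout: two nearly parallel arms hinged at a common apex.
        # Only this geometry makes the slowest mode an opening/closing with
        # anti-parallel block velocities; two collinear domains can only
        # seesaw (which is a near-rigid rotation) or stretch (stiff).
        alpha = np.deg2rad(spec.apex_angle)
        reach = (14.0 + radii[0] + radii[1]) / (2 * np.sin(alpha / 2))
        apex = np.zeros(3)
        centers = [apex + reach * np.array([-np.sin(alpha / 2), np.cos(alpha / 2), 0.0]),
                   apex + reach * np.array([+np.sin(alpha / 2), np.cos(alpha / 2), 0.0])]
    else:
        bend = np.deg2rad(spec.bend_angle)
        centers = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        gap = 2 * BOND + max(spec.linker_length - 2, 0) * 3.2 + 6.0
        for s in range(1, n_spheres):
            centers.append(centers[-1] + direction * (radii[s - 1] + radii[s] + gap))
            direction = _rot_z(bend) @ direction

    for restart in range(40):
        rng = np.random.default_rng((spec.seed, restart))
        try:
            placed: list[np.ndarray] = []
            seg_slices: list[tuple[int, int]] = []
            bridge_slices: list[tuple[int, int]] = []
            n_bridges_at: dict[tuple[int, int], int] = {}
            start = centers[plan[0][0]] - 0.5 * radii[plan[0][0]] * np.array([1.0, 0, 0])
            for seg_idx, (sphere, n_beads) in enumerate(plan):
                center, radius = centers[sphere], radii[sphere]
                exit_pt = None
                if seg_idx < len(plan) - 1:
                    nxt = plan[seg_idx + 1][0]
                    key = tuple(sorted((sphere, nxt)))
                    k = n_bridges_at.get(key, 0)
                    if apex is not None:
                        wp = apex + np.array([0.0, 0.0, 2.5 if k == 0 else -2.5])
                        exit_pt = center + 0.9 * radius * _unit(wp - center)
                    else:
                        # lateral offset so multiple bridges between the
                        # same sphere pair attach at separated points
                        u = _unit(centers[nxt] - center)
                        off = _rot_z(np.deg2rad(18.0 if k == 0 else -18.0)) @ u
                        exit_pt = center + 0.9 * radius * off
                blob = _grow_blob(rng, start, center, radius, n_beads,
                                  placed, bonded_prev=(seg_idx > 0),
                                  exit_point=exit_pt)
                i0 = len(placed)
                placed.extend(blob)
                seg_slices.append((i0, len(placed)))
                if seg_idx < len(plan) - 1:
                    nxt = plan[seg_idx + 1][0]
                    key = tuple(sorted((sphere, nxt)))
                    k = n_bridges_at.get(key, 0)
                    n_bridges_at[key] = k + 1
                    if apex is not None:
                        wp = apex + np.array([0.0, 0.0, 2.5 if k == 0 else -2.5])
                        entry = centers[nxt] + 0.8 * radii[nxt] * _unit(wp - centers[nxt])
                        max_beads = int(np.linalg.norm(centers[nxt] - apex) / 2.5) + 20
                    else:
                        wp = None
                        u_back = _unit(center - centers[nxt])
                        entry = centers[nxt] + 0.8 * radii[nxt] * (
                            _rot_z(np.deg2rad(-18.0 if k == 0 else 18.0)) @ u_back)
                        max_beads = spec.linker_length + 12
                    i0 = len(placed)
                    bridge, landing = _walk_bridge(
                        rng, placed, centers[nxt], radii[nxt], entry,
                        max_beads=max_beads, waypoint=wp)
                    placed.extend(bridge)
                    bridge_slices.append((i0, len(placed)))
                    start = landing
            coords = np.asarray(placed)
            break
        except GenerationError:
            continue
    else:
        raise GenerationError(f"packing failed after 40 restarts (seed {spec.seed})")

    n = coords.shape[0]
    structure = Structure(
        coords=coords,
        node_kind=np.full(n, AMINO),
        chain_id=np.full(n, spec.chain_id),
        residue_number=np.arange(1, n + 1),
        residue_name=np.full(n, "GLY"),
    )
    dm = DomainMap()
    seg_names = _segment_names(spec, plan)
    for name, (i0, i1) in zip(seg_names, seg_slices):
        dm.add(name, spec.chain_id, i0 + 1, i1)
    for li, (i0, i1) in enumerate(bridge_slices, start=1):
        dm.add(f"linker{li}", spec.chain_id, i0 + 1, i1)
    # arms: labelled sub-ranges at the ends of the long core tail segment
    if spec.n_domains >= 3 and spec.arm_fraction > 0:
        core_sphere = 1
        core_segs = [i for i, (sph, _) in enumerate(plan) if sph == core_sphere]
        c0, c1 = max((seg_slices[i] for i in core_segs),
                     key=lambda sl: sl[1] - sl[0])
        arm = max(3, int((c1 - c0) * spec.arm_fraction))
        dm.add("Arm1", spec.chain_id, c0 + 1, c0 + arm)
        dm.add("Arm2", spec.chain_id, c1 - arm + 1, c1)
    return structure, dm


def _segment_names(spec: ToySpec, plan: list[tuple[int, int]]) -> list[str]:
    names = spec.domain_names
    out = []
    for sphere, _ in plan:
        out.append(names[sphere] if sphere < len(names) else f"D{sphere + 1}")
    return out


# ---------------------------------------------------------------------------
# Pseudo-trajectories
# ---------------------------------------------------------------------------

def _anchor_domain(structure: Structure, domains: DomainMap,
                   names: list[str]) -> str:
    """The largest named domain is treated as the fixed core."""
    sizes = {n: domains.resolve(structure, n, report_missing=False).size
             for n in names}
    return max(sizes, key=sizes.get)


def _hinge_pivot(structure: Structure, domains: DomainMap,
                 name: str) -> np.ndarray:
    """Centroid of the linker beads flanking a domain (its hinge point)."""
    idx = domains.resolve(structure, name, report_missing=False)
    residues = set(structure.residue_number[idx].tolist())
    flank = []
    li = 1
    while f"linker{li}" in domains.ranges:
        lidx = domains.resolve(structure, f"linker{li}", report_missing=False)
        lres = structure.residue_number[lidx]
        if (lres.min() - 1 in residues) or (lres.max() + 1 in residues):
            flank.append(lidx)
        li += 1
    if not flank:
        raise GenerationError(f"domain {name!r} has no flanking linker")
    return structure.coords[np.concatenate(flank)].mean(axis=0)


def make_trajectory(structure: Structure, domains: DomainMap,
                    spec: ToySpec) -> Trajectory:
    """Pseudo-trajectory: anti-phase hinge swings plus per-node noise.

    Every named domain except the largest (the core, which stays anchored)
    rigidly swings about the centroid of its flanking linkers, in the
    structure plane, with a sinusoidal angle scaled so the peak centroid
    displacement equals ``spec.amplitude`` Angstrom.  Alternating domains
    swing in anti-phase, emulating the opening/closing motions seen in the
    slow modes.  Optionally a fraction of frames is drawn from a
    semi-collapsed base (last mobile domain folded by 60 degrees) to
    produce bimodal descriptor histograms.  Seeded and deterministic; the
    per-frame linker geometry is not re-idealised (the frames are
    descriptor fodder, not a physical simulation).
    """
    rng = np.random.default_rng((spec.seed, 7))
    base = structure.coords
    names = [n for n in domains.names()
             if not n.startswith("linker") and n not in ("Arm1", "Arm2")]
    anchor = _anchor_domain(structure, domains, names) if len(names) > 1 else names[0]
    mobile = [n for n in names if n != anchor]
    units = []
    for m, name in enumerate(mobile):
        idx = domains.resolve(structure, name, report_missing=False)
        pivot = _hinge_pivot(structure, domains, name)
        lever = np.linalg.norm(base[idx].mean(axis=0) - pivot)
        units.append((idx, pivot, spec.amplitude / max(lever, 1e-9),
                      m * np.pi))        # alternating domains in anti-phase
    frames = np.empty((spec.n_frames, structure.n_nodes, 3))
    n_collapsed = int(round(spec.collapsed_fraction * spec.n_frames))
    for t in range(spec.n_frames):
        coords = base.copy()
        for u, (idx, pivot, amp, phase) in enumerate(units):
            angle = amp * np.sin(2 * np.pi * t / spec.oscillation_period + phase)
            if t < n_collapsed and u == len(units) - 1:
                angle += np.deg2rad(60.0)
            rot = _rotation_about(_ZHAT, angle)
            coords[idx] = (coords[idx] - pivot) @ rot.T + pivot
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma,
                                         size=coords.shape)
        frames[t] = coords
    return Trajectory(topology=structure, coords=frames)


def fold_domain_toward(structure: Structure, domains: DomainMap,
                       move: str = "HD", toward: str = "BD",
                       fraction: float = 0.8) -> Structure:
    """Fold a domain about its hinge toward another domain.

    Rotates the *move* domain rigidly about the centroid of its flanking
    linkers, in the plane spanned by the hinge-to-*move* and
    hinge-to-*toward* directions, by *fraction* of the angle between them.
    With a large fraction this manufactures a semi-collapsed conformer
    (head folded toward the binding side), which after docking places the
    moved domain against the surface.
    """
    idx_move = domains.resolve(structure, move, report_missing=False)
    idx_toward = domains.resolve(structure, toward, report_missing=False)
    pivot = _hinge_pivot(structure, domains, move)
    v_move = _unit(structure.coords[idx_move].mean(axis=0) - pivot)
    v_toward = _unit(structure.coords[idx_toward].mean(axis=0) - pivot)
    axis = np.cross(v_move, v_toward)
    if np.linalg.norm(axis) < 1e-9:
        axis = _ZHAT
    angle = fraction * float(np.arccos(np.clip(v_move @ v_toward, -1, 1)))
    rot = _rotation_about(axis, angle)
    coords = structure.coords.copy()
    coords[idx_move] = (coords[idx_move] - pivot) @ rot.T + pivot
    return structure.with_coords(coords)


def make_collapsed_conformer(spec: ToySpec,
                             min_clash_pairs: int = 8,
                             clash_threshold: float = 4.0,
                             safe_distance: float = 6.0) -> Structure:
    """A semi-collapsed conformer whose docked pose clashes through its head.

    Starting from the extended pose that docking reproduces, the whole
    non-binding body is tilted about the binding-domain hinge until the
    head domain -- the farthest tip, which sweeps down fastest -- makes at
    least *min_clash_pairs* node pairs within *clash_threshold* of the toy
    surface while the core arms stay at least *safe_distance* away.
    Because the binding domain is untouched, docking by binding-domain
    alignment reproduces exactly this geometry.
    """
    tf, dm = make_hinge_structure(spec)
    posed = pose_extended(tf, dm, clearance=6.0)
    surface = make_anchored_surface(spec).surface
    first = dm.names()[0]
    bd_idx = dm.resolve(posed, first, report_missing=False)
    body = np.setdiff1d(np.arange(posed.n_nodes), bd_idx)
    pivot = _hinge_pivot(posed, dm, first)
    hd_idx = dm.resolve(posed, "HD", report_missing=False)
    u = _unit(posed.coords[hd_idx].mean(axis=0) - pivot)
    axis = np.cross(u, np.array([0.0, 0.0, -1.0]))
    if np.linalg.norm(axis) < 1e-9:
        axis = np.array([1.0, 0.0, 0.0])
    tree = cKDTree(surface.coords)
    arm_idx = (dm.resolve(posed, "Arm2", report_missing=False)
               if "Arm2" in dm.ranges else None)
    for theta in np.deg2rad(np.arange(1.0, 140.0, 1.0)):
        rot = _rotation_about(axis, theta)
        coords = posed.coords.copy()
        coords[body] = (coords[body] - pivot) @ rot.T + pivot
        n_pairs = sum(len(p) for p in
                      tree.query_ball_point(coords[hd_idx], clash_threshold))
        if n_pairs >= min_clash_pairs:
            if arm_idx is not None and \
                    tree.query(coords[arm_idx], k=1)[0].min() < safe_distance:
                break
            return posed.with_coords(coords)
    raise GenerationError("could not construct a head-clashing conformer")


# ---------------------------------------------------------------------------
# Toy anchored surface
# ---------------------------------------------------------------------------

def _fibonacci_cap(radius: float, spacing: float, cap_height: float) -> np.ndarray:
    """Evenly spread points on the upper cap of a sphere centred below z=0.

    The sphere is centred at (0, 0, -radius) so its north pole touches the
    origin (the marked exit site); points with height above ``-cap_height``
    are kept.
    """
    area = 4 * np.pi * radius ** 2
    n_total = int(area / (spacing ** 2 * np.sqrt(3) / 2))
    i = np.arange(n_total)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_total            # cos(theta) in [-1, 1]
    theta = np.arccos(z)
    phi = 2 * np.pi * i / golden
    pts = radius * np.column_stack([np.sin(theta) * np.cos(phi),
                                    np.sin(theta) * np.sin(phi),
                                    np.cos(theta)])
    pts[:, 2] -= radius                         # pole at the origin
    return pts[pts[:, 2] >= -cap_height]


def pose_extended(tf: Structure, domains: DomainMap,
                  clearance: float = 6.0) -> Structure:
    """Pose a hinge chain so it extends radially outward from the exit site.

    The binding (first-named) domain centroid lands on the +z axis
    *clearance* Angstrom above the origin and the axis from it to the rest
    of the chain is rotated onto +z.
    """
    first = domains.names()[0]
    bd_idx = domains.resolve(tf, first, report_missing=False)
    rest = np.setdiff1d(np.arange(tf.n_nodes), bd_idx)
    bd_c = tf.coords[bd_idx].mean(axis=0)
    axis_from = _unit(tf.coords[rest].mean(axis=0) - bd_c)
    axis_to = _ZHAT
    v = np.cross(axis_from, axis_to)
    s = np.linalg.norm(v)
    c = float(axis_from @ axis_to)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else _rotation_about(np.array([1.0, 0, 0]), np.pi)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    coords = (tf.coords - bd_c) @ rot.T + np.array([0.0, 0.0, clearance])
    return tf.with_coords(coords)


def make_anchored_surface(spec: ToySpec) -> AnchorComplex:
    """Rigid hemispherical bead surface with a tangential anchor fragment.

    The surface is a spherical-cap lattice (bead spacing ~5 Angstrom) whose
    pole marks the tunnel-exit site; a single amino-acid reference node
    (chain "L", residue 102) sits at the pole for exit-distance
    descriptors.  The anchor is the binding domain of the seed-matched
    hinge chain, posed so that the full chain extends radially away from
    the surface; docking the unmodified chain therefore reproduces an
    extended, clash-free pose.
    """
    # two concentric cap layers 6 A apart: a single thin shell is
    # bending-floppy and would contribute spurious slow modes, whereas the
    # cross-linked sandwich behaves as the rigid body the large subunit is
    outer = _fibonacci_cap(spec.surface_radius, spec.surface_spacing,
                           spec.cap_height)
    inner = _fibonacci_cap(spec.surface_radius - 6.0, spec.surface_spacing,
                           spec.cap_height - 3.0)
    inner[:, 2] -= 6.0          # concentric with the outer layer
    pts = np.vstack([outer, inner])
    n = pts.shape[0]
    surface = Structure(
        coords=np.vstack([pts, [[0.0, 0.0, -1.0]]]),
        node_kind=np.concatenate([np.full(n, NUCLEOTIDE), [AMINO]]),
        chain_id=np.concatenate([np.full(n, "S"), ["L"]]),
        residue_number=np.concatenate([np.arange(1, n + 1), [102]]),
        residue_name=np.concatenate([np.full(n, "U"), ["GLN"]]),
    )
    tf, dm = make_hinge_structure(spec)
    posed = pose_extended(tf, dm, clearance=6.0)
    bd_idx = dm.resolve(posed, dm.names()[0], report_missing=False)
    anchor = posed.subset(bd_idx)
    return AnchorComplex(surface=surface, anchor=anchor)
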