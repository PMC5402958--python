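"""Docking-by-alignment of chaperone conformers onto an anchored surface.

A crystal complex provides an *anchor*: a binding-domain fragment already
positioned on the large ribosomal subunit (or a toy surface).  A full-length
conformer is docked by Kabsch-superposing its binding domain onto the anchor
fragment, pairing nodes by residue number.  The merged complex is then
screened for steric clashes between the chaperone and the surface and
classified by where the clashes fall:

    Extended < Extended/HD close contact < HD minor clash < HD clash < Arm2 clash

The binding domain is excluded from clash detection by construction — it is
the legitimate binding interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateAlignmentError, DomainLookupError
from .structures import (
    DomainMap,
    Structure,
    Transform,
    centroid_distance,
    concatenate,
    kabsch,
    radius_of_gyration,
)

logger = logging.getLogger(__name__)

DEFAULT_CLASH_THRESHOLD = 4.0    # Angstrom between coarse-grained nodes
DEFAULT_MINOR_CLASH_MAX = 5      # clashing pairs; above this = full clash
DEFAULT_CONTACT_DISTANCE = 6.0   # Angstrom; "close contact" without clash

#: classification labels ordered from most favourable to most occluded
LABELS = ("Extended", "Extended/HD close contact", "HD minor clash",
          "HD clash", "Arm2 clash")


@dataclass
class AnchorComplex:
    """A surface plus a binding-domain fragment pre-positioned on it.

    The anchor's residue numbers map injectively onto binding-domain residue
    numbers of a full-length conformer; that intersection defines the node
    pairing used for docking.
    """

    surface: Structure
    anchor: Structure

    def anchor_residues(self) -> set[int]:
        return set(self.anchor.residue_number.tolist())


@dataclass
class ClashReport:
    """Inter-structure node pairs closer than the clash threshold.

    ``pairs`` rows are (tf_index, surface_index, distance, domain) where the
    domain is the chaperone domain of the clashing node.
    """

    threshold: float
    excluded: tuple[str, ...]
    tf_index: np.ndarray
    surface_index: np.ndarray
    distance: np.ndarray
    domain: np.ndarray

    @property
    def n_clashes(self) -> int:
        return self.tf_index.size

    def count(self, domain: str) -> int:
        return int(np.sum(self.domain == domain))

    def to_frame(self, tf: Structure, surface: Structure):
        import pandas as pd
        return pd.DataFrame({
            "tf_chain": tf.chain_id[self.tf_index],
            "tf_res": tf.residue_number[self.tf_index],
            "domain": self.domain,
            "surface_chain": surface.chain_id[self.surface_index],
            "surface_res": surface.residue_number[self.surface_index],
            "distance": self.distance,
        })


@dataclass
class ComplexModel:
    """A docked chaperone-surface complex with its clash classification."""

    tf: Structure                  # transformed full-length conformer
    surface: Structure
    transform: Transform
    alignment_rmsd: float
    clash_report: ClashReport
    label: str
    descriptors: dict = field(default_factory=dict)

    @property
    def merged(self) -> Structure:
        return concatenate([self.surface, self.tf])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _domain_of_nodes(tf: Structure, domains: DomainMap | None) -> np.ndarray:
    """Assign each chaperone node a domain label for clash grouping.

    The arms take precedence over their parent core domain so arm clashes
    are reported as such; unnamed nodes fall into "other".
    """
    out = np.full(tf.n_nodes, "other", dtype="U16")
    if domains is None:
        return out
    arms = [n for n in ("Arm1", "Arm2") if n in domains.ranges]
    priority = [n for n in domains.names() if n not in arms] + arms
    for name in priority:       # later assignments overwrite: arms win
        try:
            idx = domains.resolve(tf, name, report_missing=False)
        except DomainLookupError:
            continue
        out[idx] = name
    return out


def detect_clashes(tf: Structure, surface: Structure,
                   threshold: float = DEFAULT_CLASH_THRESHOLD,
                   domains: DomainMap | None = None,
                   exclude: tuple[str, ...] = ("BD",)) -> ClashReport:
    """All chaperone-surface node pairs closer than *threshold* (Angstrom).

    Pairs whose chaperone node lies in an excluded domain (the binding
    domain by default) are not counted.  Spatial indexing keeps this
    linear-ish in system size; it is exactly equivalent to the quadratic
    double loop.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = _domain_of_nodes(tf, domains)
    tree = cKDTree(surface.coords)
    ti, si, dist, dom = [], [], [], []
    neighbor_lists = tree.query_ball_point(tf.coords, threshold)
    for i, neighbors in enumerate(neighbor_lists):
        if labels[i] in exclude:
            continue
        for j in neighbors:
            d = float(np.linalg.norm(tf.coords[i] - surface.coords[j]))
            if d < threshold:
                ti.append(i)
                si.append(j)
                dist.append(d)
                dom.append(labels[i])
    return ClashReport(threshold=threshold, excluded=tuple(exclude),
                       tf_index=np.asarray(ti, dtype=int),
                       surface_index=np.asarray(si, dtype=int),
                       distance=np.asarray(dist, dtype=float),
                       domain=np.asarray(dom, dtype="U16"))


def min_domain_surface_distance(tf: Structure, surface: Structure,
                                domains: DomainMap, name: str) -> float:
    """Smallest node-node distance between a named domain and the surface."""
    idx = domains.resolve(tf, name, report_missing=False)
    tree = cKDTree(surface.coords)
    d, _ = tree.query(tf.coords[idx], k=1)
    return float(np.min(d))


def classify_complex(report: ClashReport, hd_surface_min_distance: float,
                     minor_threshold: int = DEFAULT_MINOR_CLASH_MAX,
                     contact_distance: float = DEFAULT_CONTACT_DISTANCE) -> str:
    """Label a docked complex from its clash report.

    Severity order (monotone in added clash pairs): any Arm2 clash wins;
    then head-domain clashes, split into "minor" (at most *minor_threshold*
    pairs) and full; a clash-free head domain within *contact_distance* of
    the surface is "Extended/HD close contact"; otherwise "Extended".
    """
    if report.count("Arm2") > 0:
        return "Arm2 clash"
    n_hd = report.count("HD")
    if n_hd > minor_threshold:
        return "HD clash"
    if n_hd >= 1:
        return "HD minor clash"
    if hd_surface_min_distance < contact_distance:
        return "Extended/HD close contact"
    return "Extended"


def dock_by_alignment(conformer: Structure, anchor_complex: AnchorComplex,
                      domains: DomainMap, selection: str = "BD",
                      clash_threshold: float = DEFAULT_CLASH_THRESHOLD,
                      minor_threshold: int = DEFAULT_MINOR_CLASH_MAX,
                      contact_distance: float = DEFAULT_CONTACT_DISTANCE,
                      tunnel_ref: tuple[str, int] | None = None,
                      arm2_ref: tuple[str, int] | None = None) -> ComplexModel:
    """Dock a full-length conformer by aligning its binding domain onto the anchor.

    Nodes are paired by residue-number intersection between the conformer's
    binding-domain selection and the anchor fragment; the resulting rigid
    transform is applied to the whole conformer, which is then merged with
    the surface, screened for clashes and classified.  Deterministic: the
    same inputs give byte-identical coordinates.
    """
    bd_idx = domains.resolve(conformer, selection, report_missing=False)
    anchor = anchor_complex.anchor
    anchor_keys = {int(r): i for i, r in enumerate(anchor.residue_number)}
    pairs = [(i, anchor_keys[int(conformer.residue_number[i])])
             for i in bd_idx if int(conformer.residue_number[i]) in anchor_keys]
    if len(pairs) < 3:
        raise DegenerateAlignmentError(
            f"only {len(pairs)} residues shared between conformer {selection} "
            "and anchor fragment")
    ci = np.asarray([p[0] for p in pairs])
    ai = np.asarray([p[1] for p in pairs])
    transform = kabsch(conformer.coords[ci], anchor.coords[ai])
    moved = transform.apply(conformer.coords[ci])
    rmsd = float(np.sqrt(np.mean(np.sum((moved - anchor.coords[ai]) ** 2, axis=1))))
    tf = transform.apply_structure(conformer)
    report = detect_clashes(tf, anchor_complex.surface, threshold=clash_threshold,
                            domains=domains, exclude=(selection,))
    hd_min = (min_domain_surface_distance(tf, anchor_complex.surface, domains, "HD")
              if "HD" in domains.ranges else np.inf)
    label = classify_complex(report, hd_min, minor_threshold=minor_threshold,
                             contact_distance=contact_distance)
    model = ComplexModel(tf=tf, surface=anchor_complex.surface,
                         transform=transform, alignment_rmsd=rmsd,
                         clash_report=report, label=label)
    model.descriptors = complex_descriptors(model, domains, tunnel_ref=tunnel_ref,
                                           arm2_ref=arm2_ref)
    return model


def complex_descriptors(complex_model: ComplexModel, domains: DomainMap,
                       tunnel_ref: tuple[str, int] | None = None,
                       arm2_ref: tuple[str, int] | None = None) -> dict:
    """Geometric descriptors of a docked complex.

    Radius of gyration of the chaperone part, BD-Arm2 and HD-Arm1 centroid
    distances, and (when both references are given) the node-to-node
    distance between a residue at the tip of Arm2 and a tunnel-exit residue
    on the surface (coarse-grained stand-in for a backbone-atom distance).
    """
    tf = complex_model.tf
    out: dict[str, float | str] = {"rg": radius_of_gyration(tf)}
    for key, a, b in (("bd_arm2", "BD", "Arm2"), ("hd_arm1", "HD", "Arm1")):
        if a in domains.ranges and b in domains.ranges:
            out[key] = centroid_distance(tf, domains, a, b)
    if tunnel_ref is not None and arm2_ref is not None:
        si = complex_model.surface.index_of(*tunnel_ref)
        ti = tf.index_of(*arm2_ref)
        out["surface_arm2"] = float(np.linalg.norm(
            complex_model.surface.coords[si] - tf.coords[ti]))
    out["label"] = complex_model.label
    return out
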