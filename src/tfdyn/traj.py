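"""Trajectory descriptors: RMSD profiles, domain-wise RMSF, Rg / distance series.

A :class:`Trajectory` is an ordered stack of coordinate frames sharing one
topology.  Descriptors reproduce the standard conformational-flexibility
analyses for a multi-domain chaperone: overall vs. domain-wise RMSD against
the first frame, per-residue RMSF about the domain-aligned mean conformation,
radius-of-gyration and inter-domain distance time series with normalized
histograms, and selection of representative conformers from a 2-D descriptor
plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateAlignmentError, DomainLookupError, EmptyStructureError
from .structures import (
    DomainMap,
    Structure,
    kabsch,
    radius_of_gyration,
    read_pdb_models,
)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``burn_in`` frames are discarded from the front by every descriptor
    (equilibration removal); it defaults to 0 and must stay below the frame
    count.
    """

    topology: Structure
    coords: np.ndarray                 # (F, N, 3)
    frame_interval: float | None = None  # time units per frame, optional
    burn_in: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.topology.n_nodes:
            raise ValueError("frames do not match topology node count")
        if not 0 <= self.burn_in < self.coords.shape[0]:
            raise ValueError("burn_in must be < frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0] - self.burn_in

    @property
    def frames(self) -> np.ndarray:
        """Frames after burn-in removal, shape (F - burn_in, N, 3)."""
        return self.coords[self.burn_in:]

    def frame_structure(self, i: int) -> Structure:
        """Post-burn-in frame *i* as a Structure."""
        return self.topology.with_coords(self.frames[i])

    @classmethod
    def from_structures(cls, frames: Sequence[Structure], **kwargs) -> "Trajectory":
        if not frames:
            raise EmptyStructureError("no frames")
        top = frames[0]
        return cls(top, np.stack([f.coords for f in frames]), **kwargs)

    @classmethod
    def from_pdb(cls, path: str | Path, **kwargs) -> "Trajectory":
        return cls.from_structures(read_pdb_models(path), **kwargs)

    @staticmethod
    def burn_in_from_time(time: float, frame_interval: float) -> int:
        """Frames to discard for an equilibration period given the recording
        interval (e.g. 20 ns at 4 ps/frame -> 5000 frames)."""
        return int(round(time / frame_interval))


@dataclass
class DescriptorSeries:
    """Per-frame scalar series with a label and histogram support."""

    values: np.ndarray
    label: str
    kind: str = "scalar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.values.size

    def histogram(self, bin_width: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Normalized histogram with fixed-width bins.

        A fixed bin width (not a fixed bin count) keeps histograms from runs
        of different lengths directly comparable.  The returned density
        integrates to 1.
        """
        lo = np.floor(self.values.min() / bin_width) * bin_width
        hi = np.ceil(self.values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(self.values, bins=edges)
        density = counts / (counts.sum() * bin_width)
        return edges, density

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"frame": np.arange(self.values.size),
                             "label": self.label, "value": self.values})


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def _align_frames(frames: np.ndarray, ref: np.ndarray,
                  fit_idx: np.ndarray) -> np.ndarray:
    """Kabsch-align every frame onto *ref* using the fit node subset."""
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        t = kabsch(frames[f][fit_idx], ref[fit_idx])
        out[f] = t.apply(frames[f])
    return out


def rmsd_profile(traj: Trajectory, domains: DomainMap | None = None,
                 selection: str | None = None,
                 align_on: str = "whole") -> DescriptorSeries:
    """Per-frame RMSD against the first retained frame.

    ``align_on="whole"`` aligns every frame on all nodes; ``"selection"``
    aligns on the named domain only (domain-wise profile).  The RMSD itself
    is computed over the selection when one is given, else over all nodes.
    """
    if align_on not in ("whole", "selection"):
        raise ValueError("align_on must be 'whole' or 'selection'")
    frames = traj.frames
    ref = frames[0]
    if selection is not None:
        if domains is None:
            raise DomainLookupError("selection given but no DomainMap")
        sel_idx = domains.resolve(traj.topology, selection, report_missing=False)
    else:
        sel_idx = np.arange(traj.topology.n_nodes)
    if align_on == "selection":
        if selection is None:
            raise DomainLookupError("align_on='selection' requires a selection")
        fit_idx = sel_idx
    else:
        fit_idx = np.arange(traj.topology.n_nodes)
    aligned = _align_frames(frames, ref, fit_idx)
    values = np.sqrt(np.mean(
        np.sum((aligned[:, sel_idx] - ref[sel_idx]) ** 2, axis=2), axis=1))
    label = selection if selection is not None else "all"
    return DescriptorSeries(values, label=f"rmsd:{label}", kind="rmsd")


def rmsf_domainwise(traj: Trajectory, domains: DomainMap,
                    names: Sequence[str] | None = None):
    """Per-node RMSF about the domain-wise mean conformation.

    For each named domain the frames are aligned on that domain only, so the
    fluctuations exclude inter-domain rearrangements.  The mean conformation
    is refined once: align on the first frame, average, re-align on the mean,
    re-average.  RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames.

    Returns a tidy pandas DataFrame with columns
    ``domain, chain, residue_number, rmsf``, concatenated over domains.
    """
    import pandas as pd

    if names is None:
        names = domains.names()
    frames = traj.frames
    records = []
    for name in names:
        idx = domains.resolve(traj.topology, name, report_missing=False)
        if idx.size < 3:
            raise DegenerateAlignmentError(f"domain {name!r} has <3 nodes")
        sub = frames[:, idx]                       # (F, n, 3)
        aligned = _align_frames(sub, sub[0], np.arange(idx.size))
        mean = aligned.mean(axis=0)
        aligned = _align_frames(sub, mean, np.arange(idx.size))
        mean = aligned.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
        for j, node in enumerate(idx):
            records.append({
                "domain": name,
                "chain": str(traj.topology.chain_id[node]),
                "residue_number": int(traj.topology.residue_number[node]),
                "rmsf": float(rmsf[j]),
            })
    return pd.DataFrame.from_records(records)


def descriptor_series(traj: Trajectory, kind: str,
                      domains: DomainMap | None = None,
                      a: str | None = None, b: str | None = None,
                      label: str | None = None) -> DescriptorSeries:
    """Per-frame scalar series: ``kind="rg"`` or ``kind="domain_distance"``.

    ``domain_distance`` needs a DomainMap and two domain names *a*, *b*.
    """
    top = traj.topology
    if kind == "rg":
        values = [radius_of_gyration(top.with_coords(f)) for f in traj.frames]
        return DescriptorSeries(np.asarray(values), label=label or "rg", kind="rg")
    if kind == "domain_distance":
        if domains is None or a is None or b is None:
            raise DomainLookupError("domain_distance needs domains, a and b")
        ia = domains.resolve(top, a, report_missing=False)
        ib = domains.resolve(top, b, report_missing=False)
        frames = traj.frames
        values = np.linalg.norm(frames[:, ia].mean(axis=1)
                                - frames[:, ib].mean(axis=1), axis=1)
        return DescriptorSeries(values, label=label or f"{a}-{b}", kind="distance")
    raise ValueError(f"unknown descriptor kind {kind!r}")


def select_conformers(series_x: DescriptorSeries, series_y: DescriptorSeries,
                      targets: Sequence[tuple[float, float]]) -> list[int]:
    """For each target (x, y) point, the frame closest in descriptor space.

    Used to pick representative conformers from distinct regions of a
    2-D descriptor plot (e.g. BD-Arm2 vs. HD-Arm1 distance).  Ties resolve
    to the earliest frame.
    """
    if len(series_x) != len(series_y):
        raise ValueError("series must have equal length")
    pts = np.column_stack([series_x.values, series_y.values])
    out = []
    for tx, ty in targets:
        d2 = np.sum((pts - np.array([tx, ty])) ** 2, axis=1)
        out.append(int(np.argmin(d2)))          # argmin returns the first tie
    return out
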