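"""Anisotropic elastic network model: slow modes, cross-correlations, domains.

The network places a node per residue (C-alpha for amino acids, phosphate for
nucleotides) and joins every pair within a cutoff (default 13 Angstrom) by a
uniform-stiffness spring.  The 3N x 3N Hessian of the quadratic energy

    E = (gamma / 2) * sum_contacts (|r_ij| - |r_ij^0|)^2

has six zero eigenvalues (rigid-body motions) for a connected 3-D network;
the smallest nonzero eigenpairs are the slow (global) modes that dominate
collective domain motions.

Cross-correlations between per-node displacement vectors in mode k,

    C_ij(k) = dR_i(k) . dR_j(k) / (|dR_i(k)| |dR_j(k)|),

and their eigenvalue-weighted average over the computed modes,

    <C_ij> = sum_k C_ij(k)/lambda_k / sum_k 1/lambda_k,

expose the dynamic-domain decomposition: blocks of positively correlated
nodes separated by hinge regions.  Because the weights are 1/lambda_k the
slowest modes dominate the average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .errors import (
    DisconnectedNetworkError,
    EmptyStructureError,
    ZeroModeCountError,
)
from .structures import Structure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 13.0     # Angstrom
DEFAULT_N_MODES = 10
ZERO_MODE_TOL = 1e-8      # relative to the largest computed eigenvalue


@dataclass
class ENMModel:
    """Elastic network over a structure: contact list plus sparse Hessian."""

    structure: Structure
    cutoff: float
    gamma: float
    contacts: np.ndarray          # (n_contacts, 2) node index pairs, i < j
    hessian: sp.csr_matrix        # (3N, 3N) symmetric

    @property
    def n_nodes(self) -> int:
        return self.structure.n_nodes

    def energy(self, displacement: np.ndarray) -> float:
        """Quadratic-form energy of a 3N displacement vector."""
        d = np.asarray(displacement, dtype=float).ravel()
        return float(0.5 * d @ (self.hessian @ d))

    def component_sizes(self) -> list[int]:
        n = self.n_nodes
        if self.contacts.size == 0:
            return [1] * n
        adj = sp.coo_matrix(
            (np.ones(len(self.contacts)), (self.contacts[:, 0], self.contacts[:, 1])),
            shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        return np.bincount(labels, minlength=n_comp).tolist()

    def is_connected(self) -> bool:
        return len(self.component_sizes()) == 1


@dataclass
class ModeSet:
    """Nonzero eigenpairs of an ENM Hessian, ascending by eigenvalue.

    ``eigenvectors[:, k]`` is the orthonormal 3N mode vector; reshaped to
    (N, 3) it gives the per-node displacement directions dR_i(k).
    """

    eigenvalues: np.ndarray        # (n_modes,), > 0
    eigenvectors: np.ndarray       # (3N, n_modes)
    structure: Structure

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def n_nodes(self) -> int:
        return self.eigenvectors.shape[0] // 3

    def displacements(self, k: int) -> np.ndarray:
        """Per-node displacement vectors of mode *k* (0-based), shape (N, 3)."""
        return self.eigenvectors[:, k].reshape(-1, 3)

    def to_frame(self):
        import pandas as pd
        rows = []
        for k in range(self.n_modes):
            disp = self.displacements(k)
            for i in range(self.n_nodes):
                rows.append((k, self.eigenvalues[k],
                             str(self.structure.chain_id[i]),
                             int(self.structure.residue_number[i]),
                             *disp[i]))
        return pd.DataFrame(rows, columns=["mode", "eigenvalue", "chain",
                                           "residue_number", "dx", "dy", "dz"])


@dataclass
class CorrelationMap:
    """N x N residue cross-correlation matrix with mode provenance."""

    matrix: np.ndarray
    mode: str                      # "mode:k" or "weighted:first-n"
    structure: Structure | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def subset(self, indices: np.ndarray) -> "CorrelationMap":
        idx = np.asarray(indices, dtype=int)
        sub = self.structure.subset(idx) if self.structure is not None else None
        return CorrelationMap(self.matrix[np.ix_(idx, idx)], self.mode, sub)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",", fmt="%.6f")


# ---------------------------------------------------------------------------
# Model construction and eigensolution
# ---------------------------------------------------------------------------

def build_enm(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
              gamma: float = 1.0) -> ENMModel:
    """Build the anisotropic-network Hessian for a structure.

    For a contacting pair (i, j) with separation d = r_j - r_i the
    off-diagonal 3x3 superblock is ``-gamma * (d d^T) / |d|^2``; diagonal
    superblocks are the negated row sums, which makes every superblock row
    sum vanish (translation invariance).
    """
    n = structure.n_nodes
    if n < 2:
        raise EmptyStructureError("ENM needs at least two nodes")
    tree = cKDTree(structure.coords)
    pairs = np.asarray(sorted(tree.query_pairs(cutoff)), dtype=int)
    rows, cols, vals = [], [], []
    diag = np.zeros((n, 3, 3))
    for i, j in pairs:
        d = structure.coords[j] - structure.coords[i]
        block = -gamma * np.outer(d, d) / (d @ d)
        diag[i] -= block
        diag[j] -= block
        for a in range(3):
            for b in range(3):
                rows.extend((3 * i + a, 3 * j + a))
                cols.extend((3 * j + b, 3 * i + b))
                vals.extend((block[a, b], block[a, b]))
    for i in range(n):
        for a in range(3):
            for b in range(3):
                rows.append(3 * i + a)
                cols.append(3 * i + b)
                vals.append(diag[i, a, b])
    hessian = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    hessian.eliminate_zeros()
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    return ENMModel(structure=structure, cutoff=cutoff, gamma=gamma,
                    contacts=pairs, hessian=hessian)


_DENSE_LIMIT = 900   # use a dense eigensolver below this 3N size


def slow_modes(model: ENMModel, n: int = DEFAULT_N_MODES) -> ModeSet:
    """The *n* smallest nonzero eigenpairs of the ENM Hessian.

    Zero (rigid-body) modes are identified by |lambda| < 1e-8 x the largest
    computed eigenvalue and removed; a connected 3-D network must show
    exactly six, anything else raises a diagnostics error.  A disconnected
    network is rejected with its component sizes (the usual cause is a
    too-small cutoff).
    """
    sizes = model.component_sizes()
    if len(sizes) > 1:
        raise DisconnectedNetworkError(sizes)
    dim = model.hessian.shape[0]
    k = n + 6
    if k >= dim:
        k = dim
    if dim <= _DENSE_LIMIT or k > dim // 3:
        from scipy.linalg import eigh
        vals, vecs = eigh(model.hessian.toarray())
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        # shift-invert about a slightly negative sigma: H - sigma*I is
        # positive definite, so the factorization is safe
        vals, vecs = sp.linalg.eigsh(model.hessian, k=k, sigma=-1e-6, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    tol = ZERO_MODE_TOL * max(vals.max(), 1e-30)
    zero = np.abs(vals) < tol
    n_zero = int(zero.sum())
    if n_zero != 6:
        raise ZeroModeCountError(
            f"expected 6 near-zero modes for a connected network, found "
            f"{n_zero} (tolerance {tol:.3e}); eigenvalues {vals[:8]}")
    vals = np.clip(vals[~zero], 0.0, None)[:n]
    vecs = vecs[:, ~zero][:, :n]
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, structure=model.structure)


# ---------------------------------------------------------------------------
# Cross-correlations and dynamic domains
# ---------------------------------------------------------------------------

def _per_mode_map(disp: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(disp, axis=1)
    ok = norms > 0
    if not ok.all():
        warnings.warn("zero-norm node displacement in mode; correlations set to 0")
    safe = np.where(ok, norms, 1.0)
    unit = disp / safe[:, None]
    c = unit @ unit.T
    c[~ok, :] = 0.0
    c[:, ~ok] = 0.0
    np.fill_diagonal(c, np.where(ok, 1.0, 0.0))
    return np.clip(c, -1.0, 1.0)


def cross_correlation(modes: ModeSet, k: int | str = "weighted") -> CorrelationMap:
    """Residue cross-correlation map for one mode or the 1/lambda-weighted set.

    ``k`` is a 0-based mode index for a per-mode map, or ``"weighted"`` for
    the average over all modes in the set with weights 1/lambda_k (normalized
    by sum of 1/lambda_k), so the slowest modes dominate.  With a single mode
    available the weighted map reduces exactly to the per-mode map.
    """
    if isinstance(k, (int, np.integer)):
        if not 0 <= k < modes.n_modes:
            raise IndexError(f"mode {k} not in ModeSet of {modes.n_modes}")
        return CorrelationMap(_per_mode_map(modes.displacements(int(k))),
                              mode=f"mode:{int(k)}", structure=modes.structure)
    if k != "weighted":
        raise ValueError("k must be a mode index or 'weighted'")
    weights = 1.0 / modes.eigenvalues
    total = np.zeros((modes.n_nodes, modes.n_nodes))
    for m in range(modes.n_modes):
        total += weights[m] * _per_mode_map(modes.displacements(m))
    mat = np.clip(total / weights.sum(), -1.0, 1.0)
    return CorrelationMap(mat, mode=f"weighted:first-{modes.n_modes}",
                          structure=modes.structure)


def dynamic_domains(cmap: CorrelationMap, k_domains: int | str = "auto") -> np.ndarray:
    """Partition nodes into correlated blocks (dynamic domains).

    Correlation clustering: agglomerative average linkage on the
    dissimilarity (1 - C)/2, which is deterministic and recovers the block
    structure a reader would mark on the map by eye.  Contiguity is not
    enforced (real domains can be non-contiguous in sequence).  With
    ``k_domains="auto"`` the 2- vs 3-group split with the larger mean
    silhouette score is chosen.

    Returns integer labels (0-based) per node.
    """
    c = np.clip(cmap.matrix, -1.0, 1.0)
    n = c.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    dis = (1.0 - c) / 2.0
    np.fill_diagonal(dis, 0.0)
    dis = (dis + dis.T) / 2.0
    if np.all(np.abs(c) >= 1.0 - 1e-12):
        off = c[~np.eye(n, dtype=bool)]
        if np.all(off >= 1.0 - 1e-12):
            warnings.warn("degenerate correlation map (all +1): single domain")
            return np.zeros(n, dtype=int)
    z = linkage(squareform(dis, checks=False), method="average")
    if k_domains == "auto":
        best_labels, best_score = None, -np.inf
        for k in (2, 3):
            labels = fcluster(z, t=k, criterion="maxclust") - 1
            if len(np.unique(labels)) < 2:
                continue
            score = _silhouette(dis, labels)
            if score > best_score:
                best_score, best_labels = score, labels
        if best_labels is None:
            warnings.warn("could not split map; single domain")
            return np.zeros(n, dtype=int)
        return best_labels
    labels = fcluster(z, t=int(k_domains), criterion="maxclust") - 1
    return labels


def _silhouette(dis: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient on a precomputed dissimilarity matrix."""
    n = dis.shape[0]
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own)
        same[i] = False
        a = dis[i, same].mean() if same.any() else 0.0
        b = min(dis[i, labels == g].mean() for g in uniq if g != own)
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


def label_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Best-permutation fraction of nodes on which two labelings agree."""
    from scipy.optimize import linear_sum_assignment

    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    ua, ub = np.unique(la), np.unique(lb)
    cost = np.zeros((ua.size, ub.size))
    for i, x in enumerate(ua):
        for j, y in enumerate(ub):
            cost[i, j] = -np.sum((la == x) & (lb == y))
    ri, ci = linear_sum_assignment(cost)
    return float(-cost[ri, ci].sum() / la.size)


# ---------------------------------------------------------------------------
# Mode-directed deformation
# ---------------------------------------------------------------------------

def deform_along(modes: ModeSet, coefficients: np.ndarray,
                 target_drms: float) -> Structure:
    """Displace the parent structure along a linear mode combination.

    The raw displacement ``sum_k c_k v_k`` is rescaled so that
    ``sqrt(|displacement|^2 / N) = target_drms`` (the deformation RMSD from
    the parent before any relaxation).  Zero modes never appear here because
    a ModeSet contains only nonzero eigenpairs.
    """
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (modes.n_modes,):
        raise ValueError(f"need {modes.n_modes} coefficients, got {c.shape}")
    if np.all(c == 0):
        raise ValueError("all-zero coefficient vector")
    disp = modes.eigenvectors @ c
    norm = np.linalg.norm(disp)
    scale = 0.0 if target_drms == 0 else target_drms * np.sqrt(modes.n_nodes) / norm
    new = modes.structure.coords + scale * disp.reshape(-1, 3)
    return modes.structure.with_coords(new)
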