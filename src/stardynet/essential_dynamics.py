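"""Dynamic cross-correlation maps and principal component analysis of
node (C-alpha / nucleotide-anchor) fluctuations.

The cross-correlation between nodes i and j is

    C_ij = <dr_i . dr_j> / (<dr_i^2>^1/2 <dr_j^2>^1/2)

with dr the full 3D displacement from the mean position after an optional
rigid-body fit, so C_ij is in [-1, 1] with 1 on the diagonal.  Maps are
conventionally read in three bands: correlated (C >= 0.25), anti-correlated
(C <= -0.25) and weak motion in between.

PCA diagonalizes the 3n x 3n covariance of the fitted coordinates; frames
from several runs may be pooled before the covariance is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fluct import fit_frames
from .trajio import AtomSelection, Trajectory

logger = logging.getLogger("stardynet")

__all__ = ["CorrelationMatrix", "PcaResult", "dccm", "pca", "classify_bands"]


@dataclass
class CorrelationMatrix:
    """Normalized cross-correlations between labeled nodes."""

    labels: list
    matrix: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)


def _pooled_displacements(
    trajs, selection: AtomSelection, fit: bool
) -> np.ndarray:
    """Mean-free (n_frames_total, n_sel, 3) displacements, frames pooled
    across trajectories before the mean is taken."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    blocks = []
    for traj in trajs:
        if traj.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if fit:
            fitted, _ = fit_frames(traj, selection)
        else:
            fitted = traj.frames
        blocks.append(fitted[:, selection.resolved_ids])
    pooled = np.concatenate(blocks, axis=0)
    return pooled - pooled.mean(axis=0)


def dccm(
    trajs,
    selection: AtomSelection,
    fit: bool = True,
    labels: list | None = None,
) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the selected nodes.

    ``trajs`` is one Trajectory or a list pooled together.  Zero-variance
    nodes get diagonal 1 and zero off-diagonals with a logged warning.
    """
    dev = _pooled_displacements(trajs, selection, fit)
    inner = np.einsum("fia,fja->ij", dev, dev) / dev.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 0
    if zero.any():
        logger.warning("%d zero-variance node(s) in DCCM", int(zero.sum()))
        var[zero] = 1.0
    norm = np.sqrt(np.outer(var, var))
    c = inner / norm
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    if labels is None:
        top = (trajs[0] if not isinstance(trajs, Trajectory) else trajs).topology
        ids = selection.resolved_ids
        labels = [
            f"{top.chain_ids[i]}:{top.residue_names[i]}{top.residue_seqs[i]}:"
            f"{top.atom_names[i]}"
            for i in ids
        ]
    return CorrelationMatrix(labels=labels, matrix=c)


def classify_bands(c: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Band classification of a DCCM: +1 correlated (C >= threshold), -1
    anti-correlated (C <= -threshold), 0 weak."""
    out = np.zeros_like(c, dtype=int)
    out[c >= threshold] = 1
    out[c <= -threshold] = -1
    return out


@dataclass
class PcaResult:
    """Eigendecomposition of the fitted-coordinate covariance.

    ``eigenvalues`` (A^2, descending) sum to the covariance trace;
    ``eigenvectors`` has orthonormal 3n-vectors in its columns;
    ``projections`` (n_frames, n_components, A) are the frame coordinates
    along each mode, whose per-mode variance equals the eigenvalue.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean_structure: np.ndarray
    projections: np.ndarray
    total_variance: float

    def mode_displacements(self, mode: int) -> np.ndarray:
        """Per-atom 3-vectors of one mode (the porcupine-arrow data)."""
        return self.eigenvectors[:, mode].reshape(-1, 3)


def pca(
    trajs,
    selection: AtomSelection,
    n_components: int = 3,
    fit: bool = True,
) -> PcaResult:
    """PCA of the 3n-dimensional fitted coordinates of the selection.

    Eigenvector signs are fixed by making each mode's largest-magnitude
    component positive, for deterministic output.
    """
    dev = _pooled_displacements(trajs, selection, fit)
    n_frames = dev.shape[0]
    flat = dev.reshape(n_frames, -1)
    dim = flat.shape[1]
    if n_components > dim:
        raise ValueError(f"n_components {n_components} exceeds 3n = {dim}")
    if n_frames <= dim:
        logger.warning(
            "PCA with %d frames for %d coordinates: covariance is rank "
            "deficient", n_frames, dim,
        )
    cov = flat.T @ flat / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        imax = np.argmax(np.abs(evecs[:, k]))
        if evecs[imax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    projections = flat @ evecs[:, :n_components]
    if isinstance(trajs, Trajectory):
        mean = trajs.frames[:, selection.resolved_ids].mean(axis=0)
    else:
        mean = np.concatenate(
            [t.frames[:, selection.resolved_ids] for t in trajs]
        ).mean(axis=0)
    return PcaResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        mean_structure=mean,
        projections=projections,
        total_variance=float(np.trace(cov)),
    )


def export_mode_pdb(result: PcaResult, topology, selection: AtomSelection,
                    mode: int, path, scale: float = 3.0) -> None:
    """Write mean - scale*mode, mean, mean + scale*mode as a 3-model PDB of
    the selected atoms, for external viewers (porcupine-style mode data)."""
    from .trajio import Trajectory, write_trajectory

    sub = topology.subset(selection.resolved_ids)
    disp = result.mode_displacements(mode)
    frames = np.stack([
        result.mean_structure - scale * disp,
        result.mean_structure,
        result.mean_structure + scale * disp,
    ])
    write_trajectory(Trajectory(sub.with_coords(frames[1]), frames), path)
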