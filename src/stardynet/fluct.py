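"""Superposition and deviation statistics: RMSD, RMSF, B-factor conversion
and RAC convergence curves.

Superposition is the Kabsch least-squares rigid fit restricted to proper
rotations.  RMSF uses a two-pass iterated reference (fit to a provisional
average, re-average, refit) since fitting to "the average structure" is
circular; two passes are enough for the reference to stabilise on stationary
ensembles.  The crystal B-factor <-> RMSF conversion is the isotropic
Debye-Waller relation RMSF = sqrt(3 B / (8 pi^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import AtomSelection, Trajectory

__all__ = [
    "SuperposeResult",
    "RacCurve",
    "superpose",
    "apply_fit",
    "rmsd_series",
    "rmsf_profile",
    "bfactor_to_rmsf",
    "rmsf_to_bfactor",
    "rac_curve",
    "fit_frames",
]


@dataclass
class SuperposeResult:
    """Optimal proper rigid fit: x_aligned = x @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def _check_fittable(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    # rank < 2 means all points collinear (or coincident)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; fit is degenerate")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: AtomSelection | None = None,
) -> SuperposeResult:
    """Kabsch fit of ``mobile`` onto ``reference`` over ``selection``.

    Only proper rotations (det = +1) are allowed; a mirror image therefore
    retains a nonzero residual.  Returns rotation, translation and the
    minimized RMSD over the selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ids = (selection.resolved_ids if selection is not None
           else np.arange(len(mobile)))
    p = mobile[ids]
    q = reference[ids]
    _check_fittable(p)
    _check_fittable(q)
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    aligned = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - q) ** 2, axis=1))))
    return SuperposeResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_fit(frame: np.ndarray, fit: SuperposeResult) -> np.ndarray:
    return np.asarray(frame, dtype=float) @ fit.rotation.T + fit.translation


def _frame_rmsd(a: np.ndarray, b: np.ndarray, ids: np.ndarray) -> float:
    d = a[ids] - b[ids]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_sel: AtomSelection,
    calc_sel: AtomSelection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A): each frame is rigid-fit on ``fit_sel`` then the
    deviation measured on ``calc_sel`` (default: the fit selection), which
    allows e.g. backbone-atom or single-domain RMSD after a C-alpha fit."""
    calc_sel = calc_sel or fit_sel
    reference = np.asarray(reference, dtype=float)
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        fit = superpose(frame, reference, fit_sel)
        out[i] = _frame_rmsd(apply_fit(frame, fit), reference,
                             calc_sel.resolved_ids)
    return out


def fit_frames(
    traj: Trajectory,
    fit_sel: AtomSelection,
    reference: np.ndarray | None = None,
    passes: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit all frames to a common reference and return (fitted, average).

    With ``reference=None`` the reference is the iterated trajectory average:
    fit to the raw mean, re-average, refit (``passes`` rounds).  With an
    explicit reference (e.g. the crystal structure) a single fit pass is done.
    """
    frames = traj.frames
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        fitted = np.stack(
            [apply_fit(f, superpose(f, ref, fit_sel)) for f in frames]
        )
        return fitted, fitted.mean(axis=0)
    ref = frames.mean(axis=0)
    fitted = frames
    for _ in range(max(1, passes)):
        fitted = np.stack(
            [apply_fit(f, superpose(f, ref, fit_sel)) for f in frames]
        )
        ref = fitted.mean(axis=0)
    return fitted, ref


def rmsf_profile(
    traj: Trajectory,
    fit_sel: AtomSelection,
    calc_sel: AtomSelection | None = None,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom RMSF (A) over ``calc_sel`` after fitting to the average
    structure (or to ``reference`` when given): RMSF_i = sqrt(<|r_i -
    <r_i>|^2>)."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    calc_sel = calc_sel or fit_sel
    fitted, mean = fit_frames(traj, fit_sel, reference=reference)
    ids = calc_sel.resolved_ids
    dev = fitted[:, ids] - mean[ids]
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


_DEBYE_WALLER = 8.0 * np.pi**2 / 3.0


def bfactor_to_rmsf(b):
    """Debye-Waller conversion RMSF = sqrt(3 B / (8 pi^2)), B in A^2."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("B-factor must be >= 0")
    return np.sqrt(b / _DEBYE_WALLER)


def rmsf_to_bfactor(rmsf):
    """Inverse Debye-Waller conversion B = 8 pi^2 RMSF^2 / 3."""
    rmsf = np.asarray(rmsf, dtype=float)
    if np.any(rmsf < 0):
        raise ValueError("RMSF must be >= 0")
    return _DEBYE_WALLER * rmsf**2


@dataclass
class RacCurve:
    """RMS average correlation: mean RMSD of running-average structures to
    the global average, as a function of averaging-window length (frames)."""

    window_lengths: np.ndarray
    rac_values: np.ndarray


def rac_curve(
    traj: Trajectory,
    selection: AtomSelection,
    window_lengths,
    stride: int = 1,
) -> RacCurve:
    """Convergence diagnostic: for each window length w, average the fitted
    frames over every contiguous window of w frames (offset stride
    configurable, default dense), RMS-fit each running average to the global
    average over ``selection``, and report the mean of those RMSDs.  The full
    window reproduces the global average, so RAC(n_frames) = 0; on a converged
    stationary trajectory the curve decays toward zero.
    """
    window_lengths = np.asarray(window_lengths, dtype=int)
    if np.any(window_lengths < 1):
        raise ValueError("window lengths must be >= 1")
    if np.any(window_lengths > traj.n_frames):
        raise ValueError("window length exceeds trajectory length")
    fitted, global_avg = fit_frames(traj, selection)
    ids = selection.resolved_ids
    csum = np.concatenate(
        [np.zeros((1, len(ids), 3)), np.cumsum(fitted[:, ids], axis=0)]
    )
    values = np.empty(len(window_lengths))
    ref = global_avg[ids]
    for wi, w in enumerate(window_lengths):
        rmsds = []
        for start in range(0, traj.n_frames - w + 1, max(1, stride)):
            avg = (csum[start + w] - csum[start]) / w
            fit = superpose(avg, ref)
            rmsds.append(fit.rmsd)
        values[wi] = float(np.mean(rmsds))
    return RacCurve(window_lengths=window_lengths, rac_values=values)
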