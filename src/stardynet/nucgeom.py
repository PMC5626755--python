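"""RNA backbone geometry: torsions, sugar pseudorotation, eta/theta
pseudo-torsions.

Sugar pucker is described by the pseudorotation phase P and amplitude tau_m
of the five endocyclic ring torsions; the phase sector (ten 36-degree wedges)
names the pucker class (C3'-endo near P = 0-36, O4'-endo near 72-108,
C2'-endo near 144-180, ...).  The coarse backbone pseudo-torsions are
eta:   C4'(i-1) - P(i) - C4'(i) - P(i+1)
theta: P(i) - C4'(i) - P(i+1) - C4'(i+1)
and are undefined at chain termini (flagged, never zero-filled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajio import Structure

logger = logging.getLogger("stardynet")

__all__ = [
    "PuckerRecord",
    "PseudoTorsionRecord",
    "dihedral",
    "pucker_from_torsions",
    "pucker_from_structure",
    "pseudo_torsions",
    "PUCKER_CLASSES",
]

# Pseudorotation wheel: ten 36-degree sectors starting at P = 0.
PUCKER_CLASSES = [
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
]

# Endocyclic ring torsions in standard nu_0..nu_4 order (atom quadruples
# around the O4'-C1'-C2'-C3'-C4' ring).
_RING_TORSION_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
]
_RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")


@dataclass
class PuckerRecord:
    label: str
    phase_p: float        # degrees in [0, 360)
    amplitude_tau_m: float  # degrees >= 0
    pucker_class: str | None  # None when the ring is (near) planar


@dataclass
class PseudoTorsionRecord:
    label: str
    eta: float | None     # degrees in (-180, 180], None at termini
    theta: float | None


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, (-180, 180], IUPAC right-handed sign)
    of four points via the atan2 construction."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate (collinear or coincident) dihedral points")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / b2n
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def pucker_from_torsions(nu, label: str = "") -> PuckerRecord:
    """Pseudorotation phase/amplitude from five ring torsions (degrees).

    The torsions are expected in the generator convention nu_j = tau_m *
    cos(P + 144 j) (reference on the first element); the solve is the exact
    discrete-Fourier projection, which for ideal torsion sets coincides with
    the classic atan2 pseudorotation formula and acts as a least-squares fit
    otherwise.  The class is read off the 36-degree sector wheel; rings with
    amplitude below 1e-3 degrees are flagged class-undefined.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,):
        raise ValueError("need exactly five ring torsions")
    if not np.all(np.isfinite(nu)):
        raise ValueError("non-finite ring torsion")
    j = np.deg2rad(144.0 * np.arange(5))
    a = (2.0 / 5.0) * np.sum(nu * np.cos(j))
    b = -(2.0 / 5.0) * np.sum(nu * np.sin(j))
    tau_m = float(np.hypot(a, b))
    phase = float(np.degrees(np.arctan2(b, a)) % 360.0)
    if phase >= 360.0:  # guard the -0.0 % 360 == 360.0 float edge
        phase = 0.0
    if tau_m < 1e-3:
        return PuckerRecord(label, phase, tau_m, None)
    sector = int(phase // 36.0) % 10
    return PuckerRecord(label, phase, tau_m, PUCKER_CLASSES[sector])


def _residue_atoms(structure: Structure, chain: str):
    """Ordered (resseq -> {atom_name: coords}) mapping for one chain."""
    out: dict[int, dict] = {}
    for i in range(structure.n_atoms):
        if str(structure.chain_ids[i]) != chain:
            continue
        out.setdefault(int(structure.residue_seqs[i]), {})[
            str(structure.atom_names[i])
        ] = structure.coords[i]
    return dict(sorted(out.items()))


def pucker_from_structure(
    structure: Structure, chain: str
) -> list[PuckerRecord]:
    """Per-residue pucker for every residue of ``chain`` carrying a complete
    O4'-C1'-C2'-C3'-C4' ring; incomplete residues are skipped with a
    warning.

    Measured standard nu_0..nu_4 are reordered to (nu2, nu3, nu4, nu0, nu1)
    before the solve, so the reported phase follows the standard
    (Altona-Sundaralingam-style, nu2-referenced) wheel while staying exactly
    consistent with the synthetic torsion generator.
    """
    records = []
    for resseq, atoms in _residue_atoms(structure, chain).items():
        missing = [a for a in _RING_ATOMS if a not in atoms]
        label = f"{chain}:{resseq}"
        if missing:
            logger.warning(
                "residue %s missing ring atom(s) %s; skipped",
                label, ",".join(missing),
            )
            continue
        nu_std = [
            dihedral(atoms[a], atoms[b], atoms[c], atoms[d])
            for a, b, c, d in _RING_TORSION_ATOMS
        ]
        nu = [nu_std[2], nu_std[3], nu_std[4], nu_std[0], nu_std[1]]
        records.append(pucker_from_torsions(nu, label=label))
    return records


def pseudo_torsions(
    structure: Structure, chain: str
) -> list[PseudoTorsionRecord]:
    """eta/theta pseudo-torsions per nucleotide of ``chain``.

    eta(i) needs C4'(i-1), P(i), C4'(i), P(i+1); theta(i) needs P(i),
    C4'(i), P(i+1), C4'(i+1).  Records at termini (or next to residues
    missing P/C4') carry None for the affected angle.
    """
    residues = _residue_atoms(structure, chain)
    seqs = list(residues.keys())
    if len(seqs) < 3:
        raise ValueError("pseudo-torsions need at least 3 nucleotides")

    def atom(resseq, name):
        r = residues.get(resseq)
        return None if r is None else r.get(name)

    records = []
    for i in seqs:
        eta = theta = None
        quad = (atom(i - 1, "C4'"), atom(i, "P"), atom(i, "C4'"),
                atom(i + 1, "P"))
        if all(q is not None for q in quad):
            eta = dihedral(*quad)
        quad = (atom(i, "P"), atom(i, "C4'"), atom(i + 1, "P"),
                atom(i + 1, "C4'"))
        if all(q is not None for q in quad):
            theta = dihedral(*quad)
        records.append(PseudoTorsionRecord(f"{chain}:{i}", eta, theta))
    return records


def display_angle(angle: float) -> float:
    """Map an angle from (-180, 180] to [0, 360) for conventional eta-theta
    plot axes (display-only transform)."""
    return angle % 360.0
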