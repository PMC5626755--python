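"""Contact maps, native-contact metrics Q/Qs, contact counts, protein-RNA
interface occupancy, and Shrake-Rupley SASA.

Distance criteria are closed (<=) everywhere.  Native contacts follow the
C-alpha convention: two residues are natively in contact when their C-alpha
atoms lie within the cutoff (8 A by default) in the reference (crystal)
structure, excluding pairs closer in sequence than the exclusion (2 residues
by default).  Q is the fraction of native pairs within the cutoff in a frame;
Qs replaces the step by a Gaussian penalty on the deviation from the native
distance, with a residue-separation-dependent width sigma_ij =
(1 + |i - j|)^0.15 A (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .constants import VDW_RADII
from .trajio import AtomSelection, Structure, Trajectory

__all__ = [
    "NativeContactSet",
    "OccupancyTable",
    "native_contacts",
    "q_series",
    "contact_count_series",
    "interface_occupancy",
    "sasa",
    "qs_sigma",
]


@dataclass
class NativeContactSet:
    """Native pairs (atom ids, i < j), their reference distances, and the
    defining cutoff/exclusion."""

    pairs: np.ndarray           # (N, 2) atom ids
    native_distances: np.ndarray  # (N,) A
    residue_separation: np.ndarray  # (N,) |resseq_i - resseq_j|
    cutoff: float
    exclusion: int

    def __len__(self) -> int:
        return len(self.pairs)


def qs_sigma(residue_separation) -> np.ndarray:
    """Width of the Qs Gaussian penalty: sigma_ij = (1 + |i-j|)^0.15 A."""
    return (1.0 + np.asarray(residue_separation, dtype=float)) ** 0.15


def native_contacts(
    reference: Structure,
    selection: AtomSelection,
    cutoff: float = 8.0,
    exclusion: int = 2,
) -> NativeContactSet:
    """All selected-atom pairs within ``cutoff`` in the reference structure
    whose residue separation exceeds ``exclusion``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ids = selection.resolved_ids
    if len(ids) == 0:
        raise ValueError("empty selection for native contacts")
    coords = reference.coords[ids]
    resseq = reference.residue_seqs[ids]
    chains = reference.chain_ids[ids]
    d = cdist(coords, coords)
    iu, ju = np.triu_indices(len(ids), k=1)
    same_chain = chains[iu] == chains[ju]
    sep = np.abs(resseq[iu] - resseq[ju])
    keep = (d[iu, ju] <= cutoff) & (~same_chain | (sep > exclusion))
    return NativeContactSet(
        pairs=np.column_stack([ids[iu[keep]], ids[ju[keep]]]),
        native_distances=d[iu, ju][keep],
        residue_separation=sep[keep],
        cutoff=cutoff,
        exclusion=exclusion,
    )


def q_series(
    traj: Trajectory,
    native: NativeContactSet,
    sigma: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (Q, Qs).

    Q = (1/N) sum 1[r_ij <= cutoff]; Qs = (1/N) sum exp(-(r_ij - r0_ij)^2 /
    (2 sigma_ij^2)).  Both are 1 on the reference frame and fall toward 0 as
    the native pairs stretch.
    """
    if len(native) == 0:
        raise ValueError("native contact set is empty")
    sig = qs_sigma(native.residue_separation) if sigma is None else sigma
    i, j = native.pairs[:, 0], native.pairs[:, 1]
    d = np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=2)
    q = np.mean(d <= native.cutoff, axis=1)
    dev = d - native.native_distances
    qs = np.mean(np.exp(-(dev**2) / (2.0 * sig**2)), axis=1)
    return q, qs


def contact_count_series(
    traj: Trajectory,
    selection_a: AtomSelection,
    selection_b: AtomSelection,
    cutoff: float = 6.0,
    exclusion: int = 2,
) -> np.ndarray:
    """Per-frame count of atom pairs between the two selections within
    ``cutoff``, excluding same-chain pairs with residue separation <=
    ``exclusion``.  When the selections overlap, each pair is counted once
    (i < j); the result is symmetric in selection order."""
    ia, ib = selection_a.resolved_ids, selection_b.resolved_ids
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("contact selections must be non-empty")
    top = traj.topology
    pair_i, pair_j = np.meshgrid(ia, ib, indexing="ij")
    pair_i, pair_j = pair_i.ravel(), pair_j.ravel()
    mask = pair_i != pair_j
    lo = np.minimum(pair_i[mask], pair_j[mask])
    hi = np.maximum(pair_i[mask], pair_j[mask])
    # each unordered pair counted once even when the selections overlap
    uniq = np.unique(lo.astype(np.int64) * top.n_atoms + hi)
    pair_i, pair_j = uniq // top.n_atoms, uniq % top.n_atoms
    same_chain = top.chain_ids[pair_i] == top.chain_ids[pair_j]
    sep = np.abs(top.residue_seqs[pair_i] - top.residue_seqs[pair_j])
    ok = ~same_chain | (sep > exclusion)
    pair_i, pair_j = pair_i[ok], pair_j[ok]
    d = np.linalg.norm(traj.frames[:, pair_i] - traj.frames[:, pair_j], axis=2)
    return (d <= cutoff).sum(axis=1)


@dataclass
class OccupancyTable:
    """Per-frame presence and time-averaged occupancy of labeled group
    pairs, e.g. "U6-Q193" nucleotide-residue interactions."""

    labels: list
    presence: np.ndarray   # (n_pairs, n_frames) bool
    occupancy: np.ndarray  # (n_pairs,)
    flagged: np.ndarray    # occupancy >= threshold
    threshold: float


def interface_occupancy(
    traj: Trajectory,
    pairs: list,
    cutoff: float = 4.5,
    threshold: float = 0.75,
) -> OccupancyTable:
    """Occupancy of labeled atom-group pairs.

    ``pairs`` is a list of (label, ids_a, ids_b); a pair is present in a
    frame when any cross-group atom distance is <= cutoff, and flagged when
    its presence fraction is >= threshold (default 75% of frames, the
    persistent-interaction criterion).
    """
    labels = [p[0] for p in pairs]
    presence = np.zeros((len(pairs), traj.n_frames), dtype=bool)
    for k, (_, ids_a, ids_b) in enumerate(pairs):
        ids_a = np.asarray(ids_a, dtype=int)
        ids_b = np.asarray(ids_b, dtype=int)
        if len(ids_a) == 0 or len(ids_b) == 0:
            raise ValueError(f"pair {labels[k]!r} resolves to an empty group")
        for f in range(traj.n_frames):
            d = cdist(traj.frames[f, ids_a], traj.frames[f, ids_b])
            presence[k, f] = bool(d.min() <= cutoff)
    occ = presence.mean(axis=1)
    return OccupancyTable(
        labels=labels,
        presence=presence,
        occupancy=occ,
        flagged=occ >= threshold,
        threshold=threshold,
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's accessible sphere (vdW radius + probe) is sampled with
    ``n_points`` deterministic quasi-uniform points; a point is accessible if
    it lies outside every other atom's accessible sphere.  Returns per-atom
    SASA (A^2) and a per-residue dict keyed by (chain, resseq) summing its
    atoms.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    try:
        r = np.array(
            [table[str(e).capitalize()] for e in structure.elements]
        )
    except KeyError:
        for i, e in enumerate(structure.elements):
            if str(e).capitalize() not in table:
                raise ValueError(
                    f"no radius for element {e!r} "
                    f"(atom {structure.atom_names[i]!r})"
                ) from None
        raise
    r_acc = r + probe_radius
    coords = structure.coords
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * r_acc.max()
    areas = np.empty(structure.n_atoms)
    tol = 1e-9
    for i in range(structure.n_atoms):
        pts = coords[i] + r_acc[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            # boundary ties (point exactly on a neighbour sphere) break by
            # atom index so coincident atoms occlude deterministically
            buried = d < r_acc[j] - tol
            if j < i:
                buried |= np.abs(d - r_acc[j]) <= tol
            accessible &= ~buried
        areas[i] = accessible.mean() * 4.0 * np.pi * r_acc[i] ** 2
    per_residue: dict = {}
    for i in range(structure.n_atoms):
        key = (str(structure.chain_ids[i]), int(structure.residue_seqs[i]))
        per_residue[key] = per_residue.get(key, 0.0) + float(areas[i])
    return areas, per_residue
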