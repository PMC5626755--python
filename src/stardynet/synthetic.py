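"""Synthetic inputs with planted, analytically known structure.

This module stands in for the molecular-dynamics stage: it produces (a)
stationary Gaussian ensembles of a structure with a planted covariance, (b)
Metropolis-sampled umbrella windows from analytic 1D potentials (with an
optional conditional auxiliary coordinate for 2D free-energy tests), (c)
furanose ring torsion sets at prescribed pseudorotation phase/amplitude, and
(d) a toy two-segment protein plus single-stranded RNA complex emulating a
KH-QUA2/mRNA architecture.  Everything is deterministic given its seed, so
downstream analyses can be validated by recovering the planted quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL_MOL_K
from .trajio import Structure, Trajectory
from .wham import UmbrellaDataset, UmbrellaWindow

logger = logging.getLogger("stardynet")

__all__ = [
    "EnsembleSpec",
    "PotentialSpec",
    "UmbrellaWindowSpec",
    "sample_harmonic_ensemble",
    "sample_umbrella_windows",
    "make_pucker_torsions",
    "build_toy_complex",
    "build_pn_backbone",
    "paper_window_layout",
]


@dataclass
class EnsembleSpec:
    """A Gaussian ensemble around a mean structure.

    ``covariance`` is either a full symmetric PSD (3n, 3n) matrix in A^2 or a
    length-n vector of per-atom isotropic per-coordinate variances.
    """

    mean_structure: Structure
    covariance: np.ndarray
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass
class PotentialSpec:
    """An analytic 1D potential on the reaction coordinate, kcal/mol over A.

    Forms: "flat"; "harmonic" (params k, x0: U = 1/2 k (x-x0)^2);
    "double_well" (params a, x0, x1: U = a (x-x0)^2 (x-x1)^2); "tabulated"
    (params x, u arrays, linear interpolation, clamped ends).
    """

    form: str
    params: dict
    temperature: float = 300.0

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            return 0.5 * p["k"] * (x - p["x0"]) ** 2
        if self.form == "double_well":
            return p["a"] * (x - p["x0"]) ** 2 * (x - p["x1"]) ** 2
        if self.form == "tabulated":
            return np.interp(x, p["x"], p["u"])
        raise ValueError(f"unknown potential form {self.form!r}")


@dataclass
class UmbrellaWindowSpec:
    """Sampling request for one harmonic window."""

    center: float
    force_constant: float
    n_samples: int = 20000
    burn_in: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if not self.n_samples > self.burn_in >= 0:
            raise ValueError("need n_samples > burn_in >= 0")


def sample_harmonic_ensemble(spec: EnsembleSpec) -> Trajectory:
    """Draw frames = mean + multivariate-normal displacements.

    For a full covariance the displacement is built from the symmetric
    eigendecomposition (eigenvalues clipped at zero after a PSD check), so any
    planted PSD matrix, including rank-deficient ones, is honoured exactly.
    """
    mean = spec.mean_structure.coords
    n = spec.mean_structure.n_atoms
    rng = np.random.default_rng(spec.seed)
    cov = spec.covariance
    if cov.ndim == 1:
        if len(cov) != n:
            raise ValueError("per-atom variance vector has wrong length")
        if np.any(cov < 0):
            raise ValueError("variances must be >= 0")
        disp = rng.standard_normal((spec.n_frames, n, 3))
        disp *= np.sqrt(cov)[None, :, None]
    elif cov.shape == (3 * n, 3 * n):
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        evals, evecs = np.linalg.eigh(cov)
        if evals.min() < -1e-8 * max(1.0, evals.max()):
            raise ValueError(
                f"covariance is not PSD (smallest eigenvalue {evals.min():.3e})"
            )
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        z = rng.standard_normal((spec.n_frames, 3 * n))
        disp = (z @ root.T).reshape(spec.n_frames, n, 3)
    else:
        raise ValueError(
            f"covariance must be (n,) or (3n, 3n); got {cov.shape}"
        )
    frames = mean[None, :, :] + disp
    return Trajectory(topology=spec.mean_structure, frames=frames)


# --------------------------------------------------------------------------
# Umbrella-window Metropolis sampler
# --------------------------------------------------------------------------

def _metropolis_window(
    potential: PotentialSpec,
    window: UmbrellaWindowSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-particle Metropolis chain for exp(-[U(x)+bias]/kT).

    The uniform proposal width is auto-tuned toward 30-50% acceptance during
    burn-in and then frozen, so only the stationary distribution matters.
    """
    kt = KB_KCAL_MOL_K * potential.temperature

    def total(x):
        return (float(potential.energy(x))
                + 0.5 * window.force_constant * (x - window.center) ** 2)

    k_eff = max(window.force_constant, 1e-3)
    width = 2.0 * np.sqrt(kt / k_eff)
    x = window.center
    ux = total(x)
    samples = np.empty(window.n_samples - window.burn_in)
    accepted_recent = 0
    accepted_total = 0
    kept = 0
    for step in range(window.n_samples):
        prop = x + width * (2.0 * rng.random() - 1.0)
        uprop = total(prop)
        if uprop <= ux or rng.random() < np.exp(-(uprop - ux) / kt):
            x, ux = prop, uprop
            accepted_recent += 1
            accepted_total += 1
        if step < window.burn_in and (step + 1) % 100 == 0:
            rate = accepted_recent / 100.0
            if rate < 0.30:
                width *= 0.8
            elif rate > 0.50:
                width *= 1.25
            accepted_recent = 0
        if step >= window.burn_in:
            samples[kept] = x
            kept += 1
    rate = accepted_total / window.n_samples
    if not 0.05 <= rate <= 0.95:
        logger.warning(
            "window at %.3f A: Metropolis acceptance rate %.2f outside "
            "[0.05, 0.95]", window.center, rate,
        )
    return samples


def sample_umbrella_windows(
    potential: PotentialSpec,
    windows: list[UmbrellaWindowSpec],
    aux_law: tuple | None = None,
) -> UmbrellaDataset:
    """Metropolis-sample every window of a harmonic umbrella layout.

    Each window holds samples from exp(-[U(x) + 1/2 k (x-x0)^2]/kT) after the
    burn-in discard.  If ``aux_law = (m, s)`` is given (m a constant or a
    callable of x, s > 0), an auxiliary coordinate y | x ~ Normal(m(x), s^2)
    is emitted per sample for 2D free-energy tests; it emulates an unbiased
    second coordinate recorded alongside the biased one.
    """
    if not windows:
        raise ValueError("no windows requested")
    out = []
    for w in windows:
        rng = np.random.default_rng(w.seed)
        x = _metropolis_window(potential, w, rng)
        y = None
        if aux_law is not None:
            m, s = aux_law
            mean = m(x) if callable(m) else np.full_like(x, float(m))
            y = mean + s * rng.standard_normal(len(x))
        out.append(
            UmbrellaWindow(
                center=w.center,
                force_constant=w.force_constant,
                samples_x=x,
                samples_y=y,
            )
        )
    return UmbrellaDataset(out, temperature=potential.temperature)


def paper_window_layout(
    n_samples: int = 20000,
    burn_in: int = 2000,
    force_constant: float = 5.0,
    seed: int = 0,
) -> list[UmbrellaWindowSpec]:
    """The umbrella layout used for the mRNA-unbinding study: 15 windows,
    centers every 0.5 A from 10.5 to 15 A then every 1 A up to 20 A, elastic
    constant 5 kcal/mol/A^2 in every window."""
    centers = np.concatenate(
        [np.arange(10.5, 15.0 + 1e-9, 0.5), np.arange(16.0, 20.0 + 1e-9, 1.0)]
    )
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(centers)) % (2**31)
    return [
        UmbrellaWindowSpec(
            center=float(c),
            force_constant=force_constant,
            n_samples=n_samples,
            burn_in=burn_in,
            seed=int(s),
        )
        for c, s in zip(centers, child_seeds)
    ]


# --------------------------------------------------------------------------
# Pucker torsions and backbone builders
# --------------------------------------------------------------------------

def make_pucker_torsions(phase_p: float, amplitude_tau_m: float) -> np.ndarray:
    """Five endocyclic torsions nu_0..nu_4 (degrees) at pseudorotation phase
    P and amplitude tau_m: nu_j = tau_m * cos(P + 144 j).

    The reference torsion of this convention is nu_0; in the standard
    Altona-Sundaralingam labelling (reference on nu_2, the C1'-C2'-C3'-C4'
    torsion) the emitted sequence corresponds to (nu2, nu3, nu4, nu0, nu1).
    """
    if amplitude_tau_m < 0:
        raise ValueError("amplitude must be >= 0")
    j = np.arange(5)
    return amplitude_tau_m * np.cos(np.deg2rad(phase_p + 144.0 * j))


def build_toy_complex(seed: int = 0) -> Structure:
    """A C-alpha-resolution two-segment "protein" (two helices + linker, 30
    residues, author numbering 69-98) docked against a 7-nucleotide RNA chain
    carrying P, O5', C4' and N1/N9 pseudo-atoms, with at least three protein
    C-alpha within 4.5 A of RNA atoms.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)

    def helix(n, origin, phase=0.0):
        i = np.arange(n)
        ang = np.deg2rad(100.0 * i + phase)
        return np.column_stack(
            [2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i]
        ) + origin

    h1 = helix(12, np.zeros(3))
    linker_start = h1[-1]
    linker = linker_start + np.outer(np.arange(1, 7),
                                     np.array([2.2, 0.0, 3.1]))
    h2 = helix(12, linker[-1] + np.array([0.0, 0.0, 3.5]), phase=40.0)
    protein_coords = np.vstack([h1, linker, h2])
    protein_coords += 0.05 * rng.standard_normal(protein_coords.shape)

    protein_resnames = [
        "ALA", "ARG", "ASN", "GLY", "LYS", "LEU", "VAL", "GLU", "PHE", "SER",
        "ARG", "GLY", "ASN", "GLN", "LYS", "ILE", "THR", "ALA", "LYS", "ARG",
        "GLY", "LEU", "GLN", "VAL", "ASN", "ARG", "SER", "LYS", "GLU", "ALA",
    ]

    rna_seq = ["A", "C", "U", "A", "A", "C", "A"]
    rna_records = []  # (name, resseq, resname, coords, element, mass key)
    for jnt, base in enumerate(rna_seq):
        z = 1.0 + 2.6 * jnt
        p = np.array([5.8, 0.6, z])
        o5 = np.array([6.4, 1.4, z + 0.8])
        c4 = np.array([5.5, -0.5, z + 1.2])
        nbase = np.array([3.9, 0.3, z + 0.5])
        base_atom = "N9" if base in ("A", "G") else "N1"
        for name, xyz, elem in [
            ("P", p, "P"), ("O5'", o5, "O"), ("C4'", c4, "C"),
            (base_atom, nbase, "N"),
        ]:
            rna_records.append((name, jnt + 1, base, xyz, elem))

    names = ["CA"] * 30 + [r[0] for r in rna_records]
    resseqs = list(range(69, 99)) + [r[1] for r in rna_records]
    resnames = protein_resnames + [r[2] for r in rna_records]
    chains = ["A"] * 30 + ["B"] * len(rna_records)
    coords = np.vstack([protein_coords] + [r[3] for r in rna_records])
    coords[30:] += 0.03 * rng.standard_normal((len(rna_records), 3))
    elements = ["C"] * 30 + [r[4] for r in rna_records]
    from .constants import ATOMIC_MASSES

    masses = [ATOMIC_MASSES[e.upper()] for e in elements]
    return Structure(
        atom_names=names,
        residue_seqs=resseqs,
        residue_names=resnames,
        chain_ids=chains,
        elements=elements,
        coords=coords,
        bfactors=np.zeros(len(names)),
        occupancies=np.ones(len(names)),
        masses=masses,
    )


def _nerf_place(a, b, c, bond: float, angle_deg: float,
                torsion_deg: float) -> np.ndarray:
    """Place atom d so |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d)
    = torsion (natural-extension reference frame construction)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion),
         np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n

def build_pn_backbone(
    eta: float,
    theta: float,
    n_residues: int = 6,
    bond: float = 3.85,
    angle: float = 105.0,
) -> Structure:
    """A virtual P/C4' backbone chain with every eta pseudo-torsion set to
    ``eta`` and every theta to ``theta`` (degrees), built by sequential
    internal-coordinate placement.  Useful as a build-measure round-trip
    fixture for the pseudo-torsion analysis."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([bond, 0.0, 0.0]),
    ]
    ang = np.deg2rad(angle)
    coords.append(coords[1] + bond * np.array([-np.cos(ang), np.sin(ang), 0.0]))
    torsions = [theta, eta]  # alternating, starting with theta(1)
    k = 0
    while len(coords) < 2 * n_residues:
        tor = torsions[k % 2]
        coords.append(
            _nerf_place(coords[-3], coords[-2], coords[-1], bond, angle, tor)
        )
        k += 1
    names, resseqs, elements = [], [], []
    for i in range(n_residues):
        names += ["P", "C4'"]
        resseqs += [i + 1, i + 1]
        elements += ["P", "C"]
    from .constants import ATOMIC_MASSES

    n_atoms = 2 * n_residues
    return Structure(
        atom_names=names,
        residue_seqs=resseqs,
        residue_names=["U"] * n_atoms,
        chain_ids=["R"] * n_atoms,
        elements=elements,
        coords=np.vstack(coords),
        bfactors=np.zeros(n_atoms),
        occupancies=np.ones(n_atoms),
        masses=[ATOMIC_MASSES[e.upper()] for e in elements],
    )
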