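# Methods

This note documents the models, conventions and numerical choices behind
`stardynet`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Coordinates, selections, IO

Internally atoms are indexed 0-based and densely; author residue numbering
from the PDB (e.g. 69–204 for a KH–QUA2 construct) is carried as data and
never used as an array index. The PDB reader covers the
ATOM/HETATM/MODEL/ENDMDL subset: missing occupancy/B-factor default to
1.0/0.0, elements are inferred from the atom name when columns 77–78 are
blank, masses come from a standard element table, and alternate locations
keep the highest-occupancy record (ties: first encountered). DCD IO is
delegated to MDAnalysis.

The selection mini-language supports `name`, `resname`, `chain`, `element`,
`resid` (values and `a to b` ranges), `protein`, `nucleic`, `all`, boolean
`and/or/not` with parentheses, and `within R of <sel>`. `within` is a
*closed* ball (≤ R) evaluated on one designated reference frame — by default
the structure's own (crystal) coordinates, matching how interface
neighbourhoods such as "Cα within 5.0 Å of mRNA" are defined. Distance
criteria are closed (≤) throughout the package. There is no
periodic-boundary handling: analyses assume a whole, already-imaged solute.

## Fluctuation statistics

Superposition is the Kabsch least-squares rigid fit restricted to proper
rotations (det R = +1), so mirror images retain a residual. RMSD series fit
each frame on a fit selection and measure on a possibly different
calculation selection (domain-wise RMSD). RMSF uses an iterated-average
reference: fitting to "the average structure" is circular, so frames are
fit to the raw mean, re-averaged and refit (two passes, which stabilises the
reference on stationary ensembles); a crystal-reference fit is available as
an option. The Debye–Waller conversion RMSF = √(3B/8π²) and its inverse are
exact formulas.

RAC (RMS average correlation) computes, for each window length w, running
averages over all contiguous w-frame windows (dense offsets by default, a
stride for speed), RMS-fits each running average to the global average over
the selection and reports the mean RMSD. RAC(n_frames) is identically 0,
and on an i.i.d. ensemble RAC ∝ 1/√w; on converged trajectories the slope
approaches zero.

## Native contacts and SASA

Native contacts are Cα pairs within the cutoff (default 8.0 Å) in the
reference structure, excluding same-chain pairs with residue separation
≤ 2. Q re-evaluates membership at the same cutoff (the simplest reading of
the definition); Qs applies a Gaussian penalty on the deviation from the
native distance with width σ_ij = (1+|i−j|)^0.15 Å, the
separation-dependent width used by standard native-similarity
implementations (the width formula is configurable). Contact counting uses
a 6.0 Å cutoff by default and counts each unordered pair once even for
overlapping selections. Interface occupancy marks a labeled group pair
present in a frame when any cross-group distance is ≤ 4.5 Å and flags pairs
present in ≥ 75% of frames.

SASA is Shrake–Rupley with deterministic golden-spiral sphere points
(default 960), element radii C 1.70, N 1.55, O 1.52, P 1.80, S 1.80,
H 1.20 Å and probe 1.4 Å. Points falling exactly on a neighbour's
accessible sphere (within 10⁻⁹ Å) are resolved by atom index so coincident
atoms occlude deterministically.

## DCCM and PCA

C_ij uses full 3D displacement dot products (not per-axis correlations)
after an optional rigid fit to the iterated average. Frames from several
runs are pooled before the mean and covariance are formed (per-run
averaging would be an alternative; pooling is the default because the
quantities are defined over "all conformations"). Zero-variance nodes get
diagonal 1 and zero off-diagonals with a warning. PCA diagonalises the
3n×3n covariance of fitted coordinates; eigenvector signs are fixed by
making each mode's largest-magnitude component positive so outputs are
deterministic; per-mode projection variance equals the eigenvalue exactly.

## Dynamical network

Nodes: one per amino-acid residue anchored at Cα; two per nucleotide — a
base node anchored at N1 (pyrimidines) or N9 (purines) owning the base-ring
atoms, and a sugar–phosphate node anchored at P owning sugar + phosphate
atoms. Node–node contact is evaluated over all heavy atoms of the
represented component (anchors only define positions for the correlation
matrix and labels), because 4.5 Å is a heavy-atom contact scale. Neighbour
exclusion removes same-residue pairs (the glycosidic base–sugar pair) and
adjacent residues of the same chain. An edge is kept when contact occupancy
is ≥ 0.75, with weight w = −log|C_ij| (|C| floored at 10⁻⁶) so strong
correlation means short network distance; the linear 1−|C| alternative is
available. The correlation matrix defaults to the DCCM of node-anchor
displacements.

Shortest paths use Floyd–Warshall (scipy csgraph); CPL is the mean over
connected unordered pairs, with unreachable pairs excluded and counted —
the treatment of disconnection is a package choice, reported explicitly.
Girvan–Newman removes maximum weighted-edge-betweenness edges until none
remain, breaking ties on the lexicographically smallest edge label; the
reported partition maximises modularity (evaluated unweighted on the
original edge set) over the removal sequence, since a stopping level is not
otherwise defined. ΔCPL scans remove either all edges incident to a node
(edge removal; the isolated node is excluded from pair averaging) or the
node itself; ΔCPL is the difference of mean shortest-path lengths over the
pairs connected in both graphs, with per-node disconnection counts.

## Umbrella sampling and WHAM

The bias is ½k(x−x₀)² with k the elastic constant as given (the sampler and
the estimator share this convention by construction; a k(x−x₀)² toggle
exists for cross-checking against other codes). The reference window layout
is 15 windows — centers every 0.5 Å from 10.5 to 15 Å, then every 1 Å to
20 Å — with k = 5 kcal/mol/Å² and T = 300 K; k_B = 0.0019872041 kcal/mol/K
everywhere.

1D WHAM iterates the standard self-consistent equations on a 1000-bin
histogram until the largest window-offset change is below 10⁻⁴ kcal/mol
(non-convergence raises, with the residual). Empty bins are reported as
NaN, never interpolated, and the defined minimum is anchored to exactly 0.
For 2D profiles the second coordinate is unbiased, so the offsets are
converged on the biased-axis marginal and reused to unbias the 2D
histogram; "500 bins" is interpreted as the biased-axis count with an
independent y-axis count (default 100). This construction makes the
Boltzmann y-marginal of the 2D profile consistent with the 1D profile on
shared binning by design, which is tested.

Bootstrap errors use a moving-block bootstrap within each window (block
length defaults to √n to respect autocorrelation; a block length equal to
the series length reproduces the data exactly and yields zero error), rerun
WHAM per replicate on shared binning, re-anchor each replicate at its own
minimum and report the per-bin standard deviation.

## RNA geometry

Dihedrals use the atan2 construction with the IUPAC right-handed sign
convention, verified against independent float64 vector-algebra and
library oracles. Pseudorotation follows the Altona–Sundaralingam picture
(144° torsion spacing, amplitude referenced to ν2 = C1'-C2'-C3'-C4'); the
synthetic generator emits torsions as ν_j = τ_m cos(P + 144°j) with the
reference on its first element, which corresponds to the standard sequence
(ν2, ν3, ν4, ν0, ν1) — the structure analyzer measures the standard ring
torsions and reorders them accordingly, so structure-derived phases follow
the standard wheel while the generator→analyzer round trip is exact. The
phase/amplitude solve is the discrete-Fourier projection of the five
torsions, identical to the classic atan2 formula for ideal sets and a
least-squares fit for real (slightly non-cosine) rings. Classes are the ten
36° sectors (C3'-endo = [0°, 36°), O4'-endo = [72°, 108°), C2'-endo =
[144°, 180°), …); amplitudes below 10⁻³ degrees leave the class undefined.
Cross-software phase offsets of up to one sector near boundaries are a
known caveat between analysis tools. η/θ pseudo-torsions follow the printed
atom quadruples and are flagged (None), not zero-filled, at chain termini.

## Synthetic data: what it does and does not emulate

`sample_harmonic_ensemble` draws i.i.d. multivariate-normal displacements
about a mean structure with a planted covariance (full 3n×3n PSD or
per-atom isotropic). It emulates a *stationary, equilibrated* fluctuating
ensemble with known second moments — not kinetics, anharmonicity,
conformational transitions or solvent effects. Passing recovery tests
therefore demonstrates correctness of the estimators, not realism of any
force field.

`sample_umbrella_windows` runs a single-particle Metropolis chain per
window on U(x) + bias with a uniform proposal auto-tuned to 30–50%
acceptance during burn-in and frozen afterwards; only the stationary
distribution is meaningful, not the dynamics. Acceptance rates outside
[0.05, 0.95] are warned about. The optional auxiliary coordinate follows a
stated conditional law y|x ~ N(m(x), s²); the real analogue (an RMSD to
the crystal recorded per window) need not be unimodal, so this is a
stand-in for testing the 2D estimator, stated as such.

`build_toy_complex` produces a Cα-resolution two-helix + linker "protein"
(30 residues, author numbering 69–98) docked against a 7-nucleotide RNA
carrying P, O5', C4' and N1/N9 pseudo-atoms, with at least three Cα within
4.5 Å of RNA atoms by construction. It reproduces the *architecture* the
network and interface analyses need (two protein segments, a two-node-per-
nucleotide RNA, a contact interface), not real geometry; its network is
deliberately sparse, so demo community output contains many singletons.
`build_pn_backbone` places a virtual P/C4' chain at prescribed (η, θ) by
internal-coordinate (NeRF) construction for build–measure round trips.

## Problem sizes and defaults

Analysis defaults are the protocol values throughout (8.0 Å/exclusion-2
native contacts, 6.0 Å counts, 4.5 Å/75% edges, 1000/500 WHAM bins at
10⁻⁴, 300 K, k = 5 kcal/mol/Å²). Validation runs use 20,000 post-burn-in
samples per umbrella window for the 1D recovery, 5·10⁴ frames for the
60-node DCCM recovery, and 2,000 frames for fluctuation closed forms; the
demo pipeline uses 600 ensemble frames and 3,500 post-burn-in samples per
window, sizes chosen so the whole pipeline runs in seconds on one CPU while
leaving Monte-Carlo errors well inside the tested tolerances.

## Known limitations

- No periodic boundaries, no solvent, no PSF/parameter topology support.
- Q/Qs and contact metrics are Cα/heavy-atom geometric criteria only; no
  hydrogen-bond geometry.
- SASA is single-structure (iterate over frames for trajectory statistics).
- WHAM provides PMFs, not binding free energies; no restraint corrections,
  no MBAR.
- The pseudorotation sector boundaries differ by up to one sector across
  analysis software near edges.
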