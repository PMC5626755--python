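# stardynet

Trajectory statistics, correlation-weighted dynamical networks and WHAM
free-energy reconstruction for protein–RNA complexes.

`stardynet` packages the post-processing pipeline used to study how
STAR-family RNA-binding proteins (the KH–QUA2 fragment of Quaking-type
proteins) recognise and release short single-stranded mRNA: deviation and
fluctuation statistics of the simulated ensemble, native-contact metrics,
essential dynamics, allosteric network analysis, umbrella-sampling
free-energy profiles of mRNA unbinding, and RNA backbone geometry. It is
aimed at structural-bioinformatics users who have coordinate ensembles
(DCD or multi-model PDB) of a protein–nucleic-acid complex and want the
full analysis chain behind one tested API and CLI.

Because real microsecond trajectories are large and rarely deposited, the
package ships a synthetic-data module that generates every input with
*planted, analytically known* structure — Gaussian ensembles with prescribed
covariance, Metropolis-sampled umbrella windows from known potentials,
furanose torsions at prescribed pucker — so each stage is validated by
recovering what was planted.

## What it computes

**Fluctuations** (`stardynet.fluct`) — Kabsch superposition; per-frame RMSD
and per-atom RMSF (fit to the iterated average structure); the
Debye–Waller conversion RMSF = √(3B/8π²) between crystallographic
B-factors and fluctuation amplitudes; and the RMS average correlation (RAC)
convergence diagnostic: the mean RMSD of running-average structures to the
global average as a function of averaging-window length.

**Contacts** (`stardynet.contacts`) — native contacts between Cα atoms
within 8.0 Å (excluding the two sequence neighbours); the fraction of
native contacts Q = ⟨1[r_ij ≤ c]⟩ and the Gaussian-penalised similarity
Qs = ⟨exp(−(r_ij − r⁰_ij)²/2σ²_ij)⟩ with σ_ij = (1+|i−j|)^0.15 Å; 6.0 Å
contact counts split by domain; interface-occupancy time series with the
75%-of-frames persistence flag; Shrake–Rupley SASA.

**Essential dynamics** (`stardynet.essential_dynamics`) — the dynamic
cross-correlation map C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩^½⟨Δr_j²⟩^½) over full 3D
displacements, and PCA of the 3n Cα-coordinate covariance with per-mode
projections.

**Networks** (`stardynet.network`) — nodes are protein residues (Cα anchor)
and two nodes per nucleotide (base anchored at N1/N9, sugar–phosphate at P);
edges connect non-neighbouring nodes in heavy-atom contact within 4.5 Å for
≥ 75% of frames, weighted w_ij = −log|C_ij|. On this graph: Floyd–Warshall
shortest paths and the characteristic path length (CPL), Girvan–Newman
communities at maximum modularity, and ΔCPL node/edge-removal perturbation
scans.

**WHAM** (`stardynet.wham`) — self-consistent 1D WHAM (1000 bins, offset
tolerance 10⁻⁴ kcal/mol, 300 K) over harmonic umbrella windows
(½k(x−x₀)², k = 5 kcal/mol/Å² in the reference layout of 15 windows from
10.5 to 20 Å); 2D WHAM over the biased coordinate plus an unbiased auxiliary
coordinate; Monte-Carlo block-bootstrap error bars.

**RNA geometry** (`stardynet.nucgeom`) — signed dihedrals, sugar
pseudorotation phase/amplitude (P, τ_m) with the ten-sector pucker
classification (C3'-endo, C2'-endo, O4'-endo, …), and the η/θ backbone
pseudo-torsions η: C4'(i−1)–P(i)–C4'(i)–P(i+1),
θ: P(i)–C4'(i)–P(i+1)–C4'(i+1).

## Worked example

Run the full pipeline on the synthetic toy complex:

```sh
stardynet demo --seed 7 --outdir demo_out
```

This builds a 30-residue two-helix "protein" bound to a 7-nucleotide RNA,
samples a 600-frame Gaussian ensemble with a planted two-block covariance,
runs every analysis stage, then Metropolis-samples the 15-window umbrella
layout over the known test potential U(x) = ½·2.0·(x−14)² kcal/mol and
reconstructs its PMF. `demo_out/summary.txt` ends with:

```
frames=600
mean_rmsd_A=0.362453
mean_Q=0.999905
mean_Qs=0.976934
network_edges=24
baseline_cpl=3.784322
communities=27
wham_iterations=512
girvan_newman_removals=24
```

Reading the numbers: the ensemble fluctuates ≈ 0.36 Å RMSD about its mean
and keeps essentially all native contacts (Q ≈ 1, Qs ≈ 0.98, as planted —
the displacements are small relative to the 8 Å contact cutoff). The
dynamical network retains 24 edges at the 4.5 Å / 75% criterion with a CPL
of 3.78 (−log|C| units). The 1D WHAM run converges in 512 iterations; in
`demo_out/pmf_1d.tsv` the profile reproduces the planted harmonic well —
F(14.0 Å) = 0.060 ± 0.148, rising to F(11.0 Å) = 9.65 ± 0.36 and
F(18.0 Å) = 15.98 ± 0.17 kcal/mol, i.e. ½·2·(x−14)² up to bootstrap noise.
The RAC table shows the 1/√w convergence decay (0.115 Å at 10 frames,
0.034 Å at 100, exactly 0 at the full window). Rerunning with the same seed
reproduces every table byte for byte.

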