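# confdyn

Comparative conformational-dynamics analysis of molecular-dynamics
ensembles, built around the kind of question asked of the four human
Argonaute paralogs (hAgo1–4): given long MD trajectories of closely related
multi-domain proteins (N, L1, PAZ, L2, MID, PIWI domains), *where* do their
internal dynamics differ, *which* geometric coordinates discriminate them,
*which* residues anchor their stability, and *how* do binding-induced
changes propagate?

It is a library plus a thin `confdyn` command line for structural
bioinformaticians who have trajectories (or want fully synthetic ones with
planted, analytically known structure) and need the comparative read-outs,
not the simulations.

## What it computes

- **Distance-fluctuation (DF) maps** — the coordination measure
  DF<sub>ij</sub> = ⟨(r<sub>ij</sub> − ⟨r<sub>ij</sub>⟩)²⟩ over Cα–Cα
  distances; low DF marks dynamically coordinated pairs, and bound−apo
  differences map where coordination changes on ligand binding
  (`confdyn.distance_fluctuations`).
- **Geometric-descriptor PCA with Calinski–Harabasz (CH) selection** —
  13 per-frame descriptors (8 domain centre-of-mass distances, 5 COM
  angles), pooled over labeled ensembles, standardized, decomposed by PCA;
  PC1–2 are excluded as common-mode conformational shifts, PC pairs with
  combined explained variance ≥ 15 % are ranked by CH =
  [B/(k−1)]/[W/(n−k)] on their 2-D projections, and the descriptors with
  the largest |loadings| on the winning pair are the discriminative
  features (`confdyn.descriptors`).
- **Energy decomposition matrices (EDM)** — residue-pair nonbonded
  energies E<sub>ij</sub> = E<sup>el</sup> + E<sup>vdW</sup> (+ optional
  distance-dependent-dielectric screening), their leading eigenvector and
  the per-residue stability profile |λ₁|v<sub>i</sub>²; residues with
  profile ≥ 0.005 kcal/mol form the "electrostatic nuclei" stability hubs
  (`confdyn.energetics`).
- **Interaction networks** — geometric H-bond and salt-bridge detection,
  occupancy traces, persistence filtering (retain ≥ 5 %, flag > 20 %),
  equivalent-atom averaging (Asp OD1/OD2 …) and intra-/inter-domain
  classification (`confdyn.networks`).
- **Pocket definition and channel volume** — the RNA-binding pocket as all
  residues within 6 Å of the bound RNA, the minimal conserved pocket
  across systems, and probe-accessible grid volumes weighted by cluster
  populations (`confdyn.pocket`).
- **Water survival probability** — P(τ) = (1/T<sub>n</sub>)
  Σ<sub>t</sub> N(t,τ)/N(t) with continuous presence, windowing and
  equilibration skip, for LAKE-style internal hydration pockets
  (`confdyn.hydration`).
- **Commute-time allostery** — Cα-contact Kirchhoff (GNM) topology, Markov
  hit/commute times, commute-weighted k-shortest communication pathways
  (Dijkstra/Yen) between residue sets, and hotspot conservation across
  cluster representatives and conditions (`confdyn.allostery`).
- **Core + synthetic data** — PDB I/O, Kabsch superposition, RMSD/RMSF/Rg,
  average-linkage RMSD clustering (ε = 3.0 Å) with representative
  conformations (`confdyn.core`), and generators for every input with
  planted parameters recorded in metadata (`confdyn.synthetic`).

## Worked example

The bundled demo simulates a six-domain Cα ensemble (apo with planted
PAZ–PIWI breathing; bound without), four labeled ensembles with a planted
discriminative descriptor, bond traces, exchanging waters and a contact
chain, then runs every stage:

```bash
confdyn demo --seed 1 --out demo_out
```

Selected numbers from `demo_out/` (seed 1):

- `pca_selection.json`: top PC pair **(3, 4)**, top descriptor
  **d_L1_L2** with |loading| **0.829** — the descriptor whose between-label
  shift was planted by the generator, recovered behind the two common-mode
  PCs (which hold 47.5 % + 25.4 % of the variance).
- `df_summary.json`: mean DF **1.195 Å²** (apo, breathing) vs
  **0.150 Å²** (bound) — the breathing motion dominates the apo
  coordination map and vanishes in the bound ensemble.
- `edm_eigen.json`: leading eigenvalue **−3.56 kcal/mol**, 40 nuclei
  residues with per-domain interacting-pair counts
  (PIWI 8, PAZ 8, MID 8, N 6, L1 2, L2 2).
- `survival_compare.json`: residence AUC **7.84** frames (bound,
  exchange rate 0.05) vs **4.07** (apo, rate 0.2) — slower exchange means
  longer-lived pocket waters.
- `pocket_volume.json`: weighted channel volume **1815.9 Å³** over the
  cluster representatives of the bound ensemble.
- `allostery.json`: mean pathway commute times 3093.6 (apo) vs 3101.0
  (bound) and a 15/15 hotspot overlap — the two near-identical chain
  conformations communicate near-identically, as they should.

Rerunning with the same seed reproduces every output byte for byte.
Individual stages run as `confdyn df|descriptors|edm|networks|pocket|
water|allostery --config run.yaml --seed N --out DIR`; a YAML config
overrides any default (unknown keys are rejected).

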