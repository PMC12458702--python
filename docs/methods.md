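# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic-data generator's scope, and the numerical and design
choices made where the underlying methodology is genuinely open.

## Data model

An ensemble is a list of atoms plus an (n_frames × n_atoms × 3) coordinate
array in Å, with an optional domain partition and an optional bound
nucleic-acid chain. Residues are indexed 0-based and contiguous
internally; author (PDB) numbering is display metadata only, because the
systems being compared (protein paralogs) carry different author
numbering — any cross-system residue identification goes through an
explicit correspondence table (see the minimal-pocket operation). Time is
measured in frames; a declared `frame_interval` converts physical-time
parameters (e.g. survival windows) when real trajectories are analysed.

## Distance fluctuations

DF_ij = ⟨r_ij²⟩ − ⟨r_ij⟩² over Cα–Cα distances, algebraically equal to
⟨(r_ij − ⟨r_ij⟩)²⟩. No superposition is applied: pairwise distances are
rigid-motion invariant, which the tests assert exactly. Accumulation is
one-pass over frame chunks with Kahan compensation; a two-pass evaluation
agrees to well below 1e−8 Å² at desk scale. An equilibration skip is
available everywhere (default 0 frames): the windowed water analysis is
the only stage whose protocol prescribes one, so the choice is made
explicit rather than implicit. Domain-block summaries average DF over
i∈A, j∈B with i≠j; within-block entries use the off-diagonal mean.

## Geometric descriptors and PC-pair selection

Thirteen per-frame descriptors: COM distances PAZ–PIWI, PAZ–N, PIWI–N,
PAZ–MID, NPAZ–MIDPIWI, PIWI–L2, PAZ–helix7, L1–L2 and COM angles for the
first five of those group pairs. COM is the unweighted Cα centroid.

Two constructions are under-determined and are package choices:

- **Angle definition.** "Angle between domains X and Y" is the angle at
  the whole-protein Cα COM subtended by COM_X and COM_Y. It uses only
  quantities the descriptor set already names and is configurable via
  `PairSpec`; alternative readings (inter-lobe hinge axes) exist. A
  consequence worth knowing: an angle between two composite lobes that
  together contain most of the protein is close to 180° (the vertex lies
  near the line joining the lobe COMs) and is therefore hypersensitive to
  small COM displacements.
- **Composite lobes.** NPAZ = N+PAZ and MIDPIWI = MID+PIWI. Folding the
  linkers into the lobes makes the whole-protein COM a convex combination
  of the two lobe COMs, which degenerates the lobe angle to exactly 180°;
  keeping the linkers out avoids that. The helix-7 sub-selection is a
  user-supplied residue range (synthetic fixtures default to the middle
  third of L2).

The pooled frames from all labeled ensembles are standardized with the
pooled mean/SD and decomposed by full PCA (correlation-matrix PCA: the 13
eigenvalues sum to 13). PC signs are fixed so each PC's largest-|loading|
coefficient is positive. PC1–2 are excluded as common-mode conformational
shifts; candidate pairs are unordered pairs from PC3 upward whose
explained-variance fractions sum to ≥ 0.15 ("at least 15 % of the
cumulative variance" is read as the pair's combined fraction — the reading
consistent with a two-PC pair being quoted at 19.2 %). Each candidate's
frames are projected on the pair and scored with
CH = [B/(k−1)]/[W/(n−k)] (B between-group, W within-group sum of squares;
W = 0 returns +inf). The top pair's descriptors are ranked by
max(|loading on PC_a|, |loading on PC_b|). When no pair qualifies the
result carries an explicit `no_qualifying_pair` flag rather than falling
back silently. A label-permutation null for the top pair's CH
(`permutation_null_pvalue`) guards against selection bias: because the
top pair is the argmax over candidates, its CH is biased high even under
the null, and the permutation test quantifies that.

## Energy decomposition

E_ij sums atom-pair terms within a 10 Å cutoff: electrostatics
k_e·q_a·q_b/(ε(r)·r) with k_e = 332.0637 kcal·Å/(mol·e²) (the Amber
convention) and 12-6 Lennard-Jones with Lorentz–Berthelot mixing. Charges
and LJ parameters come from a plain CSV table (atom_id, charge, sigma,
epsilon), not from force-field files. Choices on open points:

- **Solvation term.** The decomposition formally includes G_solv, but no
  solvent model is prescribed; the default is G_solv = 0, with a
  distance-dependent-dielectric mode (ε(r) = r/Å, i.e. 1/r² screening) as
  a stand-in. The mode is recorded in the result.
- **Sequence-adjacent exclusion.** Pairs with |i−j| < 2 are excluded:
  their energies are dominated by covalent terms this model omits.
  Configurable.
- **Per-residue profile.** The "first eigenvector" is the eigenvector of
  the largest-|λ| eigenvalue, signed so its component sum is ≥ 0. The
  plotted per-residue profile is |λ₁|·v_i² — a nonnegative,
  energy-weighted participation — with raw |v_i| available by flag, since
  the mapping from eigenvector to profile is not uniquely determined.
- **Nuclei threshold.** Residues with profile ≥ 0.005 kcal/mol
  (inclusive) are retained; per-domain counts enumerate retained pairs
  within the same domain that actually interact (|E_ij| > 0). Whether the
  threshold applies to the eigenvector-weighted profile or to raw matrix
  entries is ambiguous in the source methodology; the profile reading is
  the default, the raw mode is provided.

EDMs are computed on cluster-representative conformations (average-linkage
RMSD clustering at ε = 3.0 Å), not per frame. Near-degenerate leading
eigenvalues (gap < 1e−9) add a recorded warning instead of failing.

## Interaction networks

H-bonds: donor–acceptor heavy-atom distance ≤ 3.0 Å and D–H···A angle
≥ 160°, mirroring the common VMD-style defaults (3.0 Å / 20° cone); both
knobs are parameters. Donor hydrogens are found geometrically (same
residue, within 1.3 Å of the donor heavy atom); hydrogen-free structures
need a donor table and otherwise get an instructive error. Salt bridges:
any basic-N to acidic-O distance ≤ 4.0 Å (inclusive), reported at
residue-pair level. Chemistry and equivalence tables ship as editable
CSVs under `confdyn/data/`.

Persistence is the occupied-frame fraction. Retention uses ≥ 0.05 ("at
least 5 %" is inclusive); the "most meaningful" flag uses > 0.20
(matching a strict "present in >20 % of frames" reading).
Equivalent-atom averaging merges events identical up to a within-class
swap (Asp OD1≡OD2, Glu OE1≡OE2, Arg NH1≡NH2, Phe/Tyr ring pairs); the
merged persistence is the arithmetic mean of the members — the averaging
acts on persistences, not on traces — and the OR-ed trace is kept only
for classification. The operation is idempotent.

## Pocket and channel volume

The pocket is every protein residue with a heavy atom within 6 Å of any
RNA heavy atom; the minimal conserved pocket intersects per-system pockets
in a user-supplied common residue space (unmapped residues are excluded
with a warning). Channel volume uses a deterministic, oracle-checkable
estimator chosen for reproducibility (the source volumes' algorithm is
unspecified, so absolute literature volumes are documentation, not
targets): grid points (default 0.5 Å spacing) inside the convex hull of
the pocket heavy atoms and farther than probe (1.4 Å) + Bondi vdW radius
from every protein heavy atom, times the cell volume; volumes from
cluster representatives are averaged with population weights. The hollow
sphere fixture validates the estimator against 4/3·π·r³ within 5 % and
within 2 % under grid halving.

## Water survival

A water is in a region when its oxygen is within the inclusion radius
(4 Å, inclusive) of any anchor atom; regions are defined by LAKE-style
per-residue anchor selections (side-chain atoms, backbone oxygens, Cβ).
P(τ) averages N(t,τ)/N(t) over origins and fixed-length windows after an
equilibration skip, with empty-origin times excluded. Two choices:

- **Continuous presence.** N(t,τ) requires presence at every frame
  through t+τ (intermittency 0), the standard continuous-survival
  estimator; an intermittency option exists but endpoint-only counting is
  not the default.
- **Common origin set.** Origins satisfy t + max(τ) ≤ window end for all
  lags, which makes the estimator monotone non-increasing by construction
  (the class asserts monotonicity and P(0) = 1 on every instance).

Physical defaults for real data are 20 ns windows, 100 ns skip and
τ ∈ [0.1, 1] ns, all expressed in frames through `frame_interval`;
synthetic fixtures use arbitrary frame units.

## Allostery

The Cα contact topology at a 10 Å cutoff (a standard Cα GNM default; the
source leaves it unstated) defines the Kirchhoff matrix and the random
walk P = D⁻¹A on **binary** contacts — the cited methodology admits
weighted affinities but none are given, so weighting is an extension
hook. Hit times solve the first-passage system (one dense solve per
target); commute times C = H + Hᵀ are validated in tests against the
independent identity C = 2|E|·R_eff via the Laplacian pseudoinverse.
Disconnected graphs are rejected with the components named.

Communication pathways: contact edges weighted by C; the k (default 15)
globally shortest loopless paths from any source to any target, found by
per-pair Yen enumeration merged lazily through a heap with deterministic
(weight, node-sequence) tie-breaking, including a tie-drain so equal-weight
paths emerge in lexicographic order. Set-to-set search (rather than
per-residue-pair) is a package choice. Hotspots: a residue's score is the
number of top-k pathways across a condition's cluster representatives
containing it, endpoints excluded — one concrete operationalization of
"conserved residues", since the exact scoring is unstated; cross-condition
conservation is the intersection size of the top-n sets, and communication
efficiency is the mean pathway commute time. Representatives should cover
≥ 80 % of the population (enforced when populations are supplied).

## Synthetic data

The generators emulate the *geometry and statistics* that each stage
consumes — not force-field physics, solvent boxes, or sequence realism:

- **Toy protein**: six Gaussian Cα-bead blobs (N/L1/PAZ/L2/MID/PIWI;
  default sizes 20/6/18/6/18/22) on a documented layout — five in-plane on
  a 30 Å circle, PIWI 45 Å above PAZ so the PAZ–PIWI axis is orthogonal to
  every in-plane direction. A separate chain generator lays the same
  domains on a 3.8 Å-spaced helical curve for stages that need a
  connected contact topology (GNM/allostery, energetics demos).
- **Ensembles**: per-domain rigid Gaussian jitter (default σ = 0.3 Å)
  plus optional sinusoidal interdomain breathing along the
  centroid–centroid axis (peak-to-peak 2A by construction).
- **Labeled sets**: two common-mode Gaussian collective coordinates
  (SD 5 Å; N tangentially in-plane, PIWI vertically) occupy PC1–2;
  label effects shift the named distance descriptor by translating its
  first domain group along the pair axis. With the layout above the named
  shift is exact to first order; other descriptors receive only
  second-order or vertex-mediated (COM-weight ~n_domain/n_total) leakage,
  small against their own noise — except the near-collinear inter-lobe
  hinge angle, which is hypersensitive by construction. Centering label
  shifts around zero minimizes the second-order terms; the cleanest
  planting targets are descriptors whose domains appear in no angle
  descriptor (L1/L2). Effects on angle descriptors are not supported.
- **Waters**: memoryless (geometric-residence) exchange — inside waters
  exit with probability p per frame, giving the closed form
  P(τ) = (1−p)^τ. Slots are reused (an exited water re-enters later at a
  fresh uniform position with probability 0.5/frame) rather than ids
  retired; continuous-presence survival statistics are identical under
  both bookkeepings.
- **Bond fixtures**: Lys(NZ–HZ1)···Asp(OD1) pairs toggling between ideal
  (2.9 Å, linear) and broken (6.0 Å) geometry, realising requested
  occupancies as round(occ·n)/n, recorded in metadata.
- **Energy matrices**: block-structured depth·(indicator outer product)
  plus optional symmetric noise, with the dominant block recorded.
- **Volume cage**: a Fibonacci-sphere shell of pseudo-atoms whose free
  interior is an analytic ball.

All generators are pure functions of (spec, seed); planted parameters are
emitted in metadata so tests never re-derive them from prose. Passing
tests therefore demonstrate that each stage recovers structure *of the
planted kind* at realistic signal-to-noise — they do not certify behaviour
on real solvated all-atom trajectories, whose correlated side-chain
motions, anharmonicity and force-field detail the generators deliberately
omit.

## Problem sizes and numerics

Verification runs at desk scale, chosen so the full suite and the
acceptance script each complete in minutes on one CPU: 100-frame/30-residue
DF oracles; 50 random graphs (n ≤ 12) for the commute identity; 100 seeded
recovery runs at 4 labels × 500 frames with a 200-permutation null;
2000-frame/200-water survival fixtures; 2000-point volume cages;
90-residue demo pipelines at 200 frames. Pairwise frame RMSD uses batched
SVD Kabsch (cross-checked pairwise against the general superposition
routine); representative selection breaks ties toward the lowest frame
index; cluster ordering is by population, then representative index.
Degenerate inputs fail loudly: collinear superposition selections,
single-frame DF, zero-variance descriptor columns (named), empty pockets,
disconnected contact graphs, overlapping source/target sets.

## Known limitations

- Real-trajectory formats beyond multi-model PDB (XTC/DCD) are not wired
  into the readers, though the ensemble container is format-agnostic.
- The EDM solvation mode is a screening surrogate, not a
  generalized-Born/Poisson model; absolute energies should be compared
  only within a consistent mode.
- Channel volumes depend on the hull-bounded estimator; comparisons are
  meaningful within the estimator, absolute values are not portable
  across algorithms.
- Salt-bridge detection reports residue-pair events; per-atom-pair
  resolution exists only for hydrogen bonds.
- π–π/cation–π interactions, water-mediated bridges, DCCM-style
  cross-correlation, PME electrostatics and normal-mode (ANM) analyses
  are out of scope.
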