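"""Synthetic multi-domain ensembles with planted, analytically known structure.

Every pipeline stage is exercised on inputs generated here: Cα-bead
multi-domain "proteins" with controllable per-domain flexibility, planted
interdomain breathing, labeled between-ensemble descriptor shifts, on/off
bond traces, memoryless water exchange in a defined region, and
block-structured pairwise energy matrices.  All generators are pure
functions of (spec, seed) and record their planted parameters in metadata,
so tests never re-derive them from prose.

The generators emulate the *geometry* of multi-domain conformational
ensembles (domain blobs, rigid jitter, collective modes), not force-field
physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AtomRecord, DomainPartition, EnsembleModel
from .errors import ParameterError, SelectionError

#: Canonical domain names used when a spec has six domains (the conserved
#: Argonaute architecture: two lobes joined by linkers L1/L2).
DEFAULT_DOMAIN_NAMES = ("N", "L1", "PAZ", "L2", "MID", "PIWI")

#: Circumradius (A) of the planar polygon on which domain centroids sit.
LAYOUT_RADIUS = 30.0
#: Height (A) of the out-of-plane domain (PIWI) above its in-plane partner.
LAYOUT_HEIGHT = 45.0


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic study system.

    `domain_sigma` is the per-domain isotropic rigid-jitter scale in A
    (scalar or one value per domain).  `common_mode_amplitude` sets the SD of
    the two planted high-variance collective coordinates that occupy PC1-2
    in the labeled-set generator.
    """

    seed: int = 0
    n_frames: int = 500
    domain_sizes: tuple[int, ...] = (20, 6, 18, 6, 18, 22)
    domain_sigma: float | tuple[float, ...] = 0.3
    breathing: tuple[tuple[str, str], float, int] | None = None
    label_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    bond_traces: list[tuple[str, float]] = field(default_factory=list)
    water_spec: tuple[int, float, float] = (200, 0.1, 8.0)
    energy_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    energy_noise: float = 0.0
    common_mode_amplitude: float = 5.0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.domain_sizes):
            raise ParameterError("domain sizes must be >= 1")
        for _, occ in self.bond_traces:
            if not 0.0 <= occ <= 1.0:
                raise ParameterError("bond occupancies must lie in [0, 1]")
        n_w, rate, radius = self.water_spec
        if not 0.0 <= rate <= 1.0:
            raise ParameterError("water exchange rate must lie in [0, 1]")
        if n_w < 1 or radius <= 0:
            raise ParameterError("water_spec needs n_waters >= 1, radius > 0")

    @property
    def n_domains(self) -> int:
        return len(self.domain_sizes)

    @property
    def domain_names(self) -> list[str]:
        if self.n_domains == len(DEFAULT_DOMAIN_NAMES):
            return list(DEFAULT_DOMAIN_NAMES)
        return [f"D{i + 1}" for i in range(self.n_domains)]

    def sigmas(self) -> np.ndarray:
        s = self.domain_sigma
        if np.isscalar(s):
            return np.full(self.n_domains, float(s))
        s = np.asarray(s, dtype=float)
        if s.size != self.n_domains:
            raise ParameterError("domain_sigma length != number of domains")
        return s

    def descriptor_noise_sd(self) -> float:
        """SD of a domain-pair COM distance induced by rigid jitter alone.

        Two independent isotropic translations of scale sigma give a
        relative-displacement SD of sqrt(2)*sigma along the separation axis
        (large-separation limit).  Uses the maximum per-domain sigma.
        """
        return float(np.sqrt(2.0) * self.sigmas().max())


def layout_centers(n_domains: int) -> np.ndarray:
    """Documented domain-centroid layout.

    Domains sit on a circle of radius LAYOUT_RADIUS in the z=0 plane; with
    six domains the last one (PIWI) instead sits LAYOUT_HEIGHT above the
    third (PAZ), so that the PAZ-PIWI axis is orthogonal to every in-plane
    inter-domain direction (this makes planted PAZ-PIWI distance shifts
    first-order clean).
    """
    if n_domains == 6:
        angles = np.deg2rad([0.0, 60.0, 120.0, 180.0, 240.0])
        centers = np.zeros((6, 3))
        centers[:5, 0] = LAYOUT_RADIUS * np.cos(angles)
        centers[:5, 1] = LAYOUT_RADIUS * np.sin(angles)
        centers[5] = centers[2] + np.array([0.0, 0.0, LAYOUT_HEIGHT])
        return centers
    angles = 2.0 * np.pi * np.arange(n_domains) / n_domains
    centers = np.zeros((n_domains, 3))
    centers[:, 0] = LAYOUT_RADIUS * np.cos(angles)
    centers[:, 1] = LAYOUT_RADIUS * np.sin(angles)
    return centers


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def make_toy_protein(spec: SyntheticSpec
                     ) -> tuple[EnsembleModel, DomainPartition]:
    """Single-frame Cα-bead chain laid out as separated domain blobs.

    Each domain is a compact Gaussian blob (scale 2 A) recentred so its
    centroid coincides exactly with the documented layout position.
    """
    centers = layout_centers(spec.n_domains)
    rng = _rng(spec, 0)
    coords = []
    ranges = []
    start = 0
    for d, size in enumerate(spec.domain_sizes):
        blob = rng.normal(scale=2.0, size=(size, 3))
        blob -= blob.mean(axis=0)
        coords.append(centers[d] + blob)
        ranges.append((start, start + size - 1))
        start += size
    coords = np.vstack(coords)
    atoms = [
        AtomRecord(atom_id=i + 1, name="CA", element="C", residue_index=i,
                   residue_name="ALA", chain_id="A", position=coords[i])
        for i in range(coords.shape[0])
    ]
    partition = DomainPartition(
        domains=[(name, [rng_]) for name, rng_ in
                 zip(spec.domain_names, ranges)]
    )
    ensemble = EnsembleModel(
        atoms=atoms, frames=coords[None, :, :], label="reference",
        partition=partition,
        metadata={"planted": {"layout_centers": centers.tolist(),
                              "seed": spec.seed}},
    )
    return ensemble, partition


def _domain_atom_slices(spec: SyntheticSpec) -> list[slice]:
    edges = np.cumsum([0, *spec.domain_sizes])
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def make_ensemble(spec: SyntheticSpec, label: str = "",
                  reference: EnsembleModel | None = None,
                  rng_stream: int = 1) -> EnsembleModel:
    """Multi-frame ensemble: reference + per-domain rigid Gaussian jitter
    + optional sinusoidal interdomain breathing.

    Breathing displaces the second domain of the named pair along the
    centroid-centroid axis by A*sin(2*pi*k/period), so the centroid distance
    has peak-to-peak range 2A when jitter is zero.
    """
    if reference is None:
        reference, _ = make_toy_protein(spec)
    ref = reference.frames[0]
    slices = _domain_atom_slices(spec)
    sigmas = spec.sigmas()
    rng = _rng(spec, rng_stream)
    # draw jitter for all frames/domains up front: deterministic under seed
    jitter = rng.normal(size=(spec.n_frames, spec.n_domains, 3)) * \
        sigmas[None, :, None]
    frames = np.repeat(ref[None, :, :], spec.n_frames, axis=0)
    for d, sl in enumerate(slices):
        frames[:, sl, :] += jitter[:, d, None, :]

    planted: dict = {"domain_sigma": sigmas.tolist(), "seed": spec.seed,
                     "label": label}
    if spec.breathing is not None:
        (name_a, name_b), amplitude, period = spec.breathing
        names = spec.domain_names
        if name_a not in names or name_b not in names:
            raise SelectionError(f"unknown breathing domains {name_a}/{name_b}")
        ia, ib = names.index(name_a), names.index(name_b)
        centers = layout_centers(spec.n_domains)
        axis = centers[ib] - centers[ia]
        axis = axis / np.linalg.norm(axis)
        phase = np.sin(2.0 * np.pi * np.arange(spec.n_frames) / period)
        frames[:, slices[ib], :] += (amplitude * phase)[:, None, None] * axis
        planted["breathing"] = {"pair": (name_a, name_b),
                                "amplitude": amplitude, "period": period}

    out = reference.with_frames(frames, planted=planted)
    out.label = label or reference.label
    return out


# descriptor-name parsing shared with the labeled-set generator
def _parse_distance_descriptor(name: str) -> tuple[str, str]:
    if not name.startswith("d_"):
        raise ParameterError(
            f"label effects support distance descriptors only, got {name!r}"
        )
    parts = name[2:].split("_")
    if len(parts) != 2:
        raise SelectionError(f"unknown descriptor name {name!r}")
    return parts[0], parts[1]


def make_labeled_set(spec: SyntheticSpec, labels: list[str]
                     ) -> list[EnsembleModel]:
    """One ensemble per label with planted between-label descriptor shifts.

    Two high-variance common-mode collective coordinates (Gaussian scalars
    of SD `common_mode_amplitude` displacing the N and MID domains along
    fixed in-plane axes) are planted in every label so that they occupy
    PC1-2 of the pooled descriptor PCA.  Exactly the distance descriptors
    named in `label_effects` get first-order mean shifts, applied by
    translating the first domain of the pair away from the second along
    their reference separation axis.
    """
    from .descriptors import DESCRIPTOR_NAMES  # local: avoids cycle at import

    for lab in labels:
        if lab not in spec.label_effects:
            raise SelectionError(f"label {lab!r} has no entry in label_effects")
        for desc in spec.label_effects[lab]:
            if desc not in DESCRIPTOR_NAMES:
                raise SelectionError(f"unknown descriptor name {desc!r}")

    base, partition = make_toy_protein(spec)
    names = spec.domain_names
    slices = _domain_atom_slices(spec)
    centers = layout_centers(spec.n_domains)

    def group_center(group: str) -> np.ndarray:
        from .descriptors import resolve_group_domains
        members = resolve_group_domains(group, names)
        return centers[[names.index(m) for m in members]].mean(axis=0)

    out = []
    # common-mode targets/axes: N moves tangentially in-plane, the
    # out-of-plane domain (PIWI) moves vertically; both motions spread over
    # many descriptors (so they own PC1-2) while leaving the linker
    # separation d_L1_L2 untouched to first order
    cm_targets = (0, spec.n_domains - 1)
    cm_axes = (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    for li, lab in enumerate(labels):
        ref = base.frames[0].copy()
        shifts = spec.label_effects[lab]
        for desc, s in shifts.items():
            ga, gb = _parse_distance_descriptor(desc)
            from .descriptors import resolve_group_domains
            members = resolve_group_domains(ga, names)
            axis = group_center(ga) - group_center(gb)
            axis = axis / np.linalg.norm(axis)
            for m in members:
                ref[slices[names.index(m)], :] += s * axis
        ref_model = base.with_frames(ref[None, :, :])
        ens = make_ensemble(spec, label=lab, reference=ref_model,
                            rng_stream=100 + li)
        rng = _rng(spec, 200 + li)
        z = rng.normal(scale=spec.common_mode_amplitude,
                       size=(spec.n_frames, 2))
        frames = ens.frames
        for m, (dom, axis) in enumerate(zip(cm_targets, cm_axes)):
            frames[:, slices[dom], :] += z[:, m, None, None] * axis
        ens.metadata["planted"]["label_effects"] = shifts
        ens.metadata["planted"]["common_mode"] = {
            "amplitude": spec.common_mode_amplitude,
            "domains": [names[d] for d in cm_targets],
        }
        ens.metadata["planted"]["descriptor_noise_sd"] = \
            spec.descriptor_noise_sd()
        out.append(ens)
    return out


def make_water_region(spec: SyntheticSpec):
    """Water ensemble with memoryless (geometric-residence) exchange.

    Atom 0 is a fixed anchor at the origin; each water is a single oxygen.
    A water inside the region exits on the next frame with probability p
    (the exchange rate) and is teleported far outside; an outside water
    re-enters at a fresh uniform position with probability 0.5 per frame.
    Continuous-presence survival is therefore exactly P(tau) = (1-p)^tau.

    Returns (ensemble, region) with a :class:`confdyn.hydration.
    RegionDefinition` anchored on atom 0.
    """
    from .hydration import RegionDefinition

    n_w, p, radius = spec.water_spec
    rng = _rng(spec, 3)
    n_frames = spec.n_frames

    def inside_positions(k: int) -> np.ndarray:
        v = rng.normal(size=(k, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * 0.95 * rng.random(k) ** (1.0 / 3.0)
        return v * r[:, None]

    parked = np.stack([1000.0 + 10.0 * np.arange(n_w),
                       np.zeros(n_w), np.zeros(n_w)], axis=1)
    frames = np.zeros((n_frames, n_w + 1, 3))
    inside = np.ones(n_w, dtype=bool)
    pos = inside_positions(n_w)
    for t in range(n_frames):
        frames[t, 1:, :] = pos
        exits = inside & (rng.random(n_w) < p)
        enters = ~inside & (rng.random(n_w) < 0.5)
        stay = inside & ~exits
        inside = stay | enters
        pos[exits] = parked[exits]
        moving = stay | enters  # diffusive resampling inside the region
        pos[moving] = inside_positions(int(moving.sum()))

    atoms = [AtomRecord(atom_id=1, name="ZN", element="Zn", residue_index=0,
                        residue_name="ANC", chain_id="X",
                        position=frames[0, 0])]
    atoms += [
        AtomRecord(atom_id=w + 2, name="O", element="O", residue_index=w + 1,
                   residue_name="HOH", chain_id="W", position=frames[0, w + 1])
        for w in range(n_w)
    ]
    ens = EnsembleModel(
        atoms=atoms, frames=frames, label="water",
        metadata={"planted": {"exchange_rate": p, "n_waters": n_w,
                              "region_radius": radius, "seed": spec.seed}},
    )
    region = RegionDefinition(name="LAKE", anchor_atom_indices=[0],
                              inclusion_radius=radius)
    return ens, region


def make_energy_matrix(spec: SyntheticSpec) -> tuple[np.ndarray, dict]:
    """Block-structured symmetric residue-pair energy matrix (kcal/mol).

    matrix = sum over blocks of depth * indicator-outer-product, plus
    optional small symmetric Gaussian noise.  Returns (matrix, planted)
    where planted records the dominant (deepest) block.
    """
    n = int(sum(spec.domain_sizes))
    seen: set[int] = set()
    for residues, _ in spec.energy_blocks:
        block = set(residues)
        if block & seen:
            raise ParameterError("energy blocks must be disjoint")
        seen |= block
    mat = np.zeros((n, n))
    for residues, depth in spec.energy_blocks:
        ind = np.zeros(n)
        ind[list(residues)] = 1.0
        mat += depth * np.outer(ind, ind)
    if spec.energy_noise > 0:
        rng = _rng(spec, 4)
        noise = rng.normal(scale=spec.energy_noise, size=(n, n))
        mat += (noise + noise.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    dominant = (max(spec.energy_blocks, key=lambda b: abs(b[1]))[0]
                if spec.energy_blocks else [])
    return mat, {"dominant_block": sorted(dominant),
                 "blocks": [(sorted(r), d) for r, d in spec.energy_blocks]}


def make_chain_protein(spec: SyntheticSpec
                       ) -> tuple[EnsembleModel, DomainPartition]:
    """Connected Cα chain (3.8 A virtual-bond spacing) on a compact helical
    curve, partitioned into sequential domains.

    Unlike the separated-blob layout of make_toy_protein, this fixture has a
    realistic contact topology (consecutive and adjacent-turn contacts at a
    10 A Cα cutoff), so Gaussian-network / random-walk machinery applies
    directly.
    """
    n = int(sum(spec.domain_sizes))
    radius = 8.0
    chord = 3.8
    # chord of a helix: 2 r sin(dtheta/2) in-plane plus the rise
    rise = 1.5
    dtheta = 2.0 * np.arcsin(np.sqrt(max(chord ** 2 - rise ** 2, 0.1))
                             / (2.0 * radius))
    t = np.arange(n)
    coords = np.stack([
        radius * np.cos(t * dtheta),
        radius * np.sin(t * dtheta),
        rise * t,
    ], axis=1)
    atoms = [
        AtomRecord(atom_id=i + 1, name="CA", element="C", residue_index=i,
                   residue_name="ALA", chain_id="A", position=coords[i])
        for i in range(n)
    ]
    ranges = []
    start = 0
    for size in spec.domain_sizes:
        ranges.append((start, start + size - 1))
        start += size
    partition = DomainPartition(
        domains=[(name, [r]) for name, r in zip(spec.domain_names, ranges)]
    )
    ensemble = EnsembleModel(
        atoms=atoms, frames=coords[None, :, :], label="chain",
        partition=partition,
        metadata={"planted": {"spacing": chord, "seed": spec.seed}},
    )
    return ensemble, partition


# ---------------------------------------------------------------------------
# All-atom micro-fixtures for the chemistry-aware stages
# ---------------------------------------------------------------------------

def make_bond_fixture(spec: SyntheticSpec, n_frames: int | None = None
                      ) -> EnsembleModel:
    """Mini all-atom system with one Lys(NZ-HZ1)...Asp(OD1/OD2) pair per
    bond trace, switching between ideal-bond and broken geometry so that
    each pair's H-bond *and* salt-bridge occupancy equals the requested
    fraction (realised as round(occ*n)/n, recorded in metadata).

    On frames: NZ-OD1 = 2.9 A with a linear NZ-HZ1...OD1 arrangement.
    Off frames: the acceptor moves to 6.0 A.
    """
    n_frames = n_frames or spec.n_frames
    atoms: list[AtomRecord] = []
    n_pairs = len(spec.bond_traces)
    if n_pairs == 0:
        raise ParameterError("spec.bond_traces is empty")
    frames = np.zeros((n_frames, 5 * n_pairs, 3))
    realized = {}
    for i, (pair_label, occ) in enumerate(spec.bond_traces):
        z0 = 50.0 * i
        n_on = int(round(occ * n_frames))
        realized[pair_label] = n_on / n_frames
        base = len(atoms)
        res_d, res_a = 2 * i, 2 * i + 1
        atoms += [
            AtomRecord(base + 1, "CA", "C", res_d, "LYS", "A",
                       np.array([-2.0, 0.0, z0])),
            AtomRecord(base + 2, "NZ", "N", res_d, "LYS", "A",
                       np.array([0.0, 0.0, z0])),
            AtomRecord(base + 3, "HZ1", "H", res_d, "LYS", "A",
                       np.array([1.0, 0.0, z0])),
            AtomRecord(base + 4, "CA", "C", res_a, "ASP", "A",
                       np.array([5.0, 0.0, z0])),
            AtomRecord(base + 5, "OD1", "O", res_a, "ASP", "A",
                       np.array([2.9, 0.0, z0])),
        ]
        for t in range(n_frames):
            on = t < n_on
            acc_x = 2.9 if on else 6.0
            frames[t, base:base + 5, :] = [
                [-2.0, 0.0, z0], [0.0, 0.0, z0], [1.0, 0.0, z0],
                [acc_x + 2.1, 0.0, z0], [acc_x, 0.0, z0],
            ]
    return EnsembleModel(
        atoms=atoms, frames=frames, label="bond-fixture",
        metadata={"planted": {"occupancies": realized, "seed": spec.seed}},
    )


def make_hollow_cage(interior_radius: float = 6.0, wall_radius: float = 1.7,
                     n_points: int = 2000) -> EnsembleModel:
    """Spherical cage of pseudo-atoms whose probe-free interior is a ball
    of the given radius: centres on a Fibonacci sphere at
    interior_radius + wall_radius, so the union of atom spheres leaves a
    free ball of ~interior_radius.  Used as an analytic volume oracle."""
    shell = interior_radius + wall_radius
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n_points)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    pts = shell * np.stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ], axis=1)
    atoms = [
        AtomRecord(i + 1, "C", "C", i, "CAG", "A", pts[i])
        for i in range(n_points)
    ]
    return EnsembleModel(atoms=atoms, frames=pts[None, :, :], label="cage",
                         metadata={"planted": {
                             "interior_radius": interior_radius,
                             "wall_radius": wall_radius}})


def add_rna_strand(ensemble: EnsembleModel, near_residues: list[int],
                   distance: float = 4.0, chain_id: str = "R"
                   ) -> EnsembleModel:
    """Append a pseudo-RNA strand: one P atom per listed protein residue,
    placed `distance` A along +z from that residue's CA in every frame."""
    idx = ensemble.ca_indices(near_residues)
    offset = np.array([0.0, 0.0, distance])
    n_res = ensemble.n_residues
    new_atoms = list(ensemble.atoms)
    max_id = max(a.atom_id for a in ensemble.atoms)
    for j, ai in enumerate(idx):
        new_atoms.append(AtomRecord(
            atom_id=max_id + j + 1, name="P", element="P",
            residue_index=n_res + j, residue_name="U", chain_id=chain_id,
            position=ensemble.frames[0, ai] + offset,
        ))
    rna = ensemble.frames[:, idx, :] + offset[None, None, :]
    frames = np.concatenate([ensemble.frames, rna], axis=1)
    out = EnsembleModel(atoms=new_atoms, frames=frames,
                        frame_interval=ensemble.frame_interval,
                        label=ensemble.label, partition=ensemble.partition,
                        rna_chain=chain_id,
                        metadata=dict(ensemble.metadata))
    return out
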