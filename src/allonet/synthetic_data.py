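"""Synthetic coarse-grained systems with known ground truth.

Generators for (a) a five-fold pseudo-symmetric pentamer whose helix and
leaflet rods realize scripted radial/lateral tilt schedules exactly
before noise, (b) ligand beads following a scripted contact plan, (c)
residue-pair interaction-energy series with planted latent-factor
correlation structure, and (d) analytic two-bead fixtures for the energy
kernels.

Every generator is deterministic under its seed, and the ground truth is
available as a machine-readable manifest so recovery tests never
re-derive it.

The latent-factor (spiked covariance) model drives the planted
correlations: within a module, E_ij(t) = μ_ij + λ·F(t) + ε_ij(t) with a
shared standard-Gaussian factor F, so the within-module Pearson
correlation is analytically λ²/(λ² + σ_E²).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cg_system import (
    Bead,
    SelectionConfig,
    Topology,
    Trajectory,
)
from .interaction_energy import InteractionEnergySeries

__all__ = [
    "PlantedModule",
    "SyntheticSpec",
    "make_toy_pentamer",
    "default_selection",
    "make_ligand_trajectory",
    "make_coupled_series",
    "make_dimer_scan",
    "write_manifest",
]

Residue = tuple[str, int]

#: Free-pentamer tilt schedule (radial, lateral) in degrees per subunit,
#: emulating the near-symmetric helix/leaflet geometry of a resting
#: pentameric channel.
DEFAULT_HELIX_SCHEDULE = {
    "A": (13.8, -3.3),
    "B": (10.6, -1.5),
    "C": (9.8, -4.9),
    "D": (10.5, -4.2),
    "E": (11.0, -5.5),
}
DEFAULT_LEAFLET_SCHEDULE = {
    "A": (10.2, 6.2),
    "B": (10.6, 4.5),
    "C": (6.9, 4.1),
    "D": (11.0, -1.8),
    "E": (13.4, 0.2),
}


@dataclass
class PlantedModule:
    """A residue set sharing one latent fluctuation factor."""

    residues: list[Residue]
    loading: float = 0.8

    def __post_init__(self):
        norm = []
        for r in self.residues:
            if isinstance(r, (tuple, list)):
                norm.append((str(r[0]), int(r[1])))
            else:
                norm.append(("A", int(r)))
        self.residues = norm


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic pentamer and its planted structure.

    Geometry defaults give a desk-scale stand-in for a pentameric
    channel: five chains with C5 symmetry about z, each a straight
    "helix" rod (transmembrane) topped by a "leaflet" rod
    (extracellular), realizing the scheduled tilts exactly before
    isotropic Gaussian positional noise is added.
    """

    n_chains: int = 5
    helix_length: int = 12
    leaflet_length: int = 10
    beads_per_residue: int = 1
    bead_spacing: float = 0.35  # nm along the rod
    helix_radius: float = 1.8  # nm from the pore axis
    leaflet_radius: float = 2.4
    leaflet_z_offset: float = 2.8  # nm above the helix centroid plane
    box_length: float = 10.0
    noise_sigma: float = 0.02  # nm, per bead per frame
    n_frames: int = 200
    seed: int = 0
    tilt_schedule: dict = field(default_factory=dict)
    contact_plan: list = field(default_factory=list)  # (position, fraction)
    occupancy_cutoff: float = 0.7  # nm
    planted_modules: list = field(default_factory=list)
    sigma_e: float = 0.5  # kJ/mol, per-pair noise of the energy series
    baseline_mean_energy: float = -1.0  # kJ/mol
    n_background_pairs: int = 30
    n_decoy_pairs: int = 0  # sub-threshold |mean| decoys

    def __post_init__(self):
        if self.noise_sigma < 0 or self.sigma_e < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for pos, f in self.contact_plan:
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"contact fraction {f} for position {pos} not in [0, 1]")
        self.planted_modules = [
            m if isinstance(m, PlantedModule) else PlantedModule(**m)
            for m in self.planted_modules
        ]
        for key, val in self.full_schedule().items():
            ang = np.asarray(val, dtype=np.float64)
            if np.any(np.abs(ang) >= 90.0):
                raise ValueError(f"impossible tilt schedule for {key}: |angle| >= 90°")

    # -- schedule helpers ---------------------------------------------------

    def chain_ids(self) -> list[str]:
        return [chr(ord("A") + k) for k in range(self.n_chains)]

    def full_schedule(self) -> dict:
        """Schedule for every (chain, element), defaults filled in."""
        out = {}
        for c in self.chain_ids():
            out[(c, "helix")] = self.tilt_schedule.get(
                (c, "helix"), DEFAULT_HELIX_SCHEDULE.get(c, (11.0, -4.0))
            )
            out[(c, "leaflet")] = self.tilt_schedule.get(
                (c, "leaflet"), DEFAULT_LEAFLET_SCHEDULE.get(c, (10.0, 2.0))
            )
        return out

    def schedule_angles(self, chain: str, element: str) -> np.ndarray:
        """(n_frames, 2) array of scheduled (radial, lateral) per frame."""
        val = np.asarray(self.full_schedule()[(chain, element)], dtype=np.float64)
        if val.ndim == 1:
            return np.tile(val, (self.n_frames, 1))
        if val.shape != (self.n_frames, 2):
            raise ValueError(
                f"piecewise schedule for ({chain}, {element}) must have shape "
                f"({self.n_frames}, 2), got {val.shape}"
            )
        return val

    def manifest(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "helix_length": self.helix_length,
            "leaflet_length": self.leaflet_length,
            "n_frames": self.n_frames,
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "tilt_schedule": {
                f"{c}:{e}": np.asarray(v, dtype=float).tolist()
                for (c, e), v in self.full_schedule().items()
            },
            "contact_plan": [[int(p), float(f)] for p, f in self.contact_plan],
            "occupancy_cutoff": self.occupancy_cutoff,
            "planted_modules": [
                {"residues": [list(r) for r in m.residues], "loading": m.loading}
                for m in self.planted_modules
            ],
            "sigma_e": self.sigma_e,
            "baseline_mean_energy": self.baseline_mean_energy,
        }


def write_manifest(path, manifest: dict) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


# ---------------------------------------------------------------------------
# pentamer geometry


def _local_frame(theta: float):
    """Radial and tangential unit vectors at pore angle theta."""
    er = np.array([math.cos(theta), math.sin(theta), 0.0])
    et = np.cross(np.array([0.0, 0.0, 1.0]), er)
    return er, et


def _rod_direction(radial_deg: float, lateral_deg: float, er, et) -> np.ndarray:
    """Unit rod direction realizing the given radial/lateral tilt exactly."""
    ez = np.array([0.0, 0.0, 1.0])
    u = ez + math.tan(math.radians(radial_deg)) * er + math.tan(math.radians(lateral_deg)) * et
    return u / np.linalg.norm(u)


def make_toy_pentamer(spec: SyntheticSpec) -> tuple[Topology, Trajectory]:
    """Synthetic pentamer whose element axes realize the tilt schedule exactly.

    Each chain contributes a helix rod (residues 0 .. helix_length-1) and
    a leaflet rod (the following residues) of backbone beads along the
    scheduled direction; i.i.d. Gaussian noise of width ``noise_sigma``
    is added per bead per frame. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, spec.box_length / 2.0)
    chain_ids = spec.chain_ids()
    n_res_chain = spec.helix_length + spec.leaflet_length

    beads: list[Bead] = []
    k = 0
    for c in chain_ids:
        for r in range(n_res_chain):
            beads.append(
                Bead(
                    index=k,
                    residue_index=r,
                    chain_id=c,
                    residue_name="GLY",
                    bead_type="BB",
                    is_backbone=True,
                    charge=0.0,
                )
            )
            k += 1
            for s in range(spec.beads_per_residue - 1):
                beads.append(
                    Bead(
                        index=k,
                        residue_index=r,
                        chain_id=c,
                        residue_name="GLY",
                        bead_type=f"SC{s + 1}",
                        is_backbone=False,
                        charge=0.0,
                    )
                )
                k += 1
    topology = Topology(beads)

    n_beads = len(beads)
    coords = np.zeros((spec.n_frames, n_beads, 3))
    for ci, c in enumerate(chain_ids):
        theta = 2.0 * math.pi * ci / spec.n_chains
        er, et = _local_frame(theta)
        for element, length, radius, z_off, r0 in (
            ("helix", spec.helix_length, spec.helix_radius, 0.0, 0),
            (
                "leaflet",
                spec.leaflet_length,
                spec.leaflet_radius,
                spec.leaflet_z_offset,
                spec.helix_length,
            ),
        ):
            centroid = center + radius * er + np.array([0.0, 0.0, z_off])
            angles = spec.schedule_angles(c, element)
            offsets = (np.arange(length) - (length - 1) / 2.0) * spec.bead_spacing
            for t in range(spec.n_frames):
                u = _rod_direction(angles[t, 0], angles[t, 1], er, et)
                rod = centroid + offsets[:, None] * u[None, :]
                for j in range(length):
                    res = r0 + j
                    bb = topology.bead_index_map[
                        topology.backbone_bead_index(c, res)
                    ]
                    coords[t, bb] = rod[j]
                    for s in range(spec.beads_per_residue - 1):
                        coords[t, bb + 1 + s] = rod[j] + 0.25 * (s + 1) * er
    if spec.noise_sigma > 0:
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    box = np.full(3, spec.box_length)
    return topology, Trajectory(coords, box)


def default_selection(spec: SyntheticSpec, ligand_chain: str = "L") -> SelectionConfig:
    """Selection config matching :func:`make_toy_pentamer`'s layout."""
    h = spec.helix_length
    l = spec.leaflet_length
    return SelectionConfig(
        helix_ranges={c: (0, h - 1) for c in spec.chain_ids()},
        leaflet_ranges={c: (h, h + l - 1) for c in spec.chain_ids()},
        ligand_chain_ids=[ligand_chain],
        pore_axis_mode="fixed_z",
    )


# ---------------------------------------------------------------------------
# scripted ligand contacts


def make_ligand_trajectory(
    base: Trajectory,
    topology: Topology,
    contact_plan: list[tuple[int, float]],
    cutoff: float = 0.7,
    seed: int = 0,
    ligand_chain: str = "L",
) -> tuple[Topology, Trajectory]:
    """Append ligand beads realizing a scripted occupancy plan.

    For each planned (position, fraction) one single-bead ligand molecule
    per protein chain contacts that position's backbone bead — at
    distance 0.45·cutoff — in exactly ``round(fraction · n_frames)``
    pseudo-randomly chosen frames, and is parked far (> 1.5·cutoff from
    the protein) otherwise. All subunit copies are contacted in the same
    frames, so both occupancy combine modes recover the planned fraction
    exactly.
    """
    seen = set()
    for pos, f in contact_plan:
        if pos in seen:
            raise ValueError(
                f"conflicting contact plan: position {pos} planned twice"
            )
        seen.add(pos)
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"planned fraction {f} not in [0, 1]")
    rng = np.random.default_rng(seed)
    protein_chains = list(topology.chains)
    n_frames = base.n_frames
    box = base.box.copy()
    center = box[0] / 2.0

    new_beads = list(topology.beads)
    k = max(b.index for b in topology.beads) + 1
    lig_cols = []  # (bead array position, chain, position, contact frames)
    res_idx = 0
    coords = np.concatenate(
        [
            base.coordinates,
            np.zeros((n_frames, len(contact_plan) * len(protein_chains), 3)),
        ],
        axis=1,
    )
    col = base.n_beads
    for plan_no, (pos, f) in enumerate(contact_plan):
        n_contact = int(round(f * n_frames))
        frames = rng.choice(n_frames, size=n_contact, replace=False)
        in_contact = np.zeros(n_frames, dtype=bool)
        in_contact[frames] = True
        for ch_no, c in enumerate(protein_chains):
            new_beads.append(
                Bead(
                    index=k,
                    residue_index=res_idx,
                    chain_id=ligand_chain,
                    residue_name="LIG",
                    bead_type="BB",
                    is_backbone=True,
                    charge=0.0,
                )
            )
            bb_col = topology.bead_index_map[topology.backbone_bead_index(c, pos)]
            park = np.array(
                [0.6 + 0.35 * plan_no, 0.6 + 0.35 * ch_no, 0.6]
            )
            for t in range(n_frames):
                if in_contact[t]:
                    bb = base.coordinates[t, bb_col]
                    out = bb - np.array([center[0], center[1], bb[2]])
                    nrm = np.linalg.norm(out)
                    direction = out / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                    coords[t, col] = bb + 0.45 * cutoff * direction
                else:
                    coords[t, col] = park
            lig_cols.append((col, c, pos, np.sort(frames).tolist()))
            col += 1
            k += 1
            res_idx += 1
    new_topology = Topology(new_beads)
    return new_topology, Trajectory(coords, base.box, base.frame_stride_time)


# ---------------------------------------------------------------------------
# planted-correlation energy series


def _module_pairs(residues: list[Residue]) -> list[tuple[Residue, Residue]]:
    pairs = []
    for ra, rb in itertools.combinations(sorted(residues), 2):
        if ra[0] == rb[0] and abs(ra[1] - rb[1]) == 1:
            continue  # sequence-adjacent pairs are excluded from the analysis
        pairs.append((ra, rb))
    return pairs


def make_coupled_series(
    spec: SyntheticSpec,
) -> tuple[InteractionEnergySeries, dict]:
    """Interaction-energy series with planted latent-factor correlation.

    Within each planted module every residue pair follows
    E_ij(t) = μ_ij + λ F(t) + ε_ij(t) with a module-shared standard
    Gaussian factor F and i.i.d. Gaussian noise of width ``sigma_e``;
    background pairs get independent noise around their baseline.
    Baseline magnitudes exceed the mean-energy filter threshold except
    for the ``n_decoy_pairs`` sub-threshold decoys. Returns the series
    and its ground-truth manifest.
    """
    rng = np.random.default_rng(spec.seed)
    topo_residues = [
        (c, r)
        for c in spec.chain_ids()
        for r in range(spec.helix_length + spec.leaflet_length)
    ]
    module_residues: set[Residue] = set()
    pair_module: dict[tuple[Residue, Residue], int] = {}
    for mi, mod in enumerate(spec.planted_modules):
        for r in mod.residues:
            if r not in topo_residues:
                raise ValueError(f"planted module references unknown residue {r}")
        for pair in _module_pairs(mod.residues):
            if pair in pair_module:
                raise ValueError(
                    f"residue pair {pair} belongs to two planted modules"
                )
            pair_module[pair] = mi
        module_residues.update(mod.residues)

    background_pool = [r for r in topo_residues if r not in module_residues]
    bg_pairs: list[tuple[Residue, Residue]] = []
    candidates = _module_pairs(background_pool)
    if spec.n_background_pairs + spec.n_decoy_pairs > len(candidates):
        raise ValueError("not enough background residues for the requested pairs")
    chosen = rng.choice(
        len(candidates),
        size=spec.n_background_pairs + spec.n_decoy_pairs,
        replace=False,
    )
    bg_pairs = [candidates[i] for i in sorted(chosen)]
    decoys = set(bg_pairs[spec.n_background_pairs :])

    all_pairs = sorted(pair_module.keys() | set(bg_pairs))
    T = spec.n_frames
    factors = rng.standard_normal((max(len(spec.planted_modules), 1), T))
    values = np.empty((len(all_pairs), T))
    mu = {}
    for m, pair in enumerate(all_pairs):
        if pair in decoys:
            base = -0.25 * MEAN_FILTER_REFERENCE
        else:
            base = spec.baseline_mean_energy * (1.0 + 0.2 * (rng.random() - 0.5))
        mu[pair] = base
        noise = rng.normal(0.0, spec.sigma_e, size=T)
        if pair in pair_module:
            lam = spec.planted_modules[pair_module[pair]].loading
            values[m] = base + lam * factors[pair_module[pair]] + noise
        else:
            values[m] = base + noise

    series = InteractionEnergySeries(pairs=all_pairs, values=values)
    manifest = spec.manifest()
    manifest["series"] = {
        "n_pairs": len(all_pairs),
        "module_pairs": sum(1 for p in all_pairs if p in pair_module),
        "background_pairs": spec.n_background_pairs,
        "decoy_pairs": spec.n_decoy_pairs,
        "within_module_correlation": [
            float(m.loading**2 / (m.loading**2 + spec.sigma_e**2))
            for m in spec.planted_modules
        ],
    }
    return series, manifest


#: Reference scale for sub-threshold decoys: the 0.02 kcal/mol filter in kJ/mol.
MEAN_FILTER_REFERENCE = 0.08368


# ---------------------------------------------------------------------------
# analytic dimer fixture


def make_dimer_scan(
    separations, epsilon: float = 1.0, sigma: float = 0.47, box_length: float = 10.0
) -> tuple[Topology, Trajectory]:
    """Two single-bead residues on separate chains, one frame per separation."""
    separations = np.asarray(separations, dtype=np.float64)
    if np.any(separations <= 0):
        raise ValueError("separations must be positive")
    beads = [
        Bead(0, 0, "A", "LIG", "C1", True, 0.0),
        Bead(1, 0, "B", "LIG", "C1", True, 0.0),
    ]
    topo = Topology(beads)
    c = box_length / 2.0
    coords = np.zeros((separations.size, 2, 3))
    for t, r in enumerate(separations):
        coords[t, 0] = (c - r / 2.0, c, c)
        coords[t, 1] = (c + r / 2.0, c, c)
    return topo, Trajectory(coords, np.full(3, box_length))
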