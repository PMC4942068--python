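"""Data model and I/O for coarse-grained systems.

Beads, topologies, trajectories, nonbonded parameter tables and analysis
selections. Coordinates are stored in nanometres, energies in kJ/mol and
residue indices are 0-based internally; the 1-based numbering of GRO/PDB
files is converted at the I/O boundary.

Only orthorhombic periodic boxes are supported; triclinic input is
rejected with a clear error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Bead",
    "Topology",
    "Trajectory",
    "NonbondedTable",
    "SelectionConfig",
    "TopologyError",
    "TrajectoryError",
    "load_topology",
    "load_trajectory",
    "write_gro",
    "write_pdb",
    "minimum_image_distance",
    "minimum_image_displacement",
]

#: Bead names recognised as the residue's central backbone particle.
DEFAULT_BACKBONE_NAMES = ("BB",)


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topologies."""


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent trajectories."""


@dataclass(frozen=True)
class Bead:
    """One coarse-grained particle.

    ``residue_index`` is 0-based and counted per chain. ``is_backbone``
    marks the single central backbone particle of the residue, the
    reference point for ligand occupancy.
    """

    index: int
    residue_index: int
    chain_id: str
    residue_name: str
    bead_type: str
    is_backbone: bool
    charge: float = 0.0


class Topology:
    """Ordered bead list plus per-residue and per-chain lookups.

    Residues within a chain must be sequence-ordered (strictly increasing
    indices; gaps are permitted), so sequence adjacency (``i``, ``i+1`` of
    the same chain) is derivable. Every residue carries exactly one
    backbone bead.
    """

    def __init__(self, beads: Sequence[Bead]):
        self.beads: list[Bead] = list(beads)
        if not self.beads:
            raise TopologyError("topology has no beads")
        if len({b.index for b in self.beads}) != len(self.beads):
            raise TopologyError("bead indices are not unique")

        self.chains: list[str] = []
        residues: list[tuple[str, int]] = []
        last_chain = None
        last_res = None
        for b in self.beads:
            if b.chain_id != last_chain:
                if b.chain_id in self.chains:
                    raise TopologyError(
                        f"chain {b.chain_id!r} appears in two separate blocks"
                    )
                self.chains.append(b.chain_id)
                last_chain = b.chain_id
                last_res = None
            if last_res is None or b.residue_index > last_res:
                residues.append((b.chain_id, b.residue_index))
            elif b.residue_index != last_res:
                raise TopologyError(
                    f"residues of chain {b.chain_id!r} are not sequence-ordered: "
                    f"{last_res} followed by {b.residue_index}"
                )
            last_res = b.residue_index
        self.residues: list[tuple[str, int]] = residues
        self._residue_pos = {r: k for k, r in enumerate(residues)}

        # one backbone bead per residue
        self._backbone_bead: dict[tuple[str, int], int] = {}
        n_bb = {r: 0 for r in residues}
        for b in self.beads:
            key = (b.chain_id, b.residue_index)
            if b.is_backbone:
                n_bb[key] += 1
                self._backbone_bead[key] = b.index
        bad = [r for r, n in n_bb.items() if n != 1]
        if bad:
            raise TopologyError(
                f"residue {bad[0]} has {n_bb[bad[0]]} backbone beads (expected 1)"
            )

        self.residue_count = len(residues)
        # per-bead global residue ordinal, for fast vectorised grouping
        self.bead_residue_ordinal = np.array(
            [self._residue_pos[(b.chain_id, b.residue_index)] for b in self.beads],
            dtype=np.intp,
        )
        self.bead_index_map = {b.index: k for k, b in enumerate(self.beads)}

    def __len__(self) -> int:
        return len(self.beads)

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.beads == other.beads

    def residue_ordinal(self, chain_id: str, residue_index: int) -> int:
        """Global 0-based position of a residue in topology order."""
        return self._residue_pos[(chain_id, residue_index)]

    def backbone_bead_index(self, chain_id: str, residue_index: int) -> int:
        return self._backbone_bead[(chain_id, residue_index)]

    def chain_residue_indices(self, chain_id: str) -> list[int]:
        return [r for c, r in self.residues if c == chain_id]

    def chain_length(self, chain_id: str) -> int:
        return len(self.chain_residue_indices(chain_id))

    def beads_of_chain(self, chain_id: str) -> list[Bead]:
        return [b for b in self.beads if b.chain_id == chain_id]

    def are_adjacent(self, res_a: tuple[str, int], res_b: tuple[str, int]) -> bool:
        """Sequence adjacency: same chain and |Δindex| == 1."""
        return res_a[0] == res_b[0] and abs(res_a[1] - res_b[1]) == 1

    def subset(self, bead_positions: Sequence[int]) -> "Topology":
        return Topology([self.beads[i] for i in bead_positions])


class Trajectory:
    """Frames of bead coordinates (nm) with per-frame orthorhombic boxes."""

    def __init__(
        self,
        coordinates: np.ndarray,
        box: np.ndarray,
        frame_stride_time: float = 0.0,
    ):
        coords = np.asarray(coordinates, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TrajectoryError(
                f"coordinates must have shape (n_frames, n_beads, 3), got {coords.shape}"
            )
        boxes = np.asarray(box, dtype=np.float64)
        if boxes.ndim == 1:
            boxes = np.tile(boxes, (coords.shape[0], 1))
        if boxes.shape != (coords.shape[0], 3):
            raise TrajectoryError(
                f"box must have shape (n_frames, 3), got {boxes.shape}"
            )
        if not np.all(boxes > 0):
            raise TrajectoryError("box lengths must be positive")
        self.coordinates = coords
        self.box = boxes
        self.frame_stride_time = float(frame_stride_time)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        return self.coordinates[t], self.box[t]


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Minimum-image displacement vector(s) b→a under an orthorhombic box.

    Broadcasts over leading axes; the last axis is x, y, z.
    """
    box = np.asarray(box, dtype=np.float64)
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> float | np.ndarray:
    """Minimum-image Euclidean distance between points ``a`` and ``b``."""
    box = np.asarray(box, dtype=np.float64)
    if not np.all(box > 0):
        raise ValueError("box lengths must be positive")
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# GRO reading/writing
#
# Fixed-width GRO records: resid(5) resname(5) atomname(5) atomnum(5)
# then %8.3f coordinates in nm. Multi-frame trajectories are stored as
# concatenated frames (title/natoms/atoms/box, repeated). GRO has no chain
# field: a restart (decrease) of the residue number marks a chain break,
# and chains are labelled A, B, C, ... in file order.


def _chain_label(k: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    label = ""
    k0 = k
    while True:
        label = letters[k0 % 26] + label
        k0 = k0 // 26 - 1
        if k0 < 0:
            return label


def _parse_gro_frame(lines: list[str], offset: int):
    """Parse one GRO frame starting at ``lines[offset]``.

    Returns (records, coords, box, next_offset); records are
    (resid_1based, resname, atomname) tuples.
    """
    if offset + 2 > len(lines):
        raise TrajectoryError(f"truncated GRO frame at line {offset + 1}")
    try:
        natoms = int(lines[offset + 1].strip())
    except ValueError as exc:
        raise TrajectoryError(
            f"line {offset + 2}: expected atom count, got {lines[offset + 1]!r}"
        ) from exc
    end = offset + 2 + natoms
    if end + 1 > len(lines):
        raise TrajectoryError(
            f"truncated GRO frame: expected {natoms} atoms plus box after "
            f"line {offset + 2}"
        )
    records = []
    coords = np.empty((natoms, 3), dtype=np.float64)
    for i in range(natoms):
        ln = lines[offset + 2 + i]
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            atomname = ln[10:15].strip()
            coords[i, 0] = float(ln[20:28])
            coords[i, 1] = float(ln[28:36])
            coords[i, 2] = float(ln[36:44])
        except (ValueError, IndexError) as exc:
            raise TrajectoryError(
                f"line {offset + 3 + i}: malformed GRO atom record {ln!r}"
            ) from exc
        records.append((resid, resname, atomname))
    box_fields = lines[end].split()
    if len(box_fields) < 3:
        raise TrajectoryError(f"line {end + 1}: malformed GRO box line")
    if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
        raise TrajectoryError(
            "triclinic boxes are not supported (off-diagonal box components "
            f"found at line {end + 1})"
        )
    box = np.array([float(v) for v in box_fields[:3]], dtype=np.float64)
    return records, coords, box, end + 1


def _read_gro(path: Path, first_frame_only: bool = False):
    lines = Path(path).read_text().splitlines()
    frames = []
    boxes = []
    records = None
    offset = 0
    while offset < len(lines):
        if first_frame_only and frames:
            break
        if not lines[offset].strip() and offset + 1 >= len(lines):
            break  # trailing blank line
        recs, coords, box, offset = _parse_gro_frame(lines, offset)
        if records is None:
            records = recs
        elif recs != records:
            raise TrajectoryError(
                "GRO frames disagree on atom records (is this one trajectory?)"
            )
        frames.append(coords)
        boxes.append(box)
    if records is None:
        raise TrajectoryError(f"{path}: empty GRO file")
    return records, np.array(frames), np.array(boxes)


def write_gro(
    path,
    topology: Topology,
    trajectory: Trajectory,
    title: str = "coarse-grained system",
) -> None:
    """Write a (possibly multi-frame) GRO file.

    Residue numbering restarts at 1 on each chain so chain boundaries
    survive the round trip.
    """
    lines: list[str] = []
    for t in range(trajectory.n_frames):
        coords, box = trajectory.frame(t)
        lines.append(f"{title}, frame {t}")
        lines.append(f"{len(topology.beads):5d}")
        for k, b in enumerate(topology.beads):
            resid = (b.residue_index + 1) % 100000
            x, y, z = coords[k]
            lines.append(
                f"{resid:5d}{b.residue_name:<5.5s}{_gro_atom_name(b):>5.5s}"
                f"{(b.index + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _gro_atom_name(b: Bead) -> str:
    # bead types double as atom names (MARTINI-style "BB"/"SC1" naming),
    # so write/read round-trips preserve both the type and the backbone flag
    return b.bead_type


def _beads_from_records(
    records,
    backbone_names: Iterable[str],
    charge_map: Mapping[str, float] | None,
    chain_ids: Sequence[str] | None = None,
    resnames_as_types: bool = False,
):
    """Build beads from (resid, resname, atomname[, chain]) records."""
    backbone = set(backbone_names)
    charge_map = charge_map or {}
    beads = []
    chain_no = -1
    prev_resid = None
    prev_chain_key = object()
    res0 = 0
    for k, rec in enumerate(records):
        resid, resname, atomname = rec[:3]
        explicit_chain = rec[3] if len(rec) > 3 else None
        chain_key = explicit_chain
        new_chain = (
            chain_no < 0
            or (explicit_chain is not None and chain_key != prev_chain_key)
            or (explicit_chain is None and prev_resid is not None and resid < prev_resid)
        )
        if new_chain:
            chain_no += 1
            res0 = resid
        prev_resid = resid
        prev_chain_key = chain_key
        if explicit_chain is not None:
            cid = explicit_chain
        elif chain_ids is not None and chain_no < len(chain_ids):
            cid = chain_ids[chain_no]
        else:
            cid = _chain_label(chain_no)
        beads.append(
            Bead(
                index=k,
                residue_index=resid - res0,
                chain_id=cid,
                residue_name=resname,
                bead_type=atomname,
                is_backbone=atomname in backbone,
                charge=float(charge_map.get(atomname, 0.0)),
            )
        )
    return beads


# ---------------------------------------------------------------------------
# PDB reading/writing (via MDAnalysis)


def _read_pdb(path: Path):
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        records = []
        for atom in u.atoms:
            seg = atom.chainID if hasattr(atom, "chainID") and atom.chainID else atom.segid
            records.append((int(atom.resid), atom.resname, atom.name, seg or "A"))
        frames = []
        boxes = []
        for ts in u.trajectory:
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                raise TrajectoryError(f"{path}: PDB frame lacks a CRYST1 box")
            alpha, beta, gamma = ts.dimensions[3:6]
            if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
                raise TrajectoryError(
                    "triclinic boxes are not supported (non-90° angles in CRYST1)"
                )
            frames.append(ts.positions.astype(np.float64) / 10.0)  # Å → nm
            boxes.append(ts.dimensions[:3].astype(np.float64) / 10.0)
    return records, np.array(frames), np.array(boxes)


def write_pdb(path, topology: Topology, trajectory: Trajectory) -> None:
    """Write a multi-model PDB (one MODEL per frame), coordinates in Å."""
    lines: list[str] = []
    for t in range(trajectory.n_frames):
        coords, box = trajectory.frame(t)
        bx = box * 10.0
        lines.append(
            f"CRYST1{bx[0]:9.3f}{bx[1]:9.3f}{bx[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
        lines.append(f"MODEL     {t + 1:4d}")
        for k, b in enumerate(topology.beads):
            x, y, z = coords[k] * 10.0
            name = _gro_atom_name(b)
            serial = (b.index + 1) % 100000
            # strict column layout: name 13-16, resName 18-20, chainID 22,
            # resSeq 23-26, coordinates 31-54
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {b.residue_name:>3.3s} "
                f"{b.chain_id[:1]}{(b.residue_index + 1) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# public loaders


def load_topology(
    path,
    format: str | None = None,
    backbone_names: Iterable[str] = DEFAULT_BACKBONE_NAMES,
    charge_map: Mapping[str, float] | None = None,
    chain_ids: Sequence[str] | None = None,
) -> Topology:
    """Load a Topology from a GRO or (multi-model) PDB file.

    The backbone flag is assigned by bead-name whitelist (default ``{"BB"}``).
    File residue numbers (1-based) become 0-based per-chain indices.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        records, _, _ = _read_gro(path, first_frame_only=True)
        beads = _beads_from_records(records, backbone_names, charge_map, chain_ids)
    elif fmt == "pdb":
        records, _, _ = _read_pdb(path)
        beads = _beads_from_records(records, backbone_names, charge_map)
    else:
        raise ValueError(f"unsupported topology format {fmt!r} (use gro or pdb)")
    return Topology(beads)


def load_trajectory(path, topology: Topology, format: str | None = None) -> Trajectory:
    """Load a trajectory (concatenated-frame GRO or multi-model PDB)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        _, frames, boxes = _read_gro(path)
    elif fmt == "pdb":
        _, frames, boxes = _read_pdb(path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r} (use gro or pdb)")
    for t, frame in enumerate(frames):
        if frame.shape[0] != len(topology):
            raise TrajectoryError(
                f"frame {t} has {frame.shape[0]} beads, topology has {len(topology)}"
            )
    return Trajectory(frames, boxes)


# ---------------------------------------------------------------------------
# nonbonded parameters and selections


@dataclass
class NonbondedTable:
    """Per bead-type-pair Lennard-Jones parameters and global settings.

    ``dialect`` selects the truncation scheme: ``plain`` (truncated),
    ``cut_shift`` (potential-shifted), or ``gromacs_shift`` (polynomial
    force-shift over [r_shift, r_cut], the coarse-grained convention).
    """

    pairs: dict[tuple[str, str], tuple[float, float]]
    coulomb_eps_r: float = 2.5
    r_shift: float = 0.9
    r_cut: float = 1.2
    dialect: str = "gromacs_shift"
    use_coulomb: bool = True

    def __post_init__(self):
        if self.dialect not in ("plain", "cut_shift", "gromacs_shift"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not (0.0 <= self.r_shift < self.r_cut):
            raise ValueError("require 0 <= r_shift < r_cut")
        # symmetrise
        sym = {}
        for (ta, tb), v in self.pairs.items():
            prev = sym.get((tb, ta))
            if prev is not None and not np.allclose(prev, v):
                raise ValueError(f"asymmetric parameters for pair ({ta}, {tb})")
            sym[(ta, tb)] = v
            sym[(tb, ta)] = v
        self.pairs = sym

    def epsilon_sigma(self, type_a: str, type_b: str) -> tuple[float, float]:
        try:
            return self.pairs[(type_a, type_b)]
        except KeyError:
            raise KeyError(
                f"no nonbonded parameters for bead-type pair ({type_a}, {type_b})"
            ) from None

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NonbondedTable":
        """Read a delimited text table: type_a, type_b, epsilon_kJmol, sigma_nm."""
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python")
        required = {"type_a", "type_b", "epsilon_kJmol", "sigma_nm"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"nonbonded table needs header columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        pairs = {
            (str(r.type_a), str(r.type_b)): (float(r.epsilon_kJmol), float(r.sigma_nm))
            for r in df.itertuples()
        }
        return cls(pairs=pairs, **kwargs)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        seen = set()
        for (ta, tb), (eps, sig) in self.pairs.items():
            key = tuple(sorted((ta, tb)))
            if key in seen:
                continue
            seen.add(key)
            rows.append({"type_a": ta, "type_b": tb, "epsilon_kJmol": eps, "sigma_nm": sig})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SelectionConfig:
    """Which residues form each helix/leaflet element and which chains are ligands.

    Ranges are inclusive 0-based (start, end) residue-index intervals per chain.
    """

    helix_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    leaflet_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    ligand_chain_ids: list[str] = field(default_factory=list)
    pore_axis_mode: str = "fixed_z"

    def __post_init__(self):
        if self.pore_axis_mode not in ("fixed_z", "per_frame_principal"):
            raise ValueError(f"unknown pore_axis_mode {self.pore_axis_mode!r}")
        for name, ranges in (("helix", self.helix_ranges), ("leaflet", self.leaflet_ranges)):
            for chain, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ValueError(f"{name} range for chain {chain!r}: {lo} > {hi}")

    def validate_against(self, topology: Topology) -> None:
        for name, ranges in (("helix", self.helix_ranges), ("leaflet", self.leaflet_ranges)):
            for chain, (lo, hi) in ranges.items():
                idx = set(topology.chain_residue_indices(chain))
                if not idx.issuperset(range(lo, hi + 1)):
                    raise ValueError(
                        f"{name} range {lo}-{hi} outside chain {chain!r} bounds"
                    )

    @classmethod
    def from_yaml(cls, path) -> "SelectionConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            helix_ranges={
                str(c): (int(v[0]), int(v[1]))
                for c, v in (raw.get("helix_ranges") or {}).items()
            },
            leaflet_ranges={
                str(c): (int(v[0]), int(v[1]))
                for c, v in (raw.get("leaflet_ranges") or {}).items()
            },
            ligand_chain_ids=[str(c) for c in raw.get("ligand_chain_ids", [])],
            pore_axis_mode=raw.get("pore_axis_mode", "fixed_z"),
        )

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(
            yaml.safe_dump(
                {
                    "helix_ranges": {c: list(v) for c, v in self.helix_ranges.items()},
                    "leaflet_ranges": {c: list(v) for c, v in self.leaflet_ranges.items()},
                    "ligand_chain_ids": list(self.ligand_chain_ids),
                    "pore_axis_mode": self.pore_axis_mode,
                }
            )
        )
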