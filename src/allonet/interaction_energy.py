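"""Nonbonded residue–residue interaction energies from coarse-grained frames.

Per-frame pairwise residue interaction energies E_ij are the raw material
of the interaction-correlation analysis: for every non-adjacent residue
pair the Lennard-Jones (and optionally short-range Coulomb) energies of
all bead pairs are summed under minimum-image periodic boundary
conditions. Only short-range potentials are evaluated — the coarse-grained
convention encodes screening in the parameters and includes no long-range
electrostatics.

Truncation dialects
-------------------
``plain``          truncated LJ/Coulomb, discontinuous at the cutoff
``cut_shift``      potential shifted by its cutoff value
``gromacs_shift``  polynomial force-shift applied separately to the r^-12
                   and r^-6 (and r^-1) terms so that energy and force are
                   continuous and vanish at the cutoff
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cg_system import (
    NonbondedTable,
    Topology,
    Trajectory,
    minimum_image_displacement,
)

__all__ = [
    "COULOMB_CONSTANT",
    "InteractionEnergySeries",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "residue_pair_energies",
    "energy_series",
]

#: Coulomb constant f = 1/(4 π ε0) in kJ·nm/(mol·e²).
COULOMB_CONSTANT = 138.935458

ResiduePair = tuple[tuple[str, int], tuple[str, int]]


def _shift_constants(p: int, r1: float, rc: float) -> tuple[float, float, float]:
    """Force-shift constants (A, B, C) for a 1/r^p term over [r1, rc].

    The shifted force F(r) = p/r^(p+1) + A (r-r1)^2 + B (r-r1)^3 satisfies
    F(rc) = 0 and F'(rc) = 0; C makes the integrated potential vanish at rc.
    """
    d = rc - r1
    A = -p * ((p + 4) * rc - (p + 1) * r1) / (rc ** (p + 2) * d**2)
    B = p * ((p + 3) * rc - (p + 1) * r1) / (rc ** (p + 2) * d**3)
    C = 1.0 / rc**p - A / 3.0 * d**3 - B / 4.0 * d**4
    return A, B, C


def _phi_shifted(r, p: int, r1: float, rc: float):
    """Force-shifted 1/r^p potential term, vanishing smoothly at rc."""
    r = np.asarray(r, dtype=np.float64)
    A, B, C = _shift_constants(p, r1, rc)
    out = np.where(
        r < r1,
        1.0 / np.maximum(r, 1e-300) ** p - C,
        1.0 / np.maximum(r, 1e-300) ** p
        - A / 3.0 * np.maximum(r - r1, 0.0) ** 3
        - B / 4.0 * np.maximum(r - r1, 0.0) ** 4
        - C,
    )
    return np.where(r < rc, out, 0.0)


def lj_pair_energy(r, epsilon: float, sigma: float, table: NonbondedTable):
    """Lennard-Jones 12-6 energy (kJ/mol) at distance r (nm) under the table's dialect."""
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(r_arr <= 0):
        raise ValueError("pair distance must be positive")
    rc = table.r_cut
    if table.dialect == "gromacs_shift":
        e = 4.0 * epsilon * (
            sigma**12 * _phi_shifted(r_arr, 12, table.r_shift, rc)
            - sigma**6 * _phi_shifted(r_arr, 6, table.r_shift, rc)
        )
    else:
        sr6 = (sigma / r_arr) ** 6
        e = 4.0 * epsilon * (sr6**2 - sr6)
        if table.dialect == "cut_shift":
            src6 = (sigma / rc) ** 6
            e = e - 4.0 * epsilon * (src6**2 - src6)
        e = np.where(r_arr < rc, e, 0.0)
    e = np.where(r_arr < rc, e, 0.0)
    return float(e) if np.isscalar(r) else e


def coulomb_pair_energy(r, q1: float, q2: float, table: NonbondedTable):
    """Screened short-range Coulomb energy (kJ/mol); shift range [0, r_cut]."""
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(r_arr <= 0):
        raise ValueError("pair distance must be positive")
    if q1 == 0.0 or q2 == 0.0:
        z = np.zeros_like(r_arr)
        return float(z) if np.isscalar(r) else z
    pref = COULOMB_CONSTANT * q1 * q2 / table.coulomb_eps_r
    rc = table.r_cut
    if table.dialect == "gromacs_shift":
        e = pref * _phi_shifted(r_arr, 1, 0.0, rc)
    else:
        e = pref / r_arr
        if table.dialect == "cut_shift":
            e = e - pref / rc
        e = np.where(r_arr < rc, e, 0.0)
    e = np.where(r_arr < rc, e, 0.0)
    return float(e) if np.isscalar(r) else e


def _candidate_bead_pairs(
    coords: np.ndarray, box: np.ndarray, r_cut: float, method: str
) -> np.ndarray:
    """Bead-index pairs (k, l), k < l, within r_cut under PBC."""
    if method == "cell":
        # KD-tree with periodic boxsize wants coordinates inside the box
        wrapped = np.mod(coords, box)
        # guard against coordinates landing exactly on the upper boundary
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(r_cut, output_type="ndarray")
        return pairs
    if method == "brute":
        n = coords.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        d = minimum_image_displacement(coords[ii], coords[jj], box)
        r = np.sqrt(np.sum(d * d, axis=1))
        keep = r < r_cut
        return np.column_stack([ii[keep], jj[keep]])
    raise ValueError(f"unknown neighbor search method {method!r}")


def residue_pair_energies(
    frame: np.ndarray,
    topology: Topology,
    table: NonbondedTable,
    box: np.ndarray,
    exclude_chains: Sequence[str] = (),
    neighbor_method: str = "cell",
) -> dict[ResiduePair, float]:
    """Nonbonded residue-pair energies for one frame.

    Sums LJ (+ Coulomb if enabled) over all bead pairs of each residue
    pair, using minimum-image distances. Intra-residue pairs and
    sequence-adjacent pairs (same chain, |Δindex| = 1) are excluded —
    those residues are covalently bonded. Pairs with every bead distance
    beyond the cutoff are absent from the map.
    """
    coords = np.asarray(frame, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    keep_bead = np.array(
        [b.chain_id not in exclude_chains for b in topology.beads], dtype=bool
    )
    table_types = {t for pair in table.pairs for t in pair}
    for b, kept in zip(topology.beads, keep_bead):
        if kept and b.bead_type not in table_types:
            raise KeyError(
                f"bead type {b.bead_type!r} not present in the nonbonded table"
            )

    pairs = _candidate_bead_pairs(coords, box, table.r_cut, neighbor_method)
    if pairs.size == 0:
        return {}
    k, l = pairs[:, 0], pairs[:, 1]
    mask = keep_bead[k] & keep_bead[l]
    k, l = k[mask], l[mask]

    res_ord = topology.bead_residue_ordinal
    ok, ol = res_ord[k], res_ord[l]
    same_res = ok == ol
    beads = topology.beads
    chain_of = np.array([hash(b.chain_id) for b in beads])  # fast same-chain test
    ridx = np.array([b.residue_index for b in beads])
    bead_chain = chain_of
    adjacent = (bead_chain[k] == bead_chain[l]) & (np.abs(ridx[k] - ridx[l]) == 1)
    mask = ~(same_res | adjacent)
    k, l = k[mask], l[mask]
    if k.size == 0:
        return {}

    d = minimum_image_displacement(coords[k], coords[l], box)
    r = np.sqrt(np.sum(d * d, axis=1))

    types = [b.bead_type for b in beads]
    charges = np.array([b.charge for b in beads])
    energies = np.zeros(k.size)
    # group bead pairs by type pair so LJ evaluation is vectorised
    type_idx = {t: i for i, t in enumerate(sorted(set(types)))}
    tcode = np.array([type_idx[t] for t in types])
    pair_code = tcode[k] * len(type_idx) + tcode[l]
    inv_types = {i: t for t, i in type_idx.items()}
    for code in np.unique(pair_code):
        sel = pair_code == code
        ta = inv_types[int(code) // len(type_idx)]
        tb = inv_types[int(code) % len(type_idx)]
        eps, sig = table.epsilon_sigma(ta, tb)
        energies[sel] += lj_pair_energy(r[sel], eps, sig, table)
    if table.use_coulomb:
        qq = charges[k] * charges[l]
        charged = qq != 0.0
        if np.any(charged):
            pref = COULOMB_CONSTANT / table.coulomb_eps_r
            if table.dialect == "gromacs_shift":
                phi = _phi_shifted(r[charged], 1, 0.0, table.r_cut)
            elif table.dialect == "cut_shift":
                phi = np.where(
                    r[charged] < table.r_cut, 1.0 / r[charged] - 1.0 / table.r_cut, 0.0
                )
            else:
                phi = np.where(r[charged] < table.r_cut, 1.0 / r[charged], 0.0)
            energies[charged] += pref * qq[charged] * phi

    # accumulate bead-pair energies into residue pairs (canonical order:
    # lower global residue ordinal first)
    lo = np.minimum(ok[mask], ol[mask])
    hi = np.maximum(ok[mask], ol[mask])
    out: dict[ResiduePair, float] = {}
    residues = topology.residues
    code = lo * topology.residue_count + hi
    order = np.argsort(code, kind="stable")
    code_s, e_s = code[order], energies[order]
    uniq, start = np.unique(code_s, return_index=True)
    sums = np.add.reduceat(e_s, start)
    for c, e in zip(uniq, sums):
        i, j = divmod(int(c), topology.residue_count)
        out[(residues[i], residues[j])] = float(e)
    return out


@dataclass
class InteractionEnergySeries:
    """Time series E_ij(t), one row per retained residue pair.

    ``pairs`` are ((chain, residue_index), (chain, residue_index)) tuples
    in canonical order (lower global residue ordinal first, deduplicated);
    ``values`` has shape (n_pairs, n_frames), kJ/mol.
    """

    pairs: list[ResiduePair]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.pairs):
            raise ValueError(
                f"values shape {self.values.shape} does not match {len(self.pairs)} pairs"
            )
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate residue pairs in series")
        for (ca, ia), (cb, ib) in self.pairs:
            if ca == cb and abs(ia - ib) == 1:
                raise ValueError(
                    f"series contains sequence-adjacent pair (({ca},{ia}), ({cb},{ib}))"
                )

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def mean_energies(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def residues(self) -> list[tuple[str, int]]:
        """All residues appearing in any pair, sorted."""
        seen = {r for p in self.pairs for r in p}
        return sorted(seen)

    def to_frame(self):
        import pandas as pd

        cols: dict = {
            "chain_i": [p[0][0] for p in self.pairs],
            "res_i": [p[0][1] for p in self.pairs],
            "chain_j": [p[1][0] for p in self.pairs],
            "res_j": [p[1][1] for p in self.pairs],
        }
        for t in range(self.n_frames):
            cols[f"e{t:05d}"] = self.values[:, t]
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        """Persist as tab-delimited text (pair id columns + one column per frame)."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def load(cls, path) -> "InteractionEnergySeries":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        pair_cols = ["chain_i", "res_i", "chain_j", "res_j"]
        frame_cols = [c for c in df.columns if c not in pair_cols]
        pairs = [
            ((str(r.chain_i), int(r.res_i)), (str(r.chain_j), int(r.res_j)))
            for r in df.itertuples()
        ]
        return cls(pairs=pairs, values=df[frame_cols].to_numpy(dtype=np.float64))


def energy_series(
    trajectory: Trajectory,
    topology: Topology,
    table: NonbondedTable,
    stride: int = 1,
    exclude_chains: Sequence[str] = (),
    neighbor_method: str = "cell",
) -> InteractionEnergySeries:
    """Residue-pair interaction-energy time series over frames 0, stride, 2·stride, …

    The pair list is the union of pairs appearing in any processed frame;
    frames where a pair is beyond the cutoff contribute 0.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    frames = range(0, trajectory.n_frames, stride)
    per_frame: list[dict[ResiduePair, float]] = []
    for t in frames:
        coords, box = trajectory.frame(t)
        per_frame.append(
            residue_pair_energies(
                coords,
                topology,
                table,
                box,
                exclude_chains=exclude_chains,
                neighbor_method=neighbor_method,
            )
        )
    ordinal = {r: k for k, r in enumerate(topology.residues)}
    all_pairs = sorted(
        {p for fr in per_frame for p in fr},
        key=lambda p: (ordinal[p[0]], ordinal[p[1]]),
    )
    values = np.zeros((len(all_pairs), len(per_frame)))
    index = {p: m for m, p in enumerate(all_pairs)}
    for t, fr in enumerate(per_frame):
        for p, e in fr.items():
            values[index[p], t] = e
    return InteractionEnergySeries(pairs=all_pairs, values=values)
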