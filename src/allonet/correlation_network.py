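"""Interaction-correlation network analysis.

The core of the package. Residue-pair interaction-energy time series are
filtered by mean energy, correlated pairwise over time (Pearson), and the
surviving pair–pair correlations are projected back onto residues:

    R_ij = Σ_m Σ_n |C_{m,n}|  over retained pairs m ∋ i and n ∋ j, m ≠ n.

Row sums of R score each residue's energetic coupling to the rest of the
structure; residues above a percentile cut are the network's hot-spots.
Consensus (element-wise RMS) and difference (RMS of element-wise
differences against a reference condition) matrices compare binding
conditions, and divisive hierarchical clustering of the rows of R yields
a cross-sectional decomposition of the network.

The ``InteractionCorrelationModel`` / ``CorrelationNetworkResults`` pair
wraps these operations in a fit-once, query-many interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cg_system import Topology
from .interaction_energy import InteractionEnergySeries, ResiduePair

__all__ = [
    "MEAN_ENERGY_THRESHOLD_KJMOL",
    "CORRELATION_THRESHOLD",
    "RetainedPairSet",
    "PairCorrelationMatrix",
    "ResidueCorrelationMatrix",
    "ScoreVector",
    "HotSpotSet",
    "ClusterTree",
    "filter_by_mean_energy",
    "pair_correlations",
    "project_to_residues",
    "consensus_rms",
    "difference_rms",
    "residue_scores",
    "fold_by_subunit",
    "select_hotspots",
    "quartile_overlap",
    "row_distance_matrix",
    "divisive_cluster",
    "InteractionCorrelationModel",
    "CorrelationNetworkResults",
]

#: Mean-energy filter: 0.02 kcal/mol expressed exactly in kJ/mol.
MEAN_ENERGY_THRESHOLD_KJMOL = 0.08368
#: Pair-correlation magnitude below which entries are discarded.
CORRELATION_THRESHOLD = 0.4

Residue = tuple[str, int]


@dataclass
class RetainedPairSet:
    """Residue pairs surviving the |mean energy| filter."""

    pairs: list[ResiduePair]
    mean_energies: np.ndarray
    indices: np.ndarray  # positions of the retained pairs in the source series
    threshold: float

    def __len__(self) -> int:
        return len(self.pairs)


def filter_by_mean_energy(
    series: InteractionEnergySeries,
    threshold: float = MEAN_ENERGY_THRESHOLD_KJMOL,
) -> RetainedPairSet:
    """Retain pairs whose time-mean interaction energy has magnitude ≥ threshold.

    Interaction energies are predominantly negative (attractive), so the
    filter acts on |mean|: it removes weak, noise-dominated contacts, not
    attraction per se.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = series.mean_energies()
    keep = np.abs(means) >= threshold
    idx = np.nonzero(keep)[0]
    return RetainedPairSet(
        pairs=[series.pairs[i] for i in idx],
        mean_energies=means[idx],
        indices=idx,
        threshold=threshold,
    )


@dataclass
class PairCorrelationMatrix:
    """Sparse symmetric pair–pair Pearson correlations above the magnitude cut.

    ``matrix`` is (n_retained, n_retained) with zero diagonal; stored
    entries satisfy |C| > c_min. Row/column m corresponds to
    ``pairs[m]``.
    """

    pairs: list[ResiduePair]
    matrix: sp.csr_matrix
    c_min: float

    @property
    def n_entries(self) -> int:
        return self.matrix.nnz

    def entry(self, m: int, n: int) -> float:
        return float(self.matrix[m, n])


def pair_correlations(
    series: InteractionEnergySeries,
    retained: RetainedPairSet,
    c_min: float = CORRELATION_THRESHOLD,
) -> PairCorrelationMatrix:
    """Pearson correlation over frames between every two retained pair series.

    Entries with |C| ≤ c_min are discarded; zero-variance (constant)
    series produce no entries rather than 0/0.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to correlate")
    if not (0.0 <= c_min < 1.0):
        raise ValueError("c_min must lie in [0, 1)")
    X = series.values[retained.indices]
    P = X.shape[0]
    if P == 0:
        return PairCorrelationMatrix([], sp.csr_matrix((0, 0)), c_min)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(Xc * Xc, axis=1))
    nonconst = norms > 0
    C = np.zeros((P, P))
    if np.any(nonconst):
        Y = Xc[nonconst] / norms[nonconst, None]
        block = Y @ Y.T
        np.clip(block, -1.0, 1.0, out=block)
        idx = np.nonzero(nonconst)[0]
        C[np.ix_(idx, idx)] = block
    np.fill_diagonal(C, 0.0)
    C[np.abs(C) <= c_min] = 0.0
    return PairCorrelationMatrix(
        pairs=list(retained.pairs), matrix=sp.csr_matrix(C), c_min=c_min
    )


@dataclass
class ResidueCorrelationMatrix:
    """Dense symmetric residue×residue matrix of nonnegative coupling scores."""

    labels: list[Residue]
    R: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64)
        if self.R.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        names = [f"{c}:{i}" for c, i in self.labels]
        return pd.DataFrame(self.R, index=names, columns=names)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def load(cls, path) -> "ResidueCorrelationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = []
        for name in df.index:
            chain, idx = str(name).rsplit(":", 1)
            labels.append((chain, int(idx)))
        return cls(labels=labels, R=df.to_numpy(dtype=np.float64))

    def _check_congruent(self, other: "ResidueCorrelationMatrix") -> None:
        if self.labels != other.labels:
            raise ValueError("residue correlation matrices have mismatched labels")


def project_to_residues(
    C: PairCorrelationMatrix,
    retained: RetainedPairSet,
    residue_labels: Sequence[Residue] | None = None,
    include_self_pairs: bool = False,
) -> ResidueCorrelationMatrix:
    """Project pair–pair correlations back onto residues.

    R_ij sums |C_{m,n}| over ordered retained-pair pairs (m, n) with
    residue i in pair m and residue j in pair n. Self pair-pairs (m = n)
    are excluded by default: each would contribute a constant |C| = 1 per
    directly interacting pair and swamp the projection.
    """
    if residue_labels is None:
        seen = {r for p in retained.pairs for r in p}
        residue_labels = sorted(seen)
    labels = list(residue_labels)
    pos = {r: k for k, r in enumerate(labels)}
    P = len(retained.pairs)
    n = len(labels)
    M = sp.lil_matrix((n, P))
    for m, (ra, rb) in enumerate(retained.pairs):
        M[pos[ra], m] = 1.0
        M[pos[rb], m] = 1.0
    M = M.tocsr()
    absC = abs(C.matrix)
    if include_self_pairs:
        absC = absC + sp.eye(P, format="csr")
    R = np.asarray((M @ absC @ M.T).todense())
    return ResidueCorrelationMatrix(labels=labels, R=R)


def consensus_rms(matrices: Sequence[ResidueCorrelationMatrix]) -> ResidueCorrelationMatrix:
    """Element-wise RMS average across binding conditions."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        first._check_congruent(m)
    stack = np.stack([m.R for m in matrices])
    return ResidueCorrelationMatrix(
        labels=list(first.labels), R=np.sqrt(np.mean(stack**2, axis=0))
    )


def difference_rms(
    bound: Sequence[ResidueCorrelationMatrix], free: ResidueCorrelationMatrix
) -> ResidueCorrelationMatrix:
    """RMS over bound conditions of the element-wise difference to the free matrix."""
    if not bound:
        raise ValueError("need at least one bound-condition matrix")
    for m in bound:
        free._check_congruent(m)
    stack = np.stack([m.R - free.R for m in bound])
    return ResidueCorrelationMatrix(
        labels=list(free.labels), R=np.sqrt(np.mean(stack**2, axis=0))
    )


@dataclass
class ScoreVector:
    """Per-residue (or per-position, after folding) correlation scores."""

    labels: list
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.labels),):
            raise ValueError("scores shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": [str(l) for l in self.labels], "score": self.scores})

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def residue_scores(
    R: ResidueCorrelationMatrix, zero_diagonal: bool = True
) -> ScoreVector:
    """Row sums of R: each residue's total coupling to the structure.

    The diagonal is zeroed by default — scores measure coupling to the
    *rest* of the structure.
    """
    mat = R.R.copy()
    if zero_diagonal:
        np.fill_diagonal(mat, 0.0)
    return ScoreVector(labels=list(R.labels), scores=mat.sum(axis=1))


def fold_by_subunit(scores: ScoreVector, topology: Topology) -> ScoreVector:
    """Average scores across subunits, yielding one score per sequence position.

    All (protein) chains must have equal length; residues absent from the
    score vector contribute 0 (they sit in no retained pair).
    """
    chains = sorted({c for c, _ in scores.labels})
    lengths = {c: topology.chain_length(c) for c in chains}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"chains have unequal lengths: {lengths}")
    length = next(iter(lengths.values()))
    by_label = dict(zip(scores.labels, scores.scores))
    folded = np.zeros(length)
    for p in range(length):
        folded[p] = np.mean([by_label.get((c, p), 0.0) for c in chains])
    return ScoreVector(labels=list(range(length)), scores=folded)


@dataclass
class HotSpotSet:
    """Residues/positions whose score strictly exceeds the percentile cut."""

    members: list
    percentile: float
    cut_value: float
    scores: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item) -> bool:
        return item in set(self.members)

    def save(self, path) -> None:
        df = pd.DataFrame(
            {
                "label": [str(m) for m in self.members],
                "score": [self.scores.get(m, np.nan) for m in self.members],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def select_hotspots(scores: ScoreVector, percentile: float = 75.0) -> HotSpotSet:
    """Residues scoring strictly above the given percentile of all scores.

    The percentile is computed by linear interpolation between closest
    ranks (numpy's default convention).
    """
    if len(scores.labels) == 0:
        raise ValueError("empty score vector")
    cut = float(np.percentile(scores.scores, percentile))
    members = [l for l, s in zip(scores.labels, scores.scores) if s > cut]
    return HotSpotSet(
        members=members,
        percentile=percentile,
        cut_value=cut,
        scores=dict(zip(scores.labels, scores.scores)),
    )


def quartile_overlap(a: HotSpotSet, b: HotSpotSet) -> tuple[int, int, int]:
    """Overlap of two hot-spot sets: (shared, total in a, percent of a shared).

    Percent is rounded to the nearest integer.
    """
    total = len(a.members)
    if total == 0:
        raise ValueError("hot-spot set a is empty; overlap percent undefined")
    shared = len(set(a.members) & set(b.members))
    percent = int(round(100.0 * shared / total))
    return shared, total, percent


def row_distance_matrix(R: ResidueCorrelationMatrix) -> np.ndarray:
    """D_ij = ‖R_i − R_j‖: Euclidean distance between correlation profiles.

    Residues are close when they correlate similarly with *everything*,
    not when they correlate with each other — the cross-sectional metric.
    """
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(R.R, metric="euclidean"))


@dataclass
class ClusterTree:
    """Result of divisive hierarchical clustering.

    ``labels[i]`` is the flat cluster id of object i at the stop
    condition; ``splits`` records (parent_members, splinter_members) in
    split order.
    """

    labels: np.ndarray
    splits: list[tuple[list[int], list[int]]]

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def clusters(self) -> list[list[int]]:
        return [
            list(np.nonzero(self.labels == c)[0]) for c in np.unique(self.labels)
        ]

    def save(self, path, labels: Sequence | None = None) -> None:
        names = labels if labels is not None else list(range(len(self.labels)))
        pd.DataFrame({"label": [str(n) for n in names], "cluster": self.labels}).to_csv(
            path, sep="\t", index=False
        )


def _diameter(D: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    sub = D[np.ix_(members, members)]
    return float(sub.max())


def _split_cluster(D: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One DIANA split: seed the splinter with the object of maximal average
    dissimilarity, then migrate objects closer (on average) to the splinter.

    Deterministic: ties broken by lowest object index.
    """
    members = sorted(members)
    if len(members) == 2:
        return [members[0]], [members[1]]
    sub = D[np.ix_(members, members)]
    n = len(members)
    avg = sub.sum(axis=1) / (n - 1)
    seed = int(np.argmax(avg))  # argmax takes the first (lowest index) on ties
    splinter = [seed]
    rest = [k for k in range(n) if k != seed]
    while len(rest) > 1:
        best_gain, best_k = 0.0, None
        for k in rest:
            d_rest = sub[k, [r for r in rest if r != k]].mean()
            d_spl = sub[k, splinter].mean()
            gain = d_rest - d_spl
            if gain > best_gain + 1e-15:
                best_gain, best_k = gain, k
        if best_k is None:
            break
        splinter.append(best_k)
        rest.remove(best_k)
    return sorted(members[k] for k in rest), sorted(members[k] for k in splinter)


def divisive_cluster(
    D: np.ndarray,
    n_clusters: int | None = None,
    diameter_threshold: float | None = None,
) -> ClusterTree:
    """DIANA-style divisive hierarchical clustering of a distance matrix.

    Repeatedly splits the cluster of largest diameter until ``n_clusters``
    clusters exist or every cluster's diameter is ≤ ``diameter_threshold``.
    Fully deterministic given D (ties broken by lowest index).
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (n_clusters is None) == (diameter_threshold is None):
        raise ValueError("specify exactly one of n_clusters or diameter_threshold")
    n = D.shape[0]
    if n_clusters is not None and not (1 <= n_clusters <= n):
        raise ValueError(f"n_clusters must be in [1, {n}]")

    clusters: list[list[int]] = [list(range(n))]
    splits: list[tuple[list[int], list[int]]] = []
    while True:
        if n_clusters is not None and len(clusters) >= n_clusters:
            break
        diams = [_diameter(D, c) for c in clusters]
        if diameter_threshold is not None and max(diams) <= diameter_threshold:
            break
        splittable = [k for k, c in enumerate(clusters) if len(c) > 1]
        if not splittable:
            break
        # largest diameter; ties -> cluster containing the lowest index
        best = max(
            splittable, key=lambda k: (diams[k], -min(clusters[k]))
        )
        parent = clusters.pop(best)
        if diams[best] == 0.0:
            # identical objects but more clusters demanded: peel lowest index
            left, right = [parent[0]], parent[1:]
        else:
            left, right = _split_cluster(D, parent)
        splits.append((sorted(parent), list(right)))
        clusters.append(sorted(left))
        clusters.append(sorted(right))
    clusters.sort(key=min)
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(clusters):
        labels[members] = cid
    return ClusterTree(labels=labels, splits=splits)


# ---------------------------------------------------------------------------
# model / results interface


class InteractionCorrelationModel:
    """Interaction-correlation network model over an energy time series.

    Parameters
    ----------
    series:
        Residue-pair interaction-energy time series (kJ/mol).
    mean_energy_threshold:
        |mean E_ij| below which pairs are discarded (kJ/mol; default the
        0.02 kcal/mol convention).
    correlation_threshold:
        |C| below which pair–pair correlations are discarded.
    include_self_pairs, zero_diagonal:
        Projection and scoring conventions; defaults exclude the m = n
        terms and zero R's diagonal before row-sum scoring.
    """

    def __init__(
        self,
        series: InteractionEnergySeries,
        mean_energy_threshold: float = MEAN_ENERGY_THRESHOLD_KJMOL,
        correlation_threshold: float = CORRELATION_THRESHOLD,
        include_self_pairs: bool = False,
        zero_diagonal: bool = True,
        residue_labels: Sequence[Residue] | None = None,
    ):
        self.series = series
        self.mean_energy_threshold = mean_energy_threshold
        self.correlation_threshold = correlation_threshold
        self.include_self_pairs = include_self_pairs
        self.zero_diagonal = zero_diagonal
        self.residue_labels = (
            list(residue_labels) if residue_labels is not None else None
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "InteractionCorrelationModel":
        """Build from a table with chain_i/res_i/chain_j/res_j + frame columns."""
        pair_cols = ["chain_i", "res_i", "chain_j", "res_j"]
        frame_cols = [c for c in df.columns if c not in pair_cols]
        pairs = [
            ((str(r.chain_i), int(r.res_i)), (str(r.chain_j), int(r.res_j)))
            for r in df.itertuples()
        ]
        series = InteractionEnergySeries(
            pairs=pairs, values=df[frame_cols].to_numpy(dtype=np.float64)
        )
        return cls(series, **kwargs)

    def fit(self) -> "CorrelationNetworkResults":
        retained = filter_by_mean_energy(self.series, self.mean_energy_threshold)
        C = pair_correlations(self.series, retained, self.correlation_threshold)
        R = project_to_residues(
            C,
            retained,
            residue_labels=self.residue_labels or self.series.residues(),
            include_self_pairs=self.include_self_pairs,
        )
        scores = residue_scores(R, zero_diagonal=self.zero_diagonal)
        return CorrelationNetworkResults(model=self, retained=retained, C=C, R=R, scores=scores)


class CorrelationNetworkResults:
    """Fitted interaction-correlation network: matrices, scores, hot-spots."""

    def __init__(self, model, retained, C, R, scores):
        self.model = model
        self.retained: RetainedPairSet = retained
        self.pair_matrix: PairCorrelationMatrix = C
        self.residue_matrix: ResidueCorrelationMatrix = R
        self.scores: ScoreVector = scores

    def folded_scores(self, topology: Topology) -> ScoreVector:
        return fold_by_subunit(self.scores, topology)

    def hotspots(
        self, percentile: float = 75.0, topology: Topology | None = None
    ) -> HotSpotSet:
        """Hot-spot residues (or per-position hot-spots when a topology is
        given, folding scores across subunits first)."""
        scores = self.scores if topology is None else self.folded_scores(topology)
        return select_hotspots(scores, percentile)

    def cluster(
        self,
        n_clusters: int | None = 10,
        diameter_threshold: float | None = None,
    ) -> ClusterTree:
        D = row_distance_matrix(self.residue_matrix)
        return divisive_cluster(
            D, n_clusters=n_clusters, diameter_threshold=diameter_threshold
        )

    def summary(self, top: int = 10) -> str:
        lines = [
            "Interaction-correlation network",
            "===============================",
            f"frames:                {self.model.series.n_frames}",
            f"pairs (input):         {self.model.series.n_pairs}",
            f"pairs retained:        {len(self.retained)}"
            f" (|mean E| >= {self.model.mean_energy_threshold:g} kJ/mol)",
            f"pair correlations:     {self.pair_matrix.n_entries}"
            f" (|C| > {self.model.correlation_threshold:g})",
            f"residues in network:   {len(self.residue_matrix.labels)}",
            "",
            f"top {top} residues by correlation score:",
        ]
        order = np.argsort(self.scores.scores)[::-1][:top]
        for k in order:
            lines.append(
                f"  {self.scores.labels[k]!s:>12}  {self.scores.scores[k]:10.4f}"
            )
        return "\n".join(lines)
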