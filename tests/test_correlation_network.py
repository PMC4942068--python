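"""Eq-1/Eq-2 core: filters, correlations, projection, scores, clustering."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from allonet.cg_system import Bead, Topology
from allonet.correlation_network import (
    HotSpotSet,
    InteractionCorrelationModel,
    PairCorrelationMatrix,
    ResidueCorrelationMatrix,
    RetainedPairSet,
    ScoreVector,
    consensus_rms,
    difference_rms,
    divisive_cluster,
    filter_by_mean_energy,
    fold_by_subunit,
    pair_correlations,
    project_to_residues,
    quartile_overlap,
    residue_scores,
    row_distance_matrix,
    select_hotspots,
)
from allonet.interaction_energy import InteractionEnergySeries


def _series(pairs, values):
    return InteractionEnergySeries(pairs=pairs, values=np.asarray(values, dtype=float))


PAIR_AB = (("A", 0), ("A", 2))
PAIR_CD = (("A", 4), ("B", 1))


# ---------------------------------------------------------------------------
# mean-energy filter


def test_attractive_pair_passes_via_absolute_value():
    s = _series([PAIR_AB], [[-0.5] * 5])
    kept = filter_by_mean_energy(s, threshold=0.08368)
    assert kept.pairs == [PAIR_AB]


def test_zero_mean_fluctuation_dropped():
    s = _series([PAIR_AB], [[1.0, -1.0, 1.0, -1.0]])
    assert len(filter_by_mean_energy(s, threshold=0.08368)) == 0


def test_filter_matches_one_line_oracle(rng):
    values = rng.normal(0, 0.2, size=(40, 30))
    pairs = [(("A", 0), ("A", 2 + k)) for k in range(40)]
    s = _series(pairs, values)
    kept = filter_by_mean_energy(s, threshold=0.08368)
    expected = [p for p, v in zip(pairs, values) if abs(v.mean()) >= 0.08368]
    assert kept.pairs == expected


# ---------------------------------------------------------------------------
# pair correlations (Eq 1)


def test_identical_series_correlate_to_one():
    x = np.arange(6.0)
    s = _series([PAIR_AB, PAIR_CD], [x, x])
    kept = filter_by_mean_energy(s, threshold=0.0)
    C = pair_correlations(s, kept, c_min=0.4)
    assert C.entry(0, 1) == pytest.approx(1.0)
    assert C.entry(1, 0) == pytest.approx(1.0)


def test_anticorrelation_retained_by_magnitude():
    x = np.arange(6.0)
    s = _series([PAIR_AB, PAIR_CD], [x, -x])
    kept = filter_by_mean_energy(s, threshold=0.0)
    C = pair_correlations(s, kept, c_min=0.4)
    assert C.entry(0, 1) == pytest.approx(-1.0)


def test_textbook_pearson_value():
    # direct covariance/variance oracle: r = 1/sqrt(28/3)
    s = _series([PAIR_AB, PAIR_CD], [[1, 2, 4], [1, 3, 2]])
    kept = filter_by_mean_energy(s, threshold=0.0)
    C = pair_correlations(s, kept, c_min=0.0)
    a, b = np.array([1, 2, 4.0]), np.array([1, 3, 2.0])
    da, db = a - a.mean(), b - b.mean()
    oracle = float(np.sum(da * db) / np.sqrt(np.sum(da**2) * np.sum(db**2)))
    assert C.entry(0, 1) == pytest.approx(oracle, abs=1e-12)
    assert oracle == pytest.approx(0.32732683535398854, abs=1e-12)


def test_zero_variance_series_yield_no_entries():
    s = _series([PAIR_AB, PAIR_CD], [[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
    kept = filter_by_mean_energy(s, threshold=0.0)
    C = pair_correlations(s, kept, c_min=0.0)
    assert C.n_entries == 0


def test_too_few_frames_rejected():
    s = _series([PAIR_AB], [[1.0]])
    kept = filter_by_mean_energy(s, threshold=0.0)
    with pytest.raises(ValueError, match="2 frames"):
        pair_correlations(s, kept, c_min=0.4)


def test_correlations_match_direct_pearson(rng):
    """Every stored entry equals the textbook Pearson coefficient to 1e-12."""
    values = rng.normal(-1.0, 0.5, size=(12, 50))
    pairs = [(("A", 0), ("A", 2 + k)) for k in range(12)]
    s = _series(pairs, values)
    kept = filter_by_mean_energy(s, threshold=0.0)
    C = pair_correlations(s, kept, c_min=0.0)
    dense = C.matrix.toarray()
    for m in range(12):
        for n in range(12):
            if m == n:
                continue
            a, b = values[m], values[n]
            da, db = a - a.mean(), b - b.mean()
            r = float(np.sum(da * db) / np.sqrt(np.sum(da**2) * np.sum(db**2)))
            assert dense[m, n] == pytest.approx(r, abs=1e-12)


# ---------------------------------------------------------------------------
# projection (Eq 2)


def _retained(pairs):
    return RetainedPairSet(
        pairs=pairs,
        mean_energies=np.full(len(pairs), -1.0),
        indices=np.arange(len(pairs)),
        threshold=0.0,
    )


def _pcm(pairs, entries, c_min=0.0):
    P = len(pairs)
    mat = np.zeros((P, P))
    for (m, n), v in entries.items():
        mat[m, n] = v
        mat[n, m] = v
    return PairCorrelationMatrix(pairs=pairs, matrix=sp.csr_matrix(mat), c_min=c_min)


def test_single_entry_projection():
    pairs = [(("A", 1), ("A", 3)), (("A", 5), ("A", 7))]  # residues 1,2 and 3,4 roles
    C = _pcm(pairs, {(0, 1): 0.5})
    R = project_to_residues(C, _retained(pairs))
    labels = R.labels
    idx = {lab: k for k, lab in enumerate(labels)}
    for i in (("A", 1), ("A", 3)):
        for j in (("A", 5), ("A", 7)):
            assert R.R[idx[i], idx[j]] == pytest.approx(0.5)
            assert R.R[idx[j], idx[i]] == pytest.approx(0.5)
    # no other nonzero off-diagonal entries
    total = R.R.sum()
    assert total == pytest.approx(0.5 * 8)


def test_negative_entry_projects_by_absolute_value():
    pairs = [(("A", 1), ("A", 3)), (("A", 5), ("A", 7))]
    R_pos = project_to_residues(_pcm(pairs, {(0, 1): 0.5}), _retained(pairs))
    R_neg = project_to_residues(_pcm(pairs, {(0, 1): -0.5}), _retained(pairs))
    np.testing.assert_allclose(R_neg.R, R_pos.R)


def test_projection_matches_quadruple_loop(rng):
    """Brute-force enumeration over all ordered pair-pairs on 8 residues."""
    residues = [("A", i) for i in range(0, 16, 2)]
    pairs = [
        (residues[a], residues[b])
        for a, b in itertools.combinations(range(8), 2)
    ]
    rng_pairs = rng.choice(len(pairs), size=10, replace=False)
    pairs = [pairs[i] for i in sorted(rng_pairs)]
    P = len(pairs)
    dense = np.zeros((P, P))
    for m in range(P):
        for n in range(m + 1, P):
            if rng.random() < 0.5:
                v = rng.uniform(-1, 1)
                dense[m, n] = dense[n, m] = v
    C = PairCorrelationMatrix(pairs=pairs, matrix=sp.csr_matrix(dense), c_min=0.0)
    R = project_to_residues(C, _retained(pairs), residue_labels=residues)
    expected = np.zeros((8, 8))
    for i, ri in enumerate(residues):
        for j, rj in enumerate(residues):
            tot = 0.0
            for m in range(P):
                for n in range(P):
                    if m == n:
                        continue
                    if ri in pairs[m] and rj in pairs[n]:
                        tot += abs(dense[m, n])
            expected[i, j] = tot
    np.testing.assert_allclose(R.R, expected, atol=1e-12)


def test_raising_cmin_never_increases_projection(rng):
    values = rng.normal(-1.0, 0.5, size=(10, 60))
    pairs = [(("A", 0), ("A", 2 + k)) for k in range(10)]
    s = _series(pairs, values)
    kept = filter_by_mean_energy(s, threshold=0.0)
    R_lo = project_to_residues(pair_correlations(s, kept, 0.1), kept)
    R_hi = project_to_residues(
        pair_correlations(s, kept, 0.5), kept, residue_labels=R_lo.labels
    )
    assert np.all(R_hi.R <= R_lo.R + 1e-12)


# ---------------------------------------------------------------------------
# consensus / difference matrices


def _rcm(entries, n=3):
    labels = [("A", i) for i in range(n)]
    R = np.zeros((n, n))
    for (i, j), v in entries.items():
        R[i, j] = R[j, i] = v
    return ResidueCorrelationMatrix(labels=labels, R=R)


def test_consensus_of_one_is_identity():
    m = _rcm({(0, 1): 2.0, (1, 2): 3.0})
    out = consensus_rms([m])
    np.testing.assert_allclose(out.R, m.R)


def test_consensus_of_identical_matrices_is_that_matrix():
    m = _rcm({(0, 1): 2.0})
    out = consensus_rms([m, m, m])
    np.testing.assert_allclose(out.R, m.R)


def test_consensus_rms_arithmetic():
    out = consensus_rms([_rcm({(0, 1): 3.0}), _rcm({(0, 1): 4.0})])
    assert out.R[0, 1] == pytest.approx(np.sqrt((9 + 16) / 2))


def test_difference_of_identical_inputs_is_zero():
    m = _rcm({(0, 1): 2.0})
    out = difference_rms([m], m)
    assert np.all(out.R == 0)


def test_difference_single_bound_is_absolute_difference():
    free = _rcm({(0, 1): 2.0})
    bound = _rcm({(0, 1): 0.5})
    out = difference_rms([bound], free)
    assert out.R[0, 1] == pytest.approx(1.5)


def test_difference_rms_arithmetic():
    free = _rcm({(0, 1): 1.0})
    b1 = _rcm({(0, 1): 2.0})  # diff +1
    b2 = _rcm({(0, 1): -2.0})  # diff -3
    out = difference_rms([b1, b2], free)
    assert out.R[0, 1] == pytest.approx(np.sqrt((1 + 9) / 2))


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        consensus_rms([_rcm({}, n=3), _rcm({}, n=4)])


# ---------------------------------------------------------------------------
# scores, folding, hot-spots


def test_scores_zero_matrix():
    assert np.all(residue_scores(_rcm({})).scores == 0)


def test_scores_single_entry():
    sv = residue_scores(_rcm({(0, 1): 2.0}))
    np.testing.assert_allclose(sv.scores, [2.0, 2.0, 0.0])


def test_scores_match_row_sum_oracle(rng):
    n = 7
    M = rng.uniform(0, 2, size=(n, n))
    R = (M + M.T) / 2
    m = ResidueCorrelationMatrix(labels=[("A", i) for i in range(n)], R=R)
    sv = residue_scores(m, zero_diagonal=True)
    expected = R.sum(axis=1) - np.diag(R)
    np.testing.assert_allclose(sv.scores, expected, atol=1e-12)


def _pentamer_topology(chain_len=4, chains="ABCDE"):
    beads = []
    k = 0
    for c in chains:
        for r in range(chain_len):
            beads.append(Bead(k, r, c, "GLY", "BB", True))
            k += 1
    return Topology(beads)


def test_fold_identical_chains():
    topo = _pentamer_topology()
    labels = [(c, r) for c in "ABCDE" for r in range(4)]
    base = np.array([1.0, 2.0, 3.0, 4.0])
    sv = ScoreVector(labels=labels, scores=np.tile(base, 5))
    folded = fold_by_subunit(sv, topo)
    np.testing.assert_allclose(folded.scores, base)


def test_fold_is_the_mean_across_chains():
    topo = _pentamer_topology(chain_len=1)
    labels = [(c, 0) for c in "ABCDE"]
    sv = ScoreVector(labels=labels, scores=np.array([1.0, 2, 3, 4, 5]))
    folded = fold_by_subunit(sv, topo)
    assert folded.scores[0] == pytest.approx(3.0)


def test_fold_unequal_chains_rejected():
    beads = [
        Bead(0, 0, "A", "GLY", "BB", True),
        Bead(1, 1, "A", "GLY", "BB", True),
        Bead(2, 0, "B", "GLY", "BB", True),
    ]
    topo = Topology(beads)
    sv = ScoreVector(labels=[("A", 0), ("B", 0)], scores=np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="unequal"):
        fold_by_subunit(sv, topo)


def test_hotspot_percentile_interpolation():
    """Scores 1..8 at the 75th percentile: cut 6.25, members scoring 7 and 8."""
    sv = ScoreVector(labels=list(range(1, 9)), scores=np.arange(1.0, 9.0))
    hot = select_hotspots(sv, percentile=75)
    assert hot.cut_value == pytest.approx(6.25)
    assert sorted(hot.members) == [7, 8]


def test_hotspot_all_equal_scores_gives_empty_set():
    sv = ScoreVector(labels=list(range(5)), scores=np.full(5, 2.0))
    assert len(select_hotspots(sv, percentile=75)) == 0


def test_hotspot_percentile_zero_takes_all_above_minimum():
    sv = ScoreVector(labels=list(range(4)), scores=np.array([1.0, 2, 3, 4]))
    hot = select_hotspots(sv, percentile=0)
    assert sorted(hot.members) == [1, 2, 3]


def test_quartile_overlap_published_arithmetic():
    universe = list(range(200))
    a = HotSpotSet(members=universe[:79], percentile=75, cut_value=0.0)
    b60 = HotSpotSet(members=universe[:60] + universe[100:119], percentile=75, cut_value=0.0)
    assert quartile_overlap(a, b60) == (60, 79, 76)
    b75 = HotSpotSet(members=universe[:75] + universe[100:104], percentile=75, cut_value=0.0)
    assert quartile_overlap(a, b75) == (75, 79, 95)
    assert quartile_overlap(a, a) == (79, 79, 100)


def test_quartile_overlap_empty_rejected():
    a = HotSpotSet(members=[], percentile=75, cut_value=0.0)
    b = HotSpotSet(members=[1], percentile=75, cut_value=0.0)
    with pytest.raises(ValueError, match="empty"):
        quartile_overlap(a, b)


# ---------------------------------------------------------------------------
# row distances and divisive clustering


def test_row_distance_examples():
    m = ResidueCorrelationMatrix(
        labels=[("A", 0), ("A", 1), ("A", 2)],
        R=np.array([[1.0, 0, 0], [0, 1.0, 0], [1.0, 0, 0]]),
    )
    D = row_distance_matrix(m)
    assert D[0, 2] == 0.0
    assert D[0, 1] == pytest.approx(np.sqrt(2))
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)


def test_row_distance_matches_norm_oracle(rng):
    R = rng.uniform(0, 3, size=(6, 6))
    R = (R + R.T) / 2
    m = ResidueCorrelationMatrix(labels=[("A", i) for i in range(6)], R=R)
    D = row_distance_matrix(m)
    for i in range(6):
        for j in range(6):
            assert D[i, j] == pytest.approx(np.linalg.norm(R[i] - R[j]), abs=1e-12)


def _blob_distance_matrix(rng, sizes, centers, spread=0.1):
    pts = np.concatenate(
        [c + spread * rng.standard_normal((s, 2)) for s, c in zip(sizes, centers)]
    )
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(pts))


def test_divisive_cluster_recovers_separated_groups(rng):
    D = _blob_distance_matrix(rng, [5, 6], [np.zeros(2), np.array([10.0, 0])])
    tree = divisive_cluster(D, n_clusters=2)
    labels = tree.labels
    assert len(set(labels[:5])) == 1
    assert len(set(labels[5:])) == 1
    assert labels[0] != labels[5]


def test_divisive_cluster_all_singletons(rng):
    D = _blob_distance_matrix(rng, [4], [np.zeros(2)], spread=1.0)
    tree = divisive_cluster(D, n_clusters=4)
    assert tree.n_clusters == 4
    assert sorted(tree.labels) == [0, 1, 2, 3]


def test_divisive_cluster_planted_three_groups(rng):
    """12 objects in 3 well-separated planted groups are recovered exactly."""
    centers = [np.zeros(2), np.array([20.0, 0]), np.array([0, 20.0])]
    D = _blob_distance_matrix(rng, [4, 4, 4], centers)
    tree = divisive_cluster(D, n_clusters=3)
    planted = [set(range(0, 4)), set(range(4, 8)), set(range(8, 12))]
    got = [set(c) for c in tree.clusters()]
    assert sorted(map(sorted, got)) == sorted(map(sorted, planted))


def test_divisive_cluster_diameter_threshold(rng):
    D = _blob_distance_matrix(rng, [5, 5], [np.zeros(2), np.array([50.0, 0])])
    tree = divisive_cluster(D, diameter_threshold=5.0)
    assert tree.n_clusters == 2


def test_divisive_cluster_rejects_asymmetric():
    D = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        divisive_cluster(D, n_clusters=2)


# ---------------------------------------------------------------------------
# model interface


def test_model_fit_is_deterministic(rng):
    values = rng.normal(-1.0, 0.5, size=(15, 80))
    pairs = [(("A", 0), ("A", 2 + k)) for k in range(15)]
    s = _series(pairs, values)
    r1 = InteractionCorrelationModel(s).fit()
    r2 = InteractionCorrelationModel(s).fit()
    assert np.array_equal(r1.residue_matrix.R, r2.residue_matrix.R)
    assert np.array_equal(r1.scores.scores, r2.scores.scores)


def test_model_from_dataframe_matches_series(rng):
    values = rng.normal(-1.0, 0.5, size=(5, 20))
    pairs = [(("A", 0), ("A", 2 + k)) for k in range(5)]
    s = _series(pairs, values)
    df = s.to_frame()
    m = InteractionCorrelationModel.from_dataframe(df)
    np.testing.assert_allclose(m.series.values, values, atol=1e-12)
    assert "Interaction-correlation network" in m.fit().summary()
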