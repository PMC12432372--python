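"""Lesion encoding, consensus clustering, marker discovery, classification."""

import math

import numpy as np
import pandas as pd
import pytest

from flgenomics import simulate as sim
from flgenomics import subtyping as st


def _matrix_from_blocks(block_sizes, marker_blocks, score=2):
    """Block-diagonal lesion matrix: cluster i lesioned at marker block i."""
    n = sum(block_sizes)
    markers = [f"M{j}" for j in range(sum(marker_blocks))]
    m = pd.DataFrame(
        0, index=[f"S{i:03d}" for i in range(n)], columns=markers, dtype=np.int64
    )
    r0 = 0
    c0 = 0
    for rows, cols in zip(block_sizes, marker_blocks):
        m.iloc[r0 : r0 + rows, c0 : c0 + cols] = score
        r0 += rows
        c0 += cols
    return m


class TestEncoding:
    @pytest.mark.parametrize(
        "kind,cn,score",
        [
            ("cnv_loss_peak", 0.79, 2),
            ("cnv_loss_peak", 0.80, 2),
            ("cnv_loss_peak", 1.6, 1),
            ("cnv_loss_peak", 1.61, 0),
            ("cnv_gain_peak", 2.39, 0),
            ("cnv_gain_peak", 2.4, 1),
            ("cnv_gain_peak", 3.7, 1),
            ("cnv_gain_peak", 3.71, 2),
            ("cnv_gain_peak", 4.1, 2),
            ("cnv_loss_peak", 1.0, 1),
            # direction respected: a loss at a gain peak (and vice versa) is neutral
            ("cnv_gain_peak", 0.5, 0),
            ("cnv_loss_peak", 5.0, 0),
        ],
    )
    def test_copy_number_tiers(self, kind, cn, score):
        assert st.score_copy_number(cn, kind) == score

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            st.score_copy_number(-0.1, "cnv_gain_peak")

    def test_mutation_and_sv_scores(self):
        markers = pd.DataFrame(
            {"kind": ["mutation", "mutation", "mutation", "sv"]},
            index=["g1", "g2", "g3", "bcl2_sv"],
        )
        calls = pd.DataFrame(
            {
                "sample": ["A", "A", "A", "A", "B"],
                "marker": ["g1", "g2", "g3", "bcl2_sv", "g1"],
                "kind": ["mutation"] * 3 + ["sv", "mutation"],
                "detail": ["nonsilent", "indel", "synonymous", 1, "none"],
            }
        )
        m = st.encode_lesions(calls, markers)
        assert m.loc["A"].tolist() == [2, 2, 1, 3]
        assert m.loc["B"].tolist() == [0, 0, 0, 0]

    def test_encoding_is_deterministic_pure_function(self):
        spec = sim.ClusterSpec(samples_per_cluster=10, seed=3)
        les = sim.simulate_lesions(spec)
        a = st.encode_lesions(les.calls, les.markers)
        b = st.encode_lesions(les.calls.sample(frac=1.0, random_state=1), les.markers)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_marker_rejected(self):
        markers = pd.DataFrame({"kind": ["mutation"]}, index=["g1"])
        calls = pd.DataFrame(
            {"sample": ["A"], "marker": ["gX"], "kind": ["mutation"], "detail": ["nonsilent"]}
        )
        with pytest.raises(ValueError, match="gX"):
            st.encode_lesions(calls, markers)


class TestCophenetic:
    def test_perfect_block_consensus_gives_one(self):
        C = np.kron(np.eye(3), np.ones((5, 5)))
        np.fill_diagonal(C, 1.0)
        assert st.cophenetic_coefficient(C) == pytest.approx(1.0)

    def test_two_by_two_is_one_by_construction(self):
        C = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert st.cophenetic_coefficient(C) == 1.0

    def test_identical_distances_flagged_undefined(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        assert math.isnan(st.cophenetic_coefficient(C))

    def test_noise_scores_below_planted_structure(self, rng):
        n = 60
        planted = np.kron(np.eye(3), np.ones((20, 20)))
        np.fill_diagonal(planted, 1.0)
        noise_labels = rng.integers(0, 3, size=(50, n))
        C = np.mean(
            [(l[:, None] == l[None, :]).astype(float) for l in noise_labels], axis=0
        )
        np.fill_diagonal(C, 1.0)
        assert st.cophenetic_coefficient(C) < st.cophenetic_coefficient(planted)


class TestConsensus:
    def test_duplicated_blocks_have_unit_consensus(self):
        m = _matrix_from_blocks([10, 10], [6, 6])
        res = st.nmf_consensus(m, k_range=range(2, 4), n_runs=20, seed=0)
        C = res.consensus[2]
        assert np.allclose(C[:10, :10], 1.0)
        assert np.allclose(C[10:, 10:], 1.0)

    def test_planted_three_clusters_recovered(self):
        spec = sim.ClusterSpec(
            n_clusters=3, samples_per_cluster=30, markers_per_cluster=10, seed=4
        )
        les = sim.simulate_lesions(spec)
        m = st.encode_lesions(les.calls, les.markers)
        res = st.nmf_consensus(m, k_range=range(2, 7), n_runs=30, seed=5)
        assert res.selected_k == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(les.truth.loc[res.labels.index], res.labels) >= 0.9

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.ones((30, 5)), index=[f"S{i}" for i in range(30)])
        with pytest.raises(ValueError, match="degenerate"):
            st.nmf_consensus(m, k_range=range(2, 4), n_runs=5, seed=0)


class TestMarkers:
    def test_perfectly_separating_marker_matches_closed_form(self):
        # lesioned in all 10 cluster-A samples and none of the 20 others:
        # two-sided Fisher p is 1 / C(30, 10)
        m = _matrix_from_blocks([10, 20], [1, 1])
        labels = pd.Series([1] * 10 + [2] * 20, index=m.index)
        table = st.cluster_markers(m, labels)
        row = table[(table.marker == "M0") & (table.cluster == 1)].iloc[0]
        assert row["p"] == pytest.approx(1 / math.comb(30, 10), rel=1e-9)
        assert row["assigned"]

    def test_uniform_marker_not_assigned(self):
        m = _matrix_from_blocks([10, 10], [1, 1])
        m["M2"] = 2  # lesioned everywhere
        labels = pd.Series([1] * 10 + [2] * 10, index=m.index)
        table = st.cluster_markers(m, labels)
        rows = table[table.marker == "M2"]
        assert (rows["p"] == 1.0).all()
        assert not rows["assigned"].any()

    def test_absent_marker_not_assigned(self):
        m = _matrix_from_blocks([10, 10], [1, 1])
        m["M2"] = 0
        labels = pd.Series([1] * 10 + [2] * 10, index=m.index)
        rows = st.cluster_markers(m, labels)
        rows = rows[rows.marker == "M2"]
        assert (rows["p"] == 1.0).all()
        assert not rows["assigned"].any()

    def test_empty_cluster_rejected(self):
        m = _matrix_from_blocks([10, 10], [1, 1])
        labels = pd.Series([1] * 20, index=m.index)
        with pytest.raises(ValueError):
            st.cluster_markers(m, labels)


class TestClassification:
    def test_training_samples_self_consistent(self):
        m = _matrix_from_blocks([15, 15, 15], [5, 5, 5])
        labels = pd.Series([1] * 15 + [2] * 15 + [3] * 15, index=m.index)
        for s in m.index[::5]:
            cl, low_conf = st.classify_new_sample(m.loc[s], m, labels)
            assert cl == labels[s]
            assert not low_conf

    def test_zero_row_flagged_low_confidence(self):
        m = _matrix_from_blocks([10, 10], [3, 3])
        labels = pd.Series([1] * 10 + [2] * 10, index=m.index)
        row = pd.Series(0, index=m.columns)
        cl, low_conf = st.classify_new_sample(row, m, labels)
        assert low_conf

    def test_row_equal_to_centroid_gets_its_label(self):
        m = _matrix_from_blocks([10, 10], [3, 3])
        labels = pd.Series([1] * 10 + [2] * 10, index=m.index)
        centroid = m[labels == 2].mean(axis=0)
        cl, _ = st.classify_new_sample(centroid, m, labels)
        assert cl == 2

    def test_marker_mismatch_rejected(self):
        m = _matrix_from_blocks([10, 10], [3, 3])
        labels = pd.Series([1] * 10 + [2] * 10, index=m.index)
        with pytest.raises(ValueError, match="missing markers"):
            st.classify_new_sample(pd.Series({"M0": 1}), m, labels)
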