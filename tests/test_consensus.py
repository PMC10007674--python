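import numpy as np
import pytest

from choqfuse import (
    ViewScoreMatrix,
    fuse_views,
    power_measure,
    predict_batch,
    read_matrices_csv,
    select_class,
    write_matrices_csv,
    write_predictions,
)
from conftest import make_matrix


def softmax_cols(rng, C, K):
    z = rng.gumbel(size=(C, K))
    return np.exp(z) / np.exp(z).sum(axis=0)


class TestViewScoreMatrix:
    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="C ≥ 2"):
            make_matrix(np.ones((1, 2)))

    def test_rejects_bad_column_sum_unless_lenient(self):
        scores = np.array([[0.7, 0.5], [0.2, 0.5]])  # col 0 sums to 0.9
        with pytest.raises(ValueError, match="sums to 0.9"):
            make_matrix(scores)
        with pytest.warns(UserWarning, match="sums to 0.9"):
            make_matrix(scores, strict_columns=False)

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="distinct"):
            ViewScoreMatrix(
                scores=np.full((2, 2), 0.5),
                class_labels=["a", "a"],
                view_ids=["v0", "v1"],
            )


class TestSelectClass:
    def test_plain_argmax(self):
        idx, label, tie = select_class([0.1, 0.9, 0.05], ["a", "b", "c"])
        assert (idx, label, tie) == (1, "b", False)

    def test_exact_tie_goes_to_lowest_index(self):
        idx, _, tie = select_class([0.5, 0.5])
        assert (idx, tie) == (0, True)

    def test_near_tie_within_tolerance_flagged(self):
        idx, _, tie = select_class([0.5, 0.5 - 1e-13])
        assert (idx, tie) == (0, True)

    def test_single_entry(self):
        assert select_class([0.3]) == (0, "0", False)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_class([])


class TestFuseViews:
    def test_identical_columns_reproduce_column(self, rng):
        col = softmax_cols(rng, 6, 1)[:, 0]
        mat = make_matrix(np.tile(col[:, None], (1, 4)))
        fused = fuse_views(mat, power_measure(2.7, 4))
        np.testing.assert_allclose(fused.fused, col, atol=1e-12)
        assert fused.decided_class == int(np.argmax(col))

    def test_mean_case_with_tie(self):
        mat = make_matrix([[0.2, 0.8], [0.8, 0.2]])
        fused = fuse_views(mat, power_measure(1.0, 2))
        np.testing.assert_allclose(fused.fused, [0.5, 0.5], atol=1e-12)
        assert fused.tie_broken and fused.decided_class == 0

    def test_hand_evaluated_q2_rows(self):
        mat = make_matrix([[0.1, 0.9], [0.9, 0.1]])
        fused = fuse_views(mat, power_measure(2.0, 2))
        np.testing.assert_allclose(fused.fused, [0.3, 0.3], atol=1e-12)

    def test_per_class_internality(self, small_batch):
        m = power_measure(3.0, small_batch.config.K)
        for mat in small_batch.matrices[:10]:
            fused = fuse_views(mat, m)
            lo = mat.scores.min(axis=1)
            hi = mat.scores.max(axis=1)
            assert (fused.fused >= lo - 1e-12).all()
            assert (fused.fused <= hi + 1e-12).all()
            assert fused.fused[fused.decided_class] == fused.fused.max()

    def test_column_permutation_invariance(self, rng):
        scores = softmax_cols(rng, 5, 4)
        m = power_measure(0.7, 4)
        ref = fuse_views(make_matrix(scores), m)
        perm = rng.permutation(4)
        shuffled = ViewScoreMatrix(
            scores=scores[:, perm],
            class_labels=[f"class_{c:02d}" for c in range(5)],
            view_ids=[f"cam{k}" for k in perm],
        )
        fused = fuse_views(shuffled, m)
        np.testing.assert_allclose(fused.fused, ref.fused, atol=1e-12)
        assert fused.decided_class == ref.decided_class

    def test_measure_view_count_mismatch(self, rng):
        mat = make_matrix(softmax_cols(rng, 4, 3))
        with pytest.raises(ValueError, match="K=3"):
            fuse_views(mat, power_measure(1.0, 4))


class TestPredictBatch:
    def test_single_view_mode_is_column_argmax(self, small_batch):
        m = power_measure(1.0, small_batch.config.K)
        preds = predict_batch(small_batch.matrices, m, "single_view:0")
        for mat, p in zip(small_batch.matrices, preds):
            assert p.decided_class == int(np.argmax(mat.scores[:, 0]))

    def test_choquet_q1_equals_mean_mode(self, small_batch):
        m = power_measure(1.0, small_batch.config.K)
        a = predict_batch(small_batch.matrices, m, "choquet")
        b = predict_batch(small_batch.matrices, m, "mean")
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.fused, pb.fused, atol=1e-12)
            assert pa.decided_class == pb.decided_class

    def test_choquet_k1_equals_single_view(self, rng):
        mats = [make_matrix(softmax_cols(rng, 6, 1), f"c{i}") for i in range(5)]
        m = power_measure(2.0, 1)
        a = predict_batch(mats, m, "choquet")
        b = predict_batch(mats, m, "single_view:0")
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.fused, pb.fused)

    def test_determinism_bit_identical(self, small_batch):
        m = power_measure(1.7, small_batch.config.K)
        a = predict_batch(small_batch.matrices, m, "choquet")
        b = predict_batch(small_batch.matrices, m, "choquet")
        for pa, pb in zip(a, b):
            assert (pa.fused == pb.fused).all()
            assert pa.decided_class == pb.decided_class

    def test_inconsistent_labels_rejected(self, rng):
        m1 = make_matrix(softmax_cols(rng, 3, 2), "a")
        m2 = ViewScoreMatrix(
            scores=softmax_cols(rng, 3, 2),
            class_labels=["x", "y", "z"],
            view_ids=["cam0", "cam1"],
            capture_id="b",
        )
        with pytest.raises(ValueError, match="inconsistent class labels"):
            predict_batch([m1, m2], power_measure(1.0, 2), "choquet")

    def test_unknown_mode_rejected(self, small_batch):
        m = power_measure(1.0, small_batch.config.K)
        with pytest.raises(ValueError, match="unknown fusion mode"):
            predict_batch(small_batch.matrices, m, "vote")


class TestRoundTrip:
    def test_matrix_csv_round_trip(self, small_batch, tmp_path):
        path = tmp_path / "scores.csv"
        write_matrices_csv(small_batch.matrices, path, header_comment="test")
        loaded = read_matrices_csv(path)
        assert len(loaded) == len(small_batch.matrices)
        for orig, back in zip(small_batch.matrices, loaded):
            assert back.capture_id == orig.capture_id
            assert back.class_labels == orig.class_labels
            np.testing.assert_allclose(back.scores, orig.scores, atol=1e-12)

    def test_predictions_csv_and_json(self, small_batch, tmp_path):
        m = power_measure(1.0, small_batch.config.K)
        preds = predict_batch(small_batch.matrices, m, "choquet")
        labels = small_batch.matrices[0].class_labels
        csv_path = tmp_path / "preds.csv"
        write_predictions(preds, labels, csv_path, provenance={"q": 1.0})
        text = csv_path.read_text()
        assert text.startswith('# {"q": 1.0}')
        assert "decided_label" in text
        json_path = tmp_path / "preds.json"
        write_predictions(preds, labels, json_path, provenance={"q": 1.0},
                          fmt="json")
        import json as _json

        payload = _json.loads(json_path.read_text())
        assert payload["provenance"] == {"q": 1.0}
        assert len(payload["predictions"]) == len(preds)
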