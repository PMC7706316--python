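"""Evaluation suite: bounding boxes against a brute-force scan, SSIM limits
and protocols, the inter-annotator disagreement bound, the KNN augmentation
experiment and perception-study utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tasselgen import evaluate as ev
from tasselgen import fixtures as fx
from tasselgen.errors import DegenerateInputError, ParameterError, ShapeError


class TestBoundingBox:
    def test_known_block(self):
        mask = np.zeros((128, 128), np.uint8)
        mask[10:50, 20:40] = 1
        box = ev.bounding_box(mask)
        assert (box.height, box.width) == (40, 20)
        assert (box.row_min, box.row_max, box.col_min, box.col_max) == (10, 49, 20, 39)

    def test_full_and_single_pixel(self):
        assert ev.bounding_box(np.ones((8, 8), np.uint8)).width == 8
        single = np.zeros((10, 10), np.uint8)
        single[5, 7] = 1
        box = ev.bounding_box(single)
        assert (box.width, box.height) == (1, 1)

    def test_empty_mask_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ev.bounding_box(np.zeros((8, 8), np.uint8))

    def test_agrees_with_brute_force_scan(self, rng):
        for _ in range(20):
            mask = (rng.random((24, 24)) < 0.1).astype(np.uint8)
            if mask.sum() == 0:
                continue
            box = ev.bounding_box(mask)
            coords = np.argwhere(mask)
            assert box.row_min == coords[:, 0].min() and box.row_max == coords[:, 0].max()
            assert box.col_min == coords[:, 1].min() and box.col_max == coords[:, 1].max()

    def test_rgb_input_thresholded_on_luma(self):
        img = fx.make_tassel_image(fx.TasselParams(resolution=64), 1)
        gt = fx.make_tassel_mask(fx.TasselParams(resolution=64), 1)
        box_img = ev.bounding_box(img)
        box_gt = ev.bounding_box(gt)
        assert abs(box_img.width - box_gt.width) <= 2
        assert abs(box_img.height - box_gt.height) <= 2


class TestMorphStats:
    def test_population_std(self):
        table = pd.DataFrame(
            {"width": [10, 10, 0, 10], "height": [5, 5, 5, 5], "source": ["a", "a", "b", "b"]}
        )
        with pytest.raises(ParameterError):
            # widths must be positive
            ev.morph_stats(table)
        table["width"] = [10, 10, 2, 12]
        stats = ev.morph_stats(table)
        assert stats.loc["a", "width_std"] == 0.0
        assert stats.loc["b", "width_std"] == 5.0  # population form: ((2-7)^2+(12-7)^2)/2

    def test_wide_fraction_strict_inequality(self):
        table = pd.DataFrame(
            {"width": [60, 61, 59, 80], "height": [5] * 4, "source": ["t"] * 4}
        )
        stats = ev.morph_stats(table, wide_cutoff=60)
        assert stats.loc["t", "frac_wider_than_cutoff"] == 0.5

    def test_single_row_source_rejected(self):
        table = pd.DataFrame({"width": [10], "height": [5], "source": ["a"]})
        with pytest.raises(ParameterError):
            ev.morph_stats(table)

    def test_matches_direct_computation_on_fixture_boxes(self, small_tassel_set):
        _, masks = small_tassel_set
        rows = [
            {"width": ev.bounding_box(m).width, "height": ev.bounding_box(m).height, "source": "fixture"}
            for m in masks
        ]
        table = pd.DataFrame(rows)
        stats = ev.morph_stats(table)
        assert stats.loc["fixture", "width_std"] == pytest.approx(np.std([r["width"] for r in rows]))
        assert stats.loc["fixture", "height_mean"] == pytest.approx(np.mean([r["height"] for r in rows]))


class TestSsim:
    def test_self_similarity_exactly_one(self, small_tassel_set):
        imgs, _ = small_tassel_set
        assert ev.ssim(imgs[0], imgs[0]) == 1.0

    def test_constant_extremes_closed_form(self):
        a = np.zeros((32, 32, 3), np.uint8)
        b = np.full((32, 32, 3), 255, np.uint8)
        c1 = (0.01 * 255) ** 2
        expected = c1 / (255.0 ** 2 + c1)
        assert ev.ssim(a, b) == pytest.approx(expected, abs=1e-6)

    def test_symmetry(self, small_tassel_set, rng):
        imgs, _ = small_tassel_set
        for _ in range(5):
            i, j = rng.integers(0, len(imgs), 2)
            assert ev.ssim(imgs[i], imgs[j]) == pytest.approx(ev.ssim(imgs[j], imgs[i]), abs=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ev.ssim(np.zeros((16, 16, 3)), np.zeros((32, 32, 3)))


class TestSsimProtocols:
    def test_single_image_sets_score_one(self, small_tassel_set):
        imgs, _ = small_tassel_set
        assert ev.paired_ssim_score([imgs[0]], [imgs[0]]) == pytest.approx(1.0)

    def test_seeded_reproducibility(self, small_tassel_set):
        imgs, _ = small_tassel_set
        a, b = imgs[:5], imgs[5:10]
        assert ev.paired_ssim_score(a, b, seed=3) == ev.paired_ssim_score(a, b, seed=3)

    def test_score_within_pairwise_envelope(self, small_tassel_set):
        imgs, _ = small_tassel_set
        a, b = imgs[:5], imgs[5:10]
        pairwise = [ev.ssim(x, y) for x in a for y in b]  # exhaustive oracle
        score = ev.paired_ssim_score(a, b, n_repeats=3, seed=0)
        assert min(pairwise) <= score <= max(pairwise)

    def test_intraclass_identical_copies(self, small_tassel_set):
        imgs, _ = small_tassel_set
        copies = [imgs[0]] * 4
        assert ev.intraclass_ssim(copies) == pytest.approx(1.0)

    def test_intraclass_upper_bound_and_determinism(self, small_tassel_set):
        imgs, _ = small_tassel_set
        s1 = ev.intraclass_ssim(imgs[:6], seed=1)
        assert s1 == ev.intraclass_ssim(imgs[:6], seed=1)
        assert s1 <= 1.0

    def test_too_small_sets_rejected(self):
        with pytest.raises(ParameterError):
            ev.intraclass_ssim([np.zeros((8, 8, 3), np.uint8)])
        with pytest.raises(ParameterError):
            ev.paired_ssim_score([], [np.zeros((8, 8, 3), np.uint8)])


class TestInterannotatorError:
    def test_unanimous_is_zero(self):
        assert ev.interannotator_error(np.zeros((10, 4), dtype=int)) == 0.0

    def test_hand_cases(self):
        # N=2, K=3: votes (3,0) and (2,1) -> (0 + 1) / 6
        m = np.array([[0, 0, 0], [0, 0, 1]])
        assert ev.interannotator_error(m) == pytest.approx(1 / 6)
        # N=1, K=2, split vote -> 0.5
        assert ev.interannotator_error(np.array([[0, 1]])) == 0.5

    def test_binary_bound_on_random_matrices(self, rng):
        for _ in range(100):
            m = rng.integers(0, 2, size=(rng.integers(1, 20), rng.integers(2, 8)))
            e = ev.interannotator_error(m)
            assert 0.0 <= e <= 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(1, 12), st.integers(0, 10 ** 6))
    def test_bound_for_l_balanced_classes(self, n_labels, n_items, seed):
        m = fx.make_annotation_matrix(n_items, 5, 0.8, seed=seed, n_labels=n_labels)
        e = ev.interannotator_error(m)
        assert 0.0 <= e <= (n_labels - 1) / n_labels + 1e-12

    def test_single_annotator_rejected(self):
        with pytest.raises(ParameterError):
            ev.interannotator_error(np.zeros((3, 1), dtype=int))


class TestKnnExperiment:
    @staticmethod
    def _clusters(rng, n=40, sep=10.0):
        a = rng.normal(0.0, 1.0, (n, 2))
        b = rng.normal(sep, 1.0, (n, 2))
        X = np.vstack([a, b])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_separated_clusters_perfect_accuracy(self, rng):
        X, y = self._clusters(rng)
        Xg, yg = self._clusters(rng)
        table = ev.knn_augmentation_experiment(X, y, Xg, yg, [0.0, 0.25, 0.5, 0.75], seed=0)
        assert len(table) == 4
        assert (table["accuracy"] == 1.0).all()

    def test_zero_fraction_equals_baseline(self, rng):
        X, y = self._clusters(rng, sep=2.0)
        Xg, yg = self._clusters(rng, sep=2.0)
        t1 = ev.knn_augmentation_experiment(X, y, Xg, yg, [0.0], seed=4)
        t2 = ev.knn_augmentation_experiment(X, y, Xg, yg, [0.0, 0.5], seed=4)
        assert t1.loc[0, "accuracy"] == t2.loc[0, "accuracy"]
        assert t2.loc[0, "n_appended"] == 0

    def test_even_k_rejected(self, rng):
        X, y = self._clusters(rng)
        with pytest.raises(ParameterError):
            ev.knn_augmentation_experiment(X, y, X, y, [0.0], k=4)


class TestPerceptionDeck:
    def test_deck_length_and_key_marginals(self, rng):
        real = [rng.integers(0, 256, (8, 8, 3), dtype=np.uint8) for _ in range(51)]
        gen = [rng.integers(0, 256, (8, 8, 3), dtype=np.uint8) for _ in range(49)]
        deck, key = ev.build_perception_deck(real, gen, seed=0)
        assert len(deck) == 100
        assert key.sum() == 51 and (key == 0).sum() == 49

    def test_seeded_determinism(self, rng):
        real = [rng.integers(0, 256, (4, 4, 3), dtype=np.uint8) for _ in range(3)]
        gen = [rng.integers(0, 256, (4, 4, 3), dtype=np.uint8) for _ in range(3)]
        d1, k1 = ev.build_perception_deck(real, gen, seed=5)
        d2, k2 = ev.build_perception_deck(real, gen, seed=5)
        assert np.array_equal(k1, k2)
        assert all(np.array_equal(a, b) for a, b in zip(d1, d2))


class TestConfusionTable:
    def test_perfect_responder(self):
        key = np.array([1, 1, 0, 0])
        table = ev.confusion_table(key, key)
        assert table.loc["perceived_real", "true_real"] == 100.0
        assert table.loc["perceived_generated", "true_generated"] == 100.0
        assert table.loc["perceived_real", "true_generated"] == 0.0

    def test_columns_sum_to_100(self, rng):
        key = np.array([1] * 6 + [0] * 4)
        responses = rng.integers(0, 2, 10)
        table = ev.confusion_table(responses, key)
        assert np.allclose(table.sum(axis=0), 100.0, atol=1e-9)

    def test_all_real_responder(self):
        key = np.array([1, 0, 1, 0])
        table = ev.confusion_table(np.ones(4, dtype=int), key)
        assert (table.loc["perceived_real"] == 100.0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ev.confusion_table(np.ones(3, dtype=int), np.ones(4, dtype=int))


class TestRankAnnotators:
    def test_expert_ordering_with_index_tiebreak(self):
        truth = np.array([1, 1, 0])
        # annotator 0 gets both positives right; 1 and 2 get one each (tie)
        m = np.array([[1, 1, 0], [1, 0, 1], [0, 0, 0]])
        order = ev.rank_annotators(m, truth)
        assert order[0] == 0
        assert list(order[1:]) == [1, 2]
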