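"""Filter bank, generative layer and delta-rule read-out."""

import numpy as np
import pytest

from numerosense import network, stimuli
from numerosense.network import (
    GenerativeLayer,
    ReadoutHead,
    build_filterbank,
    corpus_features,
    encode,
    propagate,
    reconstruction_error,
    train_readout,
    train_unsupervised,
)


class TestFilterBank:
    def test_kernels_sum_to_zero(self, bank):
        for kernel in bank.kernels:
            assert abs(kernel.sum()) < 1e-6 * np.abs(kernel).sum()

    def test_on_off_sign_structure(self, bank):
        on, off = bank.kernels
        centre = tuple(s // 2 for s in on.shape)
        assert on[centre] > 0 and off[centre] < 0
        assert on[0, 0] <= 0 and off[0, 0] >= 0
        assert np.array_equal(on, -off)

    def test_constant_input_cancels_within_support(self, bank):
        # balanced antagonism: a uniform patch elicits no net response
        assert abs(bank.kernels[0].sum() * 1.0) < 1e-12

    def test_single_pixel_polarity(self, bank):
        img = np.zeros((30, 30))
        img[14, 14] = 1.0            # anchor 112 sits at (14, 14)
        feats = network.propagate_batch(img, bank)[0]
        idx = np.flatnonzero((bank.anchors == [14, 14]).all(axis=1))[0]
        assert feats[idx] > 0                       # on-centre fires
        assert feats[len(bank.anchors) + idx] == 0  # off-centre rectified away

    def test_deterministic_given_config(self):
        a = build_filterbank()
        b = build_filterbank()
        assert np.array_equal(a.weight_matrix, b.weight_matrix)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank(side=8, kernel_size=9)


class TestPropagate:
    def test_blank_image_gives_zero_features(self, bank):
        assert propagate(np.zeros((30, 30)), bank).sum() == 0

    def test_geometry_mismatch_rejected(self, bank):
        with pytest.raises(ValueError):
            propagate(np.zeros((20, 20)), bank)

    def test_matches_direct_convolution_oracle(self, bank):
        rng = np.random.default_rng(5)
        img = (rng.random((30, 30)) < 0.1).astype(float)
        feats = network.propagate_batch(img, bank)[0]
        on = bank.kernels[0]
        half = on.shape[0] // 2
        padded = np.pad(img, half)
        for idx in rng.choice(len(bank.anchors), size=12, replace=False):
            r, c = bank.anchors[idx]
            patch = padded[r:r + on.shape[0], c:c + on.shape[1]]
            resp = float((patch * on).sum())
            assert feats[idx] == pytest.approx(max(resp, 0.0), abs=1e-10)
            assert feats[len(bank.anchors) + idx] == pytest.approx(
                max(-resp, 0.0), abs=1e-10)

    def test_translation_moves_feature_mass(self, bank):
        img = np.zeros((30, 30))
        img[10:13, 10:13] = 1.0
        shifted = np.roll(img, (2, 2), axis=(0, 1))
        f0 = network.propagate_batch(img, bank)[0][:len(bank.anchors)]
        f1 = network.propagate_batch(shifted, bank)[0][:len(bank.anchors)]
        grid0 = f0.reshape(15, 15)
        grid1 = f1.reshape(15, 15)
        # stride-2 bank: a 2-pixel shift is one anchor step (interior only)
        assert np.allclose(grid1[3:12, 3:12], grid0[2:11, 2:11], atol=1e-9)
        assert grid0.sum() > 0


@pytest.fixture(scope="module")
def tiny_corpus():
    rng = np.random.default_rng(31)
    return [stimuli.generate_image(int(rng.integers(1, 17)), rng=rng)
            for _ in range(200)]


class TestGenerativeTraining:
    def test_checkpoint_schedule(self, bank, tiny_corpus):
        layer = GenerativeLayer.initialize(bank.n_features, 30,
                                           rng=np.random.default_rng(0))
        traj = train_unsupervised(tiny_corpus, bank, layer, epochs=3,
                                  checkpoint_interval=1,
                                  rng=np.random.default_rng(1))
        assert traj.epochs == [1, 2, 3]
        assert traj.interval == 1
        assert traj.final is traj.snapshots[-1]

    def test_reconstruction_error_decreases(self, bank, tiny_corpus):
        layer = GenerativeLayer.initialize(bank.n_features, 50,
                                           rng=np.random.default_rng(2))
        feats = corpus_features(tiny_corpus, bank)
        before = reconstruction_error(layer, feats)
        traj = train_unsupervised(tiny_corpus, bank, layer, epochs=10,
                                  checkpoint_interval=5,
                                  rng=np.random.default_rng(3))
        after = reconstruction_error(traj.final, feats)
        assert after < before

    def test_deterministic_under_seed(self, bank, tiny_corpus):
        runs = []
        for _ in range(2):
            layer = GenerativeLayer.initialize(bank.n_features, 20,
                                               rng=np.random.default_rng(4))
            traj = train_unsupervised(tiny_corpus, bank, layer, epochs=2,
                                      checkpoint_interval=1,
                                      rng=np.random.default_rng(5))
            runs.append(traj.final.weights.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_label_blind(self, bank, tiny_corpus):
        """Stripping all metadata from the corpus changes nothing."""
        stripped = [im.pixels for im in tiny_corpus]  # raw arrays, no labels
        weights = []
        for corpus in (tiny_corpus, stripped):
            layer = GenerativeLayer.initialize(bank.n_features, 20,
                                               rng=np.random.default_rng(6))
            traj = train_unsupervised(corpus, bank, layer, epochs=2,
                                      checkpoint_interval=2,
                                      rng=np.random.default_rng(7))
            weights.append(traj.final.weights.copy())
        assert np.array_equal(weights[0], weights[1])

    def test_filter_bank_immutable_through_training(self, bank, tiny_corpus):
        before = bank.weight_matrix.copy()
        layer = GenerativeLayer.initialize(bank.n_features, 20,
                                           rng=np.random.default_rng(8))
        train_unsupervised(tiny_corpus, bank, layer, epochs=1,
                           checkpoint_interval=1,
                           rng=np.random.default_rng(9))
        assert np.array_equal(bank.weight_matrix, before)

    def test_empty_corpus_rejected(self, bank):
        layer = GenerativeLayer.initialize(bank.n_features, 10)
        with pytest.raises(ValueError):
            train_unsupervised([], bank, layer, epochs=1)


class TestEncode:
    def test_deterministic_and_bounded(self, bank, small_layer):
        im = stimuli.generate_image(6, rng=np.random.default_rng(41))
        a = encode(im, bank, small_layer)
        b = encode(im, bank, small_layer)
        assert np.array_equal(a, b)
        assert a.shape == (small_layer.n_hidden,)
        assert ((a >= 0) & (a <= 1)).all()

    def test_distinct_images_distinct_codes(self, bank, small_layer):
        rng = np.random.default_rng(42)
        distinct = 0
        for _ in range(100):
            a = encode(stimuli.generate_image(int(rng.integers(1, 17)),
                                              rng=rng), bank, small_layer)
            b = encode(stimuli.generate_image(int(rng.integers(17, 33)),
                                              rng=rng), bank, small_layer)
            distinct += not np.allclose(a, b)
        assert distinct == 100


class TestReadout:
    def test_feedback_fraction_subset_size(self, bank, small_layer, easy_pairs):
        head = train_readout(easy_pairs, bank, small_layer,
                             feedback_fraction=0.25,
                             rng=np.random.default_rng(1), epochs=2)
        assert head.n_trained == round(0.25 * len(easy_pairs))

    def test_invalid_fraction_rejected(self, bank, small_layer, easy_pairs):
        for frac in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                train_readout(easy_pairs, bank, small_layer,
                              feedback_fraction=frac)

    def test_easy_pairs_learned_to_high_accuracy(self, bank, small_layer,
                                                 easy_pairs):
        head = train_readout(easy_pairs, bank, small_layer,
                             feedback_fraction=1.0,
                             rng=np.random.default_rng(2))
        outcomes = network.evaluate_pairs(easy_pairs, bank, small_layer, head)
        assert np.mean([o.correct for o in outcomes]) >= 0.9

    def test_antisymmetric_head_mirrors_choice(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=20)
        head = ReadoutHead(weights=np.concatenate([u, -u]), bias=0.0,
                           learning_rate=0.1)
        h_a, h_b = rng.random(20), rng.random(20)
        assert head.choose(h_a, h_b) != head.choose(h_b, h_a)

    def test_compare_consistent_under_swap(self, bank, small_layer,
                                           easy_pairs):
        import dataclasses

        head = train_readout(easy_pairs, bank, small_layer,
                             feedback_fraction=1.0,
                             rng=np.random.default_rng(4), epochs=5)
        pair = easy_pairs[0]
        flipped_side = "left" if pair.correct_side == "right" else "right"
        swapped = dataclasses.replace(pair, left=pair.right, right=pair.left,
                                      correct_side=flipped_side)
        a = network.compare(pair, bank, small_layer, head)
        b = network.compare(swapped, bank, small_layer, head)
        assert a.correct == b.correct


class TestPersistence:
    def test_model_round_trip(self, tmp_path, bank, small_layer, easy_pairs):
        head = train_readout(easy_pairs, bank, small_layer,
                             feedback_fraction=0.5,
                             rng=np.random.default_rng(5), epochs=2)
        path = tmp_path / "model.h5"
        network.save_model(path, bank, small_layer, head,
                           config={"note": "test"})
        bank2, layer2, head2, config = network.load_model(path)
        assert np.array_equal(bank2.weight_matrix, bank.weight_matrix)
        assert np.array_equal(layer2.weights, small_layer.weights)
        assert np.array_equal(head2.weights, head.weights)
        assert config == {"note": "test"}
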