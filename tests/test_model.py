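"""Fusion network, triplet losses and training behaviour."""

import itertools
import math

import numpy as np
import pytest

from gotriplet import (
    EmbeddingBundle,
    ModelConfig,
    SimilarityConfig,
    TrainingConfig,
    batch_hard_loss,
    composite_loss,
    cross_entropy_loss,
    ensemble_average,
    margin_violation_rate,
    mean_pool,
    train_model,
    triplet_loss,
)
from gotriplet.model import FusionNetwork, _pair_masks

from conftest import annotation_set


class TestMeanPool:
    def test_single_row_identity(self, rng):
        row = rng.normal(size=(1, 6))
        assert np.allclose(mean_pool(row), row[0])

    def test_two_row_average(self):
        m = np.vstack([np.zeros(4), np.full(4, 2.0)])
        assert np.allclose(mean_pool(m), np.ones(4))

    def test_matches_sum_oracle(self, rng):
        m = rng.normal(size=(5, 8))
        assert np.allclose(mean_pool(m), m.sum(axis=0) / 5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_pool(np.empty((0, 4)))


class TestForward:
    def test_identity_weights_propagate_input(self):
        cfg = ModelConfig(dim=4, terms=("q1", "q2"), n1=4, n2=4)
        net = FusionNetwork(cfg, seed=0)
        for v in range(3):
            net.params[f"W{v}"] = np.eye(4)
            net.params[f"b{v}"] = np.zeros(4)
        # fused layer picks out view 0 exactly
        wa = np.zeros((12, 4))
        wa[:4, :] = np.eye(4)
        net.params["Wa"] = wa
        net.params["ba"] = np.zeros(4)
        x = np.abs(np.random.default_rng(0).normal(size=(2, 4)))  # positive: ReLU transparent
        z, _ = net.forward([x, x * 2, x * 3])
        assert np.allclose(z, x)

    def test_sigmoid_head_hand_oracle(self):
        cfg = ModelConfig(dim=2, terms=("q1", "q2"), n1=2, n2=2)
        net = FusionNetwork(cfg, seed=0)
        for v in range(3):
            net.params[f"W{v}"] = np.eye(2)
            net.params[f"b{v}"] = np.zeros(2)
        net.params["Wa"] = np.vstack([np.eye(2)] * 3)
        net.params["ba"] = np.zeros(2)
        net.params["Wo"] = np.array([[1.0, -1.0], [0.5, 0.5]])
        net.params["bo"] = np.array([0.1, -0.1])
        x = np.array([[1.0, 2.0]])
        z, s = net.forward([x, x, x])
        z_expected = 3 * x  # sum of the three identical views
        logits = z_expected @ net.params["Wo"] + net.params["bo"]
        assert np.allclose(z, z_expected)
        assert np.allclose(s, 1 / (1 + np.exp(-logits)))

    def test_scores_inside_open_unit_interval(self, rng):
        cfg = ModelConfig(dim=5, terms=tuple("abcd"), n1=7, n2=3)
        net = FusionNetwork(cfg, seed=3)
        views = [rng.normal(size=(6, 5)) * 10 for _ in range(3)]
        _, s = net.forward(views)
        assert np.all(s > 0) and np.all(s < 1)

    def test_dimension_mismatch_rejected(self):
        cfg = ModelConfig(dim=5, terms=("a",), n1=4, n2=4)
        net = FusionNetwork(cfg)
        bad = [np.zeros((2, 6))] * 3
        with pytest.raises(ValueError):
            net.forward(bad)


class TestTripletLoss:
    def test_satisfied_margin_is_zero(self):
        a = np.zeros(3)
        p = np.array([0.5, 0.0, 0.0])
        n = np.array([2.0, 0.0, 0.0])
        assert triplet_loss(a, p, n, margin=0.5) == 0.0

    def test_arithmetic_case(self):
        a = np.zeros(2)
        p = np.array([1.2, 0.0])
        n = np.array([1.5, 0.0])
        assert triplet_loss(a, p, n, margin=0.5) == pytest.approx(0.2)

    def test_positive_equals_negative_gives_margin(self, rng):
        a, pn = rng.normal(size=2), rng.normal(size=2)
        assert triplet_loss(a, pn, pn, margin=0.7) == pytest.approx(0.7)


def exhaustive_batch_hard(z, term_sets, margin, simcfg):
    """Oracle: per anchor, enumerate all pairs to find the hardest
    positive/negative, then average the hinge over valid anchors."""
    from gotriplet import same_function

    n = len(term_sets)
    losses = []
    for i in range(n):
        d = [np.linalg.norm(z[i] - z[j]) for j in range(n)]
        pos = [j for j in range(n) if j != i and same_function(term_sets[i], term_sets[j], simcfg)]
        neg = [j for j in range(n) if j != i and not same_function(term_sets[i], term_sets[j], simcfg)]
        if not pos or not neg:
            continue
        dp = max(d[j] for j in pos)
        dn = min(d[j] for j in neg)
        losses.append(max(dp + margin - dn, 0.0))
    return float(np.mean(losses))


class TestBatchHard:
    simcfg = SimilarityConfig(cutoff=0.5)

    def _sets(self):
        # two clear functional groups
        return [
            frozenset({"a", "b"}),
            frozenset({"a", "b"}),
            frozenset({"x", "y"}),
            frozenset({"x", "y"}),
        ]

    def test_well_separated_clusters_zero_loss(self):
        z = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        loss = batch_hard_loss(z, self._sets(), margin=1.0, simcfg=self.simcfg)
        assert loss == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        z = rng.normal(size=(n, 3))
        pool = [frozenset({"a", "b"}), frozenset({"x", "y"}), frozenset({"a", "x"})]
        sets = [pool[int(rng.integers(3))] for _ in range(n)]
        oracle = exhaustive_batch_hard(z, sets, 1.0, self.simcfg)
        got = batch_hard_loss(z, sets, margin=1.0, simcfg=self.simcfg, warn_skipped=False)
        assert got == pytest.approx(oracle)

    def test_anchor_not_its_own_positive(self):
        # duplicated anchor embedding: self must be excluded from positives
        z = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        sets = [frozenset({"a"}), frozenset({"a"}), frozenset({"x"})]
        # hardest positive of each of the twins is the other twin (d=0)
        loss = batch_hard_loss(z, sets, margin=1.0, simcfg=self.simcfg, warn_skipped=False)
        assert loss == 0.0  # 0 + 1 - 5 < 0 for both anchors... third has no positive

    def test_no_valid_anchor_raises(self):
        z = np.zeros((2, 2))
        sets = [frozenset({"a"}), frozenset({"a"})]  # no negatives anywhere
        with pytest.raises(ValueError):
            batch_hard_loss(z, sets, simcfg=self.simcfg, warn_skipped=False)

    def test_skipped_anchor_warns(self):
        z = np.zeros((3, 2))
        sets = [frozenset({"a"}), frozenset({"a"}), frozenset({"x"})]
        # the 'x' anchor has no positive -> warned and skipped
        with pytest.warns(UserWarning):
            batch_hard_loss(z, sets, simcfg=self.simcfg)

    def test_rigid_rotation_invariance(self, rng):
        n, d = 6, 4
        z = rng.normal(size=(n, d))
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        sets = self._sets() + [frozenset({"a", "b"}), frozenset({"x", "y"})]
        l1 = batch_hard_loss(z, sets, simcfg=self.simcfg, warn_skipped=False)
        l2 = batch_hard_loss(z @ q, sets, simcfg=self.simcfg, warn_skipped=False)
        assert l1 == pytest.approx(l2)

    def test_nonnegative(self, rng):
        z = rng.normal(size=(6, 3))
        sets = self._sets() + [frozenset({"a", "b"}), frozenset({"x", "y"})]
        assert batch_hard_loss(z, sets, simcfg=self.simcfg, warn_skipped=False) >= 0.0


class TestCrossEntropy:
    def test_perfect_scores_near_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(y, y) < 1e-5

    def test_uniform_half_is_ln2(self):
        s = np.full((3, 4), 0.5)
        y = np.array([[1, 0, 1, 0]] * 3, dtype=float)
        assert cross_entropy_loss(s, y) == pytest.approx(math.log(2))

    def test_elementwise_oracle(self, rng):
        s = rng.uniform(0.05, 0.95, size=(3, 4))
        y = (rng.uniform(size=(3, 4)) > 0.5).astype(float)
        oracle = -np.mean(y * np.log(s) + (1 - y) * np.log(1 - s))
        assert cross_entropy_loss(s, y) == pytest.approx(oracle)


class TestCompositeLoss:
    def _batch(self, rng):
        z = rng.normal(size=(4, 3))
        sets = [
            frozenset({"a", "b"}),
            frozenset({"a", "b"}),
            frozenset({"x", "y"}),
            frozenset({"x", "y"}),
        ]
        s = rng.uniform(0.1, 0.9, size=(4, 2))
        y = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        return z, s, sets, y

    def test_alpha_zero_is_triplet_only(self, rng):
        z, s, sets, y = self._batch(rng)
        lt = batch_hard_loss(z, sets, warn_skipped=False)
        assert composite_loss(z, s, sets, y, alpha=0.0) == pytest.approx(lt)

    def test_alpha_one_is_sum(self, rng):
        z, s, sets, y = self._batch(rng)
        lt = batch_hard_loss(z, sets, warn_skipped=False)
        lc = cross_entropy_loss(s, y)
        assert composite_loss(z, s, sets, y, alpha=1.0) == pytest.approx(lt + lc)

    def test_half_alpha_components(self, rng):
        z, s, sets, y = self._batch(rng)
        lt = batch_hard_loss(z, sets, warn_skipped=False)
        lc = cross_entropy_loss(s, y)
        assert composite_loss(z, s, sets, y, alpha=0.5) == pytest.approx(lt + 0.5 * lc)

    def test_negative_alpha_rejected(self, rng):
        z, s, sets, y = self._batch(rng)
        with pytest.raises(ValueError):
            composite_loss(z, s, sets, y, alpha=-0.1)


def _toy_problem(seed=0, n=24, dim=6):
    rng = np.random.default_rng(seed)
    centers = {0: rng.normal(0, 3.0, dim), 1: rng.normal(0, 3.0, dim)}
    sets = {0: frozenset({"GO:9000001", "GO:9000002"}), 1: frozenset({"GO:9000003", "GO:9000004"})}
    vectors, annot = {}, {}
    for i in range(n):
        c = i % 2
        pid = f"P{i:03d}"
        vectors[pid] = centers[c] + rng.normal(0, 1.0, size=(3, dim))
        annot[pid] = sets[c]
    bundle = EmbeddingBundle(vectors=vectors, dim=dim)
    annotations = annotation_set(annot)
    terms = tuple(sorted({t for s in sets.values() for t in s}))
    return bundle, annotations, terms


class TestTraining:
    def test_zero_epochs_reproducible_init(self):
        bundle, annotations, terms = _toy_problem()
        mcfg = ModelConfig(dim=6, terms=terms, n1=8, n2=8)
        tcfg = TrainingConfig(seed=5, epochs=0)
        m1 = train_model(bundle, annotations, mcfg, tcfg)
        m2 = train_model(bundle, annotations, mcfg, tcfg)
        for p in m1.proteins:
            assert np.array_equal(m1.embeddings[p], m2.embeddings[p])

    def test_same_seed_bitwise_identical_scores(self):
        bundle, annotations, terms = _toy_problem()
        mcfg = ModelConfig(dim=6, terms=terms, n1=8, n2=8)
        tcfg = TrainingConfig(seed=5, epochs=3, batch_size=8)
        m1 = train_model(bundle, annotations, mcfg, tcfg)
        m2 = train_model(bundle, annotations, mcfg, tcfg)
        assert m1.saf_scores == m2.saf_scores

    def test_training_reduces_triplet_loss_and_violations(self):
        bundle, annotations, terms = _toy_problem(seed=2)
        mcfg = ModelConfig(dim=6, terms=terms, n1=8, n2=8)
        proteins = sorted(annotations.annotations)
        sets = [annotations.annotations[p] for p in proteins]

        init = train_model(bundle, annotations, mcfg, TrainingConfig(seed=3, epochs=0))
        z0 = np.stack([init.embeddings[p] for p in proteins])
        trained = train_model(
            bundle, annotations, mcfg,
            TrainingConfig(seed=3, epochs=30, batch_size=12, learning_rate=5e-3),
        )
        z1 = np.stack([trained.embeddings[p] for p in proteins])
        l0 = batch_hard_loss(z0, sets, warn_skipped=False)
        l1 = batch_hard_loss(z1, sets, warn_skipped=False)
        assert l1 <= l0
        assert margin_violation_rate(z1, sets) <= margin_violation_rate(z0, sets)

    def test_validation_fmax_recorded(self):
        bundle, annotations, terms = _toy_problem()
        mcfg = ModelConfig(dim=6, terms=terms, n1=8, n2=8)
        tcfg = TrainingConfig(seed=1, epochs=2, batch_size=8)
        m = train_model(bundle, annotations, mcfg, tcfg, validation=(bundle, annotations))
        assert all("val_fmax" in rec for rec in m.history)

    def test_checkpoint_roundtrip(self, tmp_path):
        bundle, annotations, terms = _toy_problem()
        mcfg = ModelConfig(dim=6, terms=terms, n1=8, n2=8)
        m = train_model(bundle, annotations, mcfg, TrainingConfig(seed=1, epochs=1))
        path = tmp_path / "model.npz"
        m.network.save(path)
        loaded = FusionNetwork.load(path)
        views = bundle.stacked(m.proteins)
        z1, s1 = m.network.forward(views)
        z2, s2 = loaded.forward(views)
        assert np.array_equal(z1, z2) and np.array_equal(s1, s2)
        assert loaded.config.terms == terms


class TestEnsembleAverage:
    def test_single_run_identity(self):
        runs = [{"p": {"q": 0.3}}]
        assert ensemble_average(runs) == {"p": {"q": 0.3}}

    def test_two_run_mean(self):
        runs = [{"p": {"q": 0.2}}, {"p": {"q": 0.8}}]
        assert ensemble_average(runs)["p"]["q"] == pytest.approx(0.5)

    def test_ten_run_sum_oracle(self, rng):
        vals = rng.uniform(size=10)
        runs = [{"p": {"q": float(v)}} for v in vals]
        assert ensemble_average(runs)["p"]["q"] == pytest.approx(vals.sum() / 10)

    def test_index_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([{"p": {"q": 0.1}}, {"r": {"q": 0.1}}])
        with pytest.raises(ValueError):
            ensemble_average([{"p": {"q": 0.1}}, {"p": {"z": 0.1}}])
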