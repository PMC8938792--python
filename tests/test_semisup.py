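"""Semi-supervised machinery: split arithmetic, pseudo-label filtering,
the entropy term, the EM loss mixture, and self-training bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinusvol import nn
from sinusvol.segnet import SegConfig, TrainConfig, build_model, train_supervised
from sinusvol.semisup import (
    DataSplit,
    entropy_term,
    fit_loss_mixture,
    make_split,
    pseudo_label,
    self_train,
)


class TestMakeSplit:
    def test_labeled_eighty_twenty(self):
        """50 labelled subjects at 8:2 give 40 train / 10 validation."""
        ids = [f"L{i}" for i in range(50)]
        split = make_split(ids, [f"U{i}" for i in range(5)], 0.8, 0.2, seed=0)
        assert len(split.labeled_train) == 40
        assert len(split.labeled_val) == 10

    def test_selftrain_fraction(self):
        """20% of 125 unlabelled subjects go to self-training."""
        split = make_split([f"L{i}" for i in range(50)],
                           [f"U{i}" for i in range(125)], 0.8, 0.2, seed=0)
        assert len(split.unlabeled_selftrain) == 25
        assert len(split.unlabeled_test) == 100

    def test_deterministic_and_disjoint(self):
        ids = [f"L{i}" for i in range(20)]
        uids = [f"U{i}" for i in range(30)]
        a = make_split(ids, uids, seed=5)
        b = make_split(ids, uids, seed=5)
        assert a == b
        pools = [a.labeled_train, a.labeled_val, a.unlabeled_selftrain,
                 a.unlabeled_test]
        flat = [x for p in pools for x in p]
        assert len(flat) == len(set(flat)) == 50

    def test_degenerate_ratios_rejected(self):
        ids = [f"L{i}" for i in range(10)]
        with pytest.raises(ValueError):
            make_split(ids, [], labeled_ratio=1.0)
        with pytest.raises(ValueError):
            make_split(ids, [], labeled_ratio=0.0)
        with pytest.raises(ValueError, match="empty"):
            make_split([], ["U0"])

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            DataSplit(("a",), ("a",), (), ())


class _StubModel:
    """Minimal model: returns preset logits slice-by-slice."""

    training = False

    def __init__(self, logits):
        self._logits = logits

    def forward(self, x):
        return self._logits[: len(x)]

    def eval(self):
        return self

    def train(self, mode=True):
        return self


class TestPseudoLabel:
    def test_certain_model_full_coverage(self):
        logits = np.zeros((2, 3, 4, 4), dtype=np.float32)
        logits[:, 1] = 50.0  # one-hot certainty on class 1
        ps = pseudo_label(_StubModel(logits), np.zeros((2, 1, 4, 4)), tau=1.0)
        assert ps.coverage == 1.0
        assert np.all(ps.labels == 1)

    def test_tau_one_with_uncertain_model_empty(self):
        logits = np.zeros((2, 3, 4, 4), dtype=np.float32)  # uniform 1/3
        ps = pseudo_label(_StubModel(logits), np.zeros((2, 1, 4, 4)), tau=1.0)
        assert ps.coverage == 0.0
        assert np.all(ps.labels == -1)

    def test_three_pixel_worked_example(self):
        """Probabilities (.95,.05), (.6,.4), (.5,.5) at tau 0.7: only the
        first pixel survives, labelled class 0."""
        probs = np.array([[0.95, 0.6, 0.5], [0.05, 0.4, 0.5]])
        logits = np.log(probs)[None, :, None, :].astype(np.float32)
        ps = pseudo_label(_StubModel(logits), np.zeros((1, 1, 1, 3)), tau=0.7)
        assert ps.labels.tolist() == [[[0, -1, -1]]]
        assert ps.coverage == pytest.approx(1.0 / 3.0)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            pseudo_label(_StubModel(np.zeros((1, 2, 2, 2))),
                         np.zeros((1, 1, 2, 2)), tau=0.0)
        with pytest.raises(ValueError):
            pseudo_label(_StubModel(np.zeros((1, 2, 2, 2))),
                         np.zeros((1, 1, 2, 2)), tau=1.5)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1),
           st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95)))
    def test_coverage_monotone_in_tau(self, seed, taus):
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        lo, hi = min(taus), max(taus)
        x = np.zeros((2, 1, 5, 5))
        ps_lo = pseudo_label(_StubModel(logits), x, tau=lo)
        ps_hi = pseudo_label(_StubModel(logits), x, tau=hi)
        assert ps_hi.coverage <= ps_lo.coverage
        # retained set at hi tau is a subset of the set at lo tau
        assert np.all((ps_hi.labels == -1) | (ps_hi.labels == ps_lo.labels))


class TestEntropyTerm:
    def test_one_hot_is_zero(self):
        p = np.zeros((3, 4, 4))
        p[0] = 1.0
        assert entropy_term(p) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_is_log_k(self):
        k = 13
        p = np.full((k, 4, 4), 1.0 / k)
        assert entropy_term(p) == pytest.approx(np.log(k))

    def test_mixed_map_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(2, 5, 3, 3))
        p = nn.softmax(logits, axis=1)
        direct = float(np.mean([
            -sum(p[b, :, i, j] * np.log(p[b, :, i, j]))
            for b in range(2) for i in range(3) for j in range(3)]))
        assert entropy_term(p) == pytest.approx(direct, abs=1e-10)


class TestLossMixture:
    def test_bimodal_losses_split_exactly(self):
        losses = np.array([0.01] * 10 + [0.99] * 10)
        part = fit_loss_mixture(losses)
        assert sorted(part.clean_ids) == list(range(10))
        assert sorted(part.noisy_ids) == list(range(10, 20))
        # threshold-sweep oracle: the best single threshold agrees
        best = min(np.unique(losses),
                   key=lambda t: ((losses <= t) != (losses <= 0.5)).sum())
        assert np.array_equal(part.clean_ids, np.flatnonzero(losses <= best))

    def test_identical_losses_all_clean(self):
        part = fit_loss_mixture(np.full(8, 0.3))
        assert len(part.clean_ids) == 8 and len(part.noisy_ids) == 0

    def test_separated_gaussians_recover_generator_labels(self):
        rng = np.random.default_rng(3)
        lo = rng.normal(0.1, 0.02, 50)
        hi = rng.normal(0.9, 0.02, 50)
        part = fit_loss_mixture(np.concatenate([lo, hi]))
        assert np.array_equal(np.sort(part.clean_ids), np.arange(50))

    def test_agrees_with_sklearn_mixture(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0.2, 0.05, 40),
                            rng.normal(0.8, 0.05, 40)])
        part = fit_loss_mixture(x)
        xn = ((x - x.min()) / (x.max() - x.min())).reshape(-1, 1)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(xn)
        lab = gm.predict(xn)
        clean_lab = lab[np.argmin(gm.means_.ravel()) == lab][0] \
            if False else int(np.argmin(gm.means_.ravel()))
        assert np.array_equal(np.sort(part.clean_ids),
                              np.flatnonzero(lab == clean_lab))

    def test_likelihood_monotone_over_iterations(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0.3, 0.1, 30), rng.normal(0.7, 0.1, 30)])
        part = fit_loss_mixture(x)
        assert np.all(np.diff(part.log_likelihoods) >= -1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_loss_mixture([0.1, 0.2, 0.3])


class TestSelfTrain:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        rng = np.random.default_rng(0)
        data = {}
        for i in range(4):
            x = rng.normal(size=(6, 1, 16, 16)).astype(np.float32)
            y = (x[:, 0] > 0).astype(np.int64)
            data[f"s{i}"] = (x, y)
        cfg = SegConfig(in_channels=1, n_classes=2, base_width=4, depth=2,
                        atrous_rates=(1, 2), se_reduction=2)
        return data, cfg

    def test_empty_pool_reduces_to_supervised(self, tiny_setup):
        """With no self-training pool, one round equals plain supervised
        training step-for-step."""
        data, cfg = tiny_setup
        split = DataSplit(("s0", "s1"), ("s2",), (), ())
        tc = TrainConfig(epochs=2, batch_size=4, lr=1e-3, seed=7)
        m1 = build_model(cfg, seed=1)
        state = self_train(m1, split, data, rounds=1, round_cfg=tc)
        m2 = build_model(cfg, seed=1)
        x = np.concatenate([data["s0"][0], data["s1"][0]])
        y = np.concatenate([data["s0"][1], data["s1"][1]])
        train_supervised(m2, x, y, tc)
        for p1, p2 in zip(m1.params(), m2.params()):
            assert np.allclose(p1.value, p2.value, atol=1e-7)
        assert len(state.history) == 1

    def test_history_length_and_round_indices(self, tiny_setup):
        data, cfg = tiny_setup
        split = DataSplit(("s0", "s1"), ("s2",), ("s3",), ())
        m = build_model(cfg, seed=2)
        tc = TrainConfig(epochs=1, batch_size=4, seed=0)
        state = self_train(m, split, data, rounds=3, round_cfg=tc)
        assert [h["round"] for h in state.history] == [0, 1, 2]
        assert all("coverage" in h for h in state.history)

    def test_rounds_must_be_positive(self, tiny_setup):
        data, cfg = tiny_setup
        split = DataSplit(("s0",), ("s1",), (), ())
        with pytest.raises(ValueError):
            self_train(build_model(cfg, seed=0), split, data, rounds=0)
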