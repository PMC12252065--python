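"""Constraint sampling, label budgets, and trainer contracts.

Trainer tests run at miniature scale (tiny window sets, few epochs): they
check loss decrease, determinism, one-batch overfitting, the weak-multi
reduction to weak-single at beta=0, and the stage-2 budget restriction.
"""

import numpy as np
import pytest

from harspectrum.data_synth import SynthConfig, generate_streams, segment_windows, windows_to_arrays
from harspectrum.features import build_neighborhood_index, features_matrix
from harspectrum.losses import LossWeights
from harspectrum.models import EncoderSpec
from harspectrum.training import (ConstraintSet, TrainingConfig, sample_pairs,
                                  sample_quadruples, subsample_label_budget,
                                  train_autoencoder, train_selfsup,
                                  train_supervised, train_weak_multi,
                                  train_weak_selfsup, train_weak_single)

SMALL_RAW_SPEC = EncoderSpec(input_shape=(32, 2), embedding_dim=8,
                             channels_per_block=(8, 8, 16, 16))
SMALL_FEAT_SPEC = EncoderSpec(input_shape=14, embedding_dim=6,
                              hidden_dims=(32, 16))


@pytest.fixture(scope="module")
def tiny_windows():
    cfg = SynthConfig(n_persons=2, n_activities=3, n_channels=2,
                      sampling_rate=12.5, bout_length=12.8,
                      n_bouts_per_person=6, noise_sigma=0.1,
                      person_effect_scale=0.3, seed=7)
    wins = [w for s in generate_streams(cfg)
            for w in segment_windows(s, 2.56, 1.28)]
    assert len(wins) >= 60
    return wins


@pytest.fixture(scope="module")
def tiny_arrays(tiny_windows):
    return windows_to_arrays(tiny_windows)


def cfg_for(paradigm, **kw):
    base = dict(paradigm=paradigm, epochs_stage1=3, epochs_stage2=3,
                batch_size=16, seed=11)
    base.update(kw)
    return TrainingConfig(**base)


class TestSamplePairs:
    def test_quota_contract(self):
        y = np.array([0] * 10 + [1] * 10)
        cons = sample_pairs(y, 100, positive_fraction=0.5, seed=0)
        assert len(cons) == 100
        assert cons.y_act.sum() == 50

    def test_labels_match_ground_truth_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 50)
        cons = sample_pairs(y, 1000, seed=2)
        assert np.array_equal(cons.y_act, (y[cons.idx_a] == y[cons.idx_b]).astype(int))

    def test_single_class_feasibility(self):
        y = np.zeros(10, dtype=int)
        cons = sample_pairs(y, 20, positive_fraction=1.0, seed=0)
        assert cons.y_act.all()
        with pytest.raises(ValueError):
            sample_pairs(y, 20, positive_fraction=0.5, seed=0)

    def test_budget_restriction(self):
        y = np.array([0, 1] * 20)
        allowed = np.arange(6)
        cons = sample_pairs(y, 50, seed=3, allowed=allowed)
        assert set(cons.idx_a) | set(cons.idx_b) <= set(allowed)


class TestSampleQuadruples:
    def test_balanced_cells(self):
        y_act = np.array([0, 0, 1, 1] * 10)
        y_pers = np.array([0, 1] * 20)
        cons = sample_quadruples(y_act, y_pers, 80, seed=0)
        assert len(cons) == 80
        for ca in (0, 1):
            for cp in (0, 1):
                n = np.sum((cons.y_act == ca) & (cons.y_pers == cp))
                assert n == 20

    def test_labels_audited_against_ground_truth(self):
        rng = np.random.default_rng(2)
        y_act = rng.integers(0, 3, 40)
        y_pers = rng.integers(0, 3, 40)
        cons = sample_quadruples(y_act, y_pers, 200, seed=1)
        assert np.array_equal(cons.y_act,
                              (y_act[cons.idx_a] == y_act[cons.idx_b]).astype(int))
        assert np.array_equal(cons.y_pers,
                              (y_pers[cons.idx_a] == y_pers[cons.idx_b]).astype(int))

    def test_infeasible_cell_raises(self):
        # single person: the (., y_pers=0) cells cannot be filled
        y_act = np.array([0, 1] * 10)
        y_pers = np.zeros(20, dtype=int)
        with pytest.raises(ValueError, match="quadruple quota"):
            sample_quadruples(y_act, y_pers, 40, seed=0)


class TestLabelBudget:
    def test_full_fraction_is_identity(self):
        y = np.array([0, 1, 2] * 10)
        assert len(subsample_label_budget(y, 1.0, seed=0)) == 30

    def test_ceil_arithmetic_per_class(self):
        y = np.repeat([0, 1, 2], 200)
        idx = subsample_label_budget(y, 0.1, seed=1)
        assert len(idx) == 60
        for cls in range(3):
            assert np.sum(y[idx] == cls) == 20

    def test_min_one_per_class(self):
        y = np.repeat([0, 1, 2], 5)
        idx = subsample_label_budget(y, 0.01, seed=2)
        assert set(y[idx]) == {0, 1, 2}


class TestTrainers:
    def test_supervised_loss_decreases_and_is_deterministic(self, tiny_windows):
        c = cfg_for("supervised")
        m1 = train_supervised(tiny_windows, c, spec=SMALL_RAW_SPEC)
        m2 = train_supervised(tiny_windows, c, spec=SMALL_RAW_SPEC)
        h1, h2 = m1.extras["history"], m2.extras["history"]
        assert h1[-1]["total"] < h1[0]["total"]
        assert h1[-1]["total"] == pytest.approx(h2[-1]["total"], abs=1e-6)

    def test_autoencoder_loss_decreases(self, tiny_windows):
        feats = features_matrix(tiny_windows)
        m = train_autoencoder(feats, cfg_for("unsupervised", epochs_stage1=5),
                              spec=SMALL_FEAT_SPEC)
        h = m.extras["history"]
        assert h[-1]["total"] < h[0]["total"]

    def test_weak_single_loss_decreases_and_deterministic(self, tiny_windows, tiny_arrays):
        x, y_act, _, _ = tiny_arrays
        cons = sample_pairs(y_act, 120, seed=5)
        c = cfg_for("weak_single")
        m1 = train_weak_single(x, cons, c, spec=SMALL_RAW_SPEC)
        m2 = train_weak_single(x, cons, c, spec=SMALL_RAW_SPEC)
        h = m1.extras["history"]
        assert h[-1]["total"] < h[0]["total"]
        assert m1.extras["history"][-1]["total"] == pytest.approx(
            m2.extras["history"][-1]["total"], abs=1e-6)

    def test_weak_multi_beta_zero_matches_weak_single_trajectory(self, tiny_arrays):
        x, y_act, y_pers, _ = tiny_arrays
        cons = sample_quadruples(y_act, y_pers, 96, seed=6)
        single = ConstraintSet(cons.idx_a, cons.idx_b, cons.y_act)
        c1 = cfg_for("weak_single")
        c2 = cfg_for("weak_multi",
                     weights=LossWeights(alpha=1.0, beta=0.0))
        m1 = train_weak_single(x, single, c1, spec=SMALL_RAW_SPEC)
        m2 = train_weak_multi(x, cons, c2, spec=SMALL_RAW_SPEC)
        h1 = [e["simi_act"] for e in m1.extras["history"]]
        h2 = [e["simi_act"] for e in m2.extras["history"]]
        assert np.allclose(h1, h2, atol=1e-9)
        assert np.allclose(m1.embed(x[:5]), m2.embed(x[:5]), atol=1e-9)

    def test_weak_multi_decomposition_resums(self, tiny_arrays):
        x, y_act, y_pers, _ = tiny_arrays
        cons = sample_quadruples(y_act, y_pers, 96, seed=7)
        c = cfg_for("weak_multi", weights=LossWeights(alpha=0.6, beta=0.4))
        m = train_weak_multi(x, cons, c, spec=SMALL_RAW_SPEC)
        for e in m.extras["history"]:
            assert e["total"] == pytest.approx(
                0.6 * e["simi_act"] + 0.4 * e["simi_pers"], abs=1e-9)

    def test_selfsup_decomposition_resums_and_decreases(self, tiny_windows):
        feats = features_matrix(tiny_windows)
        index = build_neighborhood_index(tiny_windows, features=feats, k=5)
        c = cfg_for("selfsup", epochs_stage1=5,
                    weights=LossWeights(alpha=0.3, beta=0.3))
        m = train_selfsup(feats, index, c, spec=SMALL_FEAT_SPEC)
        h = m.extras["history"]
        assert h[-1]["total"] < h[0]["total"]
        for e in h:
            assert e["total"] == pytest.approx(e["ae"] + e["tc"] + e["fc"], abs=1e-9)

    def test_weak_selfsup_two_stages_and_budget(self, tiny_windows, tiny_arrays):
        _, y_act, _, _ = tiny_arrays
        feats = features_matrix(tiny_windows)
        index = build_neighborhood_index(tiny_windows, features=feats, k=5)
        budget = subsample_label_budget(y_act, 0.2, seed=8)
        cons = sample_pairs(y_act, 120, seed=8, allowed=budget)
        c = cfg_for("weak_selfsup",
                    weights=LossWeights(alpha=0.1, beta=0.1, gamma=0.6))
        m = train_weak_selfsup(feats, index, cons, c, spec=SMALL_FEAT_SPEC)
        stages = {e["stage"] for e in m.extras["history"]}
        assert stages == {"stage1", "stage2"}
        assert m.siamese is not None

    def test_weak_selfsup_empty_constraints_falls_back_with_warning(self, tiny_windows):
        feats = features_matrix(tiny_windows)
        index = build_neighborhood_index(tiny_windows, features=feats, k=5)
        c = cfg_for("weak_selfsup")
        with pytest.warns(UserWarning, match="constraint"):
            m = train_weak_selfsup(feats, index, None, c, spec=SMALL_FEAT_SPEC)
        assert all(e["stage"] == "stage1" for e in m.extras["history"])
        assert m.siamese is None

    def test_overfit_one_batch(self, tiny_arrays):
        """The supervised trainer drives its loss far below the starting value
        on a single repeated batch (standard optimization sanity check)."""
        from harspectrum.losses import cross_entropy_from_logits
        from harspectrum.models import build_tcn_encoder
        from harspectrum.nn import Adam

        x, y_act, _, _ = tiny_arrays
        xb, yb = x[:16], np.eye(3)[y_act[:16]]
        b = build_tcn_encoder(SMALL_RAW_SPEC, seed=0, n_classes=3)
        opt = Adam(b.parameters(), lr=1e-3)
        first = None
        for _ in range(300):
            opt.zero_grad()
            loss = cross_entropy_from_logits(b.classifier(b.encoder(xb)), yb)
            loss.backward()
            opt.step()
            first = first if first is not None else float(loss.value)
        assert float(loss.value) < 0.1 * first


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(paradigm="nope")
    with pytest.raises(ValueError):
        TrainingConfig(label_fraction=0.0)
    with pytest.raises(ValueError):
        TrainingConfig(epochs_stage1=0)
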