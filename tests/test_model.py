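"""MIL identities, training mechanics and the prediction pipeline."""

import numpy as np
import pytest

from mhcassign.model import (
    Bag,
    EarlyStopping,
    PresentationClassifier,
    fit_constant_probability,
    smooth_targets,
)

A, B, C = "HLA-A*02:01", "HLA-B*08:01", "HLA-C*07:02"

PSEUDO = {
    A: "ACDEFGHIKLMNPQRS",
    B: "LMNPQRSTVWYACDEF",
    C: "VWYACDEFGHIKLMNP",
}


@pytest.fixture(scope="module")
def tiny_model():
    """A small fitted model (two quick epochs on separable toy data)."""
    rng = np.random.default_rng(0)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    bags, val = [], []
    for i in range(60):
        pep = "".join(rng.choice(aas, size=9))
        bag = Bag(pep, [A, B], label=int(pep[1] == "L" or i % 2 == 0))
        (bags if i < 50 else val).append(bag)
    model = PresentationClassifier(
        encoder_dim=16, encoder_layers=1, encoder_heads=2,
        classifier_hidden=16, mil_hidden=16, batch_size=16,
        learning_rate=1e-3, max_epochs=2, seed=1,
    )
    return model.fit(bags, pseudosequences=PSEUDO, val_bags=val)


class TestMilIdentities:
    def test_single_instance_bag_identity(self, tiny_model):
        recs = tiny_model.score_bag(Bag("ACDEFGHIK", [A]))
        assert recs[0].attention_weight == pytest.approx(1.0)
        assert recs[0].bag_probability == pytest.approx(
            recs[0].instance_probability, abs=1e-7
        )

    def test_attention_sums_to_one(self, tiny_model):
        # six-instance bag needs six pseudosequences; use three here
        recs = tiny_model.score_bag(Bag("ACDEFGHIK", [A, B, C]))
        assert len(recs) == 3
        assert sum(r.attention_weight for r in recs) == pytest.approx(1.0, abs=1e-6)

    def test_instance_probability_is_per_pair(self, tiny_model):
        """Instance scores depend only on (peptide, allele), not bag context."""
        solo_a = tiny_model.score_bag(Bag("ACDEFGHIK", [A]))[0]
        in_pair = {
            r.allele: r for r in tiny_model.score_bag(Bag("ACDEFGHIK", [A, B]))
        }
        assert in_pair[A].instance_probability == pytest.approx(
            solo_a.instance_probability, abs=1e-6
        )

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            Bag("ACDEFGHIK", [])

    def test_duplicate_alleles_rejected(self):
        with pytest.raises(ValueError):
            Bag("ACDEFGHIK", [A, A])


class TestTrainingMechanics:
    def test_leakage_between_splits_raises(self):
        bags = [Bag("ACDEFGHIK", [A], label=1)]
        model = PresentationClassifier(encoder_dim=16, encoder_heads=2, max_epochs=1)
        with pytest.raises(ValueError, match="both splits"):
            model.fit(bags, pseudosequences=PSEUDO, val_bags=list(bags))

    def test_history_and_best_epoch_recorded(self, tiny_model):
        assert tiny_model.n_epochs_ == len(tiny_model.history_) == 2
        assert {"epoch", "train_loss", "val_loss"} <= set(tiny_model.history_[0])
        assert 1 <= tiny_model.best_epoch_ <= 2

    def test_learning_reduces_loss(self, tiny_model):
        assert (
            tiny_model.history_[-1]["train_loss"]
            < tiny_model.history_[0]["train_loss"] + 0.05
        )

    def test_label_smoothing_formula(self):
        np.testing.assert_allclose(
            smooth_targets(np.array([0.0, 1.0]), 0.1), [0.05, 0.95]
        )

    def test_constant_model_converges_to_smoothing_optimum(self):
        prob = fit_constant_probability([1] * 64, label_smoothing=0.1)
        assert prob == pytest.approx(0.95, abs=0.01)


class TestGatedAttention:
    def test_gated_variant_trains_and_normalizes(self):
        model = PresentationClassifier(
            encoder_dim=16, encoder_heads=2, classifier_hidden=8, mil_hidden=8,
            gated_attention=True, batch_size=4, max_epochs=1, seed=3,
        )
        bags = [Bag("ACDEFGHIK", [A, B], label=1), Bag("LMNPQRSTV", [A, B], label=0)]
        val = [Bag("VWYACDEFG", [A, B], label=1)]
        model.fit(bags, pseudosequences=PSEUDO, val_bags=val)
        recs = model.score_bag(Bag("ACDEFGHIK", [A, B]))
        assert sum(r.attention_weight for r in recs) == pytest.approx(1.0, abs=1e-6)


class TestEarlyStopping:
    def test_fires_after_patience_non_improving_epochs(self):
        stopper = EarlyStopping(patience=10)
        assert not stopper.update(1, 1.0)  # improvement at epoch 1
        stops = [stopper.update(e, 1.0) for e in range(2, 12)]
        assert stops == [False] * 9 + [True]  # stops after epoch 11
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        stopper.update(1, 1.0)
        stopper.update(2, 1.1)
        stopper.update(3, 0.9)  # new best
        assert stopper.bad_epochs == 0
        assert not stopper.update(4, 1.0)
        assert stopper.update(5, 1.0)

    def test_strictly_improving_never_stops(self):
        stopper = EarlyStopping(patience=10)
        assert not any(stopper.update(e, 1.0 / e) for e in range(1, 31))
        assert stopper.best_epoch == 30


class TestPredictPipeline:
    class GateAffinity:
        """Passes only (peptide, allele) pairs listed as strong."""

        def __init__(self, strong):
            self.strong = set(strong)

        def predict(self, peptide, allele):
            return 100.0 if (peptide, allele) in self.strong else 40_000.0

    def test_no_filter_scores_full_cartesian(self, tiny_model):
        records = tiny_model.predict_presentation(["ACDEFGHIK", "LMNPQRSTV"], [A, B])
        assert len(records) == 4
        assert not any(r.filtered for r in records)

    def test_filter_renormalizes_attention(self, tiny_model):
        gate = self.GateAffinity({("ACDEFGHIK", A), ("ACDEFGHIK", B)})
        records = tiny_model.predict_presentation(
            ["ACDEFGHIK"], [A, B, C], ba_filter=gate
        )
        kept = [r for r in records if not r.filtered]
        dropped = [r for r in records if r.filtered]
        assert {r.allele for r in dropped} == {C}
        assert sum(r.attention_weight for r in kept) == pytest.approx(1.0, abs=1e-6)
        assert np.isnan(dropped[0].instance_probability)

    def test_fully_filtered_bag_reported_not_presented(self, tiny_model):
        gate = self.GateAffinity(set())
        records = tiny_model.predict_presentation(["ACDEFGHIK"], [A, B], ba_filter=gate)
        assert all(r.filtered for r in records)
        assert all(r.bag_probability == 0.0 for r in records)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        tiny_model.save(tmp_path / "model")
        loaded = PresentationClassifier.load(tmp_path / "model")
        bag = Bag("ACDEFGHIK", [A, B])
        orig = tiny_model.score_bag(bag)
        back = loaded.score_bag(bag)
        for a, b in zip(orig, back):
            assert a.instance_probability == pytest.approx(b.instance_probability, abs=1e-6)
            assert a.bag_probability == pytest.approx(b.bag_probability, abs=1e-6)


class TestSklearnInterface:
    def test_get_set_params_round_trip(self):
        model = PresentationClassifier(encoder_dim=32)
        params = model.get_params()
        assert params["encoder_dim"] == 32
        model.set_params(encoder_dim=16, learning_rate=0.01)
        assert model.encoder_dim == 16 and model.learning_rate == 0.01

    def test_predict_proba_shape_and_predict(self, tiny_model):
        bags = [Bag("ACDEFGHIK", [A, B]), Bag("LMNPQRSTV", [A])]
        proba = tiny_model.predict_proba(bags)
        assert proba.shape == (2, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        labels = tiny_model.predict(bags)
        assert set(labels) <= {0, 1}
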