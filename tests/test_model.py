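"""Two-level attention model: masking semantics, permutation/padding
invariance, horizon truncation and checkpointing."""

import numpy as np
import pytest

from longict.model import (ModelConfig, TwoLevelAttentionModel,
                           build_marker_model, marker_features)
from longict.nn.autodiff import softmax


def random_inputs(rng, b=2, l=4, t=5, d=32):
    feats = rng.normal(size=(b, l, t, d))
    valid = rng.uniform(size=(b, l, t)) < 0.7
    valid[:, 0, 0] = True
    return feats, valid


class TestFeatureExtractor:
    def test_deterministic_and_correct_dimension(self, small_model, rng):
        patch = rng.uniform(size=(32, 32, 3))
        a = small_model.extract_features(patch[None])
        b = small_model.extract_features(patch[None])
        assert np.array_equal(a, b)
        assert a.shape == (1, small_model.config.d)

    def test_distinct_inputs_give_distinct_embeddings(self, small_model):
        z = small_model.extract_features(np.zeros((1, 32, 32, 3)))
        o = small_model.extract_features(np.ones((1, 32, 32, 3)))
        assert not np.allclose(z, o)

    def test_wrong_shape_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            small_model.extract_features(rng.uniform(size=(1, 32, 32, 2)))


class TestMaskingAndInvariance:
    def test_masked_slot_content_cannot_affect_output(self, small_model, rng):
        feats, valid = random_inputs(rng)
        ref = small_model.forward_batch(feats, valid).data
        feats2 = feats.copy()
        feats2[~valid] = 1e6
        assert np.array_equal(small_model.forward_batch(feats2, valid).data, ref)

    def test_lesion_permutation_invariance(self, small_model, rng):
        feats, valid = random_inputs(rng)
        ref = small_model.forward_batch(feats, valid).data
        perm = rng.permutation(feats.shape[1])
        out = small_model.forward_batch(feats[:, perm], valid[:, perm]).data
        assert np.allclose(out, ref, atol=1e-5)

    def test_appended_masked_padding_lesions_are_inert(self, small_model, rng):
        feats, valid = random_inputs(rng)
        ref = small_model.forward_batch(feats, valid).data
        pad_f = np.concatenate([feats, rng.normal(size=(2, 3, 5, 32))], axis=1)
        pad_v = np.concatenate([valid, np.zeros((2, 3, 5), bool)], axis=1)
        out = small_model.forward_batch(pad_f, pad_v).data
        assert np.allclose(out, ref, atol=1e-5)

    def test_temporal_position_controls_time_order_sensitivity(self, rng):
        feats, _ = random_inputs(rng)
        valid = np.ones((2, 4, 5), bool)
        perm = np.array([1, 0, 3, 2, 4])
        m_on = TwoLevelAttentionModel(ModelConfig(
            d=32, patch_size=32, cnn_width=4, seed=2, use_temporal_position=True))
        a = m_on.forward_batch(feats, valid).data
        b = m_on.forward_batch(feats[:, :, perm], valid).data
        assert np.abs(a - b).max() > 1e-4
        m_off = TwoLevelAttentionModel(ModelConfig(
            d=32, patch_size=32, cnn_width=4, seed=2, use_temporal_position=False))
        a = m_off.forward_batch(feats, valid).data
        b = m_off.forward_batch(feats[:, :, perm], valid).data
        assert np.allclose(a, b, atol=1e-5)

    def test_single_valid_timepoint_ignores_masked_slots(self, small_model, rng):
        feats = rng.normal(size=(1, 1, 5, 32))
        valid = np.zeros((1, 1, 5), bool)
        valid[0, 0, 2] = True
        ref = small_model.forward_batch(feats, valid).data
        feats2 = feats.copy()
        feats2[0, 0, [0, 1, 3, 4]] = -55.0
        assert np.array_equal(small_model.forward_batch(feats2, valid).data, ref)


class TestRiskHead:
    def test_softmax_probabilities_sum_to_one(self, small_model, rng):
        feats, valid = random_inputs(rng, b=5)
        logits = small_model.forward_batch(feats, valid)
        p = softmax(logits, axis=-1).data
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_equal_logits_give_half_risk(self, small_model):
        from longict.nn.autodiff import Tensor
        assert small_model.risk_from_logits(
            Tensor(np.zeros((1, 2)))).data[0] == pytest.approx(0.5)

    def test_risk_and_complement_sum_to_one(self, small_model, rng):
        logits = rng.normal(size=(100, 2))
        p = softmax(__import__("longict.nn.autodiff", fromlist=["Tensor"])
                    .Tensor(logits), axis=-1).data
        assert np.allclose(p[:, 0] + p[:, 1], 1.0)


class TestRecordForward:
    def test_risk_in_unit_interval_with_attention_attached(self, small_model,
                                                           tiny_cohort):
        _, records, _ = tiny_cohort
        out = small_model.forward(records[0], max_followups=2)
        assert 0.0 <= out.risk <= 1.0
        rows = np.nansum(out.temporal_attention, axis=1)
        valid_rows = rows[rows > 0]
        assert np.allclose(valid_rows, 1.0, atol=1e-6)
        assert out.lesion_attention.sum() == pytest.approx(1.0, abs=1e-6)

    def test_baseline_horizon_ignores_followups(self, small_model, tiny_cohort):
        _, records, _ = tiny_cohort
        rec = records[0]
        ref = small_model.forward(rec, max_followups=0).risk
        # mutate all follow-up patches: baseline-only risk must not move
        import copy
        rec2 = copy.deepcopy(rec)
        for track in rec2.lesions:
            for t in range(1, len(track.patches)):
                if track.patches[t] is not None:
                    track.patches[t].array[:] = 0.0
        assert small_model.forward(rec2, max_followups=0).risk == ref

    def test_missing_second_followup_equals_first_followup_horizon(
            self, small_model, tiny_cohort):
        _, records, _ = tiny_cohort
        import copy
        rec = copy.deepcopy(records[0])
        for track in rec.lesions:
            for t in range(2, len(track.patches)):
                track.patches[t] = None
        r1 = small_model.forward(rec, max_followups=1).risk
        r2 = small_model.forward(rec, max_followups=2).risk
        assert r2 == r1

    def test_duplicate_lesion_record_still_scores(self, small_model,
                                                  tiny_cohort):
        import copy
        _, records, _ = tiny_cohort
        rec = copy.deepcopy(records[0])
        dup = copy.deepcopy(rec.lesions[-1])
        dup.lesion_id = 99
        rec.lesions.append(dup)
        out = small_model.forward(rec, max_followups=2)
        assert 0.0 <= out.risk <= 1.0

    def test_invalid_horizon_rejected(self, small_model, tiny_cohort):
        _, records, _ = tiny_cohort
        with pytest.raises(ValueError):
            small_model.forward(records[0], max_followups=3)


class TestTrainingPlumbing:
    def test_gradient_reaches_aggregation_token(self, rng):
        model = TwoLevelAttentionModel(ModelConfig(d=32, patch_size=32,
                                                   cnn_width=4, seed=5))
        feats, valid = random_inputs(rng)
        model.forward_batch(feats, valid).sum().backward()
        assert np.linalg.norm(model.aggregation_token.grad) > 0
        model.zero_grad()

    def test_save_load_round_trip(self, small_model, rng, tmp_path):
        feats, valid = random_inputs(rng)
        ref = small_model.forward_batch(feats, valid).data
        path = tmp_path / "model.npz"
        small_model.save(path)
        clone = TwoLevelAttentionModel.load(path)
        assert np.array_equal(clone.forward_batch(feats, valid).data, ref)


class TestMarkerVariant:
    def test_marker_model_embeds_panel_with_missingness(self):
        model = build_marker_model(3)
        markers = np.array([[1.0, np.nan, 0.5],
                            [0.2, 0.1, np.nan],
                            [np.nan, np.nan, np.nan]])
        emb, valid = marker_features(model, markers)
        assert emb.shape == (3, 3, model.config.d)
        assert valid.tolist() == [[True, True, False],
                                  [False, True, False],
                                  [True, False, False]]
        logits = model.forward_batch(emb[None], valid[None])
        p = softmax(logits, axis=-1).data
        assert np.allclose(p.sum(axis=-1), 1.0)
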