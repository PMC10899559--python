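"""Two-level attention model for longitudinal multi-lesion prognosis.

Per-lesion patches are embedded by a miniature residual CNN; a temporal-
heterogeneity transformer (TH-former) fuses each lesion's time series, an
object-heterogeneity transformer (OH-former) fuses the lesion vectors through
a learnable aggregation token, and an MLP + softmax head turns the patient
vector into the probability of poor overall survival (< 12 months).

Missing scans and padded lesions are handled by masking: invalid keys get an
additive ``-inf`` attention logit and hence exactly zero weight, so outputs
are invariant to the content of missing slots, to lesion ordering, and to
appended padding lesions.

The same skeleton applied to normalized tumor-marker vectors (one "object"
being the marker panel) yields the marker-based variant (TDLM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .data import PatientRecord
from .nn.autodiff import Tensor, concat, softmax
from .nn.layers import (Adam, Linear, LayerNorm, MiniResNet, Module,
                        TransformerEncoder)

HORIZON_TO_TIMEPOINTS = {0: 1, 1: 2, 2: 3, 4: 5}   # max_followups -> timepoints


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the smallest plausible instantiation of the two-level
    design: 2 transformer layers with 4 heads at each level, embedding
    dimension 128, and a miniature ResNet-style extractor.  ``patch_size``
    only records the expected input resolution; the extractor is fully
    convolutional and pools globally.
    """

    d: int = 128
    n_heads: int = 4
    n_layers: int = 2
    patch_size: int = 224
    cnn_width: int = 8
    cnn_stages: int = 3
    n_timepoints_max: int = 5
    max_lesions: int = 6                      # 1 primary + up to 5 targets
    use_temporal_position: bool = True
    train_extractor: bool = False
    marker_dim: int = 0                       # >0: marker-vector input (TDLM)
    seed: int = 0
    extractor_seed: int = 0                   # frozen backbone is shared across runs


@dataclass
class RiskOutput:
    """Risk probability plus the attention tensors used for explanation."""

    risk: float                                # P(poor OS), in [0, 1]
    logits: np.ndarray                         # (2,), [good, poor]
    temporal_attention: np.ndarray             # (L, T), NaN at invalid slots
    lesion_attention: np.ndarray               # (L,), aggregation-token weights
    lesion_matrix: np.ndarray                  # (L, L) inter-lesion attention
    lesion_ids: tuple = ()
    sites: tuple = ()


class TwoLevelAttentionModel(Module):
    """TH-former + OH-former risk model (LDLM on patches, TDLM on markers)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d
        if config.marker_dim > 0:
            self.extractor = None
            self.marker_proj = Linear(config.marker_dim, d, rng)
        else:
            ex_rng = np.random.default_rng(config.extractor_seed)
            self.extractor = MiniResNet(d, ex_rng, width=config.cnn_width,
                                        n_stages=config.cnn_stages)
            if not config.train_extractor:
                for p in self.extractor.parameters():
                    p.requires_grad = False
            self.marker_proj = None
        # feature standardization (training-cohort statistics, checkpointed);
        # a per-vector LayerNorm would erase the magnitude-coded size signal
        self.feature_mu = Tensor(np.zeros(d))
        self.feature_sd = Tensor(np.ones(d))
        self.temporal_position = Tensor(
            rng.normal(0.0, 0.02, size=(config.n_timepoints_max, d)),
            requires_grad=True)
        self.th_former = TransformerEncoder(d, config.n_heads, config.n_layers, rng)
        self.oh_former = TransformerEncoder(d, config.n_heads, config.n_layers, rng)
        self.aggregation_token = Tensor(rng.normal(0.0, 0.02, size=d),
                                        requires_grad=True)
        self.head_hidden = Linear(d, max(d // 2, 8), rng)
        self.head_out = Linear(max(d // 2, 8), 2, rng)

    # -- feature extraction -------------------------------------------------
    def extract_features(self, patches: np.ndarray) -> np.ndarray:
        """Embed patches (N, S, S, 3) -> (N, d) with the frozen/shared CNN."""
        out = self.extract_features_tensor(Tensor(np.asarray(patches)))
        return out.data

    def extract_features_tensor(self, patches: Tensor) -> Tensor:
        if self.extractor is None:
            raise RuntimeError("marker-input model has no image extractor")
        x = patches
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[-1] != 3:
            raise ValueError(f"patches must be (..., S, S, 3), got {x.shape}")
        x = x.swapaxes(-1, -3).swapaxes(-1, -2)     # (N, 3, S, S)
        return self.extractor(x)

    # -- transformer levels -------------------------------------------------
    def th_former_fuse(self, sequence: Tensor, valid: np.ndarray) -> Tensor:
        """Fuse one batch of time series: (B, T, d) + mask (B, T) -> (B, d).

        Self-attention runs over valid timepoints only; the fused object
        vector is the mask-weighted mean of the attended sequence.
        """
        valid = np.asarray(valid, dtype=bool)
        if not valid.any(axis=-1).all():
            raise ValueError("each object needs at least one valid timepoint")
        out = self.th_former(sequence, valid)
        w = valid.astype(float)
        w = w / w.sum(axis=-1, keepdims=True)
        return (out * Tensor(w[..., None])).sum(axis=-2)

    def oh_former_fuse(self, objects: Tensor, valid: np.ndarray) -> Tensor:
        """Fuse object vectors (B, L, d) + mask (B, L) through the
        aggregation token; returns the patient vector (B, d)."""
        valid = np.asarray(valid, dtype=bool)
        if not valid.any(axis=-1).all():
            raise ValueError("each patient needs at least one valid object")
        b, l, d = objects.shape
        tok = self.aggregation_token.reshape(1, 1, d) * Tensor(np.ones((b, 1, 1)))
        x = concat([tok, objects], axis=1)
        mask = np.concatenate([np.ones((b, 1), bool), valid], axis=1)
        out = self.oh_former(x, mask)
        return out[:, 0, :]

    def predict_risk_from_vector(self, patient_vec: Tensor) -> Tensor:
        """Patient vector (B, d) -> class logits (B, 2), order [good, poor]."""
        h = self.head_hidden(patient_vec).relu()
        return self.head_out(h)

    # -- full forward -------------------------------------------------------
    def forward_batch(self, features, valid: np.ndarray) -> Tensor:
        """Features (B, L, T, d) + mask (B, L, T) -> logits (B, 2).

        ``features`` may be a plain array (cached, frozen extractor) or a
        Tensor on the autodiff graph (live extractor / GradCAM).
        """
        x = features if isinstance(features, Tensor) else Tensor(np.asarray(features))
        valid = np.asarray(valid, dtype=bool)
        b, l, t, d = x.shape
        x = (x - self.feature_mu) * (self.feature_sd ** -1.0)
        x = x * Tensor(valid[..., None].astype(float))      # sentinel zeros
        if self.config.use_temporal_position:
            pos = self.temporal_position[:t].reshape(1, 1, t, d)
            x = x + pos
        obj_valid = valid.any(axis=-1)                       # (B, L)
        seq = x.reshape(b * l, t, d)
        seq_valid = valid.reshape(b * l, t).copy()
        # padded lesions have no valid timepoint: give them a dummy key so the
        # TH-former runs, then zero the resulting object vector
        dummy = ~seq_valid.any(axis=-1)
        seq_valid[dummy, 0] = True
        obj = self.th_former_fuse(seq, seq_valid).reshape(b, l, d)
        obj = obj * Tensor(obj_valid[..., None].astype(float))
        patient = self.oh_former_fuse(obj, obj_valid)
        return self.predict_risk_from_vector(patient)

    def set_feature_stats(self, features: np.ndarray, valid: np.ndarray) -> None:
        """Store per-dimension mean/sd of the valid training embeddings."""
        f = np.asarray(features)[np.asarray(valid, bool)]
        self.feature_mu.data[...] = f.mean(axis=0)
        sd = f.std(axis=0)
        self.feature_sd.data[...] = np.where(sd > 1e-12, sd, 1.0)

    def risk_from_logits(self, logits: Tensor) -> Tensor:
        return softmax(logits, axis=-1)[..., 1]

    def _record_features(self, record: PatientRecord, max_followups: int
                         ) -> tuple[np.ndarray, np.ndarray]:
        t_keep = HORIZON_TO_TIMEPOINTS.get(max_followups, max_followups + 1)
        tmax = self.config.n_timepoints_max
        l = len(record.lesions)
        d = self.config.d
        feats = np.zeros((1, l, tmax, d))
        valid = np.zeros((1, l, tmax), dtype=bool)
        for i, track in enumerate(record.lesions):
            for t, patch in enumerate(track.patches):
                if patch is None or t >= min(t_keep, tmax):
                    continue
                feats[0, i, t] = self.extract_features(patch.array[None])[0]
                valid[0, i, t] = True
        return feats, valid

    def forward(self, record: PatientRecord, max_followups: int = 4) -> RiskOutput:
        """Score one patient at a follow-up horizon (0 = baseline only,
        1/2/4 = up to that follow-up).  Scans absent from the record are
        masked, never an error."""
        if max_followups not in HORIZON_TO_TIMEPOINTS:
            raise ValueError("max_followups must be one of 0, 1, 2, 4")
        feats, valid = self._record_features(record, max_followups)
        if not valid.any():
            raise ValueError(f"patient {record.patient_id} has no baseline scan")
        logits = self.forward_batch(feats, valid)
        return self._build_output(record, logits, valid)

    def _build_output(self, record: PatientRecord, logits: Tensor,
                      valid: np.ndarray) -> RiskOutput:
        l = valid.shape[1]
        probs = softmax(logits, axis=-1).data[0]
        # temporal attention: last TH layer, mean over heads and valid queries
        th_att = self.th_former.last_attention.reshape(
            1, l, -1, valid.shape[2], valid.shape[2])[0]     # (L, h, T, T)
        temporal = np.full((l, valid.shape[2]), np.nan)
        for i in range(l):
            v = valid[0, i]
            if not v.any():
                continue
            rows = th_att[i][:, v][:, :, v].mean(axis=(0, 1))  # mean heads+queries
            w = rows / rows.sum() if rows.sum() > 0 else rows
            temporal[i, v] = w
        # lesion-level attention: last OH layer, aggregation-token row and
        # the inter-object block, mean over heads, renormalized over objects
        oh_att = self.oh_former.last_attention[0]            # (h, L+1, L+1)
        obj_valid = valid[0].any(axis=-1)
        agg_row = oh_att[:, 0, 1:].mean(axis=0)
        agg_row = np.where(obj_valid, agg_row, 0.0)
        s = agg_row.sum()
        lesion_att = agg_row / s if s > 0 else agg_row
        mat = oh_att[:, 1:, 1:].mean(axis=0)
        mat = np.where(np.outer(obj_valid, obj_valid), mat, np.nan)
        row_sums = np.nansum(mat, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = mat / np.where(row_sums > 0, row_sums, np.nan)
        return RiskOutput(
            risk=float(probs[1]), logits=logits.data[0].copy(),
            temporal_attention=temporal, lesion_attention=lesion_att,
            lesion_matrix=mat,
            lesion_ids=tuple(t.lesion_id for t in record.lesions),
            sites=tuple(t.site for t in record.lesions))

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self._all_tensors())}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    def _all_tensors(self) -> list[Tensor]:
        out, seen = [], set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for k, v in sorted(vars(obj).items()):
                    if k != "config" and not k.startswith("last_"):
                        walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return out

    @classmethod
    def load(cls, path) -> "TwoLevelAttentionModel":
        with np.load(path, allow_pickle=False) as archive:
            config = ModelConfig(**json.loads(str(archive["__config__"])))
            model = cls(config)
            tensors = model._all_tensors()
            for i, t in enumerate(tensors):
                t.data[...] = archive[f"p{i}"]
        return model


def build_marker_model(n_markers: int, config: ModelConfig | None = None
                       ) -> TwoLevelAttentionModel:
    """TDLM: the same two-level skeleton over the tumor-marker panel.

    Each marker is one object whose per-timepoint scalar value is projected
    into the embedding space (missing values masked), so temporal fusion and
    cross-marker interaction mirror the lesion model.
    """
    cfg = config or ModelConfig(d=32, n_heads=4, n_layers=2)
    cfg.marker_dim = 2  # (value, marker-identity scalar)
    model = TwoLevelAttentionModel(cfg)
    model._n_markers = n_markers
    return model


def marker_features(model: TwoLevelAttentionModel, markers: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Turn a normalized (T, M) marker table into per-object embeddings
    (M, T, d) + validity mask via the model's marker projection."""
    t, m = markers.shape
    valid = np.isfinite(markers.T)                    # (M, T)
    ident = np.linspace(-1.0, 1.0, m)
    inp = np.zeros((m, t, 2))
    inp[..., 0] = np.nan_to_num(markers.T)
    inp[..., 1] = ident[:, None]
    emb = model.marker_proj(Tensor(inp.reshape(m * t, 2))).data.reshape(
        m, t, model.config.d)
    return emb, valid
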