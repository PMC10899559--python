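"""Model explanation: last-layer attention importance (temporal and
inter-lesion/organ-pairwise) and GradCAM pixel heatmaps per lesion patch.

Attention tensors are captured during the ordinary forward pass (capture
never alters the computation), aggregated over heads by mean; group-level
reports contrast patients above/below the frozen Youden cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .data import ImagePatch, PatientRecord, SITES
from .model import RiskOutput, TwoLevelAttentionModel
from .nn.autodiff import Tensor


def _nanmean_cols(a: np.ndarray) -> np.ndarray:
    """Column means ignoring NaN, NaN for all-NaN columns (no warnings)."""
    mask = np.isfinite(a)
    n = mask.sum(axis=0)
    s = np.where(mask, a, 0.0).sum(axis=0)
    return np.where(n > 0, s / np.maximum(n, 1), np.nan)


@dataclass
class AttentionReport:
    temporal_importance: np.ndarray      # (T,) mean over lesions, sums to 1
    organ_matrix: pd.DataFrame           # site x site mean attention
    group: str | None = None             # "high" | "low" | None
    risk: float = np.nan


@dataclass
class Heatmap:
    array: np.ndarray                    # (S, S) in [0, 1], max-normalized
    lesion_id: int
    timepoint: int
    all_zero: bool = False


def extract_attention(model: TwoLevelAttentionModel, record: PatientRecord,
                      max_followups: int = 4,
                      cutoff: float | None = None) -> AttentionReport:
    """Attention importance for one patient from the last TH/OH layers."""
    out: RiskOutput = model.forward(record, max_followups=max_followups)
    return attention_report(out, cutoff=cutoff)


def attention_report(out: RiskOutput, cutoff: float | None = None
                     ) -> AttentionReport:
    temporal = _nanmean_cols(out.temporal_attention)
    s = np.nansum(temporal)
    if s > 0:
        temporal = temporal / s
    sites = list(out.sites)
    organ = pd.DataFrame(np.nan, index=list(SITES), columns=list(SITES))
    counts = pd.DataFrame(0.0, index=list(SITES), columns=list(SITES))
    m = out.lesion_matrix
    for i, si in enumerate(sites):
        for j, sj in enumerate(sites):
            v = m[i, j]
            if np.isfinite(v):
                prev = organ.loc[si, sj]
                organ.loc[si, sj] = v if np.isnan(prev) else prev + v
                counts.loc[si, sj] += 1.0
    organ = organ / counts.where(counts > 0)
    group = None
    if cutoff is not None:
        group = "high" if out.risk > cutoff else "low"
    return AttentionReport(temporal_importance=temporal, organ_matrix=organ,
                           group=group, risk=out.risk)


def cohort_attention(model: TwoLevelAttentionModel,
                     records: list[PatientRecord], cutoff: float,
                     max_followups: int = 4) -> dict:
    """Group-averaged attention reports ({'high': ..., 'low': ...})."""
    buckets: dict[str, list[AttentionReport]] = {"high": [], "low": []}
    for rec in records:
        rep = extract_attention(model, rec, max_followups, cutoff=cutoff)
        buckets[rep.group].append(rep)
    out = {}
    for grp, reps in buckets.items():
        if not reps:
            continue
        temporal = _nanmean_cols(np.stack([r.temporal_importance for r in reps]))
        s = np.nansum(temporal)
        organ = pd.concat([r.organ_matrix for r in reps]).groupby(level=0).mean()
        organ = organ.reindex(index=list(SITES), columns=list(SITES))
        out[grp] = AttentionReport(
            temporal_importance=temporal / s if s > 0 else temporal,
            organ_matrix=organ, group=grp)
    return out


def gradcam(model: TwoLevelAttentionModel, patch: ImagePatch,
            target_class: int = 1) -> Heatmap:
    """Gradient-weighted class-activation map for one lesion patch.

    The patch is scored as a single-lesion, single-timepoint patient; the
    target-class logit is backpropagated to the last convolutional feature
    maps, whose gradient-weighted, ReLU-rectified sum is upsampled to patch
    size and max-normalized.
    """
    if model.extractor is None:
        raise ValueError("GradCAM requires the image model")
    x = Tensor(np.asarray(patch.array, dtype=float)[None], requires_grad=True)
    feat = model.extract_features_tensor(x)            # (1, d)
    acts = model.extractor.last_conv_activations       # (1, C, h, w)
    logits = model.forward_batch(feat.reshape(1, 1, 1, -1),
                                 np.ones((1, 1, 1), bool))
    logits[0, target_class].backward()
    grad = acts.grad[0]                                # (C, h, w)
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts.data[0]).sum(axis=0), 0.0)
    model.zero_grad()
    size = patch.array.shape[0]
    cam = resize(cam, (size, size), order=1, mode="edge", anti_aliasing=False)
    peak = cam.max()
    if peak <= 0:
        return Heatmap(array=np.zeros((size, size)), lesion_id=patch.lesion_id,
                       timepoint=patch.timepoint, all_zero=True)
    return Heatmap(array=cam / peak, lesion_id=patch.lesion_id,
                   timepoint=patch.timepoint)
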