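"""Training: survival labels, the combined classification + ranking loss
(l_ce + l_surv), and the seeded training loop.

The binary head classifies poor (< 12 months, death observed) versus good
(>= 12 months) overall survival; patients censored before 12 months have an
undefined class and are excluded from the cross-entropy term but still
contribute to the survival loss, which is the batch-wise negative Cox
partial log-likelihood (Breslow ties) of the risk score and orders all
patients regardless of class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PatientRecord, POOR_OS_MONTHS
from .model import HORIZON_TO_TIMEPOINTS, TwoLevelAttentionModel
from .nn.autodiff import Tensor, logsumexp
from .nn.layers import Adam

POOR, GOOD, INDETERMINATE = 1, 0, -1


@dataclass(frozen=True)
class SurvivalLabel:
    os_months: float
    event: int

    @property
    def binary_class(self) -> int:
        """1 = poor (< 12 mo, death observed), 0 = good (>= 12 mo regardless
        of censoring), -1 = indeterminate (censored before 12 mo)."""
        if self.os_months >= POOR_OS_MONTHS:
            return GOOD
        return POOR if self.event == 1 else INDETERMINATE


def make_labels(os_months, events) -> np.ndarray:
    return np.array([SurvivalLabel(t, e).binary_class
                     for t, e in zip(os_months, events)])


@dataclass
class LossConfig:
    use_ce: bool = True
    use_surv: bool = True
    ce_weight: float = 1.0
    surv_weight: float = 1.0
    batch_size: int = 32
    surv_batch_size: int | None = None     # defaults to batch_size
    lr: float = 5e-3
    epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (self.use_ce or self.use_surv):
            raise ValueError("at least one loss term must be enabled")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def ce_loss(risks, labels):
    """Mean binary cross-entropy of risk probabilities over poor/good
    patients; indeterminate labels are skipped.  Accepts a plain array or a
    Tensor (autodiff)."""
    labels = np.asarray(labels)
    keep = labels != INDETERMINATE
    if not keep.any():
        raise ValueError("empty effective batch: all labels indeterminate")
    y = labels[keep].astype(float)
    if isinstance(risks, Tensor):
        r = risks[np.nonzero(keep)[0]]
        terms = Tensor(y) * r.log() + Tensor(1.0 - y) * (1.0 - r).log()
        return -terms.mean()
    r = np.asarray(risks, dtype=float)[keep]
    return float(-np.mean(y * np.log(r) + (1 - y) * np.log(1 - r)))

def ce_loss_from_logits(logits: Tensor, labels) -> Tensor:
    """Numerically stable cross-entropy on class logits [good, poor]."""
    labels = np.asarray(labels)
    keep = np.nonzero(labels != INDETERMINATE)[0]
    if keep.size == 0:
        raise ValueError("empty effective batch: all labels indeterminate")
    sel = logits[keep]
    lse = logsumexp(sel, axis=-1)
    picked = (sel * Tensor(np.eye(2)[labels[keep]])).sum(axis=-1)
    return (lse - picked).mean()


def surv_loss(scores, os_months, events):
    """Negative Cox partial log-likelihood (Breslow ties) of the risk score,
    averaged over events; invariant to adding a constant to all scores.

    Accepts a Tensor (for training) or an array (evaluation/oracles)."""
    os_months = np.asarray(os_months, dtype=float)
    events = np.asarray(events, dtype=int)
    ev_idx = np.nonzero(events == 1)[0]
    if ev_idx.size == 0:
        raise ValueError(
            "survival loss needs at least one event in the mini-batch; "
            "increase surv_batch_size")
    riskset = (os_months[None, :] >= os_months[:, None]).astype(float)  # j in R(i)
    if isinstance(scores, Tensor):
        c = float(scores.data.max())
        lse_all = ((Tensor(riskset) @ (scores - c).exp().reshape(-1, 1))
                   .reshape(-1).log() + c)
        terms = lse_all[ev_idx] - scores[ev_idx]
        return terms.mean()
    s = np.asarray(scores, dtype=float)
    c = s.max()
    lse_all = np.log(riskset @ np.exp(s - c)) + c
    return float(np.mean(lse_all[ev_idx] - s[ev_idx]))


def total_loss(logits: Tensor, labels, os_months, events,
               config: LossConfig):
    """Weighted sum of the enabled loss terms on one batch of logits.

    Returns (total, l_ce, l_surv) where disabled/inapplicable terms are None.
    The survival score is the poor-class logit margin (monotone in risk)."""
    parts, l_ce, l_surv = [], None, None
    if config.use_ce and (np.asarray(labels) != INDETERMINATE).any():
        l_ce = ce_loss_from_logits(logits, labels)
        parts.append(l_ce * config.ce_weight)
    if config.use_surv and np.asarray(events).sum() > 0:
        margin = logits[:, 1] - logits[:, 0]
        l_surv = surv_loss(margin, os_months, events)
        parts.append(l_surv * config.surv_weight)
    if not parts:
        raise ValueError("no applicable loss term for this batch")
    total = parts[0]
    for p in parts[1:]:
        total = total + p
    return total, l_ce, l_surv


# ---------------------------------------------------------------------------
# feature caching and training loop
# ---------------------------------------------------------------------------

def cohort_features(model: TwoLevelAttentionModel,
                    records: list[PatientRecord],
                    max_followups: int = 4,
                    chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Embed every available patch once with the (frozen) extractor.

    Returns features (N, L_max, T, d) and the validity mask (N, L_max, T).
    """
    tmax = model.config.n_timepoints_max
    t_keep = min(HORIZON_TO_TIMEPOINTS[max_followups], tmax)
    lmax = max(len(r.lesions) for r in records)
    d = model.config.d
    patches, where = [], []
    for i, rec in enumerate(records):
        for j, track in enumerate(rec.lesions):
            for t, patch in enumerate(track.patches):
                if patch is not None and t < t_keep:
                    patches.append(patch.array)
                    where.append((i, j, t))
    feats = np.zeros((len(records), lmax, tmax, d))
    valid = np.zeros((len(records), lmax, tmax), dtype=bool)
    for lo in range(0, len(patches), chunk):
        batch = np.stack(patches[lo:lo + chunk]).astype(float)
        emb = model.extract_features(batch)
        for (i, j, t), e in zip(where[lo:lo + chunk], emb):
            feats[i, j, t] = e
            valid[i, j, t] = True
    return feats, valid


@dataclass
class TrainResult:
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def final_loss(self) -> float:
        return float(self.history["total"].iloc[-1])


def train(model: TwoLevelAttentionModel,
          records: list[PatientRecord],
          config: LossConfig | None = None,
          features: tuple[np.ndarray, np.ndarray] | None = None,
          verbose: bool = False) -> TrainResult:
    """Fit the transformer levels, aggregation token, temporal embedding and
    head on a training cohort.  Training always sees up to four follow-ups;
    the evaluation horizon is chosen independently at prediction time.

    Deterministic given ``config.seed`` (single-threaded numpy)."""
    config = config or LossConfig()
    rng = np.random.default_rng(config.seed)
    feats, valid = features if features is not None else cohort_features(model, records)
    if np.all(model.feature_sd.data == 1.0) and np.all(model.feature_mu.data == 0.0):
        model.set_feature_stats(feats, valid)
    os_months = np.array([r.os_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    labels = make_labels(os_months, events)
    n = len(records)
    surv_bs = config.surv_batch_size or config.batch_size
    params = [p for p in model.parameters()]
    opt = Adam(params, lr=config.lr)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep = {"ce": [], "surv": [], "total": []}
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if surv_bs > idx.size and config.use_surv:
                extra = rng.choice(np.setdiff1d(np.arange(n), idx),
                                   size=min(surv_bs - idx.size,
                                            n - idx.size), replace=False)
                idx = np.concatenate([idx, extra])
            logits = model.forward_batch(feats[idx], valid[idx])
            try:
                loss, l_ce, l_surv = total_loss(
                    logits, labels[idx], os_months[idx], events[idx], config)
            except ValueError:
                continue   # batch with no applicable term
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}; "
                    "lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep["total"].append(float(loss.data))
            ep["ce"].append(float(l_ce.data) if l_ce is not None else np.nan)
            ep["surv"].append(float(l_surv.data) if l_surv is not None else np.nan)
        def _mean(xs):
            xs = [x for x in xs if np.isfinite(x)]
            return float(np.mean(xs)) if xs else np.nan

        row = {"epoch": epoch, "l_ce": _mean(ep["ce"]),
               "l_surv": _mean(ep["surv"]), "total": _mean(ep["total"])}
        rows.append(row)
        if verbose:
            print(f"epoch {epoch}: l_ce={row['l_ce']:.4f} "
                  f"l_surv={row['l_surv']:.4f} total={row['total']:.4f}")
    return TrainResult(history=pd.DataFrame(rows))


def predict_cohort(model: TwoLevelAttentionModel,
                   records: list[PatientRecord],
                   max_followups: int = 2,
                   features: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> pd.DataFrame:
    """Risk probability per patient at the requested follow-up horizon."""
    if features is not None:
        feats, valid = features
        t_keep = HORIZON_TO_TIMEPOINTS[max_followups]
        valid = valid.copy()
        valid[:, :, t_keep:] = False
        logits = model.forward_batch(feats, valid)
        risks = model.risk_from_logits(logits).data
    else:
        risks = [model.forward(r, max_followups=max_followups).risk
                 for r in records]
    return pd.DataFrame({"patient_id": [r.patient_id for r in records],
                         "risk": np.asarray(risks, dtype=float)})
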