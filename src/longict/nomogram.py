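"""Cox-regression nomogram fusing the image-model (LDLM) score, the
marker-model (TDLM) score, the RECIST category and clinical covariates into
one risk score, with the classic point mapping, one-year calibration curve
and Hosmer-Lemeshow test.

Two variants mirror the dual-nomogram design: the full model and the
"without TDLM" refit used when a cohort has no tumor markers (missingness is
handled by the variant, not by imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sps

from .data import POOR_OS_MONTHS
from .metrics import km_curve
from .recist import RECIST_ORDER

POINT_RANGE = 100.0


def encode_recist(categories) -> pd.DataFrame:
    """Ordered-categorical dummy coding of RECIST (CR/PR merged as objective
    response, the reference level; SD and PD each get an indicator)."""
    level = [RECIST_ORDER.get(c, np.nan) for c in categories]
    return pd.DataFrame({
        "recist_sd": [float(v == 2) for v in level],
        "recist_pd": [float(v == 3) for v in level],
    })


@dataclass
class NomogramModel:
    covariates: list
    coefficients: dict
    covariate_means: dict
    covariate_ranges: dict                   # training min/max per covariate
    baseline_survival_1yr: float
    point_span: float                        # lp units worth 100 points
    includes_tdlm: bool = True

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, (list, tuple)) else v)
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, payload: dict) -> "NomogramModel":
        return cls(**payload)


def fit_nomogram(df: pd.DataFrame, duration_col: str = "os_months",
                 event_col: str = "event", covariates: list | None = None,
                 t_star: float = POOR_OS_MONTHS) -> NomogramModel:
    """Cox partial-likelihood fit on the training cohort.

    ``df`` must hold numeric covariate columns (use :func:`encode_recist` and
    0/1 codes for sex/HER2 beforehand).  Dropping ``tdlm_score`` from
    ``covariates`` and refitting yields the without-TDLM variant.  The
    Breslow baseline survival at ``t_star`` months (12 = one year) is stored
    for absolute-risk prediction.
    """
    covariates = list(covariates or
                      [c for c in df.columns if c not in (duration_col, event_col)])
    if df[covariates].isna().any().any():
        raise ValueError("missing covariate values; fit the without-TDLM "
                         "variant or drop incomplete patients explicitly")
    cph = CoxPHFitter()
    cph.fit(df[covariates + [duration_col, event_col]],
            duration_col=duration_col, event_col=event_col)
    coef = {c: float(cph.params_[c]) for c in covariates}
    means = {c: float(df[c].mean()) for c in covariates}
    ranges = {c: (float(df[c].min()), float(df[c].max())) for c in covariates}
    base_sf = cph.baseline_survival_
    idx = np.searchsorted(base_sf.index.to_numpy(dtype=float), t_star, side="right") - 1
    base_1yr = float(base_sf.iloc[idx, 0]) if idx >= 0 else 1.0
    spans = [abs(coef[c]) * (ranges[c][1] - ranges[c][0]) for c in covariates]
    span = max(spans) if max(spans) > 0 else 1.0
    return NomogramModel(covariates=covariates, coefficients=coef,
                         covariate_means=means, covariate_ranges=ranges,
                         baseline_survival_1yr=base_1yr,
                         point_span=span,
                         includes_tdlm="tdlm_score" in covariates)


def linear_predictor(model: NomogramModel, df: pd.DataFrame) -> np.ndarray:
    lp = np.zeros(len(df))
    for c in model.covariates:
        if c not in df.columns or df[c].isna().any():
            raise ValueError(f"covariate {c!r} missing for this variant")
        lp += model.coefficients[c] * df[c].to_numpy(dtype=float)
    return lp


def covariate_points(model: NomogramModel, df: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate nomogram points: each covariate's contribution
    beta * x, shifted to start at 0 over the training range and scaled so
    the widest span is worth 100 points."""
    out = {}
    for c in model.covariates:
        contrib = model.coefficients[c] * df[c].to_numpy(dtype=float)
        lo = min(model.coefficients[c] * r for r in model.covariate_ranges[c])
        out[c] = (contrib - lo) * POINT_RANGE / model.point_span
    return pd.DataFrame(out, index=df.index)


def points_to_lp(model: NomogramModel, total_points: np.ndarray) -> np.ndarray:
    """Invert the affine point mapping back to the linear predictor."""
    offset = sum(min(model.coefficients[c] * r for r in model.covariate_ranges[c])
                 for c in model.covariates)
    return np.asarray(total_points) * model.point_span / POINT_RANGE + offset


def nomo_score(model: NomogramModel, df: pd.DataFrame) -> pd.DataFrame:
    """Linear predictor, total nomogram points and predicted one-year
    survival (Breslow: S(12)^(exp(lp - mean training lp)))."""
    lp = linear_predictor(model, df)
    lp_mean = sum(model.coefficients[c] * model.covariate_means[c]
                  for c in model.covariates)
    surv = model.baseline_survival_1yr ** np.exp(lp - lp_mean)
    pts = covariate_points(model, df).sum(axis=1).to_numpy()
    return pd.DataFrame({"lp": lp, "points": pts, "surv_1yr": surv},
                        index=df.index)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    predicted: np.ndarray                  # mean predicted survival per bin
    observed: np.ndarray                   # KM-observed survival per bin
    bin_n: np.ndarray
    hl_stat: float
    hl_df: int
    hl_p: float
    merged_bins: int = 0


def hosmer_lemeshow(p_event: np.ndarray, events: np.ndarray, g: int = 10,
                    df_offset: int = 2) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi-square on binary outcomes grouped into ``g``
    quantile bins of predicted event probability; df = g - ``df_offset``
    (the classic choice for fitted models)."""
    p_event = np.asarray(p_event, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(p_event, kind="mergesort")
    bins = np.array_split(order, g)
    bins = [b for b in bins if b.size > 0]
    stat = 0.0
    for b in bins:
        n = b.size
        e = float(p_event[b].sum())
        o = float(events[b].sum())
        denom = e * (1.0 - e / n)
        if denom <= 0:
            continue
        stat += (o - e) ** 2 / denom
    df = max(len(bins) - df_offset, 1)
    return stat, df, float(sps.chi2.sf(stat, df))


def calibration_curve(pred_surv_1yr, os_months, events, g: int = 10,
                      t_star: float = POOR_OS_MONTHS) -> CalibrationResult:
    """One-year calibration: deciles of predicted survival versus the
    Kaplan-Meier observed survival per bin, plus a Hosmer-Lemeshow test on
    the implied event counts (df = bins - 2).  Bins with no patients or no
    information are merged into their neighbour and logged."""
    pred = np.asarray(pred_surv_1yr, dtype=float)
    os_months = np.asarray(os_months, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(pred) < 20:
        raise ValueError("calibration needs at least 20 patients")
    order = np.argsort(pred, kind="mergesort")
    raw_bins = [b for b in np.array_split(order, g) if b.size > 0]
    merged = 0
    bins = []
    for b in raw_bins:
        if len(b) < 2 and bins:
            bins[-1] = np.concatenate([bins[-1], b])
            merged += 1
            continue
        bins.append(b)
    pred_mean, obs, ns = [], [], []
    stat = 0.0
    for b in bins:
        n = b.size
        p_ev = float((1.0 - pred[b]).sum())
        km = km_curve(os_months[b], events[b])
        s_obs = km.at(t_star)
        o_ev = n * (1.0 - s_obs)
        denom = p_ev * (1.0 - p_ev / n)
        if denom > 0:
            stat += (o_ev - p_ev) ** 2 / denom
        pred_mean.append(float(pred[b].mean()))
        obs.append(s_obs)
        ns.append(n)
    df = max(len(bins) - 2, 1)
    return CalibrationResult(predicted=np.array(pred_mean),
                             observed=np.array(obs),
                             bin_n=np.array(ns), hl_stat=stat, hl_df=df,
                             hl_p=float(sps.chi2.sf(stat, df)),
                             merged_bins=merged)


def build_covariate_table(ldlm_scores, recist_categories, sex, her2,
                          tdlm_scores=None, os_months=None, events=None
                          ) -> pd.DataFrame:
    """Assemble the numeric covariate table for nomogram fitting/scoring."""
    df = pd.DataFrame({"ldlm_score": np.asarray(ldlm_scores, dtype=float)})
    if tdlm_scores is not None:
        df["tdlm_score"] = np.asarray(tdlm_scores, dtype=float)
    df = pd.concat([df, encode_recist(recist_categories)], axis=1)
    df["sex_male"] = [float(s == "M") for s in sex]
    df["her2_3plus"] = [float(h == "3+") for h in her2]
    if os_months is not None:
        df["os_months"] = np.asarray(os_months, dtype=float)
        df["event"] = np.asarray(events, dtype=int)
    return df
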