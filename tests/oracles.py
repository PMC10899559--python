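"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration, deliberately independent of
the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def cindex_bruteforce(scores, times, events) -> float:
    """Harrell's C by explicit pair enumeration (risk convention: higher
    score should pair with shorter survival; ties in score count 1/2).

    A pair (i, j) is comparable when the smaller time carries an event.
    Tied survival times are excluded (callers draw continuous times)."""
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                continue
            first, second = (i, j) if times[i] < times[j] else (j, i)
            if events[first] != 1:
                continue
            den += 1
            if scores[first] > scores[second]:
                num += 1
            elif scores[first] == scores[second]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def youden_bruteforce(scores, labels) -> float:
    """Exhaustive scan of all midpoints between adjacent distinct scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    best_j, best_c = -np.inf, None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        c = (lo + hi) / 2.0
        sens = np.mean(scores[labels == 1] > c)
        spec = np.mean(scores[labels == 0] <= c)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_c


def km_bruteforce(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Hand product-limit estimator: S(t) = prod (1 - d_i / n_i)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    event_times = np.unique(times[events == 1])
    s, out_t, out_s = 1.0, [0.0], [1.0]
    for t in event_times:
        at_risk = np.sum(times >= t)
        deaths = np.sum((times == t) & (events == 1))
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_bruteforce(t1, e1, t2, e2) -> float:
    """Two-group log-rank chi-square from the observed-minus-expected table."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(all_t[all_e == 1]):
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        n = n1 + n2
        d = np.sum((all_t == t) & (all_e == 1))
        d1 = np.sum((t1 == t) & (e1 == 1))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def recist_bruteforce(base: float, follow: float, new_lesion: bool) -> str:
    """Literal RECIST v1.1 diameter-sum rules, spelled out independently."""
    if new_lesion:
        return "PD"
    if follow == 0:
        return "CR"
    pct = (follow - base) / base * 100.0
    absolute = follow - base
    if pct >= 20.0 and absolute >= 5.0:
        return "PD"
    if pct <= -30.0:
        return "PR"
    return "SD"


def cox_partial_loglik_bruteforce(scores, times, events) -> float:
    """Negative Breslow partial log-likelihood, averaged over events,
    computed with explicit risk-set loops."""
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    terms = []
    for i in np.nonzero(events == 1)[0]:
        risk_set = [j for j in range(len(times)) if times[j] >= times[i]]
        denom = sum(np.exp(scores[j]) for j in risk_set)
        terms.append(np.log(denom) - scores[i])
    if not terms:
        raise ValueError("no events")
    return float(np.mean(terms))


def auc_mannwhitney(scores, labels) -> float:
    """AUC via the rank-sum formula with midrank ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
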