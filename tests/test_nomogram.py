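"""Cox nomogram: coefficient recovery, point mapping, calibration and the
Hosmer-Lemeshow statistic."""

import numpy as np
import pandas as pd
import pytest

from longict.nomogram import (NomogramModel, build_covariate_table,
                              calibration_curve, covariate_points,
                              encode_recist, fit_nomogram, hosmer_lemeshow,
                              linear_predictor, nomo_score, points_to_lp)


def ph_data(rng, n=800, beta=1.0, extra=False):
    z = rng.normal(size=n)
    lp = beta * z
    t = rng.exponential(1.0, n) / np.exp(lp) * 14.0
    c = rng.exponential(1.0, n) * 30.0
    df = pd.DataFrame({"ldlm_score": z,
                       "os_months": np.minimum(t, c),
                       "event": (t < c).astype(int)})
    if extra:
        df["tdlm_score"] = rng.normal(size=n)
    return df


class TestFit:
    def test_recovers_unit_coefficient(self, rng):
        df = ph_data(rng, n=1000, beta=1.0)
        m = fit_nomogram(df, covariates=["ldlm_score"])
        assert m.coefficients["ldlm_score"] == pytest.approx(1.0, abs=0.15)

    def test_null_coefficient_stays_small(self, rng):
        ps = []
        for rep in range(10):
            df = ph_data(np.random.default_rng(rep), n=400, beta=0.0)
            m = fit_nomogram(df, covariates=["ldlm_score"])
            ps.append(abs(m.coefficients["ldlm_score"]))
        assert np.median(ps) < 0.1

    def test_dropping_tdlm_shortens_coefficient_vector(self, rng):
        df = ph_data(rng, extra=True)
        full = fit_nomogram(df, covariates=["ldlm_score", "tdlm_score"])
        reduced = fit_nomogram(df, covariates=["ldlm_score"])
        assert full.includes_tdlm and not reduced.includes_tdlm
        assert len(full.coefficients) == len(reduced.coefficients) + 1

    def test_missing_covariates_rejected(self, rng):
        df = ph_data(rng, extra=True)
        df.loc[3, "tdlm_score"] = np.nan
        with pytest.raises(ValueError, match="TDLM"):
            fit_nomogram(df, covariates=["ldlm_score", "tdlm_score"])


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(42)
    df = ph_data(rng, n=600, beta=1.0, extra=True)
    return df, fit_nomogram(df, covariates=["ldlm_score", "tdlm_score"])


class TestScoring:
    def test_linear_predictor_is_exact_dot_product(self, fitted):
        df, m = fitted
        lp = linear_predictor(m, df)
        hand = sum(m.coefficients[c] * df[c].to_numpy() for c in m.covariates)
        assert np.allclose(lp, hand, atol=1e-12)

    def test_patient_at_covariate_means_gets_baseline_survival(self, fitted):
        df, m = fitted
        mean_patient = pd.DataFrame([{c: m.covariate_means[c]
                                      for c in m.covariates}])
        out = nomo_score(m, mean_patient)
        assert out["surv_1yr"].iloc[0] == pytest.approx(m.baseline_survival_1yr)

    def test_higher_risk_covariate_lowers_predicted_survival(self, fitted):
        df, m = fitted
        lo = pd.DataFrame([{"ldlm_score": -1.0, "tdlm_score": 0.0}])
        hi = pd.DataFrame([{"ldlm_score": 1.0, "tdlm_score": 0.0}])
        assert nomo_score(m, hi)["surv_1yr"].iloc[0] < \
            nomo_score(m, lo)["surv_1yr"].iloc[0]

    def test_points_mapping_round_trips_to_lp(self, fitted):
        df, m = fitted
        total = covariate_points(m, df).sum(axis=1).to_numpy()
        assert np.allclose(points_to_lp(m, total), linear_predictor(m, df),
                           atol=1e-6)

    def test_widest_covariate_spans_hundred_points(self, fitted):
        df, m = fitted
        pts = covariate_points(m, df)
        spans = {}
        for c in m.covariates:
            lo, hi = m.covariate_ranges[c]
            grid = pd.DataFrame({c2: [m.covariate_means[c2]] * 2
                                 for c2 in m.covariates})
            grid[c] = [lo, hi]
            spans[c] = np.ptp(covariate_points(m, grid)[c].to_numpy())
        assert max(spans.values()) == pytest.approx(100.0)

    def test_serialization_round_trip(self, fitted):
        _, m = fitted
        clone = NomogramModel.from_dict(m.to_dict())
        assert clone.coefficients == m.coefficients
        assert clone.baseline_survival_1yr == m.baseline_survival_1yr


class TestRecistEncoding:
    def test_ordered_dummies(self):
        df = encode_recist(["CR", "PR", "SD", "PD"])
        assert df["recist_sd"].tolist() == [0.0, 0.0, 1.0, 0.0]
        assert df["recist_pd"].tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_covariate_table_assembly(self):
        df = build_covariate_table([0.2], ["PD"], ["M"], ["2+/FISH+"],
                                   tdlm_scores=[0.4])
        assert df.loc[0, "recist_pd"] == 1.0
        assert df.loc[0, "sex_male"] == 1.0
        assert df.loc[0, "her2_3plus"] == 0.0


class TestCalibration:
    def test_two_bin_hand_chi_square(self):
        # bin A: p=0.2 each, n=5, 2 events; bin B: p=0.6 each, n=5, 3 events
        p = np.array([0.2] * 5 + [0.6] * 5)
        y = np.array([1, 1, 0, 0, 0, 1, 1, 1, 0, 0])
        stat, df, pv = hosmer_lemeshow(p, y, g=2)
        ea, eb = 1.0, 3.0
        hand = (2 - ea) ** 2 / (ea * (1 - ea / 5)) + (3 - eb) ** 2 / (eb * (1 - eb / 5))
        assert stat == pytest.approx(hand, abs=1e-12)

    def test_flat_predictions_match_event_rate(self, rng):
        n = 200
        t = np.where(rng.uniform(size=n) < 0.5, 5.0, 20.0)
        e = np.ones(n, int)
        cal = calibration_curve(np.full(n, 0.5), t, e, g=5)
        assert cal.observed.mean() == pytest.approx(0.5, abs=0.1)

    def test_calibrated_predictions_pass_hl(self, rng):
        n = 400
        p_surv = rng.uniform(0.2, 0.9, n)
        died = rng.uniform(size=n) > p_surv
        t = np.where(died, 6.0 + rng.uniform(size=n), 20.0)
        cal = calibration_curve(p_surv, t, np.ones(n, int))
        assert cal.hl_p > 0.01
        assert np.corrcoef(cal.predicted, cal.observed)[0, 1] > 0.9

    def test_small_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            calibration_curve(rng.uniform(size=10), rng.uniform(size=10) * 20,
                              np.ones(10, int))


class TestFusionTendency:
    def test_fused_score_beats_best_single_covariate_in_majority(self):
        """When image and marker channels carry independent signal, the Cox
        fusion should rank at least as well as the best single channel in a
        majority of simulated cohorts."""
        from longict.metrics import c_index
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = 300
            z = rng.normal(size=n)
            ldlm = z + rng.normal(0, 0.8, n)
            tdlm = z + rng.normal(0, 0.8, n)
            t = rng.exponential(1.0, n) / np.exp(z) * 14.0
            c = rng.exponential(1.0, n) * 40.0
            df = pd.DataFrame({"ldlm_score": ldlm, "tdlm_score": tdlm,
                               "os_months": np.minimum(t, c),
                               "event": (t < c).astype(int)})
            tr, te = df.iloc[:200], df.iloc[200:]
            m = fit_nomogram(tr, covariates=["ldlm_score", "tdlm_score"])
            lp = linear_predictor(m, te)
            fused = c_index(lp, te.os_months, te.event).value
            single = max(c_index(te.ldlm_score, te.os_months, te.event).value,
                         c_index(te.tdlm_score, te.os_months, te.event).value)
            wins += fused >= single
        assert wins >= 11
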