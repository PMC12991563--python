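"""Conditional logistic regression: likelihood, fit, oracles, invariance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from tpt_adherence import MatchedData, analyze_all, conditional_loglik, fit_clogit
from tpt_adherence.stats import NonIdentifiableError


def _sets_frame(rng, n_sets=10, m=4, p_case=0.4, p_ctrl=0.15, extra_cov=True):
    rows = []
    for s in range(n_sets):
        for j in range(m + 1):
            rows.append(
                {
                    "set_id": s,
                    "is_case": j == 0,
                    "x": float(rng.binomial(1, p_case if j == 0 else p_ctrl)),
                    "z": float(rng.normal()) if extra_cov else 0.0,
                }
            )
    return pd.DataFrame(rows)


class TestConditionalLoglik:
    def test_uniform_softmax_at_beta_zero(self):
        rng = np.random.default_rng(1)
        df = _sets_frame(rng, n_sets=12, m=4)
        data = MatchedData.from_frame(df, ["x", "z"])
        ll, _, _ = conditional_loglik(data, np.zeros(2))
        assert ll == pytest.approx(-12 * np.log(5), rel=1e-12)

    def test_hand_evaluated_single_set(self):
        # one 1:2 set, one covariate: ll = b*x1 - log(e^{b x1}+e^{b x2}+e^{b x3})
        x = np.array([[1.0], [0.0], [2.0]])
        data = MatchedData(
            x=x, group=np.zeros(3), is_case=np.array([True, False, False]), terms=["x"]
        )
        beta = np.array([0.7])
        expected = 0.7 * 1.0 - np.log(np.exp(0.7) + 1.0 + np.exp(1.4))
        ll, _, _ = conditional_loglik(data, beta)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        df = _sets_frame(rng)
        data = MatchedData.from_frame(df, ["x", "z"])
        beta = np.array([0.8, -0.3])
        _, grad, hess = conditional_loglik(data, beta)
        eps = 1e-6
        for j in range(2):
            d = np.zeros(2)
            d[j] = eps
            ll_hi, g_hi, _ = conditional_loglik(data, beta + d)
            ll_lo, g_lo, _ = conditional_loglik(data, beta - d)
            assert grad[j] == pytest.approx((ll_hi - ll_lo) / (2 * eps), abs=1e-6)
            np.testing.assert_allclose(
                hess[:, j], (g_hi - g_lo) / (2 * eps), atol=1e-5
            )


class TestFitClogit:
    def test_discordant_pair_closed_form(self):
        # 1:1 pairs, binary exposure: conditional MLE of the OR equals the
        # ratio of discordant pair counts n10/n01 = 15/5 = 3.
        rows = []
        sid = 0
        for _ in range(15):  # case exposed, control not
            rows += [
                {"set_id": sid, "is_case": True, "x": 1.0},
                {"set_id": sid, "is_case": False, "x": 0.0},
            ]
            sid += 1
        for _ in range(5):  # control exposed, case not
            rows += [
                {"set_id": sid, "is_case": True, "x": 0.0},
                {"set_id": sid, "is_case": False, "x": 1.0},
            ]
            sid += 1
        for _ in range(7):  # concordant pairs: no information
            rows += [
                {"set_id": sid, "is_case": True, "x": 1.0},
                {"set_id": sid, "is_case": False, "x": 1.0},
            ]
            sid += 1
        df = pd.DataFrame(rows)
        res = fit_clogit(MatchedData.from_frame(df, ["x"]))
        assert res.converged
        assert res.odds_ratio[0] == pytest.approx(3.0, abs=1e-6)

    def test_matches_brute_force_maximiser(self):
        rng = np.random.default_rng(3)
        df = _sets_frame(rng, n_sets=10, m=4, extra_cov=False)
        data = MatchedData.from_frame(df, ["x"])
        res = fit_clogit(data)
        brute = minimize_scalar(
            lambda b: -conditional_loglik(data, np.array([b]))[0],
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.beta[0] == pytest.approx(brute.x, abs=1e-4)

    def test_grid_oracle_small_sets(self):
        # 1:2 sets, one covariate: dense grid search of the conditional
        # likelihood agrees with the Newton fit to 1e-3.
        rng = np.random.default_rng(4)
        df = _sets_frame(rng, n_sets=8, m=2, extra_cov=False)
        data = MatchedData.from_frame(df, ["x"])
        res = fit_clogit(data)
        grid = np.linspace(-8, 8, 160_001)
        lls = np.array([conditional_loglik(data, np.array([b]))[0] for b in grid[:: 400]])
        coarse = grid[::400][np.argmax(lls)]
        fine = np.linspace(coarse - 0.05, coarse + 0.05, 2001)
        lls = np.array([conditional_loglik(data, np.array([b]))[0] for b in fine])
        assert res.beta[0] == pytest.approx(fine[np.argmax(lls)], abs=1e-3)

    def test_constant_exposure_non_identifiable(self):
        df = pd.DataFrame(
            {
                "set_id": [0, 0, 1, 1],
                "is_case": [True, False, True, False],
                "x": [1.0, 1.0, 0.0, 0.0],
            }
        )
        with pytest.raises(NonIdentifiableError):
            fit_clogit(MatchedData.from_frame(df, ["x"]))

    def test_separation_flagged(self):
        # exposure perfectly predicts the case in every set
        rows = []
        for s in range(12):
            rows += [
                {"set_id": s, "is_case": True, "x": 1.0},
                {"set_id": s, "is_case": False, "x": 0.0},
                {"set_id": s, "is_case": False, "x": 0.0},
            ]
        res = fit_clogit(MatchedData.from_frame(pd.DataFrame(rows), ["x"]))
        assert not res.converged
        assert "separation" in res.message
        assert np.isnan(res.beta).all()

    def test_within_set_location_invariance(self):
        # adding a per-set constant to a covariate leaves estimates unchanged
        rng = np.random.default_rng(5)
        df = _sets_frame(rng, n_sets=12)
        data = MatchedData.from_frame(df, ["x", "z"])
        res = fit_clogit(data)
        shifted = df.copy()
        shifted["z"] = shifted["z"] + shifted["set_id"].map(
            {s: rng.normal(0, 10) for s in range(12)}
        )
        res2 = fit_clogit(MatchedData.from_frame(shifted, ["x", "z"]))
        np.testing.assert_allclose(res.beta, res2.beta, atol=1e-6)

    def test_wald_summary_consistency(self):
        rng = np.random.default_rng(6)
        df = _sets_frame(rng, n_sets=25)
        res = fit_clogit(MatchedData.from_frame(df, ["x", "z"]))
        frame = res.summary_frame()
        assert ((frame["ci_low"] <= frame["or"]) & (frame["or"] <= frame["ci_high"])).all()
        assert frame["p"].between(0, 1).all()

    def test_cross_check_against_statsmodels(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(7)
        df = _sets_frame(rng, n_sets=28)
        res = fit_clogit(MatchedData.from_frame(df, ["x", "z"]))
        sm_fit = ConditionalLogit(
            df["is_case"].astype(int), df[["x", "z"]], groups=df["set_id"]
        ).fit(disp=0)
        np.testing.assert_allclose(res.beta, sm_fit.params, atol=1e-4)
        np.testing.assert_allclose(res.se, sm_fit.bse, atol=1e-4)

    def test_malformed_sets_rejected(self):
        df = pd.DataFrame(
            {"set_id": [0, 0], "is_case": [True, True], "x": [1.0, 0.0]}
        )
        with pytest.raises(ValueError, match="expected exactly 1"):
            MatchedData.from_frame(df, ["x"])


class TestAnalyzeAll:
    def _calls_and_participants(self, rng, p_case=0.5, p_ctrl=0.15):
        parts, calls = [], []
        for s in range(20):
            for j in range(5):
                pid = f"P{s}_{j}"
                parts.append(
                    {
                        "participant_id": pid,
                        "set_id": f"S{s}",
                        "group": "case" if j == 0 else "control",
                        "sex": "male" if s % 2 else "female",
                        "weight_kg": 50 + rng.normal(0, 3),
                    }
                )
                for week in (2, 4, 8):
                    calls.append(
                        {
                            "participant_id": pid,
                            "drug": "pyrazinamide",
                            "week": week,
                            "method": "lloq",
                            "status": "non-adherent"
                            if rng.random() < (p_case if j == 0 else p_ctrl)
                            else "not-confirmed",
                        }
                    )
        return pd.DataFrame(calls), pd.DataFrame(parts)

    def test_one_fit_per_cell_and_isolation(self):
        rng = np.random.default_rng(8)
        calls, parts = self._calls_and_participants(rng)
        # make week 8 fully uninformative: everyone not-confirmed
        calls.loc[calls["week"] == 8, "status"] = "not-confirmed"
        res = analyze_all(calls, parts)
        cells = res.groupby("week")
        for week in (2, 4):
            sub = res[(res["week"] == week) & (res["term"] == "non_adherent")]
            assert len(sub) == 1
            assert sub["status"].iloc[0] in ("converged",) or "separation" in sub["status"].iloc[0]
        w8 = res[res["week"] == 8]
        assert (w8["status"].str.contains("non-identifiable")).all()

    def test_exposure_effect_recovered_on_average(self):
        # null scenario: equal probabilities -> mean log-OR near 0
        rng = np.random.default_rng(9)
        betas = []
        for _ in range(30):
            calls, parts = self._calls_and_participants(rng, p_case=0.3, p_ctrl=0.3)
            res = analyze_all(calls, parts, weeks=(2,))
            row = res[(res["term"] == "non_adherent") & (res["status"] == "converged")]
            if len(row):
                betas.append(row["estimate"].iloc[0])
        betas = np.array(betas)
        assert abs(betas.mean()) < 3 * betas.std(ddof=1) / np.sqrt(len(betas))

    def test_sex_dropped_when_exactly_matched(self):
        rng = np.random.default_rng(10)
        calls, parts = self._calls_and_participants(rng)
        res = analyze_all(calls, parts, weeks=(2,))
        assert "sex_male" not in set(res["term"].dropna())


class TestScoreTest:
    def test_agrees_with_wald_on_well_powered_problem(self):
        from tpt_adherence.stats import score_test

        rng = np.random.default_rng(11)
        df = _sets_frame(rng, n_sets=400, m=4, p_case=0.5, p_ctrl=0.25)
        data = MatchedData.from_frame(df, ["x", "z"])
        res = fit_clogit(data)
        p_score = score_test(data, 0)
        # both tests target the same null; at this size they nearly coincide
        assert p_score == pytest.approx(res.p_values[0], abs=0.01)

    def test_defined_under_separation(self):
        from tpt_adherence.stats import score_test

        rows = []
        for s in range(12):
            rows += [
                {"set_id": s, "is_case": True, "x": 1.0},
                {"set_id": s, "is_case": False, "x": 0.0},
                {"set_id": s, "is_case": False, "x": 0.0},
            ]
        data = MatchedData.from_frame(pd.DataFrame(rows), ["x"])
        p = score_test(data, 0)
        assert 0.0 <= p <= 0.05  # exposure perfectly predicts the case
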