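import numpy as np
import pandas as pd
import pytest

from actbenefit import (balance_table, fit_propensity, match_nearest,
                        select_ps_covariates)
from actbenefit.psmatch import _quotas, age_category


def logistic_frame(seed, n=500, beta_x=0.0):
    """Treatment depends on x with log-odds beta_x; z is pure noise."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.choice(["u", "v"], size=n)
    logit = -0.2 + beta_x * x
    act = rng.random(n) < 1 / (1 + np.exp(-logit))
    return pd.DataFrame({
        "sample_id": [f"s{i:04d}" for i in range(n)],
        "act": act.astype(int),
        "xcat": np.where(x > 0, "hi", "lo"),
        "z": z,
        "age_years": np.clip(np.round(60 + 8 * x), 35, 90),
    })


class TestCovariateSelection:
    def test_noise_covariate_usually_excluded(self):
        excluded = sum(
            "z" not in select_ps_covariates(logistic_frame(seed), ["z"])
            for seed in range(40))
        assert excluded >= 36

    def test_strong_covariate_usually_included(self):
        included = sum(
            "xcat" in select_ps_covariates(logistic_frame(seed, beta_x=1.0),
                                           ["xcat"])
            for seed in range(40))
        assert included >= 38

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="empty"):
            select_ps_covariates(logistic_frame(0), [])


class TestPropensity:
    def test_coefficient_recovery(self):
        # binary covariate with known log-odds 1.0, large n
        import statsmodels.api as sm

        for seed in range(5):
            frame = logistic_frame(seed, n=2000, beta_x=1.0)
            ps = fit_propensity(frame, ["xcat"])
            design = (frame["xcat"] == "hi").astype(float)
            res = sm.Logit(frame["act"], sm.add_constant(design)).fit(disp=0)
            # implied coefficient on the dichotomized covariate: E[x|hi]-E[x|lo]
            # under N(0,1) is 2*phi(0)=1.596, so expect ~1.6 less shrinkage
            assert res.params.iloc[1] == pytest.approx(1.6, abs=0.35)
            assert ps.between(0, 1, inclusive="neither").all()

    def test_row_permutation_equivariance(self):
        frame = logistic_frame(3, n=400, beta_x=0.8)
        ps1 = fit_propensity(frame, ["xcat", "age_years"])
        shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        ps2 = fit_propensity(shuffled, ["xcat", "age_years"])
        np.testing.assert_allclose(ps1.sort_index().to_numpy(),
                                   ps2.sort_index().to_numpy(), atol=1e-8)

    def test_constant_covariate_errors(self):
        frame = logistic_frame(0)
        frame["xcat"] = "hi"
        with pytest.raises(ValueError):
            fit_propensity(frame, ["xcat"])


class TestMatching:
    def test_quota_sequence_alternates_for_three_halves(self):
        q = _quotas(29, 1.5)
        assert sum(q) == 44                       # ceil(1.5 * 29)
        assert set(q) == {1, 2}
        assert q[0] == 2

    def test_identical_ps_ratio_one_matches_all(self):
        ids = [f"t{i}" for i in range(5)] + [f"c{i}" for i in range(5)]
        ps = pd.Series(0.5, index=ids)
        treated = pd.Series([True] * 5 + [False] * 5, index=ids)
        res = match_nearest(ps, treated, ratio=1.0, caliper=1.0)
        assert sorted(res.matched_treated) == [f"t{i}" for i in range(5)]
        assert len(res.matched_controls) == 5
        # deterministic assignment by id order
        res2 = match_nearest(ps, treated, ratio=1.0, caliper=1.0)
        assert res.pairing == res2.pairing

    def test_ratio_three_halves_total_controls(self):
        rng = np.random.default_rng(0)
        n_t, n_c = 29, 80
        ids = [f"t{i:02d}" for i in range(n_t)] + [f"c{i:02d}" for i in range(n_c)]
        ps = pd.Series(np.concatenate([rng.uniform(0.4, 0.6, n_t),
                                       rng.uniform(0.35, 0.65, n_c)]), index=ids)
        treated = pd.Series([True] * n_t + [False] * n_c, index=ids)
        res = match_nearest(ps, treated, ratio=1.5, caliper=5.0)
        assert len(res.matched_treated) == 29
        assert len(res.matched_controls) == 44
        assert len(set(res.matched_controls)) == 44   # without replacement

    def test_treated_outside_support_unmatched(self):
        ids = ["t0", "t1", "c0", "c1"]
        ps = pd.Series([0.99, 0.5, 0.5, 0.49], index=ids)
        treated = pd.Series([True, True, False, False], index=ids)
        res = match_nearest(ps, treated, ratio=1.0, caliper=0.5)
        assert res.unmatched_treated == ["t0"]
        assert "t1" in res.matched_treated

    def test_empty_arm_errors(self):
        ps = pd.Series([0.5, 0.6], index=["a", "b"])
        with pytest.raises(ValueError, match="both arms"):
            match_nearest(ps, pd.Series([True, True], index=["a", "b"]))


class TestBalance:
    def test_perfectly_balanced_match_near_one(self):
        # after matching, arms have identical covariate distributions
        rows = []
        for arm, prefix in ((1, "t"), (0, "c")):
            for i in range(30):
                rows.append({"sample_id": f"{prefix}{i:02d}", "act": arm,
                             "sex": "male" if i % 2 else "female",
                             "age_years": 55 + (i % 4) * 8})
        frame = pd.DataFrame(rows)
        ps = pd.Series(0.5, index=frame["sample_id"])
        treated = pd.Series(frame["act"].astype(bool).to_numpy(),
                            index=frame["sample_id"])
        res = match_nearest(ps, treated, ratio=1.0, caliper=1.0)
        table = balance_table(frame, res, ["sex", "age_years"])
        assert (table["p_after"] > 0.9).all()

    def test_matching_reduces_standardized_differences(self):
        """On confounded cohorts, matching must not worsen balance."""
        from actbenefit import SyntheticConfig, generate_cohort

        def smd(frame, col):
            a = frame.loc[frame["act"] == 1, col].astype(float)
            b = frame.loc[frame["act"] == 0, col].astype(float)
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return 0.0 if pooled == 0 else abs(a.mean() - b.mean()) / pooled

        worst_increase = 0.0
        age_changes = []
        for seed in range(25):
            ds, _ = generate_cohort(SyntheticConfig(n_patients=300), seed)
            frame = pd.DataFrame([{
                "sample_id": r.sample_id, "act": int(r.act),
                "stage3": 1.0 if r.tnm_stage == "III" else 0.0,
                "age_years": r.age_years, "n_stage": r.n_stage,
                "tnm_stage": r.tnm_stage} for r in ds.clinical])
            # n_stage subsumes tnm_stage in these cohorts (N0 <=> stage II)
            ps = fit_propensity(frame, ["n_stage"])
            treated = frame.set_index("sample_id").loc[ps.index, "act"] == 1
            res = match_nearest(ps, treated, ratio=1.0)
            if not res.matched_treated:
                continue
            keep = list(res.matched_treated) + list(res.matched_controls)
            after = frame[frame["sample_id"].isin(keep)]
            # modeled confounder: balance must never degrade
            worst_increase = max(worst_increase,
                                 smd(after, "stage3") - smd(frame, "stage3"))
            # unmodeled independent covariate: no systematic degradation
            # (per-seed SMD is pure sampling noise at the matched n)
            age_changes.append(smd(after, "age_years") - smd(frame, "age_years"))
        assert worst_increase <= 0.05
        assert abs(np.mean(age_changes)) <= 0.05


def test_age_categories():
    assert [age_category(a) for a in (30, 55, 64.9, 65, 80)] == \
        ["<55", "55-65", "55-65", "65-75", ">75"]
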