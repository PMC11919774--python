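import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gazesal import stats as gs


def two_group_frame(rng, n1, n2, shift=0.0, sd=1.0):
    return pd.DataFrame({
        "score": np.r_[rng.normal(0, sd, n1), rng.normal(shift, sd, n2)],
        "diagnosis": ["HC"] * n1 + ["SZ"] * n2,
        "site": "S1",
        "age": rng.normal(35, 10, n1 + n2),
        "sex": rng.choice(["M", "F"], n1 + n2),
    })


def closed_form_hedges_g(a, b):
    n1, n2 = len(a), len(b)
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    d = (b.mean() - a.mean()) / sp
    J = 1 - 3 / (4 * (n1 + n2 - 2) - 1)
    var = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2))
    return J * d, J * np.sqrt(var)


class TestUnbiasedD:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_hedges_g_without_covariates(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(5, 30)), int(rng.integers(5, 30))
        frame = two_group_frame(rng, n1, n2, shift=rng.normal(0, 1))
        rec = gs.unbiased_d(frame, "score", covariates=())
        g, se = closed_form_hedges_g(frame["score"][:n1].to_numpy(),
                                     frame["score"][n1:].to_numpy())
        assert rec.d == pytest.approx(g, abs=1e-10)
        assert rec.se == pytest.approx(se, abs=1e-10)

    def test_hedges_correction_value(self):
        assert gs.hedges_correction(38) == pytest.approx(1 - 3 / 151)

    def test_unit_shift_recovers_d_of_one(self):
        rng = np.random.default_rng(1)
        frame = two_group_frame(rng, 20000, 20000, shift=1.0)
        rec = gs.unbiased_d(frame, "score")
        assert rec.d == pytest.approx(1.0, abs=0.05)

    def test_null_distribution_is_centred(self):
        rng = np.random.default_rng(2)
        ds = []
        for _ in range(60):
            rec = gs.unbiased_d(two_group_frame(rng, 50, 50), "score")
            ds.append(rec.d)
        ds = np.array(ds)
        assert abs(ds.mean()) < 0.1
        # |d| below ~2 null SEs in at least 90% of replicates
        assert (np.abs(ds) < 0.4).mean() >= 0.90

    def test_single_sex_site_drops_covariate(self):
        rng = np.random.default_rng(3)
        frame = two_group_frame(rng, 30, 30)
        frame["sex"] = "M"
        with pytest.warns(UserWarning, match="sex"):
            rec = gs.unbiased_d(frame, "score")
        assert np.isfinite(rec.d)

    def test_tiny_groups_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            gs.unbiased_d(two_group_frame(rng, 1, 10), "score")


class TestMeta:
    def test_single_record_identity(self):
        rec = gs.EffectSizeRecord("A", "full", 0.7, 0.1, 50, 50)
        meta = gs.fixed_effects_meta([rec])
        assert meta.d_overall == pytest.approx(0.7)
        assert meta.se_overall == pytest.approx(0.1)
        assert gs.forest_table(meta).iloc[0]["weight_pct"] == pytest.approx(100.0)

    def test_two_equal_records_halve_the_variance(self):
        recs = [gs.EffectSizeRecord(s, "full", 0.5, 0.1, 50, 50) for s in "AB"]
        meta = gs.fixed_effects_meta(recs)
        assert meta.d_overall == pytest.approx(0.5)
        assert meta.se_overall == pytest.approx(0.1 / np.sqrt(2))

    def test_inverse_variance_worked_case(self):
        recs = [gs.EffectSizeRecord("A", "full", 0.2, 0.1, 50, 50),
                gs.EffectSizeRecord("B", "full", 0.8, 0.2, 50, 50)]
        meta = gs.fixed_effects_meta(recs)
        assert meta.d_overall == pytest.approx(0.32, abs=1e-12)
        assert meta.se_overall == pytest.approx(np.sqrt(1 / 125), abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(d=st.floats(-2, 2), se=st.floats(0.01, 1.0), k=st.integers(1, 8))
    def test_pooling_identical_records(self, d, se, k):
        recs = [gs.EffectSizeRecord(f"S{i}", "full", d, se, 10, 10)
                for i in range(k)]
        meta = gs.fixed_effects_meta(recs)
        assert meta.d_overall == pytest.approx(d, rel=1e-9, abs=1e-9)
        assert meta.se_overall == pytest.approx(se / np.sqrt(k), rel=1e-9)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            gs.EffectSizeRecord("A", "full", 0.5, 0.0, 10, 10)
        with pytest.raises(ValueError):
            gs.fixed_effects_meta([])


class TestForest:
    def test_confidence_interval_formula(self):
        rec = gs.EffectSizeRecord("pooled-like", "full", 0.78, 0.08, 100, 100)
        lo, hi = rec.ci
        assert lo == pytest.approx(0.6232, abs=1e-3)
        assert hi == pytest.approx(0.9368, abs=1e-3)

    def test_weights_sum_to_100(self):
        recs = [gs.EffectSizeRecord(s, "full", 0.3 + i / 10, 0.05 + i / 50, 40, 40)
                for i, s in enumerate("ABCD")]
        table = gs.forest_table(gs.fixed_effects_meta(recs))
        assert table[table["site"] != "pooled"]["weight_pct"].sum() == \
            pytest.approx(100.0)


def five_group_frame(rng, n_per=40, effects=None, n_sites=2):
    effects = effects or {}
    groups = ["HC", "SZ", "BD", "MDD", "ASD"]
    rows = []
    for g in groups:
        for _ in range(n_per):
            rows.append({
                "diagnosis": g,
                "age": rng.normal(35, 10),
                "sex": rng.choice(["M", "F"]),
                "site": f"S{rng.integers(n_sites) + 1}",
                "score_full": effects.get(g, 0.0) + rng.normal(),
            })
    return pd.DataFrame(rows)


class TestGlm:
    def test_bonferroni_arithmetic(self):
        assert gs.bonferroni(0.004, 10) == pytest.approx(0.04, abs=1e-15)
        assert gs.bonferroni(0.01, 8) == pytest.approx(0.08, abs=1e-15)
        assert gs.bonferroni(0.2, 10) == 1.0

    def test_strong_effects_are_detected_in_order(self):
        rng = np.random.default_rng(5)
        effects = {"HC": 0.0, "SZ": 2.0, "BD": 1.4, "MDD": 0.9, "ASD": 0.3}
        res = gs.cross_disorder_glm(five_group_frame(rng, 80, effects),
                                    "score_full")
        assert res.p_diagnosis < 1e-10
        emm = res.emmeans.set_index("diagnosis")["emmean"]
        assert emm["SZ"] > emm["BD"] > emm["MDD"] > emm["ASD"] > emm["HC"]
        assert len(res.pairwise) == 10
        assert (res.pairwise["p_bonf"] >= res.pairwise["p_raw"] - 1e-15).all()

    def test_null_main_effect_p_is_uniform(self):
        """Under identical groups the diagnosis F-test p-value is uniform
        across replicates (KS test)."""
        rng = np.random.default_rng(6)
        ps = [gs.cross_disorder_glm(five_group_frame(rng, 25), "score_full").p_diagnosis
              for _ in range(120)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_single_site_glm_agrees_with_unbiased_d(self):
        """With one site and two groups the standardized GLM contrast and
        the covariate-adjusted d agree in sign and within 5%."""
        rng = np.random.default_rng(7)
        frame = two_group_frame(rng, 150, 150, shift=0.6)
        frame = frame.rename(columns={"score": "score_full"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = gs.cross_disorder_glm(frame, "score_full")
        rec = gs.unbiased_d(frame, "score_full")
        pair = res.pairwise.iloc[0]
        contrast_std = -pair["estimate"] / res.residual_sd  # SZ - HC
        assert np.sign(contrast_std) == np.sign(rec.d)
        assert abs(contrast_std - rec.d) / abs(rec.d) < 0.05

    def test_single_group_rejected(self):
        rng = np.random.default_rng(8)
        frame = five_group_frame(rng, 10)
        with pytest.raises(ValueError):
            gs.cross_disorder_glm(frame[frame["diagnosis"] == "HC"], "score_full")


class TestCorrelationScreen:
    def test_perfect_correlation(self, rng):
        frame = pd.DataFrame({"score_full": np.arange(20.0)})
        frame["panss"] = frame["score_full"]
        out = gs.correlation_screen(frame, ["score_full"], ["panss"])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_uses_screen_size(self, rng):
        frame = pd.DataFrame({
            f"score_{c}": rng.normal(size=30) for c in "abcd"
        } | {"panss": rng.normal(size=30), "dose": rng.normal(size=30)})
        out = gs.correlation_screen(frame, [f"score_{c}" for c in "abcd"],
                                    ["panss", "dose"])
        assert len(out) == 8
        ok = out["p_raw"].notna()
        np.testing.assert_allclose(out.loc[ok, "p_bonf"],
                                   np.minimum(1, out.loc[ok, "p_raw"] * 8))

    def test_zero_variance_column_warns(self, rng):
        frame = pd.DataFrame({"score_full": rng.normal(size=10),
                              "panss": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = gs.correlation_screen(frame, ["score_full"], ["panss"])
        assert np.isnan(out["r"].iloc[0])

    def test_null_screen_rejects_at_alpha(self):
        rng = np.random.default_rng(9)
        rejections = []
        for _ in range(300):
            frame = pd.DataFrame({"score_full": rng.normal(size=40),
                                  "panss": rng.normal(size=40)})
            out = gs.correlation_screen(frame, ["score_full"], ["panss"])
            rejections.append(out["p_raw"].iloc[0] < 0.05)
        assert 0.01 < np.mean(rejections) < 0.10
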