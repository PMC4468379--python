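import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrtzf.expression import (
    angular_transform,
    anova_posthoc,
    ddct,
    germination_test,
    log2_transform,
    one_way_anova,
    recovery_bias,
)
from rrtzf.synth import generate_ct_table, generate_germination


def make_table(rows):
    return pd.DataFrame(rows, columns=["gene", "group", "bio_rep", "tech_rep", "ct"])


class TestDdct:
    def test_equal_cts_give_ratio_one(self):
        rows = [(g, grp, b, t, 20.0)
                for g in ("tgt", "ref") for grp in ("cal", "trt")
                for b in (1, 2) for t in (1, 2)]
        rel = ddct(make_table(rows), "tgt", "ref", "cal")
        assert np.allclose(rel.per_replicate["ratio"], 1.0)
        assert np.allclose(rel.per_replicate["log2_ratio"], 0.0)

    def test_one_cycle_lower_doubles(self):
        rows = []
        for grp, ct in (("cal", 20.0), ("trt", 19.0)):
            for b in (1, 2):
                rows += [("tgt", grp, b, 1, ct), ("ref", grp, b, 1, 15.0)]
        rel = ddct(make_table(rows), "tgt", "ref", "cal")
        trt = rel.per_replicate[rel.per_replicate["group"] == "trt"]
        assert np.allclose(trt["ratio"], 2.0)

    def test_technical_replicates_averaged_first(self):
        rows = [("tgt", "cal", 1, 1, 19.0), ("tgt", "cal", 1, 2, 21.0),
                ("ref", "cal", 1, 1, 15.0)]
        rel = ddct(make_table(rows), "tgt", "ref", "cal")
        assert rel.per_replicate["dct"].iloc[0] == pytest.approx(5.0)

    def test_shift_invariance(self):
        """Adding a constant to every CT within a (group, bio-rep) cancels
        in the reference subtraction."""
        base = [("tgt", "cal", 1, 1, 20.0), ("ref", "cal", 1, 1, 15.0),
                ("tgt", "trt", 1, 1, 18.0), ("ref", "trt", 1, 1, 15.0)]
        shifted = [(g, grp, b, t, ct + (3.7 if grp == "trt" else 0.0))
                   for g, grp, b, t, ct in base]
        r1 = ddct(make_table(base), "tgt", "ref", "cal")
        r2 = ddct(make_table(shifted), "tgt", "ref", "cal")
        assert np.allclose(r1.per_replicate["ratio"], r2.per_replicate["ratio"])

    def test_log2_ratio_is_negative_ddct(self):
        table = generate_ct_table({"cal": 0.0, "t": 1.3}, calibrator_group="cal",
                                  seed=5)
        rel = ddct(table, "target", "ref", "cal")
        assert np.allclose(rel.per_replicate["log2_ratio"],
                           -rel.per_replicate["ddct"])

    def test_calibrator_mean_zero_without_noise(self):
        table = generate_ct_table({"cal": 0.0, "t": 2.0}, calibrator_group="cal",
                                  noise_sd=0.0, seed=1)
        rel = ddct(table, "target", "ref", "cal")
        cal = rel.per_group[rel.per_group["group"] == "cal"]
        assert cal["mean_log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        t = rel.per_group[rel.per_group["group"] == "t"]
        assert t["mean_log2_ratio"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_missing_reference_names_cell(self):
        rows = [("tgt", "cal", 1, 1, 20.0), ("ref", "cal", 1, 1, 15.0),
                ("tgt", "trt", 2, 1, 18.0)]
        with pytest.raises(ValueError, match=r"\(trt, bio_rep=2\)"):
            ddct(make_table(rows), "tgt", "ref", "cal")

    def test_planted_fold_change_bias_small(self):
        """Across the ±2 log2 grid, mean recovery error over replicate
        simulations stays below 0.1 (noise sd 0.15, n=3)."""
        planted = {"cal": 0.0, "g-2": -2.0, "g-1": -1.0, "g0": 0.0,
                   "g1": 1.0, "g2": 2.0}

        def simulate(seed):
            return generate_ct_table(planted, calibrator_group="cal",
                                     noise_sd=0.15, n_bio=3, seed=seed)

        def estimate(table):
            rel = ddct(table, "target", "ref", "cal")
            return dict(zip(rel.per_group["group"],
                            rel.per_group["mean_log2_ratio"]))

        bias = recovery_bias(planted, simulate, estimate, n_sims=40, seed=123)
        assert max(abs(b) for b in bias.values()) < 0.1


class TestAnovaPosthoc:
    def test_identical_groups_p_one(self):
        groups = np.repeat(["a", "b", "c"], 3)
        vals = np.tile([0.99, 1.0, 1.01], 3)  # identical group distributions
        res = anova_posthoc(vals, groups, method="bonferroni")
        assert all(r.p_value == 1.0 for r in res)

    def test_large_separation_significant(self):
        """Two groups 10 pooled SDs apart, n=3 → p < 0.01."""
        a = np.array([0.0, 0.1, -0.1])
        b = a + 10 * a.std(ddof=1)
        res = anova_posthoc(np.r_[a, b], np.repeat(["a", "b"], 3),
                            method="bonferroni")
        assert res[0].p_value < 0.01 and res[0].significant_01

    def test_bonferroni_equals_k_times_raw(self):
        """Against the oracle: unadjusted pooled-variance t-test × number
        of contrasts."""
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 12)
        groups = np.repeat(["a", "b", "c", "d"], 3)
        res = anova_posthoc(vals, groups, method="bonferroni")
        k = len(res)
        assert k == 6
        samples = {g: vals[groups == g] for g in "abcd"}
        n_total, ngr = 12, 4
        mse = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / (n_total - ngr)
        for r in res:
            a, b = r.contrast
            t = (samples[a].mean() - samples[b].mean()) / np.sqrt(mse * (2 / 3))
            raw = 2 * stats.t.sf(abs(t), n_total - ngr)
            assert r.p_value == pytest.approx(min(1.0, raw * k))

    def test_dunnett_matches_scipy_directly(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 15)
        vals[10:] += 2.0
        groups = np.repeat(["ctrl", "t1", "t2"], 5)
        res = anova_posthoc(vals, groups, method="dunnett", control_group="ctrl",
                            seed=42)
        ref = stats.dunnett(vals[5:10], vals[10:], control=vals[:5], rng=42)
        assert [r.p_value for r in res] == pytest.approx(list(ref.pvalue))
        assert [r.contrast for r in res] == [("t1", "ctrl"), ("t2", "ctrl")]

    def test_dunnett_requires_control(self):
        with pytest.raises(ValueError, match="control"):
            anova_posthoc(np.arange(6.0), np.repeat(["a", "b"], 3), method="dunnett")

    def test_single_value_groups_refused(self):
        with pytest.raises(ValueError, match="at least 2 values"):
            anova_posthoc(np.array([1.0, 2.0]), np.array(["a", "b"]))

    def test_one_way_anova_detects_group_trend(self):
        f, p = one_way_anova(np.arange(9.0), np.repeat(["a", "b", "c"], 3))
        assert p < 0.05

    def test_dunnett_type_one_error_calibrated(self):
        """FWER of the Dunnett procedure near nominal 0.05 under the null
        (500 sims here; acceptance runs 1,000)."""
        rng = np.random.default_rng(7)
        rej = 0
        nsim = 500
        for _ in range(nsim):
            groups = [rng.normal(0, 1, 5) for _ in range(4)]
            res = stats.dunnett(*groups[1:], control=groups[0])
            rej += bool((res.pvalue < 0.05).any())
        assert 0.03 <= rej / nsim <= 0.07


class TestTransforms:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4),
    ])
    def test_angular_closed_form(self, p, expected):
        assert angular_transform(p) == pytest.approx(expected)

    def test_angular_rejects_outside_unit(self):
        with pytest.raises(ValueError):
            angular_transform(1.2)

    def test_log2(self):
        out = log2_transform([1.0, 2.0, 0.25])
        assert list(out) == [0.0, 1.0, -2.0]
        with pytest.raises(ValueError):
            log2_transform([0.0])


class TestGermination:
    def test_planted_difference_detected(self):
        table = generate_germination(
            {("Col0", "NaCl"): 0.6, ("ox", "NaCl"): 0.2, ("kd", "NaCl"): 0.9},
            total_seeds=75, n_rep=3, seed=4)
        res = germination_test(table, "NaCl", "Col0", method="dunnett")
        assert {r.contrast[0] for r in res} == {"ox", "kd"}
        assert all(r.p_value < 0.05 for r in res)

    def test_fixture_file_pipeline(self, data_dir):
        from rrtzf.io import read_germination_table
        table = read_germination_table(data_dir / "germination_example.tsv")
        res = germination_test(table, "NaCl", "Col0", method="bonferroni")
        assert len(res) == 3
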