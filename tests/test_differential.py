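"""Baseline OLS, longitudinal mixed model, significance and overlap logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import glycopipe as gp
from glycopipe.differential import SummaryGroupStats, volcano_table


def _cohort(n_dec=8, n_non=14, seed=0, two_visits=True):
    cfg = gp.SimulationConfig(n_decliners=n_dec, n_nondecliners=n_non)
    meta = gp.simulate_cohort(cfg, seed)
    return meta if two_visits else meta[meta["timepoint"] == "T1"].copy()


def _matrix_from_array(y, meta, prefix="f"):
    samples = meta["sample_id"].astype(str).tolist()
    vals = pd.DataFrame(y, columns=samples,
                        index=[f"{prefix}{i}" for i in range(y.shape[0])])
    return gp.IntensityMatrix(vals, vals.notna())


class TestBaselineDifferential:
    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        meta = _cohort(seed=3)
        t1 = meta[meta["timepoint"] == "T1"]
        rng = np.random.default_rng(3)
        y = rng.normal(20, 1, (5, len(t1)))
        m = _matrix_from_array(y, t1)
        res = gp.baseline_differential(m, meta)
        g = (t1["group"] == "decliner").to_numpy(float)
        X = sm.add_constant(np.column_stack([g, t1["mean_hba1c"].to_numpy()]))
        for i in range(5):
            fit = sm.OLS(y[i], X).fit()
            assert res["log2fc"].iloc[i] == pytest.approx(fit.params[1], abs=1e-10)
            assert res["p"].iloc[i] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_null_type_one_error_near_nominal(self):
        meta = _cohort(seed=7)
        t1 = meta[meta["timepoint"] == "T1"]
        rng = np.random.default_rng(7)
        y = rng.normal(20, 1, (2000, len(t1)))
        res = gp.baseline_differential(_matrix_from_array(y, t1), meta)
        rate = (res["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07

    def test_recovers_injected_effect(self):
        meta = _cohort(seed=11)
        t1 = meta[meta["timepoint"] == "T1"].reset_index(drop=True)
        g = (t1["group"] == "decliner").to_numpy(float)
        rng = np.random.default_rng(11)
        n_rep = 200
        y = 20 + 2.0 * g[None, :] + rng.normal(0, 0.3, (n_rep, len(t1)))
        res = gp.baseline_differential(_matrix_from_array(y, t1), meta)
        assert res["log2fc"].mean() == pytest.approx(2.0, abs=0.3)
        power = (res["p"] < 0.05).mean()
        assert power > 0.9

    def test_constant_covariate_dropped_with_warning(self):
        meta = _cohort(seed=5)
        meta["mean_hba1c"] = 6.5
        t1 = meta[meta["timepoint"] == "T1"]
        rng = np.random.default_rng(5)
        y = rng.normal(20, 1, (3, len(t1)))
        m = _matrix_from_array(y, t1)
        with pytest.warns(UserWarning, match="constant"):
            adj = gp.baseline_differential(m, meta)
        plain = gp.baseline_differential(m, meta, covariates=())
        assert np.allclose(adj["log2fc"], plain["log2fc"])

    def test_rank_deficient_design_flags_not_crashes(self):
        meta = _cohort(seed=6)
        # covariate perfectly collinear with the group indicator
        meta["mean_hba1c"] = np.where(meta["group"] == "decliner", 7.0, 6.0)
        t1 = meta[meta["timepoint"] == "T1"]
        y = np.random.default_rng(6).normal(20, 1, (3, len(t1)))
        res = gp.baseline_differential(_matrix_from_array(y, t1), meta)
        assert (res["error"] == "rank_deficient").all()
        assert res["p"].isna().all()


class TestRateOfChange:
    def _planted(self, delta, seed, n_feat=5, subject_sd=0.5, residual_sd=0.3):
        meta = _cohort(seed=seed)
        g = (meta["group"] == "decliner").to_numpy(float)
        t2 = (meta["timepoint"] == "T2").to_numpy(float)
        subj = meta["subject_id"].to_numpy()
        _, sidx = np.unique(subj, return_inverse=True)
        rng = np.random.default_rng(seed)
        b = rng.normal(0, subject_sd, (n_feat, sidx.max() + 1))
        y = (
            20
            + b[:, sidx]
            + delta * (g * t2)[None, :]
            + rng.normal(0, residual_sd, (n_feat, len(meta)))
        )
        return _matrix_from_array(y, meta), meta

    def test_diff_in_diff_oracle_noise_free(self):
        m, meta = self._planted(1.5, seed=21, subject_sd=0.0, residual_sd=0.0)
        res = gp.rate_of_change_lmm(m, meta, engine="paired")
        assert np.allclose(res["effect"], 1.5, atol=1e-6)
        # explicit hand oracle: DiD of group x time cell means
        mm = meta.set_index("sample_id")
        for key in m.values.index:
            cell = {}
            for grp in ("decliner", "non-decliner"):
                for tp in ("T1", "T2"):
                    sel = mm[(mm["group"] == grp) & (mm["timepoint"] == tp)].index
                    cell[(grp, tp)] = m.values.loc[key, sel].mean()
            did = (cell[("decliner", "T2")] - cell[("decliner", "T1")]) - (
                cell[("non-decliner", "T2")] - cell[("non-decliner", "T1")]
            )
            assert res.loc[key, "effect"] == pytest.approx(did, abs=1e-6)

    def test_paired_and_mixedlm_estimates_agree(self):
        m, meta = self._planted(1.0, seed=22, n_feat=6)
        a = gp.rate_of_change_lmm(m, meta, engine="paired")
        b = gp.rate_of_change_lmm(m, meta, engine="mixedlm")
        assert np.allclose(a["effect"], b["effect"], atol=1e-6)
        assert np.allclose(a["p"], b["p"], rtol=0.05, atol=1e-4)

    def test_recovery_of_planted_interaction(self):
        ests = []
        for rep in range(40):
            m, meta = self._planted(1.5, seed=300 + rep, n_feat=2)
            res = gp.rate_of_change_lmm(m, meta)
            ests.extend(res["effect"].tolist())
        assert np.mean(ests) == pytest.approx(1.5, abs=0.2)

    def test_null_p_values_approximately_uniform(self):
        m, meta = self._planted(0.0, seed=23, n_feat=1000)
        res = gp.rate_of_change_lmm(m, meta)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01
        assert res["effect"].mean() == pytest.approx(0.0, abs=0.05)

    def test_t1_only_input_errors(self):
        m, meta = self._planted(1.0, seed=24)
        t1 = meta[meta["timepoint"] == "T1"]
        m_t1 = gp.IntensityMatrix(
            m.values[t1["sample_id"].tolist()], m.observed[t1["sample_id"].tolist()]
        )
        with pytest.raises(ValueError, match="T1 and T2|both"):
            gp.rate_of_change_lmm(m_t1, t1)


class TestSignificanceAndOverlap:
    def _results(self):
        return pd.DataFrame(
            {
                "baseline_log2fc": [1.32, 0.58, -2.0, 0.1],
                "baseline_p": [0.04, 0.04, 0.001, 0.5],
                "rate_effect": [0.3, -1.0, 0.2, 2.0],
                "rate_p": [0.049, 0.2, 0.01, 0.051],
            },
            index=["a", "b", "c", "d"],
        )

    def test_rules(self):
        out, counts = gp.call_significance(self._results())
        assert out.loc["a", "sig_baseline"]          # p<.05 and 2.5-fold
        assert not out.loc["b", "sig_baseline"]      # only 1.5-fold
        assert out.loc["a", "sig_rate"]              # p=0.049 < 0.05
        assert not out.loc["d", "sig_rate"]          # p=0.051
        assert counts == {"n_sig_baseline": 2, "n_sig_rate": 2, "n_overlap": 2}

    def test_overlap_and_venn(self):
        out, _ = gp.call_significance(self._results())
        ov = gp.overlap_biomarkers(out)
        assert set(ov["both"]) == {"a", "c"}
        assert ov["venn"] == (0, 0, 2)
        n1, n2, both = ov["venn"]
        assert n1 + n2 + both == len(
            set(out.index[out["sig_baseline"]]) | set(out.index[out["sig_rate"]])
        )

    def test_disjoint_sets(self):
        res = pd.DataFrame(
            {
                "baseline_log2fc": [2.0, 0.0],
                "baseline_p": [0.01, 0.9],
                "rate_effect": [0.0, 1.0],
                "rate_p": [0.9, 0.01],
            },
            index=["x", "y"],
        )
        out, _ = gp.call_significance(res)
        ov = gp.overlap_biomarkers(out)
        assert ov["both"] == []
        assert ov["venn"] == (1, 1, 0)

    def test_planted_overlap_recovered(self):
        rng = np.random.default_rng(8)
        idx = [f"f{i}" for i in range(50)]
        res = pd.DataFrame(
            {
                "baseline_log2fc": 0.0,
                "baseline_p": 1.0,
                "rate_effect": 0.0,
                "rate_p": 1.0,
            },
            index=idx,
        )
        planted = ["f3", "f7", "f11", "f21", "f40"]
        res.loc[planted, ["baseline_log2fc", "baseline_p", "rate_p"]] = [2.0, 0.01, 0.01]
        out, _ = gp.call_significance(res)
        assert set(gp.overlap_biomarkers(out)["both"]) == set(planted)


class TestFoldChangeAndProportions:
    @pytest.mark.parametrize(
        "log2fc,expected",
        [(4.2, 18.379), (0.0, 1.0), (-4.0, -16.0), (1.0, 2.0), (-1.0, -2.0)],
    )
    def test_signed_fold_change(self, log2fc, expected):
        assert gp.signed_fold_change(log2fc) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("log2fc", [-3.2, -1.0, 0.0, 0.7, 4.2])
    def test_signed_fold_change_roundtrip(self, log2fc):
        assert gp.signed_to_log2fc(gp.signed_fold_change(log2fc)) == pytest.approx(log2fc)

    def test_glycation_proportion_printed_scale(self):
        feats = pd.DataFrame({"mod_class": ["glycation"] * 1264 + ["glycosylation"] * 1486})
        frac, pct = gp.glycation_proportion(feats)
        assert pct == 46
        feats = pd.DataFrame({"mod_class": ["glycation"] * 1300 + ["glycosylation"] * 1663})
        assert gp.glycation_proportion(feats)[1] == 44

    def test_zero_glycation(self):
        feats = pd.DataFrame({"mod_class": ["glycosylation"] * 10})
        assert gp.glycation_proportion(feats) == (0.0, 0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gp.glycation_proportion(pd.DataFrame({"mod_class": []}))


class TestMultiplicity:
    def test_all_singletons(self):
        feats = pd.DataFrame(
            {
                "protein_accession": ["P1", "P2", "P3"],
                "site_1based": [1, 2, 3],
                "glycan": ["Hex(1)"] * 3,
            }
        )
        out = gp.multiplicity_stats(feats)
        assert out["glycopeptiforms_per_protein"] == {1: 3}
        assert out["frac_proteins_multi_form"] == 0.0
        assert out["frac_proteins_multi_glycan_site"] == 0.0

    def test_toy_table_against_recount_oracle(self):
        feats = pd.DataFrame(
            {
                "protein_accession": ["P1", "P1", "P1", "P2", "P2", "P3", "P4", "P5"],
                "site_1based": [1, 1, 2, 5, 5, 9, 4, 2],
                "glycan": ["A", "B", "A", "A", "A", "C", "A", "B"],
            }
        )
        # P2 has duplicate (site, glycan)? no: both (P2,5,A) -> 1 distinct glycan
        out = gp.multiplicity_stats(feats)
        assert out["glycopeptiforms_per_protein"] == {1: 3, 2: 1, 3: 1}
        assert out["frac_proteins_multi_form"] == pytest.approx(2 / 5)
        # only P1 site 1 bears two distinct glycans
        assert out["frac_proteins_multi_glycan_site"] == pytest.approx(1 / 5)
        total = sum(out["glycopeptiforms_per_protein"].values())
        assert total == out["n_proteins"]


class TestSummaryTtest:
    @pytest.mark.parametrize(
        "m1,sd1,n1,m2,sd2,n2,p_expected",
        [
            (75.58, 2.90, 8, 73.87, 2.18, 14, 0.132),   # age
            (12.13, 2.90, 8, 13.29, 3.43, 14, 0.430),   # education years
            (26.92, 3.40, 8, 27.29, 2.78, 14, 0.782),   # BMI
            (172.42, 22.19, 8, 161.71, 22.99, 14, 0.300),  # cholesterol
            (132.81, 8.65, 8, 132.18, 6.01, 14, 0.841),    # systolic BP
            (10.39, 0.79, 8, 10.66, 0.70, 14, 0.417),      # diabetes duration
        ],
    )
    def test_published_style_summaries(self, m1, sd1, n1, m2, sd2, n2, p_expected):
        t, df, p = gp.summary_stats_ttest(SummaryGroupStats(m1, sd1, n1, m2, sd2, n2))
        assert df == n1 + n2 - 2
        assert p == pytest.approx(p_expected, abs=0.01)

    def test_agrees_with_raw_data_ttest(self):
        # construct raw samples with exactly the stated summary stats
        def fabricate(mean, sd, n, seed):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = fabricate(75.58, 2.90, 8, 1)
        b = fabricate(73.87, 2.18, 14, 2)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t, df, p = gp.summary_stats_ttest(SummaryGroupStats(75.58, 2.90, 8, 73.87, 2.18, 14))
        assert t == pytest.approx(t_raw, abs=1e-9)
        assert p == pytest.approx(p_raw, abs=1e-9)

    def test_degenerate_cases(self):
        t, df, p = gp.summary_stats_ttest(SummaryGroupStats(5.0, 0.0, 5, 5.0, 0.0, 5))
        assert (t, p) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="zero variance"):
            t, df, p = gp.summary_stats_ttest(SummaryGroupStats(6.0, 0.0, 5, 5.0, 0.0, 5))
        assert p == 0.0

    def test_equal_means_any_sds(self):
        t, _, p = gp.summary_stats_ttest(SummaryGroupStats(5.0, 1.0, 5, 5.0, 3.0, 9))
        assert t == 0.0 and p == 1.0


class TestVolcano:
    def test_neg_log10_and_flags_match_significance(self):
        res = pd.DataFrame(
            {
                "baseline_log2fc": [2.0, -1.5],
                "baseline_p": [0.001, 0.2],
                "rate_effect": [1.0, -1.0],
                "rate_p": [0.01, 0.6],
                "mod_class": ["glycation", "glycosylation"],
            },
            index=["a", "b"],
        )
        out, _ = gp.call_significance(res)
        tab = volcano_table(out, "baseline")
        assert tab.loc[0, "neg_log10_p"] == pytest.approx(3.0)
        assert list(tab["significant"]) == list(out["sig_baseline"])
        assert list(tab["direction"]) == ["up", "down"]

    def test_empty_results(self):
        tab = volcano_table(pd.DataFrame(), "baseline")
        assert tab.empty and "neg_log10_p" in tab.columns
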