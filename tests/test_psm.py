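"""P-score calibration, decoy-FDR thresholding, and PSM export."""

import numpy as np
import pandas as pd
import pytest

import glycopipe as gp
from glycopipe.psm import choose_pscore_threshold, per_class_fdr, read_quant_input


def _separated_psms(n_target=700, n_decoy=300, seed=0, gap=3.0):
    rng = np.random.default_rng(seed)
    n = n_target + n_decoy
    is_decoy = np.r_[np.zeros(n_target, bool), np.ones(n_decoy, bool)]
    log_p = np.where(is_decoy, rng.normal(1.0, 1.0, n), rng.normal(1.0 + gap, 1.0, n))
    delta_mod = np.where(is_decoy, rng.normal(2.0, 2.0, n), rng.normal(2.0 + 3 * gap, 2.0, n))
    return pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "run_id": [f"r{i % 4}" for i in range(n)],
            "peptide": ["PEPTIDEK"] * n,
            "protein_accession": ["P1"] * n,
            "site_1based": 1,
            "residue": "K",
            "glycan": "Hex(1)",
            "score": np.where(is_decoy, rng.normal(150, 50, n), rng.normal(400, 80, n)).clip(0),
            "log_p": log_p,
            "delta_mod": delta_mod,
            "is_decoy": is_decoy,
            "precursor_intensity": rng.lognormal(14, 1, n),
        }
    )


def _auc(scores, labels):
    """Brute-force rank-comparison AUC: P(target score > decoy score)."""
    pos = scores[~labels]
    neg = scores[labels]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestFitPscore:
    def test_separated_scores_give_high_auc(self):
        psms = _separated_psms(seed=1)
        _, scored = gp.fit_pscore(psms)
        auc = _auc(scored["pscore"].to_numpy(), scored["is_decoy"].to_numpy())
        assert auc > 0.95

    def test_targets_score_higher_on_average(self):
        _, scored = gp.fit_pscore(_separated_psms(seed=2))
        assert (
            scored.loc[~scored["is_decoy"], "pscore"].mean()
            > scored.loc[scored["is_decoy"], "pscore"].mean()
        )

    def test_uninformative_labels_give_flat_pscores(self):
        # decoy labels permuted independently of scores: P-score ~ prevalence
        rng = np.random.default_rng(5)
        psms = _separated_psms(seed=5)
        psms["is_decoy"] = rng.permutation(psms["is_decoy"].to_numpy())
        _, scored = gp.fit_pscore(psms)
        prevalence = 1.0 - psms["is_decoy"].mean()
        assert scored["pscore"].std() < 0.1
        assert scored["pscore"].mean() == pytest.approx(prevalence, abs=0.05)

    @pytest.mark.parametrize("all_decoy", [True, False])
    def test_single_class_input_errors(self, all_decoy):
        psms = _separated_psms(n_target=50, n_decoy=50)
        psms["is_decoy"] = all_decoy
        with pytest.raises(ValueError):
            gp.fit_pscore(psms)

    def test_model_predicts_the_stored_pscores(self):
        model, scored = gp.fit_pscore(_separated_psms(seed=3))
        pred = model.predict_pscore(scored["log_p"], scored["delta_mod"])
        assert np.allclose(pred, scored["pscore"], atol=1e-8)


class TestThreshold:
    def test_matches_exhaustive_scan_oracle(self):
        psms = _separated_psms(n_target=800, n_decoy=200, seed=9, gap=2.0)
        _, scored = gp.fit_pscore(psms)
        thr, passed = choose_pscore_threshold(scored, 0.01)
        # oracle: try every observed pscore as a threshold, smallest winner
        s = scored["pscore"].to_numpy()
        y = scored["is_decoy"].to_numpy()
        feasible = []
        for t in np.unique(s):
            sel = s >= t
            n_t = (~y[sel]).sum()
            n_d = y[sel].sum()
            if n_t > 0 and n_d / n_t < 0.01:
                feasible.append(t)
        assert thr == pytest.approx(min(feasible))
        assert len(passed) == (s >= thr).sum()

    def test_fdr_among_survivors_is_below_target(self):
        _, scored = gp.fit_pscore(_separated_psms(seed=4))
        thr, passed = choose_pscore_threshold(scored, 0.01)
        assert gp.estimate_effective_fdr(passed) < 0.01

    def test_zero_decoys_pass_everything(self):
        psms = _separated_psms(n_target=100, n_decoy=0)
        psms["pscore"] = np.linspace(0.2, 0.9, len(psms))
        thr, passed = choose_pscore_threshold(psms, 0.01)
        assert thr == pytest.approx(0.2)
        assert len(passed) == len(psms)

    def test_unreachable_target_errors_with_best_fdr(self):
        psms = pd.DataFrame(
            {
                "pscore": [0.9, 0.8, 0.7, 0.6],
                "is_decoy": [True, False, True, False],
                "score": [300.0] * 4,
            }
        )
        with pytest.raises(ValueError, match="best achievable"):
            choose_pscore_threshold(psms, 0.01)

    def test_monotone_in_fdr_target(self):
        _, scored = gp.fit_pscore(_separated_psms(seed=6, gap=2.0))
        sizes = []
        for target in (0.005, 0.01, 0.05, 0.2):
            _, passed = choose_pscore_threshold(scored, target)
            sizes.append(len(passed))
        assert sizes == sorted(sizes)


class TestHardFilterAndFdr:
    def test_score_filter_is_strict(self):
        psms = pd.DataFrame({"score": [199.9, 200.0, 200.1], "is_decoy": [False] * 3})
        out = gp.apply_hard_filters(psms, 200.0)
        assert out["score"].tolist() == [200.1]

    def test_empty_input_allowed(self):
        out = gp.apply_hard_filters(pd.DataFrame({"score": [], "is_decoy": []}), 200.0)
        assert len(out) == 0

    def test_filter_count_matches_recount_oracle(self):
        rng = np.random.default_rng(12)
        psms = pd.DataFrame({"score": rng.uniform(0, 500, 500), "is_decoy": False})
        out = gp.apply_hard_filters(psms, 200.0)
        assert len(out) == int((psms["score"] > 200.0).sum())

    def test_filters_commute(self):
        _, scored = gp.fit_pscore(_separated_psms(seed=7))
        thr, passed = choose_pscore_threshold(scored, 0.05)
        a = gp.apply_hard_filters(passed, 200.0)
        b0 = gp.apply_hard_filters(scored, 200.0)
        b = b0[b0["pscore"] >= thr]
        assert sorted(a["spectrum_id"]) == sorted(b["spectrum_id"])

    def test_effective_fdr_arithmetic(self):
        psms = pd.DataFrame({"is_decoy": [True] + [False] * 500})
        assert gp.estimate_effective_fdr(psms) == pytest.approx(1 / 500)
        psms = pd.DataFrame({"is_decoy": [False] * 10})
        assert gp.estimate_effective_fdr(psms) == 0.0
        with pytest.raises(ValueError):
            gp.estimate_effective_fdr(pd.DataFrame({"is_decoy": []}))

    def test_per_class_fdr_reporting(self):
        psms = pd.DataFrame(
            {
                "is_decoy": [True, True, False, False, False, False],
                "is_seq_decoy": [True, False, False, False, False, False],
                "is_glycan_decoy": [False, True, False, False, False, False],
            }
        )
        out = per_class_fdr(psms)
        assert out["pooled"] == pytest.approx(0.5)
        assert out["sequence"] == pytest.approx(0.25)
        assert out["glycan"] == pytest.approx(0.25)


class TestQuantExport:
    def test_export_sorted_and_roundtrips(self, tmp_path):
        psms = _separated_psms(n_target=6, n_decoy=2, seed=8)
        path = tmp_path / "quant_input.tsv"
        out = gp.export_quant_input(psms, path)
        assert list(out["File Name"]) == sorted(out["File Name"])
        again = read_quant_input(path)
        assert len(again) == len(psms)
        assert list(again["Base Sequence"]) == list(out["Base Sequence"])
        assert list(again["File Name"]) == list(out["File Name"])

    def test_missing_run_id_errors(self, tmp_path):
        psms = _separated_psms(n_target=3, n_decoy=1)
        psms.loc[0, "run_id"] = None
        with pytest.raises(ValueError, match="run_id"):
            gp.export_quant_input(psms, tmp_path / "x.tsv")

    def test_glycan_annotation_embedded_in_full_sequence(self, tmp_path):
        psms = _separated_psms(n_target=3, n_decoy=1)
        out = gp.export_quant_input(psms, tmp_path / "q.tsv")
        assert out["Full Sequence"].str.contains(r"\[Hex\(1\)\]").all()


class TestFdrControlProperty:
    def test_false_match_proportion_controlled(self):
        """Scaled-down control check: with incorrect targets sharing the
        decoy score distribution, the realized false-match proportion at
        the chosen threshold stays within 2x the decoy estimate."""
        cfg = gp.SimulationConfig(
            psm=gp.PSMSimConfig(n_targets=2000, n_decoys=200, frac_incorrect=0.05)
        )
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            psms, truth = gp.simulate_psm_table(cfg, seed=100 + rep)
            _, scored = gp.fit_pscore(psms)
            thr, passed = choose_pscore_threshold(scored, 0.01)
            surv_t = passed[~passed["is_decoy"]]
            fmp = 1.0 - truth[surv_t.index].mean()
            if fmp <= 0.02:
                hits += 1
        assert hits >= int(0.9 * n_rep)
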