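"""Baseline and longitudinal differential analysis of glycopeptiforms.

Two comparisons drive the biomarker logic:

* **baseline** — per feature, OLS of the log2 intensity at the first
  visit on a decliner indicator plus covariates (HbA1c by default); the
  group coefficient is the log2 fold change, tested with a two-sided t.
* **rate of change** — per feature, a linear mixed model
  ``log2 intensity ~ group + time + group:time + baseline_age +
  mean_hba1c + (1 | subject)``; the group x time interaction is the
  difference in the T1->T2 rate of change between groups.

With the balanced complete two-visit design the pipeline produces after
imputation, the mixed model's interaction estimate equals the
difference-in-differences of the group means, and the model can be fit
exactly by the orthogonal between/within (paired) decomposition — that
closed form is the default engine; the general engine delegates to
statsmodels ``MixedLM``.

Decliners are coded 1, so positive effects mean *up in decliners*.
Significance at baseline requires p < 0.05 and at least a two-fold
change (|log2fc| >= 1); the rate analysis uses p < 0.05 alone.  No
multiple-testing correction gates the calls, but BH q-values are
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import IntensityMatrix

__all__ = [
    "SummaryGroupStats",
    "baseline_differential",
    "rate_of_change_lmm",
    "call_significance",
    "overlap_biomarkers",
    "signed_fold_change",
    "signed_to_log2fc",
    "glycation_proportion",
    "multiplicity_stats",
    "summary_stats_ttest",
    "volcano_table",
]


def _group_indicator(meta: pd.DataFrame, samples) -> np.ndarray:
    g = meta.set_index("sample_id")["group"].reindex(samples)
    if g.isna().any():
        raise ValueError("matrix contains samples missing from metadata")
    return (g == "decliner").to_numpy(float)


def baseline_differential(
    m: IntensityMatrix,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = ("mean_hba1c",),
    timepoint: str = "T1",
) -> pd.DataFrame:
    """Per-feature OLS of log2 intensity on group (+ covariates) at one visit.

    Returns a frame indexed by glycopeptiform key with columns
    ``log2fc`` (decliner minus non-decliner, adjusted), ``se``, ``t``,
    ``p``, ``q`` (BH) and ``error``.  Covariates that are constant across
    subjects are dropped with a warning; a rank-deficient design flags
    every feature instead of raising.
    """
    mm = meta[meta["timepoint"] == timepoint]
    if mm.empty:
        raise ValueError(f"no samples at timepoint {timepoint!r}")
    samples = [s for s in m.values.columns if s in set(mm["sample_id"].astype(str))]
    if not samples:
        raise ValueError(f"matrix has no samples at timepoint {timepoint!r}")
    sub = mm.set_index("sample_id").reindex(samples)
    grp = (sub["group"] == "decliner").to_numpy(float)
    if grp.min() == grp.max():
        raise ValueError("both groups must be present at baseline")

    cols: list[np.ndarray] = [np.ones(len(samples)), grp]
    names = ["intercept", "group"]
    for cov in covariates:
        x = sub[cov].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {cov!r} is constant; dropped from the baseline model")
            continue
        cols.append(x)
        names.append(cov)
    X = np.column_stack(cols)
    n, p = X.shape

    out = pd.DataFrame(
        index=m.values.index,
        columns=["log2fc", "se", "t", "p", "q", "error"],
    )
    out["error"] = ""
    if np.linalg.matrix_rank(X) < p:
        out["error"] = "rank_deficient"
        out[["log2fc", "se", "t", "p", "q"]] = np.nan
        return out

    Y = m.values[samples].to_numpy(float)  # features x n
    finite = np.isfinite(Y).all(axis=1)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = (xtx_inv @ X.T @ Y[finite].T)  # p x F
    resid = Y[finite].T - X @ beta
    df_resid = n - p
    sigma2 = (resid**2).sum(axis=0) / df_resid
    gi = names.index("group")
    se = np.sqrt(sigma2 * xtx_inv[gi, gi])
    tvals = beta[gi] / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    out.loc[finite, "log2fc"] = beta[gi]
    out.loc[finite, "se"] = se
    out.loc[finite, "t"] = tvals
    out.loc[finite, "p"] = pvals
    out.loc[~finite, "error"] = "non_finite_values"
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"].to_numpy(float), method="fdr_bh")[1]
    return out.astype({"log2fc": float, "se": float, "t": float, "p": float, "q": float})


def _paired_layout(m: IntensityMatrix, meta: pd.DataFrame):
    """Map the matrix onto (subject x timepoint) arrays; None if unbalanced."""
    mm = meta.set_index("sample_id")
    samples = [s for s in m.values.columns if s in mm.index]
    mm = mm.loc[samples]
    wide = mm.reset_index().pivot(index="subject_id", columns="timepoint", values="sample_id")
    if "T1" not in wide.columns or "T2" not in wide.columns or wide.isna().any().any():
        return None
    subj = wide.index.to_numpy()
    s1 = wide["T1"].astype(str).to_numpy()
    s2 = wide["T2"].astype(str).to_numpy()
    if not (set(s1) | set(s2)) <= set(m.values.columns):
        return None
    grp = (mm.groupby("subject_id")["group"].first().reindex(wide.index) == "decliner").to_numpy(float)
    return subj, s1, s2, grp


def rate_of_change_lmm(
    m: IntensityMatrix,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = ("baseline_age", "mean_hba1c"),
    engine: str = "auto",
) -> pd.DataFrame:
    """Per-feature group x time interaction from the longitudinal model.

    Returns a frame with ``effect`` (difference in T1->T2 change,
    decliner minus non-decliner, log2 units), ``se``, ``p``, ``q`` and
    ``method``.  ``engine='paired'`` uses the exact between/within
    decomposition (balanced complete designs only); ``engine='mixedlm'``
    fits statsmodels MixedLM per feature with a containment-style t test
    on the interaction and an OLS-on-differences fallback on
    non-convergence; ``'auto'`` picks paired when the design allows it.
    """
    tps = set(meta.loc[meta["sample_id"].isin(m.values.columns), "timepoint"])
    if "T2" not in tps or "T1" not in tps:
        raise ValueError("rate-of-change analysis needs samples at both T1 and T2")
    for g in ("decliner", "non-decliner"):
        n_both = (
            meta[meta["group"] == g].groupby("subject_id")["timepoint"].nunique() == 2
        ).sum()
        if n_both < 2:
            raise ValueError(f"need >= 2 {g} subjects with both timepoints")

    layout = _paired_layout(m, meta)
    complete = layout is not None and np.isfinite(m.values.to_numpy(float)).all()
    if engine == "auto":
        engine = "paired" if complete else "mixedlm"
    if engine == "paired":
        if not complete:
            raise ValueError("paired engine requires a balanced, fully observed design")
        return _rate_paired(m, layout)
    if engine == "mixedlm":
        return _rate_mixedlm(m, meta, covariates)
    raise ValueError(f"unknown engine {engine!r}")


def _rate_paired(m: IntensityMatrix, layout) -> pd.DataFrame:
    subj, s1, s2, grp = layout
    Y1 = m.values[list(s1)].to_numpy(float)
    Y2 = m.values[list(s2)].to_numpy(float)
    D = (Y2 - Y1).T  # subjects x features
    # within-subject stratum of the mixed model: d ~ time + group:time;
    # between-subject covariates cancel in the differences
    X = np.column_stack([np.ones(len(subj)), grp])
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ D
    resid = D - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    tvals = np.zeros_like(se)
    nz = se > 0
    tvals[nz] = beta[1][nz] / se[nz]
    tvals[(~nz) & (beta[1] != 0)] = np.inf  # noise-free data with a real effect
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    out = pd.DataFrame(
        {
            "effect": beta[1],
            "se": se,
            "p": pvals,
            "method": "paired",
        },
        index=m.values.index,
    )
    out["q"] = multipletests(out["p"].to_numpy(float), method="fdr_bh")[1]
    return out[["effect", "se", "p", "q", "method"]]


def _rate_mixedlm(m: IntensityMatrix, meta: pd.DataFrame, covariates) -> pd.DataFrame:
    import statsmodels.api as sm

    mm = meta.set_index("sample_id")
    samples = [s for s in m.values.columns if s in mm.index]
    mm = mm.loc[samples]
    grp = (mm["group"] == "decliner").to_numpy(float)
    time = (mm["timepoint"] == "T2").to_numpy(float)
    cols = [np.ones(len(samples)), grp, time, grp * time]
    names = ["intercept", "group", "time", "group:time"]
    for cov in covariates:
        x = mm[cov].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {cov!r} is constant; dropped from the mixed model")
            continue
        cols.append(x)
        names.append(cov)
    X = np.column_stack(cols)
    groups = mm["subject_id"].to_numpy()
    gi = names.index("group:time")
    n_subj = len(np.unique(groups))
    # containment df: within-subject effects are tested against
    # n_obs - n_subjects - (# within-varying fixed effects)
    n_within = sum(
        1
        for k, name in enumerate(names)
        if pd.DataFrame({"g": groups, "x": X[:, k]}).groupby("g")["x"].nunique().gt(1).any()
    )
    df_within = len(samples) - n_subj - n_within

    effects, ses, ps, methods = [], [], [], []
    for key in m.values.index:
        y = m.values.loc[key, samples].to_numpy(float)
        ok = np.isfinite(y)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y[ok], X[ok], groups=groups[ok]).fit(reml=True)
            if not np.isfinite(res.bse_fe[gi]):
                raise np.linalg.LinAlgError("non-finite SE")
            eff = float(res.fe_params[gi])
            se = float(res.bse_fe[gi])
            t = eff / se
            p = float(2.0 * stats.t.sf(abs(t), max(df_within, 1)))
            method = "mixedlm"
        except Exception:
            eff, se, p, method = _ols_diff_fallback(y, X, groups, names)
        effects.append(eff)
        ses.append(se)
        ps.append(p)
        methods.append(method)
    out = pd.DataFrame(
        {"effect": effects, "se": ses, "p": ps, "method": methods}, index=m.values.index
    )
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"].to_numpy(float), method="fdr_bh")[1]
    return out[["effect", "se", "p", "q", "method"]]


def _ols_diff_fallback(y, X, groups, names):
    """OLS of per-subject T2-T1 differences on group (+ covariates)."""
    ti = names.index("time")
    gi = names.index("group")
    df = pd.DataFrame({"y": y, "subject": groups, "time": X[:, ti], "group": X[:, gi]})
    df = df.dropna(subset=["y"])
    wide = df.pivot_table(index="subject", columns="time", values="y", aggfunc="mean")
    if 0.0 not in wide.columns or 1.0 not in wide.columns:
        return np.nan, np.nan, np.nan, "failed"
    wide = wide.dropna()
    d = (wide[1.0] - wide[0.0]).to_numpy()
    g = df.groupby("subject")["group"].first().reindex(wide.index).to_numpy(float)
    if len(d) < 3 or g.min() == g.max():
        return np.nan, np.nan, np.nan, "failed"
    Xd = np.column_stack([np.ones(len(d)), g])
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    beta = xtx_inv @ Xd.T @ d
    resid = d - Xd @ beta
    dof = len(d) - 2
    se = float(np.sqrt(resid @ resid / dof * xtx_inv[1, 1]))
    t = beta[1] / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return float(beta[1]), se, p, "ols_fallback"


def call_significance(
    results: pd.DataFrame,
    baseline_p_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    rate_p_max: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Apply the a-priori significance rules and count the calls.

    ``results`` holds per-feature columns from both analyses
    (``baseline_log2fc``, ``baseline_p``, ``rate_effect``, ``rate_p``;
    missing analyses yield all-False flags).  Baseline significance
    requires p < 0.05 AND at least a two-fold change; the rate analysis
    is gated on p alone.
    """
    out = results.copy()
    if {"baseline_log2fc", "baseline_p"} <= set(out.columns):
        out["sig_baseline"] = (out["baseline_p"] < baseline_p_max) & (
            out["baseline_log2fc"].abs() >= min_abs_log2fc
        )
    else:
        out["sig_baseline"] = False
    if "rate_p" in out.columns:
        out["sig_rate"] = out["rate_p"] < rate_p_max
    else:
        out["sig_rate"] = False
    out["sig_baseline"] = out["sig_baseline"].fillna(False).astype(bool)
    out["sig_rate"] = out["sig_rate"].fillna(False).astype(bool)
    counts = {
        "n_sig_baseline": int(out["sig_baseline"].sum()),
        "n_sig_rate": int(out["sig_rate"].sum()),
        "n_overlap": int((out["sig_baseline"] & out["sig_rate"]).sum()),
    }
    return out, counts


def overlap_biomarkers(results: pd.DataFrame) -> dict:
    """Intersect the two significant sets and report the Venn triple."""
    base = set(results.index[results["sig_baseline"]])
    rate = set(results.index[results["sig_rate"]])
    both = base & rate
    return {
        "both": sorted(both),
        "baseline_only": sorted(base - rate),
        "rate_only": sorted(rate - base),
        "venn": (len(base - rate), len(rate - base), len(both)),
    }


def signed_fold_change(log2fc: float) -> float:
    """Log2 effect -> signed fold change (e.g. -4 -> -16.0, 0 -> 1.0)."""
    log2fc = float(log2fc)
    return float(2.0**log2fc) if log2fc >= 0 else float(-(2.0 ** (-log2fc)))


def signed_to_log2fc(fc: float) -> float:
    """Inverse of :func:`signed_fold_change`."""
    fc = float(fc)
    if fc == 0 or -1 < fc < 1:
        raise ValueError("signed fold change has magnitude >= 1")
    return float(np.log2(fc)) if fc > 0 else float(-np.log2(-fc))


def glycation_proportion(features: pd.DataFrame) -> tuple[float, int]:
    """Percent of features that are glycated; also the integer display value."""
    if len(features) == 0:
        raise ValueError("no features")
    frac = 100.0 * (features["mod_class"] == "glycation").mean()
    return float(frac), int(round(frac))


def multiplicity_stats(features: pd.DataFrame) -> dict:
    """Glycopeptiform-multiplicity summaries of the identified features.

    Two distributions: how many glycopeptiforms each protein carries,
    and how many distinct glycans each (protein, site) carries; plus the
    headline fractions (proteins with >= 2 forms; proteins with a site
    bearing >= 2 distinct glycans).
    """
    per_protein = features.groupby("protein_accession").size()
    forms_hist = per_protein.value_counts().sort_index().to_dict()
    glycans_per_site = features.groupby(["protein_accession", "site_1based"])["glycan"].nunique()
    site_hist = glycans_per_site.value_counts().sort_index().to_dict()
    multi_site_proteins = (
        glycans_per_site[glycans_per_site >= 2].index.get_level_values(0).unique()
    )
    n_prot = per_protein.size
    return {
        "glycopeptiforms_per_protein": {int(k): int(v) for k, v in forms_hist.items()},
        "glycans_per_site": {int(k): int(v) for k, v in site_hist.items()},
        "frac_proteins_multi_form": float((per_protein >= 2).mean()) if n_prot else 0.0,
        "frac_proteins_multi_glycan_site": (
            len(multi_site_proteins) / n_prot if n_prot else 0.0
        ),
        "n_proteins": int(n_prot),
    }


@dataclass(frozen=True)
class SummaryGroupStats:
    """Published-style group summaries: mean (SD) and n for two groups."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SDs must be non-negative")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")


def summary_stats_ttest(s: SummaryGroupStats) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t-test from summary statistics.

    Returns (t, df, two-sided p); reproduces the group-comparison tests
    typically printed in a demographics table.
    """
    df = s.n1 + s.n2 - 2
    if s.sd1 == 0 and s.sd2 == 0:
        if s.mean1 == s.mean2:
            return 0.0, df, 1.0
        warnings.warn("zero variance with unequal means: p underflows to 0")
        return float(np.inf) if s.mean1 > s.mean2 else float(-np.inf), df, 0.0
    t, p = stats.ttest_ind_from_stats(
        s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2, equal_var=True
    )
    return float(t), df, float(p)


def volcano_table(results: pd.DataFrame, analysis: str = "baseline") -> pd.DataFrame:
    """Plot-ready table: log2 effect vs -log10 p with direction flags."""
    if analysis == "baseline":
        eff_col, p_col, sig_col = "baseline_log2fc", "baseline_p", "sig_baseline"
    elif analysis == "rate":
        eff_col, p_col, sig_col = "rate_effect", "rate_p", "sig_rate"
    else:
        raise ValueError("analysis must be 'baseline' or 'rate'")
    cols = ["feature_key", "mod_class", "log2_effect", "neg_log10_p", "significant", "direction"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(
        {
            "feature_key": results.index,
            "mod_class": results.get("mod_class", pd.Series("", index=results.index)).to_numpy(),
            "log2_effect": results[eff_col].to_numpy(float),
            "neg_log10_p": -np.log10(results[p_col].to_numpy(float)),
            "significant": results[sig_col].to_numpy(bool) if sig_col in results else False,
        }
    )
    out["direction"] = np.where(out["log2_effect"] >= 0, "up", "down")
    return out[cols]
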