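"""Target-decoy FDR control for glyco-PSMs via a combined P-score.

The search engine emits three quality scores per peptide-spectrum match
(Score, Log-P, Delta-Mod).  A combined P-score is obtained by logistic
regression of the pooled decoy state (sequence decoy OR glycan decoy) on
Log-P and Delta-Mod; the P-score of a PSM is the model's predicted
probability of being a *target*, so higher is better.  A lower-bound
P-score threshold is then chosen so that the decoy-estimated FDR among
survivors is below a target (1% by default), followed by a hard
``Score > 200`` cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .glycans import GlycanComposition

__all__ = [
    "PSM_COLUMNS",
    "PSMRecord",
    "PscoreModel",
    "read_psm_table",
    "write_psm_table",
    "fit_pscore",
    "choose_pscore_threshold",
    "apply_hard_filters",
    "estimate_effective_fdr",
    "export_quant_input",
    "read_quant_input",
    "summarize_psm_intensities",
]

#: Canonical column schema of an in-memory PSM table.
PSM_COLUMNS = [
    "spectrum_id",
    "run_id",
    "peptide",
    "protein_accession",
    "site_1based",
    "residue",
    "glycan",
    "score",
    "log_p",
    "delta_mod",
    "is_decoy",
    "precursor_intensity",
]

#: Default mapping from search-engine export headers to canonical names.
DEFAULT_PSM_COLUMN_MAP = {
    "Spectrum": "spectrum_id",
    "Run": "run_id",
    "Peptide": "peptide",
    "Protein": "protein_accession",
    "Site": "site_1based",
    "Residue": "residue",
    "Glycans": "glycan",
    "Score": "score",
    "LogP": "log_p",
    "DeltaMod": "delta_mod",
    "Decoy": "is_decoy",
    "Intensity": "precursor_intensity",
}


@dataclass
class PSMRecord:
    """One peptide-spectrum match with engine scores and annotations."""

    spectrum_id: str
    run_id: str
    peptide: str
    protein_accession: str
    score: float
    log_p: float
    delta_mod: float
    is_decoy: bool
    site_1based: int | None = None
    residue: str | None = None
    glycan: GlycanComposition | str | None = None
    precursor_intensity: float | None = None


def psm_frame(records: list[PSMRecord]) -> pd.DataFrame:
    """Convert records to the canonical PSM table."""
    rows = []
    for r in records:
        d = asdict(r)
        g = d["glycan"]
        if isinstance(g, GlycanComposition):
            d["glycan"] = g.render()
        rows.append(d)
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def read_psm_table(path, column_map: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited PSM export into the canonical schema.

    ``column_map`` maps file headers to canonical names; unmapped extra
    columns are kept as-is.  The delimiter is sniffed from the extension
    unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    cmap = dict(DEFAULT_PSM_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = df.rename(columns=cmap)
    missing = [c for c in ("peptide", "score", "log_p", "delta_mod", "is_decoy") if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks required columns {missing}")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    if (df["score"] < 0).any():
        raise ValueError("Score must be non-negative")
    return df


def write_psm_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class PscoreModel:
    """Fitted combined P-score model (logistic on Log-P and Delta-Mod)."""

    intercept: float
    coef_log_p: float
    coef_delta_mod: float
    fdr_target: float = 0.01
    threshold: float | None = None

    def predict_pscore(self, log_p, delta_mod) -> np.ndarray:
        """Predicted probability of being a target; higher = better."""
        eta = self.intercept + self.coef_log_p * np.asarray(log_p, float) \
            + self.coef_delta_mod * np.asarray(delta_mod, float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_pscore(psms: pd.DataFrame, max_iter: int = 200) -> tuple[PscoreModel, pd.DataFrame]:
    """Fit the combined P-score and annotate the table with it.

    Regresses the binary decoy indicator on (Log-P, Delta-Mod) with an
    (effectively unpenalised) logistic model; the P-score is the
    predicted target probability, orientation-checked so that targets
    score at least as high as decoys on average.  Returns the model and a
    copy of the table with a ``pscore`` column.
    """
    y = psms["is_decoy"].to_numpy(bool)
    if y.all() or (~y).all():
        raise ValueError("need both target and decoy PSMs to fit the P-score")
    X = psms[["log_p", "delta_mod"]].to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite Log-P or Delta-Mod scores")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("both predictors are constant; cannot fit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=max_iter)
        clf.fit(X, y.astype(int))
    if clf.n_iter_[0] >= max_iter:
        warnings.warn("P-score regression hit the iteration bound (scores may be separable)")
    # model predicts decoy probability; P-score is the target probability
    p_decoy = clf.predict_proba(X)[:, 1]
    pscore = 1.0 - p_decoy
    intercept = -float(clf.intercept_[0])
    coef_lp, coef_dm = (-clf.coef_[0]).tolist()
    if pscore[~y].mean() < pscore[y].mean():
        # orientation guard; with a sane fit targets already score higher
        pscore = 1.0 - pscore
        intercept, coef_lp, coef_dm = -intercept, -coef_lp, -coef_dm
    model = PscoreModel(intercept=intercept, coef_log_p=coef_lp, coef_delta_mod=coef_dm)
    out = psms.copy()
    out["pscore"] = pscore
    return model, out


def choose_pscore_threshold(
    psms: pd.DataFrame, fdr_target: float = 0.01
) -> tuple[float, pd.DataFrame]:
    """Pick the lowest observed P-score threshold controlling decoy-FDR.

    Among PSMs with ``pscore >= t`` the decoy-FDR estimate is
    ``#decoys / #targets``; the returned ``t`` is the smallest observed
    P-score for which that estimate is strictly below ``fdr_target``.
    Returns the threshold and the passing subset.
    """
    if "pscore" not in psms.columns:
        raise ValueError("run fit_pscore first: no pscore column")
    s = psms["pscore"].to_numpy(float)
    y = psms["is_decoy"].to_numpy(bool)
    order = np.argsort(-s, kind="stable")  # descending
    dec_cum = np.cumsum(y[order])
    tgt_cum = np.cumsum(~y[order])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(tgt_cum > 0, dec_cum / np.maximum(tgt_cum, 1), np.inf)
    ok = fdr < fdr_target
    if not ok.any():
        best = float(np.nanmin(np.where(tgt_cum > 0, fdr, np.nan)))
        raise ValueError(
            f"no P-score threshold achieves decoy-FDR < {fdr_target}; "
            f"best achievable is {best:.4f}"
        )
    # ties: a threshold equal to s[k] admits every PSM with that score, so
    # only positions where the next score differs are feasible cut points
    s_sorted = s[order]
    boundary = np.ones(len(s), bool)
    boundary[:-1] = s_sorted[:-1] != s_sorted[1:]
    feasible = ok & boundary
    if not feasible.any():
        raise ValueError(f"no tie-consistent threshold achieves decoy-FDR < {fdr_target}")
    k = np.nonzero(feasible)[0].max()
    threshold = float(s_sorted[k])
    passed = psms[psms["pscore"] >= threshold].copy()
    return threshold, passed


def apply_hard_filters(psms: pd.DataFrame, score_min: float = 200.0) -> pd.DataFrame:
    """Keep PSMs with engine Score strictly greater than ``score_min``."""
    return psms[psms["score"] > score_min].copy()


def estimate_effective_fdr(psms: pd.DataFrame) -> float:
    """Decoy/target ratio among surviving PSMs (the effective FDR)."""
    if len(psms) == 0:
        raise ValueError("empty PSM set; effective FDR undefined")
    n_dec = int(psms["is_decoy"].sum())
    n_tgt = len(psms) - n_dec
    if n_tgt == 0:
        raise ValueError("no target PSMs among survivors")
    return n_dec / n_tgt


def per_class_fdr(psms: pd.DataFrame) -> dict[str, float]:
    """Effective FDR split by decoy class when the flags are present."""
    out = {"pooled": estimate_effective_fdr(psms)}
    n_tgt = int((~psms["is_decoy"]).sum())
    for col, name in (("is_seq_decoy", "sequence"), ("is_glycan_decoy", "glycan")):
        if col in psms.columns and n_tgt > 0:
            out[name] = int(psms[col].sum()) / n_tgt
    return out


QUANT_INPUT_COLUMNS = [
    "File Name",
    "Scan Retention Time",
    "Scan Number",
    "Base Sequence",
    "Full Sequence",
    "Peptide Monoisotopic Mass",
    "Protein Accession",
    "Charge",
    "Intensity",
]


def export_quant_input(psms: pd.DataFrame, path) -> pd.DataFrame:
    """Write surviving PSMs as a generic quantification-input TSV.

    One row per PSM in the tab-separated dialect downstream label-free
    quantification tools accept (file name, scan, full/base sequence,
    accession, intensity).  Rows are sorted by run then spectrum id for
    byte-stable output.
    """
    required = ["run_id", "peptide", "spectrum_id"]
    for c in required:
        if c not in psms.columns or psms[c].isna().any():
            raise ValueError(f"every PSM needs a non-null {c!r} for quant export")
    df = psms.sort_values(["run_id", "spectrum_id"], kind="stable")
    full_seq = df["peptide"].astype(str)
    if "glycan" in df.columns:
        gly = df["glycan"].fillna("")
        full_seq = np.where(
            gly != "",
            df["peptide"].astype(str) + "[" + gly.astype(str) + "]",
            df["peptide"].astype(str),
        )
    out = pd.DataFrame(
        {
            "File Name": df["run_id"].to_numpy(),
            "Scan Retention Time": 0.0,
            "Scan Number": df["spectrum_id"].to_numpy(),
            "Base Sequence": df["peptide"].to_numpy(),
            "Full Sequence": full_seq,
            "Peptide Monoisotopic Mass": df.get("peptide_mass", pd.Series(np.nan, index=df.index)).to_numpy(),
            "Protein Accession": df.get("protein_accession", pd.Series("", index=df.index)).to_numpy(),
            "Charge": df.get("charge", pd.Series(2, index=df.index)).to_numpy(),
            "Intensity": df.get("precursor_intensity", pd.Series(np.nan, index=df.index)).to_numpy(),
        },
        columns=QUANT_INPUT_COLUMNS,
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return out


def read_quant_input(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def summarize_psm_intensities(psms: pd.DataFrame) -> pd.DataFrame:
    """Sum precursor intensities per (glycopeptiform key, run).

    A deliberately simple MS1 quantification stand-in: the intensity of a
    glycopeptiform in a run is the sum of its surviving PSMs' precursor
    intensities.  Returns long-format rows
    (protein_accession, site_1based, residue, glycan, peptide, sample_id,
    intensity) ready for matrix assembly.
    """
    needed = ["protein_accession", "site_1based", "glycan", "run_id"]
    for c in needed:
        if c not in psms.columns:
            raise ValueError(f"PSM table lacks column {c!r}")
    df = psms.dropna(subset=["precursor_intensity"])
    grouped = (
        df.groupby(
            ["protein_accession", "site_1based", "residue", "glycan", "peptide", "run_id"],
            dropna=False,
        )["precursor_intensity"]
        .sum()
        .reset_index()
        .rename(columns={"run_id": "sample_id", "precursor_intensity": "intensity"})
    )
    return grouped.sort_values(
        ["protein_accession", "site_1based", "glycan", "sample_id"], kind="stable"
    ).reset_index(drop=True)
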