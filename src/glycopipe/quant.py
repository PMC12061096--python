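"""Glycopeptiform x sample intensity matrices: assembly, normalization,
valid-value filtering, and left-censored imputation.

Intensities live on the log2 scale throughout.  Missingness here is
treated as left-censored (values below the detection limit), which is
why imputation draws from a Gaussian down-shifted from each sample's
observed distribution (shift 1.8 SD, width 0.3 SD by default).
The matrix keeps an explicit ``observed`` mask that is never altered by
imputation, so every downstream step can distinguish measured from
imputed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glycans import GlycanComposition

__all__ = [
    "Glycopeptiform",
    "IntensityMatrix",
    "read_sample_meta",
    "build_intensity_matrix",
    "normalize_matrix",
    "filter_valid_values",
    "impute_missing",
    "missingness_report",
    "read_quant_table",
    "write_matrix",
]

GROUPS = ("decliner", "non-decliner")
TIMEPOINTS = ("T1", "T2")

FEATURE_COLUMNS = ["protein_accession", "site_1based", "residue", "mod_class", "glycan", "peptide"]


@dataclass(frozen=True)
class Glycopeptiform:
    """The quantified analyte: protein + site + modification + glycan.

    Identity is (accession, 1-based site, canonical glycan string).
    """

    protein_accession: str
    site_1based: int
    residue: str
    mod_class: str
    glycan: GlycanComposition | str
    peptide: str = ""

    @property
    def glycan_str(self) -> str:
        g = self.glycan
        return g.render() if isinstance(g, GlycanComposition) else str(g)

    @property
    def key(self) -> str:
        return f"{self.protein_accession}|{self.site_1based}|{self.glycan_str}"


def feature_key_frame(features: pd.DataFrame) -> pd.Index:
    """Identity keys for a feature annotation table."""
    return pd.Index(
        features["protein_accession"].astype(str)
        + "|"
        + features["site_1based"].astype(int).astype(str)
        + "|"
        + features["glycan"].astype(str),
        name="glycopeptiform_key",
    )


@dataclass
class IntensityMatrix:
    """Feature x sample log2 intensities with an explicit observed mask.

    ``values`` and ``observed`` share index (glycopeptiform keys) and
    columns (sample ids); ``features`` carries the per-feature annotation
    (accession, site, residue, mod_class, glycan, peptide) on the same
    index.  Cells where ``observed`` is False hold NaN until imputation.
    """

    values: pd.DataFrame
    observed: pd.DataFrame
    features: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.observed.index) or not self.values.columns.equals(
            self.observed.columns
        ):
            raise ValueError("values and observed mask must be aligned")
        vals = self.values.to_numpy(float)
        obs = self.observed.to_numpy(bool)
        if not np.isfinite(vals[obs]).all():
            raise ValueError("observed cells must hold finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.observed.copy(), self.features.copy()
        )


META_COLUMNS = ["sample_id", "subject_id", "group", "timepoint", "baseline_age", "mean_hba1c"]


def read_sample_meta(path) -> pd.DataFrame:
    """Read the sample metadata CSV and validate its structure."""
    meta = pd.read_csv(path)
    return validate_sample_meta(meta)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks columns {missing}")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}; expected {GROUPS}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}")
    dup = meta.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError("a subject has more than one sample at a timepoint")
    g_per_subj = meta.groupby("subject_id")["group"].nunique()
    if (g_per_subj > 1).any():
        raise ValueError("group must be constant within subject")
    return meta


def build_intensity_matrix(quant_rows: pd.DataFrame, meta: pd.DataFrame) -> IntensityMatrix:
    """Assemble long-format quant rows into a log2 IntensityMatrix.

    Duplicate (feature, sample) rows are summed on the raw scale before
    the log2 transform; zero or absent intensities become missing cells.
    Samples appearing in the quant rows but not in ``meta`` are an error;
    samples in ``meta`` with no rows appear as all-missing columns.
    """
    validate_sample_meta(meta)
    known = set(meta["sample_id"].astype(str))
    seen = set(quant_rows["sample_id"].astype(str))
    unknown = seen - known
    if unknown:
        raise ValueError(f"quant rows reference samples absent from metadata: {sorted(unknown)}")
    if (quant_rows["intensity"] < 0).any():
        raise ValueError("raw intensities must be >= 0")

    df = quant_rows.copy()
    df["glycopeptiform_key"] = (
        df["protein_accession"].astype(str)
        + "|"
        + df["site_1based"].astype(int).astype(str)
        + "|"
        + df["glycan"].astype(str)
    )
    raw = (
        df.groupby(["glycopeptiform_key", "sample_id"])["intensity"].sum().unstack(fill_value=0.0)
    )
    raw = raw.reindex(columns=[str(s) for s in meta["sample_id"]], fill_value=0.0)
    raw = raw.sort_index()
    observed = raw > 0
    values = pd.DataFrame(
        np.where(observed, np.log2(raw.where(raw > 0, 1.0)), np.nan),
        index=raw.index,
        columns=raw.columns,
    )
    feat_cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    features = (
        df.drop_duplicates("glycopeptiform_key").set_index("glycopeptiform_key")[feat_cols]
    ).reindex(values.index)
    return IntensityMatrix(values=values, observed=observed, features=features)


def normalize_matrix(m: IntensityMatrix) -> IntensityMatrix:
    """Median-center each sample's observed log2 values to the grand median.

    The grand median is the median of the per-sample medians, so the
    operation is idempotent.  Masks are untouched; a sample with no
    observed value cannot be normalized and is an error.
    """
    obs_counts = m.observed.sum(axis=0)
    if (obs_counts == 0).any():
        empty = list(obs_counts.index[obs_counts == 0])
        raise ValueError(f"samples with zero observed values cannot be normalized: {empty}")
    vals = m.values.where(m.observed)
    sample_medians = vals.median(axis=0)
    grand = sample_medians.median()
    shifted = m.values.add(grand - sample_medians, axis=1)
    return IntensityMatrix(values=shifted, observed=m.observed.copy(), features=m.features.copy())


def _strata(meta: pd.DataFrame, validity_strata: str) -> pd.Series:
    if validity_strata == "group":
        return meta.set_index("sample_id")["group"].astype(str)
    if validity_strata in ("group_time", "group×time", "group x time"):
        mm = meta.set_index("sample_id")
        return mm["group"].astype(str) + ":" + mm["timepoint"].astype(str)
    raise ValueError(f"unknown validity_strata {validity_strata!r}")


def filter_valid_values(
    m: IntensityMatrix,
    meta: pd.DataFrame,
    min_frac: float = 0.70,
    validity_strata: str = "group",
) -> IntensityMatrix:
    """Keep features with >= ``min_frac`` observed values in some stratum.

    Strata are groups (baseline analysis) or group x timepoint cells
    (longitudinal analysis).  Counting always uses the original observed
    mask, so the result is the same whether filtering runs before or
    after imputation.
    """
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    strata = _strata(meta, validity_strata)
    cols = [c for c in m.values.columns if c in strata.index]
    if not cols:
        raise ValueError("no matrix samples found in metadata")
    keep = np.zeros(m.n_features, dtype=bool)
    for stratum, members in strata.groupby(strata):
        scols = [c for c in cols if c in set(members.index)]
        if not scols:
            raise ValueError(f"stratum {stratum!r} has zero samples in the matrix")
        frac = m.observed[scols].mean(axis=1).to_numpy()
        # tolerance so that e.g. 7/10 compares as exactly 0.70
        keep |= frac >= min_frac - 1e-12
    idx = m.values.index[keep]
    return IntensityMatrix(
        values=m.values.loc[idx].copy(),
        observed=m.observed.loc[idx].copy(),
        features=m.features.loc[idx].copy() if len(m.features) else m.features,
    )


def impute_missing(
    m: IntensityMatrix, shift: float = 1.8, width: float = 0.3, seed: int = 0
) -> IntensityMatrix:
    """Fill missing cells from a down-shifted Gaussian, per sample.

    For each sample the observed log2 values give (mean, SD); missing
    cells are drawn i.i.d. from Normal(mean - shift*SD, (width*SD)^2),
    the usual model for signal below the detection limit.  Observed cells
    and the observed mask are untouched.  Deterministic for a fixed seed.
    """
    obs_counts = m.observed.sum(axis=0)
    if (obs_counts < 2).any():
        bad = list(obs_counts.index[obs_counts < 2])
        raise ValueError(f"samples need >= 2 observed values to impute: {bad}")
    rng = np.random.default_rng(seed)
    vals = m.values.to_numpy(float).copy()
    obs = m.observed.to_numpy(bool)
    for j, sample in enumerate(m.values.columns):
        col_obs = vals[obs[:, j], j]
        mu, sd = col_obs.mean(), col_obs.std(ddof=1)
        miss = ~obs[:, j]
        n_miss = int(miss.sum())
        if n_miss:
            vals[miss, j] = rng.normal(mu - shift * sd, width * sd, size=n_miss)
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(values=out, observed=m.observed.copy(), features=m.features.copy())


def missingness_report(m: IntensityMatrix) -> dict:
    """Overall and per-sample missing fractions (from the observed mask)."""
    obs = m.observed.to_numpy(bool)
    total = obs.size
    overall = 1.0 - obs.sum() / total if total else 0.0
    per_sample = (1.0 - m.observed.mean(axis=0)).to_dict()
    return {"overall": float(overall), "per_sample": per_sample}


def read_quant_table(path) -> pd.DataFrame:
    """Read a quantified-peptides style TSV into long quant rows.

    Accepts either the long format written by this package
    (protein_accession, site_1based, residue, glycan, peptide, sample_id,
    intensity) or a wide table with ``Intensity_<run>`` columns keyed by
    Sequence / Protein Groups / Site / Glycan.
    """
    df = pd.read_csv(path, sep="\t")
    if "intensity" in df.columns and "sample_id" in df.columns:
        return df
    int_cols = [c for c in df.columns if c.startswith("Intensity_")]
    if not int_cols:
        raise ValueError(f"{path}: neither long-format nor Intensity_<run> columns found")
    rename = {
        "Protein Groups": "protein_accession",
        "Sequence": "peptide",
        "Site": "site_1based",
        "Residue": "residue",
        "Glycan": "glycan",
        "Mod Class": "mod_class",
    }
    id_cols = [c for c in rename if c in df.columns]
    long = df.melt(id_vars=id_cols, value_vars=int_cols, var_name="sample_id", value_name="intensity")
    long["sample_id"] = long["sample_id"].str.removeprefix("Intensity_")
    return long.rename(columns=rename)


def write_matrix(m: IntensityMatrix, path) -> None:
    """Write the matrix as TSV: feature key + annotation + sample columns."""
    out = pd.concat([m.features, m.values], axis=1)
    out.index.name = "glycopeptiform_key"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_quant_rows(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False, float_format="%.10g")
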