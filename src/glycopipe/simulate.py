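"""Synthetic cohorts, intensity matrices, and PSM tables with known truth.

The generator emulates the statistical structure the analysis assumes: a
small two-group longitudinal cohort (8 decliners vs 14 non-decliners,
two visits each), log-normal glycopeptiform intensities with subject
random intercepts, planted group and group x time effects, ~36%
intensity-dependent left-censored missingness, ~45% glycated (single
hexose on lysine) features, and engine-score distributions separating
target from decoy PSMs.  Every planted effect and censored cell is
recorded in a :class:`GroundTruth`, so downstream tests can score
recovery exactly.

All randomness flows from one master seed; each stage derives its own
substream as ``default_rng([seed, STREAM])`` with the fixed stream ids
below, so any stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glycans import GlycanDatabase, builtin_glycan_database
from .quant import IntensityMatrix, validate_sample_meta

__all__ = [
    "PSMSimConfig",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_intensity_matrix",
    "simulate_psm_table",
    "write_synthetic_bundle",
]

# substream ids (see module docstring)
STREAM_COHORT = 1
STREAM_FEATURES = 2
STREAM_MATRIX = 3
STREAM_PSM = 4
STREAM_PATHWAYS = 5


@dataclass(frozen=True)
class PSMSimConfig:
    """Score distributions for the simulated search-engine output.

    Correct targets draw from the high-scoring distributions; decoys and
    the ``frac_incorrect`` share of targets draw from the low ones.
    Tuples are (mean, sd) of normals; engine Scores are clipped at 0.
    """

    n_targets: int = 5000
    n_decoys: int = 500
    frac_incorrect: float = 0.05
    target_log_p: tuple[float, float] = (5.0, 1.2)
    decoy_log_p: tuple[float, float] = (1.5, 1.0)
    target_delta_mod: tuple[float, float] = (15.0, 5.0)
    decoy_delta_mod: tuple[float, float] = (3.0, 2.5)
    target_score: tuple[float, float] = (400.0, 120.0)
    decoy_score: tuple[float, float] = (120.0, 60.0)
    n_runs: int = 44


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort and intensity-model parameters (study-scale defaults)."""

    n_decliners: int = 8
    n_nondecliners: int = 14
    n_features: int = 3000
    n_proteins: int = 300
    frac_glycated: float = 0.45
    frac_missing_target: float = 0.36
    censor_scale: float = 1.0
    n_true_baseline_effects: int = 150
    baseline_effect_log2: float = 2.0
    n_true_interaction_effects: int = 150
    interaction_effect_log2: float = 1.5
    time_effect_log2: float = 0.3
    subject_sd: float = 0.5
    residual_sd: float = 0.3
    feature_mean_range: tuple[float, float] = (18.0, 26.0)
    age_mean: float = 74.5
    age_sd: float = 2.5
    hba1c_mean: float = 6.7
    hba1c_sd: float = 0.55
    psm: PSMSimConfig = field(default_factory=PSMSimConfig)

    def __post_init__(self) -> None:
        for name in ("frac_glycated", "frac_missing_target"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_decliners", "n_nondecliners", "n_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by glycopeptiform."""

    features: pd.DataFrame
    baseline_effects: pd.Series
    interaction_effects: pd.Series
    censored: pd.DataFrame
    clean_values: pd.DataFrame


def simulate_cohort(cfg: SimulationConfig, seed: int = 0) -> pd.DataFrame:
    """Draw the sample metadata: two visits for every subject."""
    rng = np.random.default_rng([seed, STREAM_COHORT])
    n = cfg.n_decliners + cfg.n_nondecliners
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    groups = ["decliner"] * cfg.n_decliners + ["non-decliner"] * cfg.n_nondecliners
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    hba1c = rng.normal(cfg.hba1c_mean, cfg.hba1c_sd, n)
    rows = []
    for i, subj in enumerate(subjects):
        for tp in ("T1", "T2"):
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "subject_id": subj,
                    "group": groups[i],
                    "timepoint": tp,
                    "baseline_age": round(float(age[i]), 2),
                    "mean_hba1c": round(float(hba1c[i]), 3),
                }
            )
    return validate_sample_meta(pd.DataFrame(rows))


def _simulate_features(cfg: SimulationConfig, seed: int, db: GlycanDatabase) -> pd.DataFrame:
    """Assign each feature a protein, site, modification class and glycan."""
    rng = np.random.default_rng([seed, STREAM_FEATURES])
    proteins = [f"P{i + 1:05d}" for i in range(cfg.n_proteins)]
    # Zipf-ish protein weights: a few proteins carry many glycopeptiforms
    w = 1.0 / np.arange(1, cfg.n_proteins + 1) ** 0.7
    w /= w.sum()
    glycans = [g.render() for g in db.targets]
    n_gly = int(round(cfg.frac_glycated * cfg.n_features))
    rows: list[dict] = []
    seen: set[tuple] = set()
    attempts = 0
    while len(rows) < cfg.n_features:
        attempts += 1
        if attempts > 50 * cfg.n_features:
            raise RuntimeError("could not generate enough unique glycopeptiforms")
        acc = proteins[int(rng.choice(cfg.n_proteins, p=w))]
        glycated = len(rows) < n_gly
        if glycated:
            site = int(rng.integers(1, 600))
            residue, mod_class, glycan = "K", "glycation", "Hex(1)"
        else:
            site = int(rng.integers(1, 600))
            residue, mod_class = "N", "glycosylation"
            glycan = glycans[int(rng.integers(len(glycans)))]
        key = (acc, site, glycan)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "glycopeptiform_key": f"{acc}|{site}|{glycan}",
                "protein_accession": acc,
                "site_1based": site,
                "residue": residue,
                "mod_class": mod_class,
                "glycan": glycan,
                "peptide": "",
            }
        )
    return pd.DataFrame(rows).set_index("glycopeptiform_key")


def _censor_midpoint(y: np.ndarray, target: float, scale: float) -> float:
    """Bisection for the logistic-censoring midpoint hitting the target rate."""
    lo, hi = y.min() - 30.0, y.max() + 30.0
    for _ in range(200):
        c = 0.5 * (lo + hi)
        rate = float(np.mean(1.0 / (1.0 + np.exp((y - c) / scale))))
        if rate < target:
            lo = c
        else:
            hi = c
    return 0.5 * (lo + hi)


def simulate_intensity_matrix(
    meta: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int = 0,
    glycan_db: GlycanDatabase | None = None,
) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate the log2 intensity matrix with planted effects and MNAR holes.

    Per feature f and sample s of subject i at visit t:
    ``y = mu_f + b_{f,i} + beta_f * decliner + gamma * T2
    + delta_f * decliner * T2 + eps`` with
    ``b ~ N(0, subject_sd^2)`` and ``eps ~ N(0, residual_sd^2)``.
    beta is non-zero for ``n_true_baseline_effects`` features and delta
    for ``n_true_interaction_effects`` (random signs).  Missingness is
    intensity-dependent left censoring: cell (f, s) is removed with
    probability ``sigmoid((c - y)/censor_scale)`` where c is calibrated
    by bisection so the overall missing fraction matches the target.
    """
    if glycan_db is None:
        glycan_db = builtin_glycan_database()
    features = _simulate_features(cfg, seed, glycan_db)
    keys = features.index
    F = len(keys)
    samples = meta["sample_id"].astype(str).tolist()
    subjects = meta["subject_id"].astype(str).to_numpy()
    subj_ids, subj_idx = np.unique(subjects, return_inverse=True)
    decliner = (meta["group"] == "decliner").to_numpy(float)
    t2 = (meta["timepoint"] == "T2").to_numpy(float)

    rng = np.random.default_rng([seed, STREAM_MATRIX])
    mu = rng.uniform(*cfg.feature_mean_range, F)
    beta = np.zeros(F)
    delta = np.zeros(F)
    nb = min(cfg.n_true_baseline_effects, F)
    ni = min(cfg.n_true_interaction_effects, F)
    b_idx = rng.choice(F, nb, replace=False)
    i_idx = rng.choice(F, ni, replace=False)
    beta[b_idx] = cfg.baseline_effect_log2 * rng.choice([-1.0, 1.0], nb)
    delta[i_idx] = cfg.interaction_effect_log2 * rng.choice([-1.0, 1.0], ni)

    b_subj = rng.normal(0.0, cfg.subject_sd, (F, len(subj_ids)))
    eps = rng.normal(0.0, cfg.residual_sd, (F, len(samples)))
    y = (
        mu[:, None]
        + b_subj[:, subj_idx]
        + beta[:, None] * decliner[None, :]
        + cfg.time_effect_log2 * t2[None, :]
        + delta[:, None] * (decliner * t2)[None, :]
        + eps
    )

    if cfg.frac_missing_target > 0:
        c = _censor_midpoint(y.ravel(), cfg.frac_missing_target, cfg.censor_scale)
        p_miss = 1.0 / (1.0 + np.exp((y - c) / cfg.censor_scale))
        miss = rng.random(y.shape) < p_miss
        achieved = float(miss.mean())
        if abs(achieved - cfg.frac_missing_target) > 0.1:
            raise RuntimeError(
                f"censoring achieved {achieved:.2f} missing vs target "
                f"{cfg.frac_missing_target:.2f}; adjust censor_scale"
            )
    else:
        miss = np.zeros(y.shape, bool)

    values = pd.DataFrame(np.where(miss, np.nan, y), index=keys, columns=samples)
    observed = pd.DataFrame(~miss, index=keys, columns=samples)
    matrix = IntensityMatrix(values=values, observed=observed, features=features)
    truth = GroundTruth(
        features=features,
        baseline_effects=pd.Series(beta, index=keys, name="beta"),
        interaction_effects=pd.Series(delta, index=keys, name="delta"),
        censored=pd.DataFrame(miss, index=keys, columns=samples),
        clean_values=pd.DataFrame(y, index=keys, columns=samples),
    )
    return matrix, truth


def simulate_psm_table(
    cfg: SimulationConfig,
    seed: int = 0,
    glycan_db: GlycanDatabase | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a search-engine PSM table with known correctness labels.

    Correct targets draw high scores; decoys and a ``frac_incorrect``
    share of targets share the decoy score distribution.  Returns the
    canonical PSM table plus a separate boolean ``is_correct`` series
    (the ground truth the FDR pipeline is scored against).
    """
    p = cfg.psm
    if p.n_targets < 1 or p.n_decoys < 0:
        raise ValueError("need >= 1 target and >= 0 decoys")
    if p.target_log_p[1] == 0 and p.target_delta_mod[1] == 0:
        raise ValueError("degenerate score distributions: both predictor SDs are zero")
    if glycan_db is None:
        glycan_db = builtin_glycan_database()
    rng = np.random.default_rng([seed, STREAM_PSM])
    n = p.n_targets + p.n_decoys
    is_decoy = np.zeros(n, bool)
    is_decoy[p.n_targets:] = True
    n_incorrect = int(round(p.frac_incorrect * p.n_targets))
    is_correct = np.zeros(n, bool)
    correct_idx = rng.choice(p.n_targets, p.n_targets - n_incorrect, replace=False)
    is_correct[correct_idx] = True

    def draw(mean_sd_hi, mean_sd_lo):
        hi = rng.normal(*mean_sd_hi, n)
        lo = rng.normal(*mean_sd_lo, n)
        return np.where(is_correct, hi, lo)

    log_p = draw(p.target_log_p, p.decoy_log_p)
    delta_mod = draw(p.target_delta_mod, p.decoy_delta_mod)
    score = np.clip(draw(p.target_score, p.decoy_score), 0.0, None)

    targets = [g.render() for g in glycan_db.targets]
    decoy_glycans = [g.render() for g in glycan_db.decoys] or targets
    glycan_is_decoy = is_decoy & (rng.random(n) < 0.5)  # half the decoys via glycan list
    glycans = np.where(
        glycan_is_decoy,
        rng.choice(decoy_glycans, n),
        rng.choice(targets, n),
    )
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    peptides = ["".join(rng.choice(aa, int(rng.integers(8, 20)))) for _ in range(n)]
    run_ids = [f"run{(i % p.n_runs) + 1:02d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "spectrum_id": [f"sc{i + 1:06d}" for i in range(n)],
            "run_id": run_ids,
            "peptide": peptides,
            "protein_accession": [f"P{int(rng.integers(1, 400)):05d}" for _ in range(n)],
            "site_1based": rng.integers(1, 500, n),
            "residue": rng.choice(["N", "K"], n),
            "glycan": glycans,
            "score": score,
            "log_p": log_p,
            "delta_mod": delta_mod,
            "is_decoy": is_decoy,
            "is_seq_decoy": is_decoy & ~glycan_is_decoy,
            "is_glycan_decoy": glycan_is_decoy,
            "precursor_intensity": np.exp(rng.normal(14.0, 1.5, n)),
        }
    )
    perm = rng.permutation(n)
    table = table.iloc[perm].reset_index(drop=True)
    truth = pd.Series(is_correct[perm], name="is_correct")
    return table, truth


def simulate_pathways(
    features: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    pathway_size: int = 25,
) -> list[tuple[str, str, list[str]]]:
    """Random pathway partition plus one pathway enriched in planted hits."""
    rng = np.random.default_rng([seed, STREAM_PATHWAYS])
    universe = sorted(features["protein_accession"].unique())
    shuffled = list(rng.permutation(universe))
    pathways = []
    for i in range(0, len(shuffled), pathway_size):
        chunk = shuffled[i : i + pathway_size]
        if len(chunk) >= 3:
            pathways.append((f"PW{i // pathway_size + 1:03d}", "random pathway", chunk))
    planted = truth.interaction_effects[truth.interaction_effects != 0].index
    planted_prot = sorted(features.loc[features.index.isin(planted), "protein_accession"].unique())
    if len(planted_prot) >= 3:
        pathways.append(("PW_TRUE_RATE", "proteins with planted rate effects", planted_prot))
    return pathways


def write_synthetic_bundle(
    out_dir, cfg: SimulationConfig | None = None, seed: int = 0
) -> dict[str, Path]:
    """Write a full synthetic input bundle in the pipeline's file dialects.

    Emits the PSM TSV, long-format quant TSV (raw intensities, censored
    cells absent), metadata CSV, target/decoy glycan lists, a GMT file,
    and ground-truth tables.  Synthetic and real inputs are
    interchangeable: the pipeline readers accept both.
    """
    cfg = cfg or SimulationConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = builtin_glycan_database()
    meta = simulate_cohort(cfg, seed)
    matrix, truth = simulate_intensity_matrix(meta, cfg, seed, glycan_db=db)
    psms, psm_truth = simulate_psm_table(cfg, seed, glycan_db=db)

    paths = {k: out_dir / v for k, v in {
        "psm": "psms.tsv",
        "quant": "quant.tsv",
        "meta": "meta.csv",
        "targets": "glycans_target.txt",
        "decoys": "glycans_decoy.txt",
        "gmt": "pathways.gmt",
        "truth_effects": "truth_effects.tsv",
        "truth_psm": "truth_psm.tsv",
    }.items()}

    psms.to_csv(paths["psm"], sep="\t", index=False, float_format="%.6g")
    long = matrix.values.where(matrix.observed).stack().rename("log2_intensity").reset_index()
    long.columns = ["glycopeptiform_key", "sample_id", "log2_intensity"]
    feat = matrix.features.reset_index()
    long = long.merge(feat, on="glycopeptiform_key")
    long["intensity"] = 2.0 ** long["log2_intensity"]
    long[
        ["protein_accession", "site_1based", "residue", "mod_class", "glycan", "peptide",
         "sample_id", "intensity"]
    ].to_csv(paths["quant"], sep="\t", index=False, float_format="%.10g")
    meta.to_csv(paths["meta"], index=False)
    paths["targets"].write_text(
        "# synthetic target glycan panel\n" + "\n".join(g.render() for g in db.targets) + "\n"
    )
    paths["decoys"].write_text(
        "# synthetic decoy glycan panel\n" + "\n".join(g.render() for g in db.decoys) + "\n"
    )
    with open(paths["gmt"], "wt") as fh:
        for pid, desc, members in simulate_pathways(matrix.features, truth, seed):
            fh.write("\t".join([pid, desc, *members]) + "\n")
    effects = pd.DataFrame(
        {
            "baseline_effect": truth.baseline_effects,
            "interaction_effect": truth.interaction_effects,
        }
    )
    effects.index.name = "glycopeptiform_key"
    effects.to_csv(paths["truth_effects"], sep="\t", float_format="%.6g")
    pd.DataFrame({"is_correct": psm_truth}).to_csv(paths["truth_psm"], sep="\t", index=False)
    return paths
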