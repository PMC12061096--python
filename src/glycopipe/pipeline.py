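"""End-to-end pipeline: PSM FDR -> matrix -> differential -> enrichment.

Stages run in the fixed order of the workflow; each reads/writes plain
TSV/CSV/GMT/JSON only, every output carries the configuration hash and
seed, and re-running with identical inputs and seed reproduces
byte-identical tabular outputs.  Any stage failure aborts with the stage
name and a machine-readable error code.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import enrichment as enr
from . import psm as psm_mod
from . import quant as quant_mod

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger("glycopipe")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All paths and thresholds of one pipeline run.

    The fixed analysis constants default to the workflow's published
    operating point: decoy-FDR < 1%, Score > 200, imputation shift 1.8
    SD / width 0.3 SD, 70% valid values in at least one group, baseline
    significance at p < 0.05 with a two-fold change, rate significance
    at p < 0.05, and enrichment at q < 1e-3.  ``provenance`` holds
    free-text upstream search settings, recorded but unused.
    """

    psm_path: str | None = None
    glycan_targets_path: str | None = None
    glycan_decoys_path: str | None = None
    quant_path: str | None = None
    meta_path: str | None = None
    gmt_path: str | None = None

    fdr_target: float = 0.01
    score_min: float = 200.0
    min_frac: float = 0.70
    baseline_p_max: float = 0.05
    min_abs_log2fc: float = 1.0
    rate_p_max: float = 0.05
    ora_q_max: float = 1e-3
    impute_shift: float = 1.8
    impute_width: float = 0.3
    adjust_age_baseline: bool = False
    lmm_engine: str = "auto"
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, lo, hi in (
            ("fdr_target", 0.0, 1.0),
            ("min_frac", 0.0, 1.0),
            ("baseline_p_max", 0.0, 1.0),
            ("rate_p_max", 0.0, 1.0),
            ("ora_q_max", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise StageError("config", "validation", f"{name}={v} outside [{lo}, {hi}]")
        if self.score_min < 0 or self.impute_width <= 0 or self.min_abs_log2fc < 0:
            raise StageError("config", "validation", "negative threshold")
        if self.meta_path is None:
            raise StageError("config", "validation", "meta_path is required")
        if self.psm_path is None and self.quant_path is None:
            raise StageError("config", "validation", "need psm_path or quant_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", "validation", f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _header(cfg: PipelineConfig) -> str:
    return f"# glycopipe config={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = True) -> None:
    with open(path, "wt", newline="") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def _write_json(obj: dict, path: Path, cfg: PipelineConfig) -> None:
    obj = {"config": cfg.config_hash(), "seed": cfg.seed, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_pipeline_tsv(path, index_col=0) -> pd.DataFrame:
    """Read a pipeline-written TSV, skipping the provenance header line."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


@dataclass
class PipelineResult:
    """In-memory handles plus the written file manifest of one run."""

    out_dir: Path
    files: dict[str, Path]
    fdr_report: dict | None
    results: pd.DataFrame | None
    counts: dict
    overlap: dict | None
    enrichment: dict[str, pd.DataFrame] | None
    timings: dict[str, float]


def run_pipeline(cfg: PipelineConfig, out_dir) -> PipelineResult:
    """Execute all stages and write the result bundle under ``out_dir``."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    timings: dict[str, float] = {}

    # ---- stage 1: PSM FDR -------------------------------------------------
    t0 = time.perf_counter()
    fdr_report = None
    filtered_psms = None
    if cfg.psm_path is not None:
        try:
            psms = psm_mod.read_psm_table(cfg.psm_path)
            n_in = len(psms)
            model, scored = psm_mod.fit_pscore(psms)
            threshold, passed = psm_mod.choose_pscore_threshold(scored, cfg.fdr_target)
            filtered_psms = psm_mod.apply_hard_filters(passed, cfg.score_min)
            eff_fdr = psm_mod.estimate_effective_fdr(filtered_psms)
            fdr_report = {
                "n_psms_in": n_in,
                "n_after_pscore": len(passed),
                "n_after_score_filter": len(filtered_psms),
                "pscore_threshold": threshold,
                "effective_fdr": eff_fdr,
                "per_class_fdr": psm_mod.per_class_fdr(filtered_psms),
                "model": {
                    "intercept": model.intercept,
                    "coef_log_p": model.coef_log_p,
                    "coef_delta_mod": model.coef_delta_mod,
                },
            }
            files["filtered_psms"] = out_dir / "filtered_psms.tsv"
            _write_tsv(filtered_psms.drop(columns=["pscore"]).assign(pscore=filtered_psms["pscore"]),
                       files["filtered_psms"], cfg, index=False)
            files["quant_input"] = out_dir / "quant_input.tsv"
            psm_mod.export_quant_input(filtered_psms, files["quant_input"])
            files["fdr_report"] = out_dir / "fdr_report.json"
            _write_json(fdr_report, files["fdr_report"], cfg)
            log.info("psm_fdr: %d -> %d PSMs (threshold %.4f, effective FDR %.4f)",
                     n_in, len(filtered_psms), threshold, eff_fdr)
        except StageError:
            raise
        except Exception as e:
            raise StageError("psm_fdr", "data", str(e)) from e
    timings["psm_fdr"] = time.perf_counter() - t0

    # ---- stage 2: quant matrix -------------------------------------------
    t0 = time.perf_counter()
    try:
        meta = quant_mod.read_sample_meta(cfg.meta_path)
        if cfg.quant_path is not None:
            quant_rows = quant_mod.read_quant_table(cfg.quant_path)
        elif filtered_psms is not None:
            quant_rows = psm_mod.summarize_psm_intensities(filtered_psms)
        else:
            raise StageError("quant_matrix", "validation", "no quantification input available")
        matrix = quant_mod.build_intensity_matrix(quant_rows, meta)
        matrix = quant_mod.normalize_matrix(matrix)
        miss = quant_mod.missingness_report(matrix)
        imputed = quant_mod.impute_missing(
            matrix, shift=cfg.impute_shift, width=cfg.impute_width, seed=cfg.seed
        )
        # baseline analysis: T1 samples, >= min_frac observed in one group
        t1_samples = [
            s for s in imputed.values.columns
            if s in set(meta.loc[meta["timepoint"] == "T1", "sample_id"].astype(str))
        ]
        m_t1 = quant_mod.IntensityMatrix(
            imputed.values[t1_samples], imputed.observed[t1_samples], imputed.features
        )
        m_t1 = quant_mod.filter_valid_values(m_t1, meta, cfg.min_frac, "group")
        # rate analysis: all samples, >= min_frac in one group x time cell
        m_rate = quant_mod.filter_valid_values(imputed, meta, cfg.min_frac, "group_time")
        files["missingness"] = out_dir / "missingness.json"
        _write_json(
            {
                "overall_missing": miss["overall"],
                "per_sample_missing": miss["per_sample"],
                "n_features_quantified": matrix.n_features,
                "n_features_baseline": m_t1.n_features,
                "n_features_rate": m_rate.n_features,
            },
            files["missingness"], cfg,
        )
        files["matrix_baseline"] = out_dir / "matrix_baseline.tsv"
        files["matrix_rate"] = out_dir / "matrix_rate.tsv"
        with open(files["matrix_baseline"], "wt") as fh:
            fh.write(_header(cfg))
            quant_mod.write_matrix(m_t1, fh)
        with open(files["matrix_rate"], "wt") as fh:
            fh.write(_header(cfg))
            quant_mod.write_matrix(m_rate, fh)
        log.info("quant_matrix: %d features (%.1f%% missing) -> %d baseline / %d rate",
                 matrix.n_features, 100 * miss["overall"], m_t1.n_features, m_rate.n_features)
    except StageError:
        raise
    except Exception as e:
        raise StageError("quant_matrix", "data", str(e)) from e
    timings["quant_matrix"] = time.perf_counter() - t0

    # ---- stage 3: differential -------------------------------------------
    t0 = time.perf_counter()
    try:
        covs = ["mean_hba1c"] + (["baseline_age"] if cfg.adjust_age_baseline else [])
        base = diff.baseline_differential(m_t1, meta, covariates=covs)
        rate = diff.rate_of_change_lmm(m_rate, meta, engine=cfg.lmm_engine)
        results = pd.DataFrame(index=sorted(set(base.index) | set(rate.index)))
        ann = pd.concat([m_t1.features, m_rate.features])
        ann = ann[~ann.index.duplicated()]
        results = results.join(ann)
        results["baseline_log2fc"] = base["log2fc"]
        results["baseline_p"] = base["p"]
        results["baseline_q"] = base["q"]
        results["rate_effect"] = rate["effect"]
        results["rate_p"] = rate["p"]
        results["rate_q"] = rate["q"]
        results["rate_method"] = rate["method"]
        results, counts = diff.call_significance(
            results, cfg.baseline_p_max, cfg.min_abs_log2fc, cfg.rate_p_max
        )
        results["t1_fold_change"] = [
            diff.signed_fold_change(v) if np.isfinite(v) else np.nan
            for v in results["baseline_log2fc"].astype(float)
        ]
        results.index.name = "glycopeptiform_key"
        overlap = diff.overlap_biomarkers(results)
        counts["glycated_pct_baseline"] = diff.glycation_proportion(m_t1.features)[0]
        counts["glycated_pct_rate"] = diff.glycation_proportion(m_rate.features)[0]
        mult = diff.multiplicity_stats(m_rate.features.reset_index())

        files["differential"] = out_dir / "differential_results.tsv"
        _write_tsv(results, files["differential"], cfg)
        files["volcano_baseline"] = out_dir / "volcano_baseline.tsv"
        _write_tsv(diff.volcano_table(results, "baseline"), files["volcano_baseline"], cfg, index=False)
        files["volcano_rate"] = out_dir / "volcano_rate.tsv"
        _write_tsv(diff.volcano_table(results, "rate"), files["volcano_rate"], cfg, index=False)
        files["venn"] = out_dir / "venn.json"
        _write_json(
            {
                "baseline_only": overlap["venn"][0],
                "rate_only": overlap["venn"][1],
                "both": overlap["venn"][2],
                "counts": counts,
            },
            files["venn"], cfg,
        )
        biomarkers = results.loc[results["sig_baseline"] & results["sig_rate"]]
        files["biomarkers"] = out_dir / "biomarkers.tsv"
        _write_tsv(
            biomarkers[
                ["protein_accession", "site_1based", "residue", "mod_class", "glycan",
                 "rate_effect", "rate_p", "t1_fold_change", "baseline_p"]
            ].sort_values(["protein_accession", "site_1based"], kind="stable"),
            files["biomarkers"], cfg,
        )
        files["multiplicity"] = out_dir / "multiplicity.json"
        _write_json({k: v for k, v in mult.items()}, files["multiplicity"], cfg)
        log.info("differential: %d baseline-sig, %d rate-sig, %d overlap",
                 counts["n_sig_baseline"], counts["n_sig_rate"], counts["n_overlap"])
    except StageError:
        raise
    except Exception as e:
        raise StageError("differential", "data", str(e)) from e
    timings["differential"] = time.perf_counter() - t0

    # ---- stage 4: enrichment ---------------------------------------------
    t0 = time.perf_counter()
    enrichment = None
    if cfg.gmt_path is not None:
        try:
            pathways = enr.read_gmt(cfg.gmt_path)
            background = set(m_rate.features["protein_accession"].astype(str))
            hit_lists = enr.split_hit_lists(results)
            enrichment = {}
            tables = []
            for name, hits in sorted(hit_lists.items()):
                tab = enr.ora_hypergeometric(hits & background, background, pathways, cfg.ora_q_max)
                tab.insert(0, "hit_list", name)
                enrichment[name] = tab
                tables.append(tab)
            files["enrichment"] = out_dir / "enrichment.tsv"
            _write_tsv(pd.concat(tables, ignore_index=True), files["enrichment"], cfg, index=False)
            log.info("enrichment: %d pathways tested against %d-protein background",
                     len(pathways), len(background))
        except StageError:
            raise
        except Exception as e:
            raise StageError("enrichment", "data", str(e)) from e
    timings["enrichment"] = time.perf_counter() - t0

    files["manifest"] = out_dir / "manifest.json"
    _write_json(
        {
            "files": {k: str(v.name) for k, v in files.items() if k != "manifest"},
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "counts": counts,
        },
        files["manifest"], cfg,
    )
    return PipelineResult(
        out_dir=out_dir,
        files=files,
        fdr_report=fdr_report,
        results=results,
        counts=counts,
        overlap=overlap,
        enrichment=enrichment,
        timings=timings,
    )
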