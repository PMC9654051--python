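"""End-to-end orchestration: simulate -> FPKM/filter -> DE -> weights ->
signature -> multivariate -> report.

Every run resolves its configuration, derives one RNG seed per stage from the
master seed (stable hash of ``"{seed}:{stage}"``), writes each artifact as
tab-separated text or JSON, and finishes with a manifest of output files and
their SHA-256 checksums — identical config + seed reproduces identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import (
    CountMatrix,
    assemble_mined_table,
    compute_fpkm,
    filter_low_expression,
    read_counts,
    read_metadata,
    validate_design,
    write_counts,
    write_metadata,
    write_mined_table,
)
from .diffexp import DEOptions, fold_change_wide, run_de_all_tissues
from .multivariate import cluster_similarity, pca_correlation
from .sexit import sexit_summary
from .signature import (
    format_signature_table,
    rank_and_top_k,
    sum_weights,
    tissue_independence_check,
)
from .synthetic import SyntheticConfig, generate_counts
from .weighting import WeightingConfig, run_all_models

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fpkm", "de", "weights", "signature", "multivariate", "sexit")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed by stage name, < 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; unknown keys are rejected."""

    outdir: str = "crsig_output"
    seed: int = 0
    # simulation (used when counts_path is unset)
    simulate: bool = True
    n_genes: int = 500
    n_per_cell: int = 5
    effect_fold: float = 3.0
    frac_signature: float = 0.02
    frac_tissue_dep: float = 0.02
    dispersion: float = 0.3
    # external inputs (used when simulate is False)
    counts_path: str | None = None
    metadata_path: str | None = None
    # stage parameters
    fpkm_threshold: float = 5.0
    n_bins: int = 5
    relief_k: int = 5
    top_k: int = 20
    top_n_multivariate: int = 40
    linkage: str = "complete"
    hdi_mass: float = 0.95
    rope_within_hdi: bool = False
    sd_y: float = 1.0
    draws_path: str | None = None  # optional JSON map {effect: [draws...]}
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info("crsignature %s, seed %d", __version__, config.seed)

    resolved = out / "resolved_config.yaml"
    resolved.write_text(
        yaml.safe_dump({**dataclasses.asdict(config), "version": __version__}, sort_keys=True)
    )
    artifacts: list[Path] = [resolved]
    failed_stage = None
    try:
        cm, meta = _load_inputs(config, out, artifacts)
        fpkm_kept = mined = None
        if "fpkm" in config.stages:
            fpkm = compute_fpkm(cm)
            fpkm_kept, removed = filter_low_expression(fpkm, config.fpkm_threshold)
            (out / "filtered_genes.json").write_text(
                json.dumps({"threshold": config.fpkm_threshold, "removed": removed}, indent=1)
            )
            mined = assemble_mined_table(fpkm_kept, meta)
            write_mined_table(mined, out / "mined_table.tsv")
            artifacts += [out / "filtered_genes.json", out / "mined_table.tsv"]

        de_long = None
        if "de" in config.stages:
            de_long = run_de_all_tissues(cm, meta, DEOptions())
            de_flat = de_long.reset_index()
            de_flat.to_csv(out / "de_results.tsv", sep="\t", index=False)
            fold_change_wide(de_long).to_csv(out / "de_fold_changes.tsv", sep="\t")
            artifacts += [out / "de_results.tsv", out / "de_fold_changes.tsv"]

        ranking = None
        if "weights" in config.stages:
            if mined is None:
                raise ValueError("weights stage requires the fpkm stage")
            wcfg = WeightingConfig(
                n_bins=config.n_bins, relief_k=config.relief_k,
                seed=stage_seed(config.seed, "weights"),
            )
            wm = run_all_models(mined, wcfg)
            wm.to_frame().to_csv(out / "weights.tsv", sep="\t", index_label="feature")
            artifacts.append(out / "weights.tsv")
            if "signature" in config.stages:
                top, ranking = rank_and_top_k(sum_weights(wm), config.top_k, wm)
                format_signature_table(top).to_csv(out / "signature.tsv", sep="\t", index=False)
                ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
                check = tissue_independence_check(ranking)
                (out / "tissue_check.json").write_text(json.dumps(check, indent=1))
                artifacts += [out / "signature.tsv", out / "ranking.tsv", out / "tissue_check.json"]

        if "multivariate" in config.stages and de_long is not None:
            _run_multivariate(config, de_long, out, artifacts)

        if "sexit" in config.stages and config.draws_path:
            draws_map = json.loads(Path(config.draws_path).read_text())
            summaries = {
                name: sexit_summary(
                    vals, sd_y=config.sd_y, mass=config.hdi_mass,
                    rope_within_hdi=config.rope_within_hdi,
                ).to_dict()
                for name, vals in draws_map.items()
            }
            (out / "sexit_summaries.json").write_text(json.dumps(summaries, indent=1))
            artifacts.append(out / "sexit_summaries.json")
    except Exception as exc:  # noqa: BLE001 - record failing stage, then re-raise
        failed_stage = type(exc).__name__
        logger.error("pipeline failed: %s", exc)
        _write_manifest(out, config, artifacts, failed=str(exc))
        raise

    manifest = _write_manifest(out, config, artifacts, failed=None)
    return manifest


def _load_inputs(config: PipelineConfig, out: Path, artifacts: list[Path]):
    if config.counts_path:
        cm = read_counts(config.counts_path)
        meta = read_metadata(config.metadata_path)
        validate_design(cm, meta)
        return cm, meta
    if not config.simulate:
        raise ValueError("either enable simulate or provide counts_path/metadata_path")
    scfg = SyntheticConfig(
        n_genes=config.n_genes, n_per_cell=config.n_per_cell,
        effect_fold=config.effect_fold, frac_signature=config.frac_signature,
        frac_tissue_dep=config.frac_tissue_dep, dispersion=config.dispersion,
        seed=stage_seed(config.seed, "simulate"),
    )
    cm, meta, truth = generate_counts(scfg)
    write_counts(cm, out / "counts.tsv")
    write_metadata(meta, out / "metadata.tsv")
    truth.to_json(out / "truth.json")
    artifacts += [out / "counts.tsv", out / "metadata.tsv", out / "truth.json"]
    return cm, meta


def _run_multivariate(config: PipelineConfig, de_long: pd.DataFrame, out: Path, artifacts: list[Path]):
    fc = fold_change_wide(de_long).dropna()
    if len(fc) < 2 or fc.shape[1] < 2:
        logger.warning("multivariate stage skipped: fold-change matrix too small")
        return
    # top-N genes by best (smallest) Wald p across tissues
    best_p = de_long["wald_p"].groupby("gene_id").min()
    top_genes = best_p.loc[fc.index].nsmallest(min(config.top_n_multivariate, len(fc))).index
    sub = fc.loc[top_genes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pca = pca_correlation(sub)
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)
            pca = None
    if pca is not None:
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca.explained.to_frame().to_csv(out / "pca_explained.tsv", sep="\t")
        artifacts += [out / "pca_loadings.tsv", out / "pca_scores.tsv", out / "pca_explained.tsv"]
    merges = cluster_similarity(sub, config.linkage)
    merges.to_csv(out / "cluster_merges.tsv", sep="\t", index=False)
    artifacts.append(out / "cluster_merges.tsv")


def _write_manifest(out: Path, config: PipelineConfig, artifacts: list[Path], failed: str | None) -> dict:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "failed": failed,
        "files": {p.name: _sha256(p) for p in artifacts if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
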