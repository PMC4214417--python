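"""End-to-end orchestration: images -> features -> models -> GWAS -> loci."""

from __future__ import annotations

import dataclasses
import logging
import pathlib

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from . import imaging, traits
from .io import (
    RunConfig,
    read_vcf,
    write_association,
    write_loci,
    write_provenance,
    write_thresholds,
)

logger = logging.getLogger("phenokit")

__all__ = ["ResultBundle", "features_stage", "train_stage", "gwas_stage", "run_pipeline"]


@dataclasses.dataclass
class ResultBundle:
    feature_table: pd.DataFrame | None = None
    selection: traits.SelectionReport | None = None
    association: "gwas_mod.AssociationResult | None" = None
    loci: "list[gwas_mod.ClumpedLocus] | None" = None
    thresholds: "gwas_mod.ThresholdPair | None" = None


def features_stage(
    image_groups: dict[str, list[np.ndarray]],
    config: RunConfig,
    stage_label: str = "",
) -> pd.DataFrame:
    """Extract and aggregate the descriptor catalogue per plant."""
    rows = []
    for plant_id, views in image_groups.items():
        per_view = [
            imaging.extract_view_features(
                img, min_object_px=config.min_object_px, levels=config.glcm_levels
            )
            for img in views
        ]
        vec = imaging.aggregate_views(
            per_view, plant_id=plant_id, stage=stage_label, how=config.view_aggregation
        )
        row = {"plant_id": plant_id, "stage": stage_label, "n_views": vec.n_views}
        row.update(vec.features)
        rows.append(row)
    return pd.DataFrame(rows)


def train_stage(
    table: pd.DataFrame,
    trait: str,
    config: RunConfig,
    morph_pool: list[str] | None = None,
    texture_pool: list[str] | None = None,
) -> tuple[traits.SelectionReport, traits.EvalMetrics]:
    """Split, search all families, select, and evaluate on the test half."""
    morph_pool = morph_pool or [
        c for c in table.columns if c in imaging.MORPH_FEATURE_NAMES
    ]
    texture_pool = texture_pool or [
        c for c in table.columns if c in imaging.TEXTURE_FEATURE_NAMES
    ]
    train, test = traits.split_train_test(
        table, fraction=config.train_fraction, seed=config.seed
    )
    report = traits.run_selection(
        train,
        trait,
        morph_pool,
        texture_pool,
        rel_press_margin=config.rel_press_margin,
        abs_adj_r2_margin=config.abs_adj_r2_margin,
    )
    metrics = traits.evaluate_predictions(report.chosen, test, trait)
    return report, metrics


def gwas_stage(
    G: "gwas_mod.GenotypeMatrix",
    phenotype: pd.Series,
    config: RunConfig,
    out_dir: str | pathlib.Path | None = None,
) -> ResultBundle:
    """Filter, kinship, scan, thresholds, clump — the full association chain."""
    aligned = phenotype.reindex(G.accessions)
    y = aligned.to_numpy(dtype=float)
    keep, dropped = gwas_mod.phenotype_preprocess(y, z_max=config.z_max)
    if dropped.size:
        logger.info("dropped %d phenotype outliers", dropped.size)
    keep_idx = np.flatnonzero(keep)
    G = gwas_mod.GenotypeMatrix(
        dosages=G.dosages[keep_idx],
        chrom=G.chrom,
        pos=G.pos,
        accessions=[G.accessions[i] for i in keep_idx],
        snp_ids=G.snp_ids,
        ref=G.ref,
        alt=G.alt,
    )
    y = y[keep_idx]

    G = gwas_mod.maf_filter(G, config.maf_min, config.mac_accessions_min)
    K = gwas_mod.kinship_identity_proportion(
        G, subset_size=min(config.kinship_subset, G.m), seed=config.seed
    )
    result = gwas_mod.lmm_scan(G, y, K, mode=config.lmm_mode)
    n_eff = gwas_mod.effective_marker_number(G, block_size=config.block_size)
    thresholds = gwas_mod.significance_thresholds(n_eff, alpha=config.alpha)
    loci = gwas_mod.clump_loci(
        result,
        G,
        p_threshold=thresholds.suggestive,
        r2_threshold=config.r2_threshold,
        window_kb=config.window_kb,
    )
    if config.peak_filter:
        loci = gwas_mod.peak_filter(
            loci,
            result,
            G,
            p_threshold=thresholds.suggestive,
            min_support=config.min_support,
            window_kb=config.window_kb,
        )
    bundle = ResultBundle(association=result, loci=loci, thresholds=thresholds)
    if out_dir is not None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_association(result, out_dir / "association.tsv")
        write_loci(loci, result, out_dir / "loci.tsv")
        write_thresholds(thresholds, out_dir / "thresholds.json")
        write_provenance(config, out_dir)
    return bundle


def run_pipeline(
    config: RunConfig,
    vcf: str | pathlib.Path,
    pheno_csv: str | pathlib.Path,
    trait: str,
    out_dir: str | pathlib.Path,
) -> ResultBundle:
    """File-level entry point for the genotype->loci part of the flow."""
    vcf = pathlib.Path(vcf)
    pheno_csv = pathlib.Path(pheno_csv)
    for path, name in ((vcf, "vcf"), (pheno_csv, "pheno")):
        if not path.exists():
            raise FileNotFoundError(f"missing required input '{name}': {path}")
    G, _ = read_vcf(vcf)
    pheno = pd.read_csv(pheno_csv).set_index("accession")
    if trait not in pheno.columns:
        raise ValueError(f"trait {trait!r} not found in {pheno_csv}")
    return gwas_stage(G, pheno[trait], config, out_dir=out_dir)
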