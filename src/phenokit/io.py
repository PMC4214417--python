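"""Readers, writers and the end-to-end pipeline configuration.

Table conventions: comma-separated for feature/trait tables, tab-separated
for association and loci tables.  Genotypes move as minimal VCF (biallelic
GT records) or as a TSV dosage matrix with a SNP-metadata sidecar.  Every
output directory receives a provenance JSON echoing the configuration and
its hash so identical runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from typing import Any

import numpy as np
import pandas as pd

from .gwas import AssociationResult, ClumpedLocus, GenotypeMatrix, ThresholdPair

logger = logging.getLogger("phenokit")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "write_association",
    "write_loci",
    "write_thresholds",
    "RunConfig",
    "write_provenance",
]

_MISSING = {".", "./.", ".|."}


def read_vcf(path: str | pathlib.Path) -> tuple[GenotypeMatrix, int]:
    """Parse a minimal uncompressed VCF into a dosage matrix.

    Only biallelic SNP records are used; others are skipped and counted.
    GT parsing tolerates ``/`` and ``|`` separators; any missing allele
    yields a missing dosage.  Returns ``(matrix, n_skipped)``.
    """
    path = pathlib.Path(path)
    samples: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[list[float]] = []
    snp_ids: list[str] = []
    skipped = 0
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError("malformed VCF header: no sample columns")
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError("VCF data before #CHROM header")
            fields = line.split("\t")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                skipped += 1
                continue
            fmt = fields[8].split(":")
            try:
                gt_at = fmt.index("GT")
            except ValueError:
                skipped += 1
                continue
            row = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_at]
                if gt in _MISSING or "." in gt:
                    row.append(np.nan)
                    continue
                alleles = gt.replace("|", "/").split("/")
                row.append(float(sum(int(a) for a in alleles)))
            chroms.append(chrom)
            positions.append(int(pos))
            refs.append(ref)
            alts.append(alt)
            snp_ids.append(vid if vid != "." else f"{chrom}:{pos}")
            rows.append(row)
    if not rows:
        raise ValueError("no usable biallelic SNP records in VCF")
    if skipped:
        logger.info("skipped %d non-biallelic/unsupported VCF records", skipped)
    matrix = GenotypeMatrix(
        dosages=np.array(rows, dtype=float).T,
        chrom=np.array(chroms),
        pos=np.array(positions, dtype=np.int64),
        accessions=samples,
        snp_ids=snp_ids,
        ref=np.array(refs),
        alt=np.array(alts),
    )
    return matrix, skipped


def write_vcf(G: GenotypeMatrix, path: str | pathlib.Path) -> None:
    """Write a dosage matrix as a minimal uncompressed VCF."""
    path = pathlib.Path(path)
    ref = G.ref if G.ref is not None else np.full(G.m, "A")
    alt = G.alt if G.alt is not None else np.full(G.m, "T")
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accessions)
            + "\n"
        )
        for j in range(G.m):
            gts = [
                "./." if np.isnan(d) else code[float(d)] for d in G.dosages[:, j]
            ]
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t{G.snp_ids[j]}\t{ref[j]}\t{alt[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_dosage_matrix(G: GenotypeMatrix, prefix: str | pathlib.Path) -> None:
    """TSV dosage matrix (accessions x SNPs) plus a SNP-metadata sidecar."""
    prefix = pathlib.Path(prefix)
    df = pd.DataFrame(G.dosages, index=G.accessions, columns=G.snp_ids)
    df.to_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", float_format="%.0f")
    meta = pd.DataFrame(
        {"snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos}
    )
    meta.to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)


def read_dosage_matrix(prefix: str | pathlib.Path) -> GenotypeMatrix:
    prefix = pathlib.Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        chrom=meta["chrom"].to_numpy(dtype=str),
        pos=meta["pos"].to_numpy(dtype=np.int64),
        accessions=[str(i) for i in df.index],
        snp_ids=[str(s) for s in meta["snp_id"]],
    )


def association_frame(result: AssociationResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": result.snp_ids,
            "chrom": result.chrom,
            "pos": result.pos,
            "beta": result.beta,
            "lr_stat": result.lr_stat,
            "p_value": result.p_value,
        }
    )


def write_association(result: AssociationResult, path: str | pathlib.Path) -> None:
    association_frame(result).to_csv(path, sep="\t", index=False, float_format="%.6g")


def loci_frame(loci: list[ClumpedLocus], result: AssociationResult) -> pd.DataFrame:
    rows = []
    for locus in loci:
        rows.append(
            {
                "lead_snp": result.snp_ids[locus.lead_index],
                "chrom": locus.lead_chrom,
                "lead_pos": locus.lead_pos,
                "lead_p": locus.lead_p,
                "n_members": len(locus.member_indices),
                "span_start": locus.span[0],
                "span_end": locus.span[1],
                "members": ";".join(result.snp_ids[i] for i in locus.member_indices),
            }
        )
    columns = [
        "lead_snp", "chrom", "lead_pos", "lead_p",
        "n_members", "span_start", "span_end", "members",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_loci(
    loci: list[ClumpedLocus], result: AssociationResult, path: str | pathlib.Path
) -> None:
    loci_frame(loci, result).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_thresholds(thresholds: ThresholdPair, path: str | pathlib.Path) -> None:
    with pathlib.Path(path).open("w") as fh:
        json.dump(
            {
                "effective_n": thresholds.effective_n,
                "suggestive": thresholds.suggestive,
                "significant": thresholds.significant,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


@dataclasses.dataclass
class RunConfig:
    """All stage parameters of a pipeline run; hashable for provenance."""

    seed: int = 0
    min_object_px: int = 64
    glcm_levels: int = 32
    view_aggregation: str = "mean"
    train_fraction: float = 0.5
    rel_press_margin: float = 0.05
    abs_adj_r2_margin: float = 0.01
    cv_folds: int = 10
    maf_min: float = 0.05
    mac_accessions_min: int = 6
    kinship_subset: int = 188165
    z_max: float = 3.0
    lmm_mode: str = "null_delta"
    block_size: int = 200
    alpha: float = 0.05
    r2_threshold: float = 0.25
    window_kb: int = 250
    peak_filter: bool = False
    min_support: int = 2

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(
    config: RunConfig, out_dir: str | pathlib.Path, extra: dict | None = None
) -> None:
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"config": config.to_dict(), "config_hash": config.hash()}
    if extra:
        record.update(extra)
    with (out_dir / "provenance.json").open("w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
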