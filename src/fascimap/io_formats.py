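"""Readers and writers for the formats the mapping pipeline consumes.

Variant sites come in as VCF with per-sample allelic depths (the ``AD``
FORMAT subfield), gene models as GFF3 or BED, and expression as a plain
genes × samples TSV of fragment counts.  All coordinates are held 1-based
inclusive internally; BED is converted at the boundary.  No statistics live
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARENT_GENOTYPES = ("hom_ref", "hom_alt", "het", "missing")


@dataclass
class AlleleDepthRecord:
    """One biallelic site with per-pool ref/alt read depths.

    ``depth_mut_*`` are read counts in the mutant-phenotype (fasciated-ear)
    bulk, ``depth_wt_*`` in the normal-ear bulk.  ``parent_gt`` is the
    mutant parent's genotype call at the site.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth_mut_ref: int
    depth_mut_alt: int
    depth_wt_ref: int
    depth_wt_alt: int
    parent_gt: str = "missing"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("depth_mut_ref", "depth_mut_alt", "depth_wt_ref", "depth_wt_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        if self.parent_gt not in PARENT_GENOTYPES:
            raise ValueError(f"parent_gt must be one of {PARENT_GENOTYPES}")


@dataclass
class GeneModel:
    """A gene span in 1-based inclusive coordinates plus its transcript length."""

    gene_id: str
    chrom: str
    start: int
    end: int
    length_bp: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates must be >= 1")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.length_bp == 0:
            self.length_bp = self.end - self.start + 1
        if self.length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: length_bp must be > 0")


@dataclass
class CountsMatrix:
    """Gene-level fragment counts for a two-condition, replicated design."""

    gene_ids: list[str]
    sample_ids: list[str]
    conditions: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicated gene id in counts matrix")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
            if (self.counts.sum(axis=0) > self.library_sizes).any():
                raise ValueError("column sums exceed declared library sizes")

    def columns(self, condition: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.conditions) if c == condition])


def _parse_gt(gt_indices: Sequence[int] | None) -> str:
    """Map a pair of VCF allele indices to a parent genotype label."""
    if gt_indices is None:
        return "missing"
    alleles = [a for a in gt_indices if a is not None and a >= 0]
    if len(alleles) < 2:
        return "missing"
    a, b = alleles[0], alleles[1]
    if a == b == 0:
        return "hom_ref"
    if a == b:
        return "hom_alt"
    return "het"


def read_allele_depths(
    path: str | Path,
    mut_pool_id: str,
    wt_pool_id: str,
    parent_id: str | None = None,
) -> list[AlleleDepthRecord]:
    """Read per-pool allelic depths from a VCF.

    One record per biallelic site; multiallelic sites are skipped with a
    logged count.  Missing ``AD`` fields yield depths of 0, a missing or
    absent parent genotype yields ``parent_gt='missing'``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (mut_pool_id, wt_pool_id):
        if name not in samples:
            raise KeyError(f"sample {name!r} not found in VCF (has {samples})")
    if parent_id is not None and parent_id not in samples:
        raise KeyError(f"parent sample {parent_id!r} not found in VCF (has {samples})")
    i_mut = samples.index(mut_pool_id)
    i_wt = samples.index(wt_pool_id)
    i_par = samples.index(parent_id) if parent_id is not None else None

    records: list[AlleleDepthRecord] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            dm_r = dm_a = dw_r = dw_a = 0
        else:
            ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
            dm_r, dm_a = int(ad[i_mut][0]), int(ad[i_mut][1])
            dw_r, dw_a = int(ad[i_wt][0]), int(ad[i_wt][1])
        if i_par is not None:
            parent_gt = _parse_gt(v.genotypes[i_par][:2])
        else:
            parent_gt = "missing"
        records.append(
            AlleleDepthRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                depth_mut_ref=dm_r,
                depth_mut_alt=dm_a,
                depth_wt_ref=dw_r,
                depth_wt_alt=dw_a,
                parent_gt=parent_gt,
            )
        )
    if n_multi:
        logger.info("skipped %d multiallelic site(s)", n_multi)
    return records


_GT_CODE = {"hom_ref": "0/0", "hom_alt": "1/1", "het": "0/1", "missing": "./."}


def write_allele_depths(
    records: Iterable[AlleleDepthRecord],
    path: str | Path,
    mut_pool_id: str = "mut_pool",
    wt_pool_id: str = "wt_pool",
    parent_id: str = "parent",
) -> None:
    """Write records as a minimal VCF with GT:AD per sample (round-trippable)."""
    records = list(records)
    chroms = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{mut_pool_id}\t{wt_pool_id}\t{parent_id}\n"
        )
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            par = _GT_CODE[r.parent_gt]
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.\t"
                f"GT:AD\t"
                f"./.:{r.depth_mut_ref},{r.depth_mut_alt}\t"
                f"./.:{r.depth_wt_ref},{r.depth_wt_alt}\t"
                f"{par}:0,0\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene spans from GFF3 (1-based inclusive) or BED (0-based half-open).

    Format is chosen by extension (``.bed`` vs anything else = GFF3).
    Output is sorted by (chrom, start); unsorted input is allowed.
    """
    path = Path(path)
    models = (
        _read_bed(path) if path.suffix.lower() == ".bed" else _read_gff3(path)
    )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


def _read_bed(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if start0 < 0:
                raise ValueError(f"{path}:{ln}: negative coordinate")
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            # BED half-open [start0, end0) -> 1-based inclusive [start0+1, end0]
            models.append(GeneModel(gene_id=name, chrom=chrom, start=start0 + 1, end=end0))
    return models


def _gff3_attr(attrs: str, key: str) -> str | None:
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def _read_gff3(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 line needs 9 fields")
            if parts[2] != "gene":
                continue
            start, end = int(parts[3]), int(parts[4])
            if start < 1 or end < 1:
                raise ValueError(f"{path}:{ln}: negative/zero coordinate")
            gid = (
                _gff3_attr(parts[8], "ID")
                or _gff3_attr(parts[8], "gene_id")
                or f"gene_{ln}"
            )
            gid = gid.removeprefix("gene:")
            models.append(GeneModel(gene_id=gid, chrom=parts[0], start=start, end=end))
    return models


def write_gene_models_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene spans as BED (converted back to 0-based half-open)."""
    with open(path, "w") as fh:
        for g in sorted(models, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def read_counts(
    path: str | Path,
    conditions: Sequence[str] | None = None,
    library_sizes: Sequence[int] | None = None,
) -> CountsMatrix:
    """Read a genes × samples TSV of integer fragment counts.

    First column holds gene ids, header row sample ids.  ``conditions``
    assigns a condition label per sample column; when omitted, labels are
    inferred from sample-id prefixes before the last underscore.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated gene id(s) in counts table: {dups}")
    bad = df.apply(lambda col: ~col.map(lambda x: float(x).is_integer()))
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-integer count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if conditions is None:
        conditions = [s.rsplit("_", 1)[0] for s in df.columns]
    return CountsMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        conditions=list(conditions),
        counts=df.values.astype(np.int64),
        library_sizes=None if library_sizes is None else np.asarray(library_sizes),
    )


def write_counts(matrix: CountsMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
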