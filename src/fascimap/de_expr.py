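"""Expression stage: FPKM, a log-CPM differential test, BH-FDR, DEG filters.

FPKM is fragments per kilobase of transcript per million mapped fragments:
count * 1e9 / (library_size * gene_length_bp).  The differential test is a
two-sample t-test on log2(CPM + 0.5) across replicates with the fold
change taken on mean CPM with the same pseudo-count — a deliberately
transparent test whose behaviour on the filter chain matches the standard
count-based tools at the effect sizes this pipeline targets.  Adjusted
p-values use the Benjamini–Hochberg step-up.

A gene is called differentially expressed when it is expressed
(max condition FPKM strictly above the floor, default 0.1), its |log2FC|
is at least 1, and its BH-adjusted p is at most 0.05.  Direction is
reported relative to normal ears: "up" means higher in normal than in the
mutant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountsMatrix, GeneModel

PSEUDO_COUNT = 0.5
FPKM_FLOOR = 0.1
LFC_MIN = 1.0
FDR_MAX = 0.05


@dataclass
class ExpressionRecord:
    gene_id: str
    fpkm_normal: float
    fpkm_mut: float
    log2fc: float  # log2(mutant / normal) on normalized abundance
    p_value: float
    fdr: float = np.nan
    is_deg: bool = False
    direction: str = ""  # 'up' | 'down' relative to normal ears


def fpkm(count: float, gene_length_bp: int, library_size: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count * 1e9 / (library_size * gene_length_bp)


def de_test(
    counts_normal: np.ndarray,
    counts_mut: np.ndarray,
    lib_normal: np.ndarray,
    lib_mut: np.ndarray,
    pseudo: float = PSEUDO_COUNT,
) -> tuple[float, float]:
    """log2 fold-change (mutant over normal) and two-sided p for one gene.

    log2FC = log2((mean CPM_mut + c) / (mean CPM_normal + c)); the p-value
    is a pooled-variance two-sample t-test on log2(CPM + c) per replicate
    (with 3 replicates per group, pooling keeps the residual df at
    n1 + n2 - 2; an unequal-variance test would be nearly powerless
    here).  All-zero genes return (0, 1).
    """
    counts_normal = np.asarray(counts_normal, dtype=float)
    counts_mut = np.asarray(counts_mut, dtype=float)
    if len(counts_normal) < 2 or len(counts_mut) < 2:
        raise ValueError("need >= 2 replicates per group")
    if counts_normal.sum() == 0 and counts_mut.sum() == 0:
        return 0.0, 1.0
    cpm_n = counts_normal / np.asarray(lib_normal, dtype=float) * 1e6
    cpm_m = counts_mut / np.asarray(lib_mut, dtype=float) * 1e6
    log2fc = float(np.log2((cpm_m.mean() + pseudo) / (cpm_n.mean() + pseudo)))
    x = np.log2(cpm_n + pseudo)
    y = np.log2(cpm_m + pseudo)
    if np.allclose(x.std(), 0) and np.allclose(y.std(), 0):
        p = 1.0 if np.allclose(x.mean(), y.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(y, x, equal_var=True).pvalue)
    return log2fc, p


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, stable under input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def expression_table(
    matrix: CountsMatrix,
    gene_lengths: dict[str, int] | list[GeneModel],
    normal_label: str = "normal",
    mut_label: str = "fea5",
) -> list[ExpressionRecord]:
    """Per-gene FPKM means, log2FC, p and BH-FDR for the full matrix."""
    if not isinstance(gene_lengths, dict):
        gene_lengths = {g.gene_id: g.length_bp for g in gene_lengths}
    cols_n = matrix.columns(normal_label)
    cols_m = matrix.columns(mut_label)
    if len(cols_n) == 0 or len(cols_m) == 0:
        raise ValueError("both condition labels must be present in the matrix")
    lib = matrix.library_sizes
    records = []
    for i, gid in enumerate(matrix.gene_ids):
        length = gene_lengths[gid]
        fp_n = np.mean(
            [fpkm(matrix.counts[i, j], length, lib[j]) for j in cols_n]
        )
        fp_m = np.mean(
            [fpkm(matrix.counts[i, j], length, lib[j]) for j in cols_m]
        )
        log2fc, p = de_test(
            matrix.counts[i, cols_n],
            matrix.counts[i, cols_m],
            lib[cols_n],
            lib[cols_m],
        )
        records.append(
            ExpressionRecord(
                gene_id=gid,
                fpkm_normal=float(fp_n),
                fpkm_mut=float(fp_m),
                log2fc=log2fc,
                p_value=p,
            )
        )
    fdrs = bh_fdr([r.p_value for r in records])
    for r, q in zip(records, fdrs):
        r.fdr = float(q)
    return records


def filter_degs(
    records: list[ExpressionRecord],
    fpkm_floor: float = FPKM_FLOOR,
    lfc_min: float = LFC_MIN,
    fdr_max: float = FDR_MAX,
) -> tuple[list[ExpressionRecord], int, int]:
    """Apply the expression / fold-change / FDR filter chain.

    Expressed means max(FPKM_normal, FPKM_mut) strictly above the floor.
    Direction is relative to normal ears: "up" = higher in normal
    (log2FC of mutant over normal is negative).  Returns (DEG list,
    n_up, n_down); flags are set in place on all records.
    """
    degs = []
    n_up = n_down = 0
    for r in records:
        expressed = max(r.fpkm_normal, r.fpkm_mut) > fpkm_floor
        r.is_deg = bool(expressed and abs(r.log2fc) >= lfc_min and r.fdr <= fdr_max)
        if r.is_deg:
            r.direction = "up" if r.log2fc < 0 else "down"
            if r.direction == "up":
                n_up += 1
            else:
                n_down += 1
            degs.append(r)
        else:
            r.direction = ""
    return degs, n_up, n_down


def records_to_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    """Results table mirroring the conventional DE report columns."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "fpkm_normal": [r.fpkm_normal for r in records],
            "fpkm_mut": [r.fpkm_mut for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "is_deg": [r.is_deg for r in records],
            "direction": [r.direction for r in records],
        }
    )
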