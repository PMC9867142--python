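"""Forward simulator for the bulked-segregant study design.

Simulates an F2 population from a biparental cross segregating a single
fully penetrant recessive locus, phenotype-selected bulks of extreme
individuals, pooled short-read sequencing of each bulk, a replicated
RNA-seq count matrix with planted differentially expressed genes, and an
inbred association panel carrying a small-effect QTL at candidate promoter
SNPs.  Every downstream stage of the pipeline is testable against the
known truth these generators record.

Transmission model: each gamete is a Markov walk along the marker grid of
a chromosome, with recombination fraction between adjacent markers from
Haldane's map function r = (1 - exp(-2d))/2 at a uniform rate (default
1 cM/Mb).  The mutant-line allele is the ALT allele everywhere: the cross
is mutant line × reference line, so every marker is informative.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so each stage is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlleleDepthRecord, CountsMatrix, GeneModel

DEFAULT_CM_PER_MB = 1.0


def _default_chrom_lengths() -> dict[str, int]:
    # Scaled-down ten-chromosome genome; chr4 carries the locus and the
    # other nine are unlinked background.  Keeping the linked fraction of
    # the genome small matters for the genome-wide ED threshold.
    return {f"chr{i}": 60_000_000 for i in range(1, 11)}


def _grid(length: int, spacing: int) -> np.ndarray:
    return np.arange(spacing, length + 1, spacing, dtype=np.int64)


@dataclass
class CrossDesign:
    """Parameters of the cross, bulking and pooled-sequencing stages.

    Defaults follow the study design this simulator emulates: bulks of 50
    phenotype-selected individuals per pool, mean pool depths of 71x
    (mutant bulk) and 44x (normal bulk), a single recessive causal locus.
    The marker grid defaults to 100 kb spacing on a reduced ten-chromosome
    genome so a full replicate runs in a fraction of a second.
    """

    chrom_lengths_bp: dict[str, int] = field(default_factory=_default_chrom_lengths)
    marker_spacing_bp: int = 100_000
    marker_positions: dict[str, np.ndarray] | None = None
    causal_chrom: str = "chr4"
    causal_pos: int = 8_000_000
    n_f2: int = 400
    bulk_size: int = 50
    mean_depth_mut: float = 71.0
    mean_depth_wt: float = 44.0
    seq_error: float = 0.001
    cm_per_mb: float = DEFAULT_CM_PER_MB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 <= 0:
            raise ValueError("n_f2 must be positive")
        if self.mean_depth_mut <= 0 or self.mean_depth_wt <= 0:
            raise ValueError("pool depths must be positive")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.marker_positions is None:
            self.marker_positions = {
                c: _grid(l, self.marker_spacing_bp)
                for c, l in self.chrom_lengths_bp.items()
            }
        self.marker_positions = {
            c: np.asarray(p, dtype=np.int64) for c, p in self.marker_positions.items()
        }
        if self.causal_chrom not in self.marker_positions:
            raise ValueError(f"causal_chrom {self.causal_chrom!r} has no markers")
        pos = self.marker_positions[self.causal_chrom]
        if self.causal_pos not in pos:
            # snap onto the grid so the causal site is observable
            self.marker_positions[self.causal_chrom] = np.unique(
                np.append(pos, self.causal_pos)
            )

    @property
    def marker_index(self) -> dict[str, np.ndarray]:
        return self.marker_positions  # type: ignore[return-value]

    def causal_marker_offset(self) -> int:
        """Flat column index of the causal marker in the genotype matrix."""
        offset = 0
        for chrom in self.marker_positions:  # insertion order
            pos = self.marker_positions[chrom]
            if chrom == self.causal_chrom:
                return offset + int(np.searchsorted(pos, self.causal_pos))
            offset += len(pos)
        raise RuntimeError("causal chromosome not found")  # pragma: no cover


def _recomb_fractions(positions: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Haldane recombination fraction between adjacent markers."""
    d_morgan = np.diff(positions) / 1e6 * cm_per_mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def _simulate_gametes(
    n: int, positions: np.ndarray, cm_per_mb: float, rng: np.random.Generator
) -> np.ndarray:
    """n gametes (0/1 mutant-allele carriage) along one chromosome."""
    m = len(positions)
    out = np.empty((n, m), dtype=np.int8)
    out[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        r = _recomb_fractions(positions, cm_per_mb)
        switches = rng.random((n, m - 1)) < r[None, :]
        # cumulative XOR of switch indicators propagates the walk
        out[:, 1:] = out[:, [0]] ^ np.cumsum(switches, axis=1, dtype=np.int64) % 2
    return out


def simulate_f2(design: CrossDesign, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate F2 genotypes as mutant-allele dosage (0/1/2) per marker.

    Returns an (n_f2, total markers) int8 matrix; columns follow the
    design's chromosome insertion order and per-chromosome position order.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])
    blocks = []
    for chrom, positions in design.marker_positions.items():  # type: ignore[union-attr]
        g1 = _simulate_gametes(design.n_f2, positions, design.cm_per_mb, rng)
        g2 = _simulate_gametes(design.n_f2, positions, design.cm_per_mb, rng)
        blocks.append((g1 + g2).astype(np.int8))
    return np.concatenate(blocks, axis=1)


def phenotype_and_bulk(
    genotypes: np.ndarray,
    design: CrossDesign,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Phenotype the population and draw the two extreme bulks.

    The phenotype is fasciated iff causal dosage = 2 (fully penetrant
    recessive).  Returns (mutant_bulk_ids, normal_bulk_ids,
    (n_normal, n_fasciated)) where the counts cover the whole population.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(2)[1])
    causal = design.causal_marker_offset()
    fasciated = np.flatnonzero(genotypes[:, causal] == 2)
    normal = np.flatnonzero(genotypes[:, causal] < 2)
    seg = (len(normal), len(fasciated))
    if len(fasciated) < design.bulk_size:
        raise ValueError(
            f"only {len(fasciated)} fasciated individuals for a bulk of "
            f"{design.bulk_size}; raise n_f2"
        )
    if len(normal) < design.bulk_size:
        raise ValueError(
            f"only {len(normal)} normal individuals for a bulk of "
            f"{design.bulk_size}; raise n_f2"
        )
    mut_bulk = rng.choice(fasciated, size=design.bulk_size, replace=False)
    wt_bulk = rng.choice(normal, size=design.bulk_size, replace=False)
    return mut_bulk, wt_bulk, seg


def pool_reads(
    genotypes: np.ndarray,
    mut_bulk: np.ndarray,
    wt_bulk: np.ndarray,
    design: CrossDesign,
    rng: np.random.Generator | None = None,
) -> list[AlleleDepthRecord]:
    """Simulate pooled shotgun sequencing of the two bulks.

    Per site the pool's mutant-allele frequency is mean(dosage)/2; total
    depth is Poisson around the pool's mean depth and alt reads are
    binomial at frequency f(1-e) + (1-f)e with e the per-read miscall
    probability.  The parent is hom_alt at every marker (all markers are
    mutant-line derived).
    """
    if len(mut_bulk) == 0 or len(wt_bulk) == 0:
        raise ValueError("bulks must be non-empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(3)[2])
    f_mut = genotypes[mut_bulk].mean(axis=0) / 2.0
    f_wt = genotypes[wt_bulk].mean(axis=0) / 2.0
    e = design.seq_error
    p_mut = f_mut * (1 - e) + (1 - f_mut) * e
    p_wt = f_wt * (1 - e) + (1 - f_wt) * e
    m = genotypes.shape[1]
    depth_mut = rng.poisson(design.mean_depth_mut, size=m)
    depth_wt = rng.poisson(design.mean_depth_wt, size=m)
    alt_mut = rng.binomial(depth_mut, p_mut)
    alt_wt = rng.binomial(depth_wt, p_wt)

    records = []
    col = 0
    for chrom, positions in design.marker_positions.items():  # type: ignore[union-attr]
        for pos in positions:
            records.append(
                AlleleDepthRecord(
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele="A",
                    alt_allele="T",
                    depth_mut_ref=int(depth_mut[col] - alt_mut[col]),
                    depth_mut_alt=int(alt_mut[col]),
                    depth_wt_ref=int(depth_wt[col] - alt_wt[col]),
                    depth_wt_alt=int(alt_wt[col]),
                    parent_gt="hom_alt",
                )
            )
            col += 1
    return records


def simulate_bsa_experiment(
    design: CrossDesign,
) -> tuple[list[AlleleDepthRecord], tuple[int, int]]:
    """Run cross → phenotyping → bulking → pooled sequencing in one call."""
    ss = np.random.SeedSequence(design.seed).spawn(3)
    rng_f2 = np.random.default_rng(ss[0])
    rng_bulk = np.random.default_rng(ss[1])
    rng_reads = np.random.default_rng(ss[2])
    genotypes = simulate_f2(design, rng_f2)
    mut_bulk, wt_bulk, seg = phenotype_and_bulk(genotypes, design, rng_bulk)
    records = pool_reads(genotypes, mut_bulk, wt_bulk, design, rng_reads)
    return records, seg


@dataclass
class ExpressionDesign:
    """Parameters of the replicated RNA-seq count simulation.

    ``n_in_region`` true DE genes are planted inside the causal interval
    (the study scenario: exactly two), the rest outside it.
    """

    n_genes: int = 2000
    n_de: int = 100
    log2fc_range: tuple[float, float] = (1.5, 3.0)
    # NB dispersion 0.02 = biological CV of ~14%, the regime expected for
    # replicated inbred-line bulk RNA-seq
    dispersion: float = 0.02
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)
    n_in_region: int = 2
    n_reps: int = 3
    region_chrom: str = "chr4"
    region_start: int = 4_680_000
    region_end: int = 11_260_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de must be <= n_genes")
        if self.n_in_region > self.n_de:
            raise ValueError("n_in_region must be <= n_de")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def _nb_draw(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative binomial via gamma-Poisson: var = mean + dispersion * mean^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(
    expr_design: ExpressionDesign, gene_models: list[GeneModel]
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Simulate a genes × (normal, mutant) replicated NB count matrix.

    Returns the counts matrix and a truth table with columns
    gene_id, is_de, true_log2fc, in_region.  DE direction is the log2
    fold-change of the mutant condition over normal.
    """
    d = expr_design
    if d.n_genes > len(gene_models):
        raise ValueError("n_genes exceeds the number of gene models supplied")
    rng = np.random.default_rng(np.random.SeedSequence(d.seed).spawn(1)[0])
    genes = gene_models[: d.n_genes]
    in_region_idx = [
        i
        for i, g in enumerate(genes)
        if g.chrom == d.region_chrom
        and g.start <= d.region_end
        and g.end >= d.region_start
    ]
    out_region_idx = [i for i in range(d.n_genes) if i not in set(in_region_idx)]
    if len(in_region_idx) < d.n_in_region:
        raise ValueError("not enough gene models inside the causal interval")
    de_in = list(rng.choice(in_region_idx, size=d.n_in_region, replace=False))
    n_out = d.n_de - d.n_in_region
    if len(out_region_idx) < n_out:
        raise ValueError("not enough gene models outside the causal interval")
    de_out = list(rng.choice(out_region_idx, size=n_out, replace=False))
    de_idx = np.array(sorted(de_in + de_out), dtype=int)

    base = rng.uniform(*d.baseline_mean_range, size=d.n_genes)
    lfc = np.zeros(d.n_genes)
    if len(de_idx):
        mag = rng.uniform(*d.log2fc_range, size=len(de_idx))
        sign = rng.choice([-1.0, 1.0], size=len(de_idx))
        lfc[de_idx] = mag * sign

    mean_normal = base
    mean_mut = base * 2.0**lfc
    counts = np.empty((d.n_genes, 2 * d.n_reps), dtype=np.int64)
    for r in range(d.n_reps):
        counts[:, r] = _nb_draw(mean_normal, d.dispersion, rng)
        counts[:, d.n_reps + r] = _nb_draw(mean_mut, d.dispersion, rng)

    sample_ids = [f"normal_{r+1}" for r in range(d.n_reps)] + [
        f"fea5_{r+1}" for r in range(d.n_reps)
    ]
    conditions = ["normal"] * d.n_reps + ["fea5"] * d.n_reps
    matrix = CountsMatrix(
        gene_ids=[g.gene_id for g in genes],
        sample_ids=sample_ids,
        conditions=conditions,
        counts=counts,
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_de": np.isin(np.arange(d.n_genes), de_idx),
            "true_log2fc": lfc,
            "in_region": np.isin(np.arange(d.n_genes), np.array(in_region_idx)),
        }
    )
    return matrix, truth





def uniform_gene_models(
    chrom_lengths: dict[str, int],
    n_genes: int,
    gene_length: int = 3000,
    seed: int = 0,
) -> list[GeneModel]:
    """Lay n_genes non-overlapping genes uniformly over the genome."""
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    models = []
    i = 0
    for chrom, length in chrom_lengths.items():
        n_here = max(1, round(n_genes * length / total))
        if chrom == list(chrom_lengths)[-1]:
            n_here = n_genes - i
        starts = np.linspace(1, length - gene_length, n_here).astype(np.int64)
        for s in starts:
            i += 1
            models.append(
                GeneModel(
                    gene_id=f"gene{i:05d}",
                    chrom=chrom,
                    start=int(s),
                    end=int(s) + gene_length - 1,
                    length_bp=int(rng.integers(800, 5000)),
                )
            )
    return models


def effect_for_pve(pve_percent: float, hap1_freq: float, noise_sd: float) -> float:
    """Group-mean shift giving the requested percent variance explained.

    For a binary group indicator with frequency q and residual SD s, the
    model R^2 is b^2 q(1-q) / (b^2 q(1-q) + s^2); invert for b.
    """
    if not 0 < pve_percent < 100:
        raise ValueError("pve_percent must lie in (0, 100)")
    q = hap1_freq
    pve = pve_percent / 100.0
    return noise_sd * np.sqrt(pve / (1.0 - pve) / (q * (1.0 - q)))


@dataclass
class HaplotypePanel:
    """Inbred association panel: promoter-SNP dosages, KRN, haplotype labels."""

    line_ids: list[str]
    dosages: np.ndarray  # (n_lines, n_snps), values 0/2 (inbred)
    krn: np.ndarray
    haplotype: np.ndarray  # 'Hap1' | 'Hap2' | '' (unassigned)

    @property
    def group_sizes(self) -> tuple[int, int]:
        return int((self.haplotype == "Hap1").sum()), int(
            (self.haplotype == "Hap2").sum()
        )


def simulate_panel(
    n_lines: int = 350,
    maf: float = 0.1,
    qtl_effect: float | None = None,
    pve_percent: float = 7.9,
    flip_prob: float = 0.002,
    krn_baseline: float = 14.0,
    krn_sd: float = 2.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate the natural-variation panel at three promoter SNPs.

    Three SNPs copy one latent haplotype with a small per-SNP flip
    probability, so pairwise LD r^2 stays high (> 0.9 at the default flip
    probability).  KRN is baseline + effect x (Hap1 indicator) + Gaussian
    noise; when ``qtl_effect`` is None it is sized from ``pve_percent``.
    Lines whose three SNPs disagree get no haplotype label, mimicking
    panel attrition.
    """
    if not 0 < maf < 0.5:
        raise ValueError("maf must lie in (0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    latent = (rng.random(n_lines) < maf).astype(np.int8)  # 1 = minor haplotype
    flips = rng.random((n_lines, 3)) < flip_prob
    snps = (latent[:, None] ^ flips).astype(np.int8)
    dosages = (2 * snps).astype(np.int8)

    all_alt = (snps == 1).all(axis=1)
    all_ref = (snps == 0).all(axis=1)
    haplotype = np.where(all_alt, "Hap1", np.where(all_ref, "Hap2", ""))

    if qtl_effect is None:
        qtl_effect = effect_for_pve(pve_percent, maf, krn_sd)
    hap1 = latent.astype(float)
    krn = krn_baseline + qtl_effect * hap1 + rng.normal(0.0, krn_sd, size=n_lines)
    return HaplotypePanel(
        line_ids=[f"line{i+1:03d}" for i in range(n_lines)],
        dosages=dosages,
        krn=krn,
        haplotype=haplotype,
    )
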