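"""Bulked-segregant genome scan: SNP-index, ΔSNP-index, Euclidean distance.

The SNP-index of a pool at a site is the fraction of reads carrying the
alternate (mutant-line) allele.  ΔSNP-index is the mutant-pool index minus
the normal-pool index; near a fully penetrant recessive causal locus its
expectation is 2/3 (mutant pool fixed at 1, normal pool at 1/3) and it is
0 at unlinked sites.  The Euclidean-distance statistic is

    ED = sqrt(sum over alleles of (f_mut - f_wt)^2),

taken over {ref, alt} frequencies in each pool, and is raised to a power k
(default 5) to suppress sampling noise.  For biallelic sites
ED = sqrt(2) * |Δ| identically.

Significance is assessed per statistic: |Δ| against a simulated null of
unlinked F2 pooled sampling at matched depth, and ED^k against the
conventional genome-wide median + 3 SD rule.  Runs of significant windows
are merged into candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AlleleDepthRecord

DEFAULT_ED_POWER = 5
DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_STEP_BP = 100_000
DEFAULT_MIN_SITES = 10
DEFAULT_MIN_DEPTH = 10


@dataclass
class ScanPoint:
    chrom: str
    pos: int
    snp_index_mut: float
    snp_index_wt: float
    delta: float
    ed: float
    ed_k: float


@dataclass
class Window:
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_delta: float
    mean_ed_k: float
    threshold_delta: float | None = None
    threshold_ed: float | None = None
    significant_delta: bool = False
    significant_ed: bool = False


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    statistic: str = "intersection"

    @property
    def width_mb(self) -> float:
        return round((self.end - self.start) / 1e6, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def filter_variants(
    records: list[AlleleDepthRecord],
    min_depth_per_pool: int = DEFAULT_MIN_DEPTH,
    require_parent_hom: bool = True,
) -> tuple[list[AlleleDepthRecord], dict[str, int]]:
    """Drop heterozygous/missing-parent sites and low-depth sites.

    Returns the kept records and per-rule drop counts.  An empty result is
    allowed (with a warning via the counts, not an exception).
    """
    kept = []
    drops = {"parent_het": 0, "parent_missing": 0, "low_depth": 0}
    for r in records:
        if require_parent_hom and r.parent_gt == "het":
            drops["parent_het"] += 1
            continue
        if require_parent_hom and r.parent_gt == "missing":
            drops["parent_missing"] += 1
            continue
        if (
            r.depth_mut_ref + r.depth_mut_alt < min_depth_per_pool
            or r.depth_wt_ref + r.depth_wt_alt < min_depth_per_pool
        ):
            drops["low_depth"] += 1
            continue
        kept.append(r)
    return kept, drops


def snp_index(ref_depth: int, alt_depth: int) -> float:
    """Fraction of reads carrying the alternate allele."""
    total = ref_depth + alt_depth
    if total <= 0:
        raise ValueError("snp_index undefined at zero total depth")
    return alt_depth / total


def delta_snp_index(idx_mut: float, idx_wt: float) -> float:
    """Mutant-pool SNP-index minus normal-pool SNP-index (sign fixed)."""
    return idx_mut - idx_wt


def euclidean_distance(
    freqs_mut: np.ndarray, freqs_wt: np.ndarray, power: float = DEFAULT_ED_POWER
) -> tuple[float, float]:
    """ED over per-allele frequency vectors, and its k-th power."""
    freqs_mut = np.asarray(freqs_mut, dtype=float)
    freqs_wt = np.asarray(freqs_wt, dtype=float)
    for f in (freqs_mut, freqs_wt):
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("allele frequency vector must sum to 1")
    ed = float(np.sqrt(((freqs_mut - freqs_wt) ** 2).sum()))
    return ed, ed**power


def compute_scan(
    records: list[AlleleDepthRecord], ed_power: float = DEFAULT_ED_POWER
) -> list[ScanPoint]:
    """Per-site scan statistics; zero-total-depth sites are excluded."""
    points = []
    for r in records:
        tm = r.depth_mut_ref + r.depth_mut_alt
        tw = r.depth_wt_ref + r.depth_wt_alt
        if tm == 0 or tw == 0:
            continue
        im = snp_index(r.depth_mut_ref, r.depth_mut_alt)
        iw = snp_index(r.depth_wt_ref, r.depth_wt_alt)
        ed, ed_k = euclidean_distance(
            np.array([1 - im, im]), np.array([1 - iw, iw]), ed_power
        )
        points.append(
            ScanPoint(
                chrom=r.chrom,
                pos=r.pos,
                snp_index_mut=im,
                snp_index_wt=iw,
                delta=delta_snp_index(im, iw),
                ed=ed,
                ed_k=ed_k,
            )
        )
    return points


def sliding_window(
    points: list[ScanPoint],
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[Window]:
    """Unweighted per-window means of Δ and ED^k.

    Windows are [start, start + window_bp - 1], advanced by step_bp from
    position 1 on each chromosome; windows with fewer than ``min_sites``
    sites are omitted.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    windows: list[Window] = []
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in points],
            "pos": [p.pos for p in points],
            "delta": [p.delta for p in points],
            "ed_k": [p.ed_k for p in points],
        }
    )
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        ed_k = sub["ed_k"].to_numpy()
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window_bp - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            if n >= min_sites:
                windows.append(
                    Window(
                        chrom=str(chrom),
                        start=start,
                        end=end,
                        n_sites=int(n),
                        mean_delta=float(delta[lo:hi].mean()),
                        mean_ed_k=float(ed_k[lo:hi].mean()),
                    )
                )
            start += step_bp
    return windows


def null_threshold_delta(
    depths: np.ndarray | list[int],
    bulk_size: int,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    n_sites_per_window: int = 1,
) -> dict[int, float]:
    """Simulated null cutoff on |ΔSNP-index| per sequencing depth.

    Under no linkage each pool's allele frequency is the mean of
    ``bulk_size`` F2 dosages (each Binomial(2, 1/2)) over 2, and reads are
    binomial at that frequency and the given depth.  The threshold is the
    (1 - alpha) quantile of |Δ| over ``n_sim`` null draws.

    With ``n_sites_per_window`` > 1 the null quantity is the mean Δ over
    that many sites sharing one pool-frequency draw (sites within a
    window are tightly linked, so the bulk-composition component of the
    noise is common while read noise averages out); this calibrates the
    cutoff for window means rather than single sites.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for a stable quantile")
    if n_sites_per_window < 1:
        raise ValueError("n_sites_per_window must be >= 1")
    rng = np.random.default_rng(seed)
    k = n_sites_per_window
    out: dict[int, float] = {}
    for depth in np.unique(np.asarray(depths, dtype=int)):
        if depth <= 0:
            raise ValueError("depths must be positive")
        f1 = rng.binomial(2 * bulk_size, 0.5, size=n_sim) / (2 * bulk_size)
        f2 = rng.binomial(2 * bulk_size, 0.5, size=n_sim) / (2 * bulk_size)
        idx1 = rng.binomial(depth, np.repeat(f1, k)) / depth
        idx2 = rng.binomial(depth, np.repeat(f2, k)) / depth
        delta_bar = (idx1 - idx2).reshape(n_sim, k).mean(axis=1)
        out[int(depth)] = float(np.quantile(np.abs(delta_bar), 1.0 - alpha))
    return out


def null_threshold_ed(ed_k_values: np.ndarray | list[float], min_points: int = 100) -> float:
    """Genome-wide ED^k cutoff: median + 3 standard deviations."""
    v = np.asarray(ed_k_values, dtype=float)
    if v.size < min_points:
        raise ValueError(f"need >= {min_points} points for a stable ED threshold")
    return float(np.median(v) + 3.0 * v.std(ddof=1))


def annotate_thresholds(
    windows: list[Window],
    delta_threshold: float,
    ed_threshold: float,
) -> list[Window]:
    """Attach thresholds and set significance flags (ties count as significant)."""
    for w in windows:
        w.threshold_delta = delta_threshold
        w.threshold_ed = ed_threshold
        w.significant_delta = abs(w.mean_delta) >= delta_threshold
        w.significant_ed = w.mean_ed_k >= ed_threshold
    return windows


def _is_significant(w: Window, which: str) -> bool:
    if which == "delta":
        return w.significant_delta
    if which == "ed":
        return w.significant_ed
    if which == "intersection":
        return w.significant_delta and w.significant_ed
    raise ValueError("which_statistic must be 'delta', 'ed' or 'intersection'")


def call_regions(
    windows: list[Window],
    which_statistic: str = "intersection",
    gap_windows: int = 1,
) -> list[CandidateRegion]:
    """Merge runs of significant windows into candidate regions.

    Consecutive significant windows — tolerating up to ``gap_windows``
    non-significant windows between them — are merged; region bounds are
    the outermost window bounds.  Runs whose spans overlap in bp (possible
    when windows overlap) are merged again, so the result is sorted and
    non-overlapping.  No significant windows → empty list.
    """
    regions: list[CandidateRegion] = []
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.start)
        sig_idx = [i for i, w in enumerate(ws) if _is_significant(w, which_statistic)]
        if not sig_idx:
            continue
        run_start = sig_idx[0]
        prev = sig_idx[0]
        for i in sig_idx[1:] + [None]:  # type: ignore[list-item]
            if i is not None and i - prev <= gap_windows + 1:
                prev = i
                continue
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start=ws[run_start].start,
                    end=ws[prev].end,
                    statistic=which_statistic,
                )
            )
            if i is not None:
                run_start = prev = i
    merged: list[CandidateRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end + 1:
            merged[-1].end = max(merged[-1].end, r.end)
        else:
            merged.append(r)
    return merged


def scan_pipeline(
    records: list[AlleleDepthRecord],
    bulk_size: int,
    min_depth_per_pool: int = DEFAULT_MIN_DEPTH,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_sites: int = DEFAULT_MIN_SITES,
    ed_power: float = DEFAULT_ED_POWER,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    which_statistic: str = "intersection",
    seed: int = 0,
) -> tuple[list[ScanPoint], list[Window], list[CandidateRegion]]:
    """Filter → per-site statistics → windows → thresholds → regions.

    The Δ threshold is simulated at the median per-pool depth of the
    filtered sites, calibrated for window means at the median window site
    count; the ED^k threshold is the genome-wide median + 3 SD of the
    per-site ED^k values.
    """
    kept, _ = filter_variants(records, min_depth_per_pool=min_depth_per_pool)
    points = compute_scan(kept, ed_power=ed_power)
    if not points:
        return [], [], []
    windows = sliding_window(points, window_bp, step_bp, min_sites)
    depths = [
        (r.depth_mut_ref + r.depth_mut_alt + r.depth_wt_ref + r.depth_wt_alt) // 2
        for r in kept
    ]
    med_depth = int(np.median(depths))
    med_sites = int(np.median([w.n_sites for w in windows])) if windows else 1
    thr_delta = null_threshold_delta(
        [med_depth], bulk_size=bulk_size, n_sim=n_sim, alpha=alpha, seed=seed,
        n_sites_per_window=med_sites,
    )[med_depth]
    thr_ed = null_threshold_ed([p.ed_k for p in points])
    annotate_thresholds(windows, thr_delta, thr_ed)
    regions = call_regions(windows, which_statistic=which_statistic)
    return points, windows, regions


def points_to_frame(points: list[ScanPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in points],
            "pos": [p.pos for p in points],
            "snp_index_mut": [p.snp_index_mut for p in points],
            "snp_index_wt": [p.snp_index_wt for p in points],
            "delta": [p.delta for p in points],
            "ed": [p.ed for p in points],
            "ed_k": [p.ed_k for p in points],
        }
    )


def windows_to_frame(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": [w.n_sites for w in windows],
            "mean_delta": [w.mean_delta for w in windows],
            "mean_ed_k": [w.mean_ed_k for w in windows],
            "significant_delta": [w.significant_delta for w in windows],
            "significant_ed": [w.significant_ed for w in windows],
        }
    )


def write_regions_bed(regions: list[CandidateRegion], path) -> None:
    """Write candidate regions as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.statistic}\t{r.width_mb}\n")
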