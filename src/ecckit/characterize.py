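"""Per-sample eccDNA abundance, GC content, and size-distribution statistics.

Circle-seq studies consistently report three headline descriptors of an
eccDNA population: how many circles each sample yields, how GC-rich they
are relative to the genome, and a characteristic multi-modal size
distribution with peaks a few hundred bp apart. This module computes all
three plus the two-group rank-sum comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .core_io import EccDNARecord, Genome, SampleSheet


def gc_fraction(genome: Genome, record: EccDNARecord) -> float:
    """GC fraction of the reference span of a record, N bases excluded.

    The circle consists of the same bases as its reference span (the
    junction only reorders them), so span GC equals circle GC. Returns
    NaN for an all-N span; callers exclude such records from summaries.
    """
    seq = genome.fetch(record.chrom, record.start, record.end)
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return float("nan")
    return gc / acgt


def gc_values(genome: Genome, records: list[EccDNARecord]) -> np.ndarray:
    """Per-record GC fractions with all-N records omitted."""
    vals = np.array([gc_fraction(genome, r) for r in records], dtype=float)
    return vals[~np.isnan(vals)]


@dataclass
class SizeStats:
    n: int
    median: float
    p75: float
    fraction_below_1kb: float
    histogram: list[tuple[int, int]]  # (bin start bp, count)
    peaks: list[float]  # bp positions (bin centers) of smoothed-histogram maxima


def size_stats(
    lengths,
    bin_width: int = 10,
    smooth_sd: float = 2.0,
    prominence_frac: float = 0.05,
) -> SizeStats:
    """Summarize an eccDNA length distribution.

    Median/p75 use linear interpolation between order statistics (the
    type-7 quantile convention) on the raw lengths. Peaks are local
    maxima of the Gaussian-smoothed histogram (sd in bins) with
    prominence at least ``prominence_frac`` of the global maximum;
    positions are reported as bin centers.
    """
    lengths = np.asarray(
        [r.length if isinstance(r, EccDNARecord) else r for r in lengths], dtype=float
    )
    if lengths.size == 0:
        raise ValueError("size_stats requires at least one record")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    median = float(np.percentile(lengths, 50))
    p75 = float(np.percentile(lengths, 75))
    frac = float(np.mean(lengths < 1000))
    edges = np.arange(0, lengths.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    smoothed = ndimage.gaussian_filter1d(counts.astype(float), smooth_sd)
    # zero-pad so maxima in the first/last bin are detectable
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peak_idx, _ = signal.find_peaks(padded, prominence=prominence_frac * padded.max())
    centers = edges[:-1] + bin_width / 2
    peaks = [float(centers[i - 1]) for i in peak_idx]
    histogram = [(int(edges[i]), int(counts[i])) for i in range(len(counts))]
    return SizeStats(int(lengths.size), median, p75, frac, histogram, peaks)


def per_sample_counts(
    records_by_sample: dict[str, list[EccDNARecord]], sheet: SampleSheet
) -> pd.DataFrame:
    """One row per sample (sample, group, n_eccdna) plus per-group total rows."""
    rows = []
    for sample, records in records_by_sample.items():
        if sample not in sheet.groups:
            raise ValueError(f"sample {sample!r} not present in the sample sheet")
        rows.append({"sample": sample, "group": sheet.groups[sample],
                     "n_eccdna": len(records), "is_group_total": False})
    for group in sheet.group_order:
        total = sum(r["n_eccdna"] for r in rows if not r["is_group_total"] and r["group"] == group)
        rows.append({"sample": group, "group": group, "n_eccdna": total, "is_group_total": True})
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of rank assignments when nA + nB <= 12 and there
    are no ties; otherwise the normal approximation with tie and
    continuity corrections. Returns (U statistic of the first sample,
    two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2
    tie_counts = np.unique(pooled, return_counts=True)[1]
    has_ties = bool(np.any(tie_counts > 1))
    big_n = n1 + n2

    if big_n <= 12 and not has_ties:
        rank_sums = [sum(c) for c in combinations(range(1, big_n + 1), n1)]
        n_total = len(rank_sums)
        n_le = sum(s <= r1 for s in rank_sums)
        n_ge = sum(s >= r1 for s in rank_sums)
        p = min(1.0, 2 * min(n_le, n_ge) / n_total)
        return u1, p

    mu = n1 * n2 / 2
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return u1, 1.0  # all values identical across both groups
    num = u1 - mu
    num -= 0.5 * np.sign(num)  # continuity correction toward the mean
    z = num / np.sqrt(var)
    return u1, min(1.0, 2 * stats.norm.sf(abs(z)))
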