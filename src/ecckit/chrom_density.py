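"""Per-chromosome eccDNA density (per Mb) and correlation with gene/Alu density.

Chromosomes rich in protein-coding genes and Alu elements (chr19, chr17
in human) yield disproportionately many eccDNAs; the quantities here
make that comparison: circles per megabase per chromosome, features per
megabase, and the Pearson correlation between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import EccDNARecord, ElementAnnotation, Genome

MB = 1e6


def density_per_mb(
    records: list[EccDNARecord], genome: Genome, exclude: tuple[str, ...] = ()
) -> pd.DataFrame:
    """eccDNA count and density per chromosome; zero-count chromosomes included."""
    lengths = {c: n for c, n in genome.lengths.items() if c not in exclude}
    counts = dict.fromkeys(lengths, 0)
    for rec in records:
        if rec.chrom in exclude:
            continue
        if rec.chrom not in lengths:
            raise ValueError(f"record chromosome {rec.chrom!r} not in genome")
        counts[rec.chrom] += 1
    rows = {
        chrom: {
            "n_eccdna": counts[chrom],
            "size_mb": lengths[chrom] / MB,
            "eccdna_per_mb": counts[chrom] / (lengths[chrom] / MB),
        }
        for chrom in lengths
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "chrom"
    return df


def feature_density(
    annotation: ElementAnnotation, genome: Genome, exclude: tuple[str, ...] = ()
) -> pd.Series:
    """Annotation intervals per Mb per chromosome.

    Raw interval count, no merging: each annotation record is one
    element. (Coverage-based statistics merge; element counting does not.)
    """
    lengths = {c: n for c, n in genome.lengths.items() if c not in exclude}
    counts = dict.fromkeys(lengths, 0)
    for chrom, _start, _end in annotation.intervals:
        if chrom in counts:
            counts[chrom] += 1
    dens = pd.Series(
        {c: counts[c] / (lengths[c] / MB) for c in lengths},
        name=f"{annotation.class_name}_per_mb",
    )
    dens.index.name = "chrom"
    return dens


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value.

    p is computed from t = R * sqrt((n-2) / (1-R^2)) on n-2 degrees of
    freedom; R = +/-1 gives p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires at least 3 paired points")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(np.dot(xd, xd))
    syy = float(np.dot(yd, yd))
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    r = float(np.dot(xd, yd) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def chrom_density_table(
    records: list[EccDNARecord],
    genome: Genome,
    gene_annotation: ElementAnnotation,
    alu_annotation: ElementAnnotation,
    exclude: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict]:
    """Full per-chromosome table plus eccDNA-vs-gene and eccDNA-vs-Alu correlations."""
    df = density_per_mb(records, genome, exclude)
    df["genes_per_mb"] = feature_density(gene_annotation, genome, exclude)
    df["alu_per_mb"] = feature_density(alu_annotation, genome, exclude)
    correlations = {}
    for feature in ("genes_per_mb", "alu_per_mb"):
        r, p = pearson(df["eccdna_per_mb"], df[feature])
        correlations[f"eccdna_vs_{feature}"] = {"R": r, "p": p, "n": int(len(df))}
    return df, correlations
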