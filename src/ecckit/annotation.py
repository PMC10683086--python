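"""Normalized genomic coverage over element classes and repeat read fractions.

The enrichment statistic for a class of genomic elements is

    ratio = (% of eccDNA molecules whose START position falls in the
             class) / (% of genome bases covered by the merged class)

so a value of 1 means "no enrichment over a uniform start distribution".
Membership uses the start position only and half-open interval logic.
Repeat classes are instead scored by reads: a record's reads count
toward every repeat class its interval overlaps by >= 1 bp, so repeat
percentages may sum to more than 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from . import intervals as iv
from .core_io import EccDNARecord, ElementAnnotation, Genome


@dataclass
class NormalizedCoverage:
    class_name: str
    n_in_class: int
    n_total: int
    pct_molecules: float
    pct_genome: float
    ratio: float


def genome_pct_covered(annotation: ElementAnnotation, genome: Genome) -> float:
    """Percentage of genome bases covered by the merged (union) class."""
    merged = annotation.merged()
    return iv.covered_bases(merged) / genome.total_bases * 100.0


def normalized_coverage(
    records: list[EccDNARecord], annotation: ElementAnnotation, genome: Genome
) -> NormalizedCoverage:
    """Enrichment of eccDNA start positions within one element class."""
    if not records:
        raise ValueError("normalized_coverage requires at least one record")
    pct_genome = genome_pct_covered(annotation, genome)
    if pct_genome == 0:
        raise ValueError(f"class {annotation.class_name!r} covers no genome bases")
    merged = annotation.merged()
    n_in = sum(1 for r in records if iv.point_in(merged, r.chrom, r.start))
    n_total = len(records)
    pct_molecules = n_in / n_total * 100.0
    return NormalizedCoverage(
        class_name=annotation.class_name,
        n_in_class=n_in,
        n_total=n_total,
        pct_molecules=pct_molecules,
        pct_genome=pct_genome,
        ratio=pct_molecules / pct_genome,
    )


def normalized_coverage_table(
    records: list[EccDNARecord],
    annotations: Iterable[ElementAnnotation],
    genome: Genome,
) -> pd.DataFrame:
    """Normalized coverage for each class, evaluated independently."""
    rows = []
    for ann in annotations:
        nc = normalized_coverage(records, ann, genome)
        rows.append(
            {
                "class": nc.class_name,
                "n_in_class": nc.n_in_class,
                "n_total": nc.n_total,
                "pct_molecules": nc.pct_molecules,
                "pct_genome": nc.pct_genome,
                "ratio": nc.ratio,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RepeatReadFraction:
    class_name: str
    reads_in_class: int
    total_reads: int
    percent: float


def repeat_read_fraction(
    records: list[EccDNARecord], annotations: Iterable[ElementAnnotation]
) -> pd.DataFrame:
    """Percent of eccDNA reads attributable to each repeat class.

    A record contributes its full read count to every class it overlaps
    by at least one base (classes are not exclusive).
    """
    total_reads = sum(r.total_count() for r in records)
    if total_reads <= 0:
        raise ValueError("total read count is zero")
    rows = []
    for ann in annotations:
        merged = ann.merged()
        reads = sum(
            r.total_count()
            for r in records
            if iv.overlaps(merged, r.chrom, r.start, r.end)
        )
        rows.append(
            {
                "class": ann.class_name,
                "reads_in_class": reads,
                "total_reads": total_reads,
                "percent": reads / total_reads * 100.0,
            }
        )
    return pd.DataFrame(rows)
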