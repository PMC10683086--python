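"""Conjoint analysis: differential eccDNAs vs differential mRNAs.

A differential eccDNA is mapped to its host genes (any overlap of the
eccDNA interval with a gene body extended by 2 kb flanks), then joined
against a differential-gene table. A pair is "shared" only when both
sides are significant and change in the same direction, with "up"
meaning higher in the first group (e.g. young donors) on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_DIRECTIONS = {"up", "down", "ns"}


def map_host_genes(
    eccdna_intervals: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000
) -> dict[str, set[str]]:
    """Map each eccDNA to the symbols of every gene it overlaps.

    ``eccdna_intervals`` needs columns eccdna_id, chrom, start, end;
    ``genes`` needs chrom, start, end, symbol. Overlap is >= 1 bp against
    the gene body extended by ``flank`` bp on both sides. eccDNAs
    touching no gene map to the empty set.
    """
    out: dict[str, set[str]] = {}
    by_chrom = {chrom: g for chrom, g in genes.groupby("chrom")}
    for row in eccdna_intervals.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            out[row.eccdna_id] = set()
            continue
        hit = (g["start"].to_numpy() - flank < row.end) & (
            g["end"].to_numpy() + flank > row.start
        )
        out[row.eccdna_id] = set(g["symbol"].to_numpy()[hit])
    return out


@dataclass
class OverlapResult:
    shared_eccdnas: pd.DataFrame  # eccdna_id, gene, direction
    shared_genes: pd.DataFrame  # gene, direction
    counts: dict


def _check_directions(values, what: str) -> None:
    bad = set(values) - VALID_DIRECTIONS
    if bad:
        raise ValueError(f"unknown direction labels {sorted(bad)} in {what}")


def overlap_same_direction(
    diff_table: pd.DataFrame,
    host_map: dict[str, set[str]],
    de_genes: pd.DataFrame,
) -> OverlapResult:
    """Shared (eccDNA, gene) pairs: both significant, same direction.

    ``diff_table`` is the differential-eccDNA table (index eccdna_id,
    column direction); ``de_genes`` carries symbol and direction.
    Distinct eccDNAs and distinct genes are counted separately.
    """
    _check_directions(diff_table["direction"], "differential eccDNA table")
    _check_directions(de_genes["direction"], "differential gene table")
    gene_dir = {
        row.symbol: row.direction
        for row in de_genes.itertuples(index=False)
        if row.direction != "ns"
    }
    pairs = []
    for eccdna_id, direction in diff_table["direction"].items():
        if direction == "ns":
            continue
        for gene in sorted(host_map.get(eccdna_id, ())):
            if gene_dir.get(gene) == direction:
                pairs.append({"eccdna_id": eccdna_id, "gene": gene, "direction": direction})
    shared_eccdnas = pd.DataFrame(pairs, columns=["eccdna_id", "gene", "direction"])
    shared_genes = (
        shared_eccdnas[["gene", "direction"]].drop_duplicates().reset_index(drop=True)
    )
    ecc_distinct = shared_eccdnas[["eccdna_id", "direction"]].drop_duplicates()
    counts = {
        "shared_eccdnas": int(ecc_distinct["eccdna_id"].nunique()),
        "shared_genes": int(shared_genes["gene"].nunique()),
        "up_shared_eccdnas": int((ecc_distinct["direction"] == "up").sum()),
        "down_shared_eccdnas": int((ecc_distinct["direction"] == "down").sum()),
        "up_shared_genes": int((shared_genes["direction"] == "up").sum()),
        "down_shared_genes": int((shared_genes["direction"] == "down").sum()),
    }
    return OverlapResult(shared_eccdnas, shared_genes, counts)


def venn_counts(
    overlap: OverlapResult, diff_table: pd.DataFrame, de_genes: pd.DataFrame
) -> dict:
    """Venn set sizes (eccDNA-only, gene-only, shared) per direction."""
    out: dict = {}
    for direction in ("up", "down"):
        ecc_sig = int((diff_table["direction"] == direction).sum())
        genes_sig = int(
            de_genes.loc[de_genes["direction"] == direction, "symbol"].nunique()
        )
        shared_ecc = int(
            (
                overlap.shared_eccdnas[["eccdna_id", "direction"]]
                .drop_duplicates()["direction"]
                == direction
            ).sum()
        )
        shared_gene = int((overlap.shared_genes["direction"] == direction).sum())
        out[direction] = {
            "eccdna_total": ecc_sig,
            "gene_total": genes_sig,
            "shared_eccdnas": shared_ecc,
            "shared_genes": shared_gene,
            "eccdna_only": ecc_sig - shared_ecc,
            "gene_only": genes_sig - shared_gene,
        }
    return out
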