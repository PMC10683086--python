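"""Junction flank extraction, nucleotide/trinucleotide profiles, spacer scan.

The start/end (junction) sequences of eccDNAs carry information about
the circularization mechanism. This module extracts the 10 bp up- and
downstream reference sequence at each junction coordinate, profiles
per-position nucleotide and trinucleotide frequencies against the
genome-wide trinucleotide background, and scans for the characteristic
pattern of a pair of identical trinucleotides separated by a short
fixed-length spacer.

Flanks are taken from the reference plus strand only: interval callers
emit unstranded circles. Offsets are relative to the junction
coordinate, so a flank of half-width ``w`` covers offsets -w .. w-1 and
trinucleotide windows start at offsets -w .. w-3 (the offset labels the
leftmost base of the window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core_io import EccDNARecord, Genome

logger = logging.getLogger("ecckit")

TRINUCLEOTIDES = ["".join(p) for p in product("ACGT", repeat=3)]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

BACKGROUND_FLOOR = 1e-6  # guards division for trinucleotides absent from toy genomes


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def extract_flanks(genome: Genome, record: EccDNARecord, w: int = 10) -> tuple[str, str]:
    """Return (start flank, end flank), each ``2w`` bp centred on the junction.

    Raises ValueError when either window would run off the chromosome;
    use :func:`collect_flanks` to drop such records with a warning.
    """
    length = genome.lengths[record.chrom] if record.chrom in genome else None
    if length is None:
        raise KeyError(f"chromosome {record.chrom!r} not in genome")
    if record.start < w or record.end > length - w:
        raise ValueError(
            f"flanks of {record.display_id} extend outside the chromosome at w={w}"
        )
    start_flank = genome.fetch(record.chrom, record.start - w, record.start + w)
    end_flank = genome.fetch(record.chrom, record.end - w, record.end + w)
    return start_flank, end_flank


def collect_flanks(
    genome: Genome, records: list[EccDNARecord], w: int = 10
) -> tuple[list[str], list[str], int]:
    """Flanks for all records whose windows fit; returns the exclusion count."""
    starts: list[str] = []
    ends: list[str] = []
    excluded = 0
    for rec in records:
        try:
            s, e = extract_flanks(genome, rec, w)
        except (ValueError, KeyError):
            excluded += 1
            continue
        starts.append(s)
        ends.append(e)
    if excluded:
        logger.warning("excluded %d records with out-of-bounds junction flanks", excluded)
    return starts, ends, excluded


def genome_background_trinuc(genome: Genome) -> pd.Series:
    """Genome-wide overlapping 3-mer frequencies (windows containing N skipped)."""
    counts = np.zeros(64, dtype=np.int64)
    any_window = False
    for seq in genome.sequences.values():
        if len(seq) < 3:
            continue
        any_window = True
        k = _encode(seq)
        valid = k < 4
        idx = 16 * k[:-2].astype(np.int64) + 4 * k[1:-1] + k[2:]
        ok = valid[:-2] & valid[1:-1] & valid[2:]
        counts += np.bincount(idx[ok], minlength=64)
    if not any_window:
        raise ValueError("genome has no chromosome of length >= 3")
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no N-free trinucleotide window")
    return pd.Series(counts / total, index=TRINUCLEOTIDES, name="background")


@dataclass
class MotifProfile:
    """Observed and expected junction-flank composition."""

    side: str  # "start" | "end" | "pooled"
    w: int
    n_flanks: int
    nucleotide_freq: pd.DataFrame  # index: offset -w..w-1, columns ACGT
    trinuc_obs: pd.DataFrame  # index: offset -w..w-3, columns 64 trinucleotides
    background: pd.Series  # genome trinucleotide frequencies
    enrichment: pd.DataFrame  # trinuc_obs / max(background, floor)


def build_motif_profile(
    flanks: list[str], background: pd.Series, side: str = "pooled"
) -> MotifProfile:
    """Per-position nucleotide and trinucleotide profile of equal-length flanks."""
    if not flanks:
        raise ValueError("no flank sequences supplied")
    length = len(flanks[0])
    if any(len(f) != length for f in flanks):
        raise ValueError("flank sequences must all have the same length")
    if length % 2 or length < 6:
        raise ValueError("flank length must be even and >= 6")
    w = length // 2
    codes = np.vstack([_encode(f) for f in flanks])
    offsets = np.arange(-w, w)

    nuc = np.zeros((length, 4), dtype=float)
    for j in range(length):
        col = codes[:, j]
        valid = col < 4
        if valid.any():
            cnt = np.bincount(col[valid], minlength=4)[:4]
            nuc[j] = cnt / cnt.sum()
    nucleotide_freq = pd.DataFrame(nuc, index=offsets, columns=list("ACGT"))
    nucleotide_freq.index.name = "offset"

    tri_offsets = np.arange(-w, w - 2)
    obs = np.zeros((len(tri_offsets), 64), dtype=float)
    for row, j in enumerate(range(length - 2)):
        a, b, c = codes[:, j], codes[:, j + 1], codes[:, j + 2]
        ok = (a < 4) & (b < 4) & (c < 4)
        if ok.any():
            idx = 16 * a[ok].astype(np.int64) + 4 * b[ok] + c[ok]
            cnt = np.bincount(idx, minlength=64)
            obs[row] = cnt / cnt.sum()
    trinuc_obs = pd.DataFrame(obs, index=tri_offsets, columns=TRINUCLEOTIDES)
    trinuc_obs.index.name = "offset"

    bg = background.reindex(TRINUCLEOTIDES).fillna(0.0).clip(lower=BACKGROUND_FLOOR)
    enrichment = trinuc_obs / bg
    return MotifProfile(side, w, len(flanks), nucleotide_freq, trinuc_obs, background, enrichment)


@dataclass
class SpacerScanResult:
    trinucleotide: str
    offsets: tuple[int, int]
    spacer: int
    score: float
    per_spacer: pd.DataFrame  # columns: spacer, trinucleotide, offset, score


def spacer_scan(profile: MotifProfile, spacers=range(0, 9)) -> SpacerScanResult:
    """Scan for a repeated trinucleotide separated by a fixed spacer.

    For trinucleotide t at offset i paired with the same t at offset
    j = i + 3 + s, the score is min(enrichment(i, t), enrichment(j, t));
    a pattern only scores high when both copies are enriched.
    """
    enr = profile.enrichment
    offsets = enr.index.to_numpy()
    rows = []
    best = None
    for s in spacers:
        shift = 3 + s
        valid_i = offsets[np.isin(offsets + shift, offsets)]
        if valid_i.size == 0:
            continue
        left = enr.loc[valid_i].to_numpy()
        right = enr.loc[valid_i + shift].to_numpy()
        score = np.minimum(left, right)
        flat = int(np.argmax(score))
        i_idx, t_idx = np.unravel_index(flat, score.shape)
        entry = {
            "spacer": int(s),
            "trinucleotide": TRINUCLEOTIDES[t_idx],
            "offset": int(valid_i[i_idx]),
            "score": float(score[i_idx, t_idx]),
        }
        rows.append(entry)
        if best is None or entry["score"] > best["score"]:
            best = entry
    if best is None:
        raise ValueError("flank window too short for any trinucleotide pair")
    per_spacer = pd.DataFrame(rows)
    return SpacerScanResult(
        trinucleotide=best["trinucleotide"],
        offsets=(best["offset"], best["offset"] + 3 + best["spacer"]),
        spacer=best["spacer"],
        score=best["score"],
        per_spacer=per_spacer,
    )
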