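"""Domain types, coordinate conventions, and readers/writers.

Internal coordinates are 0-based half-open (BED convention). Display
identifiers such as ``"chr1: 48305638-48307008"`` are 1-based inclusive:
the display start is ``start + 1`` and the display end equals the
half-open end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import intervals as iv

logger = logging.getLogger("ecckit")

_DISPLAY_ID_RE = re.compile(r"^(?P<chrom>\S+):\s*(?P<start>\d+)-(?P<end>\d+)$")


def to_display_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_display_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def parse_display_id(text: str) -> tuple[str, int, int]:
    """Parse ``"chr1: 48305638-48307008"`` into (chrom, start, end), 0-based half-open."""
    m = _DISPLAY_ID_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse eccDNA id {text!r}")
    start, end = from_display_coords(int(m["start"]), int(m["end"]))
    return m["chrom"], start, end


@dataclass
class EccDNARecord:
    """One circular DNA molecule: a genomic interval plus per-sample read counts."""

    chrom: str
    start: int
    end: int
    counts: dict[str, int] = field(default_factory=dict)
    sample_of_origin: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"eccDNA interval must satisfy end > start, got {self.chrom}:{self.start}-{self.end}"
            )
        for sample, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative read count {count} for sample {sample}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def display_id(self) -> str:
        s1, e1 = to_display_coords(self.start, self.end)
        return f"{self.chrom}: {s1}-{e1}"

    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class Genome:
    """Named chromosome sequences; the sole source of GC and flank sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def total_bases(self) -> int:
        return sum(len(seq) for seq in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Extract the [start, end) slice of a chromosome, with bounds checks."""
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 0 or end > len(self.sequences[chrom]) or end <= start:
            raise ValueError(
                f"span {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        sequences: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
            sequences[rec.id] = str(rec.seq).upper()
        if not sequences:
            raise ValueError(f"no sequences found in FASTA {path}")
        return cls(sequences)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> Genome:
    return Genome.from_fasta(path)


@dataclass
class ElementAnnotation:
    """A named class of genomic intervals (e.g. Alu, exon) used for enrichment."""

    class_name: str
    intervals: list[tuple[str, int, int]]

    def merged(self) -> iv.Merged:
        return iv.merge(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_against(self, genome: Genome) -> None:
        lengths = genome.lengths
        for chrom, start, end in self.intervals:
            if chrom not in lengths:
                raise ValueError(f"{self.class_name}: chromosome {chrom!r} not in genome")
            if start < 0 or end > lengths[chrom]:
                raise ValueError(
                    f"{self.class_name}: interval {chrom}:{start}-{end} outside bounds"
                )

    @classmethod
    def from_bed(cls, path: str | Path, class_name: str | None = None) -> "ElementAnnotation":
        name = class_name if class_name is not None else Path(path).stem
        ivs: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path} line {lineno}: expected >=3 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
                ivs.append((fields[0], start, end))
        return cls(name, ivs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{self.class_name}\n")


@dataclass
class SampleSheet:
    """Sample identifiers with their group labels (exactly two groups)."""

    groups: dict[str, str]  # sample -> group
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        names = list(dict.fromkeys(self.groups.values()))
        if len(names) != 2:
            raise ValueError(f"sample sheet must define exactly two groups, got {names}")
        if self.group_order is None:
            self.group_order = (names[0], names[1])
        elif set(self.group_order) != set(names):
            raise ValueError(
                f"group_order {self.group_order} does not match groups {names}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def from_tsv(cls, path: str | Path, group_order: tuple[str, str] | None = None) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t")
        if not {"sample", "group"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'sample' and 'group'")
        return cls(dict(zip(df["sample"].astype(str), df["group"].astype(str))), group_order)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample": list(self.groups), "group": list(self.groups.values())}
        ).to_csv(path, sep="\t", index=False)


def read_eccdna_bed(path: str | Path, sample: str | None = None) -> list[EccDNARecord]:
    """Read a Circle-Map-style BED (chrom, start, end[, read count]).

    A missing count column defaults to 1 read (presence/absence mode).
    Duplicate intervals are merged by summing their counts.
    """
    sample_label = sample if sample is not None else Path(path).stem
    merged: dict[tuple[str, int, int], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path} line {lineno}: end <= start ({start} >= {end})")
            count = 1
            if len(fields) >= 4 and fields[3] != "":
                try:
                    count = int(round(float(fields[3])))
                except ValueError:
                    count = 1  # 4th column is not a count (e.g. a name); presence mode
            key = (chrom, start, end)
            merged[key] = merged.get(key, 0) + count
    records = [
        EccDNARecord(chrom, start, end, counts={sample_label: count}, sample_of_origin=sample_label)
        for (chrom, start, end), count in sorted(merged.items())
    ]
    return records


def write_eccdna_bed(records: list[EccDNARecord], path: str | Path) -> None:
    """Write records as BED with a count and a 1-based-inclusive display id column."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcount\tid\n")
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.total_count()}\t{rec.display_id}\n"
            )


def filter_records_to_genome(
    records: list[EccDNARecord], genome: Genome
) -> list[EccDNARecord]:
    """Drop records on chromosomes absent from the genome, with a warning."""
    kept = [r for r in records if r.chrom in genome]
    dropped = len(records) - len(kept)
    if dropped:
        logger.warning("dropped %d eccDNA records on chromosomes absent from the genome", dropped)
    return kept


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts matrix (rows = eccDNA id, columns = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty counts matrix in {path}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="eccdna_id")


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene BED with a symbol in column 4."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "symbol"], usecols=[0, 1, 2, 3],
    )
    return df


def read_de_genes(path: str | Path) -> pd.DataFrame:
    """Read a differential-gene table (symbol, log2fc, q, direction)."""
    df = pd.read_csv(path, sep="\t")
    if "symbol" not in df.columns or "direction" not in df.columns:
        raise ValueError(f"{path}: expected at least 'symbol' and 'direction' columns")
    return df
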