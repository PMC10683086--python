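"""Synthetic genomes, annotations, and eccDNA populations with known truth.

Every downstream stage of the pipeline is exercised against data drawn
from this module: a toy multi-chromosome genome with configurable GC and
gene/Alu densities, element annotations derived from the placed genes,
an eccDNA population with a mixture-of-Gaussians size distribution and
configurable start-position enrichment inside element classes, a
planted junction trinucleotide-with-spacer motif, and a per-sample
negative-binomial count matrix with planted group fold changes. The
defaults emulate the statistical structure reported for eccDNA in
cultured human cells: a dominant size peak near 150 bp with secondary
peaks a few hundred bp apart, start positions enriched in the 2 kb
gene-flank regions and depleted in CpG islands, gene-dense chromosomes
yielding more circles per Mb, and mostly "up" fold changes in the first
group.

All randomness flows through a single integer seed; the generated
artifacts are byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import intervals as iv
from .conjoint import map_host_genes
from .core_io import (
    EccDNARecord,
    ElementAnnotation,
    Genome,
    SampleSheet,
    write_counts,
    write_eccdna_bed,
)

logger = logging.getLogger("ecckit")

# fixed element geometries (bp)
GENE_FLANK = 2000
UTR_LEN = 200
EXON_LEN = 200
INTRON_LEN = 400
ELEMENT_LENGTHS = {
    "Alu": 300,
    "CpG": 500,
    "satellite": 1000,
    "LINE": 800,
    "SINE": 300,
    "LTR": 500,
    "DNA": 400,
    "simple_repeat": 150,
}


@dataclass
class ChromSpec:
    name: str
    length: int
    gc: float
    genes_per_mb: float
    alu_per_mb: float


@dataclass
class SizePeak:
    mode: float
    sd: float
    weight: float


@dataclass
class PlantedMotif:
    trinucleotide: str = "CCG"
    spacer: int = 3
    fraction: float = 0.4


@dataclass
class CountsModel:
    mean: float = 50.0
    dispersion: float = 0.1  # variance = mean + dispersion * mean^2
    library_factors: dict[str, float] = field(default_factory=dict)


@dataclass
class DEConfig:
    n_differential: int = 300
    log2fc: float = 2.0
    up_fraction: float = 0.8  # share of planted changes higher in group 1


def _default_chromosomes() -> list[ChromSpec]:
    # gene/Alu densities span the gradient seen across human chromosomes
    # (chr19-like dense to chr13-like sparse)
    return [
        ChromSpec("chr1", 1_200_000, 0.45, 25.0, 60.0),
        ChromSpec("chr2", 1_000_000, 0.42, 12.0, 30.0),
        ChromSpec("chr3", 1_000_000, 0.40, 6.0, 15.0),
        ChromSpec("chr4", 800_000, 0.38, 2.0, 5.0),
    ]


def _default_size_peaks() -> list[SizePeak]:
    # four modes with a dominant sharp peak at 150 bp and a broad large-
    # circle component, giving a population median near 480 bp and ~100%
    # of circles below 1 kb
    return [
        SizePeak(150.0, 15.0, 0.30),
        SizePeak(240.0, 20.0, 0.12),
        SizePeak(400.0, 40.0, 0.10),
        SizePeak(800.0, 120.0, 0.48),
    ]


def _default_samples() -> dict[str, str]:
    return {
        "Y1": "young", "Y2": "young", "Y3": "young",
        "O1": "old", "O2": "old", "O3": "old",
    }


@dataclass
class SimulationConfig:
    """Full specification of a synthetic study; the seed determines everything."""

    seed: int = 0
    chromosomes: list[ChromSpec] = field(default_factory=_default_chromosomes)
    size_peaks: list[SizePeak] = field(default_factory=_default_size_peaks)
    n_eccdna: int = 2000
    min_length: int = 50
    edge_margin: int = 50  # keeps 10 bp junction flanks extractable
    element_enrichment: dict[str, float] = field(
        default_factory=lambda: {"Gene2KbU": 3.0, "Gene2KbD": 3.0, "CpG": 0.5}
    )
    planted_motif: PlantedMotif = field(default_factory=PlantedMotif)
    counts: CountsModel = field(default_factory=CountsModel)
    de: DEConfig = field(default_factory=DEConfig)
    samples: dict[str, str] = field(default_factory=_default_samples)
    group_order: tuple[str, str] = ("young", "old")
    gene_length: int = 4000
    repeat_densities: dict[str, float] = field(
        default_factory=lambda: {
            "CpG": 3.0, "satellite": 2.0, "LINE": 6.0, "SINE": 8.0,
            "LTR": 3.0, "DNA": 3.0, "simple_repeat": 5.0,
        }
    )
    # eccDNA rate per chromosome scales as length * (1 + coupling * genes_per_mb)
    chrom_gene_coupling: float = 0.05
    de_gene_agreement: float = 0.6  # share of DE eccDNA host genes echoed in the DE gene table
    n_noise_de_genes: int = 40

    def __post_init__(self) -> None:
        total = sum(p.weight for p in self.size_peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size peak weights must sum to 1, got {total}")
        for cls, fold in self.element_enrichment.items():
            if fold <= 0:
                raise ValueError(f"enrichment fold for {cls} must be > 0")
        if not 0.0 <= self.planted_motif.fraction <= 1.0:
            raise ValueError("motif fraction must lie in [0, 1]")
        for spec in self.chromosomes:
            if spec.length < 10_000:
                raise ValueError(f"chromosome {spec.name} shorter than 10 kb")

    def sheet(self) -> SampleSheet:
        return SampleSheet(dict(self.samples), tuple(self.group_order))

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["group_order"] = list(self.group_order)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        kwargs = dict(data)
        if "chromosomes" in kwargs:
            kwargs["chromosomes"] = [
                ChromSpec(**c) if isinstance(c, dict) else ChromSpec(*c)
                for c in kwargs["chromosomes"]
            ]
        if "size_peaks" in kwargs:
            kwargs["size_peaks"] = [
                SizePeak(**p) if isinstance(p, dict) else SizePeak(*p)
                for p in kwargs["size_peaks"]
            ]
        if isinstance(kwargs.get("planted_motif"), dict):
            kwargs["planted_motif"] = PlantedMotif(**kwargs["planted_motif"])
        if isinstance(kwargs.get("counts"), dict):
            kwargs["counts"] = CountsModel(**kwargs["counts"])
        if isinstance(kwargs.get("de"), dict):
            kwargs["de"] = DEConfig(**kwargs["de"])
        if "group_order" in kwargs:
            kwargs["group_order"] = tuple(kwargs["group_order"])
        return cls(**kwargs)


def _place_intervals(
    rng: np.random.Generator, chrom_len: int, n: int, elem_len: int, class_name: str
) -> list[tuple[int, int]]:
    """Place n non-overlapping intervals of elem_len uniformly at random."""
    if n == 0:
        return []
    if n * elem_len > 0.6 * chrom_len:
        raise ValueError(f"infeasible density for class {class_name}: "
                         f"{n} x {elem_len} bp on {chrom_len} bp")
    placed: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(f"infeasible density for class {class_name}")
        start = int(rng.integers(0, chrom_len - elem_len + 1))
        end = start + elem_len
        if any(s < end and e > start for s, e in placed):
            continue
        placed.append((start, end))
    placed.sort()
    return placed


def _gene_substructure(
    gene_ivs: list[tuple[str, int, int]], lengths: dict[str, int]
) -> dict[str, list[tuple[str, int, int]]]:
    """Derive UTRs, exons, introns, and 2 kb flanks from gene bodies."""
    out: dict[str, list[tuple[str, int, int]]] = {
        "UTR5": [], "UTR3": [], "exon": [], "intron": [],
        "Gene2KbU": [], "Gene2KbD": [],
    }
    for chrom, start, end in gene_ivs:
        out["UTR5"].append((chrom, start, start + UTR_LEN))
        out["UTR3"].append((chrom, end - UTR_LEN, end))
        pos = start + UTR_LEN
        body_end = end - UTR_LEN
        is_exon = True
        while pos < body_end:
            seg = EXON_LEN if is_exon else INTRON_LEN
            seg_end = min(pos + seg, body_end)
            out["exon" if is_exon else "intron"].append((chrom, pos, seg_end))
            pos = seg_end
            is_exon = not is_exon
        if start > 0:
            out["Gene2KbU"].append((chrom, max(0, start - GENE_FLANK), start))
        if end < lengths[chrom]:
            out["Gene2KbD"].append((chrom, end, min(lengths[chrom], end + GENE_FLANK)))
    return out


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, dict[str, ElementAnnotation], pd.DataFrame]:
    """Draw the toy genome and all element annotations.

    Returns the genome, a mapping class name -> annotation (gene, exon,
    intron, UTR5, UTR3, Gene2KbU, Gene2KbD, plus the repeat classes),
    and a gene table with symbols for host-gene mapping.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    classes: dict[str, list[tuple[str, int, int]]] = {
        name: [] for name in ("gene", "Alu", *ELEMENT_LENGTHS)
    }
    gene_rows = []
    bases = np.array(list("ACGT"))
    for spec in config.chromosomes:
        p_gc = spec.gc / 2
        p_at = (1 - spec.gc) / 2
        seq = rng.choice(bases, size=spec.length, p=[p_at, p_gc, p_gc, p_at])
        sequences[spec.name] = "".join(seq)

        n_genes = int(round(spec.genes_per_mb * spec.length / 1e6))
        genes = _place_intervals(rng, spec.length, n_genes, config.gene_length, "gene")
        for i, (s, e) in enumerate(genes):
            classes["gene"].append((spec.name, s, e))
            gene_rows.append(
                {"chrom": spec.name, "start": s, "end": e, "symbol": f"{spec.name}_g{i + 1}"}
            )
        n_alu = int(round(spec.alu_per_mb * spec.length / 1e6))
        for s, e in _place_intervals(rng, spec.length, n_alu, ELEMENT_LENGTHS["Alu"], "Alu"):
            classes["Alu"].append((spec.name, s, e))
        for cls, per_mb in config.repeat_densities.items():
            n = int(round(per_mb * spec.length / 1e6))
            for s, e in _place_intervals(rng, spec.length, n, ELEMENT_LENGTHS[cls], cls):
                classes[cls].append((spec.name, s, e))

    genome = Genome(sequences)
    derived = _gene_substructure(classes["gene"], genome.lengths)
    classes.update(derived)
    annotations = {
        name: ElementAnnotation(name, ivs) for name, ivs in classes.items() if ivs
    }
    genes_df = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "symbol"])
    return genome, annotations, genes_df


def sample_lengths(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    peaks = config.size_peaks
    weights = np.array([p.weight for p in peaks])
    comp = rng.choice(len(peaks), size=n, p=weights)
    lengths = np.empty(n, dtype=np.int64)
    for i, c in enumerate(comp):
        while True:
            val = int(round(rng.normal(peaks[c].mode, peaks[c].sd)))
            if val >= config.min_length:
                lengths[i] = val
                break
    return lengths


@dataclass
class TruthTable:
    """Ground truth of a simulated eccDNA population."""

    records: pd.DataFrame  # eccdna_id, chrom, start, end, length, start_classes, motif_carrier, de_status, de_direction
    class_enrichment: dict[str, float]
    chrom_weights: dict[str, float]


def simulate_eccdna_population(
    genome: Genome,
    annotations: dict[str, ElementAnnotation],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Draw the eccDNA population with enriched start positions.

    Start positions follow a uniform base rate multiplied by the
    configured fold inside each enriched class (rejection sampling);
    chromosome totals scale with length times (1 + coupling * gene
    density). Circles that would run past a chromosome end (or inside
    the edge margin) are resampled, never emitted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chrom_specs = config.chromosomes
    names = [c.name for c in chrom_specs]
    weights = np.array(
        [c.length / 1e6 * (1 + config.chrom_gene_coupling * c.genes_per_mb) for c in chrom_specs]
    )
    weights = weights / weights.sum()
    lengths = genome.lengths

    folds = dict(config.element_enrichment)
    merged_by_class = {}
    weights_by_class = {}
    total_bases = genome.total_bases
    for cls, fold in folds.items():
        if cls not in annotations:
            raise ValueError(f"enrichment requested for missing class {cls!r}")
        merged_by_class[cls] = annotations[cls].merged()
        # calibrate the in-class rejection weight so the induced start
        # distribution has normalized coverage equal to the requested
        # fold: with class mass q, a raw weight f realizes f/(1+(f-1)q),
        # so use w = f(1-q)/(1-fq) instead (requires fq < 1)
        q = iv.covered_bases(merged_by_class[cls]) / total_bases
        if fold * q >= 1.0:
            raise ValueError(
                f"enrichment fold {fold} infeasible for class {cls!r} covering "
                f"{q:.1%} of the genome"
            )
        weights_by_class[cls] = fold * (1 - q) / (1 - fold * q)
    max_w = (
        float(np.prod([max(w, 1.0) for w in weights_by_class.values()]))
        if folds
        else 1.0
    )
    all_merged = {name: ann.merged() for name, ann in annotations.items()}

    seen: set[str] = set()
    rows = []
    margin = config.edge_margin
    while len(rows) < config.n_eccdna:
        chrom = names[int(rng.choice(len(names), p=weights))]
        clen = lengths[chrom]
        length = int(sample_lengths(rng, config, 1)[0])
        if clen - 2 * margin <= length:
            continue
        start = int(rng.integers(margin, clen - margin - length + 1))
        if folds:
            w = 1.0
            for cls, class_w in weights_by_class.items():
                if iv.point_in(merged_by_class[cls], chrom, start):
                    w *= class_w
            if rng.random() >= w / max_w:
                continue
        end = start + length
        rec_id = f"{chrom}: {start + 1}-{end}"
        if rec_id in seen:
            continue
        seen.add(rec_id)
        start_classes = sorted(
            name for name, m in all_merged.items() if iv.point_in(m, chrom, start)
        )
        rows.append(
            {
                "eccdna_id": rec_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "length": length,
                "start_classes": ";".join(start_classes),
                "motif_carrier": False,
                "de_status": False,
                "de_direction": "ns",
            }
        )
    population = pd.DataFrame(rows)
    truth = TruthTable(
        records=population.copy(),
        class_enrichment=dict(folds),
        chrom_weights=dict(zip(names, weights)),
    )
    return population, truth


def plant_junction_motif(
    genome: Genome,
    population: pd.DataFrame,
    motif: PlantedMotif,
    rng: np.random.Generator | None = None,
) -> tuple[Genome, np.ndarray]:
    """Rewrite the genome so flagged junctions carry the spacer motif.

    For each carrier the trinucleotide is written at offsets
    -(3 + spacer) and 0 relative to both the start and the end
    coordinate, i.e. the two copies are separated by a ``spacer``-bp
    gap. Rewrites that would collide with an earlier record's planted
    bases are skipped with a warning (their carrier flag stays False).
    Returns the modified genome and the realized carrier mask.
    """
    n = len(population)
    carriers = np.zeros(n, dtype=bool)
    if motif.fraction <= 0 or n == 0:
        return genome, carriers
    if len(motif.trinucleotide) != 3:
        raise ValueError("planted motif must be a trinucleotide")
    if motif.spacer < 0:
        raise ValueError("spacer must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    selected = rng.random(n) < motif.fraction
    seqs = {name: bytearray(seq, "ascii") for name, seq in genome.sequences.items()}
    written = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.sequences.items()}
    tri = motif.trinucleotide.encode("ascii")
    offsets = (-(3 + motif.spacer), 0)
    skipped = 0
    for i, row in enumerate(population.itertuples(index=False)):
        if not selected[i]:
            continue
        targets = [
            (pos + off, pos + off + 3)
            for pos in (row.start, row.end)
            for off in offsets
        ]
        mask = written[row.chrom]
        if any(s < 0 or e > len(mask) for s, e in targets) or any(
            mask[s:e].any() for s, e in targets
        ):
            skipped += 1
            continue
        for s, e in targets:
            seqs[row.chrom][s:e] = tri
            mask[s:e] = True
        carriers[i] = True
    if skipped:
        logger.warning("skipped %d motif rewrites due to collisions", skipped)
    new_genome = Genome({name: bts.decode("ascii") for name, bts in seqs.items()})
    return new_genome, carriers


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if np.any(mean <= 0):
        raise ValueError("negative-binomial mean must be positive")
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    population: pd.DataFrame,
    sheet: SampleSheet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample negative-binomial counts with planted group fold changes.

    The planted log2 fold change is split symmetrically: "up" records
    get group-1 means scaled by 2^(lfc/2) and group-2 means by
    2^(-lfc/2) (and conversely for "down"), so the planted pooled
    log2FC equals the configured value in expectation. Returns the
    counts matrix and a truth frame (eccdna_id, de_status, de_direction).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(population)
    if config.de.n_differential > n:
        raise ValueError("n_differential exceeds population size")
    de_idx = rng.choice(n, size=config.de.n_differential, replace=False)
    n_up = int(round(config.de.up_fraction * config.de.n_differential))
    directions = np.full(n, "ns", dtype=object)
    directions[de_idx[:n_up]] = "up"
    directions[de_idx[n_up:]] = "down"

    g1, _g2 = sheet.group_order
    half = config.de.log2fc / 2
    scale_up = 2.0**half
    scale_dn = 2.0**-half
    base = np.full(n, config.counts.mean, dtype=float)
    lib = config.counts.library_factors
    data = {}
    for sample in sheet.samples:
        in_g1 = sheet.groups[sample] == g1
        mu = base.copy()
        up_mask = directions == "up"
        dn_mask = directions == "down"
        if in_g1:
            mu[up_mask] *= scale_up
            mu[dn_mask] *= scale_dn
        else:
            mu[up_mask] *= scale_dn
            mu[dn_mask] *= scale_up
        mu *= lib.get(sample, 1.0)
        data[sample] = _nb_draw(rng, mu, config.counts.dispersion)
    counts = pd.DataFrame(data, index=population["eccdna_id"])
    counts.index.name = "eccdna_id"
    de_truth = pd.DataFrame(
        {
            "eccdna_id": population["eccdna_id"],
            "de_status": directions != "ns",
            "de_direction": directions,
        }
    )
    return counts, de_truth


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, plus file paths if written."""

    config: SimulationConfig
    genome: Genome
    annotations: dict[str, ElementAnnotation]
    genes: pd.DataFrame
    population: pd.DataFrame
    counts: pd.DataFrame
    truth: TruthTable
    sheet: SampleSheet
    de_genes: pd.DataFrame
    paths: dict[str, object] = field(default_factory=dict)

    def records(self, sample: str | None = None) -> list[EccDNARecord]:
        """Records with nonzero count in ``sample`` (or all records when None)."""
        out = []
        for i, row in enumerate(self.population.itertuples(index=False)):
            counts_row = self.counts.iloc[i]
            if sample is None:
                counts = {s: int(c) for s, c in counts_row.items() if c > 0}
                if not counts:
                    continue
                out.append(EccDNARecord(row.chrom, row.start, row.end, counts))
            else:
                c = int(counts_row[sample])
                if c > 0:
                    out.append(
                        EccDNARecord(row.chrom, row.start, row.end, {sample: c}, sample)
                    )
        return out


def _synthesize_de_genes(
    dataset_population: pd.DataFrame,
    de_truth: pd.DataFrame,
    genes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build a differential-gene table that echoes part of the planted signal."""
    pop = dataset_population.merge(de_truth, on="eccdna_id", suffixes=("", "_de"))
    host = map_host_genes(
        pop[["eccdna_id", "chrom", "start", "end"]], genes, flank=GENE_FLANK
    )
    gene_dir: dict[str, str] = {}
    for row in pop.itertuples(index=False):
        if row.de_direction == "ns":
            continue
        for gene in sorted(host.get(row.eccdna_id, ())):
            if gene not in gene_dir and rng.random() < config.de_gene_agreement:
                gene_dir[gene] = row.de_direction
    unused = [g for g in genes["symbol"] if g not in gene_dir]
    n_noise = min(config.n_noise_de_genes, len(unused))
    if n_noise:
        noise = rng.choice(len(unused), size=n_noise, replace=False)
        for j in noise:
            gene_dir[unused[j]] = "up" if rng.random() < 0.5 else "down"
    rows = [
        {
            "symbol": g,
            "log2fc": config.de.log2fc if d == "up" else -config.de.log2fc,
            "q": 1e-6,
            "direction": d,
        }
        for g, d in sorted(gene_dir.items())
    ]
    return pd.DataFrame(rows, columns=["symbol", "log2fc", "q", "direction"])


def simulate(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Run the full generator; optionally write the fixture file set.

    Files written under ``outdir``: genome.fa, elements/<class>.bed,
    genes.bed, eccdna/<sample>.bed, counts.tsv, samples.tsv, truth.tsv,
    de_genes.tsv, and the resolved config as config.yaml.
    """
    rng = np.random.default_rng(config.seed)
    genome, annotations, genes = simulate_genome(config, rng)
    population, truth = simulate_eccdna_population(genome, annotations, config, rng)
    genome, carriers = plant_junction_motif(genome, population, config.planted_motif, rng)
    population["motif_carrier"] = carriers
    sheet = config.sheet()
    counts, de_truth = simulate_counts(population, sheet, config, rng)
    population["de_status"] = de_truth["de_status"].to_numpy()
    population["de_direction"] = de_truth["de_direction"].to_numpy()
    truth.records = population.copy()
    de_genes = _synthesize_de_genes(population, de_truth, genes, config, rng)

    dataset = SimulatedDataset(
        config=config,
        genome=genome,
        annotations=annotations,
        genes=genes,
        population=population,
        counts=counts,
        truth=truth,
        sheet=sheet,
        de_genes=de_genes,
    )
    if outdir is not None:
        dataset.paths = write_fixture_set(dataset, outdir)
    return dataset


def write_fixture_set(dataset: SimulatedDataset, outdir: str | Path) -> dict:
    """Write every artifact of a simulated dataset as plain-text files."""
    outdir = Path(outdir)
    (outdir / "elements").mkdir(parents=True, exist_ok=True)
    (outdir / "eccdna").mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    genome_path = outdir / "genome.fa"
    dataset.genome.to_fasta(genome_path)
    paths["genome"] = genome_path
    element_paths = {}
    for name, ann in sorted(dataset.annotations.items()):
        p = outdir / "elements" / f"{name}.bed"
        ann.to_bed(p)
        element_paths[name] = p
    paths["elements"] = element_paths
    genes_path = outdir / "genes.bed"
    dataset.genes.to_csv(genes_path, sep="\t", header=False, index=False)
    paths["genes"] = genes_path
    bed_paths = {}
    for sample in dataset.sheet.samples:
        p = outdir / "eccdna" / f"{sample}.bed"
        write_eccdna_bed(dataset.records(sample), p)
        bed_paths[sample] = p
    paths["eccdna_beds"] = bed_paths
    counts_path = outdir / "counts.tsv"
    write_counts(dataset.counts, counts_path)
    paths["counts"] = counts_path
    samples_path = outdir / "samples.tsv"
    dataset.sheet.to_tsv(samples_path)
    paths["samples"] = samples_path
    truth_path = outdir / "truth.tsv"
    dataset.truth.records.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    de_genes_path = outdir / "de_genes.tsv"
    dataset.de_genes.to_csv(de_genes_path, sep="\t", index=False)
    paths["de_genes"] = de_genes_path
    config_path = outdir / "config.yaml"
    dataset.config.to_yaml(config_path)
    paths["config"] = config_path
    return paths
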