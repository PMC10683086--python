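"""End-to-end orchestration: characterize -> density -> annotation -> motif
-> differential -> conjoint, with a machine-readable report.

Results go to files only (TSV/JSON under the output directory); logging,
including per-stage timers, goes to stderr. ``report.json`` contains no
timestamps so that two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chrom_density as cd
from . import conjoint as cj
from . import differential as diff
from . import motif as mt
from .annotation import normalized_coverage_table, repeat_read_fraction
from .characterize import gc_values, per_sample_counts, size_stats, wilcoxon_rank_sum
from .core_io import (
    ElementAnnotation,
    Genome,
    SampleSheet,
    filter_records_to_genome,
    read_counts,
    read_de_genes,
    read_eccdna_bed,
    read_gene_bed,
)
from .synthetic import SimulationConfig, simulate

logger = logging.getLogger("ecckit")

SCHEMA_VERSION = 1

ELEMENT_CLASSES = ("exon", "intron", "UTR5", "UTR3", "Gene2KbU", "Gene2KbD", "CpG", "Alu")
REPEAT_CLASSES = ("satellite", "LINE", "SINE", "LTR", "DNA", "simple_repeat")


@dataclass
class PipelineParams:
    bin_width: int = 10
    smooth_sd: float = 2.0
    flank_w: int = 10
    spacer_max: int = 8
    fc_threshold: float = 2.0
    q_threshold: float = 0.001
    pseudocount: float = 0.5
    exclude_chroms: tuple[str, ...] = ()


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path = "ecckit_out"
    simulate: SimulationConfig | None = None
    paths: dict = field(default_factory=dict)
    params: PipelineParams = field(default_factory=PipelineParams)
    group_order: tuple[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if isinstance(kwargs.get("simulate"), dict):
            kwargs["simulate"] = SimulationConfig.from_dict(kwargs["simulate"])
        if isinstance(kwargs.get("params"), dict):
            p = dict(kwargs["params"])
            if "exclude_chroms" in p:
                p["exclude_chroms"] = tuple(p["exclude_chroms"])
            kwargs["params"] = PipelineParams(**p)
        if kwargs.get("group_order") is not None:
            kwargs["group_order"] = tuple(kwargs["group_order"])
        return cls(**kwargs)


def default_config(seed: int = 0, outdir: str | Path = "ecckit_out") -> PipelineConfig:
    """The bundled synthetic demonstration: simulate, then run every stage."""
    return PipelineConfig(seed=seed, outdir=outdir, simulate=SimulationConfig(seed=seed))


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        yield
    except Exception:
        logger.error("stage %s: FAILED after %.1fs", name, time.perf_counter() - t0)
        raise
    logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)


def _load_inputs(config: PipelineConfig, outdir: Path) -> dict:
    if config.simulate is not None:
        sim_cfg = config.simulate
        if sim_cfg.seed != config.seed:
            sim_cfg = SimulationConfig.from_dict(
                {**_sim_cfg_dict(sim_cfg), "seed": config.seed}
            )
        with _stage("simulate"):
            dataset = simulate(sim_cfg, outdir / "sim")
        sheet = dataset.sheet
        records_by_sample = {s: dataset.records(s) for s in sheet.samples}
        return {
            "genome": dataset.genome,
            "annotations": dataset.annotations,
            "genes": dataset.genes,
            "records_by_sample": records_by_sample,
            "counts": dataset.counts,
            "sheet": sheet,
            "de_genes": dataset.de_genes,
            "population": dataset.population,
        }

    paths = config.paths
    required = ("genome", "elements_dir", "eccdna_beds", "counts", "samples")
    missing = [
        key for key in required
        if key not in paths
        or (key != "eccdna_beds" and not Path(paths[key]).exists())
    ]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")
    with _stage("load"):
        genome = Genome.from_fasta(paths["genome"])
        annotations = {
            p.stem: ElementAnnotation.from_bed(p)
            for p in sorted(Path(paths["elements_dir"]).glob("*.bed"))
        }
        sheet = SampleSheet.from_tsv(paths["samples"], config.group_order)
        records_by_sample = {
            sample: filter_records_to_genome(read_eccdna_bed(path, sample), genome)
            for sample, path in paths["eccdna_beds"].items()
        }
        counts = read_counts(paths["counts"])
        genes = read_gene_bed(paths["genes"]) if "genes" in paths else None
        de_genes = read_de_genes(paths["de_genes"]) if "de_genes" in paths else None
    return {
        "genome": genome,
        "annotations": annotations,
        "genes": genes,
        "records_by_sample": records_by_sample,
        "counts": counts,
        "sheet": sheet,
        "de_genes": de_genes,
        "population": None,
    }


def _sim_cfg_dict(cfg: SimulationConfig) -> dict:
    import dataclasses

    d = dataclasses.asdict(cfg)
    d["group_order"] = list(cfg.group_order)
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    inputs = _load_inputs(config, outdir)
    genome = inputs["genome"]
    annotations = inputs["annotations"]
    sheet: SampleSheet = inputs["sheet"]
    records_by_sample = inputs["records_by_sample"]
    by_group = {
        g: [r for s in sheet.samples_in(g) for r in records_by_sample.get(s, [])]
        for g in sheet.group_order
    }
    all_records = [r for recs in records_by_sample.values() for r in recs]
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "params": {
            "bin_width": params.bin_width,
            "smooth_sd": params.smooth_sd,
            "flank_w": params.flank_w,
            "spacer_range": [0, params.spacer_max],
            "fc_threshold": params.fc_threshold,
            "q_threshold": params.q_threshold,
            "pseudocount": params.pseudocount,
            "exclude_chroms": list(params.exclude_chroms),
        },
    }

    with _stage("characterize"):
        counts_table = per_sample_counts(records_by_sample, sheet)
        rows = []
        for sample in sheet.samples:
            recs = records_by_sample.get(sample, [])
            gc = gc_values(genome, recs)
            stats_ = size_stats(recs, params.bin_width, params.smooth_sd) if recs else None
            rows.append(
                {
                    "sample": sample,
                    "group": sheet.groups[sample],
                    "n_eccdna": len(recs),
                    "gc_mean": float(gc.mean()) if gc.size else float("nan"),
                    "median_bp": stats_.median if stats_ else float("nan"),
                    "p75_bp": stats_.p75 if stats_ else float("nan"),
                    "fraction_below_1kb": stats_.fraction_below_1kb if stats_ else float("nan"),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "characterize.tsv", sep="\t", index=False)
        group_summ = {}
        size_rows = []
        for g in sheet.group_order:
            recs = by_group[g]
            gc = gc_values(genome, recs)
            stats_ = size_stats(recs, params.bin_width, params.smooth_sd)
            for bin_start, count in stats_.histogram:
                size_rows.append({"group": g, "bin_start_bp": bin_start, "count": count})
            group_summ[g] = {
                "n_eccdna": len(recs),
                "gc_mean_pct": float(gc.mean() * 100),
                "median_bp": stats_.median,
                "p75_bp": stats_.p75,
                "fraction_below_1kb": stats_.fraction_below_1kb,
                "peaks_bp": stats_.peaks,
            }
        pd.DataFrame(size_rows).to_csv(outdir / "sizes.tsv", sep="\t", index=False)
        g1, g2 = sheet.group_order
        _, gc_p = wilcoxon_rank_sum(gc_values(genome, by_group[g1]), gc_values(genome, by_group[g2]))
        _, size_p = wilcoxon_rank_sum(
            [r.length for r in by_group[g1]], [r.length for r in by_group[g2]]
        )
        report["characterize"] = {
            "per_sample": {r["sample"]: r["n_eccdna"] for r in rows},
            "groups": group_summ,
            "wilcoxon_gc_p": gc_p,
            "wilcoxon_size_p": size_p,
        }

    with _stage("chrom_density"):
        gene_ann = annotations.get("gene")
        alu_ann = annotations.get("Alu")
        density_section = {}
        for g in sheet.group_order:
            table, correlations = cd.chrom_density_table(
                by_group[g], genome, gene_ann, alu_ann, params.exclude_chroms
            )
            table.to_csv(outdir / f"chrom_density_{g}.tsv", sep="\t")
            density_section[g] = correlations
        with open(outdir / "correlations.json", "w") as fh:
            json.dump(density_section, fh, indent=2, sort_keys=True)
        report["chrom_density"] = density_section

    with _stage("genomic_annotation"):
        element_anns = [annotations[c] for c in ELEMENT_CLASSES if c in annotations]
        cov = normalized_coverage_table(all_records, element_anns, genome)
        cov.to_csv(outdir / "normalized_coverage.tsv", sep="\t", index=False)
        repeat_anns = [annotations[c] for c in REPEAT_CLASSES if c in annotations]
        rep = repeat_read_fraction(all_records, repeat_anns)
        rep.to_csv(outdir / "repeat_fraction.tsv", sep="\t", index=False)
        report["genomic_annotation"] = {
            "normalized_coverage": dict(zip(cov["class"], cov["ratio"])),
            "repeat_read_pct": dict(zip(rep["class"], rep["percent"])),
        }

    with _stage("junction_motif"):
        background = mt.genome_background_trinuc(genome)
        motif_section = {}
        profile_rows = []
        logo_rows = []
        for g in sheet.group_order:
            starts, ends, _ = mt.collect_flanks(genome, by_group[g], params.flank_w)
            profiles = {
                "start": mt.build_motif_profile(starts, background, "start"),
                "end": mt.build_motif_profile(ends, background, "end"),
                "pooled": mt.build_motif_profile(starts + ends, background, "pooled"),
            }
            for side, prof in profiles.items():
                melted = prof.enrichment.reset_index().melt(
                    id_vars="offset", var_name="trinucleotide", value_name="enrichment"
                )
                melted.insert(0, "group", g)
                melted.insert(1, "side", side)
                melted["obs"] = prof.trinuc_obs.reset_index().melt(id_vars="offset")["value"]
                profile_rows.append(melted)
                logo = prof.nucleotide_freq.reset_index()
                logo.insert(0, "group", g)
                logo.insert(1, "side", side)
                logo_rows.append(logo)
            scan = mt.spacer_scan(profiles["pooled"], range(0, params.spacer_max + 1))
            motif_section[g] = {
                "best_trinucleotide": scan.trinucleotide,
                "best_spacer": scan.spacer,
                "best_offsets": list(scan.offsets),
                "score": scan.score,
                "per_spacer": scan.per_spacer.to_dict(orient="records"),
            }
        pd.concat(profile_rows).to_csv(outdir / "motif_profile.tsv", sep="\t", index=False)
        pd.concat(logo_rows).to_csv(outdir / "logo_matrix.tsv", sep="\t", index=False)
        with open(outdir / "spacer_scan.json", "w") as fh:
            json.dump(motif_section, fh, indent=2, sort_keys=True)
        report["junction_motif"] = {
            g: {k: v for k, v in sec.items() if k != "per_spacer"}
            for g, sec in motif_section.items()
        }

    with _stage("differential"):
        table, summary = diff.call_differential(
            inputs["counts"], sheet, params.fc_threshold, params.q_threshold, params.pseudocount
        )
        table.to_csv(outdir / "differential.tsv", sep="\t")
        report["differential"] = summary

    conjoint_possible = inputs["genes"] is not None and inputs["de_genes"] is not None
    if conjoint_possible:
        with _stage("conjoint"):
            if inputs["population"] is not None:
                intervals = inputs["population"][["eccdna_id", "chrom", "start", "end"]]
            else:
                from .core_io import parse_display_id

                parsed = [parse_display_id(i) for i in table.index]
                intervals = pd.DataFrame(
                    {
                        "eccdna_id": table.index,
                        "chrom": [p[0] for p in parsed],
                        "start": [p[1] for p in parsed],
                        "end": [p[2] for p in parsed],
                    }
                )
            host = cj.map_host_genes(intervals, inputs["genes"])
            overlap = cj.overlap_same_direction(table, host, inputs["de_genes"])
            overlap.shared_eccdnas.to_csv(outdir / "overlap_eccdnas.tsv", sep="\t", index=False)
            overlap.shared_genes.to_csv(outdir / "overlap_genes.tsv", sep="\t", index=False)
            venn = cj.venn_counts(overlap, table, inputs["de_genes"])
            with open(outdir / "venn.json", "w") as fh:
                json.dump(venn, fh, indent=2, sort_keys=True)
            report["conjoint"] = {"counts": overlap.counts, "venn": venn}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; report at %s", outdir / "report.json")
    return report
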