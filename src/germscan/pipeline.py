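"""End-to-end orchestration: simulate -> Fst scan -> classify -> annotate ->
evaluate -> panel -> liftover -> LEM library, with per-stage counts logged and
a machine-readable summary."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as mclassify
from . import diffscan, evaluate, funcanno, lemdb, liftmap, panel, synthpop
from . import io as gio
from .model import Variant

log = logging.getLogger("germscan")


@dataclass
class PipelineConfig:
    """All stage parameters with their default thresholds.

    Defaults: 100-kb windows stepped 10 kb, <10-SNP windows excluded, top 5%
    of windows merged into regions; typing thresholds 0.05/0.95 (fixation)
    and 0.20/0.80 (polymorphism); RSF bands 0.30/0.80 with a 0.50 simple
    threshold; 20-Mb panel spacing; 500-bp ARMS InDel exclusion; 5-marker
    panel at per-marker accuracy 0.95; 100-bp flanks; MAF >= 0.01 LEM filter.
    """

    seed: int = 0
    window: int = 100_000
    step: int = 10_000
    min_snps: int = 10
    top_fraction: float = 0.05
    fixed_low: float = 0.05
    fixed_high: float = 0.95
    poly_low: float = 0.20
    poly_high: float = 0.80
    min_called: int = 10
    rsf_wild_max: float = 0.30
    rsf_cult_min: float = 0.80
    rsf_simple: float = 0.50
    min_markers: int = 10
    dup_threshold: float = 0.99
    min_spacing: int = 20_000_000
    arms_flank: int = 500
    panel_n: int = 5
    panel_p: float = 0.95
    flank: int = 100
    maf_threshold: float = 0.01
    mode: str = "three_band"
    sim: synthpop.SimConfig = field(default_factory=synthpop.default_config)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            windows = [synthpop.PlantedWindow(**w) for w in sim.pop("planted_windows", [])]
            lems = [synthpop.PlantedLEM(**l) for l in sim.pop("planted_lems", [])]
            bg = sim.pop("bg_beta", (2.0, 0.5))
            cfg.sim = synthpop.SimConfig(
                planted_windows=windows, planted_lems=lems,
                bg_beta=tuple(bg), **sim,
            )
        return cfg


def full_run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a simulated dataset; returns the summary dict.

    Artifacts (tables, FASTA/GFF3/VCF, summary.json) land in ``outdir``; each
    stage logs its input/retained/excluded counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    ds = synthpop.simulate_dataset(sim_cfg)
    ds.write(outdir / "sim")
    summary["n_variants"] = ds.matrix.n_variants
    summary["n_accessions"] = ds.matrix.n_accessions
    log.info("simulate: %d variants x %d accessions", ds.matrix.n_variants,
             ds.matrix.n_accessions)

    comp = diffscan.fst_components_table(ds.matrix, ds.pops)
    windows = diffscan.window_scan(
        comp, window=config.window, step=config.step, min_snps=config.min_snps,
        chrom_lengths={c: len(s) for c, s in ds.genome.items()},
    )
    threshold, regions = diffscan.call_regions(windows, top_fraction=config.top_fraction)
    diffscan.regions_frame(regions).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    gio.write_regions_bed(regions, outdir / "regions.bed")
    summary["n_windows"] = len(windows)
    summary["fst_threshold"] = threshold
    summary["n_regions"] = len(regions)
    log.info("fst-scan: %d windows (excluded %d low-SNP), threshold %.4f, %d regions",
             len(windows), windows.attrs.get("n_excluded_min_snps", 0), threshold,
             len(regions))

    thr = mclassify.TypeThresholds(config.fixed_low, config.fixed_high,
                                   config.poly_low, config.poly_high)
    markers = mclassify.classify_in_regions(
        ds.matrix, ds.pops, regions, "both", thresholds=thr,
        min_called=config.min_called,
    )
    gio.write_marker_table(markers, outdir / "markers.tsv", overwrite=True)
    type_counts = markers["mtype"].value_counts().to_dict()
    summary["marker_counts"] = {k: int(v) for k, v in type_counts.items()}
    log.info("classify: %s", summary["marker_counts"])

    annotations = funcanno.annotate_matrix(ds.matrix, ds.gene_models, ds.genome)
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    summary["n_exonic"] = int((annotations["region"] == "exonic").sum())
    summary["n_lem"] = int(annotations["is_lem"].sum())

    report = evaluate.rsf_report(ds.matrix, markers, mode=config.mode,
                                 min_markers=config.min_markers)
    report.to_csv(outdir / "rsf_report.tsv", sep="\t", index=False)
    truth_origin = dict(zip(ds.truth.accessions["accession"],
                            ds.truth.accessions["origin"]))
    called = report[~report["low_data"]]
    agree = sum(
        1 for r in called.itertuples(index=False)
        if truth_origin.get(r.accession, "").startswith(("wild", "cultivated"))
        and r.call == truth_origin[r.accession]
    )
    denom = sum(1 for r in called.itertuples(index=False)
                if truth_origin.get(r.accession, "") in ("wild", "cultivated"))
    summary["rsf_call_agreement"] = agree / denom if denom else float("nan")

    dup_pairs = evaluate.find_duplicates(ds.matrix, threshold=config.dup_threshold)
    pd.DataFrame(
        [(p.accession_a, p.accession_b, p.concordance, p.n_compared) for p in dup_pairs],
        columns=["accession_a", "accession_b", "concordance", "n_compared"],
    ).to_csv(outdir / "duplicates.tsv", sep="\t", index=False)
    summary["n_duplicate_pairs"] = len(dup_pairs)

    typed = markers[markers["mtype"] != "none"]
    trimmed = panel.trim_by_distance(typed, min_spacing=config.min_spacing)
    trimmed.to_csv(outdir / "panel.tsv", sep="\t", index=False)
    summary["n_trimmed_markers"] = len(trimmed)
    summary["panel_accuracy"] = panel.panel_accuracy(config.panel_n, config.panel_p)

    # liftover of type-1 SNP markers onto a derived assembly
    t1 = typed[(typed["mtype"] == "type1") & (typed["vclass"] == "SNP")]
    lift_markers = [Variant(r.chrom, int(r.pos), r.ref, r.alt)
                    for r in t1.itertuples(index=False)]
    protect = {}
    for v in lift_markers:
        protect.setdefault(v.chrom, []).append((v.pos - config.flank - 1,
                                                v.pos + config.flank + 1))
    target, tmap = synthpop.derive_target_genome(
        ds.genome,
        synthpop.TargetGenomeConfig(
            seed=config.seed + 1,
            revcomp_contigs=(ds.config.chrom_names()[-1],),
        ),
        protect=protect,
    )
    flanks, skipped = liftmap.extract_flanks(lift_markers, ds.genome, flank=config.flank)
    lifted = liftmap.map_all(flanks, target)
    lifted = [liftmap.confirm_allele(l, target) for l in lifted]
    liftmap.lifted_frame(lifted).to_csv(outdir / "lifted.tsv", sep="\t", index=False)
    summary["n_lift_candidates"] = len(flanks)
    summary["liftover_consistent_rate"] = (
        liftmap.validation_rate(lifted) if lifted else float("nan")
    )

    # LEM library against an independently genotyped panel on the derived assembly
    ds_b = synthpop.simulate_validation(ds, target, tmap, seed=config.seed + 2)
    lems_a = lemdb.high_freq_lems(annotations, ds.matrix, threshold=config.maf_threshold)
    ann_b = funcanno.annotate_matrix(ds_b.matrix, ds_b.gene_models, ds_b.genome)
    lems_b = lemdb.high_freq_lems(ann_b, ds_b.matrix, threshold=config.maf_threshold)
    unify = lambda c, p: ds_b.truth.liftover_pairs.get((c, p), (None, None))
    shared, discordant, concord = lemdb.intersect_populations(lems_a, lems_b, unify)
    lemdb.emit_library(shared, outdir / "lem_library.tsv")
    summary["n_lems_a"] = len(lems_a)
    summary["n_lems_b"] = len(lems_b)
    summary["n_shared_lems"] = len(shared)
    summary["n_discordant_lems"] = len(discordant)
    summary["lem_annotation_concordance"] = concord

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("full-run complete: %s", outdir / "summary.json")
    return summary
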