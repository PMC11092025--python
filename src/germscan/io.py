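"""Readers and writers for VCF, GFF3, FASTA, population tables and pipeline tables.

Standard formats go through established parsers (cyvcf2, gffutils, pyfaidx,
Biopython); the functions here only adapt them to the package's data model.
Every table writer has a matching reader and round-trips losslessly.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    GeneModel,
    GenotypeMatrix,
    PopulationTable,
    Variant,
    HOM_REF,
    HET,
    HOM_ALT,
    MISSING,
    variant_class,
)

log = logging.getLogger("germscan")


@dataclass
class VcfReadStats:
    n_records: int = 0
    n_kept: int = 0
    n_multiallelic_dropped: int = 0
    n_invalid_dropped: int = 0


def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Load a multi-sample VCF into a GenotypeMatrix.

    Only the GT field is used; phased and unphased genotypes are equivalent and
    half-missing diploid calls (``./1`` etc.) are treated as fully MISSING.
    Multiallelic records are dropped (and counted in the log) when
    ``biallelic_only`` is set.
    """
    stats = VcfReadStats()
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    rows: list[tuple[str, int, str, str, str]] = []
    call_rows: list[np.ndarray] = []
    for rec in vcf:
        stats.n_records += 1
        alts = rec.ALT
        if len(alts) != 1:
            if biallelic_only:
                stats.n_multiallelic_dropped += 1
                continue
            raise ValueError(
                f"{path}: multiallelic record at {rec.CHROM}:{rec.POS} "
                "with biallelic_only=False unsupported"
            )
        ref, alt = rec.REF, alts[0]
        if ref == alt or (len(ref) != 1 and len(alt) != 1 and len(ref) == len(alt)):
            stats.n_invalid_dropped += 1
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        calls = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:  # includes half-missing ./x
                calls[i] = MISSING
            else:
                calls[i] = HOM_REF if a + b == 0 else (HET if a + b == 1 else HOM_ALT)
        rows.append((rec.CHROM, rec.POS, ref, alt, variant_class(ref, alt)))
        call_rows.append(calls)
    vcf.close()
    stats.n_kept = len(rows)
    log.info(
        "read_vcf %s: %d records, %d kept, %d multiallelic dropped",
        path, stats.n_records, stats.n_kept, stats.n_multiallelic_dropped,
    )
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass"])
    calls = np.vstack(call_rows) if call_rows else np.empty((0, len(samples)), dtype=np.int8)
    matrix = GenotypeMatrix(variants, samples, calls)
    matrix.read_stats = stats  # type: ignore[attr-defined]
    return matrix


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal GT-only VCF 4.2 text file."""
    code_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.accessions) + "\n")
        for i, row in enumerate(matrix.variants.itertuples(index=False)):
            gts = "\t".join(code_to_gt[int(c)] for c in matrix.calls[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_population_table(path: str | Path) -> PopulationTable:
    """Read a two-column accession<TAB>label table (header optional)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            if ln == 1 and parts[0].lower() in ("accession", "sample", "id"):
                continue
            labels[parts[0]] = parts[1]
    return PopulationTable(labels)


def write_population_table(pops: PopulationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tlabel\n")
        for acc, label in pops.labels.items():
            fh.write(f"{acc}\t{label}\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (gene/mRNA/CDS/exon/UTR with Parent links) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            utrs = [
                (f.start, f.end)
                for t in ("five_prime_UTR", "three_prime_UTR", "UTR")
                for f in db.children(mrna, featuretype=t)
            ]
            if not cds:
                log.warning("mRNA %s has no CDS; skipped", mrna.id)
                continue
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    transcript_id=mrna.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    cds=sorted(cds),
                    exons=sorted(exons) if exons else sorted(cds),
                    utrs=sorted(utrs),
                )
            )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS/UTR)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(f"{m.chrom}\tgermscan\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            fh.write(f"{m.chrom}\tgermscan\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                     f"ID={m.transcript_id};Parent={m.gene_id}\n")
            for s, e in m.exons:
                fh.write(f"{m.chrom}\tgermscan\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"Parent={m.transcript_id}\n")
            for s, e in m.cds:
                fh.write(f"{m.chrom}\tgermscan\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                         f"Parent={m.transcript_id}\n")
            for s, e in m.utrs:
                fh.write(f"{m.chrom}\tgermscan\tUTR\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"Parent={m.transcript_id}\n")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# pipeline tables


def _write_table(df: pd.DataFrame, path: str | Path, overwrite: bool) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    df.to_csv(path, sep="\t", index=False)


MARKER_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vclass",
    "wild_ref_freq", "cult_ref_freq", "wild_called", "cult_called",
    "mtype", "in_region",
]


def write_marker_table(markers: pd.DataFrame, path: str | Path,
                       overwrite: bool = False) -> None:
    """Write typed markers, tab-separated, sorted by (chrom, pos), 1-based."""
    df = markers.copy()
    for col in MARKER_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"marker table missing column {col!r}")
    df = df[MARKER_COLUMNS].sort_values(["chrom", "pos"], kind="mergesort")
    _write_table(df, path, overwrite)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    df["pos"] = df["pos"].astype(np.int64)
    df["in_region"] = df["in_region"].astype(bool)
    return df


def write_regions_bed(regions, path: str | Path) -> None:
    """Export differentiation regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
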