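"""Two-population synthetic datasets with the structure the pipeline assumes.

The generator emulates a wild-vs-cultivated resequencing callset: a small
multi-chromosome genome with a grid of two-exon protein-coding genes, SNPs
and InDels whose reference-allele frequencies follow a shared
reference-biased Beta background (expected Fst ~ 0), planted high-Fst
windows realizing the three marker archetypes, Hardy-Weinberg genotype
draws, missing calls, admixed (hybrid) accessions, near-identical duplicate
accessions, and low-MAF large-effect mutations planted inside annotated
genes.  A second "assembly" can be derived from the first (substitutions,
reverse-complemented contigs, coordinate offsets) with an exact truth map,
so the liftover and cross-population stages are testable offline.

Everything is driven by one seeded generator: identical configs give
byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as gio
from .model import (
    GeneModel,
    GenotypeMatrix,
    PopulationTable,
    Variant,
    HOM_REF,
    HET,
    HOM_ALT,
    MISSING,
    WILD,
    CULTIVATED,
    UNKNOWN,
    variant_class,
)

__all__ = [
    "SimConfig",
    "PlantedWindow",
    "PlantedLEM",
    "TargetGenomeConfig",
    "SyntheticDataset",
    "TruthLiftover",
    "simulate_dataset",
    "derive_target_genome",
    "simulate_validation",
    "default_config",
]

# archetype -> (wild ref freq, cultivated ref freq)
ARCHETYPE_FREQS = {
    "type1": (0.03, 0.97),
    "type2": (0.03, 0.50),
    "type3": (0.50, 0.97),
}

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedWindow:
    """A genomic window whose variants realize an archetype's frequencies."""

    chrom: str
    start: int
    end: int
    archetype: str  # type1 | type2 | type3
    wild_ref_freq: float | None = None
    cult_ref_freq: float | None = None
    n_snps: int | None = None  # None -> from snp_density

    def freqs(self) -> tuple[float, float]:
        w, c = ARCHETYPE_FREQS[self.archetype]
        return (
            self.wild_ref_freq if self.wild_ref_freq is not None else w,
            self.cult_ref_freq if self.cult_ref_freq is not None else c,
        )


@dataclass(frozen=True)
class PlantedLEM:
    """A large-effect mutation planted inside a gridded gene."""

    gene_index: int
    effect: str  # stopgain | stoploss | startloss | frameshift | nonframeshift | splicing
    maf: float = 0.05


@dataclass
class SimConfig:
    """Study conditions of the synthetic two-population dataset.

    Sample sizes default to the test-population composition (345 wild, 418
    cultivated, 18 natural hybrids); genome shape, densities and rates are
    desk-scale defaults documented in the methods note.
    """

    seed: int = 0
    n_wild: int = 345
    n_cult: int = 418
    n_hybrids: int = 18
    n_duplicates: int = 2
    n_chrom: int = 2
    chrom_len: int = 500_000
    bg_beta: tuple[float, float] = (2.0, 0.5)  # ref-allele frequency law, both pops
    snp_density: float = 0.002
    indel_density: float = 0.0002
    missing_rate: float = 0.02
    duplicate_error: float = 0.005
    planted_windows: list[PlantedWindow] = field(default_factory=list)
    planted_lems: list[PlantedLEM] = field(default_factory=list)
    gene_spacing: int = 25_000
    edge_margin: int = 300  # keep variants clear of contig ends (full flanks)
    genic_background: bool = True  # False -> background variants avoid gene spans

    def __post_init__(self) -> None:
        for rate in (self.snp_density, self.indel_density, self.missing_rate,
                     self.duplicate_error):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.snp_density + self.indel_density > 0.2:
            raise ValueError("variant density too high (>0.2/bp)")
        for w in self.planted_windows:
            if w.start < 1 or w.end > self.chrom_len:
                raise ValueError(f"planted window {w} outside chromosome")

    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chrom)]


def default_config(seed: int = 0) -> SimConfig:
    """A full-featured demonstration config: one window per archetype, LEMs,
    hybrids and duplicates."""
    return SimConfig(
        seed=seed,
        n_chrom=3,
        chrom_len=600_000,
        # each differentiation interval carries near-fixed (type1) driver sites
        # that push the window Fst into the top quantile; the Chr02/Chr03
        # intervals additionally carry the polymorphic type2/type3 patterns,
        # mirroring how minority frequency patterns sit inside real
        # domestication regions
        planted_windows=[
            PlantedWindow("Chr01", 200_001, 300_000, "type1", n_snps=120),
            PlantedWindow("Chr02", 200_001, 300_000, "type1", n_snps=120),
            PlantedWindow("Chr02", 200_001, 300_000, "type2", n_snps=80),
            PlantedWindow("Chr03", 200_001, 300_000, "type1", n_snps=120),
            PlantedWindow("Chr03", 200_001, 300_000, "type3", n_snps=80),
        ],
        planted_lems=[
            PlantedLEM(1, "stopgain", 0.05),
            PlantedLEM(3, "frameshift", 0.05),
            PlantedLEM(5, "splicing", 0.03),
            PlantedLEM(7, "stoploss", 0.05),
            PlantedLEM(9, "startloss", 0.03),
            PlantedLEM(11, "nonframeshift", 0.05),
        ],
    )


@dataclass(frozen=True)
class ContigTransform:
    strand: str  # + / -
    prefix: int  # bases inserted before the source sequence
    source_len: int


class TruthLiftover:
    """Exact source->target coordinate map of a derived assembly."""

    def __init__(self, transforms: dict[str, ContigTransform]):
        self.transforms = transforms

    def map_snp(self, chrom: str, pos: int) -> tuple[str, int, str]:
        t = self.transforms[chrom]
        if t.strand == "+":
            return chrom, pos + t.prefix, "+"
        return chrom, t.prefix + (t.source_len - pos + 1), "-"

    def unmap(self, chrom: str, tpos: int) -> int:
        t = self.transforms[chrom]
        if t.strand == "+":
            return tpos - t.prefix
        return t.source_len - (tpos - t.prefix) + 1


@dataclass
class TruthTable:
    variants: pd.DataFrame  # chrom,pos,ref,alt,vclass,wild_ref_freq,cult_ref_freq,archetype,lem_effect
    accessions: pd.DataFrame  # accession, origin, source
    lems: pd.DataFrame  # gene_id, chrom, pos, ref, alt, effect, maf
    liftover: TruthLiftover | None = None
    liftover_pairs: dict[tuple[str, int], tuple[str, int]] | None = None


@dataclass
class SyntheticDataset:
    config: SimConfig
    genome: dict[str, str]
    gene_models: list[GeneModel]
    matrix: GenotypeMatrix
    pops: PopulationTable
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome FASTA, GFF3, VCF, population table and truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "vcf": outdir / "variants.vcf",
            "pops": outdir / "populations.tsv",
            "truth_variants": outdir / "truth_variants.tsv",
            "truth_accessions": outdir / "truth_accessions.tsv",
            "truth_lems": outdir / "truth_lems.tsv",
        }
        gio.write_fasta(self.genome, paths["fasta"])
        gio.write_gff3(self.gene_models, paths["gff3"])
        gio.write_vcf(
            self.matrix, paths["vcf"],
            contig_lengths={c: len(s) for c, s in self.genome.items()},
        )
        gio.write_population_table(self.pops, paths["pops"])
        self.truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
        self.truth.accessions.to_csv(paths["truth_accessions"], sep="\t", index=False)
        self.truth.lems.to_csv(paths["truth_lems"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# genome and gene construction

# gene architecture relative to gene start (1-based offsets, inclusive):
#   exon1 [0, 249]  = UTR [0, 49] + CDS [50, 249]
#   intron [250, 349]
#   exon2 [350, 649] = CDS [350, 599] + UTR [600, 649]
_GENE_LEN = 650
_CDS1 = (50, 249)
_CDS2 = (350, 599)
_CDS_LEN = (_CDS1[1] - _CDS1[0] + 1) + (_CDS2[1] - _CDS2[0] + 1)  # 450, % 3 == 0


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + TAA."""
    sense = [c1 + c2 + c3 for c1 in "ACGT" for c2 in "ACGT" for c3 in "ACGT"
             if c1 + c2 + c3 not in _STOPS]
    body = rng.choice(np.array(sense), size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _build_genome_and_genes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_counter = 0
    for chrom in config.chrom_names():
        seq = rng.choice(_BASES, size=config.chrom_len)
        n_genes = max(0, (config.chrom_len - 2 * config.gene_spacing) // config.gene_spacing)
        for g in range(n_genes):
            gstart = config.gene_spacing * (g + 1) + 1
            strand = "+" if gene_counter % 2 == 0 else "-"
            cds = _random_cds(rng, _CDS_LEN // 3)
            fwd = cds if strand == "+" else str(Seq(cds).reverse_complement())
            part1, part2 = fwd[: _CDS1[1] - _CDS1[0] + 1], fwd[_CDS1[1] - _CDS1[0] + 1 :]
            s1, e1 = gstart + _CDS1[0], gstart + _CDS1[1]
            s2, e2 = gstart + _CDS2[0], gstart + _CDS2[1]
            seq[s1 - 1 : e1] = np.frombuffer(part1.encode(), dtype="S1")
            seq[s2 - 1 : e2] = np.frombuffer(part2.encode(), dtype="S1")
            models.append(
                GeneModel(
                    gene_id=f"gene{gene_counter:04d}",
                    transcript_id=f"gene{gene_counter:04d}.t1",
                    chrom=chrom,
                    strand=strand,
                    cds=[(s1, e1), (s2, e2)],
                    exons=[(gstart, gstart + 249), (gstart + 350, gstart + 649)],
                    utrs=[(gstart, gstart + 49), (gstart + 600, gstart + 649)],
                )
            )
            gene_counter += 1
        genome[chrom] = seq.tobytes().decode()
    return genome, models


# ---------------------------------------------------------------------------
# planted LEM construction


def _coding_positions(model: GeneModel) -> list[int]:
    out: list[int] = []
    for s, e in model.cds:
        out.extend(range(s, e + 1))
    return out


def _coding_index_to_genomic(model: GeneModel, cidx: int) -> int:
    """Genomic position of coding-sense base ``cidx`` (0-based)."""
    positions = _coding_positions(model)
    if model.strand == "+":
        return positions[cidx]
    return positions[len(positions) - 1 - cidx]


def _comp(base: str) -> str:
    return str(Seq(base).complement())


def _plant_lem(
    lem: PlantedLEM, models: list[GeneModel], genome: dict[str, str],
    rng: np.random.Generator,
) -> Variant:
    model = models[lem.gene_index % len(models)]
    chrom_seq = genome[model.chrom]
    coding = "".join(
        chrom_seq[s - 1 : e] for s, e in model.cds
    )
    if model.strand == "-":
        coding = str(Seq(coding).reverse_complement())

    def snp_at(cidx: int, new_base_coding: str) -> Variant:
        gpos = _coding_index_to_genomic(model, cidx)
        ref = chrom_seq[gpos - 1]
        alt = new_base_coding if model.strand == "+" else _comp(new_base_coding)
        return Variant(model.chrom, gpos, ref, alt)

    if lem.effect == "stopgain":
        # find a codon one substitution away from a stop (never codon 0 / last)
        n_codons = len(coding) // 3
        order = rng.permutation(np.arange(1, n_codons - 1))
        for ci in order:
            codon = coding[3 * ci : 3 * ci + 3]
            for stop in _STOPS:
                diff = [k for k in range(3) if codon[k] != stop[k]]
                if len(diff) == 1:
                    return snp_at(3 * int(ci) + diff[0], stop[diff[0]])
        raise RuntimeError("no stopgain-capable codon found (regenerate the gene)")
    if lem.effect == "stoploss":
        # terminal TAA -> TAC (Tyr)
        cidx = len(coding) - 1
        return snp_at(cidx, "C")
    if lem.effect == "startloss":
        return snp_at(0, "C")  # ATG -> CTG
    if lem.effect == "splicing":
        intron_s, intron_e = model.introns[0]
        gpos = intron_s if model.strand == "+" else intron_e
        ref = chrom_seq[gpos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return Variant(model.chrom, gpos, ref, alt)
    if lem.effect in ("frameshift", "nonframeshift"):
        span = 1 if lem.effect == "frameshift" else 3
        s1, e1 = model.cds[0]
        anchor = int(rng.integers(s1 + 3, e1 - span - 3))
        ref = chrom_seq[anchor - 1 : anchor + span]
        return Variant(model.chrom, anchor, ref, ref[0])
    raise ValueError(f"unknown planted LEM effect {lem.effect!r}")


# ---------------------------------------------------------------------------
# main simulation


def _sample_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, forbidden: set[int],
    min_gap: int = 8,
) -> list[int]:
    """Sorted distinct positions in [lo, hi], min_gap apart, avoiding forbidden."""
    if n <= 0 or hi < lo:
        return []
    cand = np.sort(rng.choice(np.arange(lo, hi + 1), size=min(n, hi - lo + 1),
                              replace=False))
    out: list[int] = []
    last = None
    for p in cand:
        p = int(p)
        if p in forbidden:
            continue
        if last is not None and p - last < min_gap:
            continue
        out.append(p)
        last = p
    return out


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset from a config (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    genome, models = _build_genome_and_genes(config, rng)
    chrom_names = config.chrom_names()

    # planted LEM variants first (they reserve their neighbourhoods)
    lem_variants: list[tuple[Variant, PlantedLEM, str]] = []
    for lem in config.planted_lems:
        v = _plant_lem(lem, models, genome, rng)
        model = models[lem.gene_index % len(models)]
        lem_variants.append((v, lem, model.gene_id))
    forbidden: dict[str, set[int]] = {c: set() for c in chrom_names}
    for v, _, _ in lem_variants:
        forbidden[v.chrom].update(range(v.pos - 10, v.pos + 10))
    if not config.genic_background:
        for m in models:
            lo, hi = m.span
            forbidden[m.chrom].update(range(lo - 3, hi + 4))

    windows_by_chrom: dict[str, list[PlantedWindow]] = {c: [] for c in chrom_names}
    for w in config.planted_windows:
        windows_by_chrom[w.chrom].append(w)

    records: list[tuple[str, int, str, str, str, float, float, str, str, float]] = []
    # columns: chrom,pos,ref,alt,vclass,wild_f,cult_f,archetype,lem_effect,lem_maf

    for chrom in chrom_names:
        seq = genome[chrom]
        L = len(seq)
        lo, hi = config.edge_margin + 1, L - config.edge_margin
        win_spans = [(w.start, w.end) for w in windows_by_chrom[chrom]]

        def outside_windows(p: int) -> bool:
            return all(not (s <= p <= e) for s, e in win_spans)

        # background variants outside planted windows
        n_bg_snp = int(round(config.snp_density * L))
        n_bg_ind = int(round(config.indel_density * L))
        bg_pos = _sample_positions(rng, lo, hi, n_bg_snp + n_bg_ind,
                                   forbidden[chrom])
        bg_pos = [p for p in bg_pos if outside_windows(p)]
        is_indel = np.zeros(len(bg_pos), dtype=bool)
        if len(bg_pos) and n_bg_ind:
            k = min(n_bg_ind, len(bg_pos))
            is_indel[rng.choice(len(bg_pos), size=k, replace=False)] = True
        bg_freq = rng.beta(*config.bg_beta, size=len(bg_pos))
        for (p, ind, f) in zip(bg_pos, is_indel, bg_freq):
            ref, alt = _make_alleles(seq, p, bool(ind), rng)
            records.append((chrom, p, ref, alt, variant_class(ref, alt),
                            float(f), float(f), "", "", np.nan))

        # planted-window variants
        for w in windows_by_chrom[chrom]:
            wf, cf = w.freqs()
            n_w = w.n_snps if w.n_snps is not None else int(
                round(config.snp_density * (w.end - w.start + 1))
            )
            pos_w = _sample_positions(rng, max(lo, w.start), min(hi, w.end), n_w,
                                      forbidden[chrom])
            n_ind_w = int(round(len(pos_w) * config.indel_density /
                                max(config.snp_density, 1e-12)))
            ind_mask = np.zeros(len(pos_w), dtype=bool)
            if len(pos_w) and n_ind_w:
                ind_mask[rng.choice(len(pos_w), size=min(n_ind_w, len(pos_w)),
                                    replace=False)] = True
            for p, ind in zip(pos_w, ind_mask):
                ref, alt = _make_alleles(seq, p, bool(ind), rng)
                records.append((chrom, p, ref, alt, variant_class(ref, alt),
                                wf, cf, w.archetype, "", np.nan))

    for v, lem, gene_id in lem_variants:
        records.append((v.chrom, v.pos, v.ref, v.alt, v.vclass,
                        1.0 - lem.maf, 1.0 - lem.maf, "", lem.effect, lem.maf))

    truth_variants = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "vclass", "wild_ref_freq",
                 "cult_ref_freq", "archetype", "lem_effect", "lem_maf"],
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    truth_variants = truth_variants.drop_duplicates(subset=["chrom", "pos"],
                                                    keep="first").reset_index(drop=True)

    matrix, pops, truth_acc = _draw_genotypes(config, truth_variants, rng)

    lem_rows = []
    for v, lem, gene_id in lem_variants:
        lem_rows.append((gene_id, v.chrom, v.pos, v.ref, v.alt, lem.effect, lem.maf))
    truth_lems = pd.DataFrame(
        lem_rows, columns=["gene_id", "chrom", "pos", "ref", "alt", "effect", "maf"]
    )

    truth = TruthTable(truth_variants, truth_acc, truth_lems)
    return SyntheticDataset(config, genome, models, matrix, pops, truth)


def _make_alleles(
    seq: str, pos: int, indel: bool, rng: np.random.Generator
) -> tuple[str, str]:
    base = seq[pos - 1]
    if not indel:
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        return base, alt
    if rng.random() < 0.5:  # deletion of 1-3 bp
        span = int(rng.integers(1, 4))
        ref = seq[pos - 1 : pos + span]
        return ref, ref[0]
    ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))).astype(str))
    return base, base + ins


def _draw_genotypes(
    config: SimConfig, truth_variants: pd.DataFrame, rng: np.random.Generator
) -> tuple[GenotypeMatrix, PopulationTable, pd.DataFrame]:
    V = len(truth_variants)
    pw = truth_variants["wild_ref_freq"].to_numpy()
    pc = truth_variants["cult_ref_freq"].to_numpy()

    wild = 2 - rng.binomial(2, pw[:, None], size=(V, config.n_wild))
    cult = 2 - rng.binomial(2, pc[:, None], size=(V, config.n_cult))
    blocks = [wild, cult]
    names = [f"W{i + 1:04d}" for i in range(config.n_wild)] + [
        f"C{i + 1:04d}" for i in range(config.n_cult)
    ]
    labels = {n: WILD for n in names[: config.n_wild]}
    labels.update({n: CULTIVATED for n in names[config.n_wild :]})
    origins = [(n, "wild", "") for n in names[: config.n_wild]] + [
        (n, "cultivated", "") for n in names[config.n_wild :]
    ]

    if config.n_hybrids:
        a1 = rng.binomial(1, pw[:, None], size=(V, config.n_hybrids))
        a2 = rng.binomial(1, pc[:, None], size=(V, config.n_hybrids))
        hyb = 2 - (a1 + a2)
        blocks.append(hyb)
        hnames = [f"H{i + 1:04d}" for i in range(config.n_hybrids)]
        names += hnames
        labels.update({n: UNKNOWN for n in hnames})
        origins += [(n, "hybrid", "") for n in hnames]

    calls = np.concatenate(blocks, axis=1).astype(np.int8)

    if config.n_duplicates:
        src_cols = rng.choice(config.n_wild + config.n_cult,
                              size=config.n_duplicates, replace=False)
        dups = []
        for k, sc in enumerate(src_cols):
            col = calls[:, sc].copy()
            if config.duplicate_error > 0:
                flip = rng.random(V) < config.duplicate_error
                for i in np.flatnonzero(flip):
                    choices = [g for g in (HOM_REF, HET, HOM_ALT) if g != col[i]]
                    col[i] = choices[int(rng.integers(0, len(choices)))]
            dups.append(col)
            dname = f"D{k + 1:04d}"
            names.append(dname)
            labels[dname] = labels[names[sc]]
            origins.append((dname, f"duplicate-of:{names[sc]}", names[sc]))
        calls = np.concatenate([calls] + [d[:, None] for d in dups], axis=1)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)

    matrix = GenotypeMatrix(
        truth_variants[["chrom", "pos", "ref", "alt", "vclass"]].copy(),
        names,
        calls.astype(np.int8),
    )
    pops = PopulationTable(labels)
    truth_acc = pd.DataFrame(origins, columns=["accession", "origin", "source"])
    return matrix, pops, truth_acc


# ---------------------------------------------------------------------------
# derived target assembly


@dataclass
class TargetGenomeConfig:
    seed: int = 0
    substitution_rate: float = 0.0005  # per bp, outside protected intervals
    revcomp_contigs: tuple[str, ...] = ()  # contig names to reverse-complement
    prefix_len: int = 1000  # bases prepended per contig (coordinate offset)


def derive_target_genome(
    genome: dict[str, str],
    config: TargetGenomeConfig = TargetGenomeConfig(),
    protect: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[dict[str, str], TruthLiftover]:
    """Derive a second assembly: substitutions, RC contigs, prefix offsets.

    ``protect`` lists source intervals (e.g. planted-marker flanks) excluded
    from substitutions.  The returned TruthLiftover records the exact affine
    map and strand per contig.
    """
    rng = np.random.default_rng(config.seed)
    target: dict[str, str] = {}
    transforms: dict[str, ContigTransform] = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        if config.substitution_rate > 0:
            protected = np.zeros(len(arr), dtype=bool)
            for s, e in (protect or {}).get(chrom, []):
                protected[max(0, s - 1) : e] = True
            hit = (rng.random(len(arr)) < config.substitution_rate) & ~protected
            for i in np.flatnonzero(hit):
                cur = arr[i].decode()
                arr[i] = str(rng.choice([b for b in "ACGT" if b != cur])).encode()
        out = arr.tobytes().decode()
        strand = "+"
        if chrom in config.revcomp_contigs:
            out = str(Seq(out).reverse_complement())
            strand = "-"
        prefix = ""
        if config.prefix_len > 0:
            prefix = "".join(rng.choice(_BASES, size=config.prefix_len).astype(str))
        target[chrom] = prefix + out
        transforms[chrom] = ContigTransform(strand, len(prefix), len(seq))
    return target, TruthLiftover(transforms)


# ---------------------------------------------------------------------------
# validation dataset on the derived assembly


def simulate_validation(
    dataset: SyntheticDataset,
    target_genome: dict[str, str],
    liftover: TruthLiftover,
    n_wild: int = 103,
    n_cult: int = 200,
    keep_fraction: float = 1.0,
    discordant_lems: int = 0,
    missing_rate: float | None = None,
    seed: int = 1,
) -> SyntheticDataset:
    """Re-express the source dataset's variants on the derived assembly and
    re-draw genotypes for an independent accession panel.

    Planted LEMs are always carried over; a random ``1 - keep_fraction`` of
    the remaining variants is dropped (emulating sites absent from the second
    callset).  ``discordant_lems`` planted SNP-class LEMs on forward-mapped
    contigs are replaced by a 1-bp frameshift deletion at the same unified
    position, creating position-shared but annotation-discordant records.
    The truth table's ``liftover_pairs`` maps each target-variant key back to
    its source key.
    """
    rng = np.random.default_rng(seed)
    src = dataset.truth.variants
    lem_keys = {(r.chrom, int(r.pos)) for r in dataset.truth.lems.itertuples(index=False)}

    keep = np.ones(len(src), dtype=bool)
    if keep_fraction < 1.0:
        drop_ok = np.array(
            [(c, int(p)) not in lem_keys for c, p in zip(src["chrom"], src["pos"])]
        )
        rnd = rng.random(len(src))
        keep = ~(drop_ok & (rnd > keep_fraction))

    # choose which planted LEMs become annotation-discordant: a 1-bp deletion
    # at the SNP anchor must still remove a coding base, so the anchor's next
    # base has to lie inside the CDS of the same gene
    gene_by_id = {m.gene_id: m for m in dataset.gene_models}
    snp_lems_fwd = [
        (r.chrom, int(r.pos))
        for r in dataset.truth.lems.itertuples(index=False)
        if len(r.ref) == 1 and len(r.alt) == 1
        and r.effect in ("stopgain", "startloss")
        and liftover.transforms[r.chrom].strand == "+"
        and gene_by_id[r.gene_id].in_cds(int(r.pos) + 1)
    ]
    discordant = set(snp_lems_fwd[:discordant_lems])
    if len(discordant) < discordant_lems:
        raise ValueError(
            f"only {len(discordant)} forward-strand SNP LEMs available for "
            f"discordance (requested {discordant_lems})"
        )

    rows = []
    pairs: dict[tuple[str, int], tuple[str, int]] = {}
    for i in np.flatnonzero(keep):
        r = src.iloc[i]
        chrom, pos = r.chrom, int(r.pos)
        t = liftover.transforms[chrom]
        tchrom = chrom
        R = len(r.ref)
        is_snp = R == 1 and len(r.alt) == 1
        if t.strand == "+":
            if (chrom, pos) in discordant:
                ta = pos + t.prefix
                ref_t = target_genome[tchrom][ta - 1 : ta + 1]
                alt_t = ref_t[0]
            elif is_snp or len(r.alt) > R:  # SNP or insertion: anchor maps directly
                ta = pos + t.prefix
                ref_t = target_genome[tchrom][ta - 1 : ta - 1 + R]
                alt_t = r.alt if ref_t == r.ref else None
                if alt_t is None:  # substitution hit the site; drop
                    continue
            else:  # deletion
                ta = pos + t.prefix
                ref_t = target_genome[tchrom][ta - 1 : ta - 1 + R]
                if ref_t != r.ref:
                    continue
                alt_t = ref_t[0]
        else:
            Lc, f = t.source_len, t.prefix
            if is_snp:
                ta = f + (Lc - pos + 1)
                ref_t = target_genome[tchrom][ta - 1]
                if ref_t != _comp(r.ref):
                    continue
                alt_t = _comp(r.alt)
            elif R > len(r.alt):  # deletion
                ta = f + Lc - pos - R + 1
                if ta < 1:
                    continue
                ref_t = target_genome[tchrom][ta - 1 : ta - 1 + R]
                alt_t = ref_t[0]
            else:  # insertion
                ta = f + Lc - pos
                if ta < 1:
                    continue
                ref_t = target_genome[tchrom][ta - 1]
                alt_t = ref_t + str(Seq(r.alt[1:]).reverse_complement())
        if ref_t == alt_t:
            continue
        rows.append((tchrom, ta, ref_t, alt_t, variant_class(ref_t, alt_t),
                     float(r.wild_ref_freq), float(r.cult_ref_freq),
                     r.archetype, r.lem_effect, r.lem_maf))
        pairs[(tchrom, ta)] = (chrom, pos)

    tv = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "vclass", "wild_ref_freq",
                 "cult_ref_freq", "archetype", "lem_effect", "lem_maf"],
    ).sort_values(["chrom", "pos"], kind="mergesort")
    tv = tv.drop_duplicates(subset=["chrom", "pos"], keep="first").reset_index(drop=True)

    cfg_b = replace(
        dataset.config, seed=seed, n_wild=n_wild, n_cult=n_cult,
        n_hybrids=0, n_duplicates=0,
        missing_rate=dataset.config.missing_rate if missing_rate is None else missing_rate,
    )
    matrix, pops, truth_acc = _draw_genotypes(cfg_b, tv, rng)

    # target-space gene models
    t_models = []
    for m in dataset.gene_models:
        t = liftover.transforms[m.chrom]
        if t.strand == "+":
            shift = lambda iv: (iv[0] + t.prefix, iv[1] + t.prefix)
            strand = m.strand
        else:
            Lc, f = t.source_len, t.prefix
            shift = lambda iv: (f + Lc - iv[1] + 1, f + Lc - iv[0] + 1)
            strand = "-" if m.strand == "+" else "+"
        t_models.append(
            GeneModel(m.gene_id, m.transcript_id, m.chrom, strand,
                      cds=[shift(iv) for iv in m.cds],
                      exons=[shift(iv) for iv in m.exons],
                      utrs=[shift(iv) for iv in m.utrs])
        )

    lem_rows = []
    inv = {v: k for k, v in pairs.items()}
    for r in dataset.truth.lems.itertuples(index=False):
        tkey = inv.get((r.chrom, int(r.pos)))
        if tkey is None:
            continue
        row = tv[(tv["chrom"] == tkey[0]) & (tv["pos"] == tkey[1])].iloc[0]
        effect = "frameshift" if (r.chrom, int(r.pos)) in discordant else r.effect
        lem_rows.append((r.gene_id, tkey[0], tkey[1], row.ref, row.alt, effect, r.maf))
    truth_lems = pd.DataFrame(
        lem_rows, columns=["gene_id", "chrom", "pos", "ref", "alt", "effect", "maf"]
    )

    truth = TruthTable(tv, truth_acc, truth_lems, liftover=liftover,
                       liftover_pairs=pairs)
    return SyntheticDataset(cfg_b, target_genome, t_models, matrix, pops, truth)
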