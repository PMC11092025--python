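"""Natural-mutant (LEM) library: MAF filters, cross-population intersection.

High-frequency large-effect mutations (MAF >= 0.01, boundary inclusive) from
two independently genotyped datasets are superimposed on unified coordinates;
a mutation enters the library only if both datasets carry it at the same
(unified) position with the same gene and effect annotation.  Position-shared
but annotation-discordant records are counted separately — the fraction
concordant quantifies how strongly the choice of reference assembly and
annotation drives large-effect calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, HET, HOM_ALT, MISSING

__all__ = [
    "MAFRecord",
    "LEMRecord",
    "compute_maf",
    "maf_table",
    "high_freq_lems",
    "intersect_populations",
    "emit_library",
]


@dataclass(frozen=True)
class MAFRecord:
    chrom: str
    pos: int
    maf: float
    n_alleles: int


@dataclass
class LEMRecord:
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str
    maf: float
    carriers: list[str] = field(default_factory=list)
    shared: bool = False


def maf_table(
    matrix: GenotypeMatrix, accession_subset: list[str] | None = None
) -> pd.DataFrame:
    """Minor-allele frequency per variant over non-missing alleles."""
    m = matrix if accession_subset is None else matrix.subset_accessions(accession_subset)
    calls = m.calls
    n_het = (calls == HET).sum(axis=1)
    n_alt = (calls == HOM_ALT).sum(axis=1)
    called = (calls != MISSING).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_alt = (2 * n_alt + n_het) / (2 * called)
    df = matrix.variants[["chrom", "pos"]].copy()
    df["alt_freq"] = f_alt
    df["maf"] = np.minimum(f_alt, 1 - f_alt)
    df["n_alleles"] = 2 * called
    return df


def compute_maf(
    matrix: GenotypeMatrix, variant, accession_subset: list[str] | None = None
) -> MAFRecord:
    """MAF for one variant (errors when every genotype is missing)."""
    table = maf_table(matrix, accession_subset)
    hit = table[(table["chrom"] == variant.chrom) & (table["pos"] == variant.pos)]
    if len(hit) == 0:
        raise KeyError(f"variant {variant.chrom}:{variant.pos} not in matrix")
    row = hit.iloc[0]
    if row.n_alleles == 0:
        raise ValueError(f"all genotypes missing at {variant.chrom}:{variant.pos}")
    return MAFRecord(variant.chrom, variant.pos, float(row.maf), int(row.n_alleles))


def _carriers(matrix: GenotypeMatrix, row_index: int) -> list[str]:
    calls = matrix.calls[row_index]
    return [
        acc
        for acc, c in zip(matrix.accessions, calls)
        if c in (HET, HOM_ALT)
    ]


def high_freq_lems(
    annotations: pd.DataFrame,
    matrix: GenotypeMatrix,
    threshold: float = 0.01,
) -> list[LEMRecord]:
    """LEM variants with MAF >= threshold (inclusive), with carrier lists.

    ``annotations`` is the table from :func:`germscan.funcanno.annotate_matrix`
    computed on the same matrix.
    """
    mafs = maf_table(matrix)
    key_to_row = {
        (c, p): i
        for i, (c, p) in enumerate(zip(matrix.variants["chrom"], matrix.variants["pos"]))
    }
    out: list[LEMRecord] = []
    merged = annotations.merge(mafs[["chrom", "pos", "maf"]], on=["chrom", "pos"])
    for row in merged.itertuples(index=False):
        if not row.is_lem or not (row.maf >= threshold):
            continue
        i = key_to_row[(row.chrom, row.pos)]
        carriers = _carriers(matrix, i)
        if not carriers:
            continue
        effect = row.effect if row.effect else row.region
        out.append(
            LEMRecord(row.gene_id, row.chrom, int(row.pos), row.ref, row.alt,
                      effect, float(row.maf), carriers)
        )
    out.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return out


def intersect_populations(
    lems_a: list[LEMRecord],
    lems_b: list[LEMRecord],
    liftover_map=None,
) -> tuple[list[tuple[LEMRecord, LEMRecord]], list[tuple[LEMRecord, LEMRecord]], float]:
    """Superimpose two LEM sets on unified coordinates.

    ``liftover_map`` maps a dataset-B (chrom, pos) onto dataset-A coordinates
    (callable or dict); None means coordinates are already unified.  Returns
    (shared pairs, position-shared-but-annotation-discordant pairs, fraction
    concordant among position-shared).  Concordance is per-variant.
    """
    if liftover_map is None:
        unify = lambda c, p: (c, p)
    elif callable(liftover_map):
        unify = liftover_map
    else:
        unify = lambda c, p: liftover_map.get((c, p), (None, None))

    a_by_pos: dict[tuple[str, int], list[LEMRecord]] = {}
    for r in lems_a:
        a_by_pos.setdefault((r.chrom, r.pos), []).append(r)

    shared: list[tuple[LEMRecord, LEMRecord]] = []
    discordant: list[tuple[LEMRecord, LEMRecord]] = []
    for rb in lems_b:
        key = unify(rb.chrom, rb.pos)
        for ra in a_by_pos.get(key, []):
            if ra.gene_id == rb.gene_id and ra.effect == rb.effect:
                ra.shared = rb.shared = True
                shared.append((ra, rb))
            else:
                discordant.append((ra, rb))
    n_pos_shared = len(shared) + len(discordant)
    concordance = len(shared) / n_pos_shared if n_pos_shared else float("nan")
    return shared, discordant, concordance


def emit_library(
    shared: list[tuple[LEMRecord, LEMRecord]],
    path=None,
) -> pd.DataFrame:
    """One row per shared (gene, variant): effect, MAFs and carriers per dataset."""
    rows = [
        (
            ra.gene_id, ra.chrom, ra.pos, ra.ref, ra.alt, ra.effect,
            ra.maf, rb.maf,
            ",".join(ra.carriers), ",".join(rb.carriers),
        )
        for ra, rb in sorted(shared, key=lambda p: (p[0].gene_id, p[0].chrom, p[0].pos))
    ]
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos", "ref", "alt", "effect",
                 "maf_a", "maf_b", "carriers_a", "carriers_b"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
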