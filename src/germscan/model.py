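"""Shared data model: variants, genotype matrices, population tables, gene models.

Genotype calls are stored as a dense ``int8`` matrix (variants x accessions)
with the codes below.  All genomic coordinates are 1-based inclusive
(VCF/GFF3 convention); BED exports are the only 0-based half-open surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# genotype call codes
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

# variant classes
SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"

# population labels
WILD = "wild"
CULTIVATED = "cultivated"
UNKNOWN = "unknown"


def variant_class(ref: str, alt: str) -> str:
    """Classify a biallelic ref/alt pair as SNP, insertion or deletion."""
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    if len(alt) > len(ref):
        return INSERTION
    if len(ref) > len(alt):
        return DELETION
    raise ValueError(f"ambiguous variant class for ref={ref!r} alt={alt!r}")


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; ``pos`` is the 1-based position of the first ref base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")
        if len(self.ref) == len(self.alt) and len(self.ref) != 1:
            raise ValueError(
                f"only SNPs and length-changing InDels admitted at {self.chrom}:{self.pos}"
            )

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return self.vclass == SNP

    @property
    def is_indel(self) -> bool:
        return self.vclass != SNP

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vclass"]


def variants_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    """Tabulate Variant records into the canonical variant DataFrame."""
    rows = [(v.chrom, v.pos, v.ref, v.alt, v.vclass) for v in variants]
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64) if len(df) else df.get("pos", pd.Series(dtype=np.int64))
    return df


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic variants with calls in {HOM_REF, HET, HOM_ALT, MISSING}.

    ``variants`` is a DataFrame with columns chrom, pos, ref, alt, vclass sorted
    by (chrom, pos); ``calls`` has shape (n_variants, n_accessions).
    """

    variants: pd.DataFrame
    accessions: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.accessions)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.accessions)} accessions"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("accession IDs must be unique")
        self.variants = self.variants.reset_index(drop=True)
        order = self.variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            self.calls = self.calls[order]
            self.variants = self.variants.iloc[order].reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def accession_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def variant_at(self, i: int) -> Variant:
        row = self.variants.iloc[i]
        return Variant(row.chrom, int(row.pos), row.ref, row.alt)

    def iter_variants(self) -> Iterable[Variant]:
        for row in self.variants.itertuples(index=False):
            yield Variant(row.chrom, int(row.pos), row.ref, row.alt)

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.accessions),
            self.calls[idx],
        )

    def subset_accessions(self, names: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.accession_index(n) for n in names]
        return GenotypeMatrix(self.variants.copy(), list(names), self.calls[:, cols])


@dataclass
class PopulationTable:
    """Accession -> population label in {wild, cultivated, unknown}."""

    labels: dict[str, str] = field(default_factory=dict)

    VALID = (WILD, CULTIVATED, UNKNOWN)

    def __post_init__(self) -> None:
        bad = {l for l in self.labels.values() if l not in self.VALID}
        if bad:
            raise ValueError(f"invalid population labels: {sorted(bad)}")

    def __getitem__(self, accession: str) -> str:
        return self.labels[accession]

    def __len__(self) -> int:
        return len(self.labels)

    def members(self, label: str) -> list[str]:
        return [a for a, l in self.labels.items() if l == label]

    def indices(self, matrix: GenotypeMatrix, label: str) -> np.ndarray:
        """Column indices of ``matrix`` whose accession carries ``label``."""
        return np.array(
            [i for i, a in enumerate(matrix.accessions) if self.labels.get(a) == label],
            dtype=np.intp,
        )

    def validate_against(self, matrix: GenotypeMatrix, min_per_pop: int = 2) -> None:
        missing = [a for a in matrix.accessions if a not in self.labels]
        if missing:
            raise ValueError(f"accessions without population label: {missing[:5]}...")
        for label in (WILD, CULTIVATED):
            if len(self.indices(matrix, label)) < min_per_pop:
                raise ValueError(
                    f"population {label!r} has <{min_per_pop} accessions; "
                    "frequency computation is undefined"
                )


@dataclass
class GeneModel:
    """A protein-coding gene: CDS/exon/UTR intervals in genomic order, 1-based inclusive."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)
    malformed: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/- for {self.gene_id}")
        self.cds = sorted(self.cds)
        self.exons = sorted(self.exons) if self.exons else list(self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        if self.cds_length % 3 != 0:
            self.malformed = True

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)
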