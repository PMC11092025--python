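"""Reference-allele frequencies in differentiation regions and type-1/2/3 typing.

A marker's type is set by its reference-allele frequency in each population
(reference = the cultivated-dominant allele, since the reference assembly is a
cultivar).  With wild frequency w and cultivated frequency c, all inequalities
strict:

* type1: w < 0.05 and c > 0.95  — near-fixed in both, differentiated
* type2: w < 0.05 and 0.20 < c < 0.80 — fixed in wild, polymorphic in cultivated
* type3: 0.20 < w < 0.80 and c > 0.95 — polymorphic in wild, fixed in cultivated

SNPs and InDels are typed by the identical rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffscan import DiffRegion
from .model import (
    GenotypeMatrix,
    PopulationTable,
    HOM_REF,
    HET,
    HOM_ALT,
    WILD,
    CULTIVATED,
    SNP,
)

__all__ = ["TypeThresholds", "population_ref_freq", "assign_type", "classify_in_regions"]

TYPE1 = "type1"
TYPE2 = "type2"
TYPE3 = "type3"
NONE = "none"


@dataclass(frozen=True)
class TypeThresholds:
    """Frequency cut-offs for marker typing; all comparisons are strict."""

    fixed_low: float = 0.05
    fixed_high: float = 0.95
    poly_low: float = 0.20
    poly_high: float = 0.80


def _ref_freqs(calls: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ref-allele frequency, called count) per variant over given accessions."""
    sub = calls[:, cols]
    n_hom_ref = (sub == HOM_REF).sum(axis=1)
    n_het = (sub == HET).sum(axis=1)
    n_hom_alt = (sub == HOM_ALT).sum(axis=1)
    called = n_hom_ref + n_het + n_hom_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = (2 * n_hom_ref + n_het) / (2 * called)
    return freq, called


def allele_freq_table(
    matrix: GenotypeMatrix, pops: PopulationTable, min_called: int = 10
) -> pd.DataFrame:
    """Per-variant wild/cultivated reference-allele frequencies.

    HET contributes one reference allele; MISSING calls are excluded from
    numerator and denominator.  Variants with fewer than ``min_called``
    non-missing genotypes in either population are flagged ``low_call`` and
    are excluded from typing.
    """
    wf, wc = _ref_freqs(matrix.calls, pops.indices(matrix, WILD))
    cf, cc = _ref_freqs(matrix.calls, pops.indices(matrix, CULTIVATED))
    df = matrix.variants.copy()
    df["wild_ref_freq"] = wf
    df["cult_ref_freq"] = cf
    df["wild_called"] = wc
    df["cult_called"] = cc
    df["low_call"] = (wc < min_called) | (cc < min_called)
    return df


def population_ref_freq(
    matrix: GenotypeMatrix, pops: PopulationTable, variant, min_called: int = 10
) -> pd.Series:
    """Frequency record for one variant (row of :func:`allele_freq_table`)."""
    vdf = matrix.variants
    hit = np.flatnonzero(
        (vdf["chrom"].to_numpy() == variant.chrom)
        & (vdf["pos"].to_numpy() == variant.pos)
    )
    if len(hit) == 0:
        raise KeyError(f"variant {variant.chrom}:{variant.pos} not in matrix")
    sub = matrix.subset_variants(hit[:1])
    return allele_freq_table(sub, pops, min_called=min_called).iloc[0]


def assign_type(
    wild_ref_freq: float, cult_ref_freq: float, thresholds: TypeThresholds = TypeThresholds()
) -> str:
    """Type a single (wild, cultivated) reference-frequency pair."""
    t = thresholds
    w, c = wild_ref_freq, cult_ref_freq
    if w < t.fixed_low and c > t.fixed_high:
        return TYPE1
    if w < t.fixed_low and t.poly_low < c < t.poly_high:
        return TYPE2
    if t.poly_low < w < t.poly_high and c > t.fixed_high:
        return TYPE3
    return NONE


def _in_regions_mask(variants: pd.DataFrame, regions: list[DiffRegion]) -> np.ndarray:
    mask = np.zeros(len(variants), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    for chrom, ivals in by_chrom.items():
        ivals = sorted(ivals)
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        sel = chroms == chrom
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (idx >= 0) & (pos[sel] <= ends[np.clip(idx, 0, len(ends) - 1)])
        mask[np.flatnonzero(sel)] = ok
    return mask


def classify_in_regions(
    matrix: GenotypeMatrix,
    pops: PopulationTable,
    regions: list[DiffRegion],
    variant_class_filter: str = "both",
    thresholds: TypeThresholds = TypeThresholds(),
    min_called: int = 10,
) -> pd.DataFrame:
    """Type every in-region variant; returns the typed-marker table.

    ``variant_class_filter`` selects "snp", "indel" or "both".  Variants
    outside every region, of the wrong class, or with too few calls get
    mtype "none".
    """
    df = allele_freq_table(matrix, pops, min_called=min_called)
    df["in_region"] = _in_regions_mask(matrix.variants, regions)
    class_ok = np.ones(len(df), dtype=bool)
    if variant_class_filter == "snp":
        class_ok = (df["vclass"] == SNP).to_numpy()
    elif variant_class_filter == "indel":
        class_ok = (df["vclass"] != SNP).to_numpy()
    elif variant_class_filter != "both":
        raise ValueError("variant_class_filter must be snp, indel or both")

    t = thresholds
    w = df["wild_ref_freq"].to_numpy()
    c = df["cult_ref_freq"].to_numpy()
    typable = df["in_region"].to_numpy() & class_ok & ~df["low_call"].to_numpy()
    mtype = np.full(len(df), NONE, dtype=object)
    mtype[typable & (w < t.fixed_low) & (c > t.fixed_high)] = TYPE1
    mtype[typable & (w < t.fixed_low) & (t.poly_low < c) & (c < t.poly_high)] = TYPE2
    mtype[typable & (t.poly_low < w) & (w < t.poly_high) & (c > t.fixed_high)] = TYPE3
    df["mtype"] = mtype
    return df
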