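"""Weir-Cockerham Fst: per-site variance components, sliding windows, region calls.

The estimator is the two-allele Weir & Cockerham (1984) decomposition into
among-population (a), among-individual-within-population (b) and
within-individual (c) variance components, computed from per-population
sample sizes, allele frequencies and observed heterozygote frequencies over
non-missing calls.  Windowed Fst is the "weighted" ratio of sums
sum(a) / sum(a+b+c) over member sites, the statistic VCFtools reports for
``--fst-window-size``.  Differentiation regions are the merged top-quantile
windows of a 100-kb / 10-kb sliding scan.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    GenotypeMatrix,
    PopulationTable,
    Variant,
    HOM_REF,
    HET,
    HOM_ALT,
    WILD,
    CULTIVATED,
)

__all__ = [
    "SiteFstComponents",
    "DiffRegion",
    "fst_components_table",
    "site_fst_components",
    "window_scan",
    "call_regions",
]


@dataclass(frozen=True)
class SiteFstComponents:
    variant: Variant
    a: float
    b: float
    c: float

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else float("nan")


@dataclass(frozen=True)
class DiffRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    max_fst: float


def _pop_summaries(calls: np.ndarray, cols: np.ndarray):
    """Per-site (n called, alt-allele freq, het freq) for one population."""
    sub = calls[:, cols]
    n_hom_ref = (sub == HOM_REF).sum(axis=1)
    n_het = (sub == HET).sum(axis=1)
    n_hom_alt = (sub == HOM_ALT).sum(axis=1)
    n = n_hom_ref + n_het + n_hom_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_hom_alt + n_het) / (2 * n)
        h = n_het / n
    return n.astype(float), p, h


def fst_components_table(
    matrix: GenotypeMatrix, pops: PopulationTable
) -> pd.DataFrame:
    """Per-site Weir-Cockerham components for the wild/cultivated contrast.

    Returns a DataFrame with columns chrom, pos, a, b, c restricted to sites
    with at least one called genotype in each population and a defined
    estimator (mean sample size > 1); the number of skipped sites is stored in
    ``result.attrs["n_skipped"]``.
    """
    wild_cols = pops.indices(matrix, WILD)
    cult_cols = pops.indices(matrix, CULTIVATED)
    if len(wild_cols) == 0 or len(cult_cols) == 0:
        raise ValueError("both wild and cultivated populations must be non-empty")
    n1, p1, h1 = _pop_summaries(matrix.calls, wild_cols)
    n2, p2, h2 = _pop_summaries(matrix.calls, cult_cols)

    r = 2.0
    nbar = (n1 + n2) / r
    valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    # nc == 0 can only arise with a fully-missing population, already invalid
    out = pd.DataFrame(
        {
            "chrom": matrix.variants["chrom"].to_numpy()[valid],
            "pos": matrix.variants["pos"].to_numpy()[valid],
            "a": a[valid],
            "b": b[valid],
            "c": c[valid],
        }
    )
    out.attrs["n_skipped"] = int((~valid).sum())
    return out


def site_fst_components(
    matrix: GenotypeMatrix, pops: PopulationTable, variant: Variant
) -> SiteFstComponents:
    """Components for a single site (errors if the site is skipped)."""
    vdf = matrix.variants
    hit = np.flatnonzero(
        (vdf["chrom"].to_numpy() == variant.chrom)
        & (vdf["pos"].to_numpy() == variant.pos)
    )
    if len(hit) == 0:
        raise KeyError(f"variant {variant.chrom}:{variant.pos} not in matrix")
    sub = matrix.subset_variants(hit[:1])
    table = fst_components_table(sub, pops)
    if len(table) == 0:
        raise ValueError(
            f"site {variant.chrom}:{variant.pos} skipped "
            "(a population is fully missing or too few calls)"
        )
    row = table.iloc[0]
    return SiteFstComponents(variant, float(row.a), float(row.b), float(row.c))


def window_scan(
    components: pd.DataFrame,
    window: int = 100_000,
    step: int = 10_000,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window weighted Fst: sum(a)/sum(a+b+c) per window.

    Windows tile each chromosome from position 1 with the given step;
    terminal windows are truncated at the chromosome end.  Windows with fewer
    than ``min_snps`` member sites, or with a zero denominator, are excluded
    (counts in ``result.attrs``).
    """
    records = []
    n_too_few = 0
    n_zero_denom = 0
    for chrom, grp in components.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        a = grp["a"].to_numpy()[order]
        abc = a + grp["b"].to_numpy()[order] + grp["c"].to_numpy()[order]
        ca = np.concatenate([[0.0], np.cumsum(a)])
        cabc = np.concatenate([[0.0], np.cumsum(abc)])
        chrom_len = (
            chrom_lengths[chrom] if chrom_lengths is not None else int(pos.max())
        )
        start = 1
        while start <= chrom_len:
            end = min(start + window - 1, chrom_len)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n_snps = hi - lo
            if n_snps < min_snps:
                n_too_few += 1
            else:
                num = ca[hi] - ca[lo]
                denom = cabc[hi] - cabc[lo]
                if denom == 0:
                    n_zero_denom += 1
                else:
                    records.append((chrom, start, end, int(n_snps), num / denom))
            start += step
    out = pd.DataFrame(records, columns=["chrom", "start", "end", "n_snps", "fst"])
    out.attrs["n_excluded_min_snps"] = n_too_few
    out.attrs["n_excluded_zero_denom"] = n_zero_denom
    return out


def call_regions(
    windows: pd.DataFrame, top_fraction: float = 0.05
) -> tuple[float, list[DiffRegion]]:
    """Select windows above the (1 - top_fraction) Fst quantile and merge them.

    The threshold is the linear-interpolation empirical quantile computed
    genome-wide; selection is strict (fst > threshold); overlapping or
    book-ended selected windows merge into maximal regions per chromosome.
    """
    if len(windows) == 0:
        raise ValueError("no retained windows; cannot call regions")
    threshold = float(np.quantile(windows["fst"].to_numpy(), 1.0 - top_fraction))
    sel = windows[windows["fst"] > threshold]
    regions: list[DiffRegion] = []
    for chrom, grp in sel.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        cur_n = 0
        cur_max = -np.inf
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, cur_n, cur_max = row.start, row.end, 1, row.fst
            elif row.start <= cur_e + 1:
                cur_e = max(cur_e, row.end)
                cur_n += 1
                cur_max = max(cur_max, row.fst)
            else:
                regions.append(DiffRegion(chrom, int(cur_s), int(cur_e), cur_n, float(cur_max)))
                cur_s, cur_e, cur_n, cur_max = row.start, row.end, 1, row.fst
        if cur_s is not None:
            regions.append(DiffRegion(chrom, int(cur_s), int(cur_e), cur_n, float(cur_max)))
    return threshold, regions


def regions_frame(regions: list[DiffRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.n_windows, r.max_fst) for r in regions],
        columns=["chrom", "start", "end", "n_windows", "max_fst"],
    )
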