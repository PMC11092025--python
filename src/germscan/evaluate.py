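"""Per-accession RSF, wild/cultivated/hybrid calls, duplicate-sample QC.

RSF (reference SNP frequency) is the fraction of an accession's non-missing
typed markers at which it is homozygous for the reference (cultivated-
dominant) allele.  Heterozygous calls count as non-reference for RSF but are
tallied separately: an accession with an intermediate type-1 RSF whose
markers are mostly heterozygous is a suspected hybrid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING

__all__ = [
    "RSFReport",
    "DuplicatePair",
    "compute_rsf",
    "classify_accession",
    "rsf_report",
    "find_duplicates",
]


@dataclass(frozen=True)
class RSFReport:
    accession: str
    mtype: str
    rsf: float
    het_frac: float
    n_used: int
    call: str | None  # wild | cultivated | ambiguous | suspected_hybrid
    low_data: bool


@dataclass(frozen=True)
class DuplicatePair:
    accession_a: str
    accession_b: str
    concordance: float
    n_compared: int


def _marker_rows(matrix: GenotypeMatrix, markers: pd.DataFrame, mtype: str) -> np.ndarray:
    """Row indices of ``matrix`` matching markers of the given type."""
    sel = markers[markers["mtype"] == mtype]
    want = set(zip(sel["chrom"], sel["pos"]))
    chroms = matrix.variants["chrom"].to_numpy()
    pos = matrix.variants["pos"].to_numpy()
    return np.array(
        [i for i in range(len(pos)) if (chroms[i], pos[i]) in want], dtype=np.intp
    )


def compute_rsf(
    matrix: GenotypeMatrix,
    typed_markers: pd.DataFrame,
    accession: str,
    mtype: str,
    min_markers: int = 10,
) -> tuple[float, float, int]:
    """(rsf, het_frac, n_used) over non-missing markers of ``mtype``.

    Raises ValueError (low data) when fewer than ``min_markers`` typed markers
    are non-missing for the accession.
    """
    rows = _marker_rows(matrix, typed_markers, mtype)
    col = matrix.accession_index(accession)
    calls = matrix.calls[rows, col]
    used = calls != MISSING
    n_used = int(used.sum())
    if n_used < min_markers:
        raise ValueError(
            f"accession {accession}: only {n_used} non-missing {mtype} markers "
            f"(< {min_markers}); no call"
        )
    rsf = float((calls[used] == HOM_REF).mean())
    het = float((calls[used] == HET).mean())
    return rsf, het, n_used


def classify_accession(
    rsf: float,
    het_frac: float = 0.0,
    mode: str = "three_band",
    wild_max: float = 0.30,
    cult_min: float = 0.80,
    simple_threshold: float = 0.50,
    hybrid_het: float = 0.50,
) -> str:
    """Call an accession from its type-1 RSF.

    three_band: rsf < 0.30 -> wild; rsf > 0.80 -> cultivated; otherwise
    ambiguous.  An accession whose typed markers are majority-heterozygous
    (het_frac > 0.50) cannot be a pure line whatever its band — a first-
    generation wild x cultivated hybrid is heterozygous at ~94% of type-1
    markers yet has a *wild-like* RSF of ~3% — so the suspected_hybrid flag
    overrides the band call.  simple: a single 0.50 cut.
    """
    if mode == "simple":
        return "wild" if rsf < simple_threshold else "cultivated"
    if mode != "three_band":
        raise ValueError("mode must be three_band or simple")
    if het_frac > hybrid_het:
        return "suspected_hybrid"
    if rsf < wild_max:
        return "wild"
    if rsf > cult_min:
        return "cultivated"
    return "ambiguous"


def rsf_report(
    matrix: GenotypeMatrix,
    typed_markers: pd.DataFrame,
    mode: str = "three_band",
    min_markers: int = 10,
    mtypes: tuple[str, ...] = ("type1", "type2", "type3"),
) -> pd.DataFrame:
    """RSF per accession per marker type; the call is driven by type-1 markers."""
    rows = []
    row_idx = {t: _marker_rows(matrix, typed_markers, t) for t in mtypes}
    for col, acc in enumerate(matrix.accessions):
        per_type: dict[str, tuple[float, float, int] | None] = {}
        for t in mtypes:
            calls = matrix.calls[row_idx[t], col]
            used = calls != MISSING
            n_used = int(used.sum())
            if n_used < min_markers:
                per_type[t] = None
            else:
                per_type[t] = (
                    float((calls[used] == HOM_REF).mean()),
                    float((calls[used] == HET).mean()),
                    n_used,
                )
        t1 = per_type.get("type1")
        if t1 is None:
            call, low = "", True
        else:
            call, low = classify_accession(t1[0], t1[1], mode=mode), False
        rec: dict[str, object] = {"accession": acc, "call": call, "low_data": low}
        for t in mtypes:
            if per_type[t] is None:
                rec[f"{t}_rsf"] = np.nan
                rec[f"{t}_het_frac"] = np.nan
                rec[f"{t}_n_used"] = 0
            else:
                rsf, het, n = per_type[t]
                rec[f"{t}_rsf"] = rsf
                rec[f"{t}_het_frac"] = het
                rec[f"{t}_n_used"] = n
        rows.append(rec)
    return pd.DataFrame(rows)


def find_duplicates(
    matrix: GenotypeMatrix, threshold: float = 0.99, min_compared: int = 100
) -> list[DuplicatePair]:
    """All unordered accession pairs with genotype concordance >= threshold.

    Concordance is identity-by-state over sites where both accessions are
    called; pairs sharing fewer than ``min_compared`` co-called sites are not
    reported.  Computed with one-hot matrix products, so it scales to a few
    thousand accessions.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least two accessions")
    X = matrix.calls
    called = (X != MISSING).astype(np.float32)
    co_called = called.T @ called
    match = np.zeros_like(co_called)
    for g in (HOM_REF, HET, HOM_ALT):
        ind = (X == g).astype(np.float32)
        match += ind.T @ ind
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = match / co_called
    pairs: list[DuplicatePair] = []
    n = matrix.n_accessions
    for i in range(n):
        for j in range(i + 1, n):
            nc = int(co_called[i, j])
            if nc >= min_compared and conc[i, j] >= threshold:
                pairs.append(
                    DuplicatePair(
                        matrix.accessions[i], matrix.accessions[j],
                        float(conc[i, j]), nc,
                    )
                )
    return pairs
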