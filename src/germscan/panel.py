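"""Low-density marker panels: distance trimming, ARMS eligibility, accuracy model.

A panel of n independent markers, each calling the true origin with
probability p, classifies an accession by strict majority vote; its accuracy
is P[X >= ceil((n+1)/2)] for X ~ Binomial(n, p).  With n = 5 and p = 0.95
(the type-1 fixation threshold) the panel is correct with probability
0.99884 — fewer than six assays suffice for a >99.88%-accurate wild vs
cultivated call.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "trim_by_distance",
    "arms_eligible",
    "select_arms_panel",
    "panel_accuracy",
    "min_panel_size",
]


def trim_by_distance(
    markers: pd.DataFrame, min_spacing: int = 20_000_000
) -> pd.DataFrame:
    """Greedy physical-distance trimming, applied per marker type per chromosome.

    Markers must carry chrom, pos and mtype; within each (mtype, chrom) group
    sorted by position the first marker is kept and each subsequent marker is
    kept only if it lies at least ``min_spacing`` bp beyond the last kept one.
    Idempotent; different chromosomes are never compared.
    """
    if len(markers) == 0:
        return markers.copy()
    keep = np.zeros(len(markers), dtype=bool)
    df = markers.reset_index(drop=True)
    for (_, _), grp in df.groupby(["mtype", "chrom"], sort=False):
        grp = grp.sort_values("pos")
        last = None
        for idx, pos in zip(grp.index, grp["pos"]):
            if last is None or pos - last >= min_spacing:
                keep[idx] = True
                last = pos
    out = df[keep].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def arms_eligible(
    marker_chrom: str,
    marker_pos: int,
    variants: pd.DataFrame,
    flank: int = 500,
) -> bool:
    """ARMS-PCR marker filter: no InDel within ``flank`` bp on either side.

    ``variants`` is the full variant table (chrom, pos, vclass); an InDel at
    distance exactly ``flank`` bp is disqualifying, one at flank+1 is not.
    """
    ind = variants[(variants["vclass"] != "SNP") & (variants["chrom"] == marker_chrom)]
    if len(ind) == 0:
        return True
    dist = np.abs(ind["pos"].to_numpy() - marker_pos)
    return bool(np.all((dist > flank) | (dist == 0)))


def select_arms_panel(
    markers: pd.DataFrame,
    variants: pd.DataFrame,
    flank: int = 500,
    one_per_chrom: bool = True,
) -> pd.DataFrame:
    """Eligible ARMS markers; with ``one_per_chrom`` keep, per chromosome, the
    eligible marker with the largest |wild - cultivated| frequency difference
    (ties broken by smallest position)."""
    ok = markers[
        [
            arms_eligible(row.chrom, row.pos, variants, flank=flank)
            for row in markers.itertuples(index=False)
        ]
    ].copy()
    if not one_per_chrom or len(ok) == 0:
        return ok.reset_index(drop=True)
    ok["freq_diff"] = (ok["cult_ref_freq"] - ok["wild_ref_freq"]).abs()
    picked = []
    for chrom, grp in ok.groupby("chrom", sort=True):
        grp = grp.sort_values(["freq_diff", "pos"], ascending=[False, True], kind="mergesort")
        picked.append(grp.iloc[0])
    out = pd.DataFrame(picked).drop(columns=["freq_diff"])
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def panel_accuracy(n: int, p: float) -> float:
    """Probability a strict majority of n markers (each correct w.p. p) is correct.

    Ties (possible only for even n) count as incorrect; defaults elsewhere in
    the package use odd n.
    """
    if n <= 0:
        raise ValueError("panel size must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("per-marker accuracy must lie in [0, 1]")
    k = math.ceil((n + 1) / 2)
    return float(binom.sf(k - 1, n, p))


def min_panel_size(p: float, target_accuracy: float, max_n: int = 1001) -> int:
    """Smallest odd n whose majority-vote accuracy reaches the target."""
    if not 0.5 < p < 1.0:
        raise ValueError("per-marker accuracy must satisfy 0.5 < p < 1")
    if not 0.0 < target_accuracy < 1.0:
        raise ValueError("target accuracy must lie in (0, 1)")
    n = 1
    while n <= max_n:
        if panel_accuracy(n, p) >= target_accuracy:
            return n
        n += 2
    raise ValueError(f"target {target_accuracy} unreachable within {max_n} markers")
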