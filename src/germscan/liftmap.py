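"""Flank-sequence marker liftover across assemblies.

Each marker's 201-bp flank (100 bp up + variant base + 100 bp down, source
forward strand) is placed on the target assembly by exact-seed lookup plus
ungapped Hamming extension over the full flank, on both strands.  Gapped
placements are never produced, which enforces the no-InDels-in-flank
acceptance rule; a unique best hit within the mismatch budget maps the
marker, ties are multimapped, and allele consistency at the mapped base is
confirmed afterwards.

With non-overlapping 31-mer seeds a 201-bp flank yields six full seeds, so
any ungapped placement with at most four mismatches retains at least one
exact seed: the search is exhaustive within the default budget.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import Variant

__all__ = [
    "FlankSequence",
    "LiftedMarker",
    "extract_flanks",
    "map_flank",
    "map_all",
    "confirm_allele",
    "validation_rate",
]


@dataclass(frozen=True)
class FlankSequence:
    marker: Variant
    sequence: str  # source forward strand
    center_offset: int  # 0-based index of the variant's first ref base


@dataclass(frozen=True)
class LiftedMarker:
    marker: Variant
    target_chrom: str | None
    target_pos: int | None  # 1-based
    strand: str | None  # + / -
    n_mismatches: int | None
    status: str  # mapped_consistent | mapped_inconsistent | multimapped | unmapped | indel_in_flank


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def extract_flanks(
    markers: list[Variant],
    genome: dict[str, str],
    flank: int = 100,
    known_variants: pd.DataFrame | None = None,
) -> tuple[list[FlankSequence], list[Variant]]:
    """Extract forward-strand flank sequences; returns (flanks, skipped).

    Markers closer than ``flank`` bp to a contig end are skipped.  When a
    variant table is supplied, markers with another InDel inside the flank
    window are skipped too (the ARMS-style exclusion, surfaced downstream as
    status indel_in_flank).  A ref-allele/genome disagreement is an error.
    """
    flanks: list[FlankSequence] = []
    skipped: list[Variant] = []
    for v in markers:
        chrom_seq = genome.get(v.chrom)
        if chrom_seq is None:
            raise ValueError(f"chromosome {v.chrom} absent from source genome")
        lo = v.pos - flank
        hi = v.pos + len(v.ref) - 1 + flank
        if lo < 1 or hi > len(chrom_seq):
            skipped.append(v)
            continue
        seq = chrom_seq[lo - 1 : hi]
        center = flank
        if seq[center : center + len(v.ref)].upper() != v.ref.upper():
            raise ValueError(
                f"ref mismatch at {v.chrom}:{v.pos}: genome has "
                f"{seq[center:center + len(v.ref)]!r}, marker says {v.ref!r}"
            )
        if known_variants is not None:
            near = known_variants[
                (known_variants["chrom"] == v.chrom)
                & (known_variants["vclass"] != "SNP")
                & (known_variants["pos"] >= lo)
                & (known_variants["pos"] <= hi)
                & (known_variants["pos"] != v.pos)
            ]
            if len(near):
                skipped.append(v)
                continue
        flanks.append(FlankSequence(v, seq, center))
    return flanks, skipped


class SeedIndex:
    """Exact-match positions of query seeds on a target genome's forward strand."""

    def __init__(self, genome: dict[str, str], seed_len: int = 31):
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] | None = None
        self._wanted: set[str] = set()

    def build(self, seeds: set[str]) -> None:
        """One pass over the target recording positions of the given seeds."""
        k = self.seed_len
        index: dict[str, list[tuple[str, int]]] = {s: [] for s in seeds}
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                s = seq[i : i + k]
                hit = index.get(s)
                if hit is not None:
                    hit.append((name, i))
        self._index = index
        self._wanted = set(seeds)

    def lookup(self, seed: str) -> list[tuple[str, int]]:
        assert self._index is not None, "call build() first"
        return self._index.get(seed, [])


def _seed_offsets(length: int, k: int) -> list[int]:
    offs = list(range(0, length - k + 1, k))
    if offs[-1] != length - k:
        offs.append(length - k)
    return offs


def _query_seeds(flanks: list[FlankSequence], seed_len: int) -> set[str]:
    seeds: set[str] = set()
    for f in flanks:
        q = f.sequence.upper()
        rc = _revcomp(q)
        for o in _seed_offsets(len(q), seed_len):
            seeds.add(q[o : o + seed_len])
            seeds.add(rc[o : o + seed_len])
    return seeds


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def map_flank(
    flank: FlankSequence,
    index: SeedIndex,
    max_mismatch: int = 4,
) -> LiftedMarker:
    """Place one flank on the target; ungapped best-hit with unique-minimum rule."""
    q = flank.sequence.upper()
    L = len(q)
    k = index.seed_len
    candidates: set[tuple[str, int, str]] = set()  # (contig, start0, strand)
    for strand, query in (("+", q), ("-", _revcomp(q))):
        for o in _seed_offsets(L, k):
            for contig, hit in index.lookup(query[o : o + k]):
                start = hit - o
                if start >= 0 and start + L <= len(index.genome[contig]):
                    candidates.add((contig, start, strand))
    best: list[tuple[str, int, str]] = []
    best_mm = max_mismatch + 1
    for contig, start, strand in sorted(candidates):
        target = index.genome[contig][start : start + L]
        query = q if strand == "+" else _revcomp(q)
        mm = _hamming(query, target)
        if mm < best_mm:
            best_mm = mm
            best = [(contig, start, strand)]
        elif mm == best_mm:
            best.append((contig, start, strand))
    if best_mm > max_mismatch or not best:
        return LiftedMarker(flank.marker, None, None, None, None, "unmapped")
    if len(best) > 1:
        return LiftedMarker(flank.marker, None, None, None, best_mm, "multimapped")
    contig, start, strand = best[0]
    if strand == "+":
        pos = start + flank.center_offset + 1
    else:
        pos = start + (L - 1 - flank.center_offset) + 1
    return LiftedMarker(flank.marker, contig, pos, strand, best_mm, "mapped")


def map_all(
    flanks: list[FlankSequence],
    target_genome: dict[str, str],
    max_mismatch: int = 4,
    seed_len: int = 31,
) -> list[LiftedMarker]:
    index = SeedIndex(target_genome, seed_len=seed_len)
    index.build(_query_seeds(flanks, seed_len))
    return [map_flank(f, index, max_mismatch=max_mismatch) for f in flanks]


def confirm_allele(
    lifted: LiftedMarker,
    target_genome: dict[str, str],
    target_variants: pd.DataFrame | None = None,
) -> LiftedMarker:
    """Confirm allele consistency at the mapped position.

    The strand-adjusted target base must equal the source ref or alt leading
    base; when a target variant table (chrom, pos, ref, alt) is given, a
    variant with the same strand-adjusted {ref, alt} set must also exist at
    the position.
    """
    if not (lifted.status or "").startswith("mapped"):
        return lifted
    base = target_genome[lifted.target_chrom][lifted.target_pos - 1].upper()
    src_ref = lifted.marker.ref[0].upper()
    src_alt = lifted.marker.alt[0].upper()
    if lifted.strand == "-":
        src_ref = src_ref.translate(_COMPLEMENT)
        src_alt = src_alt.translate(_COMPLEMENT)
    if base not in (src_ref, src_alt):
        return replace(lifted, status="mapped_inconsistent")
    if target_variants is not None:
        hit = target_variants[
            (target_variants["chrom"] == lifted.target_chrom)
            & (target_variants["pos"] == lifted.target_pos)
        ]
        found = any(
            {str(r.ref)[0].upper(), str(r.alt)[0].upper()} == {src_ref, src_alt}
            for r in hit.itertuples(index=False)
        )
        if not found:
            return replace(lifted, status="mapped_inconsistent")
    return replace(lifted, status="mapped_consistent")


def validation_rate(lifted: list[LiftedMarker]) -> float:
    """Fraction of candidate markers confirmed consistent on the target."""
    if not lifted:
        raise ValueError("empty candidate set")
    ok = sum(1 for l in lifted if l.status == "mapped_consistent")
    return ok / len(lifted)


def lifted_frame(lifted: list[LiftedMarker]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                l.marker.chrom, l.marker.pos, l.marker.ref, l.marker.alt,
                l.target_chrom or "", l.target_pos or 0, l.strand or "",
                -1 if l.n_mismatches is None else l.n_mismatches, l.status,
            )
            for l in lifted
        ],
        columns=["chrom", "pos", "ref", "alt", "target_chrom", "target_pos",
                 "strand", "n_mismatches", "status"],
    )
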