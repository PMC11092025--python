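"""Gene-model-based functional annotation of SNPs and InDels.

Each variant is placed against every overlapping transcript (intergenic /
intronic / splicing / UTR / exonic), exonic SNPs get a codon-level effect via
translation with the standard genetic code, exonic InDels are frameshift when
the coding-length change is not a multiple of three, and the most severe
per-transcript call is reported.  Large-effect mutations (LEM) are stopgain,
stoploss, startloss, frameshift, stop-introducing nonframeshift InDels and
splice-site disruptions — the classes expected to abolish protein function.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import GeneModel, GenotypeMatrix, Variant

__all__ = [
    "Annotation",
    "CodonChange",
    "annotate_variant",
    "annotate_matrix",
    "translate_cds",
    "LEM_EFFECTS",
]

# effects counted as large-effect mutations
LEM_EFFECTS = frozenset(
    {"stopgain", "stoploss", "startloss", "frameshift", "stopgain_indel"}
)

# most severe first; splicing is a region, listed here for cross-transcript ranking
SEVERITY = [
    "stopgain",
    "startloss",
    "frameshift",
    "stopgain_indel",
    "stoploss",
    "splicing",
    "nonsynonymous",
    "nonframeshift",
    "synonymous",
    "UTR",
    "intronic",
    "intergenic",
]
_SEV_RANK = {name: i for i, name in enumerate(SEVERITY)}

SPLICE_WINDOW = 2  # bp into the intron counted as splice site


@dataclass(frozen=True)
class CodonChange:
    transcript_id: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str


@dataclass(frozen=True)
class Annotation:
    variant: Variant
    gene_id: str | None
    transcript_id: str | None
    region: str  # intergenic | intronic | splicing | UTR | exonic
    effect: str | None  # codon/frame effect, present iff region == exonic
    is_lem: bool
    codon: CodonChange | None = None
    span_warning: bool = False


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def _forward_cds(model: GeneModel, genome: dict[str, str]) -> tuple[str, list[int]]:
    """Concatenated CDS on the forward strand, with per-base genomic positions."""
    chrom_seq = genome[model.chrom]
    parts: list[str] = []
    positions: list[int] = []
    for s, e in model.cds:
        parts.append(chrom_seq[s - 1 : e])
        positions.extend(range(s, e + 1))
    return "".join(parts), positions


def _check_ref(variant: Variant, genome: dict[str, str]) -> None:
    chrom_seq = genome.get(variant.chrom)
    if chrom_seq is None:
        raise ValueError(f"chromosome {variant.chrom} absent from genome")
    observed = chrom_seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref)]
    if observed.upper() != variant.ref.upper():
        raise ValueError(
            f"ref allele mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF says {variant.ref!r}, genome has {observed!r}"
        )


def translate_cds(
    model: GeneModel, genome: dict[str, str], applied_variant: Variant | None = None
) -> str:
    """Translate a transcript's CDS (strand-adjusted), optionally with a variant applied.

    Serves as the brute-force oracle for exonic effect calls: the effect of a
    SNP equals the effect inferred by diffing the reference and variant
    proteins.  An internal stop in the *reference* CDS flags the transcript
    (returned protein still contains the '*').
    """
    fwd, positions = _forward_cds(model, genome)
    if applied_variant is not None:
        v = applied_variant
        _check_ref(v, genome)
        bases = list(fwd)
        if v.is_snp:
            i = bisect.bisect_left(positions, v.pos)
            if i >= len(positions) or positions[i] != v.pos:
                raise ValueError(f"SNP {v.chrom}:{v.pos} not inside CDS of {model.transcript_id}")
            bases[i] = v.alt
        elif len(v.ref) > len(v.alt):  # deletion: remove pos+1 .. pos+len(ref)-1
            doomed = set(range(v.pos + 1, v.pos + len(v.ref)))
            bases = [b for b, p in zip(bases, positions) if p not in doomed]
        else:  # insertion: alt[1:] inserted after pos
            i = bisect.bisect_left(positions, v.pos)
            if i >= len(positions) or positions[i] != v.pos:
                raise ValueError(
                    f"insertion anchor {v.chrom}:{v.pos} not inside CDS of {model.transcript_id}"
                )
            bases[i] = bases[i] + v.alt[1:]
        fwd = "".join(bases)
    coding = fwd if model.strand == "+" else _revcomp(fwd)
    coding = coding[: len(coding) - len(coding) % 3]
    return _translate(coding)


def _snp_codon_effect(
    variant: Variant, model: GeneModel, genome: dict[str, str]
) -> tuple[str, CodonChange]:
    fwd, positions = _forward_cds(model, genome)
    o = bisect.bisect_left(positions, variant.pos)
    if model.strand == "+":
        cidx = o
        alt_base = variant.alt
        coding = fwd
    else:
        coding = _revcomp(fwd)
        cidx = len(fwd) - 1 - o
        alt_base = _revcomp(variant.alt)
    codon_i = cidx // 3
    within = cidx % 3
    ref_codon = coding[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:  # trailing partial codon of a malformed transcript
        return "synonymous", CodonChange(model.transcript_id, codon_i, ref_codon, ref_codon, "", "")
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    change = CodonChange(model.transcript_id, codon_i, ref_codon, alt_codon, ref_aa, alt_aa)
    if ref_aa == alt_aa:
        return "synonymous", change
    if codon_i == 0 and ref_codon == "ATG":
        return "startloss", change
    if alt_aa == "*":
        return "stopgain", change
    if ref_aa == "*":
        return "stoploss", change
    return "nonsynonymous", change


def _indel_effect(
    variant: Variant, model: GeneModel, genome: dict[str, str]
) -> tuple[str, bool]:
    """(effect, span_warning) for an InDel overlapping CDS."""
    span_warning = False
    if len(variant.ref) > len(variant.alt):
        removed = [
            p
            for p in range(variant.pos + 1, variant.pos + len(variant.ref))
            if model.in_cds(p)
        ]
        if len(removed) != len(variant.ref) - len(variant.alt):
            span_warning = True
        delta = len(removed)
    else:
        delta = len(variant.alt) - len(variant.ref)
    if delta % 3 != 0:
        return "frameshift", span_warning
    # nonframeshift: the edit introduces a premature stop iff the variant
    # protein stops earlier than the in-frame length change alone explains
    try:
        prot_ref = translate_cds(model, genome)
        prot_alt = translate_cds(model, genome, variant)
        ref_stop = prot_ref.find("*")
        alt_stop = prot_alt.find("*")
        delta_aa = (len(prot_alt) - len(prot_ref))
        if alt_stop != -1 and (ref_stop == -1 or alt_stop < ref_stop + delta_aa):
            return "stopgain_indel", span_warning
    except ValueError:
        span_warning = True
    return "nonframeshift", span_warning


def _near_splice(pos_lo: int, pos_hi: int, model: GeneModel) -> bool:
    """True if [pos_lo, pos_hi] touches the first/last SPLICE_WINDOW bp of an intron."""
    for s, e in model.introns:
        donor = (s, min(e, s + SPLICE_WINDOW - 1))
        acceptor = (max(s, e - SPLICE_WINDOW + 1), e)
        for a, b in (donor, acceptor):
            if pos_lo <= b and pos_hi >= a:
                return True
    return False


def _classify_against(
    variant: Variant, model: GeneModel, genome: dict[str, str]
) -> Annotation | None:
    """Annotation of ``variant`` against one transcript, or None if disjoint."""
    lo, hi = model.span
    if variant.is_snp:
        v_lo = v_hi = variant.pos
    elif len(variant.ref) > len(variant.alt):
        v_lo, v_hi = variant.pos + 1, variant.pos + len(variant.ref) - 1
    else:
        v_lo = v_hi = variant.pos  # insertion anchored at pos
    if v_hi < lo or v_lo > hi:
        return None

    if variant.is_snp:
        if model.in_cds(variant.pos):
            effect, change = _snp_codon_effect(variant, model, genome)
            return Annotation(
                variant, model.gene_id, model.transcript_id, "exonic",
                effect, effect in LEM_EFFECTS, codon=change,
            )
        if model.in_exon(variant.pos):
            return Annotation(variant, model.gene_id, model.transcript_id, "UTR", None, False)
        if _near_splice(variant.pos, variant.pos, model):
            return Annotation(variant, model.gene_id, model.transcript_id, "splicing", None, True)
        return Annotation(variant, model.gene_id, model.transcript_id, "intronic", None, False)

    # InDel
    in_cds = any(model.in_cds(p) for p in range(v_lo, v_hi + 1)) if len(
        variant.ref
    ) > len(variant.alt) else (
        model.in_cds(variant.pos)
        and model.in_cds(min(variant.pos + 1, hi))
    )
    if in_cds:
        effect, warn = _indel_effect(variant, model, genome)
        return Annotation(
            variant, model.gene_id, model.transcript_id, "exonic",
            effect, effect in LEM_EFFECTS, span_warning=warn,
        )
    if any(model.in_exon(p) for p in range(v_lo, v_hi + 1)):
        return Annotation(variant, model.gene_id, model.transcript_id, "UTR", None, False)
    if _near_splice(v_lo, v_hi, model):
        return Annotation(variant, model.gene_id, model.transcript_id, "splicing", None, True)
    return Annotation(variant, model.gene_id, model.transcript_id, "intronic", None, False)


def _severity_key(ann: Annotation) -> int:
    label = ann.effect if ann.region == "exonic" else ann.region
    return _SEV_RANK.get(label, len(SEVERITY))


def annotate_variant(
    variant: Variant, gene_models: list[GeneModel], genome: dict[str, str]
) -> Annotation:
    """Annotate one variant; with several overlapping transcripts the most
    severe effect wins (stopgain/startloss/frameshift > stoploss > splicing >
    nonsynonymous > nonframeshift > synonymous > UTR > intronic)."""
    _check_ref(variant, genome)
    hits = [
        ann
        for m in gene_models
        if m.chrom == variant.chrom
        for ann in [_classify_against(variant, m, genome)]
        if ann is not None
    ]
    if not hits:
        return Annotation(variant, None, None, "intergenic", None, False)
    return min(hits, key=_severity_key)


def annotate_matrix(
    matrix: GenotypeMatrix, gene_models: list[GeneModel], genome: dict[str, str]
) -> pd.DataFrame:
    """Annotate every variant in a matrix; one row per variant."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in gene_models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for lst in by_chrom.values():
        lst.sort(key=lambda m: m.span[0])
    rows = []
    for v in matrix.iter_variants():
        models = by_chrom.get(v.chrom, [])
        # cheap pre-filter on gene span
        cand = [m for m in models if m.span[0] - 10 <= v.pos <= m.span[1] + 10]
        ann = annotate_variant(v, cand, genome) if cand else Annotation(
            v, None, None, "intergenic", None, False
        )
        rows.append(
            (v.chrom, v.pos, v.ref, v.alt, v.vclass, ann.gene_id or "",
             ann.transcript_id or "", ann.region, ann.effect or "", ann.is_lem)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "vclass", "gene_id",
                 "transcript_id", "region", "effect", "is_lem"],
    )
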