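"""Codon-effect annotation against the whole-CDS translation oracle."""
from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from germscan import funcanno, synthpop as sp
from germscan.model import GeneModel, Variant


def single_exon_gene(seq_cds: str, start: int = 101, strand: str = "+",
                     chrom_len: int = 600):
    """A one-exon gene embedded in random sequence; returns (genome, model)."""
    rng = np.random.default_rng(5)
    backbone = "".join(rng.choice(list("ACGT"), size=chrom_len))
    placed = seq_cds if strand == "+" else str(Seq(seq_cds).reverse_complement())
    genome = {"ChrT": backbone[: start - 1] + placed + backbone[start - 1 + len(placed):]}
    model = GeneModel("gT", "gT.t1", "ChrT", strand,
                      cds=[(start, start + len(placed) - 1)])
    return genome, model


def protein_diff_effect(model, genome, variant):
    """Oracle: effect inferred by diffing full reference vs variant proteins."""
    ref_p = funcanno.translate_cds(model, genome)
    alt_p = funcanno.translate_cds(model, genome, variant)
    if ref_p == alt_p:
        return "synonymous"
    i = next(k for k in range(min(len(ref_p), len(alt_p)) + 1)
             if k >= len(ref_p) or k >= len(alt_p) or ref_p[k] != alt_p[k])
    if i == 0 and ref_p[0] == "M":
        return "startloss"
    if i < len(alt_p) and alt_p[i] == "*" and (i >= len(ref_p) or ref_p[i] != "*"):
        return "stopgain"
    if i < len(ref_p) and ref_p[i] == "*":
        return "stoploss"
    return "nonsynonymous"


def test_direct_translation_and_strand_symmetry():
    genome, model = single_exon_gene("ATGTGGTAA")
    assert funcanno.translate_cds(model, genome) == "MW*"
    genome_m, model_m = single_exon_gene("ATGTGGTAA", strand="-")
    assert funcanno.translate_cds(model_m, genome_m) == "MW*"


def test_stopgain_and_synonymous_examples():
    # TGG -> TGA: stopgain (position 6 of CDS, third base of codon 2)
    genome, model = single_exon_gene("ATGTGGAAATAA")
    v = Variant("ChrT", 106, "G", "A")
    ann = funcanno.annotate_variant(v, [model], genome)
    assert (ann.region, ann.effect, ann.is_lem) == ("exonic", "stopgain", True)
    # AAA -> AAG: synonymous Lys
    v2 = Variant("ChrT", 109, "A", "G")
    ann2 = funcanno.annotate_variant(v2, [model], genome)
    assert (ann2.effect, ann2.is_lem) == ("synonymous", False)


def test_startloss_and_stoploss():
    genome, model = single_exon_gene("ATGTGGAAATAA")
    ann = funcanno.annotate_variant(Variant("ChrT", 101, "A", "C"), [model], genome)
    assert ann.effect == "startloss" and ann.is_lem
    # terminal TAA (110-112): third base A -> C gives TAC (Tyr)
    ann2 = funcanno.annotate_variant(Variant("ChrT", 112, "A", "C"), [model], genome)
    assert ann2.effect == "stoploss" and ann2.is_lem


def test_indel_mod3_rule():
    genome, model = single_exon_gene("ATG" + "GGC" * 20 + "TAA")
    pos = 110
    ref2 = genome["ChrT"][pos - 1 : pos + 1]
    ann = funcanno.annotate_variant(Variant("ChrT", pos, ref2, ref2[0]), [model], genome)
    assert ann.effect == "frameshift" and ann.is_lem
    ref4 = genome["ChrT"][pos - 1 : pos + 3]
    ann3 = funcanno.annotate_variant(Variant("ChrT", pos, ref4, ref4[0]), [model], genome)
    assert ann3.effect == "nonframeshift" and not ann3.is_lem


def test_ref_mismatch_is_an_error():
    genome, model = single_exon_gene("ATGTGGTAA")
    actual = genome["ChrT"][104]
    wrong = "A" if actual != "A" else "C"
    with pytest.raises(ValueError, match="ChrT:105"):
        funcanno.annotate_variant(Variant("ChrT", 105, wrong, "T"), [model], genome)


def test_splice_window_and_intron():
    model = GeneModel("gS", "gS.t1", "ChrS", "+",
                      cds=[(101, 160), (261, 320)],
                      exons=[(101, 160), (261, 320)])
    rng = np.random.default_rng(9)
    genome = {"ChrS": "".join(rng.choice(list("ACGT"), size=400))}
    for pos, region in [(161, "splicing"), (162, "splicing"), (163, "intronic"),
                        (258, "intronic"), (259, "splicing"), (260, "splicing")]:
        ref = genome["ChrS"][pos - 1]
        alt = "A" if ref != "A" else "G"
        ann = funcanno.annotate_variant(Variant("ChrS", pos, ref, alt), [model], genome)
        assert ann.region == region, pos
        assert ann.is_lem == (region == "splicing")


def test_utr_and_intergenic():
    model = GeneModel("gU", "gU.t1", "ChrU", "+", cds=[(121, 180)],
                      exons=[(101, 180)], utrs=[(101, 120)])
    rng = np.random.default_rng(13)
    genome = {"ChrU": "".join(rng.choice(list("ACGT"), size=400))}
    ref = genome["ChrU"][109]
    ann = funcanno.annotate_variant(
        Variant("ChrU", 110, ref, "A" if ref != "A" else "G"), [model], genome)
    assert ann.region == "UTR" and ann.effect is None and not ann.is_lem
    ref2 = genome["ChrU"][299]
    ann2 = funcanno.annotate_variant(
        Variant("ChrU", 300, ref2, "A" if ref2 != "A" else "G"), [model], genome)
    assert ann2.region == "intergenic"


def test_annotation_invariant_under_cds_segment_permutation():
    ds = sp.simulate_dataset(sp.SimConfig(seed=21, n_wild=5, n_cult=5, n_chrom=1,
                                          chrom_len=60_000, snp_density=0.0005,
                                          gene_spacing=10_000))
    model = ds.gene_models[0]
    shuffled = GeneModel(model.gene_id, model.transcript_id, model.chrom,
                         model.strand, cds=list(reversed(model.cds)),
                         exons=list(reversed(model.exons)),
                         utrs=list(reversed(model.utrs)))
    pos = model.cds[0][0] + 7
    ref = ds.genome[model.chrom][pos - 1]
    v = Variant(model.chrom, pos, ref, "A" if ref != "A" else "G")
    a1 = funcanno.annotate_variant(v, [model], ds.genome)
    a2 = funcanno.annotate_variant(v, [shuffled], ds.genome)
    assert (a1.region, a1.effect) == (a2.region, a2.effect)


def test_codon_effect_matches_translation_oracle_on_random_snps():
    """100 random exonic SNPs on random transcripts, both strands."""
    rng = np.random.default_rng(17)
    ds = sp.simulate_dataset(sp.SimConfig(seed=23, n_wild=5, n_cult=5, n_chrom=2,
                                          chrom_len=200_000, snp_density=0.0002))
    n_checked = 0
    while n_checked < 100:
        model = ds.gene_models[rng.integers(0, len(ds.gene_models))]
        s, e = model.cds[rng.integers(0, len(model.cds))]
        pos = int(rng.integers(s, e + 1))
        ref = ds.genome[model.chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        v = Variant(model.chrom, pos, ref, alt)
        ann = funcanno.annotate_variant(v, [model], ds.genome)
        assert ann.region == "exonic"
        assert ann.effect == protein_diff_effect(model, ds.genome, v), (
            f"{v} on {model.gene_id}({model.strand})"
        )
        n_checked += 1


def test_most_severe_effect_across_overlapping_transcripts():
    genome, model = single_exon_gene("ATGTGGAAATAA")
    # second transcript whose CDS excludes the site -> intronic there
    other = GeneModel("gT", "gT.t2", "ChrT", "+", cds=[(101, 103)],
                      exons=[(101, 103), (109, 112)])
    v = Variant("ChrT", 106, "G", "A")  # stopgain on t1
    ann = funcanno.annotate_variant(v, [other, model], genome)
    assert ann.effect == "stopgain" and ann.transcript_id == "gT.t1"
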