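"""Flank extraction, seed-and-extend placement, allele confirmation."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from germscan import liftmap, synthpop as sp
from germscan.model import Variant


@pytest.fixture(scope="module")
def source():
    ds = sp.simulate_dataset(
        sp.SimConfig(seed=31, n_wild=10, n_cult=10, n_chrom=2, chrom_len=60_000,
                     snp_density=0.0008, indel_density=0.0001, missing_rate=0.0,
                     n_hybrids=0, n_duplicates=0)
    )
    all_snps = [v for v in ds.matrix.iter_variants() if v.is_snp]
    snps = all_snps[:30] + [v for v in all_snps if v.chrom == "Chr02"][:10]
    return ds, snps


def test_flank_extraction_geometry(source):
    ds, snps = source
    flanks, skipped = liftmap.extract_flanks(snps, ds.genome)
    assert len(flanks) == len(snps) and not skipped
    for f in flanks:
        assert len(f.sequence) == 201
        assert f.center_offset == 100
        assert f.sequence[100] == f.marker.ref
        # sequence matches the source genome exactly
        chrom = ds.genome[f.marker.chrom]
        assert chrom[f.marker.pos - 101 : f.marker.pos + 100] == f.sequence


def test_flank_whole_contig_and_edge_skip():
    rng = np.random.default_rng(2)
    contig = "".join(rng.choice(list("ACGT"), size=201))
    genome = {"C": contig}
    v = Variant("C", 101, contig[100], "A" if contig[100] != "A" else "G")
    flanks, skipped = liftmap.extract_flanks([v], genome)
    assert flanks[0].sequence == contig and flanks[0].center_offset == 100
    v_edge = Variant("C", 50, contig[49], "A" if contig[49] != "A" else "G")
    flanks2, skipped2 = liftmap.extract_flanks([v_edge], genome)
    assert not flanks2 and skipped2 == [v_edge]


def test_ref_mismatch_raises(source):
    ds, snps = source
    v = snps[0]
    wrong = "A" if v.ref != "A" else "C"
    with pytest.raises(ValueError, match="ref mismatch"):
        liftmap.extract_flanks([Variant(v.chrom, v.pos, wrong, "T")], ds.genome)


def test_identity_genome_maps_all_markers_exactly(source):
    ds, snps = source
    flanks, _ = liftmap.extract_flanks(snps, ds.genome)
    lifted = liftmap.map_all(flanks, ds.genome)
    lifted = [liftmap.confirm_allele(l, ds.genome) for l in lifted]
    assert all(l.status == "mapped_consistent" for l in lifted)
    for l in lifted:
        assert (l.target_chrom, l.target_pos, l.strand, l.n_mismatches) == (
            l.marker.chrom, l.marker.pos, "+", 0
        )
    assert liftmap.validation_rate(lifted) == 1.0


def test_revcomp_and_offset_agree_with_truth_map(source):
    ds, snps = source
    target, truth = sp.derive_target_genome(
        ds.genome,
        sp.TargetGenomeConfig(seed=1, substitution_rate=0.0,
                              revcomp_contigs=("Chr02",), prefix_len=1000),
    )
    flanks, _ = liftmap.extract_flanks(snps, ds.genome)
    lifted = liftmap.map_all(flanks, target)
    lifted = [liftmap.confirm_allele(l, target) for l in lifted]
    for l in lifted:
        tchrom, tpos, strand = truth.map_snp(l.marker.chrom, l.marker.pos)
        assert l.status == "mapped_consistent"
        assert (l.target_chrom, l.target_pos, l.strand) == (tchrom, tpos, strand)
    # Chr02 markers must be minus-strand placements
    assert all(l.strand == "-" for l in lifted if l.marker.chrom == "Chr02")


def test_too_many_substitutions_unmap(source):
    ds, snps = source
    v = snps[0]
    flanks, _ = liftmap.extract_flanks([v], ds.genome)
    target = {c: s for c, s in ds.genome.items()}
    arr = list(target[v.chrom])
    for off in (-80, -40, 0, 40, 80):  # 5 substitutions inside the flank
        i = v.pos - 1 + off
        arr[i] = "A" if arr[i] != "A" else "C"
    target[v.chrom] = "".join(arr)
    lifted = liftmap.map_all(flanks, target, max_mismatch=4)
    assert lifted[0].status == "unmapped"
    # a larger budget recovers the placement (monotonicity)
    lifted6 = liftmap.map_all(flanks, target, max_mismatch=6)
    assert lifted6[0].status == "mapped"
    assert lifted6[0].n_mismatches == 5


def test_duplicate_placement_is_multimapped(source):
    ds, snps = source
    v = snps[0]
    flanks, _ = liftmap.extract_flanks([v], ds.genome)
    seg = ds.genome[v.chrom][v.pos - 101 : v.pos + 100]
    target = {"C1": ds.genome[v.chrom], "C2": "T" * 500 + seg + "T" * 500}
    lifted = liftmap.map_all(flanks, target)
    assert lifted[0].status == "multimapped"


def test_allele_consistency_rules(source):
    ds, snps = source
    v = snps[0]
    flanks, _ = liftmap.extract_flanks([v], ds.genome)
    # target carrying the alt base at the site is still consistent
    target = {c: s for c, s in ds.genome.items()}
    arr = list(target[v.chrom])
    arr[v.pos - 1] = v.alt
    target[v.chrom] = "".join(arr)
    l = liftmap.map_all(flanks, target)[0]
    assert liftmap.confirm_allele(l, target).status == "mapped_consistent"
    # a third base is inconsistent
    third = next(b for b in "ACGT" if b not in (v.ref, v.alt))
    arr[v.pos - 1] = third
    target[v.chrom] = "".join(arr)
    l2 = liftmap.map_all(flanks, target)[0]
    assert liftmap.confirm_allele(l2, target).status == "mapped_inconsistent"


def test_minus_strand_variant_set_complement_match(source):
    ds, snps = source
    v = next(s for s in snps if s.chrom == "Chr02")
    target, truth = sp.derive_target_genome(
        ds.genome, sp.TargetGenomeConfig(seed=2, substitution_rate=0.0,
                                         revcomp_contigs=("Chr02",), prefix_len=0)
    )
    flanks, _ = liftmap.extract_flanks([v], ds.genome)
    l = liftmap.map_all(flanks, target)[0]
    assert l.strand == "-"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    tv = pd.DataFrame(
        {"chrom": [l.target_chrom], "pos": [l.target_pos],
         "ref": [comp[v.ref]], "alt": [comp[v.alt]]}
    )
    assert liftmap.confirm_allele(l, target, tv).status == "mapped_consistent"
    tv_bad = tv.assign(ref="A", alt="A")
    tv_bad = pd.DataFrame({"chrom": [l.target_chrom], "pos": [l.target_pos],
                           "ref": ["N"], "alt": ["N"]})
    assert liftmap.confirm_allele(l, target, tv_bad).status == "mapped_inconsistent"


def test_validation_rate_bookkeeping(source):
    ds, snps = source
    flanks, _ = liftmap.extract_flanks(snps[:10], ds.genome)
    lifted = liftmap.map_all(flanks, ds.genome)
    # target variant set missing one marker -> rate 0.9 exactly
    tv = pd.DataFrame(
        [(l.marker.chrom, l.marker.pos, l.marker.ref, l.marker.alt)
         for l in lifted[1:]],
        columns=["chrom", "pos", "ref", "alt"],
    )
    confirmed = [liftmap.confirm_allele(l, ds.genome, tv) for l in lifted]
    assert liftmap.validation_rate(confirmed) == pytest.approx(0.9)
    # empty target set -> rate 0; empty candidate set -> error
    empty = tv.iloc[0:0]
    none_ok = [liftmap.confirm_allele(l, ds.genome, empty) for l in lifted]
    assert liftmap.validation_rate(none_ok) == 0.0
    with pytest.raises(ValueError):
        liftmap.validation_rate([])


def test_indel_in_flank_exclusion(source):
    ds, snps = source
    v = snps[0]
    variants = pd.DataFrame(
        {"chrom": [v.chrom], "pos": [v.pos + 60], "vclass": ["deletion"]}
    )
    flanks, skipped = liftmap.extract_flanks([v], ds.genome, known_variants=variants)
    assert not flanks and skipped == [v]
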