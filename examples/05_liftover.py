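"""Map markers onto a second assembly by 201-bp flank placement.

Each marker's flank (100 bp either side) is placed on the target genome by
exact 31-mer seeding plus ungapped mismatch counting on both strands; the
unique best hit within 4 mismatches maps the marker and the target base must
match one of the source alleles (strand-adjusted).
"""
from germscan import synthpop as sp, liftmap

ds = sp.simulate_dataset(sp.SimConfig(
    seed=5, n_wild=20, n_cult=20, n_hybrids=0, n_duplicates=0,
    n_chrom=2, chrom_len=100_000, snp_density=0.0005, indel_density=0.0))
snps = [v for v in ds.matrix.iter_variants() if v.is_snp]

# derived assembly: Chr02 reverse-complemented, 1-kb prefix on every contig
target, truth = sp.derive_target_genome(
    ds.genome, sp.TargetGenomeConfig(seed=6, substitution_rate=0.0002,
                                     revcomp_contigs=("Chr02",),
                                     prefix_len=1000))
flanks, skipped = liftmap.extract_flanks(snps, ds.genome)
lifted = [liftmap.confirm_allele(l, target) for l in liftmap.map_all(flanks, target)]

from collections import Counter
print("status counts:", dict(Counter(l.status for l in lifted)))
ok = [l for l in lifted if l.status == "mapped_consistent"]
exact = sum((l.target_chrom, l.target_pos, l.strand)
            == truth.map_snp(l.marker.chrom, l.marker.pos) for l in ok)
print(f"{exact}/{len(ok)} consistent markers land exactly on the truth map")
print(f"validation rate: {liftmap.validation_rate(lifted):.4f}")
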