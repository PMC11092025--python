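"""Generate a synthetic wild/cultivated resequencing dataset and inspect it.

The generator draws Hardy-Weinberg genotypes for two populations from shared
background allele frequencies (expected Fst ~ 0) and plants differentiated
windows, hybrids, duplicate accessions and large-effect mutations, writing
standard FASTA/GFF3/VCF plus truth tables.
"""
from germscan import synthpop as sp

ds = sp.simulate_dataset(sp.default_config(seed=1))
paths = ds.write("scratch/example_sim")

print(f"genome: {len(ds.genome)} chromosomes x {len(ds.genome['Chr01']):,} bp, "
      f"{len(ds.gene_models)} gene models")
print(f"matrix: {ds.matrix.n_variants:,} variants x {ds.matrix.n_accessions} accessions")
print("accession origins:")
print(ds.truth.accessions["origin"].str.split(":").str[0].value_counts().to_string())
print("planted large-effect mutations:")
print(ds.truth.lems.to_string(index=False))
# Every variant and accession is covered by the truth tables, so downstream
# stages can be scored against the planted structure.
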