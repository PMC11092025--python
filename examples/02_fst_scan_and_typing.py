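"""Windowed Fst scan, differentiation regions, and marker typing.

Per-site Weir-Cockerham variance components are summed over 100-kb windows
stepped every 10 kb (windows with <10 SNPs dropped); the top 5% of windows
merge into differentiation regions, and in-region variants are typed by
their per-population reference-allele frequencies.
"""
from germscan import synthpop as sp, diffscan, classify

ds = sp.simulate_dataset(sp.default_config(seed=1))
comp = diffscan.fst_components_table(ds.matrix, ds.pops)
windows = diffscan.window_scan(
    comp, window=100_000, step=10_000, min_snps=10,
    chrom_lengths={c: len(s) for c, s in ds.genome.items()})
threshold, regions = diffscan.call_regions(windows, top_fraction=0.05)

print(f"{len(windows)} windows retained; top-5% Fst threshold = {threshold:.3f}")
for r in regions:
    print(f"  region {r.chrom}:{r.start:,}-{r.end:,} "
          f"({r.n_windows} windows, max Fst {r.max_fst:.3f})")

markers = classify.classify_in_regions(ds.matrix, ds.pops, regions, "both")
print("marker types inside the regions (type1 = fixed-differentiated, "
      "type2 = polymorphic in cultivated, type3 = polymorphic in wild):")
print(markers[markers["mtype"] != "none"]["mtype"].value_counts().to_string())
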