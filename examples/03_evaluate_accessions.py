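"""Score accessions by RSF and flag hybrids and duplicates.

RSF = fraction of an accession's non-missing typed markers that are
homozygous-reference.  At type-1 markers wild accessions sit near 0, pure
cultivars near 1, and the 0.50 line separates them; majority-heterozygous
accessions are suspected hybrids.
"""
from germscan import synthpop as sp, diffscan, classify, evaluate

ds = sp.simulate_dataset(sp.default_config(seed=1))
comp = diffscan.fst_components_table(ds.matrix, ds.pops)
windows = diffscan.window_scan(
    comp, chrom_lengths={c: len(s) for c, s in ds.genome.items()})
_, regions = diffscan.call_regions(windows)
markers = classify.classify_in_regions(ds.matrix, ds.pops, regions, "both")

report = evaluate.rsf_report(ds.matrix, markers, mode="three_band")
print("calls:", report["call"].value_counts().to_dict())
truth = dict(zip(ds.truth.accessions["accession"], ds.truth.accessions["origin"]))
wild = report[[truth[a] == "wild" for a in report["accession"]]]
cult = report[[truth[a] == "cultivated" for a in report["accession"]]]
print(f"type1 RSF: wild range {wild['type1_rsf'].min():.3f}-"
      f"{wild['type1_rsf'].max():.3f}, cultivated range "
      f"{cult['type1_rsf'].min():.3f}-{cult['type1_rsf'].max():.3f}")

pairs = evaluate.find_duplicates(ds.matrix, threshold=0.99)
for p in pairs:
    print(f"duplicate pair {p.accession_a}/{p.accession_b}: "
          f"concordance {p.concordance:.4f} over {p.n_compared:,} sites")
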