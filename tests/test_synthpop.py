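"""Generator contracts: determinism, planted structure, truth-table coverage."""
from __future__ import annotations

import dataclasses
import filecmp

import numpy as np
import pytest
from scipy import stats

from germscan import synthpop as sp
from germscan.model import HET, MISSING, HOM_REF


def test_same_seed_gives_byte_identical_files(tmp_path, tiny_config):
    d1 = sp.simulate_dataset(tiny_config)
    d2 = sp.simulate_dataset(tiny_config)
    p1 = d1.write(tmp_path / "a")
    p2 = d2.write(tmp_path / "b")
    for key in p1:
        assert filecmp.cmp(p1[key], p2[key], shallow=False), key


def test_different_seed_differs(tiny_config):
    other = dataclasses.replace(tiny_config, seed=tiny_config.seed + 1)
    d1, d2 = sp.simulate_dataset(tiny_config), sp.simulate_dataset(other)
    assert not np.array_equal(d1.matrix.calls, d2.matrix.calls)


def test_truth_covers_every_variant_and_accession(tiny_dataset):
    ds = tiny_dataset
    assert len(ds.truth.variants) == ds.matrix.n_variants
    assert set(ds.truth.accessions["accession"]) == set(ds.matrix.accessions)


def test_planted_type1_window_realizes_frequencies():
    cfg = sp.SimConfig(
        seed=5, n_wild=250, n_cult=250, n_hybrids=0, n_duplicates=0,
        n_chrom=1, chrom_len=200_000, missing_rate=0.0,
        snp_density=0.0005,
        planted_windows=[sp.PlantedWindow("Chr01", 50_001, 150_000, "type1",
                                          n_snps=60)],
    )
    ds = sp.simulate_dataset(cfg)
    tv = ds.truth.variants
    planted = tv[tv["archetype"] == "type1"]
    assert len(planted) >= 55
    wild_cols = ds.pops.indices(ds.matrix, "wild")
    cult_cols = ds.pops.indices(ds.matrix, "cultivated")
    idx = tv.index[tv["archetype"] == "type1"].to_numpy()
    calls = ds.matrix.calls
    # realized frequencies within binomial noise of 0.03 / 0.97 at n=250
    for i in idx:
        w = calls[i, wild_cols]
        c = calls[i, cult_cols]
        wf = (2 * (w == 0).sum() + (w == 1).sum()) / (2 * len(w))
        cf = (2 * (c == 0).sum() + (c == 1).sum()) / (2 * len(c))
        assert wf < 0.10 and cf > 0.90


def test_realized_frequency_converges_binomial_ci():
    """Realized allele frequencies at n=500 sit inside the 99% binomial CI."""
    cfg = sp.SimConfig(seed=6, n_wild=500, n_cult=500, n_hybrids=0,
                       n_duplicates=0, n_chrom=1, chrom_len=100_000,
                       missing_rate=0.0, snp_density=0.001)
    ds = sp.simulate_dataset(cfg)
    tv = ds.truth.variants
    wild_cols = ds.pops.indices(ds.matrix, "wild")
    calls = ds.matrix.calls
    n_alleles = 2 * len(wild_cols)
    n_outside = 0
    for i, p in enumerate(tv["wild_ref_freq"]):
        w = calls[i, wild_cols]
        k = 2 * (w == 0).sum() + (w == 1).sum()
        lo, hi = stats.binom.interval(0.99, n_alleles, p)
        if not (lo <= k <= hi):
            n_outside += 1
    # ~1% of sites may fall outside a 99% interval
    assert n_outside <= max(5, 0.03 * len(tv))


def test_background_sites_share_frequencies_across_populations(tiny_dataset):
    tv = tiny_dataset.truth.variants
    bg = tv[tv["archetype"] == ""]
    assert np.allclose(bg["wild_ref_freq"], bg["cult_ref_freq"])


def test_duplicate_without_error_is_identical():
    cfg = sp.SimConfig(seed=9, n_wild=20, n_cult=20, n_hybrids=0,
                       n_duplicates=1, duplicate_error=0.0, missing_rate=0.0,
                       n_chrom=1, chrom_len=50_000, snp_density=0.001)
    ds = sp.simulate_dataset(cfg)
    dup = ds.truth.accessions[ds.truth.accessions["origin"].str.startswith("duplicate")]
    row = dup.iloc[0]
    i = ds.matrix.accession_index(row.accession)
    j = ds.matrix.accession_index(row.source)
    assert np.array_equal(ds.matrix.calls[:, i], ds.matrix.calls[:, j])


def test_hybrids_have_elevated_heterozygosity():
    cfg = sp.SimConfig(
        seed=10, n_wild=50, n_cult=50, n_hybrids=5, n_duplicates=0,
        n_chrom=1, chrom_len=100_000, missing_rate=0.0, snp_density=0.0003,
        planted_windows=[sp.PlantedWindow("Chr01", 1_001, 99_000, "type1",
                                          n_snps=100)],
    )
    ds = sp.simulate_dataset(cfg)
    het_by_acc = (ds.matrix.calls == HET).mean(axis=0)
    origins = dict(zip(ds.truth.accessions["accession"], ds.truth.accessions["origin"]))
    hyb = [het_by_acc[i] for i, a in enumerate(ds.matrix.accessions)
           if origins[a] == "hybrid"]
    pure = [het_by_acc[i] for i, a in enumerate(ds.matrix.accessions)
            if origins[a] in ("wild", "cultivated")]
    assert min(hyb) > 3 * np.mean(pure)


def test_missing_rate_realized(tiny_dataset):
    frac = (tiny_dataset.matrix.calls == MISSING).mean()
    assert frac == pytest.approx(tiny_dataset.config.missing_rate, abs=0.01)


def test_density_error():
    with pytest.raises(ValueError):
        sp.SimConfig(snp_density=0.3)


def test_identity_target_genome():
    ds = sp.simulate_dataset(sp.SimConfig(seed=12, n_wild=5, n_cult=5,
                                          n_chrom=1, chrom_len=30_000,
                                          snp_density=0.0005))
    target, truth = sp.derive_target_genome(
        ds.genome, sp.TargetGenomeConfig(substitution_rate=0.0, prefix_len=0)
    )
    assert target == ds.genome
    assert truth.map_snp("Chr01", 1234) == ("Chr01", 1234, "+")


def test_revcomp_and_prefix_truth():
    ds = sp.simulate_dataset(sp.SimConfig(seed=13, n_wild=5, n_cult=5,
                                          n_chrom=2, chrom_len=30_000,
                                          snp_density=0.0005))
    target, truth = sp.derive_target_genome(
        ds.genome, sp.TargetGenomeConfig(substitution_rate=0.0,
                                         revcomp_contigs=("Chr02",),
                                         prefix_len=1000),
    )
    assert truth.transforms["Chr02"].strand == "-"
    # affine shift on the forward contig
    assert truth.map_snp("Chr01", 77) == ("Chr01", 1077, "+")
    # reflection on the reverse-complemented contig
    c, p, s = truth.map_snp("Chr02", 1)
    assert (c, p, s) == ("Chr02", 1000 + 30_000, "-")
    # base-level agreement: target base is the complement of the source base
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos in (1, 500, 29_999):
        _, tpos, _ = truth.map_snp("Chr02", pos)
        assert target["Chr02"][tpos - 1] == comp[ds.genome["Chr02"][pos - 1]]
    # round trip
    assert truth.unmap("Chr02", truth.map_snp("Chr02", 777)[1]) == 777


def test_protected_intervals_escape_substitution():
    ds = sp.simulate_dataset(sp.SimConfig(seed=14, n_wild=5, n_cult=5,
                                          n_chrom=1, chrom_len=30_000,
                                          snp_density=0.0005))
    protect = {"Chr01": [(10_000, 12_000)]}
    target, truth = sp.derive_target_genome(
        ds.genome, sp.TargetGenomeConfig(substitution_rate=0.02, prefix_len=0),
        protect=protect,
    )
    assert target["Chr01"][9_999:12_000] == ds.genome["Chr01"][9_999:12_000]
    assert target["Chr01"] != ds.genome["Chr01"]
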