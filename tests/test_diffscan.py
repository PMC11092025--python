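"""Weir-Cockerham components, window arithmetic and region calling.

The per-site oracle is a literal scalar transcription of the 1984 two-allele
variance-component formulas (r populations, observed heterozygote
correction), written independently of the vectorized implementation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germscan import diffscan
from germscan.model import Variant, HOM_REF, HET, HOM_ALT, MISSING
from conftest import make_matrix, two_pop_table


def wc_components_scalar(pops_calls):
    """Independent transcription of the Weir & Cockerham (1984) a, b, c."""
    r = len(pops_calls)
    n, p, h = [], [], []
    for calls in pops_calls:
        called = [c for c in calls if c != MISSING]
        ni = len(called)
        pi = (2 * sum(1 for c in called if c == HOM_ALT)
              + sum(1 for c in called if c == HET)) / (2 * ni)
        hi = sum(1 for c in called if c == HET) / ni
        n.append(ni); p.append(pi); h.append(hi)
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def test_fixed_difference_gives_fst_one():
    calls = np.array([[HOM_ALT] * 20 + [HOM_REF] * 20])
    m = make_matrix(calls)
    comp = diffscan.site_fst_components(m, two_pop_table(m, 20), m.variant_at(0))
    assert comp.fst == pytest.approx(1.0, abs=1e-12)


def test_identical_populations_have_no_among_population_variance():
    # all-heterozygous in both populations: a is exactly zero
    m = make_matrix(np.array([[HET] * 12 + [HET] * 12]))
    comp = diffscan.site_fst_components(m, two_pop_table(m, 12), m.variant_at(0))
    assert comp.a == pytest.approx(0.0, abs=1e-12)
    # identical polymorphic vectors with homozygotes: a is the estimator's
    # small negative, never positive
    vec = [HOM_REF] * 6 + [HOM_ALT] * 6
    m2 = make_matrix(np.array([vec + vec]))
    comp2 = diffscan.site_fst_components(m2, two_pop_table(m2, 12), m2.variant_at(0))
    assert comp2.a <= 0.0 and abs(comp2.a) < 0.05


def test_components_match_scalar_oracle_on_random_sites():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n1, n2 = rng.integers(3, 9), rng.integers(3, 9)
        while True:
            g1 = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=n1,
                            p=[0.4, 0.2, 0.3, 0.1])
            g2 = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=n2,
                            p=[0.3, 0.2, 0.4, 0.1])
            if (g1 != MISSING).sum() >= 2 and (g2 != MISSING).sum() >= 2:
                break
        m = make_matrix(np.concatenate([g1, g2])[None, :])
        comp = diffscan.site_fst_components(m, two_pop_table(m, n1), m.variant_at(0))
        a, b, c = wc_components_scalar([g1.tolist(), g2.tolist()])
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)
        assert comp.c == pytest.approx(c, abs=1e-12)


def test_fully_missing_population_site_is_skipped():
    calls = np.array(
        [[MISSING] * 4 + [HOM_REF] * 4,
         [HOM_REF] * 4 + [HOM_ALT] * 4]
    )
    m = make_matrix(calls)
    table = diffscan.fst_components_table(m, two_pop_table(m, 4))
    assert len(table) == 1 and table.attrs["n_skipped"] == 1
    with pytest.raises(ValueError):
        diffscan.site_fst_components(m, two_pop_table(m, 4), m.variant_at(0))


def test_window_tiling_and_min_snps():
    # 30 SNPs in [1, 100000], 9 SNPs in [100001, 200000]
    pos = np.concatenate([np.linspace(1000, 99000, 30).astype(int),
                          np.linspace(101000, 149000, 9).astype(int)])
    comp = pd.DataFrame(
        {"chrom": "Chr01", "pos": pos, "a": 1.0, "b": 0.0, "c": 0.0}
    )
    w = diffscan.window_scan(comp, window=100_000, step=10_000, min_snps=10,
                             chrom_lengths={"Chr01": 150_000})
    # starts tile from 1 by step; windows with <10 member SNPs absent
    assert w["start"].min() == 1
    assert set(w["start"]).issubset({1 + 10_000 * k for k in range(15)})
    for row in w.itertuples(index=False):
        assert row.n_snps >= 10
        assert row.end == min(row.start + 99_999, 150_000)
    # a window of 9 SNPs only ([60001..]) must be excluded
    assert w.attrs["n_excluded_min_snps"] > 0
    # all member sites fixed-difference -> fst exactly 1
    assert np.allclose(w["fst"], 1.0)


def test_region_quantile_count_and_merge():
    fst = np.concatenate([np.linspace(0.0, 0.5, 95), [0.9, 0.91, 0.92, 0.93, 0.94]])
    windows = pd.DataFrame(
        {
            "chrom": "Chr01",
            "start": 1 + 10_000 * np.arange(100),
            "end": 100_000 + 10_000 * np.arange(100),
            "n_snps": 50,
            "fst": fst,
        }
    )
    threshold, regions = diffscan.call_regions(windows, top_fraction=0.05)
    selected = windows[windows["fst"] > threshold]
    assert len(selected) == 5
    # the five top windows are consecutive and overlap -> one merged region
    assert len(regions) == 1
    assert regions[0].n_windows == 5
    assert regions[0].max_fst == pytest.approx(0.94)


def test_bookended_windows_merge():
    windows = pd.DataFrame(
        {
            "chrom": ["Chr01", "Chr01", "Chr02", "Chr03"],
            "start": [1, 100_001, 1, 1],
            "end": [100_000, 200_000, 100_000, 100_000],
            "n_snps": [50, 50, 50, 50],
            "fst": [0.9, 0.92, 0.91, 0.0],
        }
    )
    # threshold falls between the background window and the three high ones
    threshold, regions = diffscan.call_regions(windows, top_fraction=0.9)
    assert [(r.chrom, r.start, r.end) for r in regions] == [
        ("Chr01", 1, 200_000), ("Chr02", 1, 100_000)
    ]
    assert regions[0].n_windows == 2


def test_planted_window_recovered_and_label_permutation_destroys_it(tiny_dataset):
    ds = tiny_dataset
    comp = diffscan.fst_components_table(ds.matrix, ds.pops)
    w = diffscan.window_scan(comp, window=20_000, step=2_000, min_snps=5,
                             chrom_lengths={c: len(s) for c, s in ds.genome.items()})
    thr, regions = diffscan.call_regions(w, top_fraction=0.10)
    planted = ds.config.planted_windows[0]
    hit = [r for r in regions if r.start <= planted.start and r.end >= planted.end]
    assert hit, f"planted window {planted} not inside any region {regions}"

    # permuted labels: mean window fst collapses toward zero
    rng = np.random.default_rng(0)
    perm = rng.permutation(ds.matrix.accessions).tolist()
    relabel = {a: ds.pops.labels[b] for a, b in zip(ds.matrix.accessions, perm)}
    from germscan.model import PopulationTable

    comp_p = diffscan.fst_components_table(ds.matrix, PopulationTable(relabel))
    w_p = diffscan.window_scan(comp_p, window=20_000, step=2_000, min_snps=5)
    assert w_p["fst"].mean() < 0.05 < w["fst"].mean()
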