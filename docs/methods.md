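# Methods

## Scope and model

`germscan` operates on a biallelic multi-sample genotype matrix (calls in
{hom-ref, het, hom-alt, missing}) with a wild/cultivated population
assignment, a reference genome and gene models.  Only biallelic records are
admitted: every frequency criterion in the method is a two-allele statement,
so multiallelic records are dropped (and counted) on input rather than
decomposed.  Coordinates are 1-based inclusive throughout (VCF/GFF3
convention); BED exports are 0-based half-open.  Half-missing diploid calls
(`./1`) are treated as fully missing — the conservative reading, since a
half-call carries no usable diploid genotype for RSF or heterozygosity.

## Differentiation scan

Per site, the two-population Weir–Cockerham (1984) components are computed
from per-population sample sizes n_i, alternate-allele frequencies p_i and
observed heterozygote frequencies h_i over non-missing calls:

    n̄ = Σn_i/r,  n_c = (r·n̄ − Σn_i²/(r·n̄))/(r−1),
    p̄ = Σn_i·p_i/(r·n̄),  s² = Σn_i(p_i−p̄)²/((r−1)·n̄),  h̄ = Σn_i·h_i/(r·n̄)
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2

Sites with a fully missing population, or mean sample size ≤ 1, are skipped
with a count.  Windowed Fst is the weighted ratio Σa/Σ(a+b+c) over member
sites — negative per-site sums are deliberately retained in the window sums,
standard practice for this estimator.  Note that the a-component of two
populations with *identical* genotype vectors is not exactly zero unless the
vectors are all-heterozygous: with s² = 0, a ∝ −(p̄q̄ − h̄/4)/(n̄−1), the
estimator's well-known small negative bias at undifferentiated sites.

Windows tile each chromosome from position 1 (window 100 kb, step 10 kb by
default), terminal windows truncated at the chromosome end and retained if
they still hold `min_snps` (10) sites.  The region threshold is the
linear-interpolation empirical quantile of window Fst computed genome-wide
(one threshold for the whole scan, matching a single genome-wide cut-off;
per-chromosome quantiles would shift region counts on heterogeneous
genomes); selection is strict (`fst > threshold`) and selected windows that
overlap or are book-ended merge into maximal regions.

## Marker typing

Reference-allele frequency per population is (2·hom-ref + het)/(2·called);
a heterozygote contributes one reference allele, missing calls contribute
nothing to either side.  Variants with fewer than 10 called genotypes in
either population are excluded from typing (degenerate frequencies).  The
three archetypes use strict inequalities at 0.05/0.95 (near-fixation, the
conventional low-frequency-allele line) and 0.20/0.80 (useful polymorphism):

* type 1 — wild < 0.05, cultivated > 0.95: fixed and differentiated;
* type 2 — wild < 0.05, 0.20 < cultivated < 0.80: polymorphic only in the
  cultivated pool;
* type 3 — 0.20 < wild < 0.80, cultivated > 0.95: polymorphic only in the
  wild pool (the domestication-selection signature).

SNPs and InDels pass through the identical rule; the labels are mutually
exclusive by construction.

## Accession evaluation

RSF for one accession over one marker type is hom-ref count / non-missing
count; the denominator excludes missing markers so that missingness is not
conflated with non-reference genotype.  Heterozygotes count as non-reference
for RSF but are tallied separately as `het_frac`.  Calls need at least 10
non-missing type-1 markers, otherwise the accession is reported `low_data`.

Bands: `rsf < 0.30` → wild, `rsf > 0.80` → cultivated, otherwise ambiguous
(band edges on the ambiguous side).  The hybrid flag is `het_frac > 0.50`
and *overrides* the band: a first-generation wild × cultivated hybrid is
heterozygous at ~2·0.03·0.97 ≈ 94% of type-1 markers while its RSF
(~0.03·0.97 ≈ 3%) lands in the wild band, so restricting the flag to the
ambiguous band would classify obvious F1s as wild.  Pure accessions at
type-1 markers are ≤ ~6% heterozygous, leaving a wide margin around the 0.50
flag.  The `simple` mode is a single 0.50 cut.

Duplicate detection uses pairwise identity-by-state concordance (identical
genotype at co-called sites), computed with one-hot matrix products; pairs
with concordance ≥ 0.99 over ≥ 100 co-called sites are reported.  At a 0.5%
per-site genotype-error rate a true duplicate's expected concordance is
≈ 0.995·(1 + small co-missing correction), safely above the threshold, while
unrelated accessions under any realistic frequency spectrum fall far below.

## Panel design and accuracy model

Distance trimming is greedy left-to-right per (marker type, chromosome):
keep the first marker, then each subsequent marker at least 20 Mb beyond the
last kept one.  Greedy trimming is deterministic, order-independent given
sorted input, and idempotent.  ARMS-PCR eligibility rejects a marker with
any InDel within 500 bp on either side (distance ≤ 500 disqualifies);
`one_per_chrom` keeps the eligible marker with the largest
|wild − cultivated| frequency difference, ties broken toward the smaller
position.

A panel of n markers, each independently calling the true origin with
probability p, votes by strict majority; accuracy is
P[X ≥ ⌈(n+1)/2⌉], X ~ Binomial(n, p).  Ties (even n) count as incorrect, so
defaults are odd; p defaults to 0.95, the type-1 fixation threshold.  At
n = 5, p = 0.95 the model gives 0.998842, verified in the tests against
exhaustive enumeration of all 2⁵ outcome vectors.

## Flank-based liftover

Flanks are 201 bp (100 up + ref base + 100 down) on the source forward
strand; markers within 100 bp of a contig end, or with another InDel inside
the flank window when a variant set is supplied, are skipped with a count.
Placement is exact-seed + ungapped extension: the flank's non-overlapping
31-mers (plus the terminal 31-mer) are looked up in the target, each hit
proposes a placement, and placements are scored by Hamming distance over the
full 201 bp on both strands.  Six non-overlapping seeds cover 201 bp, so any
ungapped placement with ≤ 4 mismatches (the default budget) retains at
least one exact seed — the search is exhaustive within the budget, and no
gapped placement can ever be produced, which is precisely the
no-InDels-in-flank acceptance rule.  A unique minimum maps the marker; tied
minima are `multimapped` and excluded (a "best hit" must be unique); no
candidate within budget is `unmapped`.  The mapped position is the placement
start plus the centre offset (reflected for minus-strand placements), and
allele confirmation requires the strand-adjusted target base to equal the
source ref or alt (and, when a target variant set is given, a target variant
with the same strand-adjusted allele pair).  For InDel markers the flank
anchors on the first ref base and the centre comparison uses the leading
base only — a documented approximation.

## Annotation and the LEM library

Region assignment per transcript: exonic (in CDS), UTR (in exon, outside
CDS), splicing (inside an intron within 2 bp of either boundary), intronic,
else intergenic.  Exonic SNP effects are codon-local: the variant base is
substituted into its codon on the coding strand (minus-strand transcripts
reverse-complemented) and translated with the standard genetic code;
startloss is any change in an ATG initiator codon, stopgain any change
producing a stop, stoploss any change destroying one.  The tests verify the
codon-local call against a whole-CDS translation diff on random transcripts
of both strands.  Exonic InDels are frameshift when the coding-length change
is not a multiple of 3 (for boundary-spanning deletions, only the removed
coding bases count, with a span warning); in-frame edits that stop
translation earlier than the length change alone explains are
`stopgain_indel`.  With several overlapping transcripts the most severe
effect is reported (stopgain/startloss/frameshift > stoploss > splicing >
nonsynonymous > nonframeshift > synonymous > UTR > intronic).

Large-effect mutations (LEM) are stopgain, stoploss, startloss, frameshift,
stop-introducing in-frame InDels, and splice-site disruptions — the classes
standard resequencing annotation treats as protein-breaking.  The library
keeps LEMs with minor-allele frequency ≥ 0.01 (boundary inclusive) in *both*
datasets at the same unified position with identical (gene, effect)
annotation; position-shared records with discordant annotation are counted
separately, and the per-variant concordance fraction quantifies how strongly
the reference assembly and annotation drive large-effect calls.  A carrier
is any accession with at least one alternate allele at the site.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the package's
study conditions.

* **Samples** — 345 wild, 418 cultivated, 18 hybrids, 2 duplicate
  re-sequencings (the test-population composition); validation panels
  default to 103 wild / 200 cultivated.
* **Genome** — 3 chromosomes × 600 kb, a gene every 25 kb with a fixed
  two-exon architecture (450-bp CDS split 200+250, 100-bp intron, 50-bp
  UTRs, alternating strands); CDSs are ATG + random stop-free codons + TAA
  so translation oracles are well-posed.  Desk-scale by design: the point is
  statistical structure, not genome size.
* **Frequencies** — background sites draw one reference-allele frequency per
  site from Beta(2, 0.5) (mean 0.8, reference-biased, as expected when the
  reference assembly comes from the cultivated pool) *shared by both
  populations*, so background Fst ≈ 0 in expectation.  Planted windows
  override the pair with archetype targets (type 1: 0.03/0.97, type 2:
  0.03/0.50, type 3: 0.50/0.97 — the centres of the three frequency boxes).
* **Genotypes** — independent Hardy–Weinberg draws at the site's population
  frequency: HWE is the minimal genotype-level model consistent with
  allele-frequency criteria.  Hybrids draw one allele from each population's
  frequency, giving the elevated-heterozygosity signature.  Duplicates copy
  a source accession with a 0.5% per-site error; missingness (2% default) is
  applied independently afterwards.  Densities: 2 SNPs/kb, 0.2 InDels/kb.
* **Planted LEMs** — constructed inside chosen genes by direct sequence
  design (a codon one substitution from a stop, an initiator or terminator
  change, a 1-bp or 3-bp CDS deletion, a donor/acceptor SNP) with a target
  MAF applied to both populations.  `genic_background=False` keeps random
  background variants out of gene spans so a planted LEM set is exactly the
  LEM truth.
* **Derived assembly** — per contig: optional random substitutions (outside
  protected intervals), optional reverse complement, and a random prefix
  insertion; the truth object records the exact affine map and strand, and
  the validation-dataset builder re-expresses source variants in target
  coordinates (reading alleles from the target sequence, so minus-strand
  InDels re-anchor correctly) and re-draws genotypes for an independent
  panel.  A configurable number of planted SNP-class LEMs can be replaced by
  a 1-bp frameshift deletion at the same unified position to create
  position-shared, annotation-discordant records.
* **Determinism** — one `numpy` generator seeded from the config; identical
  configs give byte-identical output files.

What passing tests on this generator do *not* show: behaviour under linkage
disequilibrium, demographic structure within populations, genotyping-error
models beyond the duplicate channel, multiallelic sites, or realistic gene
architecture diversity.  The frequency-based stages depend only on per-site
marginals, which the generator reproduces; haplotype-sensitive conclusions
would need a coalescent simulator.

## Numerical and degenerate-input choices

Quantiles are numpy's linear-interpolation empirical quantile.  Zero window
denominators exclude the window with a count.  Ties in ARMS selection break
toward the smaller position; tied best liftover hits are excluded rather
than arbitrarily resolved.  Even-n panels count ties as incorrect.
Annotation raises on a VCF-ref/genome disagreement, naming the site.
Empty marker lists produce header-only tables; empty candidate sets make
`validation_rate` an error rather than a silent 0/0.

## Problem sizes

The test and acceptance runs use desk-scale configurations chosen so every
statistical claim is measured with adequate power: oracle checks on 200
random small cases, region recovery on 10 independent seeds at n = 200 per
population, typing and RSF at n = 500 per population with 300 planted
variants per archetype, liftover on ~160 markers over two contigs, and LEM
recovery with 23 planted mutations across two derived assemblies.  The full
suite runs in well under a minute.
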