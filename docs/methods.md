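# Methods

## Ks/Ka estimation (NG86 with Jukes–Cantor correction)

For each codon, the number of synonymous sites is the per-position fraction
of single-base changes that preserve the encoded amino acid, renormalised
over changes that yield a sense codon (changes to stop codons are excluded
from the denominator), summed over the three positions. This convention
makes site counts conserve exactly: S + N = 3L for L codons, which every
pair is tested against. Sites are averaged over the two sequences of a
pair. Differences between codons differing at k positions are averaged with
equal weight over the k! mutational pathways; pathways passing through a
stop codon are skipped and the remainder re-weighted equally. In the
degenerate case where *every* ordering passes through a stop (possible only
for specific 2–3-difference codon pairs), all orderings are counted with
stop-crossing steps treated as nonsynonymous — a documented fallback that
keeps the estimator total-difference-conserving rather than undefined.
Codons containing a base outside {A,C,G,T} in either sequence are skipped
from both site and difference counts; an internal stop is an input error.

The raw proportions p\_s = Sd/S and p\_n = Nd/N are corrected with
d = −(3/4)·ln(1 − (4/3)p), undefined at p ≥ 3/4; a pair with saturated
p\_s is flagged and excluded from age distributions (the exclusion count is
reported with each distribution). A counting estimator was chosen over
codon-model maximum likelihood because it is deterministic, dependency-free
and verifiable against a brute-force enumeration oracle; the quantity the
downstream analysis consumes is the *position* of distribution modes, which
the two estimator families locate equivalently at the divergences involved
(Ks ≲ 1), so the acceptance surface is parameter recovery rather than
numeric identity with any particular likelihood implementation.

## Peak detection

Density modes are found by Gaussian KDE on log-transformed Ks values
(Silverman bandwidth by default) over a 512-point grid spanning the search
range extended by three bandwidths per side, so near-boundary maxima are
not clipped; local maxima with prominence above 5% of the peak density are
kept and mapped back to the Ks scale, discarding any that fall outside the
search range. On the log scale the mode of a lognormal component is its
median, so a component planted at location m is recovered at Ks = m. The
anchor-peak search band defaults to (0.4, 1.0); multi-peak scans default to
(0.05, 3.0), the lower bound suppressing the allele/tandem-duplicate spike
near zero. A distribution that is empty after range filtering returns a
no-mode result with a diagnostic rather than an error. Degenerate
point-mass inputs (log-range < 1e−9) return the common value directly,
since a zero-variance KDE is singular.

## WGD placement and dating

Placement partitions speciation events (each a Ks peak from a one-to-one
ortholog distribution) into strictly older (smaller peak) and strictly
younger (larger peak) than the WGD peak; an event within |ΔKs| < 0.02 of
the WGD is flagged unresolved instead of being forced onto a side. Dating
calibrates a per-lineage rate λ\_i = ks\_i/t\_i for each dated event and
reports T\_i = Ks\_WGD/λ\_i with the min/max/mean over lineages; because it
is ambiguous whether a single "average" age should summarise the
per-species estimates or the range endpoints, both the per-species mean and
the range midpoint are reported. Rate comparability across lineages is
checked by comparing each species' ortholog-peak position against a common
outgroup: lineages are "rate-comparable" when the largest pairwise mode
difference is ≤ 0.1 Ks (configurable), the condition under which ortholog
and paralog distributions can be compared without rate correction.

The bundled dating table (`data/synthetic_dating_table.tsv`) is a
**synthetic stand-in**, not measured data: four per-species (Ks peak, time)
rows constructed to be mutually consistent with a WGT peak at Ks 0.65, a
WGT age range of 64.83–75.54 Mya (mean 69.0), event times younger than the
82.8-Mya family/outgroup split, and intra-family peaks below / the
family–Convolvulaceae peak above the WGT peak.

## Hotspot scan

Variant filtering retains heterozygous genotypes (any two distinct called
alleles; missing genotypes ignored) with 2 ≤ DP ≤ 20 and QUAL ≥ 20. DP is
read from the first sample's FORMAT field, falling back to INFO; whether
the quality floor applies to site QUAL or genotype GQ is configurable
(site QUAL by default). Windows tile each chromosome from 0; the step
defaults to the window width (200 kb) because a fixed per-window count
cutoff is only coherent for non-overlapping windows — an overlapping step
is exposed as an option. The trailing partial window is kept at its true
width. Full windows are hotspots iff count > 1000 (strict); partial windows
iff rate > 0.5%, the width-independent form of the same cutoff. An optional
quantile mode instead takes the right tail (default 95th percentile) of the
full-window count density, reproducing the exploratory route to a cutoff.
Gene–hotspot intersection uses any-overlap (≥ 1 bp) on 0-based half-open
intervals (GFF3 converted at the boundary). Enrichment is a per-term
two-sided Fisher exact test on the (in-set/out-set × with/without term)
table with Benjamini–Hochberg adjustment across terms.

## S-RNase classification

Pattern 4 is scanned over the full sequence with overlapping windows; this
is a superset of matching within a curated alignment, hence conservative
for *excluding* candidates (any occurrence anywhere disqualifies). The
isoelectric point is the unique root of the monotone net-charge function
Q(pH) = Σ n⁺/(1+10^(pH−pKa)) − Σ n⁻/(1+10^(pKa−pH)) over N-terminus, K, R,
H (positive) and C-terminus, D, E, C, Y (negative), found by bisection on
[0, 14] to |Q| < 0.001. The Bjellqvist/ProtParam pKa table is the default
and an EMBOSS alternative ships alongside; the [8, 10] candidate band is
closed at both ends and robust to the table choice. pI is computed on the
sequence as provided (no signal-peptide trimming). S-locus detection
reports, for each candidate gene, the F-box genes on the same chromosome
intersecting the gene span extended by a configurable flank (default 1 Mb —
a deliberate, configurable choice, as no canonical flank width exists),
with gap distances.

## Synthetic data

`gen_ks_sample` draws from a mixture of lognormal components
(parameterised by median = peak location and log-sd, the standard shape for
empirical Ks peaks, which are right-skewed) over a uniform background.
`gen_cds_pair` draws a stop-free ancestor uniformly over sense codons and
places at most one single-base change per codon — synonymous changes at
codons with a synonymous one-step neighbour (preferring fourfold third
positions, which leave site counts untouched), nonsynonymous changes at
the remaining codons — with per-codon probabilities chosen so the expected
NG86 estimate equals the target; it raises a saturation error when the
implied proportion reaches 3/4 or the sequence lacks capacity. Because
changed codons differ at exactly one position, pathway averaging is exact
and the construction unbiased in expectation; the residual bias of the
JC inversion at 400–500 codons is within ±0.03 on the mean over seeds.
`gen_het_vcf` places heterozygous sites by a Poisson process at a
piecewise-constant rate (planted intervals *replace* the background rate),
writes VCF v4.2 with ##contig lengths, and fixes DP=10/QUAL=50 so records
sit inside the default filter band; filter behaviour itself is tested with
separately constructed sites. `gen_protein_set` plants one motif instance
into motif-class sequences and builds basic/acidic classes by 35% K/R
(resp. D/E) enrichment with the opposing charge class excluded; the truth
table records the intended class and the pI of each sequence as generated.

What the generators deliberately do not emulate: alignment error and indels
(pairs are constructed pre-aligned), read-level noise and genotype
likelihoods (VCF records are clean calls), linked variation or demographic
structure, and real RNase-T2 domain architecture. Passing tests therefore
demonstrate correctness of the estimators, scans and classifiers under the
stated statistical models, not robustness to upstream artefacts.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale chosen for tight
statistical bounds at interactive runtimes: 500 pairs × 500 codons for
anchor-peak recovery (mode within ±0.05 of the target across seeds),
3000-value mixtures for peak counting, 1-Mb chromosomes for hotspot
recovery (20 seeds, exact sensitivity/specificity at 10× rate separation).
The brute-force NG86 oracle comparison is exhaustive over all 61×61
single-codon pairs and sampled over multi-codon pairs (full enumeration of
3-codon pairs is combinatorially impossible). Every stochastic component
takes an explicit seed and is byte-reproducible; corrected distances are
compared to oracles only below p ≈ 0.7, because the Jukes–Cantor log
amplifies float rounding without bound as p → 3/4.

## Known limitations

- The counting estimator ignores transition/transversion bias and codon
  usage; heavily biased genes can shift individual Ks values, though peak
  positions are robust in practice.
- KDE mode positions carry the usual smoothing bias (a few hundredths of
  Ks at default bandwidth near 0.65) toward the centre of mass.
- One value per retained duplicate pair: no gene-family node weighting, so
  large families are over-represented in paranome distributions.
- Hotspot calls use a hard threshold; no multiple-testing control across
  windows and no local-rate modelling.
- pI on precursor sequences can differ from the mature peptide's; the
  [8, 10] band absorbs small shifts but signal peptides are not trimmed.
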