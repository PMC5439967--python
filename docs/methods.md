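# Methods

This note records the models, conventions, parameter choices and known
limitations behind `motifcoloc`, in the spirit of the methods sections of
the established genomics toolkits.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open (BED convention); 1-based inputs are
converted on read. The integer center of `[s, e)` is `(s + e − 1) // 2`, so
width-1 summits are their own center and even-width intervals have a
deterministic center. Signed anchor-to-site distances are
`center(site) − center(anchor)`, sign-flipped for minus-strand anchors;
equidistant neighbors break toward the negative (upstream) side so that
histograms are deterministic. Window extension clips at chromosome ends
rather than rejecting intervals, matching how extension-then-overlap is
used on real genomes; extension never merges — merging is a separate,
idempotent operation whose covered length is checked in tests against a
per-base boolean-mask oracle.

## Motif model and scanning

Count matrices follow the JASPAR PFM text format. The log-odds score in
bits at position `i` for base `b` is
`log2((c[i][b] + k·q[b]) / (Σ c[i][·] + k) / q[b])` with uniform background
`q` and total pseudocount `k = 0.8` distributed by background frequency — a
common JASPAR practice; both are configurable. Scanning reports every
window on both strands at or above the threshold (no greedy masking:
downstream co-localization statistics need complete site lists); windows
containing N are skipped; minus-strand hits are reported on forward
coordinates.

Published scans of this kind rarely state their cutoffs, so stringency is
defined *relative to the matrix*: threshold = `min + f·(max − min)` with
`f = 0.90` (high) or `0.80` (low). This is reproducible and
genome-independent, and preserves the two-tier (high/low stringency)
design of the analyses the package supports. An alternative cutoff by
match p-value is available (`score_threshold_for_pvalue`), computed from
the exact null score distribution by per-position convolution at 0.001-bit
resolution — practical for motif lengths up to ~20. Genome-scale hit
counts published for specific genomes are not reproducible targets without
the original cutoffs.

## Density profiles and their normalizer

Profiles count *all* site centers (not nearest-only) in bins around anchor
centers, optionally strand-oriented. The published description of the
normalization — the average number of sites per window genome-wide — is
implemented as

    density(bin) = count(bin) / (n_anchors · n_sites · bin_width / G)

with `G` the total genome length, or an effective (e.g. mappable) length
when supplied (default: total length). This makes 1.0 the exact null
level: a uniformly random site set has expected density 1 in every bin,
which the test suite verifies. For mean per-bin counts around 10 (the
standard null-calibration setting of 10,000 sites, 100 anchors, 10 bp bins
on 1 Mb), a 3-standard-error band around 1.0 across 10 bins excludes a
marginal exceedance in only ~96% of random draws — single marginal
excursions in one bin are expected behavior, not a calibration failure.

## Fisher overlap against a background universe

The 2×2 table is: foreground row = all a-sites genome-wide split by
whether their w-extension hits a b-site; background row = the same split
after restricting both site sets to intervals whose centers lie inside the
background union (e.g. combined open chromatin). "Direct overlap" means
w = 0 (≥1 shared bp). The two-sided p-value sums hypergeometric
probabilities no larger than the observed table's (verified against
exhaustive enumeration to 1e-12 for margins ≤ 60); the 95% CI uses the
Woolf log-OR normal approximation — closed-form and deterministic; the
conditional-MLE interval is out of scope.

## Rotational phasing

With `r = d mod 10`: phased if `min(r, 10 − r) ≤ tol`, un-phased if
`|r − 5| ≤ tol`, otherwise unclassified; `d = 0` is phased (limit of the
same-face rule). The default tolerance is 1 bp — real spacings jitter, and
±1 keeps the two classes maximally separated; tolerance 0 reproduces the
literal multiples-of-10 versus 5+10n rule, and values above 2 are rejected
because the classes would overlap at 2.5. Distances are unsigned and
center-to-center: rotational phase depends only on |Δ|. Pairing is
nearest-neighbor with a 45 bp default radius (the largest distance in the
un-phased family); each a-site pairs at most once while b-sites may pair
multiply. Pair regions are the union span of the two sites.

## Binomial GWAS enrichment

The statistic is `P(X ≥ x)` for `X ~ Binomial(n, p)`: `n` = trait SNP
count, `x` = SNPs inside the window-extended regions, `p` = fraction of
the uniquely mappable genome covered by those regions. SNP membership uses
the single-base SNP position; regions are merged after extension so
overlapping windows are never double-counted (required for `p` to be a
probability, and making results invariant to splitting a region into
adjacent pieces). The default window sweep is {1000, 2000, 5000, 10000} bp
— the union of the half-widths used in the analyses this implements.
Without a mappability track the whole genome is treated as mappable, so
synthetic runs need no mask. Raw binomial p-values are the primary
statistic; Benjamini–Hochberg q-values are attached as a convenience
column. LD expansion adds linked SNPs at strictly `r² > r²_min` (default
0.8), deduplicated by rsid and position. The two-proportion comparison
uses the pooled z-test with `p = 2(1 − Φ(|z|))`; a degenerate pooled
proportion returns z = 0, p = 1.

## Correlation-dissimilarity clustering

Pearson r is computed on pairwise-complete observations with a minimum of
3 shared samples (proteomic matrices are sparse); pairs below the minimum,
or involving a zero-variance row, get undefined r and are treated as
maximally dissimilar (D = 1) when clustering. p-values use the t transform
with pairwise-complete degrees of freedom; the Bonferroni factor is the
number of distinct off-diagonal pairs. `D = 1 − |r|` deliberately discards
the correlation sign so that co-regulated and counter-regulated rows
cluster together. Default linkage is complete — the common default of the
heatmap routines this emulates — with average and single available; the
merge tree exports as Newick.

## Synthetic data: what it emulates and what it does not

The generators plant the exact structure each statistic is meant to
detect, each deterministic under `(seed, stream)` and paired with a truth
table.

* **Genome**: i.i.d. bases at 41% GC (human-like), 1 Mb over two
  chromosomes by default. No repeats, no CpG structure, no N gaps.
* **Motifs**: two bundled synthetic 14-bp count matrices (97/1/1/1
  columns) whose consensi embed the GCGTG bHLH/PAS core and the CAGCTG
  E-box. Length and sharpness are chosen so high-stringency scanning
  recovers planted consensus sites exactly while chance decoy hits on a
  megabase random genome are rare enough (expected « 1 within pairing
  range of planted sites) not to perturb nearest-neighbor pairing on any
  seed.
* **Pairs**: 200 phased + 200 un-phased by default, spacings drawn from
  {20, 30, 40} and {15, 25, 35} — the members of the 10n and 5+10n
  families that let two 14-bp exact-consensus sites coexist without
  overwriting each other (a spacing below the motif width would corrupt
  the first site) and stay within the 45 bp pairing radius after ±1 bp
  jitter. Pairs keep ≥ 60 bp of clearance so pairing cannot cross pair
  boundaries; site strands alternate deterministically to exercise strand
  handling. The classifier itself is tested over the full published
  distance lists (5–45 bp) with width-1 abstract sites.
* **Summits**: width-1 points at planted site centers plus Normal(0,
  20 bp) jitter (rounded, clipped), with optional uniform decoys.
* **TSS**: oriented width-1 starts with synthetic gene names; a companion
  generator plants motif consensus downstream at +30 and +200 bp of
  oriented TSS to reproduce a double-peak promoter profile with a
  +1-nucleosome-boundary peak.
* **GWAS**: per trait, `round(f·n)` SNPs uniform inside the
  region∩mappable union and the rest uniform over the mappable genome;
  defaults are ten 100-SNP traits with one planted at f = 0.5. Each lead
  gains 0–3 linked SNPs within ±5 kb, r² from a half-high (0.8–1.0) /
  half-low (0–0.8) mixture. No realistic human LD block structure.
* **Mappability**: striped mask (first fraction of every 1 kb period),
  fully mappable by default so synthetic runs need no mask.
* **Expression**: blocks share a latent per-sample factor with
  alternating-sign loadings and Gaussian noise of
  sd = sqrt((1 − r)/r), giving within-block |r| = r exactly in
  expectation (default 3 blocks × 10 rows × 20 samples at r = 0.9).

Passing tests on these inputs demonstrate the statistics and their
implementations, not robustness to repeat structure, motif degeneracy,
realistic LD, or batch effects in real data.

## Problem sizes and numerics

The standard benchmark sizes — 1 Mb genome, 400 planted pairs, 1000 null
traits for type-I calibration, 100 replicates for enrichment power — keep
every check well-powered while the whole suite runs in seconds. Binomial
tails use the survival function (no 1 − CDF cancellation); test oracles
recompute them by direct pmf summation in 50-digit decimal arithmetic.
Type-I error of the enrichment test is conservative by discreteness (the
achievable level at α = 0.05 with n = 100, p = 0.05 is ≈ 0.037), so
calibration is asserted against the upper edge of the 99% binomial band
only. Cluster labels are renumbered in order of first appearance so
partitions are comparable across row permutations.

## Known limitations

* Interval sets are in-memory Python structures: fine for desk-scale and
  megabase simulations, not for hundreds of millions of intervals.
* No BigWig/BAM/tabix support; inputs are plain text (FASTA, BED, TSV,
  JASPAR PFM).
* The Fisher CI is Woolf-only; exact conditional intervals are not
  implemented.
* Scanning uses a zeroth-order background; no dinucleotide shuffling or
  higher-order null models.
* GO-term enrichment and external annotation services are out of scope;
  the package stops at region → nearest-gene assignment.
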