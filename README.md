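# motifcoloc

Genome-wide co-localization analysis for transcription-factor binding
sites: position-weight-matrix scanning, spatial co-localization profiling,
DNA helical-pitch rotational phasing, mappability-corrected binomial
GWAS-SNP enrichment, and correlation-dissimilarity clustering — with a
synthetic-data module that generates every input with planted, controlled
structure.

The package is aimed at regulatory genomicists asking whether two
transcription factors co-bind: do their predicted sites cluster in space,
are the spacings compatible with the two proteins facing the same side of
the DNA double helix, do the co-bound regions concentrate disease-associated
variants, and do the downstream proteins co-vary?

## The statistics at the core

**PWM scanning.** A JASPAR-style count matrix `c[i][b]` becomes a log-odds
scorer (bits)

    log_odds[i][b] = log2( (c[i][b] + k·q[b]) / (Σ_b' c[i][b'] + k) / q[b] )

with background `q` (uniform by default) and total pseudocount `k = 0.8`.
Every window on both strands scoring at or above a threshold is a hit; the
built-in `high`/`low` stringencies put the threshold at 90% / 80% of the
dynamic score range `[min_score, max_score]`.

**Co-localization.** For anchor sites and partner sites, the package
computes nearest-distance histograms (one oriented signed distance per
anchor) and density profiles counting *all* partner-site centers per bin,
normalized by the genome-wide uniform expectation
`n_anchors · n_sites · bin_width / G` so that 1.0 is the null level.
Overlap enrichment against a background universe (e.g. open chromatin) uses
the two-sided Fisher exact test with a Woolf 95% CI on the odds ratio.

**Rotational phasing.** A co-localized pair at center distance `d` is
*phased* when `d mod 10` is within a tolerance of 0 (same helical face,
direct contact possible) and *un-phased* when within a tolerance of 5
(opposite faces).

**GWAS enrichment.** For a trait with `n` SNPs, `x` of them inside the
window-extended merged regions, and `p` the fraction of the uniquely
mappable genome covered by those regions, the enrichment p-value is the
upper binomial tail `P(X ≥ x)` for `X ~ Binomial(n, p)` and the fold change
is `x / (n·p)`. Traits can be LD-expanded (`r² > 0.8`) first; site families
are compared with the two-proportion z-score test.

**Clustering.** Row-row Pearson correlations (pairwise-complete,
Bonferroni-corrected) become the dissimilarity `D = 1 − |r|`, clustered by
complete-linkage agglomeration.

## Worked example

`examples/03_gwas_enrichment.py` builds a 1 Mb genome with an 80% mappable
striped mask, 100 regions of 1 kb, and ten 100-SNP traits of which one has
half its SNPs planted inside the regions:

```
LD expansion: planted trait 100 lead SNPs -> 176 lead+linked
        trait  window  x   n     p  fold  p_value  q_value
planted trait    1000 59 100 0.299  1.97 1.55e-09 1.55e-08
 null trait 5    1000 34 100 0.299  1.14    0.214    0.512
 null trait 6    1000 34 100 0.299  1.14    0.214    0.512
 null trait 2    1000 33 100 0.299   1.1    0.282    0.512
```

With ±1000 bp extension the regions cover p = 0.299 of the mappable
genome; the planted trait has 59/100 SNPs inside (fold 2.0, binomial
p = 1.6e-9) while null traits sit near fold 1. The other example scripts
cover scanning + co-localization profiling (`01`), rotational phasing and
nearest-gene assignment (`02`), and proteome-style clustering (`04`); each
prints its numbers with a closing line on what they mean.

## Command-line pipeline

A thin CLI chains the same library calls on files:

```bash
motifcoloc all --out run/ --seed 11           # simulate → scan → coloc → phase → enrich → cluster
motifcoloc scan --config run.cfg --out hits/  # individual stages
```

Configuration is a flat `key=value` file overridden by flags; every stage
writes a `manifest.json` naming its inputs, parameters, and outputs. Exit
codes: 0 success, 1 internal error, 2 bad user input.

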