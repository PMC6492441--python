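# Methods

## The genetic model

`sdrmap` models one chromosome of length `length_bp` (default 18 Mb)
in a dioecious diploid with an active-Y sex system. The mother carries
founder haplotypes X1/X2, the father X3/Y1; an individual is male iff
its paternal gamete carries Y1 at the sex locus. The terminal segment
`[0, sdr_end_bp)` (default 5.5 Mb, the midpoint of the 5–6 Mb extent
typical of the kiwifruit sex chromosome) is the sex-determining region
(SDR): crossover intensity is zero there. The remainder — the
pseudoautosomal region (PAR) — recombines at a piecewise-constant
density in cM/Mb. All coordinates are 0-based half-open internally;
VCF I/O converts to 1-based.

### Meiosis

Per meiosis the crossover count is Poisson with mean (total PAR
cM)/100 and breakpoints are placed proportionally to local density —
no crossover interference. Interference is omitted because the cM/Mb
densities are the only calibrated quantities; it matters for
coincidence statistics, not for the map-length and rate-profile
recoveries this package targets, and the Haldane mapping function is
the internally consistent choice under this process (hence the
default; Kosambi is provided for data with interference).

Gene conversions are Poisson(`conversion_rate`) per meiosis, each
copying a tract of uniform length in `tract_len_range` (default
50–1000 bp, the span estimated for plant non-crossover tracts) with a
uniform start anywhere on the chromosome — including the SDR, where
conversions are the only permitted origin switches. No genome-wide
conversion rate is established for this system, so the default rate is
0 and tests that need conversions either set the rate or plant isolated
events explicitly (`plant_ssr_conversions`), which also guarantees the
planted events are detectable (interior fully informative SDR markers,
one event per progeny side).

### Genotyping error

Error is genotype replacement: with probability `error_rate` a dosage
call is replaced by a uniformly chosen *different* dosage. Replacement
(rather than allele flipping) is the simplest model that moves
identical-sample kinship below 0.5, the behaviour the full-sib
analyses depend on. SSR calls take an analogous replacement model with
a separate `ssr_error_rate` (default 0).

### Sex-ratio calculators

`expected_sex_ratio` enumerates gametes and offspring with exact
rational arithmetic. Diploids transmit each chromosome with
probability 1/2; tetraploids segregate tetrasomically by random
*chromosome* segregation into balanced two-chromosome gametes (all
C(4,2) pairs equally likely), which yields XX:XY:YY = 1:4:1 from an
XXYY male and hence the 5:1 ratio; random-chromatid models would not.

## Linkage maps and the SDR boundary

Pseudo-testcross selection keeps sites where exactly one parent is
heterozygous; the progeny dosage then reveals the transmitted
haplotype of that parent, or is recorded missing when incompatible.
Markers failing an exact binomial 1:1 test (default α = 0.001) are
flagged distorted but retained — dropping them would shorten maps and
bias rate profiles. Marker order is taken from physical positions, not
re-estimated; de novo grouping/ordering is out of scope. A/B phase
labels are aligned greedily along the chromosome so adjacent r ≤ 0.5.

r is estimated per adjacent pair from pairwise-complete progeny (no
multipoint likelihood — sufficient for rate profiles and far simpler);
r ≥ `r_max` (default 0.45) is capped and flagged so a single noisy
interval cannot blow up the map. Window rates interpolate cumulative
cM linearly at window edges; windows without flanking markers are
reported missing, never zero.

The SDR boundary is the breakpoint of a continuous two-segment least
squares fit of cumulative cM against position: flat (slope 0) up to
the breakpoint, linear beyond, joined at the breakpoint; the search is
exhaustive over marker positions with ties to the smaller position.
The continuity constraint matters: fitting the two segments
independently lets the flat segment absorb early PAR markers (the free
intercept re-fits the rest), biasing the estimate upward by several
hundred kb at low rates. Degenerate inputs are flagged rather than
guessed: a zero-length map returns the last marker with
`no_recombination`; a fit whose PAR/SDR rate ratio is below 5 returns
`no_suppression`.

## SSR origins and conversion scanning

A marker's informativeness is decided by enumeration: a parental side
is resolvable iff every possible progeny allele pair decomposes
uniquely on that side. (Four distinct lengths always qualify as fully
informative; enumeration also admits rare three-length configurations
that are just as resolvable.) Allele matching is exact in bp with an
optional ± tolerance (default 0) for capillary sizing noise.

Each progeny side's expected origin is its global consensus (modal
determined origin) over SDR markers — the right model for a
non-recombining region, where each side is one haplotype. An isolated
determined departure with ≥ `flank_k` (default 1) consensus-agreeing
determined markers on both sides is a conversion event, labelled
donor-recipient with the donor being the chromosome of the observed
unexpected allele; terminal markers need ≥2 consecutive consensus
markers on their single flank. Runs of ≥2 consecutive departures are
reported separately as possible crossovers/long tracts, never counted.
Denominators count determined calls per (side, consensus) context;
markers outside the SDR serve group-assignment QC only and are
excluded. Undetermined handling in denominators is one consistent
choice among several the source data would admit.

## Window statistics

Windows are fixed non-overlapping `[kW, (k+1)W)` (default 1 Mb) so
site membership is deterministic. Kinship uses the KING-robust moment
estimator over pairwise-complete sites; π uses available haplotypes
per site with the n/(n−1) factor; F<sub>ST</sub> is Weir–Cockerham
(1984) combined per window as a ratio of summed variance components
(stable for low-count windows), skipping sites monomorphic over both
groups; LD is the squared Pearson correlation of unphased dosages —
deterministic and oracle-checkable, unlike haplotype-EM r², which
would require phasing that is out of scope. Negative φ and
F<sub>ST</sub> are reported as computed; truncation would hide
estimator behaviour the validation relies on.

The unrelated-population simulator gives every male one shared
ancestral Y haplotype inside the SDR over an X background drawn from
per-site Bernoulli frequencies U(0.05, 0.95). That reproduces the
qualitative SDR signatures (elevated male-female F<sub>ST</sub>, male
identity) but not linkage disequilibrium structure, demography, or
selection — window statistics on real resequencing data will show LD
decay and diversity gradients this generator does not emulate, so
passing tests certify the estimators, not population-genetic realism.

## Problem sizes and validation conditions

Defaults mirror the study conditions the analyses are calibrated to:
236 progeny and ~210 markers for mapping families; 87 progeny and a
21-marker SSR panel (17 in the SDR; mixed informativeness ~7 fully / 4
female- / 4 male-informative / 2 uninformative) for the conversion
scan; 8 males + 6 females for the population panel; PAR rates 16.7
(paternal) and 7.52 (maternal) cM/Mb. Rate-recovery checks run 20
seeded replicates and compare the across-seed mean within 3σ of the
seed spread. Full-sib kinship simulations use 9,000 SNPs (500 per Mb),
a density at which 0.5% genotype error reliably places every SDR
window in the high 0.4s — sparser panels leave individual windows
error-free (φ exactly 0.5) or noisy below 0.46. Sequence-level
simulation (reads, alignment, variant calling) and multi-generation
pedigrees are out of scope.

## Known limitations

- The boundary estimator assumes a single terminal flat segment; a
  chromosome with interstitial suppression would need a multi-segment
  search.
- Conversion tracts shorter than the inter-marker spacing are only
  detectable if they cover a marker; no tract-length estimation is
  attempted from single-marker events.
- The tetraploid calculator covers tetrasomic random chromosome
  segregation only (no preferential pairing, no double reduction).
- `orient_phase` is greedy; with extremely sparse or noisy data an
  orientation error can propagate past a weakly informative interval
  (flagged indirectly via capped r).
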