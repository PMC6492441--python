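# sdrmap

Delimiting the non-recombining **sex-determining region (SDR)** of a
partially differentiated plant sex chromosome from ordinary F1 family
data — no cytology, no phased assemblies.

Young sex chromosomes, as found in dioecious plants such as kiwifruit
(*Actinidia*), carry an active-Y system: females are X1X2, males X3Y1,
and presence of a Y makes a plant male. The X and Y differ not by
morphology but by a terminal chromosome segment in which recombination
is suppressed. `sdrmap` implements the three genetic analyses that
together delimit such a region, plus a forward simulator that generates
every input with known ground truth, so the whole tool chain is
verifiable end to end:

1. **Pseudo-testcross linkage maps** (`sdrmap.linkage_map`). Markers
   heterozygous in one parent and homozygous in the other (`ab x aa`)
   segregate 1:1 and give per-parent maps. Adjacent-marker
   recombination fractions *r* are turned into map distance with
   Haldane's function, d = −50 ln(1 − 2r) cM (Kosambi optional), the
   windowed cM/Mb profile is computed, and the SDR boundary is found by
   an exhaustive continuous two-segment least-squares fit of cumulative
   cM against position (flat segment joined to a rising line).
2. **SSR chromosome-of-origin scanning** (`sdrmap.ssr_origin`). With the
   four parental allele lengths a→X1, b→X2, c→X3, d→Y1 assigned, each
   progeny allele is traced to a founder chromosome. Across a
   non-recombining SDR each progeny has one constant origin per
   parental side; an isolated single-marker departure flanked by
   consensus markers is a **gene conversion** (runs of ≥2 departures are
   excluded as possible crossovers), counted per donor-recipient
   direction with denominators of determined calls.
3. **Windowed population statistics** (`sdrmap.popgen_windows`).
   KING-robust kinship φ = (N_Aa,Aa − 2 N_AA,aa)/(N_Aa,i + N_Aa,j)
   (0.5 for identical genotypes), nucleotide diversity π with the
   n/(n−1) factor, Weir–Cockerham (1984) F<sub>ST</sub> between sexes
   as a ratio of summed variance components, and LD decay as the median
   dosage-correlation r² over 1–10 kb site pairs, all in 1-Mb windows.

The simulator (`sdrmap.family_sim`) draws Poisson crossovers outside
the SDR at a configurable cM/Mb profile, plants 50–1000 bp gene
conversion tracts, applies genotype-replacement error, and includes
exact sex-ratio calculators for active-Y crosses (XX×XY → 1:1, XY
selfed → 3:1, XXXX×XXYY → 5:1 by enumeration).

## Worked example

```sh
python examples/recombination_profile.py
```

simulates 236 progeny on an 18 Mb chromosome (terminal 5.5 Mb SDR,
pseudoautosomal rate 16.7 cM/Mb), rebuilds the paternal map and prints:

```
210 paternal-informative markers, map length 213.3 cM
estimated SDR boundary: 5.37 Mb (truth 5.50)
mean PAR rate: 17.01 cM/Mb (truth 16.70)

windowed recombination rate (cM/Mb):
   0.0- 1.0 Mb  0.0
   ...
   5.0- 6.0 Mb  9.4 #########
   6.0- 7.0 Mb 18.4 ##################
   ...
```

The flat-then-linear profile is the signature of a terminal
suppressed-recombination region: the boundary estimate and the
recovered pseudoautosomal rate both match the simulated truth to
within sampling error. The other scripts in `examples/` demonstrate the
sex-ratio calculators, the SSR conversion scan (which recovers planted
per-direction conversion totals exactly), the windowed
F<sub>ST</sub>/π/LD/kinship panel, and the one-call reproducible
pipeline (`sdrmap demo --seed 1 --out-dir out/` from the shell).

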