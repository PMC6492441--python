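"""Windowed Fst, diversity, LD and kinship across a partially sex-linked
chromosome.

Simulates 8 males and 6 females in which every male shares one ancestral
Y haplotype over the terminal 5.5 Mb (no X-Y recombination there), plus
three full-sib males who inherited the same X and Y haplotypes. The
male-female Fst is elevated inside the SDR, and the full sibs' windowed
kinship plateaus just below 0.5 there.
"""

import numpy as np

import sdrmap as sm

chrom = sm.ChromosomeModel.uniform_par(16.7)
pop, sexes = sm.simulate_population(chrom, n_males=8, n_females=6, n_snps=2000, seed=31)
stats = sm.window_stats(pop, groups=sexes)

in_sdr = stats["window_end"] <= chrom.sdr_end_bp // 10**6 * 10**6
print("male-female Weir-Cockerham Fst:")
print(f"  SDR windows  (0-5 Mb): mean {stats.loc[in_sdr, 'fst'].mean():.3f}")
print(f"  PAR windows (6-18 Mb): mean {stats.loc[~in_sdr, 'fst'].mean():.3f}")
print(f"per-bp diversity pi, chromosome mean: {stats['pi'].mean():.2e}")
print(f"median r2 (1-10 kb pairs), chromosome mean: {stats['median_r2'].mean():.3f}")

# three full-sib males sharing both SDR haplotypes, 0.5% genotype error
mother, father = sm.make_outbred_parents(chrom, n_snps=9000, seed=32)
fam = sm.simulate_family(mother, father, chrom, 60, error_rate=0.005, seed=33)
probe = chrom.sex_locus_bp
sibs = [
    p
    for i, p in enumerate(fam.progeny)
    if fam.progeny_sex[i] == "male"
    and fam.truth_origin(i, "maternal", probe) == "X1"
    and fam.truth_origin(i, "paternal", probe) == "Y1"
][:3]
kin = sm.kinship(fam.snp_genotypes, (sibs[0], sibs[1]))
sdr_phi = kin.loc[kin["window_end"] <= 5_000_000, "phi"]
par_phi = kin.loc[kin["window_start"] >= chrom.sdr_end_bp, "phi"]
print()
print(f"full-sib kinship, SDR windows: {sdr_phi.min():.3f}-{sdr_phi.max():.3f}")
print(f"full-sib kinship, PAR windows: {par_phi.min():.3f}-{par_phi.max():.3f}")
print()
print("Identical genotypes give kinship 0.5; the 0.5% error rate pulls the")
print("SDR plateau into the high 0.4s, while PAR windows range down toward")
print("zero wherever the sibs inherited no shared haplotype.")
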