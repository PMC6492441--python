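"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive (scalar loops, enumeration,
textbook formulas applied site by site) and shares no code with the
package; any agreement with the vectorised implementations is therefore
meaningful.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def pi_pairwise(genotypes: np.ndarray, window_bp: int) -> float:
    """Nucleotide diversity as the average pairwise haplotype difference.

    Per site: among the n non-missing haplotypes (two per genotyped
    diploid, c1 of them alternate), the number of differing unordered
    haplotype pairs is c0*c1 out of n-choose-2. Summed over sites,
    divided by window length.
    """
    total = 0.0
    for j in range(genotypes.shape[1]):
        c0 = c1 = 0
        for g in genotypes[:, j]:
            if g == MISSING:
                continue
            c1 += int(g)
            c0 += 2 - int(g)
        n = c0 + c1
        if n >= 2:
            total += (c0 * c1) / (n * (n - 1) / 2)
    return total / window_bp


def fst_wc84(g1: np.ndarray, g2: np.ndarray) -> float:
    """Weir & Cockerham 1984 theta for two groups, ratio of summed components.

    Scalar per-site evaluation of the a, b, c components for r=2
    subpopulations of diploids, skipping sites monomorphic over both
    groups or with <2 genotyped individuals in either group.
    """
    num = den = 0.0
    r = 2
    for j in range(g1.shape[1]):
        x1 = [g for g in g1[:, j] if g != MISSING]
        x2 = [g for g in g2[:, j] if g != MISSING]
        n1, n2 = len(x1), len(x2)
        if n1 < 2 or n2 < 2:
            continue
        p1 = sum(x1) / (2 * n1)
        p2 = sum(x2) / (2 * n2)
        pall = (sum(x1) + sum(x2)) / (2 * (n1 + n2))
        if pall in (0.0, 1.0):
            continue
        h1 = sum(1 for g in x1 if g == 1) / n1
        h2 = sum(1 for g in x2 if g == 1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def median_r2(genotypes: np.ndarray, positions: np.ndarray, lo: int, hi: int) -> tuple[float, int]:
    """Median squared Pearson dosage correlation over pairs lo..hi bp apart."""
    vals = []
    n_sites = genotypes.shape[1]
    for j in range(n_sites):
        for k in range(j + 1, n_sites):
            d = positions[k] - positions[j]
            if d < lo or d > hi:
                continue
            pairs = [
                (float(genotypes[i, j]), float(genotypes[i, k]))
                for i in range(genotypes.shape[0])
                if genotypes[i, j] != MISSING and genotypes[i, k] != MISSING
            ]
            if len(pairs) < 2:
                continue
            x = [p[0] for p in pairs]
            y = [p[1] for p in pairs]
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            mx, my = sum(x) / len(x), sum(y) / len(y)
            sxy = sum((a - mx) * (b - my) for a, b in pairs)
            sxx = sum((a - mx) ** 2 for a in x)
            syy = sum((b - my) ** 2 for b in y)
            vals.append(sxy * sxy / (sxx * syy))
    return (float(np.median(vals)) if vals else float("nan")), len(vals)


def king_phi(gi: np.ndarray, gj: np.ndarray) -> float:
    """KING-robust kinship by direct count over pairwise-complete sites."""
    n_hh = n_opp = n_i = n_j = 0
    for a, b in zip(gi, gj):
        if a == MISSING or b == MISSING:
            continue
        if a == 1 and b == 1:
            n_hh += 1
        if (a == 0 and b == 2) or (a == 2 and b == 0):
            n_opp += 1
        if a == 1:
            n_i += 1
        if b == 1:
            n_j += 1
    if n_i + n_j == 0:
        return float("nan")
    return (n_hh - 2 * n_opp) / (n_i + n_j)


def truth_recombinant_fraction(family, side: str, pos_a: int, pos_b: int) -> float:
    """Fraction of truth gametes whose origin differs between two positions."""
    idx = 0 if side == "maternal" else 1
    rec = 0
    for gametes in family.truth_gametes:
        g = gametes[idx]
        if g.hap_at(pos_a) != g.hap_at(pos_b):
            rec += 1
    return rec / len(family.truth_gametes)


def truth_switch_count(gamete) -> int:
    """Origin switches counted by scanning the segment list."""
    haps = [h for _, _, h in gamete.segments]
    return sum(1 for a, b in zip(haps, haps[1:]) if a != b)
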