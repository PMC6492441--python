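"""Windowed population-genetic statistics over a diploid genotype matrix.

Implements the four per-window summaries used to characterise a
suppressed-recombination region from resequenced unrelated (or
full-sib) individuals:

* KING-robust pairwise kinship (the ``relatedness2`` moment estimator):
  phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa,i + N_Aa,j), 0.5 for identical
  genotype vectors.
* Nucleotide diversity pi per bp, with the n/(n-1) small-sample factor.
* Weir-Cockerham (1984) Fst between two labelled groups, combined per
  window as a ratio of summed variance components.
* LD decay summarised as the median squared dosage correlation over
  site pairs 1-10 kb apart (by default).

Windows are fixed, non-overlapping, 0-based half-open [kW, (k+1)W).
Missing genotypes are handled per site: pairwise-complete for kinship
and r2, available haplotypes for pi and Fst. Negative phi and Fst are
reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, window_slices


@dataclass
class WindowSpec:
    """Window and LD-distance settings for the Fig.-3-style panel."""

    window_bp: int = 1_000_000
    ld_dist_range_bp: tuple[int, int] = (1_000, 10_000)
    ld_min_pairs: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.ld_dist_range_bp
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 < lo <= hi <= self.window_bp:
            raise ValueError("ld range must satisfy 0 < lo <= hi <= window_bp")


def kinship(
    genotypes: GenotypeMatrix,
    pair: tuple[str, str],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """KING-robust kinship for one sample pair, per window.

    Over pairwise-complete sites in each window: ``N_Aa_Aa`` counts
    sites where both samples are heterozygous, ``N_AA_aa`` opposite
    homozygotes, ``N_Aa_i``/``N_Aa_j`` heterozygous sites per sample;
    phi = (N_Aa_Aa - 2 N_AA_aa)/(N_Aa_i + N_Aa_j). Windows with a zero
    denominator get phi = NaN. A self-pair is allowed (phi = 0.5
    wherever the sample has a het site).
    """
    gi = genotypes.row(pair[0]).astype(np.int16)
    gj = genotypes.row(pair[1]).astype(np.int16)
    ok = (gi != MISSING) & (gj != MISSING)
    rows = []
    for start, end, sl in window_slices(genotypes.positions, window_bp):
        m = ok[sl]
        a, b = gi[sl][m], gj[sl][m]
        n_hh = int(np.sum((a == 1) & (b == 1)))
        n_opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
        n_i = int(np.sum(a == 1))
        n_j = int(np.sum(b == 1))
        denom = n_i + n_j
        phi = (n_hh - 2.0 * n_opp) / denom if denom > 0 else np.nan
        rows.append(
            {
                "window_start": start,
                "window_end": end,
                "n_sites": int(m.sum()),
                "N_Aa_Aa": n_hh,
                "N_AA_aa": n_opp,
                "N_Aa_i": n_i,
                "N_Aa_j": n_j,
                "phi": phi,
            }
        )
    return pd.DataFrame(rows)


def nucleotide_diversity(genotypes: GenotypeMatrix, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Per-window nucleotide diversity pi per bp.

    Per site, with n non-missing haplotypes (2 per genotyped diploid)
    and alternate frequency p: pi_site = (n/(n-1)) * 2 p (1-p) — the
    mean pairwise difference among sampled haplotypes. Window pi sums
    pi_site over sites and divides by the window length in bp.
    """
    g = genotypes.genotypes.astype(float)
    g[g == MISSING] = np.nan
    rows = []
    for start, end, sl in window_slices(genotypes.positions, window_bp):
        gw = g[:, sl]
        n_hap = 2 * np.sum(~np.isnan(gw), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(gw, axis=0) / n_hap
            per_site = np.where(n_hap >= 2, n_hap / np.maximum(n_hap - 1, 1) * 2 * p * (1 - p), 0.0)
        rows.append(
            {
                "window_start": start,
                "window_end": end,
                "n_sites": int(np.sum(n_hap >= 2)),
                "pi": float(np.nansum(per_site)) / window_bp,
            }
        )
    return pd.DataFrame(rows)


def _wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) a, b, c variance components per site.

    ``g1``/``g2`` are dosage matrices (individuals x sites) of the two
    groups with NaN for missing. Sites where either group has fewer
    than two genotyped individuals yield NaN components.
    """
    r = 2
    n1 = np.sum(~np.isnan(g1), axis=0).astype(float)
    n2 = np.sum(~np.isnan(g2), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(g1, axis=0) / (2 * n1)
        p2 = np.nansum(g2, axis=0) / (2 * n2)
        h1 = np.nansum(g1 == 1, axis=0) / n1
        h2 = np.nansum(g2 == 1, axis=0) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    invalid = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[invalid] = np.nan
    return a, b, c


def fst_weir_cockerham(
    genotypes: GenotypeMatrix,
    groups: dict[str, str],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham Fst between two groups (e.g. sexes).

    ``groups`` maps sample name to group label; exactly two labels with
    at least two individuals each are required. Per window, Fst is the
    ratio of summed a components to summed a+b+c over polymorphic
    sites (monomorphic-in-both sites are skipped). Negative estimates
    are reported as computed.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    members = {lab: [s for s in genotypes.samples if groups.get(s) == lab] for lab in labels}
    for lab, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 individuals")
    g = genotypes.genotypes.astype(float)
    g[g == MISSING] = np.nan
    idx1 = [genotypes.sample_index(s) for s in members[labels[0]]]
    idx2 = [genotypes.sample_index(s) for s in members[labels[1]]]
    a, b, c = _wc_components(g[idx1], g[idx2])
    with np.errstate(invalid="ignore"):
        p_all = np.nansum(g, axis=0) / (2 * np.sum(~np.isnan(g), axis=0))
    poly = ~np.isnan(a) & (p_all > 0) & (p_all < 1)

    rows = []
    for start, end, sl in window_slices(genotypes.positions, window_bp):
        use = poly[sl]
        num = float(np.sum(a[sl][use]))
        den = float(np.sum((a + b + c)[sl][use]))
        rows.append(
            {
                "window_start": start,
                "window_end": end,
                "n_sites": int(use.sum()),
                "fst": num / den if den != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ld_median_r2(
    genotypes: GenotypeMatrix,
    window_bp: int = 1_000_000,
    dist_range_bp: tuple[int, int] = (1_000, 10_000),
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Median squared dosage correlation over close site pairs, per window.

    For every pair of polymorphic sites in a window whose bp distance
    lies in ``dist_range_bp`` (inclusive), r2 is the squared Pearson
    correlation of dosages over pairwise-complete individuals; pairs
    with a zero-variance member are skipped. Windows with fewer than
    ``min_pairs`` usable pairs report NaN.
    """
    lo, hi = dist_range_bp
    g = genotypes.genotypes.astype(float)
    g[g == MISSING] = np.nan
    rows = []
    for start, end, sl in window_slices(genotypes.positions, window_bp):
        pos = genotypes.positions[sl]
        gw = g[:, sl]
        r2s = []
        for j in range(len(pos)):
            for k in range(j + 1, len(pos)):
                d = pos[k] - pos[j]
                if d < lo:
                    continue
                if d > hi:
                    break
                x, y = gw[:, j], gw[:, k]
                m = ~np.isnan(x) & ~np.isnan(y)
                if m.sum() < 2:
                    continue
                xv, yv = x[m], y[m]
                if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                    continue
                rho = np.corrcoef(xv, yv)[0, 1]
                r2s.append(rho * rho)
        rows.append(
            {
                "window_start": start,
                "window_end": end,
                "n_pairs": len(r2s),
                "median_r2": float(np.median(r2s)) if len(r2s) >= min_pairs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def window_stats(
    genotypes: GenotypeMatrix,
    groups: dict[str, str] | None = None,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Convenience: pi, Fst (if groups given) and median r2 in one frame."""
    spec = spec or WindowSpec()
    out = nucleotide_diversity(genotypes, spec.window_bp)
    ld = ld_median_r2(genotypes, spec.window_bp, spec.ld_dist_range_bp, spec.ld_min_pairs)
    out = out.merge(
        ld[["window_start", "n_pairs", "median_r2"]], on="window_start", how="left"
    )
    if groups is not None:
        fst = fst_weir_cockerham(genotypes, groups, spec.window_bp)
        out = out.merge(fst[["window_start", "fst"]], on="window_start", how="left")
    return out
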