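"""Forward simulator of an F1 family on a partially sex-linked chromosome.

The model is a dioecious diploid with an active-Y system: the mother
carries X1/X2, the father X3/Y1, and a progeny is male iff its paternal
gamete carries Y1 at the sex locus. The chromosome has a terminal
non-recombining sex-determining region (SDR, ``[0, sdr_end_bp)``) and a
pseudoautosomal region (PAR) with a piecewise-constant crossover density
in cM/Mb. Crossovers follow a Poisson process with no interference;
gene conversions are Poisson-many short tracts (uniform length within a
range, uniform start) copied from the homologous chromosome, and may
fall anywhere, including inside the SDR.

Exact sex-ratio calculators for diploid and tetrasomic-tetraploid
crosses are provided alongside (``expected_sex_ratio``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .containers import MISSING, GenotypeMatrix, SSRMarker, SSRTable

MATERNAL_LABELS = ("X1", "X2")
PATERNAL_LABELS = ("X3", "Y1")


@dataclass
class ChromosomeModel:
    """Physical and genetic model of the sex chromosome.

    Parameters
    ----------
    length_bp : int
        Chromosome length. Default 18 Mb.
    sdr_end_bp : int
        End (exclusive) of the terminal SDR ``[0, sdr_end_bp)``; zero
        crossover intensity inside. Default 5.5 Mb, the midpoint of the
        5-6 Mb extent seen in kiwifruit recombination maps.
    rate_profile : list of (start_bp, end_bp, cM_per_Mb)
        Piecewise-constant crossover density tiling the PAR
        ``[sdr_end_bp, length_bp)``.
    conversion_rate : float
        Expected gene-conversion events per meiosis per chromosome.
    tract_len_range : (int, int)
        Min/max conversion tract length in bp (inclusive); default
        50-1000 bp, the span estimated for plant non-crossover tracts.
    """

    length_bp: int = 18_000_000
    sdr_end_bp: int = 5_500_000
    rate_profile: list[tuple[int, int, float]] | None = None
    conversion_rate: float = 0.0
    tract_len_range: tuple[int, int] = (50, 1000)

    def __post_init__(self) -> None:
        if not 0 <= self.sdr_end_bp < self.length_bp:
            raise ValueError("need 0 <= sdr_end_bp < length_bp")
        if self.rate_profile is None:
            self.rate_profile = [(self.sdr_end_bp, self.length_bp, 10.0)]
        segs = sorted(self.rate_profile)
        if segs[0][0] != self.sdr_end_bp or segs[-1][1] != self.length_bp:
            raise ValueError("rate_profile must tile [sdr_end_bp, length_bp)")
        for (s0, e0, r0), (s1, e1, _) in zip(segs, segs[1:]):
            if e0 != s1:
                raise ValueError("rate_profile segments must be contiguous")
        for s, e, r in segs:
            if e <= s or r < 0:
                raise ValueError("rate segments need end > start and rate >= 0")
        tmin, tmax = self.tract_len_range
        if tmin < 1 or tmin > tmax:
            raise ValueError("tract_len_range needs 1 <= min <= max")
        if self.conversion_rate < 0:
            raise ValueError("conversion_rate must be >= 0")
        self.rate_profile = segs

    @classmethod
    def uniform_par(
        cls,
        cm_per_mb: float,
        length_bp: int = 18_000_000,
        sdr_end_bp: int = 5_500_000,
        **kw,
    ) -> "ChromosomeModel":
        """Chromosome with a single uniform PAR crossover density."""
        return cls(
            length_bp=length_bp,
            sdr_end_bp=sdr_end_bp,
            rate_profile=[(sdr_end_bp, length_bp, cm_per_mb)],
            **kw,
        )

    @property
    def total_par_cm(self) -> float:
        return sum((e - s) / 1e6 * r for s, e, r in self.rate_profile)

    @property
    def sex_locus_bp(self) -> int:
        # midpoint of the SDR; exact position is unobservable given zero
        # recombination across the region
        return self.sdr_end_bp // 2


@dataclass
class ParentHaplotypes:
    """Two founder haplotypes of one parent with SNP and SSR alleles."""

    role: str  # "maternal" | "paternal"
    labels: tuple[str, str]
    snp_positions: np.ndarray
    snp_alleles: np.ndarray  # (2, n_snps) of 0/1
    ssr_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ssr_alleles: np.ndarray = field(default_factory=lambda: np.empty((2, 0), dtype=np.int32))
    ssr_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("maternal", "paternal"):
            raise ValueError("role must be 'maternal' or 'paternal'")
        expected = MATERNAL_LABELS if self.role == "maternal" else PATERNAL_LABELS
        if tuple(self.labels) != expected:
            raise ValueError(f"{self.role} labels must be {expected}")
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)
        self.snp_alleles = np.asarray(self.snp_alleles, dtype=np.int8)
        self.ssr_positions = np.asarray(self.ssr_positions, dtype=np.int64)
        self.ssr_alleles = np.asarray(self.ssr_alleles, dtype=np.int32)
        if self.snp_alleles.shape != (2, len(self.snp_positions)):
            raise ValueError("snp_alleles must be (2, n_snps)")
        if self.ssr_alleles.shape != (2, len(self.ssr_positions)):
            raise ValueError("ssr_alleles must be (2, n_ssr)")

    @property
    def snp_dosage(self) -> np.ndarray:
        return self.snp_alleles.sum(axis=0).astype(np.int8)


@dataclass
class Gamete:
    """Chromosome-of-origin mosaic transmitted by one meiosis.

    ``segments`` is an ordered list of (start_bp, end_bp, hap_index)
    tiling [0, length_bp); hap_index indexes the parent's two founder
    haplotypes. Switch points arise only at crossovers or at conversion
    tract boundaries.
    """

    segments: list[tuple[int, int, int]]
    crossovers: list[int]
    conversions: list[tuple[str, str, int, int]]  # donor, recipient, start, end

    def hap_at(self, pos: int) -> int:
        for s, e, h in self.segments:
            if s <= pos < e:
                return h
        raise ValueError(f"position {pos} outside gamete span")

    def haps_at(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        starts = np.array([s for s, _, _ in self.segments])
        haps = np.array([h for _, _, h in self.segments], dtype=np.int8)
        idx = np.searchsorted(starts, positions, side="right") - 1
        return haps[idx]

    def n_switches(self) -> int:
        return sum(
            1 for (_, _, h0), (_, _, h1) in zip(self.segments, self.segments[1:]) if h0 != h1
        )


@dataclass
class SimulatedFamily:
    """An F1 family plus the ground truth needed to audit every stage."""

    mother: ParentHaplotypes
    father: ParentHaplotypes
    chrom: ChromosomeModel
    progeny: list[str]
    progeny_sex: list[str]
    snp_genotypes: GenotypeMatrix
    ssr_table: SSRTable | None
    truth_gametes: list[tuple[Gamete, Gamete]]  # (maternal, paternal) per progeny
    seed: int | None

    def truth_origin(self, progeny_idx: int, side: str, pos: int) -> str:
        mg, pg = self.truth_gametes[progeny_idx]
        if side == "maternal":
            return self.mother.labels[mg.hap_at(pos)]
        return self.father.labels[pg.hap_at(pos)]


def _flip_interval(
    segments: list[tuple[int, int, int]], start: int, end: int
) -> list[tuple[int, int, int]]:
    """Invert the haplotype index over [start, end), splitting segments."""
    out: list[tuple[int, int, int]] = []
    for s, e, h in segments:
        if e <= start or s >= end:
            out.append((s, e, h))
            continue
        if s < start:
            out.append((s, start, h))
        out.append((max(s, start), min(e, end), 1 - h))
        if e > end:
            out.append((end, e, h))
    # merge adjacent same-hap segments
    merged = [out[0]]
    for s, e, h in out[1:]:
        ps, pe, ph = merged[-1]
        if ph == h and pe == s:
            merged[-1] = (ps, e, h)
        else:
            merged.append((s, e, h))
    return merged


def _sample_crossover_positions(chrom: ChromosomeModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Place n crossovers in the PAR proportionally to local cM/Mb."""
    segs = chrom.rate_profile
    weights = np.array([(e - s) / 1e6 * r for s, e, r in segs])
    total = weights.sum()
    if total == 0 or n == 0:
        return np.empty(0, dtype=np.int64)
    cum = np.concatenate([[0.0], np.cumsum(weights)])
    u = rng.uniform(0.0, total, size=n)
    seg_idx = np.searchsorted(cum, u, side="right") - 1
    seg_idx = np.clip(seg_idx, 0, len(segs) - 1)
    pos = np.empty(n, dtype=np.int64)
    for i, k in enumerate(seg_idx):
        s, e, _ = segs[k]
        frac = (u[i] - cum[k]) / weights[k]
        pos[i] = s + int(frac * (e - s))
    return np.sort(pos)


def simulate_meiosis(
    parent: ParentHaplotypes, chrom: ChromosomeModel, rng: np.random.Generator
) -> Gamete:
    """One meiosis: Poisson crossovers in the PAR plus conversion tracts.

    The crossover count is Poisson with mean ``total PAR cM / 100``;
    breakpoints fall proportionally to the local density. Conversion
    events are Poisson(``conversion_rate``); each copies a tract of
    uniform length within ``tract_len_range`` (uniform start anywhere on
    the chromosome) from the homologue into the transmitted strand.
    """
    n_xo = rng.poisson(chrom.total_par_cm / 100.0)
    xo_pos = _sample_crossover_positions(chrom, n_xo, rng)
    start_hap = int(rng.integers(2))

    segments: list[tuple[int, int, int]] = []
    bounds = [0] + list(xo_pos) + [chrom.length_bp]
    hap = start_hap
    for s, e in zip(bounds, bounds[1:]):
        if e > s:
            segments.append((s, e, hap))
        hap = 1 - hap

    conversions: list[tuple[str, str, int, int]] = []
    n_conv = rng.poisson(chrom.conversion_rate) if chrom.conversion_rate > 0 else 0
    tmin, tmax = chrom.tract_len_range
    for _ in range(n_conv):
        length = int(rng.integers(tmin, tmax + 1))
        length = min(length, chrom.length_bp)
        start = int(rng.integers(0, chrom.length_bp - length + 1))
        end = start + length
        bg = None
        for s, e, h in segments:
            if s <= start < e:
                bg = h
                break
        recipient = parent.labels[bg]
        donor = parent.labels[1 - bg]
        conversions.append((donor, recipient, start, end))
        segments = _flip_interval(segments, start, end)

    return Gamete(segments=segments, crossovers=list(map(int, xo_pos)), conversions=conversions)


def simulate_family(
    mother: ParentHaplotypes,
    father: ParentHaplotypes,
    chrom: ChromosomeModel,
    n_progeny: int,
    error_rate: float = 0.0,
    ssr_error_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    paternal_chrom: ChromosomeModel | None = None,
    progeny_prefix: str = "P",
) -> SimulatedFamily:
    """Simulate an F1 family of ``n_progeny`` from the two parents.

    ``chrom`` governs the maternal meioses (and the paternal ones unless
    ``paternal_chrom`` overrides, allowing the sexes' different PAR
    densities). SNP genotypes are read off the gametes then perturbed
    per-call with probability ``error_rate`` by replacing the dosage
    with a uniformly chosen different dosage. SSR calls are error-free
    unless ``ssr_error_rate`` is set, in which case a call is replaced
    by a uniformly chosen *different* maternal+paternal allele pair.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    pat_chrom = paternal_chrom or chrom
    for par, cm in ((mother, chrom), (father, pat_chrom)):
        for arr in (par.snp_positions, par.ssr_positions):
            if len(arr) and (arr.min() < 0 or arr.max() >= cm.length_bp):
                raise ValueError("marker positions outside chromosome")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_snps = len(mother.snp_positions)
    if not np.array_equal(mother.snp_positions, father.snp_positions):
        raise ValueError("parents must share the SNP marker panel")
    n_ssr = len(mother.ssr_positions)

    names = [f"{progeny_prefix}{i+1:03d}" for i in range(n_progeny)]
    sexes: list[str] = []
    truth: list[tuple[Gamete, Gamete]] = []
    geno = np.empty((n_progeny, n_snps), dtype=np.int8)
    ssr_calls = np.full((n_progeny, n_ssr, 2), MISSING, dtype=np.int32)
    col = np.arange(n_snps)
    ssr_col = np.arange(n_ssr)

    for i in range(n_progeny):
        mg = simulate_meiosis(mother, chrom, rng)
        pg = simulate_meiosis(father, pat_chrom, rng)
        truth.append((mg, pg))
        sexes.append("male" if father.labels[pg.hap_at(pat_chrom.sex_locus_bp)] == "Y1" else "female")
        if n_snps:
            mat = mother.snp_alleles[mg.haps_at(mother.snp_positions), col]
            pat = father.snp_alleles[pg.haps_at(father.snp_positions), col]
            geno[i] = mat + pat
        if n_ssr:
            mhap = mg.haps_at(mother.ssr_positions)
            phap = pg.haps_at(father.ssr_positions)
            ssr_calls[i, :, 0] = mother.ssr_alleles[mhap, ssr_col]
            ssr_calls[i, :, 1] = father.ssr_alleles[phap, ssr_col]

    if error_rate > 0 and n_snps:
        err = rng.random(geno.shape) < error_rate
        shift = rng.integers(1, 3, size=geno.shape).astype(np.int8)
        geno[err] = (geno[err] + shift[err]) % 3

    if ssr_error_rate > 0 and n_ssr:
        for i in range(n_progeny):
            for j in range(n_ssr):
                if rng.random() < ssr_error_rate:
                    cur = (ssr_calls[i, j, 0], ssr_calls[i, j, 1])
                    options = [
                        (int(m), int(p))
                        for m in mother.ssr_alleles[:, j]
                        for p in father.ssr_alleles[:, j]
                        if (m, p) != cur
                    ]
                    if options:
                        ssr_calls[i, j] = options[int(rng.integers(len(options)))]

    snp_gm = GenotypeMatrix(samples=names, positions=mother.snp_positions.copy(), genotypes=geno)

    ssr_table = None
    if n_ssr:
        markers = [
            SSRMarker(
                id=mid,
                position_bp=int(pos),
                a=int(mother.ssr_alleles[0, j]),
                b=int(mother.ssr_alleles[1, j]),
                c=int(father.ssr_alleles[0, j]),
                d=int(father.ssr_alleles[1, j]),
            )
            for j, (mid, pos) in enumerate(zip(mother.ssr_ids, mother.ssr_positions))
        ]
        ssr_table = SSRTable(markers=markers, progeny=names, calls=ssr_calls)

    return SimulatedFamily(
        mother=mother,
        father=father,
        chrom=chrom,
        progeny=names,
        progeny_sex=sexes,
        snp_genotypes=snp_gm,
        ssr_table=ssr_table,
        truth_gametes=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# founder construction


def make_testcross_parents(
    chrom: ChromosomeModel,
    n_snps: int = 210,
    frac_maternal: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    positions: np.ndarray | None = None,
) -> tuple[ParentHaplotypes, ParentHaplotypes]:
    """Founders whose SNPs are pseudo-testcross markers (het x hom).

    A fraction ``frac_maternal`` of markers is heterozygous in the
    mother and homozygous in the father; the rest the reverse. Marker
    positions are evenly spaced over the chromosome unless given.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if positions is None:
        positions = np.linspace(0, chrom.length_bp - 1, n_snps + 2)[1:-1].astype(np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        n_snps = len(positions)
    mat_hap = np.zeros((2, n_snps), dtype=np.int8)
    pat_hap = np.zeros((2, n_snps), dtype=np.int8)
    is_maternal = rng.random(n_snps) < frac_maternal
    # het parent: haplotypes carry 0 and 1 in random phase; hom parent: 0/0 or 1/1
    phase = rng.integers(2, size=n_snps)
    hom = rng.integers(2, size=n_snps).astype(np.int8)
    for j in range(n_snps):
        if is_maternal[j]:
            mat_hap[phase[j], j] = 1
            pat_hap[:, j] = hom[j]
        else:
            pat_hap[phase[j], j] = 1
            mat_hap[:, j] = hom[j]
    mother = ParentHaplotypes("maternal", MATERNAL_LABELS, positions, mat_hap)
    father = ParentHaplotypes("paternal", PATERNAL_LABELS, positions, pat_hap)
    return mother, father


def make_outbred_parents(
    chrom: ChromosomeModel,
    n_snps: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ParentHaplotypes, ParentHaplotypes]:
    """Founders with independent Bernoulli(0.5) alleles on all four haplotypes.

    Suitable for kinship and window-statistics simulations where dense,
    unconstrained polymorphism is wanted.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    positions = np.linspace(0, chrom.length_bp - 1, n_snps + 2)[1:-1].astype(np.int64)
    mother = ParentHaplotypes(
        "maternal", MATERNAL_LABELS, positions, rng.integers(2, size=(2, n_snps)).astype(np.int8)
    )
    father = ParentHaplotypes(
        "paternal", PATERNAL_LABELS, positions, rng.integers(2, size=(2, n_snps)).astype(np.int8)
    )
    return mother, father


def default_ssr_mix(n_sdr: int) -> dict[str, int]:
    """Mixed-informativeness split: ~1/4 female-, 1/4 male-informative,
    ~1/8 uninformative, the rest fully informative (for 17 SDR markers:
    7 fully, 4 female, 4 male, 2 uninformative)."""
    female = male = n_sdr // 4
    uninf = n_sdr // 8 if n_sdr >= 8 else 0
    return {
        "fully": n_sdr - female - male - uninf,
        "female": female,
        "male": male,
        "uninformative": uninf,
    }


def attach_ssr_panel(
    mother: ParentHaplotypes,
    father: ParentHaplotypes,
    chrom: ChromosomeModel,
    n_sdr: int = 17,
    n_par: int = 4,
    mix: dict[str, int] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[SSRMarker]:
    """Attach an SSR marker panel of mixed informativeness to both parents.

    ``n_sdr`` markers fall inside the SDR, ``n_par`` outside. ``mix``
    gives how many SDR markers are fully / female- / male-informative /
    uninformative (PAR markers are always fully informative; they serve
    group-assignment QC, not conversion counting).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mix = dict(mix) if mix is not None else default_ssr_mix(n_sdr)
    if sum(mix.values()) != n_sdr:
        raise ValueError("mix must sum to n_sdr")
    sdr_pos = np.linspace(0, chrom.sdr_end_bp - 1, n_sdr + 2)[1:-1].astype(np.int64)
    par_pos = np.linspace(chrom.sdr_end_bp, chrom.length_bp - 1, n_par + 2)[1:-1].astype(np.int64)
    kinds = (
        ["fully"] * mix["fully"]
        + ["female"] * mix["female"]
        + ["male"] * mix["male"]
        + ["uninformative"] * mix["uninformative"]
    )
    rng.shuffle(kinds)
    kinds += ["fully"] * n_par
    positions = np.concatenate([sdr_pos, par_pos])
    order = np.argsort(positions)
    positions = positions[order]
    kinds = [kinds[i] for i in order]

    ids: list[str] = []
    mat = np.empty((2, len(positions)), dtype=np.int32)
    pat = np.empty((2, len(positions)), dtype=np.int32)
    markers: list[SSRMarker] = []
    for j, (pos, kind) in enumerate(zip(positions, kinds)):
        base = int(rng.integers(150, 300))
        # four candidate lengths, 2-bp ladder steps as in dinucleotide SSRs
        ladder = [base, base + 2, base + 4, base + 6]
        rng.shuffle(ladder)
        a, b, c, d = ladder
        if kind == "female":
            c = d  # paternal homozygous
        elif kind == "male":
            a = b
        elif kind == "uninformative":
            c, d = a, b  # both parents share the same heterozygote
        mid = f"Ke{j+1:03d}"
        ids.append(mid)
        mat[:, j] = (a, b)
        pat[:, j] = (c, d)
        markers.append(SSRMarker(id=mid, position_bp=int(pos), a=a, b=b, c=c, d=d))

    for par, alleles in ((mother, mat), (father, pat)):
        par.ssr_positions = positions.copy()
        par.ssr_alleles = alleles
        par.ssr_ids = list(ids)
    return markers


def plant_ssr_conversions(
    family: SimulatedFamily,
    counts: dict[str, int],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Overwrite SSR calls to plant isolated single-marker conversion events.

    ``counts`` maps direction labels ("X1-X2", "X2-X1", "X3-Y1",
    "Y1-X3"; donor-recipient) to how many events to plant. Events are
    placed at interior fully-informative SDR markers, at most one per
    progeny side, in progeny whose consensus on that side equals the
    recipient, so each planted event is isolated and detectable.
    Returns the (progeny, marker, direction) plan.
    """
    if family.ssr_table is None:
        raise ValueError("family has no SSR table")
    if rng is None:
        rng = np.random.default_rng(seed)
    table = family.ssr_table
    chrom = family.chrom
    # interior fully-informative SDR markers (need informative flanks)
    sdr_idx = [
        j
        for j, m in enumerate(table.markers)
        if m.position_bp < chrom.sdr_end_bp and len({m.a, m.b, m.c, m.d}) == 4
    ]
    if len(sdr_idx) < 3:
        raise ValueError("need >= 3 fully informative SDR markers")
    interior = sdr_idx[1:-1]

    side_of = {"X1-X2": "maternal", "X2-X1": "maternal", "X3-Y1": "paternal", "Y1-X3": "paternal"}
    label_idx = {"X1": 0, "X2": 1, "X3": 0, "Y1": 1}
    used: set[tuple[int, str]] = set()
    plan: list[tuple[str, str, str]] = []
    sdr_probe = chrom.sex_locus_bp
    for direction, k in counts.items():
        if direction not in side_of:
            raise ValueError(f"unknown direction {direction!r}")
        side = side_of[direction]
        donor, recipient = direction.split("-")
        candidates = [
            i
            for i in range(len(family.progeny))
            if family.truth_origin(i, side, sdr_probe) == recipient and (i, side) not in used
        ]
        if len(candidates) < k:
            raise ValueError(f"not enough progeny with {side} consensus {recipient}")
        chosen = rng.choice(len(candidates), size=k, replace=False)
        for ci in chosen:
            i = candidates[int(ci)]
            j = int(interior[int(rng.integers(len(interior)))])
            m = table.markers[j]
            parent = family.mother if side == "maternal" else family.father
            col = 0 if side == "maternal" else 1
            donor_len = parent.ssr_alleles[label_idx[donor], list(parent.ssr_ids).index(m.id)]
            table.calls[i, j, col] = donor_len
            used.add((i, side))
            plan.append((family.progeny[i], m.id, direction))
    return plan


# ---------------------------------------------------------------------------
# unrelated-population simulator for windowed statistics


def simulate_population(
    chrom: ChromosomeModel,
    n_males: int = 8,
    n_females: int = 6,
    n_snps: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Unrelated males and females with a shared non-recombining Y haplotype.

    X-background haplotypes draw alleles Bernoulli(p_j) with per-site
    frequencies p_j ~ U(0.05, 0.95). Every male carries, inside the SDR,
    one copy of a single population Y haplotype (its own Bernoulli(0.5)
    draw, fixed across males) — the imprint of suppressed recombination:
    male-female differentiation and male SDR identity are elevated.
    Returns the genotype matrix and a sample -> sex manifest.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    positions = np.linspace(0, chrom.length_bp - 1, n_snps + 2)[1:-1].astype(np.int64)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    in_sdr = positions < chrom.sdr_end_bp
    y_hap = (rng.random(n_snps) < 0.5).astype(np.int8)

    samples, rows, sexes = [], [], {}
    for k in range(n_females):
        name = f"F{k+1:02d}"
        h1 = (rng.random(n_snps) < p).astype(np.int8)
        h2 = (rng.random(n_snps) < p).astype(np.int8)
        samples.append(name)
        rows.append(h1 + h2)
        sexes[name] = "female"
    for k in range(n_males):
        name = f"M{k+1:02d}"
        hx = (rng.random(n_snps) < p).astype(np.int8)
        hy = (rng.random(n_snps) < p).astype(np.int8)
        hy[in_sdr] = y_hap[in_sdr]
        samples.append(name)
        rows.append(hx + hy)
        sexes[name] = "male"
    gm = GenotypeMatrix(samples=samples, positions=positions, genotypes=np.array(rows, dtype=np.int8))
    return gm, sexes


# ---------------------------------------------------------------------------
# exact sex-ratio calculators


def _gametes(genotype: str) -> dict[tuple[str, ...], Fraction]:
    """Balanced gametes of a genotype under random chromosome segregation.

    Diploids transmit one chromosome each with probability 1/2;
    tetraploids (tetrasomic) transmit each unordered pair of two of the
    four chromosomes with equal probability.
    """
    chroms = list(genotype)
    if len(chroms) == 2:
        k = 1
    elif len(chroms) == 4:
        k = 2
    else:
        raise ValueError("genotype must have 2 or 4 chromosomes")
    combos = list(itertools.combinations(range(len(chroms)), k))
    out: dict[tuple[str, ...], Fraction] = {}
    for combo in combos:
        g = tuple(sorted(chroms[i] for i in combo))
        out[g] = out.get(g, Fraction(0)) + Fraction(1, len(combos))
    return out


def expected_sex_ratio(cross: str) -> float:
    """Exact male:female ratio for a named cross under the active-Y rule.

    Supported crosses: ``"XXxXY"`` (standard diploid), ``"XY_selfed"``
    (a fruiting inconstant male selfed), ``"XXXXxXXYY"`` (tetraploid
    female x colchicine-doubled male). Any offspring carrying at least
    one Y is male. Ratios are obtained by exhaustive enumeration of
    gamete and offspring genotypes with exact rational arithmetic.
    """
    crosses = {
        "XXxXY": ("XX", "XY"),
        "XY_selfed": ("XY", "XY"),
        "XXXXxXXYY": ("XXXX", "XXYY"),
    }
    key = cross.replace("×", "x")
    if key not in crosses:
        raise ValueError(f"unsupported cross {cross!r}; choose from {sorted(crosses)}")
    mat, pat = crosses[key]
    male = Fraction(0)
    female = Fraction(0)
    for g1, p1 in _gametes(mat).items():
        for g2, p2 in _gametes(pat).items():
            offspring = g1 + g2
            if "Y" in offspring:
                male += p1 * p2
            else:
                female += p1 * p2
    if female == 0:
        raise ZeroDivisionError("cross produces no females")
    return float(male / female)
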