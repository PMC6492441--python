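"""Per-parent linkage maps from pseudo-testcross F1 genotypes.

Markers heterozygous in exactly one parent ("ab x aa") segregate 1:1
and reveal which of the informative parent's two haplotypes each
progeny inherited. Ordering markers by physical position, estimating
adjacent-pair recombination fractions, and accumulating map distance
yields a genetic-vs-physical curve whose flat terminal stretch is the
suppressed-recombination sex-determining region (SDR). A two-segment
least-squares fit (first segment constrained flat) estimates the SDR
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class TestcrossMarker:
    """One pseudo-testcross SNP with per-progeny inherited-haplotype calls.

    ``phased_calls`` holds 0 (haplotype A), 1 (haplotype B) or -1
    (missing/unresolvable); the A/B labelling is arbitrary until
    ``orient_phase`` aligns it along the chromosome.
    """

    id: str
    position_bp: int
    informative_parent: str  # "maternal" | "paternal"
    phased_calls: np.ndarray
    distorted: bool = False
    segregation_p: float = 1.0

    def __post_init__(self) -> None:
        self.phased_calls = np.asarray(self.phased_calls, dtype=np.int8)


@dataclass
class GeneticMap:
    """Ordered markers with adjacent recombination fractions and cM."""

    parent: str
    marker_ids: list[str]
    positions: np.ndarray  # (n,)
    r: np.ndarray  # (n-1,) adjacent recombination fractions (nan if no data)
    interval_cm: np.ndarray  # (n-1,)
    cum_cm: np.ndarray  # (n,)
    mapping_function: str
    n_complete: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    capped: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def total_cm(self) -> float:
        return float(self.cum_cm[-1])

    @property
    def n_markers(self) -> int:
        return len(self.positions)


@dataclass
class BoundaryResult:
    boundary_bp: int
    sse: float
    sdr_rate: float  # fitted cM/Mb in segment 1 (unconstrained, for the flag)
    par_rate: float  # fitted cM/Mb in segment 2
    flags: list[str] = field(default_factory=list)


@dataclass
class RateProfile:
    """Windowed cM/Mb profile with PAR summary and SDR boundary."""

    window_start: np.ndarray
    window_end: np.ndarray
    cm_per_mb: np.ndarray  # nan where no flanking markers
    par_mean_rate: float
    boundary: BoundaryResult


# ---------------------------------------------------------------------------
# mapping functions


def haldane_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Haldane map distance in cM: -50 ln(1-2r)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def kosambi_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map distance in cM: 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


MAPPING_FUNCTIONS = {"haldane": haldane_cm, "kosambi": kosambi_cm}


# ---------------------------------------------------------------------------
# operations


def deconvolute_markers(
    parent_genotypes: GenotypeMatrix,
    progeny_genotypes: GenotypeMatrix,
    mother: str = "mother",
    father: str = "father",
    alpha: float = 1e-3,
) -> list[TestcrossMarker]:
    """Select het x hom sites and translate progeny calls to haplotypes.

    Keeps only sites heterozygous in one parent and homozygous in the
    other; each becomes a :class:`TestcrossMarker` labelled with its
    informative parent. A progeny genotype determines the transmitted
    haplotype of the het parent unless it is missing or incompatible
    with the parental pair (then -1). Markers failing an exact 1:1
    segregation test at ``alpha`` are flagged distorted but retained.
    """
    if not np.array_equal(parent_genotypes.positions, progeny_genotypes.positions):
        raise ValueError("parent and progeny matrices must share positions")
    gm = parent_genotypes.row(mother)
    gf = parent_genotypes.row(father)
    out: list[TestcrossMarker] = []
    skipped = {"parent_missing": 0, "not_testcross": 0}
    for j, pos in enumerate(parent_genotypes.positions):
        m, f = int(gm[j]), int(gf[j])
        if m == MISSING or f == MISSING:
            skipped["parent_missing"] += 1
            continue
        if m == 1 and f in (0, 2):
            informative, hom = "maternal", f
        elif f == 1 and m in (0, 2):
            informative, hom = "paternal", m
        else:
            skipped["not_testcross"] += 1
            continue
        prog = progeny_genotypes.genotypes[:, j].astype(np.int16)
        calls = prog - hom // 2
        calls[(prog == MISSING) | (calls < 0) | (calls > 1)] = MISSING
        calls = calls.astype(np.int8)
        n0 = int(np.sum(calls == 0))
        n1 = int(np.sum(calls == 1))
        if n0 + n1 > 0:
            p = stats.binomtest(n0, n0 + n1, 0.5).pvalue
        else:
            p = 1.0
        out.append(
            TestcrossMarker(
                id=f"{parent_genotypes.chrom}:{int(pos)+1}",
                position_bp=int(pos),
                informative_parent=informative,
                phased_calls=calls,
                distorted=p < alpha,
                segregation_p=float(p),
            )
        )
    if skipped["parent_missing"] or skipped["not_testcross"]:
        logger.info("deconvolute_markers skipped sites: %s", skipped)
    out.sort(key=lambda mk: mk.position_bp)
    return out


def split_by_parent(markers: list[TestcrossMarker]) -> dict[str, list[TestcrossMarker]]:
    return {
        side: [m for m in markers if m.informative_parent == side]
        for side in ("maternal", "paternal")
    }


def _pair_r(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[float, int]:
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    n = int(ok.sum())
    if n == 0:
        return np.nan, 0
    rec = int((calls_a[ok] != calls_b[ok]).sum())
    return rec / n, n


def orient_phase(markers: list[TestcrossMarker]) -> list[TestcrossMarker]:
    """Align A/B labels along the chromosome, greedily from the first marker.

    Each marker is flipped if its recombinant fraction against the
    previous (already oriented) marker exceeds 0.5, so that adjacent r
    is always <= 0.5. Deterministic given marker order; markers must be
    sorted by position and belong to one informative parent.
    """
    if len({m.informative_parent for m in markers}) > 1:
        raise ValueError("orient_phase expects markers of a single parent")
    if any(
        b.position_bp < a.position_bp for a, b in zip(markers, markers[1:])
    ):
        raise ValueError("markers must be sorted by position")
    out = [markers[0]] if markers else []
    for mk in markers[1:]:
        prev = out[-1]
        r, n = _pair_r(prev.phased_calls, mk.phased_calls)
        calls = mk.phased_calls
        if n > 0 and r > 0.5:
            calls = np.where(calls == MISSING, MISSING, 1 - calls).astype(np.int8)
        out.append(
            TestcrossMarker(
                id=mk.id,
                position_bp=mk.position_bp,
                informative_parent=mk.informative_parent,
                phased_calls=calls,
                distorted=mk.distorted,
                segregation_p=mk.segregation_p,
            )
        )
    return out


def build_map(
    markers: list[TestcrossMarker],
    mapping_function: str = "haldane",
    r_max: float = 0.45,
) -> GeneticMap:
    """Adjacent-pair genetic map over physically ordered, oriented markers.

    r for each adjacent pair is the recombinant fraction over
    pairwise-complete progeny; values >= ``r_max`` are flagged and their
    interval's cM contribution capped at the ``r_max`` distance. With
    fewer than two markers a zero-length single-point map is returned.
    """
    if mapping_function not in MAPPING_FUNCTIONS:
        raise ValueError(f"unknown mapping function {mapping_function!r}")
    fn = MAPPING_FUNCTIONS[mapping_function]
    parent = markers[0].informative_parent if markers else "unknown"
    positions = np.array([m.position_bp for m in markers], dtype=np.int64)
    n = len(markers)
    if n < 2:
        return GeneticMap(
            parent=parent,
            marker_ids=[m.id for m in markers],
            positions=positions,
            r=np.empty(0),
            interval_cm=np.empty(0),
            cum_cm=np.zeros(max(n, 0)),
            mapping_function=mapping_function,
            n_complete=np.empty(0, dtype=int),
            capped=np.empty(0, dtype=bool),
        )
    r = np.empty(n - 1)
    n_complete = np.empty(n - 1, dtype=int)
    for k in range(n - 1):
        r[k], n_complete[k] = _pair_r(markers[k].phased_calls, markers[k + 1].phased_calls)
    capped = ~np.isnan(r) & (r >= r_max)
    r_eff = np.where(np.isnan(r), 0.0, np.minimum(r, r_max))
    interval_cm = np.asarray(fn(r_eff), dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(interval_cm)])
    return GeneticMap(
        parent=parent,
        marker_ids=[m.id for m in markers],
        positions=positions,
        r=r,
        interval_cm=interval_cm,
        cum_cm=cum,
        mapping_function=mapping_function,
        n_complete=n_complete,
        capped=capped,
    )


def detect_boundary(gmap: GeneticMap, rate_ratio_threshold: float = 5.0) -> BoundaryResult:
    """Estimate the SDR end as the breakpoint of a two-segment fit.

    Exhaustive search over marker positions for the continuous
    two-segment least-squares fit of cumulative cM vs physical position:
    flat (slope fixed at 0) up to the breakpoint, a straight line
    beyond, joined at the breakpoint. The breakpoint minimising total
    SSE is returned; ties go to the smaller position. Degenerate maps
    are flagged: a zero-length map returns the last marker flagged
    ``no_recombination``; a fit whose PAR/SDR rate ratio is below
    ``rate_ratio_threshold`` is flagged ``no_suppression``.
    """
    x = gmap.positions.astype(float)
    y = gmap.cum_cm
    n = len(x)
    if n < 2:
        return BoundaryResult(int(x[-1]) if n else 0, 0.0, 0.0, 0.0, ["too_few_markers"])
    if gmap.total_cm <= 0:
        return BoundaryResult(int(x[-1]), 0.0, 0.0, 0.0, ["no_recombination"])

    candidates = x[1:-1] if n > 2 else x[1:]
    best = None
    for b in candidates:
        hinge = np.maximum(x - b, 0.0)
        design = np.column_stack([np.ones_like(x), hinge])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ coef) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(b), float(coef[1]))
    sse, b, slope2 = best
    boundary = int(b)

    # unconstrained slope over the flat-segment markers, for the flag
    seg1 = x <= b
    slope1 = float(np.polyfit(x[seg1], y[seg1], 1)[0]) if seg1.sum() >= 2 else 0.0
    sdr_rate = max(slope1, 0.0) * 1e6
    par_rate = max(slope2, 0.0) * 1e6
    flags = []
    if sdr_rate > 0 and par_rate / sdr_rate < rate_ratio_threshold:
        flags.append("no_suppression")
    return BoundaryResult(boundary, sse, sdr_rate, par_rate, flags)


def rate_profile(
    gmap: GeneticMap,
    window_bp: int = 1_000_000,
    chrom_length_bp: int | None = None,
    boundary: BoundaryResult | None = None,
) -> RateProfile:
    """Windowed cM/Mb along the chromosome plus the PAR mean rate.

    Cumulative cM is linearly interpolated at window edges; a window's
    rate is delta-cM over the Mb it overlaps with the marker span.
    Windows with no overlap are reported missing (NaN), not zero. The
    PAR mean rate is total cM beyond the detected boundary divided by
    the physical span from the boundary to the last marker.
    """
    if gmap.n_markers < 2:
        raise ValueError("rate_profile needs >= 2 markers")
    if boundary is None:
        boundary = detect_boundary(gmap)
    length = chrom_length_bp or int(gmap.positions[-1]) + 1
    edges = np.arange(0, length + window_bp, window_bp, dtype=np.int64)
    x = gmap.positions.astype(float)
    y = gmap.cum_cm
    starts, ends, rates = [], [], []
    for s, e in zip(edges, edges[1:]):
        lo = max(float(s), x[0])
        hi = min(float(e), x[-1])
        if hi <= lo:
            rate = np.nan
        else:
            dcm = np.interp(hi, x, y) - np.interp(lo, x, y)
            rate = dcm / ((hi - lo) / 1e6)
        starts.append(int(s))
        ends.append(int(e))
        rates.append(rate)

    b = float(np.clip(boundary.boundary_bp, x[0], x[-1]))
    span_mb = (x[-1] - b) / 1e6
    if span_mb > 0:
        par_mean = float((y[-1] - np.interp(b, x, y)) / span_mb)
    else:
        par_mean = np.nan
    return RateProfile(
        window_start=np.array(starts, dtype=np.int64),
        window_end=np.array(ends, dtype=np.int64),
        cm_per_mb=np.array(rates, dtype=float),
        par_mean_rate=par_mean,
        boundary=boundary,
    )
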