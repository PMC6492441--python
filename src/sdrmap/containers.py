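"""Core in-memory containers shared across the analysis stages.

Genotypes are stored as diploid dosages (count of the alternate allele:
0, 1, 2; -1 for missing) in a samples x sites matrix. Coordinates are
0-based, half-open everywhere inside the library; VCF I/O converts to
1-based on the way out and back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes with physical positions.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per row of ``genotypes``.
    positions : ndarray of int64
        0-based physical positions, one per column, strictly increasing.
    genotypes : ndarray of int8, shape (n_samples, n_sites)
        Alternate-allele dosage per call; ``MISSING`` (-1) for no-calls.
    chrom : str
        Chromosome name used on VCF output.
    """

    samples: list[str]
    positions: np.ndarray
    genotypes: np.ndarray
    chrom: str = "chr25"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.positions)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = (self.genotypes < -1) | (self.genotypes > 2)
        if np.any(bad):
            raise ValueError("genotype dosages must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in matrix") from None

    def row(self, name: str) -> np.ndarray:
        return self.genotypes[self.sample_index(name)]

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(
            samples=list(names),
            positions=self.positions.copy(),
            genotypes=self.genotypes[idx].copy(),
            chrom=self.chrom,
        )


@dataclass
class SSRMarker:
    """A microsatellite marker with its four parental allele lengths.

    Lengths are amplicon sizes in bp. The haplotype assignment is fixed
    family-wide: ``a`` is carried by X1, ``b`` by X2 (maternal), ``c`` by
    X3 and ``d`` by Y1 (paternal). ``None`` marks a missing parental call.
    """

    id: str
    position_bp: int
    a: int | None
    b: int | None
    c: int | None
    d: int | None

    @property
    def maternal(self) -> tuple[int | None, int | None]:
        return (self.a, self.b)

    @property
    def paternal(self) -> tuple[int | None, int | None]:
        return (self.c, self.d)


@dataclass
class SSRTable:
    """Parent and progeny allele-length calls at named SSR markers.

    ``calls`` holds the two allele lengths per progeny per marker
    (unordered; -1 encodes a missing allele).
    """

    markers: list[SSRMarker]
    progeny: list[str]
    calls: np.ndarray  # (n_progeny, n_markers, 2) int32

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.progeny), len(self.markers), 2):
            raise ValueError("calls shape mismatch")

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.id == marker_id:
                return i
        raise KeyError(f"marker {marker_id!r} not in table")


def window_edges(max_pos: int, window_bp: int) -> np.ndarray:
    """Edges of fixed non-overlapping windows [k*W, (k+1)*W) covering max_pos."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n = int(max_pos) // window_bp + 1
    return np.arange(n + 1, dtype=np.int64) * window_bp


def window_slices(positions: np.ndarray, window_bp: int):
    """Yield (start_bp, end_bp, site_index_slice) per window.

    Sites are assigned by 0-based half-open membership; positions must be
    sorted. Windows run from 0 to just past the last position.
    """
    edges = window_edges(int(positions[-1]) if len(positions) else 0, window_bp)
    idx = np.searchsorted(positions, edges)
    for k in range(len(edges) - 1):
        yield int(edges[k]), int(edges[k + 1]), slice(idx[k], idx[k + 1])
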