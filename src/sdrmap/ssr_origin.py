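"""Chromosome-of-origin inference for SSR alleles and conversion scanning.

In an X1X2 x X3Y1 family, each progeny inherits one maternal (X1 or
X2) and one paternal (X3 or Y1) chromosome. Where the four parental
SSR allele lengths permit, each progeny allele can be traced to the
founder chromosome it came from; across a non-recombining SDR each
progeny then shows one constant origin per parental side, and an
isolated single-marker departure from that consensus — an allele from
the *other* homologue — is the signature of a gene-conversion tract.
Runs of two or more consecutive departures are instead flagged as
possible crossovers or long tracts and excluded from conversion counts.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, SSRMarker, SSRTable

logger = logging.getLogger(__name__)

UNDETERMINED = "."
MATERNAL_ORIGINS = ("X1", "X2")
PATERNAL_ORIGINS = ("X3", "Y1")
DIRECTIONS = ("X1-X2", "X2-X1", "X3-Y1", "Y1-X3")

FULLY = "fully"
FEMALE = "female_informative"
MALE = "male_informative"
UNINFORMATIVE = "uninformative"


@dataclass
class OriginMatrix:
    """Per progeny x marker x side origin labels, plus progeny groups."""

    maternal: pd.DataFrame  # progeny x marker, values in {X1, X2, "."}
    paternal: pd.DataFrame  # values in {X3, Y1, "."}
    group: pd.Series  # progeny -> e.g. "X1Y1" or "" if unassigned
    incompatible: pd.DataFrame  # progeny x marker bool: call fits no parental pair


@dataclass
class ConversionEvent:
    progeny: str
    marker: str
    side: str
    donor: str  # chromosome of the observed, unexpected allele
    recipient: str  # chromosome expected from the side consensus
    position_bp: int

    @property
    def direction(self) -> str:
        return f"{self.donor}-{self.recipient}"


@dataclass
class ConversionScan:
    events: list[ConversionEvent]
    denominators: dict[str, int]  # direction -> determined calls in that context
    long_runs: list[tuple[str, str, list[str]]]  # (progeny, side, marker ids)
    skipped_sides: list[tuple[str, str, str]]  # (progeny, side, reason)


def _decompositions(marker: SSRMarker, call: tuple[int, int], tol: int = 0):
    """All (maternal_hap, paternal_hap) index pairs consistent with a call."""
    lengths = sorted(call)
    out = []
    for mi, ma in enumerate(marker.maternal):
        for pi, pa in enumerate(marker.paternal):
            if ma is None or pa is None:
                continue
            pair = sorted((ma, pa))
            if abs(pair[0] - lengths[0]) <= tol and abs(pair[1] - lengths[1]) <= tol:
                out.append((mi, pi))
    return out


def classify_informativeness(marker: SSRMarker) -> str:
    """Classify a marker by which parental side its calls can resolve.

    A side is resolvable when, for *every* possible progeny allele pair
    (one maternal x one paternal allele), all consistent decompositions
    agree on that side's contribution. Both sides resolvable -> fully;
    one -> female-/male-informative; neither -> uninformative. A
    missing parental length makes the marker uninformative.
    """
    if any(v is None for v in (marker.a, marker.b, marker.c, marker.d)):
        logger.info("marker %s has a missing parental call; uninformative", marker.id)
        return UNINFORMATIVE
    mat_ok = marker.a != marker.b
    pat_ok = marker.c != marker.d
    for mi, pi in itertools.product(range(2), range(2)):
        call = (marker.maternal[mi], marker.paternal[pi])
        decomps = _decompositions(marker, call)
        if len({d[0] for d in decomps}) > 1:
            mat_ok = False
        if len({d[1] for d in decomps}) > 1:
            pat_ok = False
    if mat_ok and pat_ok:
        return FULLY
    if mat_ok:
        return FEMALE
    if pat_ok:
        return MALE
    return UNINFORMATIVE


def assign_origins(table: SSRTable, tol: int = 0, sdr_end_bp: int | None = None) -> OriginMatrix:
    """Trace every progeny SSR allele to its founder chromosome.

    Each call's two lengths are decomposed into one maternal plus one
    paternal parental allele (exact bp match, optionally +/- ``tol``).
    A side's origin is emitted only when every consistent decomposition
    agrees on it, else ``.``; calls matching no parental combination
    are flagged as genotyping errors. Progeny are grouped by the modal
    (maternal, paternal) origin over SDR markers (all markers if
    ``sdr_end_bp`` is None).
    """
    ids = table.marker_ids
    n_prog, n_mark = len(table.progeny), len(ids)
    mat = np.full((n_prog, n_mark), UNDETERMINED, dtype=object)
    pat = np.full((n_prog, n_mark), UNDETERMINED, dtype=object)
    bad = np.zeros((n_prog, n_mark), dtype=bool)

    for j, marker in enumerate(table.markers):
        if any(v is None for v in (marker.a, marker.b, marker.c, marker.d)):
            continue
        for i in range(n_prog):
            call = table.calls[i, j]
            if call[0] == MISSING or call[1] == MISSING:
                continue
            decomps = _decompositions(marker, (int(call[0]), int(call[1])), tol)
            if not decomps:
                bad[i, j] = True
                continue
            mi = {d[0] for d in decomps}
            pi = {d[1] for d in decomps}
            if len(mi) == 1:
                mat[i, j] = MATERNAL_ORIGINS[mi.pop()]
            if len(pi) == 1:
                pat[i, j] = PATERNAL_ORIGINS[pi.pop()]

    in_sdr = np.array(
        [m.position_bp < sdr_end_bp if sdr_end_bp is not None else True for m in table.markers]
    )
    groups = []
    for i in range(n_prog):
        gm = _mode([o for o in mat[i, in_sdr] if o != UNDETERMINED])
        gp = _mode([o for o in pat[i, in_sdr] if o != UNDETERMINED])
        groups.append(gm + gp if gm and gp else "")

    return OriginMatrix(
        maternal=pd.DataFrame(mat, index=table.progeny, columns=ids),
        paternal=pd.DataFrame(pat, index=table.progeny, columns=ids),
        group=pd.Series(groups, index=table.progeny, name="group"),
        incompatible=pd.DataFrame(bad, index=table.progeny, columns=ids),
    )


def _mode(labels: list[str]) -> str | None:
    """Strict mode; None on empty input or a tie."""
    if not labels:
        return None
    counts = Counter(labels).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def detect_conversions(
    origins: OriginMatrix,
    table: SSRTable,
    sdr_end_bp: int,
    flank_k: int = 1,
) -> ConversionScan:
    """Find isolated origin switches inside the SDR and count contexts.

    For each progeny and parental side, the expected origin is the
    side's consensus (modal determined origin over SDR markers). An
    event is a single determined marker whose origin departs from the
    consensus, with at least ``flank_k`` consensus-agreeing determined
    markers on each side (terminal markers need >=2 consecutive
    consensus markers on their single available side). Runs of >=2
    consecutive departures are recorded as possible crossovers / long
    tracts, never as conversions. Denominators count determined calls
    per direction context: direction "D-R" is denominated by all
    determined calls of progeny whose consensus on that side is R.
    """
    sdr = [(j, m) for j, m in enumerate(table.markers) if m.position_bp < sdr_end_bp]
    sdr.sort(key=lambda t: t[1].position_bp)
    events: list[ConversionEvent] = []
    denominators = {d: 0 for d in DIRECTIONS}
    long_runs: list[tuple[str, str, list[str]]] = []
    skipped: list[tuple[str, str, str]] = []

    for side, frame, origin_pair in (
        ("maternal", origins.maternal, MATERNAL_ORIGINS),
        ("paternal", origins.paternal, PATERNAL_ORIGINS),
    ):
        for progeny in frame.index:
            seq = [
                (m, frame.loc[progeny, m.id])
                for _, m in sdr
                if frame.loc[progeny, m.id] != UNDETERMINED
            ]
            if len(seq) < 3:
                skipped.append((progeny, side, "fewer than 3 determined SDR calls"))
                continue
            labels = [o for _, o in seq]
            consensus = _mode(labels)
            if consensus is None:
                skipped.append((progeny, side, "no consensus (tie)"))
                continue
            other = origin_pair[1] if consensus == origin_pair[0] else origin_pair[0]
            denominators[f"{other}-{consensus}"] += len(labels)

            mismatch = [o != consensus for o in labels]
            i = 0
            while i < len(labels):
                if not mismatch[i]:
                    i += 1
                    continue
                run_start = i
                while i < len(labels) and mismatch[i]:
                    i += 1
                run = list(range(run_start, i))
                if len(run) >= 2:
                    long_runs.append((progeny, side, [seq[k][0].id for k in run]))
                    continue
                k = run[0]
                left = 0  # consecutive consensus-agreeing markers abutting the run
                t = k - 1
                while t >= 0 and not mismatch[t]:
                    left += 1
                    t -= 1
                right = 0
                t = i
                while t < len(labels) and not mismatch[t]:
                    right += 1
                    t += 1
                if k == 0 or i == len(labels):
                    ok = (left >= 2) or (right >= 2)
                else:
                    ok = left >= flank_k and right >= flank_k
                if ok:
                    marker = seq[k][0]
                    events.append(
                        ConversionEvent(
                            progeny=progeny,
                            marker=marker.id,
                            side=side,
                            donor=labels[k],
                            recipient=consensus,
                            position_bp=marker.position_bp,
                        )
                    )
    return ConversionScan(
        events=events, denominators=denominators, long_runs=long_runs, skipped_sides=skipped
    )


def summarise_conversions(scan: ConversionScan) -> pd.DataFrame:
    """Per-direction conversion counts, denominators and rates."""
    counts = Counter(e.direction for e in scan.events)
    rows = []
    for d in DIRECTIONS:
        n, denom = counts.get(d, 0), scan.denominators.get(d, 0)
        rows.append(
            {
                "direction": d,
                "events": n,
                "determined_calls": denom,
                "rate": n / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)
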