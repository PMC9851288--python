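"""ChIP peak matching, cross-sample aggregation and amplitude quantification.

Peaks called independently per sample are matched by the midpoint rule: two
peaks match when the midpoint of one lies within the other's genomic range
(symmetric, either-direction by default).  Matched peaks are merged across
all samples by transitive closure (union-find), each component yielding a
unified interval spanning its members.  Per-sample amplitudes are the summed
per-base coverage over the unified interval divided by the read length --
an estimate of the read count -- producing an expression matrix for the
ChIP modality.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, GenomicInterval, MatrixIOError

__all__ = [
    "Peak",
    "PeakComponent",
    "Coverage",
    "read_bedgraph",
    "match_peaks",
    "aggregate_peaks",
    "peak_amplitude",
    "peaks_to_matrix",
    "build_peak_matrix",
]


@dataclass(frozen=True, order=True)
class Peak:
    interval: GenomicInterval
    sample_id: str
    peak_id: str = ""

    def __post_init__(self) -> None:
        if not self.peak_id:
            iv = self.interval
            object.__setattr__(self, "peak_id", f"{self.sample_id}:{iv.chrom}:{iv.start}-{iv.end}")

    @property
    def midpoint(self) -> int:
        """Floor of the mean coordinate; always within [start, end)."""
        return (self.interval.start + self.interval.end) // 2


@dataclass
class PeakComponent:
    interval: GenomicInterval           # min start .. max end over members
    member_peak_ids: list[str] = field(default_factory=list)

    @property
    def component_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


def match_peaks(a: Peak, b: Peak, mode: str = "either") -> bool:
    """Midpoint-containment peak matching (half-open interval membership).

    ``either`` (default): match if a's midpoint falls in b's range OR vice
    versa.  ``both``: require containment in both directions (strict mode).
    Peaks on different chromosomes never match.
    """
    if mode not in ("either", "both"):
        raise MatrixIOError(f"unknown match mode {mode!r}")
    if a.interval.chrom != b.interval.chrom:
        return False
    a_in_b = b.interval.start <= a.midpoint < b.interval.end
    b_in_a = a.interval.start <= b.midpoint < a.interval.end
    return (a_in_b or b_in_a) if mode == "either" else (a_in_b and b_in_a)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def aggregate_peaks(peaks: list[Peak], mode: str = "either") -> list[PeakComponent]:
    """Merge peaks across samples into components of the match relation.

    Components are the transitive closure of pairwise matches (so A-B and
    B-C matches place A and C in one component even if they do not match
    directly).  Each component's unified interval spans min(start)..max(end)
    of its members; output is ordered by (chrom, start, end).

    Candidate pairs are pruned with a coordinate sweep: midpoint containment
    implies interval overlap, so only overlapping peaks are tested.
    """
    if not peaks:
        return []
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].interval.chrom,
                                                     peaks[i].interval.start,
                                                     peaks[i].interval.end,
                                                     peaks[i].peak_id))
    uf = _UnionFind(len(peaks))
    active: list[int] = []  # indices with potential overlap, same chrom
    for i in order:
        pi = peaks[i]
        active = [j for j in active
                  if peaks[j].interval.chrom == pi.interval.chrom
                  and peaks[j].interval.end > pi.interval.start]
        for j in active:
            if match_peaks(pi, peaks[j], mode=mode):
                uf.union(i, j)
        active.append(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(peaks)):
        groups.setdefault(uf.find(i), []).append(i)
    comps = []
    for members in groups.values():
        ivs = [peaks[i].interval for i in members]
        chrom = ivs[0].chrom
        unified = GenomicInterval(chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs))
        comps.append(PeakComponent(unified, sorted(peaks[i].peak_id for i in members)))
    comps.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return comps


class Coverage:
    """Sparse per-base coverage from bedGraph segments (0 where absent)."""

    def __init__(self, segments: dict[str, list[tuple[int, int, float]]]) -> None:
        self.segments = {
            chrom: sorted(segs) for chrom, segs in segments.items()
        }
        for chrom, segs in self.segments.items():
            for (s1, e1, _), (s2, _, _) in itertools.pairwise(segs):
                if s2 < e1:
                    raise MatrixIOError(f"overlapping bedGraph segments on {chrom} at {s2}")

    def sum_over(self, interval: GenomicInterval) -> float:
        """Total per-base coverage over [start, end)."""
        segs = self.segments.get(interval.chrom, [])
        if not segs:
            return 0.0
        starts = [s for s, _, _ in segs]
        i = max(bisect_right(starts, interval.start) - 1, 0)
        total = 0.0
        for s, e, v in segs[i:]:
            if s >= interval.end:
                break
            ov = min(e, interval.end) - max(s, interval.start)
            if ov > 0:
                total += ov * v
        return total


def read_bedgraph(path) -> Coverage:
    """Read a bedGraph file into a Coverage object."""
    segments: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise MatrixIOError(f"{path}:{lineno}: bedGraph line needs 4 columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as e:
                raise MatrixIOError(f"{path}:{lineno}: malformed bedGraph fields") from e
            if not 0 <= start < end:
                raise MatrixIOError(f"{path}:{lineno}: invalid segment {start}-{end}")
            segments.setdefault(parts[0], []).append((start, end, value))
    return Coverage(segments)


def peak_amplitude(interval: GenomicInterval, coverage: Coverage, read_length: int) -> float:
    """Estimated read count: summed coverage over the interval / read length."""
    if read_length <= 0:
        raise MatrixIOError("read_length must be positive")
    return coverage.sum_over(interval) / read_length


def peaks_to_matrix(
    components: list[PeakComponent],
    amplitudes: pd.DataFrame,
) -> ExpressionMatrix:
    """Assemble the unified peak x sample amplitude matrix (ChIP modality).

    ``amplitudes`` must be indexed by component id ("chrom:start-end") with
    one column per sample.
    """
    want = [c.component_id for c in components]
    missing = [cid for cid in want if cid not in amplitudes.index]
    if missing:
        raise MatrixIOError(f"missing amplitudes for component(s): {missing}")
    return ExpressionMatrix(amplitudes.loc[want].copy(), state="raw", modality_tag="ChIP")


def build_peak_matrix(
    peak_sets: dict[str, list[Peak]],
    coverages: dict[str, Coverage],
    read_length: int,
    mode: str = "either",
) -> tuple[ExpressionMatrix, list[PeakComponent]]:
    """End-to-end: aggregate per-sample peaks, quantify every (component,
    sample) amplitude, and return the unified ChIP expression matrix."""
    all_peaks = [p for ps in peak_sets.values() for p in ps]
    comps = aggregate_peaks(all_peaks, mode=mode)
    samples = sorted(peak_sets)
    data = {
        s: [peak_amplitude(c.interval, coverages[s], read_length) for c in comps]
        for s in samples
    }
    amp = pd.DataFrame(data, index=[c.component_id for c in comps])
    return peaks_to_matrix(comps, amp), comps
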