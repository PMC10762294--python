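"""Core interval geometry: sweep join, point-depth queries, weighted medians.

All operations work on one chromosome's coverage records, sorted by start
and non-overlapping — the shape a per-base depth BED arrives in. A single
forward sweep consumes each record once, so whole-genome files stream
chromosome by chromosome without index structures.

Bases of a target absent from the coverage records are *uncovered*: they are
not emitted by :func:`overlap_join` and score depth 0 in point queries. An
unsequenced pathogenic locus therefore falls below any positive threshold,
which is exactly the failure a clinical QC must surface.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

from .errors import ClincovError, ContractViolationError
from .io import CoverageInterval


class CoveredSegment(NamedTuple):
    """A maximal constant-depth sub-interval of a target, record-backed."""

    start: int
    end: int
    depth: int


def overlap_join(
    coverage: Iterable[CoverageInterval], target: tuple[int, int]
) -> list[CoveredSegment]:
    """Clip sorted, non-overlapping coverage records to ``target``.

    Returns the maximal constant-depth segments of ``target`` that are backed
    by a coverage record, disjoint and sorted; uncovered bases are omitted
    (callers treat them as depth 0). Adjacent equal-depth records merge.

    Raises
    ------
    ContractViolationError
        If the records scanned are not sorted by start.
    """
    t_start, t_end = target
    if t_start >= t_end:
        raise ClincovError(f"empty target interval ({t_start}, {t_end})")
    out: list[CoveredSegment] = []
    prev_start = None
    for iv in coverage:
        if prev_start is not None and iv.start < prev_start:
            raise ContractViolationError(
                f"coverage not sorted: start {iv.start} after {prev_start}"
            )
        prev_start = iv.start
        if iv.end <= t_start:
            continue
        if iv.start >= t_end:
            break
        s, e = max(iv.start, t_start), min(iv.end, t_end)
        if out and out[-1].end == s and out[-1].depth == iv.depth:
            out[-1] = CoveredSegment(out[-1].start, e, iv.depth)
        else:
            out.append(CoveredSegment(s, e, iv.depth))
    return out


def point_depths(
    coverage: Iterable[CoverageInterval], positions0: Sequence[int]
) -> list[int]:
    """Depth at each 0-based position, in one forward sweep.

    ``positions0`` must be sorted ascending; positions in no record map to 0.
    """
    for a, b in zip(positions0, positions0[1:]):
        if b < a:
            raise ContractViolationError("positions must be sorted ascending")
    depths: list[int] = []
    it = iter(coverage)
    cur = next(it, None)
    prev_start = None
    for p in positions0:
        while cur is not None and cur.end <= p:
            if prev_start is not None and cur.start < prev_start:
                raise ContractViolationError("coverage not sorted by start")
            prev_start = cur.start
            cur = next(it, None)
        if cur is not None and cur.start <= p < cur.end:
            depths.append(cur.depth)
        else:
            depths.append(0)
    return depths


def weighted_median(intervals: Iterable[tuple[int, int]]) -> int:
    """Lower median of the virtual per-base depth multiset.

    Each ``(length, depth)`` entry stands for ``length`` repetitions of
    ``depth``. The lower median (element at 0-based index ``(W-1)//2`` of the
    sorted expansion, W = total length) is computed by a cumulative-weight
    scan over depth-sorted entries, never expanding the multiset. Integer
    result, matching integer read depths; invariant under entry order.
    """
    entries = sorted(
        ((d, w) for w, d in intervals if w > 0), key=lambda x: x[0]
    )
    total = sum(w for _, w in entries)
    if total < 1:
        raise ClincovError("weighted_median of an empty multiset")
    k = (total - 1) // 2  # 0-based index of the lower median
    cum = 0
    for depth, w in entries:
        cum += w
        if cum > k:
            return depth
    raise AssertionError("unreachable: cumulative weight exhausted")
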