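"""SSR region location and motif repeat counting.

Two counting strategies are provided:

* **precise** — the SSR region is delimited by ungapped placements of the
  20-bp flank anchors in the read, and the repeat number is the longest run
  of consecutive *exact* motif copies inside that region.  Any substitution
  or indel inside the array truncates the run.

* **broad** (fault-tolerant) — the SSR region is obtained by projecting the
  reference array coordinates onto the read through the alignment CIGAR
  (so flank SNVs and indels do not move the boundaries), and the repeat
  number is the maximum number of motif units that can tile a contiguous
  stretch of the region, where each unit may carry a bounded number of
  substitutions and the scan may resynchronize across small indels.

A naive whole-read scan (no flank boundaries) is included as a foil: a
flank base mutated into a motif base makes it overcount.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .align import AlignmentResult, align_semiglobal, parse_cigar
from .panel import LocusDefinition, MotifSpec
from .seqio import SequencingRead

# statuses
TYPED = "typed"
NO_LEFT_ANCHOR = "no_left_anchor"
NO_RIGHT_ANCHOR = "no_right_anchor"
UNTYPEABLE = "untypeable"


@dataclass(frozen=True)
class FlankAnchors:
    """Ungapped placements of the two 20-bp flank anchors in a read.

    ``left_end`` is the read position just after the left-flank match;
    ``right_start`` is where the right-flank match begins.  The SSR region
    of the read is ``read[left_end:right_start]``.
    """

    left_end: int
    right_start: int
    left_mismatches: int
    right_mismatches: int


@dataclass(frozen=True)
class TypingResult:
    read_id: str
    locus_id: str
    algorithm: str  # 'precise' or 'broad'
    repeat_count: int
    region_seq: str
    anchors: FlankAnchors | None
    status: str


def _best_ungapped_placement(
    seq: str, pattern: str, start: int, max_mismatch: int
) -> tuple[int, int] | None:
    """Fewest-mismatch (then leftmost) placement of pattern in seq[start:]."""
    sub = seq[start:]
    if len(sub) < len(pattern):
        return None
    arr = np.frombuffer(sub.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, len(pat))
    mismatches = (windows != pat).sum(axis=1)
    i = int(np.argmin(mismatches))
    if mismatches[i] > max_mismatch:
        return None
    return start + i, int(mismatches[i])


def locate_flanks(
    read_seq: str, locus: LocusDefinition, max_mismatch: int = 2
) -> FlankAnchors | str:
    """Place both flank anchors in a forward-oriented read.

    Returns a :class:`FlankAnchors`, or a failure status string
    (``no_left_anchor`` / ``no_right_anchor``) when no placement with at
    most ``max_mismatch`` substitutions exists.  The right anchor is
    searched only to the right of the left anchor.
    """
    left = _best_ungapped_placement(read_seq, locus.flank_left, 0, max_mismatch)
    if left is None:
        return NO_LEFT_ANCHOR
    left_end = left[0] + len(locus.flank_left)
    right = _best_ungapped_placement(read_seq, locus.flank_right, left_end, max_mismatch)
    if right is None:
        return NO_RIGHT_ANCHOR
    return FlankAnchors(left_end, right[0], left[1], right[1])


def extract_region(read_seq: str, anchors: FlankAnchors) -> str:
    """Read slice between the two flank anchors."""
    return read_seq[anchors.left_end : anchors.right_start]


def precise_count(region: str, motif: str | MotifSpec) -> int:
    """Longest run of consecutive exact motif copies within the region.

    The run may start at any offset; isolated copies separated by even a
    single substitution break the run.
    """
    unit = motif.unit if isinstance(motif, MotifSpec) else motif
    m = len(unit)
    n = len(region)
    best = 0
    i = 0
    while i <= n - m:
        if region[i : i + m] == unit:
            k = 1
            while region[i + k * m : i + (k + 1) * m] == unit:
                k += 1
            best = max(best, k)
            i += 1  # runs at interior offsets of this run cannot beat it,
            # but overlapping self-similar motifs make skipping unsafe
        else:
            i += 1
    return best


def naive_scan(full_read: str, motif: str | MotifSpec) -> int:
    """Exact repeat counting over the whole read, ignoring flank boundaries."""
    return precise_count(full_read, motif)


def broad_count(
    region: str,
    motif: str | MotifSpec,
    max_sub_per_unit: int = 1,
    max_total_sub: int = 4,
    max_indel_events: int = 2,
) -> int:
    """Fault-tolerant motif unit count.

    The region is scanned unit by unit from every possible start offset
    whose opening window is itself within tolerance.  A window of motif
    length with Hamming distance <= ``max_sub_per_unit`` counts as one unit
    (substitution case) and is always consumed.  Only where a later window
    *fails* may the scan resynchronize at a shift of up to motif length − 1
    bases in either direction: if the shifted window matches within the
    substitution tolerance, the consumed stretch counts as one unit
    carrying an indel (at most ``max_indel_events`` such events; all shifts
    are explored and the best continuation wins).  Three restrictions keep
    the count honest: resynchronization only at failing windows stops a
    perfect array from being reinterpreted as more, shorter units;
    requiring the opening window to match stops bases preceding the array
    from being counted as an extra indel-carrying unit; and the consumed
    stretch must actually be the motif with one contiguous insertion or
    deletion applied, so arbitrary bases cannot pass as an indel-carrying
    unit.  Total
    substitutions over the region are capped at ``max_total_sub``; the
    scan stops when fewer than a motif length of bases remains.
    """
    unit = motif.unit if isinstance(motif, MotifSpec) else motif
    m = len(unit)
    n = len(region)
    if n < m:
        return 0

    def ham(i: int) -> int | None:
        if i < 0 or i + m > n:
            return None
        return sum(a != b for a, b in zip(region[i : i + m], unit))

    def stretch_is_indel_unit(i: int, j: int) -> bool:
        """region[i:j] must be the unit with one contiguous indel applied."""
        stretch = region[i:j]
        a = abs(len(stretch) - m)
        if len(stretch) < m:  # unit with a contiguous a-base deletion
            return any(unit[:k] + unit[k + a :] == stretch for k in range(m - a + 1))
        # unit with a contiguous a-base insertion
        return any(stretch[:k] + stretch[k + a :] == unit for k in range(len(stretch) - a + 1))

    @lru_cache(maxsize=None)
    def best(i: int, subs: int, indels: int) -> int:
        d = ham(i)
        if d is None:
            return 0
        if d <= max_sub_per_unit and subs + d <= max_total_sub:
            return 1 + best(i + m, subs + d, indels)
        out = 0
        if indels < max_indel_events:
            for a in range(1, m):
                for s in (-a, a):
                    j = i + m + s
                    d2 = ham(j)
                    if (
                        d2 is not None
                        and d2 <= max_sub_per_unit
                        and subs + d2 <= max_total_sub
                        and stretch_is_indel_unit(i, j)
                    ):
                        out = max(out, 1 + best(j, subs, indels + 1))
        return out

    starts = [i for i in range(n - m + 1) if ham(i) <= min(max_sub_per_unit, max_total_sub)]
    result = max((best(i, 0, 0) for i in starts), default=0)
    best.cache_clear()
    return result


def project_region(
    read_seq: str, locus: LocusDefinition, alignment: AlignmentResult
) -> str | None:
    """Map the reference SSR coordinates onto the read through the CIGAR.

    Insertions inside the region extend it and insertions immediately at
    either boundary are attributed to the repeat array; deletions shrink
    it; a boundary falling inside a deletion snaps to the deletion's read
    position.  Returns ``None`` when the alignment does not cover the SSR
    region.
    """
    ops = parse_cigar(alignment.cigar)
    if alignment.ref_start > locus.ssr_start:
        return None
    ref_end = alignment.ref_start + sum(n for n, op in ops if op in "=XDM")
    if ref_end < locus.ssr_end:
        return None
    left = _ref_to_read(ops, alignment.ref_start, locus.ssr_start, skip_insertions=False)
    right = _ref_to_read(ops, alignment.ref_start, locus.ssr_end, skip_insertions=True)
    if left is None or right is None or left > right:
        return None
    return read_seq[left:right]


def _ref_to_read(
    ops: list[tuple[int, str]], ref_start: int, boundary: int, skip_insertions: bool
) -> int | None:
    """Read coordinate aligned to reference coordinate ``boundary``.

    With ``skip_insertions`` False the position *before* any insertion block
    at the boundary is returned (used for the left edge, so the insertion
    lands inside the region); with True the position after it (right edge).
    """
    q, r = 0, ref_start
    for n, op in ops:
        if op in "SI":
            if r == boundary and not skip_insertions and op == "I":
                return q
            q += n
            continue
        if r == boundary:
            return q
        if op == "D":
            if r < boundary < r + n:
                return q  # snap to the deletion's read position
            r += n
            continue
        # '=', 'X' or 'M'
        if r < boundary < r + n:
            return q + (boundary - r)
        q += n
        r += n
    return q if r == boundary else None


def type_read(
    read: SequencingRead,
    locus: LocusDefinition,
    algorithm: str,
    alignment: AlignmentResult | None = None,
    *,
    max_anchor_mismatch: int = 2,
    max_sub_per_unit: int = 1,
    max_total_sub: int = 4,
    max_indel_events: int = 2,
) -> TypingResult:
    """Type one forward-oriented, locus-assigned read.

    ``precise`` locates both flank anchors, extracts the region and counts
    exact contiguous copies; ``broad`` projects the reference SSR
    coordinates through the alignment and counts tolerantly.  A region
    yielding zero units is reported as ``untypeable`` rather than as a
    zero-repeat allele.
    """
    if algorithm == "precise":
        anchors = locate_flanks(read.seq, locus, max_anchor_mismatch)
        if isinstance(anchors, str):
            return TypingResult(read.read_id, locus.locus_id, algorithm, 0, "", None, anchors)
        region = extract_region(read.seq, anchors)
        count = precise_count(region, locus.motif)
        status = TYPED if count >= 1 else UNTYPEABLE
        return TypingResult(
            read.read_id, locus.locus_id, algorithm, count, region, anchors, status
        )
    if algorithm == "broad":
        if alignment is None:
            alignment = align_semiglobal(read.seq, locus.ref_seq, locus.locus_id)
        region = project_region(read.seq, locus, alignment)
        if region is None:
            return TypingResult(read.read_id, locus.locus_id, algorithm, 0, "", None, UNTYPEABLE)
        count = broad_count(
            region, locus.motif, max_sub_per_unit, max_total_sub, max_indel_events
        )
        status = TYPED if count >= 1 else UNTYPEABLE
        return TypingResult(
            read.read_id, locus.locus_id, algorithm, count, region, None, status
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")
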