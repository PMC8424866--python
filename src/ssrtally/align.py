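"""Assign reads to panel loci and orient them forward.

Each read is compared against every locus reference in both orientations.
Candidate ranking uses edlib's bit-parallel edit distance (cheap); the
winning candidate is then aligned with affine gap scoring (match +2,
mismatch -2, gap open -4, gap extend -1) so that a multi-base indel stays
contiguous instead of being split across equally-costing placements — the
typing stage projects SSR boundaries through this CIGAR and depends on
that.  The alignment is semi-global: the shorter sequence aligns
end-to-end, free end gaps on the longer one, so a read carrying extra
bases beyond the amplicon has them soft-clipped while a short read aligns
inside the reference.  CIGARs use the explicit '='/'X' distinction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import edlib
import numpy as np
from Bio import Align

from .panel import Panel
from .seqio import SequencingRead, flip_read, reverse_complement

MATCH_SCORE = 2
MISMATCH_SCORE = -2
GAP_OPEN = -4  # charged on top of the first extend
GAP_EXTEND = -1

_CIGAR_RE = re.compile(r"(\d+)([=XIDSM])")


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH_SCORE
    a.mismatch_score = MISMATCH_SCORE
    # gap of length L costs |GAP_OPEN| + L * |GAP_EXTEND|
    a.open_gap_score = GAP_OPEN + GAP_EXTEND
    a.extend_gap_score = GAP_EXTEND
    # free end gaps on both sequences (dovetail)
    a.open_end_insertion_score = 0
    a.extend_end_insertion_score = 0
    a.open_end_deletion_score = 0
    a.extend_end_deletion_score = 0
    return a


_ALIGNER = _make_aligner()


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) pairs."""
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def score_cigar(cigar: str) -> int:
    """Alignment score implied by an =/X/I/D/S CIGAR (soft clips are free)."""
    score = 0
    for n, op in parse_cigar(cigar):
        if op == "=":
            score += MATCH_SCORE * n
        elif op == "X":
            score += MISMATCH_SCORE * n
        elif op in "ID":
            score += GAP_OPEN + GAP_EXTEND * n
    return score


@dataclass(frozen=True)
class AlignmentResult:
    """Alignment of a read (query) against one locus reference (target)."""

    locus_id: str
    score: int
    cigar: str
    ref_start: int
    strand: str  # '+' or '-'

    def read_length_consumed(self) -> int:
        return sum(n for n, op in parse_cigar(self.cigar) if op in "=XISM")

    def ref_length_consumed(self) -> int:
        return sum(n for n, op in parse_cigar(self.cigar) if op in "=XDM")


@dataclass(frozen=True)
class AssignmentOutcome:
    read_id: str
    status: str  # 'assigned' or 'unassigned'
    best: AlignmentResult | None = None
    runner_up_score: int | None = None


def _match_runs(read_seq: str, ref_seq: str, q0: int, q1: int, t0: int, parts: list[str]) -> None:
    """Append =/X runs for the aligned block read[q0:q1] vs ref[t0:...]."""
    a = np.frombuffer(read_seq[q0:q1].encode(), dtype=np.uint8)
    b = np.frombuffer(ref_seq[t0 : t0 + (q1 - q0)].encode(), dtype=np.uint8)
    diff = a != b
    mismatch_at = np.flatnonzero(diff)
    pos = 0
    for i in mismatch_at:
        if i > pos:
            parts.append(f"{i - pos}=")
        # coalesce adjacent mismatches
        if parts and parts[-1].endswith("X"):
            n = int(parts[-1][:-1])
            parts[-1] = f"{n + 1}X"
        else:
            parts.append("1X")
        pos = i + 1
    if q1 - q0 > pos:
        parts.append(f"{q1 - q0 - pos}=")


def _cigar_from_coordinates(
    coords: np.ndarray, read_seq: str, ref_seq: str
) -> tuple[str, int]:
    """SAM-style read-vs-ref CIGAR and ref_start from alignment coordinates."""
    t = coords[0]
    q = coords[1]
    n_seg = len(t) - 1
    aligned = [
        k for k in range(n_seg) if t[k + 1] > t[k] and q[k + 1] > q[k]
    ]
    if not aligned:  # degenerate: nothing aligned at all
        return f"{len(read_seq)}S", int(t[0])
    first, last = aligned[0], aligned[-1]
    parts: list[str] = []
    ref_start = int(t[first])
    for k in range(n_seg):
        dt = int(t[k + 1] - t[k])
        dq = int(q[k + 1] - q[k])
        if dt and dq:
            _match_runs(read_seq, ref_seq, int(q[k]), int(q[k + 1]), int(t[k]), parts)
        elif dq:
            # read-only: soft clip outside the aligned core, insertion inside
            parts.append(f"{dq}{'S' if k < first or k > last else 'I'}")
        elif dt and first < k < last:
            parts.append(f"{dt}D")
        # reference overhangs outside the core are simply not covered
    return "".join(parts), ref_start


def align_semiglobal(
    read_seq: str, ref_seq: str, locus_id: str = "", strand: str = "+"
) -> AlignmentResult:
    """Best semi-global alignment of read vs reference.

    The shorter sequence aligns end-to-end with free end gaps on the longer
    one.  Unaligned read ends become soft clips; ``ref_start`` gives where
    the alignment begins on the reference.
    """
    if not read_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    # fast path: one sequence contained exactly in the other
    q, t = (ref_seq, read_seq) if len(ref_seq) <= len(read_seq) else (read_seq, ref_seq)
    hit = edlib.align(q, t, mode="HW", task="locations", k=0)
    if hit["editDistance"] == 0:
        start, end = hit["locations"][0]
        if t is read_seq:
            cigar = f"{len(ref_seq)}="
            if start:
                cigar = f"{start}S{cigar}"
            right = len(read_seq) - 1 - end
            if right:
                cigar = f"{cigar}{right}S"
            return AlignmentResult(locus_id, score_cigar(cigar), cigar, 0, strand)
        return AlignmentResult(
            locus_id, MATCH_SCORE * len(read_seq), f"{len(read_seq)}=", start, strand
        )
    aln = _ALIGNER.align(ref_seq, read_seq)[0]
    cigar, ref_start = _cigar_from_coordinates(aln.coordinates, read_seq, ref_seq)
    return AlignmentResult(locus_id, score_cigar(cigar), cigar, ref_start, strand)


def _screen_distance(query_core: str, target: str) -> int:
    q, t = (query_core, target) if len(query_core) <= len(target) else (target, query_core)
    return edlib.align(q, t, mode="HW", task="distance")["editDistance"]


def assign_read(
    read: SequencingRead,
    panel: Panel,
    min_score_frac: float = 0.6,
) -> AssignmentOutcome:
    """Pick the locus (and strand) a read belongs to, or declare it unassigned.

    Both orientations of the read are screened against every locus by edit
    distance; minimum-distance candidates are then fully aligned and the
    best score wins.  A read is assigned iff that score reaches
    ``min_score_frac * 2 * min(len(read), len(ref))`` — the stated fraction
    of the perfect score attainable over the aligned core.  An exact score
    tie between two loci leaves the read unassigned as ambiguous.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    rc_seq = reverse_complement(read.seq)
    screened: list[tuple[int, str, str, str]] = []  # (dist, locus_id, strand, oriented seq)
    for locus in panel:
        d_fwd = _screen_distance(read.seq, locus.ref_seq)
        d_rev = _screen_distance(rc_seq, locus.ref_seq)
        if d_fwd <= d_rev:
            screened.append((d_fwd, locus.locus_id, "+", read.seq))
        else:
            screened.append((d_rev, locus.locus_id, "-", rc_seq))
    screened.sort(key=lambda x: x[0])
    best_dist = screened[0][0]
    candidates = [s for s in screened if s[0] == best_dist]
    scored = [
        align_semiglobal(seq, panel[lid].ref_seq, lid, strand)
        for _, lid, strand, seq in candidates
    ]
    scored.sort(key=lambda a: -a.score)
    best = scored[0]
    runner_up = scored[1].score if len(scored) > 1 else None
    threshold = min_score_frac * 2 * min(len(read.seq), len(panel[best.locus_id].ref_seq))
    ambiguous = (
        runner_up is not None
        and runner_up == best.score
        and scored[1].locus_id != best.locus_id
    )
    if best.score >= threshold and not ambiguous:
        return AssignmentOutcome(read.read_id, "assigned", best, runner_up)
    return AssignmentOutcome(read.read_id, "unassigned", None, runner_up)


def orient_forward(
    read: SequencingRead, outcome: AssignmentOutcome, panel: Panel
) -> tuple[SequencingRead, AlignmentResult]:
    """Return the read on the forward strand of its locus, with its alignment.

    Minus-strand reads are reverse-complemented (qualities reversed); the
    stored alignment was computed on the oriented sequence, so it carries
    over with strand '+'.  Idempotent on forward reads.
    """
    if outcome.status != "assigned" or outcome.best is None:
        raise ValueError(f"{read.read_id}: cannot orient an unassigned read")
    if outcome.best.strand == "-" and read.orientation != "forward":
        read = flip_read(read)
    read = SequencingRead(read.read_id, read.seq, read.quals, "forward")
    return read, replace(outcome.best, strand="+")


def _resolve_m_ops(cigar: str, read_seq: str, ref_seq: str, ref_start: int) -> str:
    """Rewrite M ops as =/X runs against the reference."""
    out: list[str] = []
    q = 0
    r = ref_start
    for n, op in parse_cigar(cigar):
        if op == "M":
            _match_runs(read_seq, ref_seq, q, q + n, r, out)
            q += n
            r += n
        else:
            out.append(f"{n}{op}")
            if op in "=XIS":
                q += n
            if op in "=XD":
                r += n
    return "".join(out)


def load_sam_assignments(
    sam_path: str, panel: Panel
) -> list[tuple[SequencingRead, AssignmentOutcome]]:
    """Ingest pre-aligned reads from a text SAM file.

    Records are trusted for locus (RNAME), strand (FLAG 0x10) and CIGAR;
    SEQ in SAM is already reference-forward, so no flipping is needed.
    'M' ops are resolved into '='/'X' against the panel reference.
    """
    import pysam

    out: list[tuple[SequencingRead, AssignmentOutcome]] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            quals = tuple(rec.query_qualities) if rec.query_qualities is not None else None
            read = SequencingRead(rec.query_name, rec.query_sequence.upper(), quals, "forward")
            if rec.is_unmapped or rec.reference_name not in panel.loci:
                out.append((read, AssignmentOutcome(read.read_id, "unassigned")))
                continue
            locus = panel[rec.reference_name]
            cigar = _resolve_m_ops(rec.cigarstring, read.seq, locus.ref_seq, rec.reference_start)
            aln = AlignmentResult(
                locus.locus_id,
                score_cigar(cigar),
                cigar,
                rec.reference_start,
                "-" if rec.is_reverse else "+",
            )
            out.append((read, AssignmentOutcome(read.read_id, "assigned", aln)))
    return out
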