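"""Locus panel: reference amplicons, SSR motifs and region coordinates.

A *panel* describes the target loci of an amplicon assay.  Each locus is an
amplicon reference sequence together with the repeating motif of its SSR
(simple sequence repeat) and the 0-based half-open coordinates of the SSR
array on that reference.  The 20-bp sequences immediately left and right of
the array are derived from the reference and serve as flank anchors for
boundary determination during typing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLANK_LEN = 20
_DNA = set("ACGT")


class PanelError(ValueError):
    """Raised when a panel definition violates its invariants."""


def _is_primitive(unit: str) -> bool:
    # A motif is non-primitive iff it is a whole-multiple repetition of a
    # shorter string, which holds iff it occurs inside (unit+unit)[1:-1].
    return unit not in (unit + unit)[1:-1]


@dataclass(frozen=True)
class MotifSpec:
    """The repeating unit of an SSR, e.g. ``CAGCC``.

    The unit must be an uppercase DNA string of length 2-10 and primitive
    (not itself a tandem repetition of a shorter unit), so that a repeat
    number is unambiguous.
    """

    unit: str

    def __post_init__(self) -> None:
        u = self.unit
        if not (2 <= len(u) <= 10):
            raise PanelError(f"motif length must be 2-10, got {u!r}")
        if not set(u) <= _DNA:
            raise PanelError(f"motif must contain only A/C/G/T, got {u!r}")
        if not _is_primitive(u):
            raise PanelError(f"motif {u!r} is a repetition of a shorter unit")

    def __len__(self) -> int:
        return len(self.unit)

    @property
    def name(self) -> str:
        return self.unit


@dataclass(frozen=True)
class LocusDefinition:
    """One target locus: reference amplicon + SSR motif + array coordinates.

    ``ssr_start``/``ssr_end`` are 0-based half-open coordinates of the SSR
    array on the forward strand of ``ref_seq``.  The reference slice must
    consist of exact tandem copies of the motif, and at least 20 bases of
    flanking sequence must exist on both sides.
    """

    locus_id: str
    ref_seq: str
    motif: MotifSpec
    ssr_start: int
    ssr_end: int
    flank_left: str = field(init=False)
    flank_right: str = field(init=False)

    def __post_init__(self) -> None:
        ref = self.ref_seq
        if not set(ref) <= _DNA | {"N"}:
            raise PanelError(f"{self.locus_id}: reference contains non-DNA characters")
        if not (0 <= self.ssr_start < self.ssr_end <= len(ref)):
            raise PanelError(
                f"{self.locus_id}: SSR coordinates [{self.ssr_start}, {self.ssr_end}) "
                f"outside reference of length {len(ref)}"
            )
        span = self.ssr_end - self.ssr_start
        m = len(self.motif)
        if span % m != 0:
            raise PanelError(
                f"{self.locus_id}: SSR span {span} is not a multiple of motif length {m}"
            )
        region = ref[self.ssr_start : self.ssr_end]
        if region != self.motif.unit * (span // m):
            raise PanelError(
                f"{self.locus_id}: SSR slice {region!r} is not tandem copies of "
                f"{self.motif.unit!r}"
            )
        if self.ssr_start < FLANK_LEN or len(ref) - self.ssr_end < FLANK_LEN:
            raise PanelError(
                f"{self.locus_id}: SSR array sits closer than {FLANK_LEN} bases "
                "to an amplicon end"
            )
        object.__setattr__(self, "flank_left", ref[self.ssr_start - FLANK_LEN : self.ssr_start])
        object.__setattr__(self, "flank_right", ref[self.ssr_end : self.ssr_end + FLANK_LEN])


def reference_repeat_count(locus: LocusDefinition) -> int:
    """Number of motif copies in the reference SSR array."""
    return (locus.ssr_end - locus.ssr_start) // len(locus.motif)


@dataclass
class Panel:
    """Ordered collection of loci keyed by locus_id."""

    loci: dict[str, LocusDefinition]

    def __post_init__(self) -> None:
        for lid, locus in self.loci.items():
            if lid != locus.locus_id:
                raise PanelError(f"panel key {lid!r} != locus_id {locus.locus_id!r}")

    @classmethod
    def from_loci(cls, loci: list[LocusDefinition]) -> "Panel":
        ids = [l.locus_id for l in loci]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate locus_ids in panel")
        return cls({l.locus_id: l for l in loci})

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci.values())

    def __getitem__(self, locus_id: str) -> LocusDefinition:
        return self.loci[locus_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, Panel) and self.loci == other.loci


def load_panel(ref_fasta_path: str | Path, panel_table_path: str | Path) -> Panel:
    """Load and validate a panel from a reference FASTA + locus table.

    The FASTA holds one record per locus (record id = locus_id).  The table
    is tab-separated with header ``locus_id  motif  ssr_start  ssr_end``;
    lines starting with '#' are ignored.  Flank anchors are derived from the
    reference and coordinates, never read from the table.
    """
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(ref_fasta_path), "fasta")}
    loci: list[LocusDefinition] = []
    with open(panel_table_path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        raise PanelError(f"empty panel table {panel_table_path}")
    header = rows[0]
    expected = ["locus_id", "motif", "ssr_start", "ssr_end"]
    if header[:4] != expected:
        raise PanelError(f"panel table header must be {expected}, got {header}")
    for row in rows[1:]:
        lid, motif, start, end = row[0], row[1], int(row[2]), int(row[3])
        if lid not in refs:
            raise PanelError(f"locus {lid!r} missing from reference FASTA")
        loci.append(LocusDefinition(lid, refs[lid], MotifSpec(motif), start, end))
    return Panel.from_loci(loci)


def write_panel(panel: Panel, ref_fasta_path: str | Path, panel_table_path: str | Path) -> None:
    """Write a panel back to the reference FASTA + table representation."""
    records = [
        SeqRecord(Seq(l.ref_seq), id=l.locus_id, description="") for l in panel
    ]
    SeqIO.write(records, str(ref_fasta_path), "fasta")
    with open(panel_table_path, "w") as fh:
        fh.write("locus_id\tmotif\tssr_start\tssr_end\n")
        for l in panel:
            fh.write(f"{l.locus_id}\t{l.motif.unit}\t{l.ssr_start}\t{l.ssr_end}\n")
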