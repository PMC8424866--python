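"""Result tables, per-typing read grouping and the text alignment view."""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable

from .calling import AlleleTable, GenotypeCall, allele_label
from .panel import LocusDefinition
from .seqio import SequencingRead, write_fasta
from .ssr import TYPED, TypingResult, locate_flanks

TYPING_HEADER = ["read_id", "locus_id", "algorithm", "motif", "repeat_count", "allele_len", "status"]
GENOTYPE_HEADER = [
    "sample", "locus_id", "motif", "allele1_repeats", "allele2_repeats",
    "allele1_len", "allele2_len", "label", "zygosity", "support1", "support2", "qc",
]
ALLELE_HEADER = ["locus_id", "motif", "typing", "repeat_count", "read_count", "percent"]


def write_typing_tsv(
    typings: Iterable[TypingResult], motifs: dict[str, str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TYPING_HEADER) + "\n")
        for t in typings:
            motif = motifs.get(t.locus_id, "")
            fh.write(
                f"{t.read_id}\t{t.locus_id}\t{t.algorithm}\t{motif}\t"
                f"{t.repeat_count}\t{t.repeat_count * len(motif)}\t{t.status}\n"
            )


def write_allele_tables_tsv(tables: dict[str, AlleleTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALLELE_HEADER) + "\n")
        for locus_id in sorted(tables):
            tab = tables[locus_id]
            for rc, (reads, frac) in sorted(tab.entries.items()):
                star = allele_label(tab.motif, rc)[1] if tab.motif else str(rc)
                fh.write(
                    f"{locus_id}\t{tab.motif}\t{star}\t{rc}\t{reads}\t{100 * frac:.2f}\n"
                )


def write_genotypes_tsv(
    calls: dict[str, GenotypeCall], motifs: dict[str, str], sample: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENOTYPE_HEADER) + "\n")
        for locus_id in sorted(calls):
            c = calls[locus_id]
            motif = motifs.get(locus_id, "")
            m = len(motif)
            a1 = "" if c.allele1 is None else c.allele1
            a2 = "" if c.allele2 is None else c.allele2
            l1 = "" if c.allele1 is None else c.allele1 * m
            l2 = "" if c.allele2 is None else c.allele2 * m
            fh.write(
                f"{sample}\t{locus_id}\t{motif}\t{a1}\t{a2}\t{l1}\t{l2}\t{c.label}\t"
                f"{c.zygosity}\t{c.support1:.4f}\t{c.support2:.4f}\t{c.qc}\n"
            )


def write_grouped_reads(
    typings: Iterable[TypingResult],
    oriented_reads: dict[str, SequencingRead],
    motifs: dict[str, str],
    out_dir: str | Path,
) -> None:
    """One FASTA per (locus, typing), holding that typing's reads.

    The FASTA files of a locus partition its typed reads.
    """
    groups: dict[tuple[str, int], list[SequencingRead]] = defaultdict(list)
    for t in typings:
        if t.status == TYPED and t.read_id in oriented_reads:
            groups[(t.locus_id, t.repeat_count)].append(oriented_reads[t.read_id])
    for (locus_id, rc), reads in sorted(groups.items()):
        motif = motifs.get(locus_id, "")
        name = allele_label(motif, rc)[1].replace("*", "x") if motif else str(rc)
        d = Path(out_dir) / locus_id
        d.mkdir(parents=True, exist_ok=True)
        write_fasta(reads, d / f"{name}.fasta")


def render_alignment_view(
    locus: LocusDefinition,
    typed_reads: list[tuple[SequencingRead, TypingResult]],
) -> str:
    """Stack reads of one typing, left-aligned on the left flank anchor.

    The SSR-region columns are marked with '*' in a header row; flank SNPs
    remain visible as deviating characters outside the marked block.
    """
    if not typed_reads:
        raise ValueError("empty typing group")
    rows: list[tuple[int, str]] = []
    for read, typing in typed_reads:
        anchors = typing.anchors
        if anchors is None:
            found = locate_flanks(read.seq, locus, max_mismatch=2)
            if isinstance(found, str):
                continue
            anchors = found
        rows.append((anchors.left_end, read.seq))
    if not rows:
        raise ValueError("no read in the group has locatable flank anchors")
    max_left = max(left for left, _ in rows)
    repeat_count = typed_reads[0][1].repeat_count
    span = repeat_count * len(locus.motif)
    header = (
        f"{locus.locus_id} {locus.motif.unit}*{repeat_count} "
        f"({len(rows)} reads, SSR region {span} bp)"
    )
    marker = " " * max_left + "*" * span
    lines = [header, marker]
    for left, seq in rows:
        lines.append(" " * (max_left - left) + seq)
    return "\n".join(lines)
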