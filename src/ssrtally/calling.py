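"""Per-locus allele tallies and diploid genotype calling.

Reads typed at a locus are tallied by repeat count.  In a diploid sample
the one or two dominant peaks of that tally are the genotype: a single
peak holding at least ``min_major`` of the typed reads is a homozygote,
two peaks each holding at least ``min_minor`` are a heterozygote.
Satellite peaks one repeat unit away from a called allele (PCR stutter or
sequencing slippage) are flagged but never subtracted from the tally or
promoted to alleles.  Loci with no dominant peak structure are flagged as
low quality rather than force-called.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

from .ssr import TYPED, TypingResult


@dataclass
class AlleleTable:
    """Tally of repeat-count typings at one locus for one sample."""

    locus_id: str
    motif: str
    entries: dict[int, tuple[int, float]]  # repeat_count -> (reads, fraction)
    n_typed: int
    n_untyped: int

    @classmethod
    def from_counts(cls, locus_id: str, motif: str, counts: dict[int, int], n_untyped: int = 0):
        n_typed = sum(counts.values())
        entries = {
            rc: (c, c / n_typed) for rc, c in sorted(counts.items()) if c >= 1
        }
        return cls(locus_id, motif, entries, n_typed, n_untyped)


@dataclass(frozen=True)
class GenotypeCall:
    locus_id: str
    allele1: int | None
    allele2: int | None
    zygosity: str  # 'homozygous' | 'heterozygous' | 'none'
    support1: float
    support2: float
    label: str
    stutter_flags: tuple[int, ...] = ()
    qc: str = "pass"  # 'pass' or 'low_quality(<reason>)'

    @property
    def alleles(self) -> tuple[int, ...]:
        if self.allele1 is None:
            return ()
        if self.zygosity == "homozygous":
            return (self.allele1,)
        return (self.allele1, self.allele2)


def tally(typing_results: Iterable[TypingResult]) -> dict[str, AlleleTable]:
    """Group typed reads of one sample by (locus, repeat_count)."""
    counts: dict[str, Counter] = defaultdict(Counter)
    motifs: dict[str, str] = {}
    untyped: Counter = Counter()
    for tr in typing_results:
        if tr.status == TYPED:
            counts[tr.locus_id][tr.repeat_count] += 1
        else:
            untyped[tr.locus_id] += 1
        motifs.setdefault(tr.locus_id, "")
    out = {}
    for locus_id in sorted(set(counts) | set(untyped)):
        out[locus_id] = AlleleTable.from_counts(
            locus_id, motifs.get(locus_id, ""), dict(counts.get(locus_id, {})), untyped[locus_id]
        )
    return out


def allele_label(motif: str, repeat_count: int) -> tuple[str, str]:
    """Both naming conventions for one allele.

    Returns the length-style name ``SSR{count*len(motif)}`` and the
    star-style name ``{MOTIF}*{count}``.
    """
    if repeat_count < 1:
        raise ValueError("repeat count must be >= 1")
    return f"SSR{repeat_count * len(motif)}", f"{motif}*{repeat_count}"


def _stutter_flags(entries: dict[int, tuple[int, float]], alleles: tuple[int, ...]) -> tuple[int, ...]:
    flags = []
    for a in alleles:
        a_reads = entries[a][0]
        for rc in (a - 1, a + 1):
            if rc in entries and rc not in alleles and entries[rc][0] < a_reads:
                flags.append(rc)
    return tuple(sorted(set(flags)))


def call_genotype(
    table: AlleleTable,
    min_major: float = 0.8,
    min_minor: float = 0.2,
    min_reads: int = 30,
) -> GenotypeCall:
    """Call a diploid genotype from the dominant peak(s) of an allele table.

    The top entry alone (fraction >= ``min_major``) gives a homozygote; the
    top two entries (each >= ``min_minor``) give a heterozygote; otherwise
    the locus has no dominant peak and is flagged low quality.  Tables with
    fewer than ``min_reads`` typed reads are flagged for depth.
    """
    motif = table.motif

    def no_call(reason: str) -> GenotypeCall:
        return GenotypeCall(
            table.locus_id, None, None, "none", 0.0, 0.0, "", (), f"low_quality({reason})"
        )

    if table.n_typed < min_reads:
        return no_call("depth")
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1][0], kv[0]))
    top_rc, (top_reads, top_frac) = ranked[0]
    if top_frac >= min_major:
        a1 = a2 = top_rc
        s1 = s2 = top_frac
        zyg = "homozygous"
    elif len(ranked) >= 2 and top_frac >= min_minor and ranked[1][1][1] >= min_minor:
        pair = sorted([top_rc, ranked[1][0]])
        a1, a2 = pair
        s1, s2 = table.entries[a1][1], table.entries[a2][1]
        zyg = "heterozygous"
    else:
        return no_call("no dominant peak")
    label = f"{motif} ({a1},{a2})"
    alleles = (a1,) if zyg == "homozygous" else (a1, a2)
    return GenotypeCall(
        table.locus_id, a1, a2, zyg, s1, s2, label,
        _stutter_flags(table.entries, alleles), "pass",
    )


def flag_low_quality_locus(
    table: AlleleTable,
    call: GenotypeCall,
    discordant_fraction: float | None = None,
    max_dominant: int = 2,
    min_minor: float = 0.2,
    min_dominant_ratio: float = 0.3,
    max_internal_variation: float = 0.5,
) -> str:
    """Three-criteria locus quality screen.

    A locus is low quality when (a) more than ``max_dominant`` typings each
    hold a substantial fraction of reads, (b) even the top typing holds
    fewer than ``min_dominant_ratio`` of the reads, or (c) the broad and
    precise counters disagree on more than ``max_internal_variation`` of
    its reads (too much variation inside the SSR region).  Returns 'pass'
    or a low_quality(...) verdict naming the criterion.
    """
    if not table.entries:
        return call.qc if call.qc != "pass" else "low_quality(depth)"
    n_dominant = sum(1 for _, (_, frac) in table.entries.items() if frac >= min_minor)
    if n_dominant > max_dominant:
        return "low_quality(too many dominant types)"
    top_frac = max(frac for _, frac in table.entries.values())
    if top_frac < min_dominant_ratio:
        return "low_quality(low dominant ratio)"
    if discordant_fraction is not None and discordant_fraction > max_internal_variation:
        return "low_quality(internal variation)"
    return call.qc
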