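"""Synthetic targeted-sequencing read generator and typing-error metrics.

Reads are built as ``Random_L + Flank_L(35 bp) + SSR_Region + Flank_R(35 bp)
+ Random_R`` with total length uniform in [180, 220].  Five read classes
exercise the pipeline stages:

* A — valid reads, one SNP in each 35-bp flank;
* B — a heterozygous locus, two alleles differing by one repeat unit,
  split evenly across reads;
* C — a heterozygous locus where one allele carries a SNP-interrupted
  array (three perfect copies + one substituted copy + two perfect copies);
* D — fully random reads that belong to no locus;
* E — class-A structure emitted at the lowest base quality.

Four per-locus benchmark datasets carry exactly one fixed variant each:
none (A), one SNP inside the SSR array (B), one SNP in a flank (C), a 2-bp
flank deletion (D).

The evaluation metrics are the read-level error Er — the fraction of
expected-typeable reads not typed to their true (locus, repeat count) —
and the typing-level error Et — the fraction of true (locus, allele)
genotypes not recovered by the calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .calling import GenotypeCall
from .panel import LocusDefinition, MotifSpec, Panel
from .seqio import SequencingRead, flip_read
from .ssr import TYPED, TypingResult

FLANK = 35
LENGTH_RANGE = (180, 220)
Q_HIGHEST = 40
Q_LOWEST = 2

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _substitute(rng: np.random.Generator, seq: str, pos: int) -> str:
    alternatives = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alternatives[rng.integers(0, 3)] + seq[pos + 1 :]


def _make_locus(
    rng: np.random.Generator, locus_id: str, motif: str, ref_repeats: int
) -> LocusDefinition:
    """Synthetic amplicon: 35-bp flanks around an exact tandem array.

    The flank bases adjacent to the array are forced to differ from the
    abutting motif base so that repeat-length changes cannot slide into the
    flanks under equally optimal alignments; real assay flanks are chosen
    with the same property in mind.
    """
    left = _random_dna(rng, FLANK)
    right = _random_dna(rng, FLANK)
    if left[-1] == motif[-1]:
        left = left[:-1] + {"A": "C", "C": "G", "G": "T", "T": "A"}[motif[-1]]
    if right[0] == motif[0]:
        right = {"A": "C", "C": "G", "G": "T", "T": "A"}[motif[0]] + right[1:]
    ref = left + motif * ref_repeats + right
    return LocusDefinition(locus_id, ref, MotifSpec(motif), FLANK, FLANK + len(motif) * ref_repeats)


def class_panel(seed: int) -> Panel:
    """The three-locus panel behind read classes A-C (and E)."""
    rng = np.random.default_rng([seed, 101])
    return Panel.from_loci(
        [
            _make_locus(rng, "s17883", "ATA", 3),
            _make_locus(rng, "s423645", "AGCT", 5),
            _make_locus(rng, "s566749", "CGCAT", 4),
        ]
    )


def dataset_panel(seed: int) -> Panel:
    """Three benchmark loci with motif lengths 3, 4 and 5."""
    rng = np.random.default_rng([seed, 202])
    return Panel.from_loci(
        [
            _make_locus(rng, "locus1", "ATC", 8),
            _make_locus(rng, "locus2", "AGAT", 7),
            _make_locus(rng, "locus3", "AGAGA", 6),
        ]
    )


@dataclass(frozen=True)
class SimClassSpec:
    """Recipe for one read class."""

    class_label: str  # 'A'..'E'
    n_reads: int
    locus_id: str | None  # None for the random class
    # alleles: (SSR region sequence, true repeat count); reads cycle through
    alleles: tuple[tuple[str, int], ...] = ()
    flank_snps: int = 0  # SNPs per flank
    quality_tier: str = "highest"
    length_range: tuple[int, int] = LENGTH_RANGE
    expected_fate: str = "typed"  # typed | filtered | unassigned

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.class_label == "D" and self.locus_id is not None:
            raise ValueError("the random class has no locus")
        if self.class_label == "E" and self.quality_tier != "lowest":
            raise ValueError("class E reads are lowest-quality by definition")


@dataclass(frozen=True)
class SimTruth:
    read_id: str
    class_label: str
    locus_id: str | None
    true_repeat_count: int | None
    expected_fate: str  # typed | filtered | unassigned


CLASS_C_VARIANT = "CGCAT" * 3 + "CACAT" + "CGCAT" * 2  # interrupted array, 6 units


def five_class_specs(panel: Panel) -> list[SimClassSpec]:
    """Default class recipes: A=2000, B=1000, C=2000, D=1000, E=1000 reads."""
    ata = panel["s17883"].motif.unit
    agct = panel["s423645"].motif.unit
    cgcat = panel["s566749"].motif.unit
    return [
        SimClassSpec("A", 2000, "s17883", ((ata * 3, 3),), flank_snps=1),
        SimClassSpec("B", 1000, "s423645", ((agct * 5, 5), (agct * 6, 6))),
        SimClassSpec("C", 2000, "s566749", ((cgcat * 4, 4), (CLASS_C_VARIANT, 6))),
        SimClassSpec("D", 1000, None, (), expected_fate="unassigned"),
        SimClassSpec(
            "E", 1000, "s17883", ((ata * 3, 3),), flank_snps=1,
            quality_tier="lowest", expected_fate="filtered",
        ),
    ]


def _assemble_read(
    rng: np.random.Generator,
    core: str,
    length_range: tuple[int, int],
    read_id: str,
    quality: int,
) -> SequencingRead:
    total = int(rng.integers(length_range[0], length_range[1] + 1))
    pad = max(0, total - len(core))
    pad_left = int(rng.integers(0, pad + 1))
    seq = _random_dna(rng, pad_left) + core + _random_dna(rng, pad - pad_left)
    read = SequencingRead(read_id, seq, (quality,) * len(seq))
    if rng.random() < 0.5:  # half of each class on the reverse strand
        read = flip_read(read)
    return read


def make_class_reads(
    spec: SimClassSpec, panel: Panel, rng: np.random.Generator
) -> tuple[list[SequencingRead], list[SimTruth]]:
    """Generate one class of reads with per-read ground truth."""
    quality = Q_LOWEST if spec.quality_tier == "lowest" else Q_HIGHEST
    digit = "ABCDE".index(spec.class_label) + 1
    reads: list[SequencingRead] = []
    truths: list[SimTruth] = []
    locus = panel[spec.locus_id] if spec.locus_id is not None else None
    if spec.locus_id is not None and locus is None:
        raise KeyError(f"locus {spec.locus_id} missing from panel")
    half = spec.n_reads // 2
    for ordinal in range(1, spec.n_reads + 1):
        read_id = f"BMSTC_{digit}_{ordinal}"
        if locus is None:
            total = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            reads.append(SequencingRead(read_id, _random_dna(rng, total), (quality,) * total))
            truths.append(SimTruth(read_id, spec.class_label, None, None, spec.expected_fate))
            continue
        allele_idx = 0 if len(spec.alleles) == 1 or ordinal <= half else 1
        region, truth_count = spec.alleles[allele_idx]
        left = locus.ref_seq[locus.ssr_start - FLANK : locus.ssr_start]
        right = locus.ref_seq[locus.ssr_end : locus.ssr_end + FLANK]
        for _ in range(spec.flank_snps):
            left = _substitute(rng, left, int(rng.integers(0, FLANK)))
            right = _substitute(rng, right, int(rng.integers(0, FLANK)))
        core = left + region + right
        reads.append(_assemble_read(rng, core, spec.length_range, read_id, quality))
        truths.append(
            SimTruth(read_id, spec.class_label, locus.locus_id, truth_count, spec.expected_fate)
        )
    return reads, truths


def make_five_class_sim(
    seed: int, specs: Sequence[SimClassSpec] | None = None
) -> tuple[Panel, list[SequencingRead], list[SimTruth]]:
    """Full five-class simulation, reads shuffled into one pool."""
    panel = class_panel(seed)
    rng = np.random.default_rng([seed, 303])
    if specs is None:
        specs = five_class_specs(panel)
    reads: list[SequencingRead] = []
    truths: list[SimTruth] = []
    for spec in specs:
        r, t = make_class_reads(spec, panel, rng)
        reads.extend(r)
        truths.extend(t)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return panel, reads, truths


DATASET_MODES = ("A", "B", "C", "D")


def make_dataset(
    variant_mode: str,
    locus: LocusDefinition,
    n: int = 10000,
    rng: np.random.Generator | int = 0,
) -> tuple[list[SequencingRead], list[SimTruth]]:
    """Benchmark reads for one locus carrying exactly one fixed variant.

    Mode A: no variant; B: one SNP at the centre of the SSR array; C: one
    SNP at the centre of the left flank; D: a 2-bp deletion at the centre
    of the left flank.  The variant position and substituted base are the
    same for every read of the dataset.  The truth repeat count always
    equals the reference count: none of the variants changes the repeat
    number.
    """
    if variant_mode not in DATASET_MODES:
        raise ValueError(f"variant mode must be one of {DATASET_MODES}")
    if isinstance(rng, int):
        rng = np.random.default_rng([rng, 404])
    left = locus.ref_seq[locus.ssr_start - FLANK : locus.ssr_start]
    right = locus.ref_seq[locus.ssr_end : locus.ssr_end + FLANK]
    region = locus.ref_seq[locus.ssr_start : locus.ssr_end]
    truth_count = len(region) // len(locus.motif)
    if variant_mode == "B":
        region = _substitute(rng, region, len(region) // 2)
    elif variant_mode == "C":
        left = _substitute(rng, left, FLANK // 2)
    elif variant_mode == "D":
        mid = FLANK // 2
        left = left[:mid] + left[mid + 2 :]
    core = left + region + right
    reads: list[SequencingRead] = []
    truths: list[SimTruth] = []
    for ordinal in range(1, n + 1):
        read_id = f"DS{variant_mode}_{locus.locus_id}_{ordinal}"
        reads.append(_assemble_read(rng, core, LENGTH_RANGE, read_id, Q_HIGHEST))
        truths.append(SimTruth(read_id, variant_mode, locus.locus_id, truth_count, "typed"))
    return reads, truths


@dataclass(frozen=True)
class ErrorMetrics:
    """Read-level (Er) and typing-level (Et) error fractions."""

    er: float
    et: float


def compute_error_metrics(
    truths: Iterable[SimTruth],
    typing_results: Iterable[TypingResult],
    genotype_calls: Iterable[GenotypeCall],
) -> ErrorMetrics:
    """Evaluate typings and calls against simulation ground truth.

    Er = (S_ra - sum R) / S_ra where S_ra counts expected-typeable truth
    reads and sum R counts reads typed to their true (locus, repeat count).
    Et = (T_a - sum T) / T_a where T_a counts distinct true (locus, allele)
    pairs among those reads and sum T counts pairs recovered by the calls.
    """
    truths = list(truths)
    typeable = [t for t in truths if t.expected_fate == "typed"]
    s_ra = len(typeable)
    truth_alleles = {(t.locus_id, t.true_repeat_count) for t in typeable}
    t_a = len(truth_alleles)
    if s_ra == 0 or t_a == 0:
        raise ValueError("no expected-typeable reads: error metrics are undefined")
    by_read = {tr.read_id: tr for tr in typing_results}
    n_correct = 0
    for t in typeable:
        tr = by_read.get(t.read_id)
        if (
            tr is not None
            and tr.status == TYPED
            and tr.locus_id == t.locus_id
            and tr.repeat_count == t.true_repeat_count
        ):
            n_correct += 1
    called: set[tuple[str, int]] = set()
    for call in genotype_calls:
        for allele in call.alleles:
            called.add((call.locus_id, allele))
    n_typing_correct = sum(1 for pair in truth_alleles if pair in called)
    return ErrorMetrics(
        er=(s_ra - n_correct) / s_ra,
        et=(t_a - n_typing_correct) / t_a,
    )
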