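"""End-to-end typing pipeline: filter -> assign -> orient -> type -> call."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .align import AssignmentOutcome, assign_read, orient_forward
from .calling import AlleleTable, GenotypeCall, call_genotype, flag_low_quality_locus, tally
from .panel import Panel
from .seqio import SequencingRead, quality_filter
from .ssr import TYPED, TypingResult, type_read

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable thresholds of a typing run, serializable to YAML."""

    algorithm: str = "broad"  # 'precise' or 'broad'
    min_q: int = 20  # quality filter: Phred threshold
    min_pct: float = 90.0  # quality filter: % of bases required at min_q
    min_score_frac: float = 0.6  # assignment score fraction
    max_anchor_mismatch: int = 2  # flank anchor substitution tolerance
    max_sub_per_unit: int = 1  # broad: substitutions tolerated per motif unit
    max_total_sub: int = 4  # broad: substitutions tolerated per region
    max_indel_events: int = 2  # broad: indel resynchronizations per region
    min_major: float = 0.8  # calling: homozygous dominance
    min_minor: float = 0.2  # calling: heterozygous minor-allele support
    min_reads: int = 30  # calling: minimum typed depth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("precise", "broad"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 0 <= self.min_q <= 41:
            raise ValueError("min_q must be in [0, 41]")
        if not 0 <= self.min_pct <= 100:
            raise ValueError("min_pct must be in [0, 100]")
        if not 0 < self.min_score_frac <= 1:
            raise ValueError("min_score_frac must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    typings: list[TypingResult]
    tables: dict[str, AlleleTable]
    calls: dict[str, GenotypeCall]
    stage_counts: dict[str, int]
    outcomes: list[AssignmentOutcome] = field(default_factory=list)
    oriented_reads: dict[str, SequencingRead] = field(default_factory=dict)


def run_pipeline(
    reads: Iterable[SequencingRead],
    panel: Panel,
    config: RunConfig | None = None,
    keep_reads: bool = False,
) -> PipelineResult:
    """Run the full typing flow on an in-memory read pool.

    Stage conservation is enforced: reads_in == kept + filtered,
    kept == assigned + unassigned, assigned == typed + untyped.
    """
    cfg = config or RunConfig()
    reads = list(reads)
    kept, discarded = quality_filter(reads, cfg.min_q, cfg.min_pct)
    typings: list[TypingResult] = []
    outcomes: list[AssignmentOutcome] = []
    oriented: dict[str, SequencingRead] = {}
    n_assigned = 0
    for read in kept:
        outcome = assign_read(read, panel, cfg.min_score_frac)
        outcomes.append(outcome)
        if outcome.status != "assigned":
            continue
        n_assigned += 1
        fwd_read, alignment = orient_forward(read, outcome, panel)
        locus = panel[alignment.locus_id]
        typings.append(
            type_read(
                fwd_read,
                locus,
                cfg.algorithm,
                alignment,
                max_anchor_mismatch=cfg.max_anchor_mismatch,
                max_sub_per_unit=cfg.max_sub_per_unit,
                max_total_sub=cfg.max_total_sub,
                max_indel_events=cfg.max_indel_events,
            )
        )
        if keep_reads:
            oriented[read.read_id] = fwd_read
    tables = tally(typings)
    for locus_id, table in tables.items():
        if not table.motif and locus_id in panel.loci:
            table.motif = panel[locus_id].motif.unit
    calls: dict[str, GenotypeCall] = {}
    for locus_id, table in tables.items():
        call = call_genotype(table, cfg.min_major, cfg.min_minor, cfg.min_reads)
        qc = flag_low_quality_locus(table, call, min_minor=cfg.min_minor)
        if qc != call.qc:
            call = dataclasses.replace(call, qc=qc)
        calls[locus_id] = call
    n_typed = sum(1 for t in typings if t.status == TYPED)
    counts = {
        "input": len(reads),
        "kept": len(kept),
        "filtered": len(discarded),
        "assigned": n_assigned,
        "unassigned": len(kept) - n_assigned,
        "typed": n_typed,
        "untyped": n_assigned - n_typed,
    }
    for stage, n in counts.items():
        logger.info("stage %s: %d reads", stage, n)
    return PipelineResult(typings, tables, calls, counts, outcomes, oriented)
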