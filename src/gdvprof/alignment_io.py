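"""SAM alignment ingestion, organism grouping, and early read/reference filtering.

Reads are expected to have been mapped against a multi-genome reference
collection with a mapper configured to report multiple placements per read
(e.g. ``-k N``): the downstream depth and validity estimates rely on seeing
*all* plausible placements, so secondary and supplementary alignments are
retained as first-class evidence.

Reference sequences (chromosomes, plasmids) belonging to one organism are
grouped before any filtering; every downstream quantity — target counts,
unique-read counts, coverage — is computed at the organism level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "AlignmentTable",
    "OrganismGrouping",
    "SamParseError",
    "UnknownOrganismError",
    "parse_sam",
    "filter_promiscuous_reads",
    "filter_low_support_refs",
    "mapping_error_rate",
]


class SamParseError(ValueError):
    """Malformed SAM input or inconsistency between header and grouping."""


class UnknownOrganismError(KeyError):
    """An organism id was requested that has no alignments in the table."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of one read on one reference sequence.

    Positions are 0-based, half-open internally (converted from 1-based SAM).
    ``aln_len`` is the span on the reference (M/D/N operations), so that
    ``[pos, pos + aln_len)`` is the covered interval.
    """

    read_id: str
    ref_id: str
    pos: int
    aln_len: int
    edit_distance: int
    is_unmapped: bool = False

    def __post_init__(self) -> None:
        if not self.is_unmapped:
            if self.pos < 0:
                raise ValueError(f"negative position {self.pos} for read {self.read_id}")
            if self.aln_len <= 0:
                raise ValueError(f"non-positive alignment length for read {self.read_id}")
            if self.edit_distance < 0:
                raise ValueError(f"negative edit distance for read {self.read_id}")


@dataclass
class OrganismGrouping:
    """Maps reference sequence ids to organism ids.

    ``organism_length`` is the total length of all member sequences; it is
    filled in from SAM ``@SQ`` lines (or any explicit length map) via
    :meth:`with_lengths`.
    """

    seq_to_organism: dict[str, str]
    organism_length: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrganismGrouping":
        """Load a 2-column TSV: sequence_id <tab> organism_id."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise SamParseError(
                        f"{path}: line {lineno}: expected 2 tab-separated columns"
                    )
                mapping[parts[0]] = parts[1]
        return cls(seq_to_organism=mapping)

    @classmethod
    def trivial(cls, ref_ids: Iterable[str]) -> "OrganismGrouping":
        """Each reference sequence is its own organism."""
        return cls(seq_to_organism={r: r for r in ref_ids})

    def organism_of(self, seq_id: str) -> str:
        """Organism for a sequence; sequences absent from the mapping are
        treated as singleton organisms."""
        return self.seq_to_organism.get(seq_id, seq_id)

    def with_lengths(self, ref_lengths: Mapping[str, int]) -> "OrganismGrouping":
        lengths: dict[str, int] = {}
        seq_map = dict(self.seq_to_organism)
        for seq_id, length in ref_lengths.items():
            org = self.organism_of(seq_id)
            seq_map.setdefault(seq_id, org)
            lengths[org] = lengths.get(org, 0) + int(length)
        if self.organism_length:
            for org, length in self.organism_length.items():
                if org in lengths and lengths[org] != length:
                    raise SamParseError(
                        f"length conflict for organism {org!r}: grouping says "
                        f"{length}, @SQ lines sum to {lengths[org]}"
                    )
        return OrganismGrouping(seq_to_organism=seq_map, organism_length=lengths)


@dataclass
class AlignmentTable:
    """Normalized read-to-reference alignments plus derived read target sets.

    ``read_targets`` maps each read id to the set of *organism* ids it aligns
    to (post-grouping); it is recomputed whenever records change.
    """

    records: list[AlignmentRecord]
    ref_lengths: dict[str, int]
    grouping: OrganismGrouping
    read_targets: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        records: Iterable[AlignmentRecord],
        ref_lengths: Mapping[str, int],
        grouping: OrganismGrouping | None = None,
    ) -> "AlignmentTable":
        records = list(records)
        ref_lengths = dict(ref_lengths)
        for rec in records:
            if rec.ref_id not in ref_lengths:
                raise SamParseError(
                    f"alignment to {rec.ref_id!r} but no length is known for it"
                )
        if grouping is None:
            grouping = OrganismGrouping.trivial(ref_lengths)
        grouping = grouping.with_lengths(ref_lengths)
        targets: dict[str, set[str]] = {}
        for rec in records:
            targets.setdefault(rec.read_id, set()).add(grouping.organism_of(rec.ref_id))
        return cls(
            records=records,
            ref_lengths=ref_lengths,
            grouping=grouping,
            read_targets={r: frozenset(t) for r, t in targets.items()},
        )

    # -- convenience views -------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_reads(self) -> int:
        return len(self.read_targets)

    def organisms(self) -> list[str]:
        """Organism ids with at least one alignment, sorted."""
        return sorted({self.grouping.organism_of(r.ref_id) for r in self.records})

    def member_sequences(self, organism: str) -> list[str]:
        return sorted(
            s for s in self.ref_lengths if self.grouping.organism_of(s) == organism
        )

    def records_of(self, organism: str) -> list[AlignmentRecord]:
        recs = [
            r for r in self.records if self.grouping.organism_of(r.ref_id) == organism
        ]
        if not recs:
            raise UnknownOrganismError(organism)
        return recs

    def reads_of(self, organism: str) -> set[str]:
        return {r for r, t in self.read_targets.items() if organism in t}

    def unique_reads_of(self, organism: str) -> set[str]:
        """Reads whose only organism target is ``organism``."""
        return {
            r for r, t in self.read_targets.items() if t == frozenset({organism})
        }

    def _rebuild(self, records: list[AlignmentRecord]) -> "AlignmentTable":
        return AlignmentTable.build(records, self.ref_lengths, self.grouping)


def _edit_distance_of(seg: "pysam.AlignedSegment", warned: list[bool]) -> int:
    if seg.has_tag("NM"):
        return int(seg.get_tag("NM"))
    # fall back to explicit mismatch ops in an extended CIGAR (op 8 == 'X')
    if seg.cigartuples and any(op == 8 for op, _ in seg.cigartuples):
        return sum(n for op, n in seg.cigartuples if op == 8)
    if not warned[0]:
        logger.warning(
            "no NM tag or X CIGAR ops found; recording edit distance 0 "
            "(mapping error rates will be underestimated)"
        )
        warned[0] = True
    return 0


def parse_sam(
    source: str | Path,
    grouping: OrganismGrouping | None = None,
) -> AlignmentTable:
    """Parse a SAM/BAM file into an :class:`AlignmentTable`.

    All mapped alignment lines are kept (including secondary/supplementary
    placements — multi-mapping evidence is required downstream); unmapped
    lines are dropped. Reference lengths come from ``@SQ`` header lines.
    """
    try:
        fh = pysam.AlignmentFile(str(source), "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise SamParseError(f"cannot open SAM input {source!r}: {exc}") from exc
    with fh:
        ref_lengths = {
            name: length for name, length in zip(fh.references, fh.lengths)
        }
        records: list[AlignmentRecord] = []
        warned = [False]
        idx = 0
        try:
            for seg in fh:
                idx += 1
                if seg.is_unmapped:
                    continue
                aln_len = seg.reference_length
                if aln_len is None or aln_len <= 0:
                    raise SamParseError(
                        f"mapped record {idx} ({seg.query_name}) has no usable CIGAR"
                    )
                records.append(
                    AlignmentRecord(
                        read_id=seg.query_name,
                        ref_id=seg.reference_name,
                        pos=seg.reference_start,
                        aln_len=int(aln_len),
                        edit_distance=_edit_distance_of(seg, warned),
                    )
                )
        except SamParseError:
            raise
        except (ValueError, OSError) as exc:
            raise SamParseError(f"malformed SAM record {idx + 1}: {exc}") from exc
    if not ref_lengths and records:
        raise SamParseError("SAM input has alignments but no @SQ header lines")
    return AlignmentTable.build(records, ref_lengths, grouping)


def filter_promiscuous_reads(table: AlignmentTable, max_targets: int = 50) -> AlignmentTable:
    """Drop reads aligning to more than ``max_targets`` distinct organisms.

    Such reads typically originate from highly conserved regions (e.g. rRNA
    operons) shared across many genomes; they carry no organism-level signal
    and can swamp the faint evidence for low-abundance community members.
    The threshold is inclusive: a read with exactly ``max_targets`` targets
    is retained.
    """
    if max_targets < 1:
        raise ValueError("max_targets must be >= 1")
    bad = {r for r, t in table.read_targets.items() if len(t) > max_targets}
    if not bad:
        return table
    kept = [rec for rec in table.records if rec.read_id not in bad]
    logger.info("promiscuous-read filter: dropped %d reads", len(bad))
    return table._rebuild(kept)


def filter_low_support_refs(table: AlignmentTable, min_unique_reads: int = 10) -> AlignmentTable:
    """Drop organisms supported by fewer than ``min_unique_reads`` unique reads.

    A read is *unique* for an organism when that organism is its only target
    (after any prior filtering). Alignments of dropped organisms are removed
    and ``read_targets`` recomputed in a single pass (not to fixpoint).
    """
    if min_unique_reads < 0:
        raise ValueError("min_unique_reads must be >= 0")
    if min_unique_reads == 0:
        return table
    unique_counts: dict[str, int] = {}
    for targets in table.read_targets.values():
        if len(targets) == 1:
            (org,) = targets
            unique_counts[org] = unique_counts.get(org, 0) + 1
    drop = {
        org
        for org in table.organisms()
        if unique_counts.get(org, 0) < min_unique_reads
    }
    if not drop:
        return table
    kept = [
        rec
        for rec in table.records
        if table.grouping.organism_of(rec.ref_id) not in drop
    ]
    logger.info(
        "low-support filter: dropped %d organisms (< %d unique reads)",
        len(drop),
        min_unique_reads,
    )
    return table._rebuild(kept)


def mapping_error_rate(table: AlignmentTable, organism: str) -> float:
    """Mean per-base edit distance of all alignments to ``organism``.

    High values (e.g. above ~0.1) indicate that the reference diverges
    substantially from the sequenced organism.
    """
    recs = table.records_of(organism)
    return float(sum(r.edit_distance / r.aln_len for r in recs) / len(recs))
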