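"""Synthetic metagenomic communities with controlled ground truth.

Emulates the inputs the profiler expects: several sample organisms at
staggered sequencing depths, reference genomes sharing a controllable
fraction of each organism's sequence (so the true GDV of every reference is
known by construction), uniform read sampling with substitution errors, and
the resulting multi-mapping SAM alignments.

Alignments are produced by coordinate bookkeeping against the planted
shared-block layout rather than by running a mapper, keeping every test
hermetic. Shared regions are contiguous blocks (default 10) so the
low-coverage spacing model sees realistic gap structure. Indels and quality
strings are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment_io import AlignmentRecord, AlignmentTable, OrganismGrouping

__all__ = [
    "OrganismSpec",
    "ReferenceSpec",
    "CommunitySpec",
    "DerivedReference",
    "ReadSet",
    "TruthTable",
    "SimulationResult",
    "make_genome",
    "derive_reference",
    "sample_reads",
    "align_reads",
    "simulate_community",
    "write_sam",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_READ_LENGTH = 100
DEFAULT_BASE_ERROR_RATE = 0.005
DEFAULT_DIVERGENCE = 0.02
DEFAULT_N_BLOCKS = 10
DEFAULT_MIN_OVERLAP_FRACTION = 0.9


@dataclass
class OrganismSpec:
    name: str
    genome_length: int
    depth: float
    read_length: int = DEFAULT_READ_LENGTH
    base_error_rate: float = DEFAULT_BASE_ERROR_RATE

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"organism {self.name}: depth must be > 0")
        if not 0 < self.read_length < self.genome_length:
            raise ValueError(
                f"organism {self.name}: read_length must be in (0, genome_length)"
            )
        if not 0 <= self.base_error_rate < 1:
            raise ValueError(f"organism {self.name}: bad base_error_rate")


@dataclass
class ReferenceSpec:
    ref_id: str
    organism: str
    shared_fraction: float
    divergence: float = DEFAULT_DIVERGENCE
    n_blocks: int = DEFAULT_N_BLOCKS
    block_seed: int | None = None  # share a layout between references

    def __post_init__(self) -> None:
        if not 0 < self.shared_fraction <= 1:
            raise ValueError(f"reference {self.ref_id}: shared_fraction must be in (0,1]")
        if not 0 <= self.divergence < 1:
            raise ValueError(f"reference {self.ref_id}: bad divergence")


@dataclass
class CommunitySpec:
    organisms: list[OrganismSpec]
    references: list[ReferenceSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        names = {o.name for o in self.organisms}
        if len(names) != len(self.organisms):
            raise ValueError("duplicate organism names")
        for ref in self.references:
            if ref.organism not in names:
                raise ValueError(
                    f"reference {ref.ref_id} points at unknown organism {ref.organism!r}"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "CommunitySpec":
        organisms = [OrganismSpec(**o) for o in data["organisms"]]
        references = [ReferenceSpec(**r) for r in data["references"]]
        return cls(organisms=organisms, references=references, seed=int(data.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunitySpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DerivedReference:
    """A reference genome derived from an organism genome.

    ``blocks`` is a (k, 2) array of [start, end) intervals copied from the
    organism (reference and organism share coordinates); the complement is
    fresh random sequence. ``sub_positions`` are the planted substitution
    sites inside shared blocks, sorted.
    """

    ref_id: str
    organism: str
    seq: np.ndarray
    blocks: np.ndarray
    sub_positions: np.ndarray

    @property
    def shared_bases(self) -> int:
        return int((self.blocks[:, 1] - self.blocks[:, 0]).sum())

    @property
    def true_gdv(self) -> float:
        return self.shared_bases / self.seq.size

    @property
    def mean_identity(self) -> float:
        return 1.0 - self.sub_positions.size / max(self.shared_bases, 1)


@dataclass
class ReadSet:
    organism: str
    read_length: int
    starts: np.ndarray  # (n,)
    err_read: np.ndarray  # flat read index per error
    err_off: np.ndarray  # flat offset-in-read per error

    @property
    def n_reads(self) -> int:
        return int(self.starts.size)

    def read_ids(self) -> list[str]:
        return [f"{self.organism}|r{i:07d}" for i in range(self.n_reads)]


@dataclass
class TruthTable:
    organisms: pd.DataFrame  # organism, genome_length, depth, abundance
    references: pd.DataFrame  # ref_id, organism, true_gdv, mean_identity
    reads: pd.DataFrame  # read_id, organism, start


@dataclass
class SimulationResult:
    spec: CommunitySpec
    genomes: dict[str, np.ndarray]
    references: dict[str, DerivedReference]
    reads: dict[str, ReadSet]
    alignments: list[dict]
    truth: TruthTable

    @property
    def ref_lengths(self) -> dict[str, int]:
        return {r: ref.seq.size for r, ref in self.references.items()}

    def grouping(self) -> OrganismGrouping:
        return OrganismGrouping.trivial(self.ref_lengths)

    def to_alignment_table(self) -> AlignmentTable:
        records = [
            AlignmentRecord(
                read_id=a["read_id"],
                ref_id=a["ref_id"],
                pos=a["pos"],
                aln_len=a["aln_len"],
                edit_distance=a["nm"],
            )
            for a in self.alignments
        ]
        return AlignmentTable.build(records, self.ref_lengths, self.grouping())

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "references": outdir / "references.fasta",
            "sam": outdir / "alignments.sam",
            "grouping": outdir / "grouping.tsv",
            "truth_organisms": outdir / "truth_organisms.tsv",
            "truth_references": outdir / "truth_references.tsv",
            "truth_reads": outdir / "truth_reads.tsv",
        }
        write_fasta({r: ref.seq for r, ref in self.references.items()}, paths["references"])
        write_sam(self.alignments, self.ref_lengths, paths["sam"])
        with open(paths["grouping"], "w") as fh:
            for ref_id in self.references:
                fh.write(f"{ref_id}\t{ref_id}\n")
        self.truth.organisms.to_csv(paths["truth_organisms"], sep="\t", index=False)
        self.truth.references.to_csv(paths["truth_references"], sep="\t", index=False)
        self.truth.reads.to_csv(paths["truth_reads"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_genome(length: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d.-uniform nucleotide sequence as 0..3 codes."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _block_layout(
    length: int, shared_fraction: float, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    shared = int(shared_fraction * length)  # floor: exactly this many shared bases
    if shared >= length:
        return np.array([[0, length]], dtype=np.int64)
    k = max(1, min(n_blocks, shared))
    lens = np.full(k, shared // k, dtype=np.int64)
    lens[: shared % k] += 1
    # Dirichlet gap lengths scatter the blocks; near-equal gaps would place
    # every reference's blocks at the same periodic positions
    total_gap = length - shared
    gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * total_gap).astype(np.int64)
    gaps[-1] += total_gap - gaps.sum()
    blocks = np.empty((k, 2), dtype=np.int64)
    cursor = 0
    for i in range(k):
        cursor += gaps[i]
        blocks[i] = (cursor, cursor + lens[i])
        cursor += lens[i]
    return blocks


def derive_reference(
    ref_id: str,
    organism: str,
    genome: np.ndarray,
    shared_fraction: float,
    divergence: float,
    rng: np.random.Generator,
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_rng: np.random.Generator | None = None,
) -> DerivedReference:
    """Reference sharing contiguous blocks of ``genome`` at rate ``divergence``.

    The reference has the same length as the genome; shared blocks are copied
    in place (so coordinates agree) with i.i.d. substitutions at
    ``divergence``, and the complement is replaced by fresh random sequence.
    ``block_rng`` lets two references share an identical block layout.
    """
    length = genome.size
    blocks = _block_layout(length, shared_fraction, n_blocks, block_rng or rng)
    seq = make_genome(length, rng)  # complement: fresh random sequence
    sub_positions = []
    for start, end in blocks:
        seq[start:end] = genome[start:end]
        if divergence > 0:
            hits = np.nonzero(rng.random(end - start) < divergence)[0] + start
            if hits.size:
                seq[hits] = (seq[hits] + rng.integers(1, 4, size=hits.size)) % 4
                sub_positions.append(hits)
    subs = (
        np.sort(np.concatenate(sub_positions))
        if sub_positions
        else np.array([], dtype=np.int64)
    )
    return DerivedReference(
        ref_id=ref_id, organism=organism, seq=seq, blocks=blocks, sub_positions=subs
    )


def sample_reads(
    organism: str,
    genome_length: int,
    depth: float,
    read_length: int,
    base_error_rate: float,
    rng: np.random.Generator,
) -> ReadSet:
    """Uniform-start reads at the requested mean depth.

    Read count is Poisson(depth * L / read_length); substitution errors are
    i.i.d. per base (error offsets drawn with replacement; duplicates are
    negligible at realistic rates).
    """
    n = int(rng.poisson(depth * genome_length / read_length))
    starts = rng.integers(0, genome_length - read_length + 1, size=n, dtype=np.int64)
    if base_error_rate > 0 and n > 0:
        k = rng.binomial(read_length, base_error_rate, size=n)
        err_read = np.repeat(np.arange(n, dtype=np.int64), k)
        err_off = rng.integers(0, read_length, size=int(k.sum()), dtype=np.int64)
    else:
        err_read = np.array([], dtype=np.int64)
        err_off = np.array([], dtype=np.int64)
    return ReadSet(
        organism=organism,
        read_length=read_length,
        starts=starts,
        err_read=err_read,
        err_off=err_off,
    )


def align_reads(
    reads: ReadSet,
    ref: DerivedReference,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
) -> list[dict]:
    """Place each read on the reference wherever the shared blocks allow.

    A read is emitted when at least ``min_overlap_fraction`` of it lies in a
    single shared block (emulating a mapper's clipping tolerance); the
    alignment is clipped to the block and NM counts planted substitutions
    plus read errors inside the aligned span.
    """
    if reads.organism != ref.organism:
        return []
    n = reads.n_reads
    if n == 0:
        return []
    rl = reads.read_length
    s = reads.starts
    e = s + rl
    b0, b1 = ref.blocks[:, 0], ref.blocks[:, 1]

    def overlaps(j: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        valid = (j >= 0) & (j < len(b0))
        jj = np.clip(j, 0, len(b0) - 1)
        a = np.maximum(s, b0[jj])
        b = np.minimum(e, b1[jj])
        ov = np.where(valid, np.maximum(b - a, 0), 0)
        return ov, a, b

    j = np.searchsorted(b0, s, side="right") - 1
    ov1, a1, bb1 = overlaps(j)
    ov2, a2, bb2 = overlaps(j + 1)
    use2 = ov2 > ov1
    ov = np.where(use2, ov2, ov1)
    a = np.where(use2, a2, a1)
    b = np.where(use2, bb2, bb1)
    keep = ov >= min_overlap_fraction * rl
    if not keep.any():
        return []

    # planted substitutions inside each aligned span
    planted = np.searchsorted(ref.sub_positions, b) - np.searchsorted(
        ref.sub_positions, a
    )
    # read errors inside each aligned span
    err_in_span = np.zeros(n, dtype=np.int64)
    if reads.err_read.size:
        lo = (a - s)[reads.err_read]
        hi = (b - s)[reads.err_read]
        mask = (reads.err_off >= lo) & (reads.err_off < hi)
        if mask.any():
            err_in_span = np.bincount(reads.err_read[mask], minlength=n)

    ids = reads.read_ids()
    out = []
    for i in np.nonzero(keep)[0]:
        out.append(
            {
                "read_id": ids[i],
                "ref_id": ref.ref_id,
                "pos": int(a[i]),
                "aln_len": int(ov[i]),
                "nm": int(planted[i] + err_in_span[i]),
                "clip_left": int(a[i] - s[i]),
                "clip_right": int(e[i] - b[i]),
                "read_len": rl,
            }
        )
    return out


def simulate_community(
    spec: CommunitySpec,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
) -> SimulationResult:
    """Run the full generator: genomes, references, reads, alignments, truth."""
    rng = np.random.default_rng(spec.seed)
    genomes = {o.name: make_genome(o.genome_length, rng) for o in spec.organisms}
    references: dict[str, DerivedReference] = {}
    for r in spec.references:
        block_rng = (
            np.random.default_rng(r.block_seed) if r.block_seed is not None else None
        )
        references[r.ref_id] = derive_reference(
            r.ref_id,
            r.organism,
            genomes[r.organism],
            r.shared_fraction,
            r.divergence,
            rng,
            n_blocks=r.n_blocks,
            block_rng=block_rng,
        )
    reads = {
        o.name: sample_reads(
            o.name, o.genome_length, o.depth, o.read_length, o.base_error_rate, rng
        )
        for o in spec.organisms
    }
    alignments: list[dict] = []
    for o in spec.organisms:
        for r in spec.references:
            if r.organism != o.name:
                continue
            alignments.extend(
                align_reads(reads[o.name], references[r.ref_id], min_overlap_fraction)
            )

    total_depth = sum(o.depth for o in spec.organisms)
    truth = TruthTable(
        organisms=pd.DataFrame(
            {
                "organism": [o.name for o in spec.organisms],
                "genome_length": [o.genome_length for o in spec.organisms],
                "depth": [o.depth for o in spec.organisms],
                "abundance": [o.depth / total_depth for o in spec.organisms],
            }
        ),
        references=pd.DataFrame(
            {
                "ref_id": [r.ref_id for r in spec.references],
                "organism": [r.organism for r in spec.references],
                "true_gdv": [references[r.ref_id].true_gdv for r in spec.references],
                "mean_identity": [
                    references[r.ref_id].mean_identity for r in spec.references
                ],
            }
        ),
        reads=pd.DataFrame(
            {
                "read_id": [rid for rs in reads.values() for rid in rs.read_ids()],
                "organism": [
                    rs.organism for rs in reads.values() for _ in range(rs.n_reads)
                ],
                "start": np.concatenate(
                    [rs.starts for rs in reads.values()]
                    or [np.array([], dtype=np.int64)]
                ),
            }
        ),
    )
    return SimulationResult(
        spec=spec,
        genomes=genomes,
        references=references,
        reads=reads,
        alignments=alignments,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def write_fasta(seqs: dict[str, np.ndarray], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = decode(seqs[name])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_sam(
    alignments: list[dict], ref_lengths: dict[str, int], path: str | Path
) -> None:
    """Plain-text SAM with soft-clip CIGARs and NM tags (SEQ omitted)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref_id, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{ref_id}\tLN:{length}\n")
        for a in alignments:
            cigar = ""
            if a.get("clip_left", 0):
                cigar += f"{a['clip_left']}S"
            cigar += f"{a['aln_len']}M"
            if a.get("clip_right", 0):
                cigar += f"{a['clip_right']}S"
            fh.write(
                f"{a['read_id']}\t0\t{a['ref_id']}\t{a['pos'] + 1}\t255\t{cigar}"
                f"\t*\t0\t0\t*\t*\tNM:i:{a['nm']}\n"
            )
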