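"""Core in-memory containers shared across pipeline stages.

Reads are held as plain records (id, sequence, Phred+33 quality string);
alignments are held pre-oriented so that downstream damage counting always
sees the read 5'->3' as it came off the sequencer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string."""
    return seq.translate(_COMP)[::-1]


@dataclass
class Read:
    read_id: str
    sequence: str
    quality: str

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_phred(self) -> float:
        if not self.quality:
            return 0.0
        return sum(ord(c) - 33 for c in self.quality) / len(self.quality)


@dataclass
class ReadSet:
    """An ordered collection of reads for one sample.

    ``history`` records per-stage read counts so that filter accounting can be
    audited (input = output + sum of removals at every stage).
    """

    sample_id: str
    reads: list[Read] = field(default_factory=list)
    history: list[tuple[str, dict[str, int]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def log_stage(self, stage: str, counts: dict[str, int]) -> None:
        self.history.append((stage, dict(counts)))

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")

    @classmethod
    def from_fastq(cls, path, sample_id: str | None = None) -> "ReadSet":
        from Bio import SeqIO

        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(Read(rec.id, str(rec.seq).upper(), qual))
        return cls(sample_id=sample_id or str(path), reads=reads)


@dataclass
class AlignedRead:
    """One read aligned (ungapped) to a reference, oriented as sequenced.

    ``read_frag`` and ``ref_frag`` are equal-length strings covering the
    aligned portion of the read; ``read_offset`` is the distance (in bases)
    between the read's 5' end and the start of the aligned portion, and
    ``read_length`` is the full read length, so that per-position damage
    profiles can index from the true read termini even for partial alignments.
    """

    read_id: str
    taxon_id: str
    read_frag: str
    ref_frag: str
    read_offset: int = 0
    read_length: int = 0

    def __post_init__(self) -> None:
        if len(self.read_frag) != len(self.ref_frag):
            raise ValueError("aligned read and reference fragments differ in length")
        if self.read_length == 0:
            self.read_length = len(self.read_frag)

    def pairs(self) -> Iterable[tuple[int, int, str, str]]:
        """Yield (dist5, dist3, ref_base, read_base), distances 1-based."""
        L = self.read_length
        for i, (rb, qb) in enumerate(zip(self.ref_frag, self.read_frag)):
            pos = self.read_offset + i
            yield pos + 1, L - pos, rb, qb
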