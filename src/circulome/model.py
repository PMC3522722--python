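"""Core containers shared across the toolkit.

Coordinates are 0-based half-open everywhere inside the package; the I/O
layer converts to the 1-based inclusive convention of GFF3/SAM reports.
Circular molecules are represented by a plain string plus wrap-aware
accessors; the canonical form of a circle is the lexicographically least
rotation over both strands, which makes assembly output comparable across
runs regardless of where the walk happened to start.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_strand(seq: str) -> str:
    """The lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm, O(n))."""
    n = len(s)
    if n == 0:
        return 0
    s2 = s + s
    f = [-1] * (2 * n)
    k = 0
    for j in range(1, 2 * n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T (N excluded from the denominator).

    Raises ValueError when no unambiguous base is present.
    """
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases (all N or empty)")
    return gc / denom


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CircularSequence:
    """A finite circular molecule with wrap-aware access and canonical rotation."""

    seq: str
    id: str = "circle"

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC content in percent, one decimal."""
        return round(100.0 * gc_fraction(self.seq), 1)

    def fetch(self, start: int, length: int) -> str:
        """Substring of the circle starting at `start` (mod L), wrapping as needed."""
        L = len(self.seq)
        if length > L:
            raise ValueError(f"cannot fetch {length} bp from a {L} bp circle")
        start %= L
        end = start + length
        if end <= L:
            return self.seq[start:end]
        return self.seq[start:] + self.seq[: end - L]

    def doubled(self) -> str:
        return self.seq + self.seq

    def canonical(self) -> "CircularSequence":
        """Least rotation over both strands; idempotent."""
        fwd = self.seq
        rc = revcomp(fwd)
        kf = least_rotation(fwd)
        kr = least_rotation(rc)
        rf = fwd[kf:] + fwd[:kf]
        rr = rc[kr:] + rc[:kr]
        return CircularSequence(min(rf, rr), id=self.id)

    def equivalent(self, other: "CircularSequence | str") -> bool:
        """Equality up to rotation and strand."""
        o = other if isinstance(other, CircularSequence) else CircularSequence(other)
        if len(o) != len(self):
            return False
        return self.canonical().seq == o.canonical().seq


@dataclass
class FeatureRecord:
    """A genome annotation in GFF3 convention (1-based inclusive coordinates).

    `type` is drawn from {CDS, tRNA, rRNA, pseudogene, repeat, origin}; unknown
    tokens read from files are kept verbatim (with a warning at parse time).
    Features wrapping the circular origin are encoded as two records sharing a
    `Part_of` attribute, keeping files parseable by standard tools.
    """

    seq_id: str
    type: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "+"
    phase: str = "."
    score: str = "."
    source: str = "circulome"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"feature start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"feature end {self.end} < start {self.start}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end


@dataclass
class Read:
    id: str
    seq: str
    qual: str | None = None
    pair_id: str | None = None
    mate: int = 0  # 0 = unpaired, 1/2 = mate index

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadLibrary:
    """A set of sequencing reads with optional pairing and library metadata."""

    reads: list[Read] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def pairs(self) -> Iterator[tuple[Read, Read]]:
        """Yield (mate1, mate2) tuples grouped by pair_id, in first-seen order."""
        pending: dict[str, Read] = {}
        for r in self.reads:
            if r.pair_id is None:
                continue
            if r.pair_id in pending:
                first = pending.pop(r.pair_id)
                yield (first, r) if first.mate <= r.mate else (r, first)
            else:
                pending[r.pair_id] = r


@dataclass
class AlignmentRecord:
    """A read placement on a (possibly circular) reference.

    `start` is 0-based on the linearized reference; alignments that wrap the
    origin keep start < L and extend past it (consumers re-wrap with mod L).
    """

    read_id: str
    ref_id: str
    start: int
    length: int
    strand: str = "+"
    mapped: bool = True
    multi: bool = False
    mismatches: int = 0
    pair_id: str | None = None
    mate: int = 0
    mate_start: int | None = None
    insert: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class HitRecord:
    """One row of a similarity-search hit table."""

    query_id: str
    subject_id: str
    alignment_length: int
    identity: float
    origin_class: str = "unknown"

    def __post_init__(self):
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")


@dataclass
class HitFilterParams:
    """Per-library minimum alignment length for hit filtering."""

    min_alignment_length: int

    def __post_init__(self):
        if self.min_alignment_length < 1:
            raise ValueError("min_alignment_length must be >= 1")
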