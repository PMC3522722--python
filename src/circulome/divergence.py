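"""Per-gene sequence divergence from pairwise percent identity (PID).

Divergence is defined as 100 minus the pairwise percent identity of a
global alignment, computed by scoring a hit at each column whose two
symbols are identical, divided by the total number of columns. Gap columns
count toward the denominator and never as identical; terminal gaps are
included by default. Nucleotide-level divergence of coding sequences
tracks synonymous change; amino-acid-level divergence (of the translated
sequences) tracks non-synonymous change.

Alignments come from a built-in global aligner (Needleman-Wunsch/Gotoh via
Bio.Align) or are accepted verbatim as aligned FASTA from an external tool.
The affine gap convention is: a gap of length g costs open + (g-1) * extend.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .model import SequenceRecord

_STOPS = {"TAA", "TAG", "TGA"}
_ALT_STARTS = {"ACG", "ATG", "GTG"}


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class PairwiseAlignment:
    """Two gap-padded rows of equal length; degapping recovers the inputs."""

    row_a: str
    row_b: str
    score: float = 0.0
    source: str = "builtin"

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")


def global_align(a, b, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two sequences (strings or SequenceRecords)."""
    params = params or AlignParams()
    sa = a.seq if hasattr(a, "seq") else str(a)
    sb = b.seq if hasattr(b, "seq") else str(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(sa, sb)[0]
    return PairwiseAlignment(row_a=str(aln[0]), row_b=str(aln[1]), score=aln.score)


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical non-gap columns over all columns, as a percent (2 decimals)."""
    n = len(aln.row_a)
    if n == 0:
        raise ValueError("zero-length alignment")
    idents = sum(1 for x, y in zip(aln.row_a, aln.row_b) if x == y and x != "-")
    return round(100.0 * idents / n, 2)


def translate_cds(seq: str, warn_label: str = "") -> str:
    """Translate a CDS with the standard code; ACG/GTG tolerated as start.

    Incomplete terminal codons are trimmed; an internal stop warns and
    truncates; a terminal stop is dropped.
    """
    s = seq[: len(seq) // 3 * 3]
    if len(s) < 3:
        raise ValueError("CDS shorter than one codon")
    prot = str(Seq(s).translate(table=1))
    if s[:3] in _ALT_STARTS:
        prot = "M" + prot[1:]
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        warnings.warn(f"internal stop codon in CDS {warn_label or '?'}; translation truncated", stacklevel=2)
        prot = prot[: prot.index("*")]
    return prot


def gene_divergence(cds_a, cds_b, level: str = "nt", params: AlignParams | None = None) -> float:
    """Divergence (100 - PID) of two coding sequences at nt or aa level."""
    sa = cds_a.seq if hasattr(cds_a, "seq") else str(cds_a)
    sb = cds_b.seq if hasattr(cds_b, "seq") else str(cds_b)
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("CDS must be at least one codon long")
    if level == "aa":
        sa = translate_cds(sa, getattr(cds_a, "id", ""))
        sb = translate_cds(sb, getattr(cds_b, "id", ""))
    elif level != "nt":
        raise ValueError("level must be 'nt' or 'aa'")
    aln = global_align(sa, sb, params)
    return round(100.0 - percent_identity(aln), 2)


@dataclass
class DivergenceRecord:
    """Per-gene divergence for one species pair in one genome compartment."""

    gene_id: str
    species_pair: tuple[str, str]
    genome: str  # 'chloroplast' | 'mitochondrion'
    nt_divergence: float | None = None
    aa_divergence: float | None = None


@dataclass
class DivergenceSummary:
    """Genome-level means (over species-pair means) and cp/mt fold ratios."""

    pair_means: dict = field(default_factory=dict)    # (genome, level, pair) -> mean over genes
    genome_means: dict = field(default_factory=dict)  # (genome, level) -> rounded mean of pair means
    fold: dict = field(default_factory=dict)          # level -> rounded cp/mt ratio


def summarize(records: list[DivergenceRecord]) -> DivergenceSummary:
    """Average genes within each species pair, then pairs within each genome.

    Genome means are rounded to 2 decimals; fold ratios are ratios of the
    rounded genome means, themselves rounded to 2 decimals. Empty cells are
    omitted with a warning rather than raising.
    """
    cells: dict[tuple, list[float]] = {}
    for r in records:
        for level, value in (("nt", r.nt_divergence), ("aa", r.aa_divergence)):
            if value is None:
                continue
            pair = tuple(sorted(r.species_pair))
            cells.setdefault((r.genome, level, pair), []).append(value)

    summary = DivergenceSummary()
    for key, values in cells.items():
        summary.pair_means[key] = mean(values)
    by_genome: dict[tuple, list[float]] = {}
    for (genome, level, _pair), m in summary.pair_means.items():
        by_genome.setdefault((genome, level), []).append(m)
    for key, means in by_genome.items():
        summary.genome_means[key] = round(mean(means), 2)
    for level in ("nt", "aa"):
        cp = summary.genome_means.get(("chloroplast", level))
        mt = summary.genome_means.get(("mitochondrion", level))
        if cp is None and mt is None:
            continue
        if cp is None or mt is None:
            warnings.warn(f"cannot form cp/mt fold ratio at level {level}: missing cell", stacklevel=2)
            continue
        if mt == 0:
            warnings.warn(f"mitochondrial mean is zero at level {level}; fold ratio omitted", stacklevel=2)
            continue
        summary.fold[level] = round(cp / mt, 2)
    return summary


def read_aligned_fasta(records: list[SequenceRecord]) -> PairwiseAlignment:
    """Accept an external two-row aligned FASTA verbatim."""
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned records, got {len(records)}")
    return PairwiseAlignment(row_a=records[0].seq, row_b=records[1].seq, source="external")
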