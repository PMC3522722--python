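"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and FASTQ are parsed directly rather than through Bio.SeqIO because the
contract here is strict: a 4-line FASTQ dialect, and parse errors that name
the offending file and line. Writers are paired with readers and round-trip
to equal values. SAM goes through pysam; hit tables through pandas.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .model import (
    AlignmentRecord,
    FeatureRecord,
    HitFilterParams,
    HitRecord,
    Read,
    ReadLibrary,
    SequenceRecord,
)

logger = logging.getLogger(__name__)

KNOWN_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "pseudogene", "repeat", "origin"}


class ParseError(ValueError):
    """Raised for ill-formed input; carries file and line context."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        loc = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{loc}: {message}")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords (uppercased, U mapped to T)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header_line = None
    rid = None
    chunks: list[str] = []

    def flush():
        if rid is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(path, header_line, f"record '{rid}' has an empty sequence")
        if rid in seen:
            raise ParseError(path, header_line, f"duplicate record id '{rid}'")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, seq=_normalize(seq)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                rid = line[1:].split()[0] if line[1:].split() else ""
                if not rid:
                    raise ParseError(path, lineno, "header with no identifier")
                header_line = lineno
                chunks = []
            else:
                if rid is None:
                    raise ParseError(path, lineno, "sequence data before any '>' header")
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (strict 4-line records)


def _parse_fastq(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    # trailing blank lines are tolerated
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(path, len(lines), "truncated FASTQ record (file length not a multiple of 4 lines)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(path, i + 1, f"expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise ParseError(path, i + 3, "expected '+' separator line")
        if len(seq) != len(qual):
            raise ParseError(path, i + 4, f"sequence and quality lengths differ ({len(seq)} vs {len(qual)})")
        yield i + 1, head[1:].split()[0], _normalize(seq), qual


def read_fastq(path, interleaved: bool = False) -> ReadLibrary:
    """Read a FASTQ file; with interleaved=True consecutive records are mates."""
    reads: list[Read] = []
    for n, (_, rid, seq, qual) in enumerate(_parse_fastq(path)):
        if interleaved:
            pair_id = f"p{n // 2}"
            mate = n % 2 + 1
        else:
            pair_id, mate = None, 0
        reads.append(Read(id=rid, seq=seq, qual=qual, pair_id=pair_id, mate=mate))
    return ReadLibrary(reads=reads, meta={"source": str(path), "interleaved": interleaved})


def read_fastq_pair(path1, path2) -> ReadLibrary:
    """Read a pair of FASTQ files holding mate 1 and mate 2 in lockstep order."""
    r1 = list(_parse_fastq(path1))
    r2 = list(_parse_fastq(path2))
    if len(r1) != len(r2):
        raise ParseError(path2, None, f"mate files differ in record count ({len(r1)} vs {len(r2)})")
    reads: list[Read] = []
    for n, ((_, id1, s1, q1), (_, id2, s2, q2)) in enumerate(zip(r1, r2)):
        pid = f"p{n}"
        reads.append(Read(id=id1, seq=s1, qual=q1, pair_id=pid, mate=1))
        reads.append(Read(id=id2, seq=s2, qual=q2, pair_id=pid, mate=2))
    return ReadLibrary(reads=reads, meta={"source": f"{path1},{path2}"})


def write_fastq(library: ReadLibrary, path) -> None:
    with open(path, "w") as fh:
        for r in library:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3


def _format_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attributes(text: str) -> dict:
    attrs: dict = {}
    if text in (".", ""):
        return attrs
    for item in text.strip(";").split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k] = v
        else:
            attrs[item] = ""
    return attrs


def read_gff3(path) -> list[FeatureRecord]:
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 tab-separated columns, got {len(cols)}")
            seq_id, source, ftype, start, end, score, strand, phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start!r}..{end!r}") from None
            if end_i < start_i:
                raise ParseError(path, lineno, f"end {end_i} < start {start_i}")
            if ftype not in KNOWN_FEATURE_TYPES:
                logger.warning("%s:%d: unknown feature type %r kept verbatim", path, lineno, ftype)
            features.append(
                FeatureRecord(
                    seq_id=seq_id,
                    source=source,
                    type=ftype,
                    start=start_i,
                    end=end_i,
                    score=score,
                    strand=strand,
                    phase=phase,
                    attributes=_parse_attributes(attrs),
                )
            )
    return features


def write_gff3(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        f.source,
                        f.type,
                        str(f.start),
                        str(f.end),
                        f.score,
                        f.strand,
                        f.phase,
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM (read-only subset + minimal writer for the internal mapper)


def read_sam(path) -> list[AlignmentRecord]:
    """Read the QNAME/FLAG/RNAME/POS/CIGAR/TLEN subset of a text SAM file."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                records.append(AlignmentRecord(read_id=aln.query_name, ref_id="*", start=0, length=0, mapped=False))
                continue
            length = aln.reference_length or (aln.query_length or 0)
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name,
                    start=aln.reference_start,
                    length=length,
                    strand="-" if aln.is_reverse else "+",
                    mate=2 if aln.is_read2 else (1 if aln.is_read1 else 0),
                    insert=abs(aln.template_length) if aln.template_length else None,
                    mate_start=aln.next_reference_start if aln.next_reference_start >= 0 else None,
                )
            )
    return records


def write_sam(alignments, ref_lengths: dict, path, reads: dict | None = None) -> None:
    """Write AlignmentRecords as text SAM. `reads` optionally maps id -> sequence."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    ref_index = {name: i for i, name in enumerate(ref_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in alignments:
            a = pysam.AlignedSegment()
            a.query_name = rec.read_id
            flag = 0
            if not rec.mapped:
                flag |= 4
            if rec.strand == "-":
                flag |= 16
            if rec.mate == 1:
                flag |= 1 | 64
            elif rec.mate == 2:
                flag |= 1 | 128
            a.flag = flag
            if rec.mapped:
                a.reference_id = ref_index[rec.ref_id]
                a.reference_start = rec.start
                a.cigarstring = f"{rec.length}M"
                a.mapping_quality = 0 if rec.multi else 60
            if reads and rec.read_id in reads:
                a.query_sequence = reads[rec.read_id]
            if rec.insert is not None:
                a.template_length = rec.insert
            out.write(a)


# ---------------------------------------------------------------------------
# Hit tables and filtering

_HIT_COLUMNS = ["query_id", "subject_id", "identity", "alignment_length", "origin_class"]


def read_hit_table(path) -> list[HitRecord]:
    """TSV hit table: query, subject, identity, length[, origin_class]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 4:
        df[4] = "unknown"
    df.columns = _HIT_COLUMNS
    return [
        HitRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            alignment_length=int(r.alignment_length),
            identity=float(r.identity),
            origin_class=str(r.origin_class),
        )
        for r in df.itertuples()
    ]


def write_hit_table(hits, path) -> None:
    df = pd.DataFrame(
        [(h.query_id, h.subject_id, h.identity, h.alignment_length, h.origin_class) for h in hits]
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def filter_hits(hits: list[HitRecord], params: HitFilterParams) -> list[HitRecord]:
    """Retain hits with alignment_length >= the per-library minimum.

    The minimum is inclusive ("minimum alignment filter of 60" keeps length-60
    hits). Order is preserved and the input list is not mutated.
    """
    return [h for h in hits if h.alignment_length >= params.min_alignment_length]


# ---------------------------------------------------------------------------
# Config


def load_config(path) -> dict:
    """Declarative YAML config keyed by module name; missing file -> empty dict."""
    p = Path(path)
    if not p.exists():
        return {}
    with open(p) as fh:
        data = yaml.safe_load(fh)
    return data or {}
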