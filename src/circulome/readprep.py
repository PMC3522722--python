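"""Trim-and-cut preprocessing of long reads into offset short fragments.

Long mate-pair reads are first trimmed, then the remainder is sliced into
overlapping fragments of a uniform output length whose start positions step
by a fixed offset. Running the cutter with two different trim lengths and
pooling the output is how a 75 bp library is turned into a deep 35 bp
library suitable for a small-offset overlap assembly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import Read, ReadLibrary

logger = logging.getLogger(__name__)


@dataclass
class CutParams:
    """trim_length: bases removed per read (3' end by default);
    out_readlength: length of each emitted fragment;
    start_offset: step between successive fragment starts."""

    trim_length: int
    out_readlength: int
    start_offset: int

    def __post_init__(self):
        if self.trim_length < 0:
            raise ValueError("trim_length must be >= 0")
        if self.out_readlength < 1:
            raise ValueError("out_readlength must be >= 1")
        if self.start_offset < 1:
            raise ValueError("start_offset must be >= 1")


def fragment_count(read_length: int, params: CutParams) -> int:
    """Closed-form number of fragments emitted per read of the given length.

    With working length W = read_length - trim_length, fragments start at
    0, step, 2*step, ... while start + out_readlength <= W:
    count = floor((W - out_readlength)/step) + 1 when W >= out_readlength,
    else 0.
    """
    w = read_length - params.trim_length
    if w < params.out_readlength:
        return 0
    return (w - params.out_readlength) // params.start_offset + 1


def trim_and_cut(reads: ReadLibrary, params: CutParams, trim_end: str = "3p") -> ReadLibrary:
    """Trim each read then slice the remainder into offset fragments.

    Fragment ids encode the parent read and slice index; pairing metadata is
    propagated to every fragment. Reads too short to yield any fragment are
    counted and logged, never an error.
    """
    if trim_end not in ("3p", "5p"):
        raise ValueError("trim_end must be '3p' or '5p'")
    out: list[Read] = []
    n_empty = 0
    for read in reads:
        keep = max(0, len(read.seq) - params.trim_length)
        if trim_end == "3p":
            work = read.seq[:keep]
            wq = read.qual[:keep] if read.qual else None
        else:
            work = read.seq[len(read.seq) - keep :]
            wq = read.qual[len(read.qual) - keep :] if read.qual else None
        n = fragment_count(len(read.seq), params)
        if n == 0:
            n_empty += 1
            continue
        for i in range(n):
            s = i * params.start_offset
            e = s + params.out_readlength
            out.append(
                Read(
                    id=f"{read.id}|c{i}",
                    seq=work[s:e],
                    qual=wq[s:e] if wq else None,
                    pair_id=read.pair_id,
                    mate=read.mate,
                )
            )
    if n_empty:
        logger.info("trim_and_cut: %d reads too short to yield fragments", n_empty)
    meta = dict(reads.meta)
    meta.update(
        {
            "cut": {
                "trim_length": params.trim_length,
                "out_readlength": params.out_readlength,
                "start_offset": params.start_offset,
                "n_parent_reads": len(reads),
                "n_dropped": n_empty,
            }
        }
    )
    return ReadLibrary(reads=out, meta=meta)
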