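"""Synthetic circular genomes, read libraries and edited transcripts.

The generator emulates the study conditions of a plant-organelle sequencing
project: a circular molecule carrying planted direct/inverted repeat pairs,
an AT-rich replication-origin window, and a complement of CDS/tRNA/rRNA
genes; short-read libraries matching the three deposited library designs
(36 bp paired-end with ~390 bp inserts, 75 bp mate-pair with ~3 kb inserts
plus a ~220 bp shadow component, and 100 bp paired-end with ~350 bp
inserts); and transcript reads carrying C-to-U edits at known sites. Every
output is a pure function of (spec, seed) and is accompanied by a truth
table so downstream modules can be tested against known coordinates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import CircularSequence, FeatureRecord, Read, ReadLibrary, SequenceRecord, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


class PackingError(ValueError):
    """Raised when the requested features cannot be placed without overlap."""


@dataclass
class RepeatPlan:
    kind: str  # "direct" | "inverted"
    length: int
    positions: tuple[int, int] | None = None  # approximate copy starts; None = random


@dataclass
class GenePlan:
    type: str  # CDS | tRNA | rRNA
    count: int
    length_range: tuple[int, int]


@dataclass
class GenomeSpec:
    """Blueprint for a synthetic circular genome.

    Defaults mirror a desk-scale plant mitochondrial architecture: 45% GC
    background, a couple of kb-scale repeat pairs, an 80%+ AT origin window,
    and a mixed gene complement.
    """

    length: int = 50_000
    gc_background: float = 0.45
    repeats: list[RepeatPlan] = field(default_factory=list)
    origin: tuple[int, int, float] | None = None  # (position, width, AT fraction)
    genes: list[GenePlan] = field(default_factory=list)
    motif_genes: int = 0  # plant the upstream motif before this many CDS
    motif: str = "GGAGG"
    seed: int = 0


@dataclass
class LibrarySpec:
    """A paired-read library design.

    Insert sd defaults to 10% of the mean; mate-pair libraries are RF
    oriented, paired-end FR. `shadow_fraction` models the short-insert
    contaminant component of mate-pair preparations.
    """

    read_length: int
    insert_mean: float
    n_pairs: int
    insert_sd: float | None = None
    orientation: str = "FR"
    error_rate: float = 0.0
    shadow_fraction: float = 0.0
    shadow_insert_mean: float | None = None
    shadow_insert_sd: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.insert_sd is None:
            self.insert_sd = 0.1 * self.insert_mean
        if self.shadow_fraction and self.shadow_insert_sd is None and self.shadow_insert_mean:
            self.shadow_insert_sd = 0.1 * self.shadow_insert_mean
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0 <= self.shadow_fraction <= 1:
            raise ValueError("shadow_fraction must be in [0, 1]")
        if self.orientation not in ("FR", "RF"):
            raise ValueError("orientation must be FR or RF")


# Library designs used throughout the examples and tests: the three deposited
# libraries of the study (sizes are per-library read counts in the original
# data; n_pairs here is chosen per experiment).
PE36_SPEC = dict(read_length=36, insert_mean=390.0, orientation="FR")
MP75_SPEC = dict(
    read_length=75,
    insert_mean=3000.0,
    orientation="RF",
    shadow_fraction=0.05,
    shadow_insert_mean=220.0,
)
PE100_SPEC = dict(read_length=100, insert_mean=350.0, orientation="FR")


@dataclass
class TruthTable:
    """Ground truth for everything planted or simulated."""

    repeats: list[dict] = field(default_factory=list)
    features: list[FeatureRecord] = field(default_factory=list)
    origin: tuple[int, int, float] | None = None
    motif_gene_ids: list[str] = field(default_factory=list)
    read_sources: dict[str, tuple[int, int, str]] = field(default_factory=dict)  # id -> (start, length, strand)
    edit_coverage: dict[tuple[str, int], int] = field(default_factory=dict)
    edit_counts: dict[tuple[str, int], int] = field(default_factory=dict)


def _random_bases(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _at_window(rng, width: int, at_fraction: float) -> np.ndarray:
    """A window with an exact AT count (rounded), randomly arranged."""
    n_at = round(at_fraction * width)
    bases = np.empty(width, dtype=_BASES.dtype)
    at = rng.choice(np.array(["A", "T"]), size=n_at)
    gc = rng.choice(np.array(["G", "C"]), size=width - n_at)
    order = rng.permutation(width)
    bases[order[:n_at]] = at
    bases[order[n_at:]] = gc
    return bases


def _place(rng, L: int, want: int, taken: list[tuple[int, int]], fixed: int | None, label: str, tries: int = 2000):
    """Find a start for an interval of `want` bp avoiding `taken` (no wrapping)."""

    def ok(s):
        if s < 0 or s + want > L:
            return False
        return all(s + want <= a or s >= b for a, b in taken)

    if fixed is not None:
        if not ok(fixed):
            conflicts = [iv for iv in taken if not (fixed + want <= iv[0] or fixed >= iv[1])]
            raise PackingError(f"cannot place {label} ({want} bp) at {fixed}: conflicts {conflicts}")
        taken.append((fixed, fixed + want))
        return fixed
    for _ in range(tries):
        s = int(rng.integers(0, L - want)) if L > want else 0
        if ok(s):
            taken.append((s, s + want))
            return s
    raise PackingError(f"cannot place {label} ({want} bp) after {tries} tries; planned features exceed genome space")


def _make_cds(rng, length: int) -> str:
    """An open reading frame: ATG + non-stop codons + a stop codon."""
    n_codons = max(3, length // 3)
    body = rng.choice(np.array(_NONSTOP_CODONS), size=n_codons - 2)
    stop = _STOPS[int(rng.integers(0, 3))]
    return "ATG" + "".join(body) + stop


def generate_genome(spec: GenomeSpec) -> tuple[CircularSequence, list[FeatureRecord], TruthTable]:
    """Build a circular genome with planted repeats, origin and genes.

    Repeat copies are exact (direct: same strand; inverted: reverse
    complement); the origin window hits its requested AT fraction within
    rounding; everything is deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    planned = sum(r.length * 2 for r in spec.repeats) + sum(
        g.count * (g.length_range[1] + 25) for g in spec.genes
    )
    if spec.origin:
        planned += spec.origin[1]
    if planned > L:
        raise PackingError(f"planned feature length {planned} exceeds genome length {L}")

    arr = _random_bases(rng, L, spec.gc_background)
    taken: list[tuple[int, int]] = []
    truth = TruthTable(origin=spec.origin)
    features: list[FeatureRecord] = []

    if spec.origin:
        pos, width, at_frac = spec.origin
        s = _place(rng, L, width, taken, pos, "origin")
        arr[s : s + width] = _at_window(rng, width, at_frac)
        features.append(
            FeatureRecord(seq_id="genome", type="origin", start=s + 1, end=s + width, attributes={"ID": "oriC"})
        )

    for i, rp in enumerate(spec.repeats):
        if rp.kind not in ("direct", "inverted"):
            raise ValueError(f"unknown repeat kind {rp.kind!r}")
        fixed_a, fixed_b = rp.positions if rp.positions else (None, None)
        sa = _place(rng, L, rp.length, taken, fixed_a, f"repeat{i}A")
        sb = _place(rng, L, rp.length, taken, fixed_b, f"repeat{i}B")
        copy_a = _random_bases(rng, rp.length, spec.gc_background)
        arr[sa : sa + rp.length] = copy_a
        if rp.kind == "direct":
            arr[sb : sb + rp.length] = copy_a
        else:
            rc = np.array(list(revcomp("".join(copy_a))))
            arr[sb : sb + rp.length] = rc
        truth.repeats.append({"kind": rp.kind, "start_a": sa, "start_b": sb, "length": rp.length})
        pair_id = f"{'DR' if rp.kind == 'direct' else 'IR'}{i}"
        for copy, s in (("A", sa), ("B", sb)):
            features.append(
                FeatureRecord(
                    seq_id="genome",
                    type="repeat",
                    start=s + 1,
                    end=s + rp.length,
                    attributes={"ID": f"{pair_id}{copy}", "kind": rp.kind, "pair": pair_id},
                )
            )

    n_cds_planted = 0
    for gp in spec.genes:
        for j in range(gp.count):
            length = int(rng.integers(gp.length_range[0], gp.length_range[1] + 1))
            if gp.type == "CDS":
                seq = _make_cds(rng, length)
                length = len(seq)
            else:
                seq = "".join(_random_bases(rng, length, spec.gc_background))
            # reserve a 25 bp upstream margin so motif planting never collides
            s_marg = _place(rng, L, length + 25, taken, None, f"{gp.type}{j}")
            s = s_marg + 25
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gid = f"{gp.type.lower()}{len(features)}"
            if strand == "+":
                arr[s : s + length] = np.array(list(seq))
            else:
                arr[s : s + length] = np.array(list(revcomp(seq)))
            feat = FeatureRecord(
                seq_id="genome",
                type=gp.type,
                start=s + 1,
                end=s + length,
                strand=strand,
                phase="0" if gp.type == "CDS" else ".",
                attributes={"ID": gid},
            )
            features.append(feat)
            if gp.type == "CDS" and n_cds_planted < spec.motif_genes:
                gap = int(rng.integers(3, 11))
                m = spec.motif if strand == "+" else revcomp(spec.motif)
                if strand == "+":
                    ms = s - gap - len(spec.motif)
                    arr[ms : ms + len(spec.motif)] = np.array(list(m))
                else:
                    ms = s + length + gap
                    arr[ms : ms + len(spec.motif)] = np.array(list(m))
                truth.motif_gene_ids.append(gid)
                n_cds_planted += 1

    genome = CircularSequence("".join(arr), id="genome")
    truth.features = features
    return genome, features, truth


def simulate_read_library(genome: CircularSequence, spec: LibrarySpec) -> tuple[ReadLibrary, TruthTable]:
    """Sample paired reads from fragments placed uniformly on the circle.

    Insert lengths are Normal(mean, sd) truncated below at the read length;
    a shadow-fraction subset is drawn from the shadow insert distribution;
    substitution errors are i.i.d. per base. The truth table records each
    read's source interval (start mod L, length, strand).
    """
    L = len(genome)
    sd = spec.insert_sd or 0.0
    if L <= spec.insert_mean + 6 * sd:
        raise ValueError(f"genome length {L} must exceed insert_mean + 6*sd = {spec.insert_mean + 6 * sd:.0f}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    rl = spec.read_length

    starts = rng.integers(0, L, size=n)
    inserts = rng.normal(spec.insert_mean, sd, size=n)
    if spec.shadow_fraction > 0:
        shadow = rng.random(n) < spec.shadow_fraction
        inserts[shadow] = rng.normal(spec.shadow_insert_mean, spec.shadow_insert_sd, size=int(shadow.sum()))
    inserts = np.clip(np.rint(inserts), rl, L).astype(int)
    frag_strands = rng.integers(0, 2, size=n)  # 0 = forward, 1 = reverse

    doubled = genome.doubled()
    reads: list[Read] = []
    truth = TruthTable()

    def maybe_err(seq: str) -> str:
        if spec.error_rate <= 0:
            return seq
        hits = np.nonzero(rng.random(len(seq)) < spec.error_rate)[0]
        if len(hits) == 0:
            return seq
        chars = list(seq)
        for p in hits:
            alt = "ACGT".replace(chars[p], "")
            chars[p] = alt[int(rng.integers(0, 3))]
        return "".join(chars)

    for i in range(n):
        p, ins = int(starts[i]), int(inserts[i])
        frag = doubled[p : p + ins]
        rev_frag = frag_strands[i] == 1
        # source intervals of the two fragment-end reads on the genome
        left = (p % L, rl, "+")
        right = ((p + ins - rl) % L, rl, "-")
        if rev_frag:
            frag = revcomp(frag)
            left, right = (right[0], rl, "+"), (left[0], rl, "-")
            # after reverse-complementing, the fragment's 5' end sits at the
            # genomic right end; re-derive strands below from orientation
            left = ((p + ins - rl) % L, rl, "-")
            right = (p % L, rl, "+")
        r1_seq, r2_seq = frag[:rl], revcomp(frag[-rl:])
        r1_src, r2_src = left, right
        if spec.orientation == "RF":
            r1_seq, r2_seq = revcomp(frag[:rl]), frag[-rl:]
            r1_src = (left[0], rl, "-" if left[2] == "+" else "+")
            r2_src = (right[0], rl, "-" if right[2] == "+" else "+")
        pid = f"p{i}"
        id1, id2 = f"sim{i}/1", f"sim{i}/2"
        reads.append(Read(id=id1, seq=maybe_err(r1_seq), qual="I" * rl, pair_id=pid, mate=1))
        reads.append(Read(id=id2, seq=maybe_err(r2_seq), qual="I" * rl, pair_id=pid, mate=2))
        truth.read_sources[id1] = r1_src
        truth.read_sources[id2] = r2_src

    meta = {
        "read_length": rl,
        "insert_mean": spec.insert_mean,
        "insert_sd": sd,
        "orientation": spec.orientation,
        "n_pairs": n,
        "error_rate": spec.error_rate,
    }
    return ReadLibrary(reads=reads, meta=meta), truth


def simulate_edited_transcripts(
    cds_records: list[SequenceRecord],
    edit_sites: dict[str, list[int]],
    efficiency: float,
    depth: float,
    spec: LibrarySpec,
) -> tuple[ReadLibrary, TruthTable]:
    """Transcript reads carrying C-to-U edits (C→T in read sense) at known sites.

    Each read is drawn from an independent transcript molecule that carries
    each of its CDS's edit sites with probability `efficiency`. `depth` is the
    target per-base fold coverage. Positions are 1-based CDS offsets and must
    index a C.
    """
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    reads: list[Read] = []
    truth = TruthTable()

    for rec in cds_records:
        sites = sorted(edit_sites.get(rec.id, []))
        for pos in sites:
            if pos < 1 or pos > len(rec.seq):
                raise ValueError(f"{rec.id}: edit position {pos} outside CDS (length {len(rec.seq)})")
            if rec.seq[pos - 1] != "C":
                raise ValueError(f"{rec.id}: edit position {pos} is {rec.seq[pos - 1]!r}, not C")
            truth.edit_coverage.setdefault((rec.id, pos), 0)
            truth.edit_counts.setdefault((rec.id, pos), 0)
        eff_len = max(1, len(rec.seq) - rl + 1)
        n_reads = max(1, math.ceil(depth * len(rec.seq) / min(rl, len(rec.seq))))
        starts = rng.integers(0, eff_len, size=n_reads)
        for k in range(n_reads):
            s = int(starts[k])
            e = min(s + rl, len(rec.seq))
            chars = list(rec.seq[s:e])
            for pos in sites:
                covered = s < pos <= e
                edited = bool(rng.random() < efficiency)
                if covered:
                    truth.edit_coverage[(rec.id, pos)] += 1
                    if edited:
                        chars[pos - 1 - s] = "T"
                        truth.edit_counts[(rec.id, pos)] += 1
            seq = "".join(chars)
            if spec.error_rate > 0:
                hits = np.nonzero(rng.random(len(seq)) < spec.error_rate)[0]
                chars = list(seq)
                for p in hits:
                    alt = "ACGT".replace(chars[p], "")
                    chars[p] = alt[int(rng.integers(0, 3))]
                seq = "".join(chars)
            rid = f"{rec.id}|t{k}"
            reads.append(Read(id=rid, seq=seq, qual="I" * len(seq)))
            truth.read_sources[rid] = (s, e - s, "+")

    meta = {"read_length": rl, "efficiency": efficiency, "depth": depth}
    return ReadLibrary(reads=reads, meta=meta), truth
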