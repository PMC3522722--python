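"""Offset-bounded exact-overlap assembly of short uniform-length reads.

The graph joins two reads by an edge when their offset — the total length of
the non-overlapping parts of the two overlapped reads — is at most a
user-set maximum. Two maxima govern the process: the naive offset bounds the
edges used to seed unambiguous paths, and the larger extension offset bounds
the edges consulted when a path would otherwise terminate. With a uniform
working read length, offset and overlap are a bijection
(overlap = readlength - offset), so all overlap detection reduces to exact
suffix/prefix hashing.

Overlaps are exact by design: sequencing error is handled by depth
(majority consensus during polishing, multiplicity-1 tips never seed
extension decisions), which keeps the graph checkable against a brute-force
all-pairs oracle. Each read is stored once under the lexicographically
smaller of itself and its reverse complement, with strand tracked on graph
traversal; all tie-breaking is lexicographic by sequence so output is
byte-identical across runs.
"""
from __future__ import annotations

import logging
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .model import AlignmentRecord, CircularSequence, ReadLibrary, SequenceRecord, canonical_strand, revcomp

logger = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    naive_offset: int = 4
    extension_offset: int = 12
    readlength: int = 35
    min_depth: int = 1

    def __post_init__(self):
        if not 0 <= self.naive_offset <= self.extension_offset < self.readlength:
            raise ValueError(
                "require 0 <= naive_offset <= extension_offset < readlength, "
                f"got {self.naive_offset}/{self.extension_offset}/{self.readlength}"
            )


class OverlapGraph:
    """Deduplicated reads plus exact suffix-prefix overlap edges.

    Nodes are canonical-strand read sequences with multiplicity; an edge
    (A, sa) -> (B, sb) with offset o exists when the oriented suffix of A of
    length readlength - o equals the oriented prefix of B. Edge queries are
    served lazily from a prefix index so that graphs over millions of reads
    never materialize their (mostly transitive) edge lists.
    """

    def __init__(self, nodes: list[str], counts: list[int], params: AssemblyParams):
        self.nodes = nodes
        self.counts = counts
        self.params = params
        self._rc = [revcomp(s) for s in nodes]
        k0 = params.readlength - params.extension_offset
        self._k0 = k0
        index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for nid, seq in enumerate(nodes):
            index[seq[:k0]].append((nid, 0))
            rc = self._rc[nid]
            if rc != seq:
                index[rc[:k0]].append((nid, 1))
        self._prefix_index = dict(index)

    def __len__(self) -> int:
        return len(self.nodes)

    def oriented(self, nid: int, strand: int) -> str:
        return self.nodes[nid] if strand == 0 else self._rc[nid]

    def successors_at(self, nid: int, strand: int, offset: int) -> list[tuple[int, int]]:
        """All (node, strand) reachable from (nid, strand) at exactly `offset`."""
        s = self.oriented(nid, strand)
        rl = self.params.readlength
        out = []
        key = s[offset : offset + self._k0]
        for mid, mst in self._prefix_index.get(key, ()):  # verify beyond the seed
            t = self.oriented(mid, mst)
            if s[offset:] == t[: rl - offset]:
                out.append((mid, mst))
        return out

    def first_successors(self, nid: int, strand: int, max_offset: int, lo: int = 1) -> tuple[int, list]:
        """Scan offsets ascending from `lo`; return (offset, candidates) at the
        first offset with any successor, or (0, [])."""
        for o in range(lo, max_offset + 1):
            cand = self.successors_at(nid, strand, o)
            if cand:
                return o, cand
        return 0, []

    def edges(self, max_offset: int | None = None):
        """Materialize all edges with offset <= max_offset (default: naive).

        One edge per ordered (node, strand) pair, at the minimal offset.
        Intended for inspection and oracle comparison on small graphs.
        """
        mo = self.params.naive_offset if max_offset is None else max_offset
        out = []
        for nid in range(len(self.nodes)):
            strands = (0,) if self._rc[nid] == self.nodes[nid] else (0, 1)
            for st in strands:
                seen: set[tuple[int, int]] = set()
                for o in range(1, mo + 1):
                    for mid, mst in self.successors_at(nid, st, o):
                        if (mid, mst) not in seen:
                            seen.add((mid, mst))
                            out.append((nid, st, mid, mst, o))
        return out


def build_overlap_graph(reads: ReadLibrary, params: AssemblyParams) -> OverlapGraph:
    """Deduplicate reads under strand canonicalization and index overlaps.

    Reads whose length differs from params.readlength are discarded (logged).
    Raises ValueError when no usable read remains.
    """
    rl = params.readlength
    counter: Counter[str] = Counter()
    dropped = 0
    for r in reads:
        if len(r.seq) != rl:
            dropped += 1
            continue
        counter[canonical_strand(r.seq)] += 1
    if dropped:
        logger.info("build_overlap_graph: discarded %d reads with length != %d", dropped, rl)
    if not counter:
        raise ValueError("no reads of the working read length; nothing to assemble")
    nodes = sorted(counter)
    counts = [counter[s] for s in nodes]
    return OverlapGraph(nodes, counts, params)


@dataclass
class Contig:
    """A consensus sequence with per-position depth and read placements."""

    seq: str
    depth: np.ndarray
    placements: list[tuple[int, int, int]] = field(default_factory=list)  # (pos, node, strand)
    circular: bool = False
    circ_length: int | None = None

    def __len__(self) -> int:
        return len(self.seq)


def _next_step(graph: OverlapGraph, nid: int, strand: int, params: AssemblyParams):
    """One extension step with transitive reduction.

    The candidate continuation is the successor at the minimal offset within
    the naive radius (or, when none exists there, within the wider extension
    radius). Extension stops at a genuine branch: two distinct successors at
    the minimal offset, or any further successor within the extension radius
    that is not transitively implied by the chosen one (i.e. not itself an
    exact-overlap successor of it at the offset difference) — the signature
    of a repeat boundary. Returns (offset, node, strand) or None.
    """
    o1, cand = graph.first_successors(nid, strand, params.extension_offset)
    if not cand:
        return None
    if params.min_depth > 1:
        deep = [(m, s) for m, s in cand if graph.counts[m] >= params.min_depth]
        cand = deep or cand
    distinct = set(cand)
    if len(distinct) > 1:
        return None
    m, s = next(iter(distinct))
    for o2 in range(o1 + 1, params.extension_offset + 1):
        alts = graph.successors_at(nid, strand, o2)
        if not alts:
            continue
        implied = None
        for alt in alts:
            if alt == (m, s):
                continue
            if implied is None:
                implied = set(graph.successors_at(m, s, o2 - o1))
            if alt not in implied:
                return None
    return o1, m, s


def walk_contigs(graph: OverlapGraph, params: AssemblyParams | None = None) -> list[Contig]:
    """Grow maximal unambiguous paths into contigs.

    Extension follows unique successors (see _next_step); a walk that returns
    to its own starting read closes a circle and the contig is flagged
    circular with the true circle length recorded. Output order is
    deterministic: contigs sorted lexicographically by canonical consensus.
    """
    params = params or graph.params
    rl = params.readlength
    used: list[bool] = [False] * len(graph)
    contigs: list[Contig] = []

    for seed in range(len(graph)):
        if used[seed]:
            continue
        used[seed] = True
        path: list[tuple[int, int]] = [(seed, 0)]
        offsets: list[int] = []  # offsets[i] joins path[i] -> path[i+1]
        circular = False
        closing = 0
        # extend right
        while True:
            nid, st = path[-1]
            step = _next_step(graph, nid, st, params)
            if step is None:
                break
            o, m, s = step
            if (m, s) == path[0] or (m, 1 - s) == path[0] and graph.nodes[m] == graph._rc[m]:
                circular = True
                closing = o
                break
            if used[m]:
                break
            used[m] = True
            path.append((m, s))
            offsets.append(o)
        # extend left (walk right from the reverse orientation of the start)
        if not circular:
            left_path: list[tuple[int, int]] = []
            left_offsets: list[int] = []
            cur = (path[0][0], 1 - path[0][1])
            while True:
                step = _next_step(graph, cur[0], cur[1], params)
                if step is None:
                    break
                o, m, s = step
                if used[m]:
                    break
                used[m] = True
                left_path.append((m, s))
                left_offsets.append(o)
                cur = (m, s)
            if left_path:
                path = [(m, 1 - s) for m, s in reversed(left_path)] + path
                offsets = list(reversed(left_offsets)) + offsets

        parts = [graph.oriented(*path[0])]
        for (m, s), o in zip(path[1:], offsets):
            parts.append(graph.oriented(m, s)[rl - o :])
        seq = "".join(parts)
        depth = np.zeros(len(seq), dtype=np.int32)
        placements = []
        pos = 0
        for i, (m, s) in enumerate(path):
            if i > 0:
                pos += offsets[i - 1]
            placements.append((pos, m, s))
            depth[pos : pos + rl] += graph.counts[m]
        circ_length = sum(offsets) + closing if circular else None
        contigs.append(Contig(seq=seq, depth=depth, placements=placements, circular=circular, circ_length=circ_length))

    contigs.sort(key=lambda c: canonical_strand(c.seq))
    return contigs


# ---------------------------------------------------------------------------
# Circular closure


def _terminal_overlap(seq: str, min_overlap: int) -> int:
    """Largest k with seq[:k] == seq[-k:], k in [min_overlap, len-1], else 0.

    Uses the KMP border array, so arbitrary-length terminal repeats are found
    in linear time.
    """
    n = len(seq)
    if n < 2:
        return 0
    pi = [0] * n
    k = 0
    for i in range(1, n):
        while k and seq[i] != seq[k]:
            k = pi[k - 1]
        if seq[i] == seq[k]:
            k += 1
        pi[i] = k
    border = pi[-1]
    return border if border >= min_overlap else 0


def circularize(
    obj,
    params: AssemblyParams | None = None,
    min_overlap: int | None = None,
    anchor: str | None = None,
):
    """Close a contig/scaffold into a circle when its ends overlap exactly.

    A contig whose walk already closed on itself is trimmed to its true
    circle length. Otherwise the two ends must share an exact overlap of at
    least `min_overlap` (default readlength - naive_offset). On success the
    circle is rotated to canonical form (least rotation over both strands),
    or so that `anchor` sits at position 0 when given. Without a terminal
    overlap the input is returned as a linear SequenceRecord with
    circular=False and a warning.
    """
    if isinstance(obj, Contig):
        seq = obj.seq
        if obj.circular and obj.circ_length:
            return _rotate(CircularSequence(seq[: obj.circ_length]), anchor)
    elif isinstance(obj, (SequenceRecord, CircularSequence)):
        seq = obj.seq
    else:
        seq = str(obj)
    if min_overlap is None:
        if params is None:
            raise ValueError("need params or min_overlap")
        min_overlap = params.readlength - params.naive_offset
    k = _terminal_overlap(seq, min_overlap)
    if k:
        return _rotate(CircularSequence(seq[: len(seq) - k]), anchor)
    logger.warning("circularize: no terminal overlap >= %d; returning linear sequence", min_overlap)
    return SequenceRecord(id="unclosed", seq=seq, circular=False)


def _rotate(circle: CircularSequence, anchor: str | None) -> CircularSequence:
    if anchor is None:
        return circle.canonical()
    doubled = circle.doubled()
    i = doubled.find(anchor)
    if i < 0 or i >= len(circle):
        rc = revcomp(circle.seq)
        doubled = rc + rc
        i = doubled.find(anchor)
        if i < 0 or i >= len(circle):
            logger.warning("circularize: anchor not found; using canonical rotation")
            return circle.canonical()
        return CircularSequence(doubled[i : i + len(circle)], id=circle.id)
    return CircularSequence(doubled[i : i + len(circle)], id=circle.id)


# ---------------------------------------------------------------------------
# Read-back mapping (exact-seed internal mapper)


class ReferenceIndex:
    """Exact k-mer seed index over the doubled circle (or linear sequence)."""

    def __init__(self, seq: str, k: int, circular: bool = True, ref_id: str = "ref"):
        self.L = len(seq)
        self.k = k
        self.circular = circular
        self.ref_id = ref_id
        self.text = seq + seq[: self.L] if circular else seq
        idx: dict[str, list[int]] = defaultdict(list)
        n_pos = self.L if circular else max(0, self.L - k + 1)
        for i in range(n_pos):
            idx[self.text[i : i + k]].append(i)
        self.index = dict(idx)


def map_reads(
    reference: CircularSequence | SequenceRecord,
    reads: ReadLibrary,
    params: AssemblyParams,
    max_mismatch: int = 2,
) -> list[AlignmentRecord]:
    """Place reads by exact seed (k = readlength - naive_offset) plus a
    bounded-mismatch full check on the doubled circle, both strands.

    Multi-mapping reads are assigned to the lowest coordinate and flagged.
    """
    circular = isinstance(reference, CircularSequence)
    rl = params.readlength
    k = rl - params.naive_offset
    ref = ReferenceIndex(reference.seq, k, circular=circular, ref_id=getattr(reference, "id", "ref"))
    out: list[AlignmentRecord] = []
    L = ref.L
    text = ref.text
    for r in reads:
        if len(r.seq) != rl:
            out.append(AlignmentRecord(read_id=r.id, ref_id=ref.ref_id, start=0, length=0, mapped=False,
                                       pair_id=r.pair_id, mate=r.mate))
            continue
        hits: list[tuple[int, int, str]] = []  # (mismatches, pos, strand)
        for strand, s in (("+", r.seq), ("-", revcomp(r.seq))):
            for p in ref.index.get(s[:k], ()):  # verify the remainder
                if p + rl > len(text):
                    continue
                window = text[p : p + rl]
                if window == s:
                    hits.append((0, p % L if circular else p, strand))
                else:
                    mm = sum(a != b for a, b in zip(window[k:], s[k:]))
                    if mm <= max_mismatch:
                        hits.append((mm, p % L if circular else p, strand))
        if not hits:
            out.append(AlignmentRecord(read_id=r.id, ref_id=ref.ref_id, start=0, length=0, mapped=False,
                                       pair_id=r.pair_id, mate=r.mate))
            continue
        hits.sort()
        positions = {(p, st) for _, p, st in hits}
        mm, pos, strand = hits[0]
        out.append(
            AlignmentRecord(
                read_id=r.id,
                ref_id=ref.ref_id,
                start=pos,
                length=rl,
                strand=strand,
                mismatches=mm,
                multi=len(positions) > 1,
                pair_id=r.pair_id,
                mate=r.mate,
            )
        )
    _fill_mates(out, L if circular else None)
    return out


def _fill_mates(alignments: list[AlignmentRecord], L: int | None) -> None:
    by_pair: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.pair_id:
            by_pair[a.pair_id].append(a)
    for recs in by_pair.values():
        if len(recs) != 2 or not (recs[0].mapped and recs[1].mapped):
            continue
        a, b = recs
        a.mate_start, b.mate_start = b.start, a.start
        if L:
            from .qc import pair_geometry  # local import to avoid a cycle

            _, insert = pair_geometry(a.start, a.length, b.start, b.length, L)
            a.insert = b.insert = insert


# ---------------------------------------------------------------------------
# Scaffolding


@dataclass
class ScaffoldLink:
    contig_a: int
    end_a: str  # 'R' = link leaves A's right end (as oriented '+')
    contig_b: int
    end_b: str
    n_pairs: int
    gap: float


@dataclass
class Scaffold:
    """Ordered, oriented contigs with insert-derived gap estimates."""

    items: list[tuple[int, str]]  # (contig index, orientation)
    gaps: list[float] = field(default_factory=list)  # between consecutive items

    def sequence(self, contigs: list[Contig]) -> str:
        parts = []
        for i, (ci, orient) in enumerate(self.items):
            s = contigs[ci].seq
            parts.append(s if orient == "+" else revcomp(s))
            if i < len(self.gaps):
                parts.append("N" * max(1, int(round(self.gaps[i]))))
        return "".join(parts)


def scaffold_pairs(
    contigs: list[Contig],
    reads: ReadLibrary,
    params: AssemblyParams,
    insert_mean: float,
    insert_sd: float,
    min_links: int = 5,
) -> list[Scaffold]:
    """Order and orient contigs using paired-read links.

    Contigs are linked when at least `min_links` pairs agree on relative
    order/orientation with a plausible implied gap; conflicting orientations
    are resolved by majority (ties lexicographic by contig sequence), gap is
    the median implied gap. Each contig end joins at most one link, strongest
    first.
    """
    if len(contigs) <= 1:
        return [Scaffold(items=[(0, "+")])] if contigs else []

    rl = params.readlength
    k = rl - params.naive_offset
    # joint placement over all contigs
    placement: dict[str, tuple[int, int, str]] = {}  # read id -> (contig, pos, strand)
    indexes = [ReferenceIndex(c.seq, k, circular=False) for c in contigs]
    for r in reads:
        if len(r.seq) != rl or not r.pair_id:
            continue
        found = []
        for ci, ref in enumerate(indexes):
            for strand, s in (("+", r.seq), ("-", revcomp(r.seq))):
                for p in ref.index.get(s[:k], ()):  # exact full match only
                    if ref.text[p : p + rl] == s:
                        found.append((ci, p, strand))
        if len(found) == 1:
            placement[r.id] = found[0]

    votes: dict[tuple, list[float]] = defaultdict(list)
    for r1, r2 in reads.pairs():
        if r1.id not in placement or r2.id not in placement:
            continue
        c1, p1, s1 = placement[r1.id]
        c2, p2, s2 = placement[r2.id]
        if c1 == c2:
            continue
        # orient each contig so the fragment runs left-to-right through it
        def tail(ci, p, s):
            if s == "+":
                return len(contigs[ci].seq) - p, "+"
            return p + rl, "-"

        t1, o1 = tail(c1, p1, s1)
        # the mate reads toward the fragment start on its contig
        def head(ci, p, s):
            if s == "-":
                return p + rl, "+"
            return len(contigs[ci].seq) - p, "-"

        t2, o2 = head(c2, p2, s2)
        gap = insert_mean - t1 - t2
        if gap < -2 * rl or gap > insert_mean:
            continue
        if c1 <= c2:
            key = (c1, "R" if o1 == "+" else "L", c2, "L" if o2 == "+" else "R")
        else:
            key = (c2, "R" if o2 == "-" else "L", c1, "L" if o1 == "-" else "R")
        votes[key].append(gap)

    # resolve conflicting orientations between the same contig pair by majority
    best_for_pair: dict[tuple[int, int], tuple] = {}
    for key, gaps in votes.items():
        a, _, b, _ = key
        cur = best_for_pair.get((a, b))
        cand = (len(gaps), key)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and key < cur[1]):
            best_for_pair[(a, b)] = cand
    links = [
        ScaffoldLink(k2[0], k2[1], k2[2], k2[3], n, statistics.median(votes[k2]))
        for (n, k2) in best_for_pair.values()
        if n >= min_links
    ]
    links.sort(key=lambda l: (-l.n_pairs, l.contig_a, l.contig_b))

    # greedy chaining: each contig end used at most once
    end_used: set[tuple[int, str]] = set()
    adj: dict[tuple[int, str], tuple[int, str, float]] = {}
    for l in links:
        ea, eb = (l.contig_a, l.end_a), (l.contig_b, l.end_b)
        if ea in end_used or eb in end_used:
            continue
        end_used.update((ea, eb))
        adj[ea] = (l.contig_b, l.end_b, l.gap)
        adj[eb] = (l.contig_a, l.end_a, l.gap)

    # walk chains from unlinked ends; lone contigs become singleton scaffolds
    visited: set[int] = set()
    scaffolds: list[Scaffold] = []
    order = sorted(range(len(contigs)), key=lambda ci: canonical_strand(contigs[ci].seq))
    for start in order:
        if start in visited:
            continue
        # find a free end to start from (or break a cycle arbitrarily at L)
        if (start, "L") not in adj:
            cur, enter = start, "L"
        elif (start, "R") not in adj:
            cur, enter = start, "R"
        else:
            cur, enter = start, "L"
        items: list[tuple[int, str]] = []
        gaps: list[float] = []
        while True:
            visited.add(cur)
            orient = "+" if enter == "L" else "-"
            items.append((cur, orient))
            exit_end = "R" if enter == "L" else "L"
            nxt = adj.get((cur, exit_end))
            if nxt is None or nxt[0] in visited:
                break
            gaps.append(nxt[2])
            cur, enter = nxt[0], nxt[1]
        scaffolds.append(Scaffold(items=items, gaps=gaps))
    return scaffolds


# ---------------------------------------------------------------------------
# Polishing


def polish(
    reference: CircularSequence,
    reads: ReadLibrary,
    params: AssemblyParams | None = None,
    min_fraction: float = 0.8,
    min_depth: int = 5,
    max_rounds: int = 3,
    seed_k: int = 21,
    max_edits: int = 6,
) -> CircularSequence:
    """Correct single-base errors and small indels by read-back pileup.

    Reads are anchored by exact seeds, aligned to their local reference
    window with edlib (so 1 bp indels are representable), and per-column
    allele counts accumulated. A column is rewritten when an alternative
    allele holds at least `min_fraction` of at least `min_depth` covering
    reads. Iterates to fixpoint or `max_rounds`; the edit count is
    non-increasing across rounds.
    """
    seq = reference.seq
    prev_edits = None
    for _ in range(max_rounds):
        seq, n_edits = _polish_round(seq, reads, min_fraction, min_depth, seed_k, max_edits)
        if prev_edits is not None and n_edits > prev_edits:
            logger.warning("polish: edit count increased (%d -> %d); stopping", prev_edits, n_edits)
            break
        prev_edits = n_edits
        if n_edits == 0:
            break
    return CircularSequence(seq, id=reference.id)


def _polish_round(seq, reads, min_fraction, min_depth, seed_k, max_edits):
    L = len(seq)
    text = seq + seq  # doubled circle
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(L):
        index[text[i : i + seed_k]].append(i)
    cov = np.zeros(L, dtype=np.int32)
    # spanning coverage: reads with a margin of aligned bases on both sides of
    # a column; the denominator for allele decisions, so reads whose alignment
    # merely ends inside a homopolymer cannot silently dilute an indel vote
    span = np.zeros(L, dtype=np.int32)
    margin = max_edits
    subs: dict[int, Counter] = defaultdict(Counter)
    dels: Counter = Counter()
    ins: dict[int, Counter] = defaultdict(Counter)

    pad = max_edits + 2
    for r in reads:
        rlen = len(r.seq)
        if rlen < seed_k:
            continue
        anchored = False
        for s_read in (r.seq, revcomp(r.seq)):
            if anchored:
                break
            for off in (0, rlen // 2, rlen - seed_k):
                hits = index.get(s_read[off : off + seed_k])
                if not hits:
                    continue
                p0 = (hits[0] - off) % L
                window = text[p0 : p0 + rlen + pad]
                res = edlib.align(s_read, window, mode="HW", task="path", k=max_edits)
                if res["editDistance"] < 0:
                    continue
                t_end = _accumulate(res, s_read, p0, L, cov, subs, dels, ins, text)
                t0 = p0 + res["locations"][0][0]
                n_sp = (t_end - margin) - (t0 + margin)
                if n_sp > 0:
                    s_sp = (t0 + margin) % L
                    if s_sp + n_sp <= L:
                        span[s_sp : s_sp + n_sp] += 1
                    else:
                        span[s_sp:] += 1
                        span[: s_sp + n_sp - L] += 1
                anchored = True
                break
    new_parts: list[str] = []
    n_edits = 0
    for pos in range(L):
        c = int(span[pos])
        base = seq[pos]
        if c >= min_depth:
            if dels[pos] / c >= min_fraction:
                n_edits += 1
            else:
                if subs[pos]:
                    alt, n_alt = subs[pos].most_common(1)[0]
                    if alt != base and n_alt / c >= min_fraction:
                        base = alt
                        n_edits += 1
                new_parts.append(base)
            if ins[pos]:
                alt, n_alt = ins[pos].most_common(1)[0]
                if n_alt / c >= min_fraction:
                    new_parts.append(alt)
                    n_edits += 1
        else:
            new_parts.append(base)
    return "".join(new_parts), n_edits


def _accumulate(res, read_seq, p0, L, cov, subs, dels, ins, text):
    """Walk an edlib extended-CIGAR path, crediting alleles to reference columns.

    Indels are left-normalized (shifted to their leftmost equivalent position
    in the reference) so votes from reads whose alignment windows start at
    different points inside a homopolymer run still agree on one column.
    Returns the final target cursor (end of the aligned interval).
    """
    cigar = res["cigar"]
    t = p0 + res["locations"][0][0]  # target cursor (doubled coords)
    q = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            s, e = t, t + n
            if e <= L:
                cov[s:e] += 1
            else:
                s %= L
                if s + n <= L:
                    cov[s : s + n] += 1
                else:
                    cov[s:] += 1
                    cov[: s + n - L] += 1
            t += n
            q += n
        elif ch == "X":
            for i in range(n):
                pos = (t + i) % L
                cov[pos] += 1
                subs[pos][read_seq[q + i]] += 1
            t += n
            q += n
        elif ch == "D":  # bases in target absent from read
            d0 = t
            while d0 > 0 and text[d0 - 1] == text[d0 + n - 1]:
                d0 -= 1
            for i in range(n):
                cov[(t + i) % L] += 1  # coverage at the aligned columns
                dels[(d0 + i) % L] += 1  # vote at the left-normalized columns
            t += n
        elif ch == "I":  # bases in read absent from target: insert after t-1
            s_ins = read_seq[q : q + n]
            i0 = t
            while i0 > 0 and text[i0 - 1] == s_ins[-1]:
                s_ins = s_ins[-1] + s_ins[:-1]
                i0 -= 1
            ins[(i0 - 1) % L][s_ins] += 1
            q += n
    return t
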