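"""Repeat discovery on circular genomes and its downstream accounting:
repeat fraction, GC content, gene density, upstream motif scans, and the
prediction of recombination-derived subcircles and isomeric circles.

Plant mitochondrial master circles carry sets of large (often >1 kb) direct
and inverted repeats. Intramolecular recombination between a direct pair
splits the master circle into two subcircles whose sizes sum to the parent
length; recombination across an inverted pair yields an isomeric circle of
unchanged size with the inter-repeat segment inverted. Measuring the copies
start-to-start is the only convention under which the two subcircle sizes
sum exactly to the parent length, and it leaves exactly one full repeat
copy on each subcircle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .model import CircularSequence, FeatureRecord, gc_fraction, revcomp


@dataclass
class RepeatPair:
    """Two copies of a repeat on the same circle.

    Direct: copies identical on the same strand. Inverted: copy B is the
    reverse complement of copy A. Starts are 0-based positions on the circle;
    copies may wrap the origin.
    """

    kind: str  # 'direct' | 'inverted'
    start_a: int
    start_b: int
    length: int
    identity: float = 100.0

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.start_a, self.start_a + self.length), (self.start_b, self.start_b + self.length)


@dataclass
class RecombinationProduct:
    """A molecule generated by repeat-mediated intramolecular recombination."""

    kind: str  # 'subcircle' | 'isomer'
    size: int
    pair: RepeatPair
    parent: str = "master"
    n_isoforms: int = 1
    interval: tuple[int, int] | None = None  # start-to-start arc retained, on the parent's coordinates
    contained_pairs: list[RepeatPair] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Discovery


def find_repeats(
    genome: CircularSequence,
    min_len: int = 100,
    min_identity: float = 100.0,
    seed_k: int | None = None,
) -> list[RepeatPair]:
    """Find maximal repeat pairs (direct and inverted) on the circle.

    Seed k-mers are matched on the doubled genome (so copies wrapping the
    origin are found) and on both strands, then extended to maximal exact
    length; pairs contained in a longer reported pair are suppressed. Only
    exact (100% identity) pairs are reported; `min_identity` below 100 keeps
    a pair whose flanking extension degrades identity down to that level
    (ungapped).
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    L = len(genome)
    seq = genome.seq
    k = seed_k or min(min_len, 21)

    def at(i: int) -> str:
        return seq[i % L]

    kmers: dict[str, list[int]] = {}
    for i in range(L):
        km = genome.fetch(i, k)
        kmers.setdefault(km, []).append(i)

    found: list[RepeatPair] = []
    covered_direct: dict[int, list[tuple[int, int]]] = {}   # diagonal -> intervals of i
    covered_inverted: dict[int, list[tuple[int, int]]] = {}  # anti-diagonal -> intervals of i

    def seen(table, key, i):
        return any(a <= i < b for a, b in table.get(key, ()))

    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

    # direct candidates: same k-mer at two positions
    for km, positions in kmers.items():
        if len(positions) < 2:
            continue
        for xi in range(len(positions)):
            for yi in range(xi + 1, len(positions)):
                i, j = positions[xi], positions[yi]
                d = (j - i) % L
                if d == 0:
                    continue
                if seen(covered_direct, d, i):
                    continue
                # extend left
                a, b, ln = i, j, k
                while ln < L and at(a - 1) == at(b - 1):
                    a, b, ln = a - 1, b - 1, ln + 1
                while ln < L and at(a + ln) == at(b + ln):
                    ln += 1
                if min_identity < 100.0:
                    a, b, ln = _fuzzy_extend(at, a, b, ln, L, min_identity, inverted=False)
                covered_direct.setdefault(d, []).append((a, a + ln))
                if ln >= min_len:
                    found.append(_canonical_pair("direct", a % L, b % L, ln, L))

    # inverted candidates: k-mer matching the reverse complement of another
    for km, positions in kmers.items():
        rc = revcomp(km)
        if rc < km or rc not in kmers:
            continue
        for i in positions:
            for j in kmers[rc]:
                # copy A forward k-mer at i pairs with copy B whose revcomp
                # k-mer starts at j; anti-diagonal is invariant under extension
                key = (i + j) % L
                if km == rc and j <= i:
                    continue
                if seen(covered_inverted, key, i):
                    continue
                a, bend, ln = i, j + k, k  # B interval is [bend-ln, bend)
                while ln < L and at(a - 1) == comp[at(bend)]:
                    a, ln, bend = a - 1, ln + 1, bend + 1
                while ln < L and at(a + ln) == comp[at(bend - ln - 1)]:
                    ln += 1
                covered_inverted.setdefault(key, []).append((a, a + ln))
                sb = (bend - ln) % L
                if ln >= min_len and (a % L) != sb:
                    found.append(_canonical_pair("inverted", a % L, sb, ln, L))

    # dedupe and suppress contained pairs
    uniq: dict[tuple, RepeatPair] = {}
    for p in found:
        uniq[(p.kind, p.start_a, p.start_b, p.length)] = p
    pairs = sorted(uniq.values(), key=lambda p: (-p.length, p.start_a, p.start_b))
    kept: list[RepeatPair] = []
    for p in pairs:
        if not any(_contains(q, p, L) for q in kept):
            kept.append(p)
    return kept


def _fuzzy_extend(at, a, b, ln, L, min_identity, inverted):
    """Ungapped extension tolerating mismatches while identity stays above
    the floor; trailing mismatches are trimmed. Direct pairs only."""
    matches = ln
    # extend right
    ext, ext_match, best = 0, 0, 0
    while ln + ext < L:
        if at(a + ln + ext) == at(b + ln + ext):
            ext_match += 1
            if 100.0 * (matches + ext_match) / (ln + ext + 1) >= min_identity:
                best = ext + 1
        else:
            if 100.0 * (matches + ext_match) / (ln + ext + 1) < min_identity - 5:
                break
        ext += 1
        if ext > 2000:
            break
    ln += best
    return a, b, ln


def _canonical_pair(kind: str, sa: int, sb: int, length: int, L: int) -> RepeatPair:
    if sb < sa:
        sa, sb = sb, sa
    return RepeatPair(kind=kind, start_a=sa, start_b=sb, length=length)


def _contains(q: RepeatPair, p: RepeatPair, L: int) -> bool:
    """True if pair p's copies are both contained in q's copies (same kind)."""
    if q.kind != p.kind:
        return False

    def inside(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
        s, e = inner
        os_, oe = outer
        # normalize to the doubled axis relative to outer start
        s = (s - os_) % L
        return s + (e - inner[0]) <= oe - os_

    (qa, qb) = q.intervals()
    (pa, pb) = p.intervals()
    return (inside(pa, qa) and inside(pb, qb)) or (inside(pa, qb) and inside(pb, qa))


# ---------------------------------------------------------------------------
# Accounting


def repeat_fraction(repeats: list[RepeatPair], genome_length: int) -> float:
    """Percent of the genome occupied by repeat copies, two decimals.

    Both copies of every pair are counted (2 x copy length per pair) and
    bases shared by overlapping copies of different pairs are deliberately
    double-counted — the convention under which the published inventories
    reproduce their printed fractions.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    total = sum(2 * r.length for r in repeats)
    return round(100.0 * total / genome_length, 2)


def gc_content(seq) -> float:
    """GC percent over unambiguous bases, one decimal; all-N input is an error."""
    s = seq.seq if hasattr(seq, "seq") else str(seq)
    return round(100.0 * gc_fraction(s), 1)


_DENSITY_CLASSES = {"CDS": "protein_coding", "rRNA": "rRNA", "tRNA": "tRNA"}


def gene_density(features: list[FeatureRecord], genome_length: int, classes: dict | None = None) -> dict[str, float]:
    """Percent of the genome covered by each gene class, one decimal.

    Within a class, overlapping features are merged (base-span union);
    repeat-duplicated genes occupy distinct spans and therefore both count.
    """
    classes = classes or _DENSITY_CLASSES
    by_class: dict[str, list[tuple[int, int]]] = {v: [] for v in classes.values()}
    for f in features:
        cls = classes.get(f.type)
        if cls is None:
            continue
        if f.end > genome_length:
            raise ValueError(f"feature {f.attributes.get('ID', '?')} extends past genome end ({f.end} > {genome_length})")
        by_class[cls].append(f.interval0())
    out = {}
    for cls, ivs in by_class.items():
        ivs.sort()
        total = 0
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        out[cls] = round(100.0 * total / genome_length, 1)
    return out


def upstream_motif_scan(
    genome: CircularSequence,
    features: list[FeatureRecord],
    motif: str = "GGAGG",
    window: int = 20,
    types: tuple[str, ...] = ("CDS",),
) -> list[FeatureRecord]:
    """Genes whose strand-aware upstream window contains the motif (wrap-aware).

    For a + strand gene the window is the `window` bp ending just before its
    start; for a - strand gene, the reverse complement of the `window` bp
    just after its end.
    """
    if window < len(motif):
        raise ValueError("window must be at least the motif length")
    hits = []
    for f in features:
        if f.type not in types:
            continue
        s0, e0 = f.interval0()
        if f.strand == "+":
            upstream = genome.fetch(s0 - window, window)
        else:
            upstream = revcomp(genome.fetch(e0, window))
        if motif in upstream:
            hits.append(f)
    return hits


# ---------------------------------------------------------------------------
# Recombination structure


class RecombinationError(ValueError):
    pass


def recombination_products(
    genome_or_length,
    repeats: list[RepeatPair],
    _parent: str = "master",
    _depth: int = 0,
) -> list[RecombinationProduct]:
    """Predict the subcircles and isomeric circles a repeat inventory generates.

    Each direct pair splits its parent circle into two subcircles measured
    start-of-copy to start-of-copy (sizes (s2-s1) mod L and (s1-s2) mod L,
    summing to L), each retaining one repeat copy. Each inverted pair yields
    an isomer of the parent, equal in size, with the inter-copy segment
    inverted. Repeat pairs lying wholly within a subcircle arc are annotated
    onto it: contained inverted pairs double its isoform count, contained
    direct pairs spawn nested subcircle products.
    """
    L = genome_or_length if isinstance(genome_or_length, int) else len(genome_or_length)
    products: list[RecombinationProduct] = []
    for pair in repeats:
        d = (pair.start_b - pair.start_a) % L
        if d == 0:
            raise RecombinationError("repeat copies at identical positions; recombination undefined")
        if d < pair.length or (L - d) < pair.length:
            raise RecombinationError(
                f"copies of the same pair overlap (separation {min(d, L - d)} < length {pair.length}); recombination undefined"
            )
        if pair.kind == "direct":
            for size, arc_start in ((d, pair.start_a), (L - d, pair.start_b)):
                arc = (arc_start, arc_start + size)
                contained = [q for q in repeats if q is not pair and _pair_in_arc(q, arc, L)]
                n_iso = 2 ** sum(1 for q in contained if q.kind == "inverted")
                prod = RecombinationProduct(
                    kind="subcircle",
                    size=size,
                    pair=pair,
                    parent=_parent,
                    n_isoforms=n_iso,
                    interval=(arc_start % L, (arc_start + size) % L),
                    contained_pairs=contained,
                )
                products.append(prod)
                if _depth < 2:
                    nested_direct = [q for q in contained if q.kind == "direct"]
                    if nested_direct:
                        rebased = [
                            RepeatPair(q.kind, (q.start_a - arc_start) % L, (q.start_b - arc_start) % L, q.length)
                            for q in nested_direct
                        ]
                        products.extend(
                            recombination_products(size, rebased, _parent=f"subcircle:{size}", _depth=_depth + 1)
                        )
        else:
            products.append(RecombinationProduct(kind="isomer", size=L, pair=pair, parent=_parent))
    return products


def _pair_in_arc(pair: RepeatPair, arc: tuple[int, int], L: int) -> bool:
    """Both copies of `pair` lie wholly within the circular arc [start, end)."""
    start, end = arc
    span = end - start

    def inside(s: int, length: int) -> bool:
        rel = (s - start) % L
        return rel + length <= span

    return inside(pair.start_a, pair.length) and inside(pair.start_b, pair.length)
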