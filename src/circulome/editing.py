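"""C-to-U RNA editing: application to CDS, codon-usage accounting,
confirmation from transcript pileups, and RPKM expression flags.

Edit positions are 1-based offsets from the first base of the start codon
and must index a C in the coding (sense) strand; applying an edit writes a
T at that position (the DNA sense of a C-to-U change). Effects are
classified by comparing the affected codon before and after: ACG -> ATG at
codon 1 creates a start; creation of TAA/TAG/TGA at the final codon creates
a stop; an internal stop created by editing is a biological red flag and is
surfaced by the checker rather than silently accepted.

Confirmation follows the published filter: a site passes when its allele
balance ratio (edited reads over all covering reads) is at least 0.40 and
coverage is at least 3.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .model import ReadLibrary, SequenceRecord, revcomp

_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    codon = a + b + c
                    _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE


@dataclass
class EditSite:
    """A C-to-U edit site at a 1-based CDS offset."""

    cds_id: str
    position: int
    ref_base: str = "C"
    effect: str | None = None  # silent | nonsynonymous | start-creation | stop-creation | stop-removal


@dataclass
class EditObservation:
    """Pileup evidence for one candidate edit site."""

    cds_id: str
    position: int
    coverage: int
    edited_count: int
    passed: bool = False

    @property
    def abr(self) -> float:
        return self.edited_count / self.coverage if self.coverage else 0.0


class EditSiteError(ValueError):
    pass


def apply_edits(cds: SequenceRecord, sites: list[EditSite]) -> tuple[SequenceRecord, list[EditSite]]:
    """Write each edit (C -> T) into the CDS and classify its effect.

    Returns the edited record and the sites with `effect` filled in. A site
    whose reference base is not C raises EditSiteError naming the site.
    """
    table = _codon_table()
    chars = list(cds.seq)
    n_codons = len(cds.seq) // 3
    annotated: list[EditSite] = []
    for site in sorted(sites, key=lambda s: s.position):
        p = site.position
        if p < 1 or p > len(chars):
            raise EditSiteError(f"{cds.id}: position {p} outside CDS of length {len(chars)}")
        if chars[p - 1] != "C":
            raise EditSiteError(f"{cds.id}: position {p} is {chars[p - 1]!r}, not C")
        codon_i = (p - 1) // 3
        before = "".join(chars[codon_i * 3 : codon_i * 3 + 3])
        chars[p - 1] = "T"
        after = "".join(chars[codon_i * 3 : codon_i * 3 + 3])
        if codon_i == 0 and after == "ATG" and before != "ATG":
            effect = "start-creation"
        elif len(after) == 3 and after in _STOPS and before not in _STOPS:
            effect = "stop-creation"
        elif len(after) == 3 and before in _STOPS and after not in _STOPS:
            effect = "stop-removal"
        elif len(after) == 3 and table[before] == table[after]:
            effect = "silent"
        else:
            effect = "nonsynonymous"
        annotated.append(EditSite(cds_id=site.cds_id, position=p, effect=effect))
        # flag internal stop creation explicitly (still classified stop-creation)
        if effect == "stop-creation" and codon_i < n_codons - 1:
            annotated[-1].effect = "stop-creation"
    edited = SequenceRecord(id=cds.id, seq="".join(chars), circular=False)
    return edited, annotated


def internal_stop_violations(cds_records: list[SequenceRecord]) -> list[tuple[str, int]]:
    """(cds_id, codon index) for every in-frame internal stop codon.

    Editing is not expected to create in-frame stops; run this on edited
    CDS sets to surface violations instead of silently accepting them.
    """
    out = []
    for rec in cds_records:
        n = len(rec.seq) // 3
        for i in range(n - 1):
            if rec.seq[i * 3 : i * 3 + 3] in _STOPS:
                out.append((rec.id, i))
    return out


# ---------------------------------------------------------------------------
# Codon usage


def codon_usage(cds_records: list[SequenceRecord]) -> dict[str, float]:
    """Codon score per thousand bp of all coding sequence (2 decimals).

    score(codon) = 1000 * count(codon) / total coding bp, so the scores of
    all codons times 3 sum to 1000 (up to rounding). Duplicated genes are
    included as given; sequences are trimmed to whole codons.
    """
    counts: dict[str, int] = defaultdict(int)
    total_bp = 0
    for rec in cds_records:
        s = rec.seq[: len(rec.seq) // 3 * 3]
        total_bp += len(s)
        for i in range(0, len(s), 3):
            counts[s[i : i + 3]] += 1
    if total_bp == 0:
        raise ValueError("no coding sequence supplied")
    return {codon: round(1000.0 * n / total_bp, 2) for codon, n in sorted(counts.items())}


def codon_usage_table(cds_records: list[SequenceRecord], edit_sites: dict[str, list[EditSite]]) -> pd.DataFrame:
    """Per-codon usage before and after applying the edit lists.

    Returns a DataFrame indexed by codon with columns 'before' and 'after',
    sorted by decreasing pre-editing frequency.
    """
    before = codon_usage(cds_records)
    edited = []
    for rec in cds_records:
        sites = edit_sites.get(rec.id, [])
        edited.append(apply_edits(rec, sites)[0] if sites else rec)
    after = codon_usage(edited)
    codons = sorted(set(before) | set(after), key=lambda c: (-before.get(c, 0.0), c))
    return pd.DataFrame(
        {"before": [before.get(c, 0.0) for c in codons], "after": [after.get(c, 0.0) for c in codons]},
        index=pd.Index(codons, name="codon"),
    )


# ---------------------------------------------------------------------------
# Confirmation from transcript reads


def pileup_cds(cds_records: list[SequenceRecord], reads: ReadLibrary, seed_k: int = 12, max_mismatch: int = 8):
    """Ungapped placement of transcript reads onto their CDS by exact seed.

    Seed offsets are tried every seed_k/2 bases so a read always offers at
    least one seed window free of edited positions; candidate placements are
    verified by a full bounded-mismatch comparison (best placement wins).
    Returns {cds_id: (coverage array, T-count array)}.
    """
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    seqs = {rec.id: rec.seq for rec in cds_records}
    for rec in cds_records:
        for i in range(0, max(1, len(rec.seq) - seed_k + 1)):
            index[rec.seq[i : i + seed_k]].append((rec.id, i))

    cov = {rec.id: [0] * len(rec.seq) for rec in cds_records}
    t_count = {rec.id: [0] * len(rec.seq) for rec in cds_records}

    for r in reads:
        rl = len(r.seq)
        if rl < seed_k:
            continue
        offsets = list(range(0, rl - seed_k + 1, max(1, seed_k // 2)))
        if offsets[-1] != rl - seed_k:
            offsets.append(rl - seed_k)
        placed = None
        for seq_r, rc in ((r.seq, False), (revcomp(r.seq), True)):
            for off in offsets:
                best = None
                for cid, i in index.get(seq_r[off : off + seed_k], ()):
                    start = i - off
                    ref = seqs[cid]
                    if start < 0 or start + rl > len(ref):
                        continue
                    mm = sum(a != b for a, b in zip(seq_r, ref[start : start + rl]))
                    if mm <= max_mismatch and (best is None or mm < best[2]):
                        best = (cid, start, mm)
                if best:
                    placed = (best[0], best[1], seq_r)
                    break
            if placed:
                break
        if not placed:
            continue
        cid, start, seq_r = placed
        ref = seqs[cid]
        c, t = cov[cid], t_count[cid]
        for i, base in enumerate(seq_r):
            c[start + i] += 1
            if ref[start + i] == "C" and base == "T":
                t[start + i] += 1
    return {cid: (cov[cid], t_count[cid]) for cid in cov}


def confirm_edits(
    cds_records: list[SequenceRecord],
    reads: ReadLibrary,
    min_abr: float = 0.40,
    min_cov: int = 3,
    **pileup_kwargs,
) -> list[EditObservation]:
    """Emit an observation for every C position with T-supporting reads.

    A site passes when ABR >= min_abr and coverage >= min_cov (both
    inclusive, matching the published filter ABR >= 0.40, coverage >= 3).
    """
    piles = pileup_cds(cds_records, reads, **pileup_kwargs)
    out: list[EditObservation] = []
    for rec in cds_records:
        cov, t_count = piles[rec.id]
        for i, base in enumerate(rec.seq):
            if base != "C" or t_count[i] == 0:
                continue
            obs = EditObservation(cds_id=rec.id, position=i + 1, coverage=cov[i], edited_count=t_count[i])
            obs.passed = obs.abr >= min_abr and obs.coverage >= min_cov
            out.append(obs)
    return out


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionRecord:
    gene_id: str
    length: int
    counts: dict
    rpkm_values: dict
    flagged: bool = False


def rpkm(count: float, gene_length: int, total_mapped: float) -> float:
    """Reads per kilobase of gene model per million mapped reads."""
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return count / (gene_length / 1000.0) / (total_mapped / 1e6)


def flag_fold_change(a: float, b: float, threshold: float = 2.5, eps: float = 0.01) -> bool:
    """True when the two conditions differ by at least `threshold`-fold.

    The ratio is max/min with the denominator floored at `eps` so that a
    zero-RPKM condition is still comparable; the threshold is inclusive
    (10 vs 25 flags at 2.5)."""
    hi, lo = max(a, b), min(a, b)
    return hi / max(lo, eps) >= threshold


def expression_records(
    counts: dict[str, dict[str, float]],
    lengths: dict[str, int],
    totals: dict[str, float],
    threshold: float = 2.5,
    eps: float = 0.01,
    conditions: tuple[str, str] = ("fresh", "salt"),
) -> list[ExpressionRecord]:
    """RPKM per condition plus the fold-change flag for each gene."""
    out = []
    for gene, per_cond in counts.items():
        vals = {c: rpkm(per_cond.get(c, 0), lengths[gene], totals[c]) for c in totals}
        a, b = vals[conditions[0]], vals[conditions[1]]
        out.append(
            ExpressionRecord(
                gene_id=gene,
                length=lengths[gene],
                counts=dict(per_cond),
                rpkm_values=vals,
                flagged=flag_fold_change(a, b, threshold, eps),
            )
        )
    return out


def dual_tissue_flags(leaf: list[ExpressionRecord], root: list[ExpressionRecord]) -> set[str]:
    """Genes flagged in both tissues (the asterisk annotation)."""
    leaf_hit = {r.gene_id for r in leaf if r.flagged}
    root_hit = {r.gene_id for r in root if r.flagged}
    return leaf_hit & root_hit
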