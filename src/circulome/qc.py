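"""Assembly diagnostics: coverage and insert-midpoint tracks, breakpoint
flags, and AT-rich origin scanning.

The validation logic mirrors how short-read assemblies of circular genomes
are visually audited: read depth and the midpoints of properly paired
fragments should both tile the circle uniformly; a break in coverage or in
the midpoint distribution of every library at the same position indicates
mis-assembly, while a break in a single library is merely suspicious. The
replication origin of a chloroplast genome shows up as a highly AT-rich,
lowly covered window.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AlignmentRecord, CircularSequence


def coverage_track(alignments: list[AlignmentRecord], ref_length: int, circular: bool = True) -> np.ndarray:
    """Per-position read depth; wrap-aware for circles.

    depth(p) = number of alignments covering p. Alignments extending past the
    linearized end of a non-circular reference raise ValueError.
    """
    track = np.zeros(ref_length, dtype=np.int64)
    for a in alignments:
        if not a.mapped or a.length == 0:
            continue
        s, e = a.start, a.start + a.length
        if e <= ref_length:
            track[s:e] += 1
        elif circular:
            track[s:] += 1
            track[: e - ref_length] += 1
        else:
            raise ValueError(f"alignment {a.read_id} extends past linear reference end ({e} > {ref_length})")
    return track


def pair_geometry(s1: int, len1: int, s2: int, len2: int, L: int) -> tuple[int, int]:
    """(midpoint, insert) of a mate pair on a circle of length L.

    The insert is the outer distance along the minor arc containing both
    reads (rightmost inclusive end minus leftmost start); the midpoint is the
    floor-average of those two coordinates, mod L.
    """
    e1, e2 = s1 + len1 - 1, s2 + len2 - 1
    # arrangement 1: as placed on the linearized circle
    lo, hi = min(s1, s2), max(e1, e2)
    span_a = hi - lo
    # arrangement 2: the earlier-starting read shifted one turn forward
    if s1 <= s2:
        lo_b, hi_b = s2, max(e2, e1 + L)
    else:
        lo_b, hi_b = s1, max(e1, e2 + L)
    span_b = hi_b - lo_b
    if span_b < span_a:
        lo, hi, span = lo_b, hi_b, span_b
    else:
        span = span_a
    return ((lo + hi) // 2) % L, span


@dataclass
class MidpointTrack:
    """(midpoint, insert) per properly paired fragment, plus the discordant count."""

    points: list[tuple[int, int]] = field(default_factory=list)
    n_discordant: int = 0

    def midpoints(self) -> np.ndarray:
        return np.array([p for p, _ in self.points], dtype=np.int64)

    def inserts(self) -> np.ndarray:
        return np.array([i for _, i in self.points], dtype=np.int64)


def midpoint_track(
    alignments: list[AlignmentRecord],
    ref_length: int,
    insert_mean: float | None = None,
    insert_sd: float | None = None,
    max_dev_sd: float = 3.0,
    max_insert: float | None = None,
) -> MidpointTrack:
    """Collect fragment midpoints from mate pairs; discordant pairs are
    excluded and counted: one mate unmapped, same-strand mates, insert
    beyond `max_insert`, or — when the library insert distribution is given —
    implied insert more than `max_dev_sd` standard deviations from the mean
    (the proper-pair rule that makes mis-assembly gaps visible)."""
    by_pair: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        if a.pair_id:
            by_pair.setdefault(a.pair_id, []).append(a)
    track = MidpointTrack()
    for recs in by_pair.values():
        if len(recs) != 2:
            track.n_discordant += 1
            continue
        a, b = recs
        if not (a.mapped and b.mapped) or a.strand == b.strand:
            track.n_discordant += 1
            continue
        mid, insert = pair_geometry(a.start, a.length, b.start, b.length, ref_length)
        if max_insert is not None and insert > max_insert:
            track.n_discordant += 1
            continue
        if insert_mean is not None and insert_sd:
            if abs(insert - insert_mean) > max_dev_sd * insert_sd:
                track.n_discordant += 1
                continue
        track.points.append((mid, insert))
    return track


@dataclass
class Breakpoint:
    position: int  # window start
    window: int
    scope: str  # 'single-library' | 'all-libraries'
    kinds: tuple[str, ...]  # subset of ('coverage', 'midpoint')


def detect_breakpoints(
    coverage_tracks: list[np.ndarray],
    midpoint_tracks: list[MidpointTrack],
    ref_length: int,
    window: int = 100,
) -> list[Breakpoint]:
    """Flag windows with zero coverage or zero midpoint density per library,
    then intersect across libraries.

    A window flagged in every library (by either signal) is scope
    'all-libraries' — the mis-assembly signature; otherwise 'single-library'.
    """
    n_lib = max(len(coverage_tracks), len(midpoint_tracks))
    if n_lib == 0:
        return []
    n_win = (ref_length + window - 1) // window
    flags: list[dict[int, set[str]]] = [dict() for _ in range(n_lib)]

    for li in range(n_lib):
        if li < len(coverage_tracks):
            cov = coverage_tracks[li]
            for w in range(n_win):
                if cov[w * window : (w + 1) * window].sum() == 0:
                    flags[li].setdefault(w, set()).add("coverage")
        if li < len(midpoint_tracks):
            hist = np.zeros(n_win, dtype=np.int64)
            mids = midpoint_tracks[li].midpoints()
            if len(mids):
                np.add.at(hist, mids // window, 1)
            for w in np.nonzero(hist == 0)[0]:
                flags[li].setdefault(int(w), set()).add("midpoint")

    out: list[Breakpoint] = []
    all_windows = set().union(*[set(f) for f in flags])
    for w in sorted(all_windows):
        libs_hit = [f for f in flags if w in f]
        scope = "all-libraries" if len(libs_hit) == n_lib else "single-library"
        kinds = tuple(sorted(set().union(*[f[w] for f in libs_hit])))
        out.append(Breakpoint(position=w * window, window=window, scope=scope, kinds=kinds))
    return out


@dataclass
class OriginCandidate:
    start: int  # 0-based window start
    end: int    # 0-based exclusive
    at_fraction: float
    rel_coverage: float


def at_rich_scan(
    genome: CircularSequence,
    coverage: np.ndarray,
    window: int = 200,
    step: int | None = None,
    at_min: float = 0.80,
    cov_quantile: float = 0.05,
) -> list[OriginCandidate]:
    """Rank sliding windows as replication-origin candidates.

    Candidates are windows with AT fraction >= `at_min` whose mean coverage
    falls in the lowest `cov_quantile` of all windows; ranked by
    (AT fraction desc, relative coverage asc). Reports candidates only — the
    biological call requires outside evidence.
    """
    if window < 50:
        raise ValueError("window must be >= 50")
    step = step or max(1, window // 4)
    L = len(genome)
    seq = genome.doubled()
    is_at = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(np.int64)
    at_cum = np.concatenate([[0], np.cumsum(is_at)])
    cov2 = np.concatenate([coverage, coverage])
    cov_cum = np.concatenate([[0], np.cumsum(cov2)])
    genome_mean = float(coverage.mean()) if coverage.size else 0.0

    starts = list(range(0, L, step))
    at_frac = np.array([(at_cum[s + window] - at_cum[s]) / window for s in starts])
    cov_mean = np.array([(cov_cum[s + window] - cov_cum[s]) / window for s in starts])
    thresh = np.quantile(cov_mean, cov_quantile)
    out = []
    for i, s in enumerate(starts):
        if at_frac[i] >= at_min and cov_mean[i] <= thresh:
            rel = cov_mean[i] / genome_mean if genome_mean > 0 else 0.0
            out.append(OriginCandidate(start=s, end=s + window, at_fraction=float(at_frac[i]), rel_coverage=float(rel)))
    out.sort(key=lambda c: (-c.at_fraction, c.rel_coverage, c.start))
    return out
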