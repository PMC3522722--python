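import numpy as np
import pytest

import circulome as c
from circulome.repeats import RecombinationError


def bruteforce_repeats(seq: str, min_len: int):
    """Quadratic oracle: all maximal exact repeated pairs (direct and
    inverted) of length >= min_len on the circle, via naive extension from
    every seed pair of min_len-mers."""
    L = len(seq)

    def at(i):
        return seq[i % L]

    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    found = set()
    sub = {}
    for i in range(L):
        km = "".join(at(i + t) for t in range(min_len))
        sub.setdefault(km, []).append(i)
    for km, pos in sub.items():
        for i in pos:
            for j in pos:
                if i >= j:
                    continue
                a, b, ln = i, j, min_len
                while ln < L and at(a - 1) == at(b - 1):
                    a, b, ln = a - 1, b - 1, ln + 1
                while ln < L and at(a + ln) == at(b + ln):
                    ln += 1
                sa, sb = sorted((a % L, b % L))
                if (sa - sb) % L != 0:
                    found.add(("direct", sa, sb, ln))
        rc = "".join(comp[x] for x in reversed(km))
        for i in pos:
            for j in sub.get(rc, []):
                if km == rc and j <= i:
                    continue
                a, bend, ln = i, j + min_len, min_len
                while ln < L and at(a - 1) == comp[at(bend)]:
                    a, ln, bend = a - 1, ln + 1, bend + 1
                while ln < L and at(a + ln) == comp[at(bend - ln - 1)]:
                    ln += 1
                sa, sb = sorted((a % L, (bend - ln) % L))
                if sa != sb:
                    found.add(("inverted", sa, sb, ln))
    # suppress contained pairs, mirroring the reported-maximal contract
    pairs = sorted(found, key=lambda t: (-t[3], t[1], t[2]))
    kept = []
    for kind, sa, sb, ln in pairs:
        contained = False
        for k2, qa, qb, qln in kept:
            if k2 != kind:
                continue
            ra, rb = (sa - qa) % L, (sb - qb) % L
            rx, ry = (sa - qb) % L, (sb - qa) % L
            if (ra + ln <= qln and rb + ln <= qln) or (rx + ln <= qln and ry + ln <= qln):
                contained = True
                break
        if not contained:
            kept.append((kind, sa, sb, ln))
    return set(kept)


class TestFindRepeats:
    def test_planted_direct_pair_found_exactly(self):
        spec = c.GenomeSpec(length=50_000, repeats=[c.RepeatPlan("direct", 2_000)], seed=1)
        genome, _, truth = c.generate_genome(spec)
        pairs = c.find_repeats(genome, min_len=1_000)
        assert len(pairs) == 1
        p, r = pairs[0], truth.repeats[0]
        # maximal extension may pick up a few flanking bases that match by chance
        assert p.kind == "direct" and 2_000 <= p.length <= 2_010 and p.identity == 100.0
        assert abs(p.start_a - r["start_a"]) <= 10 or abs(p.start_a - r["start_b"]) <= 10
        assert genome.fetch(p.start_a, p.length) == genome.fetch(p.start_b, p.length)

    def test_planted_inverted_pair_is_revcomp(self):
        spec = c.GenomeSpec(length=30_000, repeats=[c.RepeatPlan("inverted", 1_500)], seed=2)
        genome, _, truth = c.generate_genome(spec)
        (p,) = c.find_repeats(genome, min_len=1_000)
        assert p.kind == "inverted"
        assert genome.fetch(p.start_b, p.length) == c.revcomp(genome.fetch(p.start_a, p.length))

    def test_repeat_spanning_circle_origin_found(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(np.array(list("ACGT")), size=8_000))
        rep = base[3_000:3_500]
        seq = rep[200:] + base[300:3_000] + rep + base[3_500:7_800] + rep[:200]
        (p,) = c.find_repeats(c.CircularSequence(seq), min_len=100)
        assert p.length == 500

    def test_matches_bruteforce_on_small_genome(self):
        spec = c.GenomeSpec(
            length=1_200,
            repeats=[c.RepeatPlan("direct", 60), c.RepeatPlan("inverted", 45)],
            seed=9,
        )
        genome, _, _ = c.generate_genome(spec)
        got = {(p.kind, p.start_a, p.start_b, p.length) for p in c.find_repeats(genome, min_len=40, seed_k=40)}
        assert got == bruteforce_repeats(genome.seq, 40)


class TestRepeatFraction:
    def test_published_inventories_reproduce_printed_fractions(self):
        pongamia = [
            c.RepeatPair("inverted", 0, 100_000, 6_229),
            c.RepeatPair("inverted", 20_000, 120_000, 2_274),
            c.RepeatPair("direct", 40_000, 200_000, 13_319),
            c.RepeatPair("direct", 60_000, 300_000, 3_919),
        ]
        assert c.repeat_fraction(pongamia, 425_718) == 12.09
        lotus = [
            c.RepeatPair("inverted", 0, 100_000, 4_460),
            c.RepeatPair("direct", 50_000, 250_000, 18_971),
        ]
        assert c.repeat_fraction(lotus, 380_861) == 12.30

    def test_no_repeats_zero(self):
        assert c.repeat_fraction([], 1_000) == 0.0


class TestRecombination:
    def test_toy_circle_subcircle_sizes(self):
        pair = c.RepeatPair("direct", 10, 40, 20)
        prods = c.recombination_products(100, [pair])
        assert sorted(p.size for p in prods) == [30, 70]
        assert all(p.kind == "subcircle" for p in prods)

    def test_subcircle_sizes_sum_to_parent(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            L = int(rng.integers(1_000, 1_000_000))
            length = int(rng.integers(20, 200))
            s1 = int(rng.integers(0, L))
            s2 = (s1 + int(rng.integers(length + 1, L - length - 1))) % L
            prods = c.recombination_products(L, [c.RepeatPair("direct", s1, s2, length)])
            assert sum(p.size for p in prods) == L

    def test_inverted_pair_gives_isomer_of_same_size(self):
        prods = c.recombination_products(100, [c.RepeatPair("inverted", 10, 60, 10)])
        (p,) = prods
        assert p.kind == "isomer" and p.size == 100

    def test_overlapping_copies_error(self):
        with pytest.raises(RecombinationError):
            c.recombination_products(100, [c.RepeatPair("direct", 10, 20, 30)])

    def test_contained_inverted_pair_doubles_isoforms(self):
        # direct pair splits the circle; an inverted pair inside the larger
        # arc gives that subcircle two isoforms
        direct = c.RepeatPair("direct", 0, 300, 20)
        inverted = c.RepeatPair("inverted", 50, 200, 15)
        prods = c.recombination_products(1_000, [direct, inverted])
        sub = {p.size: p for p in prods if p.kind == "subcircle"}
        assert sub[300].n_isoforms == 2 and sub[700].n_isoforms == 1


class TestGcAndDensity:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 100.0), ("AATT", 0.0), ("ACGT", 50.0)])
    def test_gc_examples(self, seq, expected):
        assert c.gc_content(seq) == expected

    def test_all_n_is_error(self):
        with pytest.raises(ValueError):
            c.gc_content("NNNN")

    def test_generator_hits_target_gc_at_scale(self):
        spec = c.GenomeSpec(length=100_000, gc_background=0.45, seed=31)
        genome, _, _ = c.generate_genome(spec)
        assert abs(c.gc_content(genome) - 45.0) <= 0.5

    def test_gene_density_simple_and_union(self):
        feats = [c.FeatureRecord("g", "CDS", 1, 500)]
        assert c.gene_density(feats, 1_000)["protein_coding"] == 50.0
        overlapping = [c.FeatureRecord("g", "CDS", 100, 300), c.FeatureRecord("g", "CDS", 200, 400)]
        assert c.gene_density(overlapping, 1_000)["protein_coding"] == 30.1  # 301 bp union

    def test_empty_features_all_zero(self):
        out = c.gene_density([], 1_000)
        assert set(out.values()) == {0.0}

    def test_feature_past_genome_end_is_error(self):
        with pytest.raises(ValueError):
            c.gene_density([c.FeatureRecord("g", "CDS", 900, 1_100)], 1_000)


class TestMotifScan:
    def test_plus_strand_motif_found(self):
        seq = "T" * 85 + "GGAGG" + "TTTTTTTTTT" + "ATGAAATAA" + "T" * 100
        genome = c.CircularSequence(seq)
        feat = c.FeatureRecord("g", "CDS", 101, 109, strand="+")
        assert c.upstream_motif_scan(genome, [feat], window=20) == [feat]

    def test_opposite_strand_motif_not_reported(self):
        seq = "T" * 85 + c.revcomp("GGAGG") + "TTTTTTTTTT" + "ATGAAATAA" + "T" * 100
        genome = c.CircularSequence(seq)
        feat = c.FeatureRecord("g", "CDS", 101, 109, strand="+")
        assert c.upstream_motif_scan(genome, [feat], window=20) == []

    def test_planted_subset_recovered_exactly(self):
        spec = c.GenomeSpec(
            length=60_000,
            genes=[c.GenePlan("CDS", 30, (300, 600))],
            motif_genes=10,
            seed=12,
        )
        genome, features, truth = c.generate_genome(spec)
        hits = c.upstream_motif_scan(genome, features, window=20)
        got = {f.attributes["ID"] for f in hits}
        assert got == set(truth.motif_gene_ids)
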