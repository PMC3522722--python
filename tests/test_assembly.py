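import numpy as np
import pytest

import circulome as c
from circulome.assembly import Contig
from circulome.model import canonical_strand


def bruteforce_edges(reads: list[str], naive_offset: int):
    """Quadratic oracle: all ordered oriented pairs with an exact
    suffix-prefix overlap at offset <= naive_offset (minimal offset kept),
    expressed over canonical node sequences."""
    rl = len(reads[0])
    nodes = sorted({canonical_strand(s) for s in reads})
    idx = {s: i for i, s in enumerate(nodes)}
    edges = set()
    for s_can in nodes:
        for sa, st_a in ((s_can, 0), (c.revcomp(s_can), 1)):
            for t_can in nodes:
                for tb, st_b in ((t_can, 0), (c.revcomp(t_can), 1)):
                    if st_b == 1 and c.revcomp(t_can) == t_can:
                        continue
                    for o in range(1, naive_offset + 1):
                        if sa[o:] == tb[: rl - o]:
                            edges.add((idx[s_can], st_a, idx[t_can], st_b, o))
                            break
    # drop duplicate orientation rows for palindromic sources
    return {e for e in edges if not (e[1] == 1 and c.revcomp(nodes[e[0]]) == nodes[e[0]])}


class TestOverlapGraph:
    def test_offset_definition_example(self):
        # "ACGTAC" then "GTACGG": non-overlapping parts total 2 -> offset 2
        lib = c.ReadLibrary(reads=[c.Read("a", "ACGTAC"), c.Read("b", "GTACGG")])
        params = c.AssemblyParams(naive_offset=2, extension_offset=2, readlength=6)
        g = c.build_overlap_graph(lib, params)
        edges = g.edges()
        assert any(o == 2 for (_, _, _, _, o) in edges)

    def test_too_small_offset_no_edge(self):
        lib = c.ReadLibrary(reads=[c.Read("a", "ACGTAC"), c.Read("b", "GTACGG")])
        params = c.AssemblyParams(naive_offset=1, extension_offset=1, readlength=6)
        g = c.build_overlap_graph(lib, params)
        assert g.edges() == []

    def test_no_reads_is_error(self):
        with pytest.raises(ValueError, match="no reads"):
            c.build_overlap_graph(c.ReadLibrary(), c.AssemblyParams(readlength=36))

    def test_wrong_length_reads_discarded(self):
        lib = c.ReadLibrary(reads=[c.Read("a", "ACGTAC"), c.Read("b", "ACG")])
        g = c.build_overlap_graph(lib, c.AssemblyParams(naive_offset=1, extension_offset=2, readlength=6))
        assert len(g) == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(13)
        genome = "".join(rng.choice(np.array(list("ACGT")), size=800))
        rl = 20
        starts = rng.integers(0, 780, size=150)
        seqs = []
        for s in starts:
            sub = genome[s : s + rl]
            seqs.append(sub if rng.integers(0, 2) == 0 else c.revcomp(sub))
        lib = c.ReadLibrary(reads=[c.Read(f"r{i}", s) for i, s in enumerate(seqs)])
        params = c.AssemblyParams(naive_offset=3, extension_offset=5, readlength=rl)
        g = c.build_overlap_graph(lib, params)
        got = set()
        for (nid, st, mid, mst, o) in g.edges():
            got.add((nid, st, mid, mst, o))
        assert got == bruteforce_edges(seqs, 3)


class TestWalkContigs:
    def test_linear_chain_yields_superstring(self):
        base = "ATTGCCGTAAGCTAGGCATC"
        rl, step = 10, 2
        reads = [base[i : i + rl] for i in range(0, len(base) - rl + 1, step)]
        lib = c.ReadLibrary(reads=[c.Read(f"r{i}", s) for i, s in enumerate(reads)])
        params = c.AssemblyParams(naive_offset=2, extension_offset=4, readlength=rl)
        contigs = c.walk_contigs(c.build_overlap_graph(lib, params))
        assert len(contigs) == 1
        assert contigs[0].seq in (base, c.revcomp(base))

    def test_dense_tiling_reconstructs_circle_exactly(self):
        rng = np.random.default_rng(5)
        L = 5_000
        genome = c.CircularSequence("".join(rng.choice(np.array(list("ACGT")), size=L)))
        rl = 36
        doubled = genome.doubled()
        lib = c.ReadLibrary(reads=[c.Read(f"r{i}", doubled[i : i + rl]) for i in range(L)])
        params = c.AssemblyParams(naive_offset=4, extension_offset=12, readlength=rl)
        contigs = c.walk_contigs(c.build_overlap_graph(lib, params))
        assert len(contigs) == 1 and contigs[0].circular
        circle = c.circularize(contigs[0], params=params)
        assert isinstance(circle, c.CircularSequence)
        assert len(circle) == L and genome.equivalent(circle)

    def test_walk_stops_at_long_repeat_flanks(self):
        # one exact 2 kb direct repeat; 36 bp reads cannot span it, so the
        # walk must terminate inside the repeat margins instead of guessing
        spec = c.GenomeSpec(length=12_000, repeats=[c.RepeatPlan("direct", 2_000)], seed=17)
        genome, _, truth = c.generate_genome(spec)
        rl = 36
        doubled = genome.doubled()
        lib = c.ReadLibrary(reads=[c.Read(f"r{i}", doubled[i : i + rl]) for i in range(len(genome))])
        params = c.AssemblyParams(naive_offset=4, extension_offset=12, readlength=rl)
        contigs = c.walk_contigs(c.build_overlap_graph(lib, params))
        assert len(contigs) >= 2
        assert all(not ct.circular for ct in contigs)
        assert max(len(ct) for ct in contigs) < len(genome)

    def test_depth_accounts_for_read_multiplicity(self):
        reads = ["ACGTACGTAA"] * 3 + ["GTACGTAACC"] * 3
        lib = c.ReadLibrary(reads=[c.Read(f"r{i}", s) for i, s in enumerate(reads)])
        params = c.AssemblyParams(naive_offset=2, extension_offset=3, readlength=10)
        contigs = c.walk_contigs(c.build_overlap_graph(lib, params))
        assert len(contigs) == 1
        assert contigs[0].depth.min() >= 3 and contigs[0].depth.max() == 6


class TestCircularize:
    def test_terminal_repeat_merges(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(np.array(list("ACGT")), size=300))
        tip = core[:40]
        seq = core + tip  # ends share 40 bp
        out = c.circularize(seq, min_overlap=30)
        assert isinstance(out, c.CircularSequence)
        assert len(out) == 300

    def test_canonical_rotation_idempotent(self):
        circ = c.CircularSequence("GATTACAGATT")
        once = circ.canonical()
        assert once.canonical().seq == once.seq

    def test_no_overlap_returned_linear(self):
        out = c.circularize("ACGTACGTTTTTGCA", min_overlap=8)
        assert isinstance(out, c.SequenceRecord) and not out.circular


class TestScaffold:
    def _setup(self):
        rng = np.random.default_rng(0)
        seg = "".join(rng.choice(np.array(list("ACGT")), size=6_000))
        A, B = seg[:2_500], seg[3_500:]
        contigs = [Contig(seq=A, depth=np.ones(len(A))), Contig(seq=B, depth=np.ones(len(B)))]
        return seg, contigs

    def _bridge_pairs(self, seg, n, start=2_350, insert=1_200, rl=63):
        reads = []
        for i in range(n):
            s = start + 2 * i
            frag = seg[s : s + insert]
            reads.append(c.Read(f"b{i}/1", frag[:rl], pair_id=f"b{i}", mate=1))
            reads.append(c.Read(f"b{i}/2", c.revcomp(frag[-rl:]), pair_id=f"b{i}", mate=2))
        return reads

    def test_bridged_contigs_form_one_scaffold_with_gap(self):
        seg, contigs = self._setup()
        lib = c.ReadLibrary(reads=self._bridge_pairs(seg, 20))
        params = c.AssemblyParams(readlength=63)
        scafs = c.scaffold_pairs(contigs, lib, params, insert_mean=1_200, insert_sd=120, min_links=5)
        assert len(scafs) == 1 and len(scafs[0].items) == 2
        assert abs(scafs[0].gaps[0] - 1_000) <= 120  # true gap within one sd

    def test_too_few_links_left_unscaffolded(self):
        seg, contigs = self._setup()
        lib = c.ReadLibrary(reads=self._bridge_pairs(seg, 2))
        params = c.AssemblyParams(readlength=63)
        scafs = c.scaffold_pairs(contigs, lib, params, insert_mean=1_200, insert_sd=120, min_links=5)
        assert len(scafs) == 2

    def test_conflicting_links_majority_wins(self):
        seg, contigs = self._setup()
        good = self._bridge_pairs(seg, 12)
        # minority: swap the mates' roles so the implied orientation conflicts
        bad = []
        for i in range(3):
            s = 2_350 + 2 * i
            frag = seg[s : s + 1_200]
            bad.append(c.Read(f"x{i}/1", c.revcomp(frag[:63]), pair_id=f"x{i}", mate=1))
            bad.append(c.Read(f"x{i}/2", frag[-63:], pair_id=f"x{i}", mate=2))
        lib = c.ReadLibrary(reads=good + bad)
        params = c.AssemblyParams(readlength=63)
        scafs = c.scaffold_pairs(contigs, lib, params, insert_mean=1_200, insert_sd=120, min_links=5)
        assert len(scafs) == 1
        # majority orientation: the two contigs run the same way (both '+' or both '-')
        orients = [o for _, o in scafs[0].items]
        assert orients in (["+", "+"], ["-", "-"])


class TestPolish:
    @pytest.fixture(scope="class")
    def genome_and_reads(self):
        spec = c.GenomeSpec(length=10_000, seed=3)
        genome, _, _ = c.generate_genome(spec)
        lib, _ = c.simulate_read_library(
            genome, c.LibrarySpec(read_length=63, insert_mean=350.0, n_pairs=4_000, seed=5)
        )
        return genome, lib

    def test_substitution_restored(self, genome_and_reads):
        genome, lib = genome_and_reads
        params = c.AssemblyParams(readlength=63)
        sq = genome.seq
        broken = sq[:5_000] + ("A" if sq[5_000] != "A" else "G") + sq[5_001:]
        out = c.polish(c.CircularSequence(broken), lib, params)
        assert out.seq == sq

    def test_deletion_restored(self, genome_and_reads):
        genome, lib = genome_and_reads
        params = c.AssemblyParams(readlength=63)
        sq = genome.seq
        broken = sq[:4_000] + sq[4_001:]
        out = c.polish(c.CircularSequence(broken), lib, params)
        assert out.seq == sq

    def test_correct_reference_is_fixpoint(self, genome_and_reads):
        genome, lib = genome_and_reads
        params = c.AssemblyParams(readlength=63)
        out = c.polish(genome, lib, params)
        assert out.seq == genome.seq


class TestMapReads:
    def test_substring_maps_at_truth(self):
        rng = np.random.default_rng(7)
        genome = c.CircularSequence("".join(rng.choice(np.array(list("ACGT")), size=3_000)))
        params = c.AssemblyParams(readlength=40)
        lib = c.ReadLibrary(reads=[c.Read("r", genome.seq[100:140])])
        (a,) = c.map_reads(genome, lib, params)
        assert a.mapped and a.start == 100 and a.strand == "+" and not a.multi

    def test_repeat_read_flagged_multimapped(self):
        spec = c.GenomeSpec(length=8_000, repeats=[c.RepeatPlan("direct", 500, (1_000, 5_000))], seed=4)
        genome, _, _ = c.generate_genome(spec)
        params = c.AssemblyParams(readlength=40)
        lib = c.ReadLibrary(reads=[c.Read("rep", genome.seq[1_100:1_140])])
        (a,) = c.map_reads(genome, lib, params)
        assert a.mapped and a.multi and a.start == 1_100  # lowest coordinate

    def test_truth_agreement_on_simulation(self, small_genome):
        genome, _, _ = small_genome
        lib, truth = c.simulate_read_library(
            genome, c.LibrarySpec(read_length=63, insert_mean=350.0, n_pairs=1_000, seed=19)
        )
        params = c.AssemblyParams(readlength=63)
        alns = c.map_reads(genome, lib, params)
        ok = 0
        for a in alns:
            s, _, strand = truth.read_sources[a.read_id]
            if a.mapped and (a.start == s and a.strand == strand or a.multi):
                ok += 1
        assert ok / len(alns) >= 0.99
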