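import itertools

import numpy as np
import pytest

import circulome as c


def bruteforce_best_score(a: str, b: str, p: c.AlignParams) -> float:
    """Exhaustive global alignment optimum for tiny sequences.

    Enumerates all monotone alignments recursively; a gap of length g costs
    open + (g-1) * extend (the package's affine convention).
    """
    best = [-1e18]

    def rec(i, j, score, prev_gap):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = p.match if a[i] == b[j] else p.mismatch
            rec(i + 1, j + 1, score + s, None)
        if i < len(a):
            g = p.gap_extend if prev_gap == "a" else p.gap_open
            rec(i + 1, j, score + g, "a")
        if j < len(b):
            g = p.gap_extend if prev_gap == "b" else p.gap_open
            rec(i, j + 1, score + g, "b")

    rec(0, 0, 0.0, None)
    return best[0]


class TestGlobalAlign:
    def test_identical_no_gaps(self):
        aln = c.global_align("ACGT", "ACGT")
        assert aln.row_a == "ACGT" and aln.row_b == "ACGT"

    def test_single_gap_column(self):
        aln = c.global_align("ACGT", "AGT")
        assert (aln.row_a + aln.row_b).count("-") == 1
        assert aln.row_a.replace("-", "") == "ACGT" and aln.row_b.replace("-", "") == "AGT"

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        params = c.AlignParams()
        for _ in range(12):
            la, lb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a = "".join(rng.choice(np.array(list("ACGT")), size=la))
            b = "".join(rng.choice(np.array(list("ACGT")), size=lb))
            aln = c.global_align(a, b, params)
            assert aln.score == pytest.approx(bruteforce_best_score(a, b, params))

    def test_degapping_recovers_inputs(self):
        aln = c.global_align("ACGTACGT", "ACTTACG")
        assert aln.row_a.replace("-", "") == "ACGTACGT"
        assert aln.row_b.replace("-", "") == "ACTTACG"


class TestPercentIdentity:
    def test_identical(self):
        assert c.percent_identity(c.PairwiseAlignment("A" * 10, "A" * 10)) == 100.00

    def test_three_of_four(self):
        assert c.percent_identity(c.PairwiseAlignment("ACGT", "ACGA")) == 75.00

    def test_gap_columns_count_in_denominator(self):
        # 4 identical of 5 columns; the gap column is never identical
        assert c.percent_identity(c.PairwiseAlignment("AC-GT", "ACTGT")) == 80.00

    def test_symmetry(self):
        a, b = "ACGTAC-GT", "ACTTACGGT"
        assert c.percent_identity(c.PairwiseAlignment(a, b)) == c.percent_identity(c.PairwiseAlignment(b, a))

    def test_zero_length_error(self):
        with pytest.raises(ValueError):
            c.percent_identity(c.PairwiseAlignment("", ""))


class TestGeneDivergence:
    def test_identical_zero_both_levels(self):
        cds = "ATG" + "GCT" * 50 + "TAA"
        assert c.gene_divergence(cds, cds, "nt") == 0.00
        assert c.gene_divergence(cds, cds, "aa") == 0.00

    def test_synonymous_third_position_change(self):
        # one silent change in a 300 bp CDS: nt 1/300, aa 0
        a = "ATG" + "GCT" * 98 + "TAA"
        b = "ATG" + "GCC" + "GCT" * 97 + "TAA"
        assert c.gene_divergence(a, b, "nt") == 0.33
        assert c.gene_divergence(a, b, "aa") == 0.00

    def test_nonsynonymous_change_100_codons(self):
        a = "ATG" + "GCT" * 98 + "TAA"  # 100 codons + stop
        b = "ATG" + "CCT" + "GCT" * 97 + "TAA"
        assert c.gene_divergence(a, b, "aa") == 1.01  # 1 of 99 aa (stop dropped)

    def test_k_substitutions_exact_fraction(self):
        rng = np.random.default_rng(8)
        base = "ATG" + "".join(rng.choice(np.array(["GCT", "GAA", "TGG", "CAT"]), size=99)) + "TAA"
        for k in (1, 3, 7):
            chars = list(base)
            idx = rng.choice(np.arange(3, len(base) - 3), size=k, replace=False)
            for i in idx:
                chars[i] = {"A": "G", "C": "A", "G": "T", "T": "C"}[chars[i]]
            div = c.gene_divergence(base, "".join(chars), "nt")
            assert div == round(100.0 * k / len(base), 2)

    def test_acg_start_translates_like_atg(self):
        a = "ATG" + "GCT" * 30 + "TAA"
        b = "ACG" + "GCT" * 30 + "TAA"
        assert c.gene_divergence(a, b, "aa") == 0.00

    def test_internal_stop_warns_and_truncates(self):
        a = "ATG" + "GCT" * 10 + "TAA" + "GCT" * 10 + "TAA"
        with pytest.warns(UserWarning, match="internal stop"):
            c.translate_cds(a)


class TestSummarize:
    PAIRS = [("Lj", "Pp"), ("Pp", "Vr"), ("Vr", "Lj")]

    def _records(self):
        recs = []
        for pair, v in zip(self.PAIRS, [7.99, 7.49, 9.62]):
            recs.append(c.DivergenceRecord("cp_genes", pair, "chloroplast", nt_divergence=v))
        for pair, v in zip(self.PAIRS, [1.60, 1.29, 1.87]):
            recs.append(c.DivergenceRecord("mt_genes", pair, "mitochondrion", nt_divergence=v))
        for pair, ident in zip(self.PAIRS, [91.58, 91.53, 89.91]):
            recs.append(c.DivergenceRecord("cp_genes", pair, "chloroplast", aa_divergence=round(100 - ident, 2)))
        for pair, ident in zip(self.PAIRS, [97.74, 97.70, 97.37]):
            recs.append(c.DivergenceRecord("mt_genes", pair, "mitochondrion", aa_divergence=round(100 - ident, 2)))
        return recs

    def test_genome_means_match_printed_values(self):
        s = c.summarize(self._records())
        assert s.genome_means[("chloroplast", "nt")] == 8.37
        assert s.genome_means[("mitochondrion", "nt")] == 1.59
        assert s.genome_means[("chloroplast", "aa")] == 8.99
        assert s.genome_means[("mitochondrion", "aa")] == 2.40

    def test_fold_ratio(self):
        s = c.summarize(self._records())
        assert s.fold["nt"] == 5.26

    def test_means_within_input_range(self):
        s = c.summarize(self._records())
        for (genome, level), m in s.genome_means.items():
            vals = [v for key, v in s.pair_means.items() if key[0] == genome and key[1] == level]
            assert min(vals) <= m <= max(vals) + 0.01

    def test_genes_average_within_pairs_first(self):
        recs = [
            c.DivergenceRecord("g1", ("A", "B"), "chloroplast", nt_divergence=2.0),
            c.DivergenceRecord("g2", ("A", "B"), "chloroplast", nt_divergence=4.0),
            c.DivergenceRecord("g1", ("A", "C"), "chloroplast", nt_divergence=10.0),
        ]
        s = c.summarize(recs)
        # pair AB mean 3.0, pair AC mean 10.0 -> genome mean 6.5 (not 16/3)
        assert s.genome_means[("chloroplast", "nt")] == 6.5
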