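"""Per-gene divergence (100 - pairwise percent identity) and its summary.

Aligns diverged copies of a coding sequence at the nucleotide and
amino-acid level, then summarizes species-pair means into genome-level
means and a chloroplast/mitochondrion fold ratio the way the published
comparison tables are condensed.
"""
import circulome as c

cds = "ATG" + "GCT" * 198 + "TAA"  # 200 codons of alanine

# a synonymous (GCT -> GCC, still Ala) and a nonsynonymous (GCT -> CCT, Pro) change
syn = cds[:3] + "GCC" + cds[6:]
nonsyn = cds[:3] + "CCT" + cds[6:]
print("single third-position change:",
      f"nt {c.gene_divergence(cds, syn, 'nt')}%, aa {c.gene_divergence(cds, syn, 'aa')}%")
print("single first-position change: ",
      f"nt {c.gene_divergence(cds, nonsyn, 'nt')}%, aa {c.gene_divergence(cds, nonsyn, 'aa')}%")

# summarize per-pair values into genome means and the cp/mt fold ratio
pairs = [("A", "B"), ("B", "C"), ("C", "A")]
records = []
for pair, v in zip(pairs, [7.99, 7.49, 9.62]):
    records.append(c.DivergenceRecord("genes", pair, "chloroplast", nt_divergence=v))
for pair, v in zip(pairs, [1.60, 1.29, 1.87]):
    records.append(c.DivergenceRecord("genes", pair, "mitochondrion", nt_divergence=v))
summary = c.summarize(records)
cp = summary.genome_means[("chloroplast", "nt")]
mt = summary.genome_means[("mitochondrion", "nt")]
print(f"chloroplast mean {cp}%, mitochondrial mean {mt}%, fold ratio {summary.fold['nt']}")
print("(chloroplast coding sequence diverges several-fold faster than mitochondrial)")
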