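"""Simulate a circular genome, sequence it, and reassemble it exactly.

Builds a 30 kb circular genome with short planted repeats and an AT-rich
origin window, simulates an error-free 63 bp paired-end library, and runs
the full pipeline: cut -> overlap graph -> contig walk -> circularize ->
polish. Prints the reconstruction verdict (exact up to rotation and strand).
"""
import circulome as c

spec = c.GenomeSpec(
    length=30_000,
    gc_background=0.45,
    repeats=[c.RepeatPlan("direct", 25), c.RepeatPlan("inverted", 25)],
    origin=(10_000, 200, 0.9),
    genes=[c.GenePlan("CDS", 6, (300, 600))],
    seed=42,
)
genome, features, truth = c.generate_genome(spec)
print(f"genome: {len(genome):,} bp, GC {genome.gc}%, {len(features)} features")

library, _ = c.simulate_read_library(
    genome, c.LibrarySpec(read_length=63, insert_mean=350.0, n_pairs=26_000, seed=7)
)
print(f"library: {len(library):,} reads of 63 bp (~{len(library) * 63 // len(genome)}x coverage)")

params = c.AssemblyParams(naive_offset=4, extension_offset=12, readlength=63)
library = c.trim_and_cut(library, c.CutParams(trim_length=0, out_readlength=63, start_offset=63))
graph = c.build_overlap_graph(library, params)
contigs = c.walk_contigs(graph, params)
print(f"assembly: {len(graph):,} unique reads -> {len(contigs)} contig(s)")

circle = c.circularize(contigs[0], params=params)
polished = c.polish(circle, library, params)
print(f"circularized length: {len(polished):,} bp (truth {len(genome):,} bp)")
print("exact reconstruction up to rotation/strand:", genome.equivalent(polished))
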