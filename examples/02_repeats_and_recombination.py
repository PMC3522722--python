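"""Repeat inventory and recombination structure of a master circle.

Plants a large direct pair and an inverted pair on a synthetic circle,
rediscovers them, and predicts the subcircles and isomeric circles that
repeat-mediated intramolecular recombination would generate. The two
subcircle sizes of any direct pair always sum to the parent length.
"""
import circulome as c

spec = c.GenomeSpec(
    length=120_000,
    repeats=[
        c.RepeatPlan("direct", 5_000, (10_000, 80_000)),
        c.RepeatPlan("inverted", 2_000, (30_000, 60_000)),
    ],
    seed=1,
)
genome, _, truth = c.generate_genome(spec)

pairs = c.find_repeats(genome, min_len=1_000)
print(f"genome {len(genome):,} bp; {len(pairs)} repeat pairs found:")
for p in pairs:
    print(f"  {p.kind:8s} copies at {p.start_a:>7,} / {p.start_b:>7,}, {p.length:,} bp, {p.identity}% identity")

print(f"repeat fraction: {c.repeat_fraction(pairs, len(genome))}% of the genome")

products = c.recombination_products(genome, pairs)
for pr in products:
    extra = f", {pr.n_isoforms} isoform(s)" if pr.kind == "subcircle" else ""
    print(f"  predicted {pr.kind}: {pr.size:,} bp (parent {pr.parent}{extra})")
sub_sizes = [pr.size for pr in products if pr.kind == "subcircle" and pr.parent == "master"]
print(f"subcircle sizes sum to parent: {sum(sub_sizes):,} == {len(genome):,}")
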