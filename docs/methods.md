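# Methods

This note documents the models, conventions and numerical choices behind
`circulome`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real data.

## Coordinates and circular conventions

Internally every interval is 0-based, half-open; the I/O layer alone
converts to the 1-based inclusive convention of GFF3 and SAM, so the
conversion is a single testable boundary. A circular molecule is a string
plus wrap-aware accessors; operations that must see across the origin
(read simulation, repeat discovery, mapping, coverage) work on the doubled
string and reduce positions mod L. The canonical form of a circle is the
lexicographically least rotation over both strands (Booth's algorithm),
which makes "equal up to rotation and strand" a string equality. Features
that wrap the origin are written as two GFF3 records sharing a `Part_of`
attribute, since GFF3 has no native circular wrap.

## Synthetic genomes and libraries

The generator emulates the conditions of a plant-organelle resequencing
project. Background sequence is i.i.d. at the requested GC (default 0.45,
the mitochondrial value; chloroplast work would use ~0.35). Repeat copies
are sampled first and written as exact copies (direct: same strand;
inverted: reverse complement), then origin and genes are placed without
overlap (a 25 bp upstream margin per gene leaves room for motif planting);
placement failure raises a packing error rather than silently overlapping.
The AT-rich origin window receives an exact rounded AT count so the
requested fraction is met within half a percentage point. CDS features are
genuine open reading frames (ATG + non-stop codons + stop) so translation
and editing tests operate on biologically well-formed input.

Libraries follow the three designs of the study data: 36 bp paired-end
reads from ~390 bp fragments, 75 bp mate-pair reads from ~3 kb fragments
with a minor short-insert "shadow" component (~220 bp, 5% by default), and
100 bp paired-end reads from ~350 bp fragments. Fragments are uniform on
the circle; insert lengths are Normal(mean, sd) truncated below at the
read length, with sd defaulting to 10% of the mean (the study reports only
approximate means). Paired-end libraries are FR-oriented, mate-pair RF,
matching the library chemistry of that sequencing era; both are
configurable. Substitution errors are i.i.d. per base; quality strings are
constant because no stage of the pipeline is quality-aware. Every read's
source interval and strand is recorded in a truth table, and with error
rate 0 extracting the truth interval reproduces the read exactly — the
test substrate for the whole assembly surface.

What the synthetic model omits about real data: sequencing error is purely
substitutional and position-independent (no quality decay, no indel
errors), coverage is exactly uniform (no GC bias, no chimeric fragments
beyond the shadow component, no nuclear-genome contamination), and repeats
are exact copies. Passing the end-to-end tests therefore demonstrates the
correctness of the algorithms under their stated assumptions, not
robustness to every artefact of a real flow cell.

## Read preparation

Trimming removes a fixed number of bases from the 3' end by default — the
end where short-read quality decays — with the 5' end available as an
option; the removed-bases reading of "trim length" is the one under which
a 75 bp read with trim 36/out 35/step 4 yields exactly 2 fragments and
trim 32 yields 3, reproducing the published fragment totals. The cutter is
a pure function; pooling multiple cut configurations is the caller's
concatenation.

## Assembly

The assembler is overlap-layout over uniform-length reads with exact
overlaps only. Offset is defined as the total length of the
non-overlapping parts of two overlapped reads, so with a fixed read length
offset and overlap are a bijection and overlap detection is exact
suffix/prefix hashing (a single prefix index at the shortest relevant
overlap length serves all offsets; edges are materialized lazily, which
keeps million-read graphs in bounded memory while small graphs remain
comparable to a brute-force all-pairs oracle).

Reads are deduplicated under strand canonicalization (each stored as the
lexicographically smaller of itself and its reverse complement) with
multiplicity kept as depth. Exactness is a deliberate choice: error
handling is delegated to depth — majority consensus during polishing, and
multiplicity thresholds available at walk time — because an exact graph is
testable against enumeration.

Contig walking uses transitive reduction: each step follows the successor
at the minimal offset, searching first within the naive offset and then,
where nothing is found, out to the extension offset. A step is refused at
a genuine branch — two distinct successors at the minimal offset, or any
further successor within the extension radius that is not itself an
exact-overlap successor of the chosen one. This is the signature of a
repeat boundary, and it is what makes the walk stop at the flanks of
repeats longer than the minimum overlap instead of guessing a
continuation. A literal "continue only when exactly one edge exists within
the extension offset" rule is not usable under random fragment sampling,
where dozens of transitively implied edges coexist at every position; the
reduction preserves the rule's intent. A walk that returns to its starting
read closes a circle, and circularization then trims the duplicated
terminal overlap to the true circle length; linear sequences are closed
when their ends share an exact overlap of at least readlength −
naive_offset (KMP border search, so arbitrarily long terminal repeats are
found in linear time). All tie-breaking, including output order, is
lexicographic by sequence, so assembly output is byte-identical across
runs.

Resolution limit: repeats shorter than the minimum overlap (readlength −
extension_offset) are resolved inside single reads; repeats at or within a
base or two of that bound can recruit spurious overlaps through
chance-matching flank bases, and repeats longer than it collapse to a
single traversal so the walk stops at their flanks. Scaffolding then
orders and orients the resulting contigs using read pairs (links need a
configurable minimum of agreeing pairs, default 5; conflicting
orientations resolved by majority, gap = median implied gap), but
re-duplicating a collapsed repeat during layout is out of scope — the
full-circle reconstruction guarantee is stated for genomes whose repeats
the graph can resolve.

Polishing maps reads back by exact seed, aligns each to its local
reference window with edlib (so 1 bp indels are representable), and
rewrites a column when an alternative allele holds ≥ 80% of ≥ 5 covering
reads (both configurable), iterating at most 3 rounds or to fixpoint.
Two details matter in homopolymer runs: indel votes are left-normalized to
their leftmost equivalent reference column so reads whose windows start at
different points agree, and the decision denominator is the *spanning*
coverage — reads with at least `max_edits` aligned bases on both sides of
the column — because a read whose alignment merely ends inside a run can
absorb an indel silently and would otherwise dilute the vote below
threshold.

The internal mapper (exact seed of readlength − naive_offset, bounded
mismatches, both strands on the doubled circle, multi-mappers assigned to
the lowest coordinate and flagged) exists so the QC surface needs no
external aligner on synthetic data; SAM from external mappers is accepted
through the same record model.

## Assembly QC

Fragment midpoints and inserts use the minor-arc convention: the insert is
the outer distance along the shorter arc containing both reads (rightmost
inclusive end minus leftmost start) and the midpoint is their
floor-average, mod L — matching how a wrap-aware mapper reports template
length. Pairs are discordant (excluded, counted) when a mate is unmapped,
mates share a strand, or — when the library insert distribution is given —
the implied insert deviates more than 3 sd from the mean. That proper-pair
rule is what makes mis-assemblies visible: fragments spanning a lesion
re-map with a shifted insert and drop out, opening a zero-density window
in the midpoint track. Breakpoint flags are windows (default 100 bp, the
order of a read length) with zero coverage or zero midpoint density,
labelled all-libraries when every library agrees — the mis-assembly
signature — and single-library otherwise. Note the flip side of the 3 sd
rule: a library's insert noise bounds the lesion size it can see (a 3 kb
mate-pair library with 10% sd cannot flag a 500 bp deletion; the
paired-end libraries can).

Origin scanning ranks sliding windows (default 200 bp, step window/4) by
(AT fraction desc, relative coverage asc) and reports windows with AT ≥
0.80 in the lowest 5% coverage quantile as candidates only — the
biological identification of an *oriC* additionally needs outside
evidence, which is out of scope.

## Repeat structure and recombination

Repeat discovery seeds exact k-mer matches (k = min(min_len, 21)) on the
doubled genome and both strands, extends each candidate pair to maximal
exact length, and suppresses pairs contained in longer ones. Maximal
extension routinely adds a base or two of chance-matching flank beyond a
planted repeat — reported lengths are maximal, not planted. Two reporting
regimes are intended: min_len = 1000 for "large repeat" inventories (the
recombinationally relevant class) and 100 for exhaustive scans.

The repeat fraction is 100 · Σ(2 · copy length)/L with overlapping copies
double-counted; this is the convention under which the published
inventories reproduce their printed fractions, and it reflects repeat
*content* rather than covered bases. Subcircle sizes are measured
start-of-copy to start-of-copy — the only convention under which the two
sizes sum exactly to the parent length — leaving one full repeat copy on
each subcircle. Inverted pairs produce isomers of unchanged size; each
inverted pair wholly contained in a subcircle arc doubles that subcircle's
isoform count, and contained direct pairs spawn nested subcircle products
(recursion depth-limited). Gene density is the per-class base-span union
over the genome length; genes duplicated on repeats occupy distinct spans
and both count, consistent with treating duplicates as genome content.
Whether introns should count toward protein-coding density is not
decidable from the published figures; full gene spans are the default and
the class map is a parameter.

## Divergence

The divergence statistic is deliberately simple: 100 minus pairwise
percent identity over a global alignment, where a column scores a hit only
when its two symbols are identical and gap columns count in the
denominator (terminal gaps included, configurable). Nucleotide-level
divergence of coding sequences is reported as the synonymous-tracking
measure and amino-acid-level divergence as the non-synonymous-tracking
measure; this is a column statistic, not a codon-model dN/dS, and should
not be compared against ML estimates. Translation uses the standard code
(plant organellar assignments are standard), tolerates ACG/GTG as an
initiation codon, trims incomplete terminal codons, and truncates at an
internal stop with a warning.

The built-in aligner is Needleman–Wunsch/Gotoh (match +1, mismatch −1, gap
open −5, gap extend −1; a gap of length g costs open + (g−1)·extend) and
is verified against exhaustive enumeration for short sequences; external
alignments in aligned FASTA are accepted verbatim, since fidelity to an
external aligner's output beats re-deriving it. Summaries average genes
within a species pair first, then pairs within a genome, round to two
decimals, and form fold ratios from the rounded means — reproducing the
published means exactly; note that the non-synonymous fold ratio computed
this way is 3.75 against a published "approximately 3.74", which is why
only the synonymous ratio is asserted numerically.

## RNA editing and expression

Edit positions are 1-based offsets from the first base of the start codon
("position after the translational start site" must be read as an offset
from the CDS start, else published start-codon edits would be
inexpressible). Applying an edit writes T at a C position (DNA sense of
C-to-U) and classifies the effect by codon comparison; editing that
creates an in-frame internal stop is surfaced by an explicit checker
rather than accepted silently, because organellar editing is not expected
to create stops. The ABR is edited reads over all covering reads at the
site — the only reading under which a pass threshold of 0.40 is coherent —
with both filter bounds inclusive (ABR ≥ 0.40, coverage ≥ 3). Codon usage
is 1000 · count/total coding bp per codon, so scores × 3 sum to 1000 up to
rounding; duplicated genes are included.

Expression is descriptive only: RPKM = count/(length/1000)/(total/10⁶),
and a gene is flagged when max(a, b)/max(min(a, b), ε) ≥ 2.5 with
ε = 0.01 RPKM guarding zero denominators (the floored denominator keeps
the threshold inclusive at exactly 2.5-fold, e.g. 10 vs 25). No
statistical testing is attempted — the study conditions provide no
biological replication — so flags mark candidates, not significant calls.

## Problem sizes in the test suite

The heavyweight check reassembles twenty randomized circles of 20–100 kb
from error-free 63 bp paired libraries at ~107× (1.7 read starts per
genome position, which keeps the largest start-position gap below the
extension offset with comfortable probability); planted repeats are
20–30 bp, within the graph's resolution limit. Polishing is validated on
120 planted lesions at 50×; edit recovery on 25 CDS at efficiency 0.8,
depth 50; breakpoint detection on a 30 kb genome with two paired-end
libraries at ~34×/~19× per-base coverage. These sizes exercise every code
path at full algorithmic generality while the whole suite stays in the
low minutes on one CPU.

## Known limitations

- Exact-overlap assembly tolerates sequencing error only through depth;
  noisy reads thin the graph rather than mis-joining it, so high error
  rates require deeper coverage or pre-correction.
- Repeats longer than the minimum overlap fragment the assembly by design;
  scaffolding orders the fragments but does not re-duplicate repeat copies.
- The divergence statistic is alignment-dependent and not a substitution
  model; fold ratios inherit rounding conventions.
- The internal mapper is exact-seeded and ungapped (indel-aware alignment
  is confined to polishing); structural variants between reads and
  reference beyond small lesions are out of scope.
- Recombination products are combinatorial predictions from repeat
  geometry; molecular abundances of subcircles and isomers are not
  modelled.
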