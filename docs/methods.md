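# Methods

`mitocomp` implements the standard comparative-analysis workflow for fungal
mitochondrial genomes: a clade of annotated circular genomes goes in, and a
set of machine-readable reports comes out — base composition and strand
skews, per-gene genetic distances, synonymous/nonsynonymous substitution
rates with selection classes, intron position classes on a reference cox1
coordinate system, circular gene-order comparisons, repeat content, shared
tRNA variability, and a distance-based tree. A fully seeded clade simulator
generates inputs with exact ground truth so that every stage can be checked
by parameter recovery rather than by eye.

## Data model and coordinates

Internally all coordinates are 0-based half-open on the deposited (direct)
strand; the GenBank dialect (1-based inclusive, `complement(join(...))`)
exists only at the I/O boundary. Multi-exon genes store exons in transcript
order, and the gap between consecutive exons is materialised as an intron
record whose `spliced_insertion_point` is the count of spliced coding
nucleotides 5' of the intron — the quantity on which all intron homology
assessment rests. Features that span the replication origin of a circular
genome are stored as an exon pair (to the sequence end, then from 0) with a
wrap flag, which keeps every interval simple and testable. Duplicated genes
(extra tRNA copies, multiple DNA-polymerase genes) are disambiguated with
`-1`, `-2` suffixes in reading order from position 0. N bases are permitted
in sequences but excluded from every count downstream, matching
pairwise-deletion conventions. Translation uses NCBI genetic code 4 (the
mold mitochondrial code): TGA encodes tryptophan and only TAA/TAG terminate.
A terminal stop is kept when the spliced length is a clean codon multiple;
spliced lengths of 1 or 2 mod 3 are rejected rather than silently repaired,
because the simulator controls frames and a real record failing this check
deserves a flag, not a fix.

## Composition and skews

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C), computed on the deposited
strand, since published per-genome values are reported per deposited strand.
Region fractions partition every base into protein-coding, rRNA, tRNA,
intronic or intergenic (priority in that order where annotations overlap),
so the five classes always total 100%. The repeat-covered fraction is
computed on the union of hit intervals with both mates of each pair counted
— one count per covered base — which avoids >100% artifacts from
overlapping hits while remaining comparable to published genome-fraction
figures.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine gaps, provided by
Biopython's `PairwiseAligner`; the first optimal traceback in its fixed
enumeration order is always taken, which makes results deterministic across
platforms. Nucleotide defaults are match +1 / mismatch −1 / gap −2; protein
alignment uses BLOSUM62 with gap open −11 / extend −1. Codon alignments are
protein-guided: the translated sequences are aligned and each protein gap is
back-threaded as a 3-nt gap, so gap runs are always codon-sized and each row
still translates to its guide protein. Multi-taxon needs are served by
pairwise alignments per pair (distances) or alignment to a common reference
(intron mapping); no progressive multiple alignment is attempted, which is
adequate at single-gene scale and far easier to verify.

## Distances and selection

The Kimura two-parameter distance separates transition (P) and transversion
(Q) proportions over pairwise-deleted columns (any gap or N drops the
column) and applies

    d = −1/2 · ln((1 − 2P − Q) · sqrt(1 − 2Q)).

Arguments outside the model's domain raise a saturation error rather than
returning a number.

Ka/Ks follows Nei & Gojobori (1986) under code 4. Per-codon synonymous site
fractions come from single-base neighbor enumeration; neighbors that are
stop codons are excluded from the neighbor set and the synonymous fraction
is scaled to 3 sites, so S + N is exactly 3 per codon. For codons differing
at multiple positions, difference counts are averaged over all orderings of
the changes; pathways passing through a stop are discarded and the remainder
reweighted equally (if every pathway hits a stop, the stop-tolerant counts
are used so the statistic stays defined). Site counts are computed on each
sequence and averaged across the pair, and both pS and pN receive the
Jukes–Cantor correction K = −3/4 · ln(1 − 4/3 · p). The ratio is flagged
undefined when Ks = 0; selection classes are purifying (<1), neutral (=1
within 1e−9) and positive (>1). Per-species-pair ratios are always retained
alongside per-gene means, because positive-selection findings in this
setting are typically pair-specific.

The tree stage is deliberately modest: neighbor joining (via scikit-bio) on
K2P distances pooled over the concatenated 15 core protein-coding genes plus
the two rRNAs, with negative branch lengths clamped to zero under a warning.
This is an explicit stand-in for Bayesian/ML phylogenetics, which is out of
scope; NJ is consistent on additive matrices and that property is what the
tests exercise.

## Intron position classes

An intron's position class (Pcl) is the nucleotide of a reference cox1 CDS
after which it inserts: the host CDS is codon-aligned to the reference
(protein-guided, for robustness at deep divergence — a deliberate departure
from plain nucleotide alignment), the host's spliced insertion point is
carried through the alignment columns, and the class is named P&lt;position&gt;
with position 1-based from the reference ATG. Sites opposite a reference gap
are reported as unmappable, never rounded to a neighbor, and near-duplicate
positions (±1 nt) are never merged — exactness is what makes the assignment
testable. Mappings below 30% protein identity are refused. A Pcl present in
more than 1/5 of surveyed species is labelled common, otherwise rare. A Pcl
found in exactly one species of a clade but also outside that clade is
flagged as a candidate horizontal transfer; a Pcl private to a single
species overall is reported as novel instead.

## Gene order

The unit of comparison is the signed circular order of the 17-gene set (15
core PCGs + 2 rRNAs); duplicated tRNAs and non-conserved genes are excluded.
Orders are normalised by rotating cox1 to the front and, when cox1 lies on
the minus strand, reflecting the circle with all signs flipped — the only
reflection allowed, so chirality is anchored deterministically rather than
free. Two taxa share an arrangement iff their normalised orders are equal
(an unsigned mode is available, since published figures do not always state
whether strand was considered). Rearrangement extent is quantified by the
signed circular breakpoint distance — adjacencies of one order absent from
the other — which is a true metric on orders with equal gene content.

## Repeats

The interspersed-repeat engine is a self-contained seed-and-extend local
aligner, not a BLAST wrapper: exact 11-mer seeds on both strands, banded
X-drop extension (band ±6, drop 20, linear gap −7 during boundary finding),
affine rescoring of the final interval pair (match +2 / mismatch −3 / gap
−5,−2), and a Karlin–Altschul-style e-value E = K·m·n·exp(−λS) with λ
solved from the scoring scheme at equal base frequencies and K fixed at
0.41. The default threshold is 1e−10 at a 30 bp minimum. Circular genomes
are searched on the doubled sequence so origin-spanning repeats are found,
with hits reported modulo genome length and de-duplicated; seeds within one
band-width of the self-diagonal (or of the doubling offset) are excluded so
the banded extension cannot slide onto a perfect self-match. Because the
statistics are fixed and documented rather than BLASTN's, hit counts on real
accessions approximate but need not equal published BLASTN counts at the
same threshold.

Tandem repeats are found by period search: for each candidate unit length p
(default cap 100 bp — published mitochondrial tandems reach 74 bp, so a
10 bp cap would be self-defeating), runs where the sequence matches itself
shifted by p are extended across isolated mismatches while identity stays
≥80%; runs spanning ≥2 copies and ≥12 bp are reported. Composite consensus
units (e.g. AAAAA at p=5) collapse to their minimal period; overlapping
calls keep the longest span, then the smallest period. Homopolymer runs are
reported by default and filterable by flag.

## tRNA comparison

tRNAs are matched across genomes by isotype + anticodon; duplicate copies
pair by reading order, an arbitrary but deterministic convention (counts for
the alternative pairing can be obtained by swapping copy indices). Variable
sites are aligned columns with a mismatch or gap, reported in the first
genome's coordinates. Arm-level localisation of variants would require
secondary-structure prediction and is out of scope; linear positions are
emitted so a downstream tool can map them onto a cloverleaf.

## The clade simulator

The simulator builds an ancestral circular genome — 15 core PCGs with
typical fungal lengths (cox1 long enough to host the classic intron sites),
rRNAs of 3150/1629 bp, a 20-isotype tRNA set, optional free-standing ORFs
and plasmid-derived DNA-polymerase genes, and random intergenic spacers
(default 400 bp) — and derives each taxon from it. Coding genes evolve by a
per-codon proposal process: a random site gets a random base; proposals
creating stops are rejected; synonymous changes are accepted with
probability min(1, 1/ω) and nonsynonymous ones with min(1, ω), iterated
until the accepted count reaches the target divergence d (substitutions per
site from the ancestor). This acceptance rule realises a nonsynonymous/
synonymous rate ratio of ω in both regimes — accepting synonymous changes
with probability 1 regardless of ω would cap the realised ratio at 1 and
make positive-selection regimes unreproducible, so the symmetric rule is
used. It is a proposal-acceptance scheme, not a full rate-matrix Markov
generator: sufficient for recovery testing, with no transition/transversion
bias and no codon-frequency structure. rRNAs and spacers evolve neutrally;
tRNAs mutate only through an explicit per-taxon count so planted variant
positions are exact truth.

Shallow phylogenetic structure comes from optional taxon groups: group
members share a cached intermediate carrying a configurable fraction of
their divergence, which is how designed sister pairs are produced. Introns
are inserted at planned reference coding positions; orthologous introns
share a per-position master sequence (lightly mutated per carrier) and may
embed an open reading frame labelled with a homing-endonuclease family.
Rearrangements (inversions, transpositions) act on whole genes — blocks
never split genes. Interspersed and tandem repeats are planted by
overwriting reserved intergenic spacer windows, so planting never shifts any
other feature's coordinates and the truth log is exact. Every random draw
flows through a generator seeded from (seed, purpose, indices); a config
therefore replays bit-identically, and plan infeasibility (bad positions,
unknown taxa, too many plantings) is rejected before simulation starts.

What the simulator does not emulate: indel processes, base-composition skew
evolution, realistic intron secondary structure, transfer-RNA structure,
plasmid integration dynamics, and rate heterogeneity along the genome.
Passing recovery tests therefore demonstrate correctness of the analysis
arithmetic under substitution-only divergence with known annotation — not
robustness to annotation error or alignment ambiguity in real data.

## Verification scale and numerical choices

The shipped verification battery uses problem sizes chosen to exercise each
stage meaningfully while keeping a full run in tens of seconds: 20-replicate
6-taxon clades at divergence 0.2 for intron-class recovery; 50-replicate
clades with 502-codon genes at pairwise divergence ≈0.3 for ω recovery
(configured ω 0.1 and 1.2, classified by per-gene mean over species pairs);
100 planted repeats of 50–800 bp at 80–100% identity plus 10 null genomes
for recall/precision; random additive matrices of up to 8 taxa for NJ;
all 3844 ordered codon-pair combinations for the Nei–Gojobori oracle.
Closed-form checks (K2P) are exact to 1e−12. Ties in alignment traceback
follow Biopython's deterministic enumeration; NJ negative branch lengths
clamp to zero; saturated distances raise rather than extrapolate. Very
short repeats at the low-identity end (≲68 bp near 80% identity) fall below
the e-value threshold by construction of the scoring statistics — they are
the expected residual of the ~98% recall figure, not detection failures.

## Known limitations

Annotation is consumed, never inferred: records must carry gene features
with exon structure. The star-style group model cannot express deep nested
topologies. The repeat engine's e-value calibration uses ungapped-style
constants with fixed K, so absolute e-values are approximate (the relative
ordering and thresholding behaviour are what the tests pin down). Fig-style
graphical output is intentionally absent; all reports are TSV/JSON.
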