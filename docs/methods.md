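# Methods

## Problem setting

Spidroin genes combine two features that defeat standard short-read
assembly: they are long (7.5–22.5 kb of coding sequence in the presets this
package models), and most of that length is an array of tens of
near-identical repeat units. A de Bruijn graph built from short reads
collapses the array into a tangle; the unique terminal domains assemble, the
interior does not. The package therefore implements a targeted
seed-and-extend strategy in which short reads resolve local sequence at high
accuracy and single long reads resolve repeat order and count.

## Synthetic gene model

The generator (`smoc.synthetic`) emits genes as
N-domain + (repeat unit × n) + C-domain, with optional inter-repeat linkers
and introns (introns are only placed between repeat copies, never inside a
motif, which keeps truth annotations unambiguous).

Repeat units are exact concatenations of motif instances drawn from a
weighted grammar over the silk vocabulary: poly-A (runs of 4–10), (GA)₃₋₈,
GPGQQ, GPGGX, GGR, GGX, XQQ, and low-complexity spacers. The wildcard X is
drawn from {S,Y,L,V,I,T} by default: A, G and Q are excluded so that
adjacent motifs cannot fuse into a different maximal motif (e.g. GPGGA
before a poly-A run), and a poly-A block is never emitted directly after a
GA-repeat for the same reason. Under these constraints every residue of a
spacer-free unit is covered by exactly one motif hit, a property the test
suite checks.

**Back-translation.** The repeat-unit template is back-translated once with
uniform synonymous codon choice; every copy inherits those codons — repeat
arrays arise by duplication, so copies are highly similar at the DNA level —
and then diverges by (i) amino-acid substitutions at `per_copy_divergence`
(default 1%, a modelling choice exposed as a parameter; real within-gene
copy divergence is not well characterized) and (ii) synonymous resampling of
`codon_noise` = 1% of codons, so copies are DNA-non-identical even at zero
protein divergence. The resulting pairwise DNA identity between copies is
roughly 98–99%, which is what makes the method's central difficulty real:
100-bp windows are frequently shared between copies, so extension hits
genuine splits, while unit placement on long reads remains easy. The
`identical_codons` toggle forces byte-identical copies for worst-case
assembly tests. Terminal domains and linkers are independent random
proteins; families share them, unrelated genes do not.

**Read simulation.** Short reads: uniform fragment sampling on both strands,
i.i.d. substitutions, paired mode with Gaussian insert (400 ± 40 bp);
realized coverage is exact up to rounding. Long reads: lognormal lengths
(mean 7.4 kb, σ = 0.4, truncated to the template — a read drawn longer than
the template spans it completely), substitution and indel errors at
post-correction rates (1% + 0.5% + 0.5% by default, i.e. ~2% total). The
simulator does **not** model per-cycle quality profiles, chimeras, coverage
bias or PCR artefacts; passing tests therefore show algorithmic correctness
under idealized uniform sampling, not robustness to instrument-specific
artefacts.

## Seed pickup

Terminal domains are found by exact local alignment
(Biopython `PairwiseAligner`; DNA 2/−3 with gaps −5/−2, protein BLOSUM62
with gaps −11/−1; a gap of length L costs open + (L−1)·extend). Protein
queries against DNA contigs use a six-frame translated search. Scores are
reported as bit scores with textbook Karlin–Altschul constants, and a fixed
bit-score floor (default 50) gates hits: an E-value would need a
database-size context that a desk-scale run does not have. Multiple
non-overlapping hits are found by best-hit masking recursion on the target.
Seeds are always emitted with the repeat array 3′, so the extender is
single-directional: N-domain hits on the gene's forward strand are kept
as-is, C-domain hits are reverse-complemented.

## PWM extension

The anchor is the last k bases of the seed (k = 100 by default — large
enough that an exact match is strong evidence of locality, small enough to
fit in a 150-bp read with room for a suffix). All reads carrying the anchor
exactly (either strand, via a precomputed k-mer index) contribute the base
immediately 3′ of the match to a position weight matrix column. The
decision rule per step, with coverage = informative (non-N) reads:

* coverage < `min_coverage` (5) → stop `low_coverage`;
* runner-up frequency ≥ `split_threshold` (0.2) → stop `split`, recording
  both bases (an exact 50/50 tie is always a split, never an arbitrary
  choice);
* top frequency ≥ `consensus_threshold` τ (0.9) → append the top base;
* otherwise → stop `split`.

No suffixes at all is `read_exhaustion`. The defaults follow a binomial
argument: at 30× coverage and ≤1% sequencing error, the runner-up count
essentially never reaches 20% of a column, while a true 50/50 copy split
always does. Both tests are applied independently; τ and `split_threshold`
are not forced to be complementary. Splits are terminal — the method
resolves repeats on long reads rather than branching. N bases never enter a
consensus: they are excluded from frequency denominators, and an all-N
column has coverage 0.

Extension is one base per step with the anchor window sliding, so an
indexed lookup keeps each step O(occurrences); a brute-force per-step
rescanning oracle in the test suite reproduces the walk exactly on hundreds
of random instances.

## Repeat-unit harvest and boundary refinement

The repeat region of a transcript contig is taken between the terminal-
domain hits. Unit length is estimated as the smallest autocorrelation lag of
residue identity within 0.02 of the maximum (multiples of the true period
score equally well up to sampling noise, so near-ties must resolve to the
fundamental); reliability is judged against an empirical null of 100
shuffles (z ≥ 4).

Because terminal queries are 170 residues but the domains they mark may be
shorter, hits reach into the first/last repeat copy. The true domain/repeat
boundary is recovered by scoring a growing tail (or head) of each terminal
element against the cyclically repeated unit — score d − 3·edits, maximized
over d — which locates the point where periodicity stops without knowing the
array phase. Terminal elements are trimmed there, and unit candidates are
re-cut on the same boundary so placements tile in true phase; without this
step the unit count is systematically low by 1–2. Candidates (transcript
chunks plus extension fragments of at least 0.8 unit lengths) are
deduplicated at 98% identity into a unit set with multiplicities.

## Long-read tiling and consensus

Each unit and terminal element is placed on each long read by iterated
best-hit edit-distance alignment with masking (edlib, infix mode), accepting
identity ≥ 0.85 (identity = 1 − edits/max(query, span); the band on edit
distance is 2·(1−min_identity)·|query|). Per read, a maximal-score collinear
chain (score = identity × length, overlap tolerance 10 bp) is built by
dynamic programming; the N element may only open a chain and the C element
only close one. Reads where the gene lies on the minus strand are chained in
mirrored coordinates. A chain from N to C is a complete tiling; others are
flagged partial and excluded from gene calls.

The consensus repeat count is the **low median** over complete tilings
(robust to an occasional truncated or chimeric read; ties are flagged). The
sequence is rebuilt slot by slot: the assembled element is the backbone and
every agreeing spanning read votes per backbone column through a global
alignment ('=', 'X' vote a base, 'D' a deletion; the backbone casts one vote
so a single noisy read cannot overturn it; read insertions are treated as
noise, which is correct for the substitution-only divergence model). With
three or more spanning reads at 2% error the residual consensus error is
well below 0.1%.

Known limitation: conflicting unit counts across reads are resolved by the
median only; merging partial tilings across reads into one gene call is not
attempted.

## Motif annotation

`scan_motifs` tiles a protein with motif hits under a deterministic overlap
rule: among all candidate matches fully inside a yet-uncovered stretch,
accept the longest; break length ties by the fixed class order poly_A,
GA_repeat, GPGQQ, GPGGX, GGR, GGX, XQQ, then by leftmost start; carve and
rescan, so maximal runs are re-derived inside remaining gaps. Leftover
stretches of ≥ 10 residues become spacer hits. The precedence is a package
convention — motif counts change under a different one — and is documented
here precisely because of that; the test oracle applies the same rule
through an independent implementation. Minimum run lengths (poly-A ≥ 4,
(GA) ≥ 3) follow common silk-literature convention and are configurable.

## Family clustering

All-vs-all best local-alignment bit scores (BLOSUM62) are normalized to
n_ij = max(b_ij, b_ji)/√(b_ii·b_jj), clipped to [0, 1], diagonal forced
to 1. The normalization denominator is isolated in one function; a
min-self-score variant is available behind a flag. Clustering is spectral on
L = I − D^(−1/2) A D^(−1/2) with self-loops removed: when k is not supplied
it is the position of the largest gap among the smallest `max_k` + 1 = 13
eigenvalues (`max_k` = 12 comfortably exceeds the seven known spidroin
orthologue groups); rows of the first k eigenvectors are length-normalized
and grouped by k-means with a fixed seed and 10 restarts, so results are
deterministic per seed. Sequences with no off-diagonal similarity become
singleton clusters with a warning. The synthetic seven-family panel
(recipes shaped after MaSp1/MaSp2/MaSp3/MiSp/Flag/CySp/AcSp, each with a
private terminal-domain pair and motif emphasis, members at 3% divergence,
~280 aa per member) is recovered with purity 1.0 and eigengap-selected
k = 7 across seeds.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale instances chosen to exercise
every stage: a 4.35-kb gene (20 × 60-aa units) with 50× short and 20× long
reads for the end-to-end check; ≤ 50 reads of ≤ 40 bp for extension-oracle
equivalence; 35 proteins of ~280 aa for clustering; 10-kb templates for
simulator calibration. Degenerate inputs are defined, not special-cased:
empty suffix sets stop extension, zero placements is a valid tiling outcome,
an all-N column has zero coverage, and a forced k = 1 labels everything
together. Coordinates are 0-based half-open everywhere in memory; conversion
to 1-based inclusive happens only at GFF3 serialization.
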