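# smoc

Targeted assembly, motif annotation and family clustering of **spidroin-like
repetitive genes**.

Spider silk genes (spidroins) are long (roughly 7.5–22.5 kb of coding
sequence), with short conserved N- and C-terminal domains flanking an array
of tens of near-identical repeat units built from a small peptide-motif
vocabulary: β-sheet blocks (poly-alanine A_n and (GA)_n), β-turn motifs
(GPGGX, GPGQQ, XQQ), 3₁₀-helix GGX, the arginine motif GGR, and
low-complexity spacers. De Bruijn assembly of short reads collapses the
repeat array, so these genes are routinely missing or fragmented in draft
genomes. `smoc` is for genome/transcriptome analysts who need full-length
repeat-gene models from a hybrid of short reads, long reads and a draft
assembly.

## The method

1. **Seed pickup.** Terminal-domain protein queries (e.g. the first/last
   170 residues of a known homologue) are located in draft contigs by exact
   Smith–Waterman local alignment (translated, six frames). Hits are cut out
   as seeds oriented so the repeat array lies 3′. A bit score
   b = (λ·S − ln K)/ln 2 with a fixed floor replaces a database-dependent
   E-value gate.
2. **PWM consensus extension.** Short reads carrying an *exact* match of a
   very large k-mer (k = 100 by default) at the seed's 3′ end are collected;
   the bases just 3′ of the match form a position weight matrix, and the
   seed grows one base at a time while the column is unambiguous:
   coverage ≥ 5 reads, top-base frequency ≥ 0.9, runner-up < 0.2. A strong
   runner-up is a *graph split* — the point where a neighbouring repeat copy
   is not resolvable from short reads — and terminates the walk.
3. **Repeat-unit harvest.** The repeat region of a transcript contig is
   located between the terminal-domain hits; its unit length is estimated by
   autocorrelation of residue identity and the region is cut into unit-sized
   candidates, deduplicated at 98% identity.
4. **Long-read tiling.** Units and termini are placed on every long read by
   edit-distance alignment (identity ≥ 0.85), chained N → units → C by
   dynamic programming, and the per-copy sequence is polished by majority
   vote across spanning reads. The repeat count is the median over complete
   tilings.

Family assignment uses all-vs-all local-alignment bit scores, normalized to
[0, 1] by n_ij = max(b_ij, b_ji)/√(b_ii·b_jj), and spectral clustering on the
symmetric normalized Laplacian L = I − D^(−1/2) A D^(−1/2), with the cluster
count chosen by the largest eigengap.

Everything is exercised on synthetic spidroin-like genes with exact
coordinate truth (`smoc.synthetic`), so the whole pipeline is testable with
no external data.

## Worked example

```bash
smoc simulate --seed 7 --out-prefix toy
smoc run --contigs toy.contigs.fasta --queries toy.queries.faa \
     --transcript toy.transcript.fasta \
     --short-reads toy.short.R1.fastq --short-reads toy.short.R2.fastq \
     --long-reads toy.long.fastq --out toy.gene.fasta --gff toy.gene.gff3
```

prints

```
gene 4350 bp, 1784 short reads, 20 long reads -> toy.*
reconstructed 4348 bp, 20 repeat units (18 spanning reads agree)
```

The simulated gene is the default MaSp-like preset: 150-aa N-domain, 20
copies of a 60-aa repeat unit at 1% per-copy divergence, 100-aa C-domain
(3 × 1450 aa = 4350 bp of coding sequence). `smoc run` reconstructs it from
50× error-free paired short reads plus 20 long reads at 2% error: all 20
repeat copies are recovered and ordered, and the 4348-bp consensus differs
from the truth by about 0.05% (boundary slop at the terminal-domain hit
edges). `toy.gene.gff3` annotates the termini and each repeat copy.

The same library is importable directly — see `smoc.pipeline.run_smoc`,
`smoc.motifs.scan_motifs` and `smoc.clustering.cluster_sequences`.

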