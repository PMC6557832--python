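"""Seed pickup: locate non-repetitive N/C-terminal domains in contigs.

Spidroin assembly starts from the conserved, non-repetitive terminal domains:
they are found by local alignment of candidate terminal-domain queries against
assembled contigs or transcripts, then cut out as seed sequences oriented so
that extension toward the repeat array always proceeds 3'.

Alignment is exact Smith-Waterman via Biopython's PairwiseAligner; scores are
reported both raw and as bit scores b = (lambda*S - ln K) / ln 2.  A fixed
bit-score floor replaces a database-dependent E-value gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import DNA_ALPHABET, SeqRecord, revcomp, translate


@dataclass
class SeedSearchParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0          # score of the first gap position
    gap_extend: float = -2.0
    protein_matrix: str = "BLOSUM62"
    protein_gap_open: float = -11.0
    protein_gap_extend: float = -1.0
    min_bit_score: float = 50.0
    domain_length: int = 170
    # Karlin-Altschul parameters for the bit-score transform
    dna_lambda: float = 0.625
    dna_k: float = 0.41
    protein_lambda: float = 0.267
    protein_k: float = 0.041

    def __post_init__(self) -> None:
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")


@dataclass
class SeedHit:
    query_id: str
    target_id: str
    target_start: int
    target_end: int
    strand: str
    raw_score: float
    bit_score: float
    identity: float


def _is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


def make_aligner(molecule: str, params: SeedSearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if molecule == "dna":
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
        aligner.open_gap_score = params.gap_open
        aligner.extend_gap_score = params.gap_extend
    else:
        aligner.substitution_matrix = substitution_matrices.load(params.protein_matrix)
        aligner.open_gap_score = params.protein_gap_open
        aligner.extend_gap_score = params.protein_gap_extend
    return aligner


def bit_score(raw: float, molecule: str, params: SeedSearchParams) -> float:
    lam = params.dna_lambda if molecule == "dna" else params.protein_lambda
    k = params.dna_k if molecule == "dna" else params.protein_k
    return (lam * raw - math.log(k)) / math.log(2)


def _min_raw_score(molecule: str, params: SeedSearchParams) -> float:
    lam = params.dna_lambda if molecule == "dna" else params.protein_lambda
    k = params.dna_k if molecule == "dna" else params.protein_k
    return (params.min_bit_score * math.log(2) + math.log(k)) / lam


def _alignment_identity(aln) -> float:
    c = aln.counts()
    denom = c.identities + c.mismatches + c.gaps
    return c.identities / denom if denom else 0.0


def _collect_hits(query: str, target: str, offset: int,
                  aligner: Align.PairwiseAligner, min_raw: float,
                  out: list[tuple[int, int, float, float]]) -> None:
    """Recursively find non-overlapping local alignments above min_raw."""
    if not target or not query:
        return
    score = aligner.score(target, query)
    if score < min_raw or score <= 0:
        return
    aln = aligner.align(target, query)[0]
    tblocks = aln.aligned[0]
    tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
    out.append((offset + tstart, offset + tend, float(score), _alignment_identity(aln)))
    _collect_hits(query, target[:tstart], offset, aligner, min_raw, out)
    _collect_hits(query, target[tend:], offset + tend, aligner, min_raw, out)


def local_align(query: SeqRecord, target: SeqRecord,
                params: Optional[SeedSearchParams] = None) -> list[SeedHit]:
    """All non-overlapping local alignments of query against target.

    DNA targets are searched on both strands; minus-strand hit coordinates are
    reported on the forward strand.  Hits are sorted by score descending, ties
    by (target_id, start).
    """
    params = params or SeedSearchParams()
    q_dna = _is_dna(query.sequence)
    t_dna = _is_dna(target.sequence)
    if q_dna != t_dna:
        raise ValueError(
            f"alphabet mismatch: query {query.id!r} is "
            f"{'DNA' if q_dna else 'protein'}, target {target.id!r} is "
            f"{'DNA' if t_dna else 'protein'}"
        )
    molecule = "dna" if q_dna else "protein"
    aligner = make_aligner(molecule, params)
    min_raw = _min_raw_score(molecule, params)

    hits: list[SeedHit] = []
    raw_hits: list[tuple[int, int, float, float]] = []
    _collect_hits(query.sequence, target.sequence, 0, aligner, min_raw, raw_hits)
    for s, e, score, ident in raw_hits:
        hits.append(SeedHit(query.id, target.id, s, e, "+", score,
                            bit_score(score, molecule, params), ident))
    if molecule == "dna":
        rc = revcomp(target.sequence)
        L = len(rc)
        raw_hits = []
        _collect_hits(query.sequence, rc, 0, aligner, min_raw, raw_hits)
        for s, e, score, ident in raw_hits:
            hits.append(SeedHit(query.id, target.id, L - e, L - s, "-", score,
                                bit_score(score, molecule, params), ident))
    hits.sort(key=lambda h: (-h.raw_score, h.target_id, h.target_start))
    return hits


def translated_search(query: SeqRecord, target: SeqRecord,
                      params: Optional[SeedSearchParams] = None) -> list[SeedHit]:
    """Protein query against a DNA target, tblastn-style: all six frames,
    hit coordinates mapped back to the forward DNA strand."""
    params = params or SeedSearchParams()
    if _is_dna(query.sequence):
        raise ValueError("translated_search expects a protein query")
    if not _is_dna(target.sequence):
        raise ValueError("translated_search expects a DNA target")
    L = len(target.sequence)
    hits: list[SeedHit] = []
    for strand, seq in (("+", target.sequence), ("-", revcomp(target.sequence))):
        for frame in (0, 1, 2):
            prot = translate(seq, frame)
            if not prot:
                continue
            sub_hits = local_align(query, SeqRecord(target.id, prot), params)
            for h in sub_hits:
                dna_s = frame + 3 * h.target_start
                dna_e = frame + 3 * h.target_end
                if strand == "-":
                    dna_s, dna_e = L - dna_e, L - dna_s
                hits.append(SeedHit(h.query_id, h.target_id, dna_s, dna_e,
                                    strand, h.raw_score, h.bit_score, h.identity))
    hits.sort(key=lambda h: (-h.raw_score, h.target_id, h.target_start))
    return hits


def extract_terminal_domains(protein: str, n: int = 170) -> tuple[str, str]:
    """First and last ``n`` residues (clamped to the sequence length)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = min(n, len(protein))
    return protein[:m], protein[len(protein) - m:]


def pick_seeds(hits: Sequence[SeedHit], targets: dict[str, SeqRecord],
               terminus: str | dict[str, str], flank: int = 0,
               ) -> list[SeqRecord]:
    """Cut out seed sequences in extension-ready orientation.

    ``terminus`` says whether each query hit marks an N- or C-terminal domain
    (a single letter applied to all hits, or a mapping query_id -> 'N'/'C').
    Seeds are oriented so the repeat array lies 3' of the seed: N-domain hits
    on the forward gene strand stay forward, C-domain hits are
    reverse-complemented.  ``flank`` extends the seed on the repeat-facing
    side; flanks running off the contig are clamped.
    """
    seeds: list[SeqRecord] = []
    for h in hits:
        term = terminus if isinstance(terminus, str) else terminus[h.query_id]
        if term not in ("N", "C"):
            raise ValueError(f"terminus must be 'N' or 'C', got {term!r}")
        target = targets[h.target_id]
        L = len(target.sequence)
        forward = (term == "N") == (h.strand == "+")
        if forward:
            end = min(L, h.target_end + flank)
            seq = target.sequence[h.target_start:end]
        else:
            start = max(0, h.target_start - flank)
            seq = revcomp(target.sequence[start:h.target_end])
        seeds.append(SeqRecord(
            id=f"{h.query_id}|{h.target_id}|{h.target_start}-{h.target_end}{h.strand}|{term}",
            sequence=seq,
        ))
    return seeds
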