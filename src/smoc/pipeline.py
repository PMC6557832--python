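"""End-to-end targeted assembly of one spidroin gene.

Stages, mirroring the seed-and-extend design of the library modules:

1. terminal-domain pickup: protein queries are located in draft contigs by
   translated local alignment and cut out as extension-ready seeds;
2. PWM extension of both seeds over the short reads;
3. repeat-unit harvest: the repeat region of a transcript contig is located
   between the terminal-domain hits, its unit length estimated by
   autocorrelation, and unit-sized candidates (plus extension fragments)
   deduplicated into a unit set;
4. long-read tiling: units and termini are placed on every long read,
   chained N -> units -> C, and polished into a consensus gene with a
   repeat count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .extend import (ExtensionParams, ExtensionState, build_kmer_index,
                     extend_to_completion, harvest_repeat_units, RepeatUnitSet)
from .io import SeqRecord, revcomp, translate
from .motifs import PeriodEstimate, detect_repeat_period
from .seeds import SeedHit, SeedSearchParams, pick_seeds, translated_search
from .tiling import (ConsensusGene, TiledGene, chain_and_tile,
                     consensus_gene, place_units)


@dataclass
class SmocConfig:
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    search: SeedSearchParams = field(default_factory=SeedSearchParams)
    min_identity: float = 0.85        # unit placement acceptance
    chain_tolerance: int = 10
    seed_flank: int = 0
    min_unit_fraction: float = 0.8    # extension fragments shorter than this
                                      # fraction of a unit are not harvested


@dataclass
class SmocResult:
    n_hit: SeedHit
    c_hit: SeedHit
    n_state: ExtensionState
    c_state: ExtensionState
    unit_period_bp: int
    period_estimate: PeriodEstimate
    unit_set: RepeatUnitSet
    tilings: list[TiledGene]
    consensus: ConsensusGene

    @property
    def n_units(self) -> int:
        return self.consensus.n_units

    @property
    def reconstruction(self) -> SeqRecord:
        return self.consensus.record


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity 1 - edits / max(len)."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _best_hit(query: SeqRecord, targets: Sequence[SeqRecord],
              params: SeedSearchParams) -> SeedHit:
    hits: list[SeedHit] = []
    for t in targets:
        hits.extend(translated_search(query, t, params))
    if not hits:
        raise ValueError(f"query {query.id!r} matches no target")
    hits.sort(key=lambda h: (-h.raw_score, h.target_id, h.target_start))
    return hits[0]


def _repeat_overhang(elem: str, unit: str, side: str,
                     max_scan: Optional[int] = None, step: int = 3,
                     mismatch_cost: int = 3, min_score: int = 12) -> int:
    """How far the repeat array reaches into a terminal element.

    Matches a growing tail (``side='tail'``) or head (``side='head'``) of
    ``elem`` anywhere inside the cyclically repeated unit (so no phase needs
    to be known), scoring d - mismatch_cost * edits; the argmax marks the
    true domain/repeat boundary.  Returns the overhang length in bases
    (0 when nothing convincing matches).
    """
    if not unit:
        return 0
    max_scan = min(max_scan or len(elem), len(elem))
    ref = unit * (max_scan // len(unit) + 3)

    def score(d: int) -> int:
        a = elem[-d:] if side == "tail" else elem[:d]
        dist = edlib.align(a, ref, mode="HW", task="distance")["editDistance"]
        return d - mismatch_cost * dist

    best_d, best_s = 0, 0
    for d in range(step, max_scan + 1, step):
        s = score(d)
        if s > best_s:
            best_d, best_s = d, s
    lo, hi = max(1, best_d - step), min(max_scan, best_d + step)
    for d in range(lo, hi + 1):
        s = score(d)
        if s > best_s:
            best_d, best_s = d, s
    return best_d if best_s >= min_score else 0


def _transcript_repeat_region(transcript: SeqRecord, n_query: SeqRecord,
                              c_query: SeqRecord, params: SeedSearchParams,
                              ) -> tuple[SeqRecord, SeedHit, SeedHit]:
    """Terminal-domain hits on a transcript contig, orientation normalized
    to the gene strand; the repeat region lies between them."""
    nh = _best_hit(n_query, [transcript], params)
    if nh.strand == "-":
        transcript = SeqRecord(transcript.id, revcomp(transcript.sequence))
        nh = _best_hit(n_query, [transcript], params)
    ch = _best_hit(c_query, [transcript], params)
    if nh.target_end >= ch.target_start:
        raise ValueError("terminal domains overlap on the transcript; "
                         "no repeat region between them")
    return transcript, nh, ch


def run_smoc(contigs: Sequence[SeqRecord],
             short_reads: Sequence[SeqRecord],
             long_reads: Sequence[SeqRecord],
             n_query: SeqRecord, c_query: SeqRecord,
             transcript: Optional[SeqRecord] = None,
             config: Optional[SmocConfig] = None,
             gene_id: str = "smoc_gene") -> SmocResult:
    """Assemble one gene from draft contigs, short reads and long reads.

    ``n_query``/``c_query`` are terminal-domain protein queries (e.g. the
    170-residue head/tail of a homologous spidroin); ``transcript`` is an
    optional transcript contig supplying repeat-region seeds.
    """
    config = config or SmocConfig()

    # 1. seed pickup
    targets = {t.id: t for t in contigs}
    n_hit = _best_hit(n_query, contigs, config.search)
    c_hit = _best_hit(c_query, contigs, config.search)
    n_seed = pick_seeds([n_hit], targets, "N", config.seed_flank)[0]
    c_seed = pick_seeds([c_hit], targets, "C", config.seed_flank)[0]

    # 2. strict PWM extension of both seeds over the short reads
    index = build_kmer_index(short_reads, config.extension.k,
                             config.extension.both_strands)
    n_state = extend_to_completion(n_seed.sequence, short_reads,
                                   config.extension, index)
    c_state = extend_to_completion(c_seed.sequence, short_reads,
                                   config.extension, index)

    # 3. repeat-unit harvest, with the array phase anchored at the true
    #    domain/repeat boundary (terminal queries usually reach a little way
    #    into the first/last repeat copy, so the raw hit boundary is not it)
    if transcript is not None:
        tx, nh, ch = _transcript_repeat_region(transcript, n_query, c_query,
                                               config.search)
        region = tx.sequence[nh.target_end:ch.target_start]
    else:
        tx = None
        region = max((n_state.extension, c_state.extension), key=len)
        if not region:
            raise ValueError("no repeat material: extensions are empty and "
                             "no transcript was given")
    period = detect_repeat_period(translate(region))
    unit_bp = 3 * period.period
    u = region[:unit_bp]
    if tx is not None:
        d_n_tx = _repeat_overhang(tx.sequence[:nh.target_end], u, "tail",
                                  max_scan=min(nh.target_end, 3 * unit_bp))
        d_c_tx = _repeat_overhang(tx.sequence[ch.target_start:], u, "head",
                                  max_scan=min(len(tx.sequence) - ch.target_start,
                                               3 * unit_bp))
        region_ext = tx.sequence[nh.target_end - d_n_tx:
                                 ch.target_start + d_c_tx]
    else:
        region_ext = region
    chunks = [region_ext[i:i + unit_bp]
              for i in range(0, len(region_ext) - unit_bp + 1, unit_bp)]
    # extension fragments start at the raw hit boundary (phase 0 of u);
    # re-cut them at the next true unit boundary
    frag_offset = (unit_bp - _repeat_overhang(
        n_state.seed[:n_state.original_length], u, "tail",
        max_scan=min(len(n_state.seed), 3 * unit_bp))) % unit_bp
    frag_chunks: list[str] = []
    for state in (n_state, c_state):
        frag = state.extension
        frag_chunks.extend(
            frag[i:i + unit_bp]
            for i in range(frag_offset, len(frag) - unit_bp + 1, unit_bp))
    min_len = int(config.min_unit_fraction * unit_bp)
    unit_set = harvest_repeat_units([], chunks + frag_chunks,
                                    min_length=min_len)

    # 4. long-read tiling (elements in gene orientation, trimmed back to the
    #    domain/repeat boundary)
    unit_seqs = unit_set.sequences()
    n_raw = n_state.seed[:n_state.original_length]
    d_n = _repeat_overhang(n_raw, u, "tail",
                           max_scan=min(max(0, len(n_raw) - 60), 3 * unit_bp))
    n_elem = n_raw[:len(n_raw) - d_n]
    c_raw = revcomp(c_state.seed[:c_state.original_length])
    d_c = _repeat_overhang(c_raw, u, "head",
                           max_scan=min(max(0, len(c_raw) - 60), 3 * unit_bp))
    c_elem = c_raw[d_c:]
    elements = {"N": n_elem, "C": c_elem}
    for i, seq in enumerate(unit_seqs):
        elements[f"unit_v{i}"] = seq
    placements = place_units(elements, long_reads, config.min_identity)
    read_lengths = {r.id: len(r.sequence) for r in long_reads}
    tilings = chain_and_tile(placements, "N", "C", read_lengths,
                             config.chain_tolerance)
    consensus = consensus_gene(tilings, long_reads, elements, "N", "C",
                               gene_id=gene_id)
    return SmocResult(n_hit, c_hit, n_state, c_state, unit_bp, period,
                      unit_set, tilings, consensus)
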