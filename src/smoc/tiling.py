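"""Long-read resolution: map repeat units and termini onto long reads and
reconstruct full-length genes with exact repeat counts.

Short reads cannot order near-identical repeat copies; single long reads can.
Pre-assembled repeat units and terminal-domain seeds are placed on each long
read by banded edit-distance alignment, chained collinearly from an
N-terminal placement to a C-terminal placement, and the per-copy sequence is
polished by majority vote across all spanning reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from statistics import median_low
from typing import Sequence

import edlib

from .io import Annotation, SeqRecord, revcomp


@dataclass
class UnitPlacement:
    read_id: str
    unit_id: str
    read_start: int          # 0-based half-open, forward read coordinates
    read_end: int
    strand: str
    identity: float
    score: float


@dataclass
class TiledGene:
    read_id: str
    strand: str
    placements: list[UnitPlacement]      # gene order: [N, unit x m, C]
    n_units: int
    complete: bool
    gaps: list[tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return (min(p.read_start for p in self.placements),
                max(p.read_end for p in self.placements))


def _identity(dist: int, qlen: int, span: int) -> float:
    return 1.0 - dist / max(qlen, span)


def place_query(query_id: str, query: str, read: SeqRecord,
                min_identity: float, max_hits: int = 1000) -> list[UnitPlacement]:
    """All placements of one query on both strands of one read, found by
    iterated best-hit alignment with masking."""
    placements: list[UnitPlacement] = []
    qlen = len(query)
    k_budget = int((1.0 - min_identity) * 2 * qlen) + 1   # band on edit distance
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        masked = list(read.sequence)
        for _ in range(max_hits):
            res = edlib.align(q, "".join(masked), mode="HW",
                              task="locations", k=k_budget)
            if res["editDistance"] < 0:
                break
            s, e = res["locations"][0]
            e += 1
            ident = _identity(res["editDistance"], qlen, e - s)
            if ident < min_identity:
                break
            placements.append(UnitPlacement(
                read.id, query_id, s, e, strand, ident,
                score=ident * qlen,
            ))
            masked[s:e] = "#" * (e - s)
    return placements


def place_units(units: dict[str, str], long_reads: Sequence[SeqRecord],
                min_identity: float = 0.85) -> list[UnitPlacement]:
    """Place every unit (and terminal element) on every long read."""
    if not units or not long_reads:
        raise ValueError("need at least one unit and one read")
    out: list[UnitPlacement] = []
    for read in long_reads:
        for uid, seq in units.items():
            out.extend(place_query(uid, seq, read, min_identity))
    return out


def _chain(placements: list[UnitPlacement], n_id: str, c_id: str,
           tolerance: int) -> tuple[float, list[UnitPlacement]]:
    """Max-score collinear chain ordered N -> units -> C (DP over placements
    sorted by start).  Returns (score, chain)."""
    order = sorted(range(len(placements)),
                   key=lambda i: (placements[i].read_start, placements[i].read_end))
    kind = []
    for i in order:
        uid = placements[i].unit_id
        kind.append("N" if uid == n_id else "C" if uid == c_id else "U")
    n = len(order)
    best = [-1e18] * n
    prev = [-1] * n
    for ii in range(n):
        p = placements[order[ii]]
        best[ii] = p.score          # any placement may open a (partial) chain
        for jj in range(ii):
            q = placements[order[jj]]
            if best[jj] <= -1e17:
                continue
            if kind[jj] == "C":
                continue                      # nothing follows the C terminus
            if kind[ii] == "N":
                continue                      # N can only open a chain
            if p.read_start < q.read_end - tolerance:
                continue
            cand = best[jj] + p.score
            if cand > best[ii]:
                best[ii] = cand
                prev[ii] = jj
    # best chain ending at a C placement (complete), else best overall
    def backtrack(ii: int) -> list[UnitPlacement]:
        chain = []
        while ii != -1:
            chain.append(placements[order[ii]])
            ii = prev[ii]
        return chain[::-1]

    c_ends = [ii for ii in range(n) if kind[ii] == "C" and best[ii] > -1e17]
    if c_ends:
        ii = max(c_ends, key=lambda x: best[x])
        return best[ii], backtrack(ii)
    valid = [ii for ii in range(n) if best[ii] > -1e17]
    if not valid:
        return -1e18, []
    ii = max(valid, key=lambda x: best[x])
    return best[ii], backtrack(ii)


def chain_and_tile(placements: Sequence[UnitPlacement], n_id: str, c_id: str,
                   read_lengths: dict[str, int],
                   tolerance: int = 10) -> list[TiledGene]:
    """Per read, the maximal-score collinear chain from an N-terminal to a
    C-terminal placement.  Reads where the gene lies on the minus strand are
    chained in mirrored coordinates.  Reads lacking either terminus yield
    partial tilings flagged ``complete=False``."""
    by_read: dict[str, list[UnitPlacement]] = {}
    for p in placements:
        by_read.setdefault(p.read_id, []).append(p)
    tilings: list[TiledGene] = []
    for read_id, plist in by_read.items():
        L = read_lengths[read_id]
        best_score, best_chain, best_strand = -1e18, [], "+"
        for gene_strand in ("+", "-"):
            if gene_strand == "+":
                sub = [p for p in plist if p.strand == "+"]
            else:
                # mirror: placements of the revcomp'd gene appear on '-' and
                # run C -> N left to right; flip coordinates and chain as '+'
                sub = [UnitPlacement(p.read_id, p.unit_id, L - p.read_end,
                                     L - p.read_start, p.strand, p.identity,
                                     p.score)
                       for p in plist if p.strand == "-"]
            if not sub:
                continue
            score, chain = _chain(sub, n_id, c_id, tolerance)
            if score > best_score and chain:
                best_score, best_chain, best_strand = score, chain, gene_strand
        if not best_chain:
            continue
        complete = (best_chain[0].unit_id == n_id
                    and best_chain[-1].unit_id == c_id)
        n_units = sum(1 for p in best_chain if p.unit_id not in (n_id, c_id))
        gaps = []
        for a, b in zip(best_chain, best_chain[1:]):
            if b.read_start - a.read_end > tolerance:
                gaps.append((a.read_end, b.read_start))
        tilings.append(TiledGene(read_id, best_strand, best_chain,
                                 n_units, complete, gaps))
    return tilings


# ---------------------------------------------------------------------------
# Consensus reconstruction
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _vote_column_consensus(backbone: str, observed: Sequence[str]) -> str:
    """Polish a backbone by per-column majority over observed copies.

    Each observed string is globally aligned to the backbone; '=' / 'X'
    columns vote a base, 'D' votes a deletion.  The backbone itself casts one
    vote, so single-read noise cannot overturn it.
    """
    votes: list[dict[str, int]] = [{b: 1} for b in backbone]
    for obs in observed:
        res = edlib.align(obs, backbone, mode="NW", task="path")
        qpos = tpos = 0
        for m in _CIGAR_RE.finditer(res["cigar"]):
            n, op = int(m.group(1)), m.group(2)
            if op in "=XM":
                for _ in range(n):
                    v = votes[tpos]
                    v[obs[qpos]] = v.get(obs[qpos], 0) + 1
                    qpos += 1
                    tpos += 1
            elif op == "I":
                qpos += n
            elif op == "D":
                for _ in range(n):
                    v = votes[tpos]
                    v["-"] = v.get("-", 0) + 1
                    tpos += 1
    out = []
    for j, v in enumerate(votes):
        base = max(v, key=lambda b: (v[b], b == backbone[j]))
        if base != "-":
            out.append(base)
    return "".join(out)


def _oriented_read_segment(read: SeqRecord, tiling: TiledGene,
                           p: UnitPlacement) -> str:
    if tiling.strand == "+":
        return read.sequence[p.read_start:p.read_end]
    L = len(read.sequence)
    return revcomp(read.sequence[L - p.read_end:L - p.read_start])


@dataclass
class ConsensusGene:
    record: SeqRecord
    annotations: list[Annotation]
    n_units: int
    n_support: int            # complete tilings agreeing with the consensus count
    low_support: bool
    count_tie: bool


def consensus_gene(tilings: Sequence[TiledGene], reads: Sequence[SeqRecord],
                   elements: dict[str, str], n_id: str, c_id: str,
                   gene_id: str = "consensus") -> ConsensusGene:
    """Consensus over complete tilings: unit count by (low) median, sequence
    by per-slot majority vote of read bases against the assembled elements."""
    complete = [t for t in tilings if t.complete]
    if not complete:
        raise ValueError("no complete tiling to build a consensus from")
    counts = sorted(t.n_units for t in complete)
    n_units = median_low(counts)
    count_tie = len(counts) % 2 == 0 and counts[len(counts) // 2 - 1] != counts[len(counts) // 2]
    agreeing = [t for t in complete if t.n_units == n_units]
    read_by_id = {r.id: r for r in reads}

    # slot s of every agreeing tiling observes the same gene element
    n_slots = n_units + 2
    pieces: list[str] = []
    annotations: list[Annotation] = []
    pos = 0
    for s in range(n_slots):
        backbones = [elements[t.placements[s].unit_id] for t in agreeing]
        backbone = backbones[0]
        observed = [_oriented_read_segment(read_by_id[t.read_id], t, t.placements[s])
                    for t in agreeing]
        cons = _vote_column_consensus(backbone, observed)
        ftype = ("n_terminal_domain" if s == 0
                 else "c_terminal_domain" if s == n_slots - 1
                 else "repeat_unit")
        label = "N" if s == 0 else "C" if s == n_slots - 1 else f"unit_{s}"
        annotations.append(Annotation(gene_id, pos, pos + len(cons), ftype, label))
        pieces.append(cons)
        pos += len(cons)
    seq = "".join(pieces)
    annotations.append(Annotation(gene_id, 0, len(seq), "gene", gene_id))
    return ConsensusGene(
        record=SeqRecord(gene_id, seq),
        annotations=annotations,
        n_units=n_units,
        n_support=len(agreeing),
        low_support=len(complete) < 3,
        count_tie=count_tie,
    )
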