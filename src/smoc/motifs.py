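"""Spidroin repeat-motif annotation.

Decomposes repeat-region protein sequence into the silk motif vocabulary:
beta-sheet blocks (poly-alanine A{n,} and (GA){m,}), beta-turn motifs
(GPGGX, GPGQQ, XQQ), 3_10-helix GGX, the arginine motif GGR, and
low-complexity spacers.  Overlaps are resolved deterministically: within any
yet-uncovered stretch the longest match wins, ties go to the earlier class
in a fixed precedence order, then to the leftmost start.  This precedence is
a package convention and changes motif counts; it is applied identically by
the scanner and by the test oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: precedence order for overlap resolution (earlier wins at equal length)
PRECEDENCE = ("poly_A", "GA_repeat", "GPGQQ", "GPGGX", "GGR", "GGX", "XQQ")


@dataclass(frozen=True)
class MotifHit:
    motif_class: str
    start: int
    end: int
    matched: str


@dataclass
class ScanParams:
    poly_a_min: int = 4
    ga_min: int = 3          # minimum number of GA pairs
    spacer_min: int = 10


def _candidates_in(seq: str, lo: int, hi: int, p: ScanParams) -> list[MotifHit]:
    """All maximal motif matches lying entirely within seq[lo:hi]."""
    window = seq[lo:hi]
    out: list[MotifHit] = []
    for m in re.finditer(rf"A{{{p.poly_a_min},}}", window):
        out.append(MotifHit("poly_A", lo + m.start(), lo + m.end(), m.group()))
    for m in re.finditer(rf"(?:GA){{{p.ga_min},}}", window):
        out.append(MotifHit("GA_repeat", lo + m.start(), lo + m.end(), m.group()))
    fixed = [("GPGQQ", r"(?=(GPGQQ))"), ("GPGGX", r"(?=(GPGG.))"),
             ("GGR", r"(?=(GGR))"), ("GGX", r"(?=(GG.))"), ("XQQ", r"(?=(.QQ))")]
    for cls, pat in fixed:
        for m in re.finditer(pat, window):
            g = m.group(1)
            out.append(MotifHit(cls, lo + m.start(), lo + m.start() + len(g), g))
    return out


def scan_motifs(protein: str, params: Optional[ScanParams] = None) -> list[MotifHit]:
    """Tile the sequence with motif hits under the fixed precedence; leftover
    runs of at least ``spacer_min`` residues become spacer hits.

    Selection iterates: among all candidate matches fully inside uncovered
    stretches, accept the best (longest, then precedence class, then
    leftmost), carve up the stretch, and rescan — so maximal runs are
    re-derived inside the remaining gaps.
    """
    params = params or ScanParams()
    rank = {c: i for i, c in enumerate(PRECEDENCE)}
    accepted: list[MotifHit] = []
    intervals = [(0, len(protein))]
    while intervals:
        lo, hi = intervals.pop()
        cands = _candidates_in(protein, lo, hi, params)
        if not cands:
            continue
        best = min(cands, key=lambda h: (-(h.end - h.start), rank[h.motif_class], h.start))
        accepted.append(best)
        if best.start > lo:
            intervals.append((lo, best.start))
        if hi > best.end:
            intervals.append((best.end, hi))
    accepted.sort(key=lambda h: h.start)
    # spacers: maximal uncovered runs of at least spacer_min residues
    hits_with_spacers: list[MotifHit] = []
    pos = 0
    for h in accepted + [MotifHit("GGX", len(protein), len(protein), "")]:
        if h.start - pos >= params.spacer_min:
            hits_with_spacers.append(
                MotifHit("spacer", pos, h.start, protein[pos:h.start]))
        if h.end > h.start:
            hits_with_spacers.append(h)
        pos = max(pos, h.end)
    return hits_with_spacers


# ---------------------------------------------------------------------------
# Gene summary
# ---------------------------------------------------------------------------

@dataclass
class GeneSummary:
    gene_id: str
    total_exonic_bp: int
    n_repeats: int
    n_terminal_aa: int
    c_terminal_aa: int
    motif_counts: dict[str, int]
    motif_coverage: float

    def to_row(self) -> dict:
        row = {
            "gene_id": self.gene_id,
            "total_exonic_bp": self.total_exonic_bp,
            "n_repeats": self.n_repeats,
            "n_terminal_aa": self.n_terminal_aa,
            "c_terminal_aa": self.c_terminal_aa,
            "motif_coverage": round(self.motif_coverage, 4),
        }
        for cls in PRECEDENCE + ("spacer",):
            row[f"n_{cls}"] = self.motif_counts.get(cls, 0)
        return row


def summarize_gene(gene_id: str, protein: str, n_terminal_aa: int,
                   c_terminal_aa: int, n_repeats: int, total_exonic_bp: int,
                   hits: Optional[Sequence[MotifHit]] = None,
                   params: Optional[ScanParams] = None) -> GeneSummary:
    """Per-gene summary: lengths, repeat count and motif composition of the
    repeat region (the protein between the terminal domains)."""
    region = protein[n_terminal_aa:len(protein) - c_terminal_aa]
    if hits is None:
        hits = scan_motifs(region, params)
    counts: dict[str, int] = {}
    covered = 0
    for h in hits:
        counts[h.motif_class] = counts.get(h.motif_class, 0) + 1
        covered += h.end - h.start
    coverage = covered / len(region) if region else 0.0
    return GeneSummary(gene_id, total_exonic_bp, n_repeats,
                       n_terminal_aa, c_terminal_aa, counts, coverage)


def summarize_model(model) -> GeneSummary:
    """Summary of a synthetic SpidroinGeneModel from its own truth."""
    exonic = sum(a.end - a.start for a in model.truth if a.feature_type == "exon")
    return summarize_gene(model.gene_id, model.protein,
                          len(model.n_terminal), len(model.c_terminal),
                          model.n_repeats, exonic)


# ---------------------------------------------------------------------------
# Repeat period detection
# ---------------------------------------------------------------------------

@dataclass
class PeriodEstimate:
    period: int
    score: float
    reliable: bool
    null_mean: float
    null_sd: float


def detect_repeat_period(region: str, min_lag: int = 10,
                         max_lag: Optional[int] = None,
                         n_shuffles: int = 100, seed: int = 0,
                         z_threshold: float = 4.0,
                         tie_tolerance: float = 0.02) -> PeriodEstimate:
    """Repeat-unit length estimate from autocorrelation of residue identity.

    score(lag) = mean over i of [s_i == s_{i+lag}]; the period is the
    smallest lag whose score reaches the maximum minus ``tie_tolerance``
    (multiples of the true period score equally well up to sampling noise,
    so near-ties resolve to the fundamental).  Reliability is judged against
    an empirical null of shuffled sequences (z-score of the best lag).
    """
    n = len(region)
    max_lag = max_lag or n // 2
    if max_lag < min_lag:
        raise ValueError("region too short for the requested lag range")
    arr = np.frombuffer(region.encode(), dtype=np.uint8)

    def best_lag(a: np.ndarray) -> tuple[int, float]:
        scores = np.array([np.mean(a[:-lag] == a[lag:])
                           for lag in range(min_lag, max_lag + 1)])
        top = scores.max()
        lag = int(np.argmax(scores >= top - tie_tolerance)) + min_lag
        return lag, float(scores[lag - min_lag])

    period, score = best_lag(arr)
    rng = np.random.default_rng(seed)
    null = np.array([best_lag(rng.permutation(arr))[1] for _ in range(n_shuffles)])
    mu, sd = float(null.mean()), float(null.std() + 1e-12)
    return PeriodEstimate(period, score, (score - mu) / sd >= z_threshold, mu, sd)
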