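"""Independent oracles used by the test suite.

Each oracle re-derives a quantity through a different algorithmic route than
the library (brute-force scans, quadratic dynamic programming, direct regex
enumeration), so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import re

import numpy as np
from numba import njit

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Smith-Waterman with affine gaps (first gap position costs gap_open,
# subsequent positions gap_extend) — quadratic DP, best local score.
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sw_best_score(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    NEG = -1e18
    H_prev = np.zeros(m + 1)
    F = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        H_cur = np.zeros(m + 1)
        E = NEG
        for j in range(1, m + 1):
            E = max(H_cur[j - 1] + gap_open, E + gap_extend)
            F[j] = max(H_prev[j] + gap_open, F[j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H_prev[j - 1] + s
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0.0:
                h = 0.0
            H_cur[j] = h
            if h > best:
                best = h
        H_prev = H_cur
    return best


def sw_best_score(a: str, b: str, match=2.0, mismatch=-3.0,
                  gap_open=-5.0, gap_extend=-2.0) -> float:
    """Best local alignment score of a vs b (single strand)."""
    ia = np.frombuffer(a.encode(), dtype=np.uint8).astype(np.int64)
    ib = np.frombuffer(b.encode(), dtype=np.uint8).astype(np.int64)
    return float(_sw_best_score(ia, ib, match, mismatch, gap_open, gap_extend))


# ---------------------------------------------------------------------------
# Naive PWM extension: rescans every read at every step, no index.
# ---------------------------------------------------------------------------

def naive_extend(seed: str, reads: list[str], k: int, min_coverage: int,
                 tau: float, split_threshold: float, max_extension: int,
                 both_strands: bool = True) -> tuple[str, str]:
    """Returns (final sequence, stop reason)."""
    seq = seed
    extended = 0
    while True:
        if extended >= max_extension:
            return seq, "max_extension"
        anchor = seq[-k:]
        nexts: list[str] = []
        for r in reads:
            variants = [r, rc(r)] if both_strands else [r]
            for s in variants:
                start = 0
                while True:
                    i = s.find(anchor, start)
                    if i == -1:
                        break
                    if i + k < len(s):
                        nexts.append(s[i + k])
                    start = i + 1
        if not nexts:
            return seq, "read_exhaustion"
        counts = {b: 0 for b in "ACGT"}
        for b in nexts:
            if b in counts:
                counts[b] += 1
        coverage = sum(counts.values())
        if coverage < min_coverage:
            return seq, "low_coverage"
        ordered = sorted("ACGT", key=lambda b: -counts[b])
        top, runner = ordered[0], ordered[1]
        if counts[runner] / coverage >= split_threshold:
            return seq, "split"
        if counts[top] / coverage >= tau:
            seq += top
            extended += 1
            continue
        return seq, "split"


# ---------------------------------------------------------------------------
# Motif scan oracle: brute-force candidate enumeration with predicates,
# recursive interval resolution under the shared precedence.
# ---------------------------------------------------------------------------

_ORACLE_ORDER = ["poly_A", "GA_repeat", "GPGQQ", "GPGGX", "GGR", "GGX", "XQQ"]


def _oracle_candidates(s: str, lo: int, hi: int, poly_a_min: int,
                       ga_min: int) -> list[tuple[str, int, int]]:
    """Enumerate every maximal-run / fixed-width motif inside s[lo:hi] by
    checking substrings directly (no shared regex machinery for runs)."""
    cands = []
    i = lo
    while i < hi:                       # maximal A-runs
        if s[i] == "A":
            j = i
            while j < hi and s[j] == "A":
                j += 1
            if j - i >= poly_a_min:
                cands.append(("poly_A", i, j))
            i = j
        else:
            i += 1
    i = lo
    while i < hi - 1:                   # maximal GA-runs
        if s[i] == "G" and s[i + 1] == "A":
            j = i
            while j + 1 < hi and s[j] == "G" and s[j + 1] == "A":
                j += 2
            if (j - i) // 2 >= ga_min:
                cands.append(("GA_repeat", i, j))
            i = j
        else:
            i += 1
    for i in range(lo, hi):
        if s[i:i + 5] == "GPGQQ" and i + 5 <= hi:
            cands.append(("GPGQQ", i, i + 5))
        if s[i:i + 4] == "GPGG" and i + 5 <= hi:
            cands.append(("GPGGX", i, i + 5))
        if s[i:i + 3] == "GGR":
            cands.append(("GGR", i, i + 3))
        if s[i:i + 2] == "GG" and i + 3 <= hi:
            cands.append(("GGX", i, i + 3))
        if s[i + 1:i + 3] == "QQ" and i + 3 <= hi:
            cands.append(("XQQ", i, i + 3))
    return cands


def oracle_scan(s: str, poly_a_min: int = 4, ga_min: int = 3,
                spacer_min: int = 10) -> set[tuple[str, int, int]]:
    rank = {c: i for i, c in enumerate(_ORACLE_ORDER)}
    accepted: list[tuple[str, int, int]] = []

    def resolve(lo: int, hi: int) -> None:
        cands = _oracle_candidates(s, lo, hi, poly_a_min, ga_min)
        if not cands:
            return
        best = min(cands, key=lambda c: (-(c[2] - c[1]), rank[c[0]], c[1]))
        accepted.append(best)
        resolve(lo, best[1])
        resolve(best[2], hi)

    resolve(0, len(s))
    accepted.sort(key=lambda c: c[1])
    out = set(accepted)
    pos = 0
    for cls, a, b in accepted + [("end", len(s), len(s))]:
        if a - pos >= spacer_min:
            out.add(("spacer", pos, a))
        pos = max(pos, b)
    out.discard(("end", len(s), len(s)))
    return out
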