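"""The SMoC extension engine.

Short reads carrying an exact match of a very large k-mer (default 100 bp)
at the 3' end of the current seed are collected; their bases strictly 3' of
the match form a position weight matrix, and the seed grows one base at a
time while the PWM column is unambiguous.  Extension terminates at a graph
split — the point where a neighbouring repeat copy is no longer resolvable
from short reads — or when coverage runs out.

Three strict thresholds control the walk: ``min_coverage`` (reads informing
the next column), ``consensus_threshold`` (minimum top-base frequency to
extend), and ``split_threshold`` (runner-up frequency that declares a split).
An exact 50/50 tie is always a split, never an arbitrary choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import SeqRecord, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass
class ExtensionParams:
    k: int = 100
    min_coverage: int = 5
    consensus_threshold: float = 0.9
    split_threshold: float = 0.2
    max_extension: int = 100_000
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0.5 < self.consensus_threshold <= 1.0):
            raise ValueError("consensus_threshold must be in (0.5, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


class KmerIndex:
    """Exact k-mer -> (read, offset, strand) occurrence index.

    Minus-strand occurrences are recorded in the coordinates of the read's
    reverse complement, so a suffix lookup works identically on both strands.
    """

    def __init__(self, reads: Sequence[SeqRecord], k: int, both_strands: bool = True):
        if not reads:
            raise ValueError("no reads to index")
        max_len = max(len(r.sequence) for r in reads)
        if k > max_len:
            raise ValueError(f"k={k} exceeds the longest read ({max_len} bp)")
        self.k = k
        self.both_strands = both_strands
        self.reads = list(reads)
        self._oriented: dict[str, list[str]] = {"+": [], "-": []}
        self.occurrences: dict[str, list[tuple[int, int, str]]] = {}
        for i, read in enumerate(self.reads):
            seq = read.sequence
            self._oriented["+"].append(seq)
            for off in range(len(seq) - k + 1):
                self.occurrences.setdefault(seq[off:off + k], []).append((i, off, "+"))
            if both_strands:
                rc = revcomp(seq)
                self._oriented["-"].append(rc)
                for off in range(len(rc) - k + 1):
                    self.occurrences.setdefault(rc[off:off + k], []).append((i, off, "-"))

    def lookup(self, kmer: str) -> list[tuple[int, int, str]]:
        return self.occurrences.get(kmer, [])

    def oriented_read(self, read_idx: int, strand: str) -> str:
        return self._oriented[strand][read_idx]


def build_kmer_index(reads: Sequence[SeqRecord], k: int,
                     both_strands: bool = True) -> KmerIndex:
    return KmerIndex(reads, k, both_strands)


def collect_suffixes(anchor: str, index: KmerIndex) -> list[str]:
    """Read bases strictly 3' of each exact anchor occurrence (anchor
    orientation); empty suffixes are dropped."""
    if len(anchor) != index.k:
        raise ValueError(f"anchor length {len(anchor)} != k={index.k}")
    suffixes = []
    for read_idx, off, strand in index.lookup(anchor):
        suffix = index.oriented_read(read_idx, strand)[off + index.k:]
        if suffix:
            suffixes.append(suffix)
    return suffixes


@dataclass
class PositionWeightMatrix:
    """Per-column base counts over aligned suffixes.

    ``counts[j]`` holds A/C/G/T counts at column j; N bases are tallied in
    ``n_counts`` and excluded from the frequency denominator, so a column of
    Ns has zero informative coverage.
    """

    counts: np.ndarray          # (n_columns, 4) int
    n_counts: np.ndarray        # (n_columns,) int

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    def coverage(self, j: int) -> int:
        return int(self.counts[j].sum())

    def freqs(self, j: int) -> np.ndarray:
        cov = self.counts[j].sum()
        if cov == 0:
            return np.zeros(4)
        return self.counts[j] / cov


def build_pwm(suffixes: Sequence[str]) -> PositionWeightMatrix:
    if not suffixes:
        return PositionWeightMatrix(np.zeros((0, 4), dtype=int),
                                    np.zeros(0, dtype=int))
    width = max(len(s) for s in suffixes)
    counts = np.zeros((width, 4), dtype=int)
    n_counts = np.zeros(width, dtype=int)
    for s in suffixes:
        for j, base in enumerate(s):
            bi = _BASE_INDEX.get(base)
            if bi is None:
                n_counts[j] += 1
            else:
                counts[j, bi] += 1
    return PositionWeightMatrix(counts, n_counts)


@dataclass
class ExtensionState:
    """Mutable state of one seed extension; the seed grows at its 3' end."""

    seed: str
    original_length: int
    extended_bases: int = 0
    stop_reason: Optional[str] = None       # split | low_coverage | max_extension | read_exhaustion
    split_alternatives: Optional[tuple[tuple[str, float], tuple[str, float]]] = None
    trace: list[tuple[str, float, int]] = field(default_factory=list)

    @property
    def stopped(self) -> bool:
        return self.stop_reason is not None

    @property
    def extension(self) -> str:
        """Bases added beyond the original seed."""
        return self.seed[self.original_length:]


def extend_step(state: ExtensionState, index: KmerIndex,
                params: ExtensionParams) -> ExtensionState:
    """One extension step: the PWM column immediately 3' of the current
    anchor either appends a base or stops the walk."""
    if state.stopped:
        return state
    anchor = state.seed[-params.k:]
    suffixes = collect_suffixes(anchor, index)
    if not suffixes:
        state.stop_reason = "read_exhaustion"
        return state
    pwm = build_pwm(suffixes)
    col = pwm.counts[0]
    coverage = int(col.sum())
    if coverage < params.min_coverage:
        state.stop_reason = "low_coverage"
        return state
    freqs = col / coverage
    order = np.argsort(freqs, kind="stable")[::-1]
    top, runner = int(order[0]), int(order[1])
    if freqs[runner] >= params.split_threshold:
        state.stop_reason = "split"
        state.split_alternatives = (
            (_BASES[top], float(freqs[top])), (_BASES[runner], float(freqs[runner])),
        )
        return state
    if freqs[top] >= params.consensus_threshold:
        base = _BASES[top]
        state.seed += base
        state.extended_bases += 1
        state.trace.append((base, float(freqs[top]), coverage))
        return state
    state.stop_reason = "split"
    state.split_alternatives = (
        (_BASES[top], float(freqs[top])), (_BASES[runner], float(freqs[runner])),
    )
    return state


def extend_to_completion(seed: str | SeqRecord, reads: Sequence[SeqRecord],
                         params: Optional[ExtensionParams] = None,
                         index: Optional[KmerIndex] = None) -> ExtensionState:
    """Iterate extend_step until a stop condition or the extension cap."""
    params = params or ExtensionParams()
    seq = seed.sequence if isinstance(seed, SeqRecord) else seed
    if len(seq) < params.k:
        raise ValueError(f"seed ({len(seq)} bp) shorter than k={params.k}")
    if index is None:
        index = build_kmer_index(reads, params.k, params.both_strands)
    state = ExtensionState(seed=seq, original_length=len(seq))
    while not state.stopped:
        if state.extended_bases >= params.max_extension:
            state.stop_reason = "max_extension"
            break
        extend_step(state, index, params)
    return state


# ---------------------------------------------------------------------------
# Repeat-unit harvesting
# ---------------------------------------------------------------------------

@dataclass
class RepeatUnit:
    sequence: str
    multiplicity: int
    provenance: str


@dataclass
class RepeatUnitSet:
    units: list[RepeatUnit]

    def sequences(self) -> list[str]:
        return [u.sequence for u in self.units]


def _pairwise_identity(a: str, b: str) -> float:
    import edlib
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def harvest_repeat_units(states: Sequence[ExtensionState],
                         repeat_seeds: Sequence[str] = (),
                         dedup_threshold: float = 0.98,
                         min_length: int = 0) -> RepeatUnitSet:
    """Collect candidate repeat units from completed extensions (the part
    grown beyond the terminal-domain seed) and from transcript-derived repeat
    seeds; near-duplicates (identity >= dedup_threshold) are merged with
    their multiplicity incremented."""
    candidates: list[tuple[str, str]] = []
    for i, state in enumerate(states):
        frag = state.extension
        if frag and len(frag) >= min_length:
            candidates.append((frag, f"extension_{i}"))
    for i, seed in enumerate(repeat_seeds):
        if seed and len(seed) >= min_length:
            candidates.append((seed, f"transcript_{i}"))
    if not candidates:
        raise ValueError("no completed extensions or repeat seeds to harvest")
    units: list[RepeatUnit] = []
    for seq, prov in candidates:
        for unit in units:
            if _pairwise_identity(seq, unit.sequence) >= dedup_threshold:
                unit.multiplicity += 1
                break
        else:
            units.append(RepeatUnit(seq, 1, prov))
    return RepeatUnitSet(units)
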