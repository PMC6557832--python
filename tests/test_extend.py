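import numpy as np
import pytest

from smoc.extend import (ExtensionParams, ExtensionState, build_kmer_index,
                         build_pwm, collect_suffixes, extend_step,
                         extend_to_completion, harvest_repeat_units)
from smoc.io import SeqRecord, revcomp
from smoc.synthetic import ReadSimParams, simulate_short_reads

from oracles import naive_extend, rc


def _reads(*seqs):
    return [SeqRecord(f"r{i}", s) for i, s in enumerate(seqs)]


def _brute_force_occurrences(reads, kmer):
    """All (read_idx, offset, strand) where the k-mer occurs, by direct scan."""
    k = len(kmer)
    out = set()
    for i, r in enumerate(reads):
        for strand, s in (("+", r.sequence), ("-", rc(r.sequence))):
            for off in range(len(s) - k + 1):
                if s[off:off + k] == kmer:
                    out.add((i, off, strand))
    return out


class TestKmerIndex:
    def test_occurrences_match_brute_force_scan(self):
        reads = _reads("GTACGG", "TTACGT")
        idx = build_kmer_index(reads, 4)
        assert set(idx.lookup("GTAC")) == _brute_force_occurrences(reads, "GTAC")
        # revcomp of read 0 is CCGTAC: one forward and one reverse occurrence
        assert set(idx.lookup("GTAC")) == {(0, 0, "+"), (0, 2, "-")}

    def test_unknown_kmer_lookup_is_empty(self):
        idx = build_kmer_index(_reads("ACGTACGT"), 5)
        assert idx.lookup("GGGGG") == []

    def test_palindromic_kmer_seen_on_both_strands(self):
        reads = _reads("TTGCGCAA")
        idx = build_kmer_index(reads, 4)
        occ = set(idx.lookup("GCGC"))
        assert occ == _brute_force_occurrences(reads, "GCGC")
        assert {s for _, _, s in occ} == {"+", "-"}

    def test_random_reads_match_brute_force(self, rng):
        reads = _reads(*("".join("ACGT"[i] for i in rng.integers(4, size=30))
                         for _ in range(20)))
        idx = build_kmer_index(reads, 6)
        for kmer in list(idx.occurrences)[:50]:
            assert set(idx.lookup(kmer)) == _brute_force_occurrences(reads, kmer)

    def test_k_longer_than_reads_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_index(_reads("ACGT"), 10)


class TestCollectSuffixes:
    def test_suffix_is_three_prime_of_match(self):
        idx = build_kmer_index(_reads("GTACGG"), 4, both_strands=False)
        assert collect_suffixes("GTAC", idx) == ["GG"]

    def test_occurrence_at_read_end_contributes_nothing(self):
        idx = build_kmer_index(_reads("AAGTAC"), 4, both_strands=False)
        assert collect_suffixes("GTAC", idx) == []

    def test_reverse_strand_suffix_from_revcomp(self):
        read = "CCGTAC"   # revcomp = GTACGG: anchor GTAC + suffix GG
        idx = build_kmer_index(_reads(read), 4)
        assert collect_suffixes("GTAC", idx) == ["GG"]


class TestPwm:
    def test_direct_counting(self):
        pwm = build_pwm(["GG", "GG", "GA"])
        assert pwm.freqs(0)[2] == 1.0
        assert pwm.freqs(1)[2] == pytest.approx(2 / 3)
        assert pwm.freqs(1)[0] == pytest.approx(1 / 3)

    def test_empty_suffixes_give_zero_columns(self):
        assert build_pwm([]).n_columns == 0

    def test_ragged_lengths(self):
        pwm = build_pwm(["A", "AC"])
        assert pwm.coverage(0) == 2 and pwm.coverage(1) == 1

    def test_n_bases_excluded_from_frequencies(self):
        pwm = build_pwm(["NG", "AG"])
        assert pwm.n_counts[0] == 1
        assert pwm.coverage(0) == 1 and pwm.freqs(0)[0] == 1.0


class TestExtendStep:
    def _state_for(self, reads, seed, **kw):
        params = ExtensionParams(k=4, min_coverage=kw.pop("min_coverage", 1),
                                 **kw)
        idx = build_kmer_index(reads, 4, both_strands=False)
        return ExtensionState(seed=seed, original_length=len(seed)), idx, params

    def test_unanimous_column_extends(self):
        reads = _reads(*["GTACG"] * 10)
        state, idx, params = self._state_for(reads, "GTAC")
        extend_step(state, idx, params)
        assert state.seed == "GTACG" and not state.stopped

    def test_even_split_halts_with_alternatives(self):
        reads = _reads(*["GTACG"] * 5, *["GTACT"] * 5)
        state, idx, params = self._state_for(reads, "GTAC")
        extend_step(state, idx, params)
        assert state.stop_reason == "split"
        assert {b for b, _ in state.split_alternatives} == {"G", "T"}
        assert state.split_alternatives[0][1] == 0.5

    def test_nine_to_one_extends_under_default_thresholds(self):
        reads = _reads(*["GTACG"] * 9, "GTACT")
        state, idx, params = self._state_for(reads, "GTAC")
        extend_step(state, idx, params)
        assert state.seed == "GTACG"
        assert state.trace == [("G", 0.9, 10)]

    def test_low_coverage_stops(self):
        reads = _reads("GTACG", "GTACG")
        state, idx, params = self._state_for(reads, "GTAC", min_coverage=5)
        extend_step(state, idx, params)
        assert state.stop_reason == "low_coverage"

    def test_no_matching_reads_is_exhaustion(self):
        reads = _reads("CCCCCC")
        state, idx, params = self._state_for(reads, "GTAC")
        extend_step(state, idx, params)
        assert state.stop_reason == "read_exhaustion"


class TestExtendToCompletion:
    def test_unique_path_is_walked_to_template_end(self, rng):
        template = "".join("ACGT"[i] for i in rng.integers(4, size=500))
        reads = simulate_short_reads(
            SeqRecord("t", template),
            ReadSimParams(read_length=40, paired=False, coverage=50,
                          error_rate_subs=0.0, seed=1))
        params = ExtensionParams(k=20, min_coverage=2)
        # seed away from the template edge, where coverage is full
        state = extend_to_completion(template[40:60], reads, params)
        assert state.seed == template[40:60 + state.extended_bases]
        assert state.stop_reason in ("low_coverage", "read_exhaustion")
        assert state.extended_bases > 380

    def test_max_extension_cap(self, rng):
        template = "".join("ACGT"[i] for i in rng.integers(4, size=200))
        reads = simulate_short_reads(
            SeqRecord("t", template),
            ReadSimParams(read_length=40, paired=False, coverage=50,
                          error_rate_subs=0.0, seed=2))
        params = ExtensionParams(k=20, min_coverage=2, max_extension=10)
        state = extend_to_completion(template[80:100], reads, params)
        assert state.extended_bases <= 10
        assert state.stop_reason == "max_extension"

    def test_determinism_including_trace(self, rng):
        template = "".join("ACGT"[i] for i in rng.integers(4, size=300))
        reads = simulate_short_reads(
            SeqRecord("t", template),
            ReadSimParams(read_length=40, paired=False, coverage=30,
                          error_rate_subs=0.0, seed=3))
        params = ExtensionParams(k=16, min_coverage=2)
        a = extend_to_completion(template[:16], reads, params)
        b = extend_to_completion(template[:16], reads, params)
        assert (a.seed, a.stop_reason, a.trace) == (b.seed, b.stop_reason, b.trace)

    def test_strand_invariance(self, rng):
        template = "".join("ACGT"[i] for i in rng.integers(4, size=300))
        reads = simulate_short_reads(
            SeqRecord("t", template),
            ReadSimParams(read_length=40, paired=False, coverage=30,
                          error_rate_subs=0.0, seed=4))
        flipped = [SeqRecord(r.id, revcomp(r.sequence)) for r in reads]
        params = ExtensionParams(k=16, min_coverage=2)
        a = extend_to_completion(template[:16], reads, params)
        b = extend_to_completion(template[:16], flipped, params)
        assert (a.seed, a.stop_reason) == (b.seed, b.stop_reason)

    def test_seed_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            extend_to_completion("ACGT", _reads("ACGTACGTACGT"),
                                 ExtensionParams(k=8))

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_naive_rescanning_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        k = int(rng.integers(4, 9))
        template = "".join("ACGT"[i] for i in rng.integers(4, size=120))
        n_reads = int(rng.integers(10, 51))
        read_len = int(rng.integers(k + 1, 41))
        reads = []
        for _ in range(n_reads):
            start = int(rng.integers(0, 120 - read_len + 1))
            s = template[start:start + read_len]
            if rng.random() < 0.5:
                s = revcomp(s)
            reads.append(s)
        params = ExtensionParams(k=k, min_coverage=2, max_extension=200)
        seed = template[:k]
        state = extend_to_completion(seed, _reads(*reads), params)
        expected_seq, expected_stop = naive_extend(
            seed, reads, k, params.min_coverage, params.consensus_threshold,
            params.split_threshold, params.max_extension)
        assert (state.seed, state.stop_reason) == (expected_seq, expected_stop)


class TestSplitDetection:
    def test_halts_exactly_at_known_divergent_site(self):
        rng = np.random.default_rng(5)
        prefix = "".join("ACGT"[i] for i in rng.integers(4, size=60))
        tail = "".join("ACGT"[i] for i in rng.integers(4, size=150))
        site = 40
        tail_b = tail[:site] + ("A" if tail[site] != "A" else "C") + tail[site + 1:]
        reads = []
        for variant in (prefix + tail, prefix + tail_b):
            reads += [r.sequence for r in simulate_short_reads(
                SeqRecord("v", variant),
                ReadSimParams(read_length=40, paired=False, coverage=40,
                              error_rate_subs=0.0, seed=6))]
        params = ExtensionParams(k=20, min_coverage=4)
        state = extend_to_completion(prefix[-20:], _reads(*reads), params)
        assert state.stop_reason == "split"
        assert state.extended_bases == site


class TestHarvest:
    def _done(self, seed, ext):
        return ExtensionState(seed=seed + ext, original_length=len(seed),
                              extended_bases=len(ext), stop_reason="split")

    def test_single_extension_single_unit(self):
        units = harvest_repeat_units([self._done("AAAA", "GGTTGGAACC")])
        assert len(units.units) == 1
        assert units.units[0].sequence == "GGTTGGAACC"
        assert units.units[0].multiplicity == 1

    def test_identical_units_deduplicated(self):
        states = [self._done("AAAA", "GGTTGGAACC"),
                  self._done("CCCC", "GGTTGGAACC")]
        units = harvest_repeat_units(states)
        assert len(units.units) == 1 and units.units[0].multiplicity == 2

    def test_units_above_divergence_threshold_kept_separate(self):
        a = "GGTTGGAACCGGTTGGAACC"           # 20 bp
        b = a[:10] + "TT" + a[12:]           # 10% different
        units = harvest_repeat_units([self._done("AAAA", a)], [b])
        assert len(units.units) == 2

    def test_nothing_to_harvest_rejected(self):
        with pytest.raises(ValueError):
            harvest_repeat_units([])
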