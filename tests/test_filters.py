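import math

import numpy as np
import pytest

from readforge.filters import (
    ChimeraScreen,
    FilterConfig,
    chastity_pass,
    chimera_flag,
    filter_stream,
    quality_pass,
    shannon_entropy,
    summarize_verdicts,
    tag_match,
)
from readforge.seqio import ILLUMINA_PE_ADAPTER, ReadRecord

from conftest import random_seq


class TestEntropy:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAAAAAAA", 0.0),
            ("ACGTACGTACGT", 1.0),
            ("GACGACGACGAC", math.log2(3) / 2),
        ],
    )
    def test_reference_values(self, seq, expected):
        assert shannon_entropy(seq) == pytest.approx(expected)

    def test_three_letter_repeat_fails_default_cutoff(self):
        cfg = FilterConfig()
        assert shannon_entropy("GACGACGACGAC") < cfg.entropy_cutoff

    def test_all_n_defined_as_zero(self):
        assert shannon_entropy("NNNN") == 0.0

    def test_permutation_invariant_and_bounded(self, rng):
        seq = random_seq(rng, 80)
        shuffled = "".join(rng.permutation(list(seq)).tolist())
        assert shannon_entropy(seq) == pytest.approx(shannon_entropy(shuffled))
        assert 0.0 <= shannon_entropy(seq) <= 1.0


class TestQualityFilter:
    def test_all_high_quality_passes(self):
        assert quality_pass([40] * 101)

    def test_allowance_boundary_101_cycles(self):
        # floor(101/20) = 5 outliers allowed
        qual = [40] * 101
        for i in range(5):
            qual[i] = 10
        assert quality_pass(qual)
        qual[5] = 10
        assert not quality_pass(qual)

    def test_short_read_has_no_allowance(self):
        qual = [40] * 19
        qual[0] = 10
        assert not quality_pass(qual)

    def test_monotone_in_cutoff(self, rng):
        qual = rng.integers(2, 41, 101).tolist()
        passed = [
            quality_pass(qual, FilterConfig(qual_cutoff=c)) for c in range(0, 41, 5)
        ]
        # once failing at some cutoff, stays failing at higher cutoffs
        assert passed == sorted(passed, reverse=True)


class TestTagFilter:
    cfg = FilterConfig(tag="GAC", tag_mismatch=1)

    @pytest.mark.parametrize(
        "seq,expected",
        [("GACTTTTT", True), ("GATTTTTT", True), ("TTTTTTTT", False)],
    )
    def test_prefix_matching(self, seq, expected):
        assert tag_match(seq, self.cfg) is expected

    def test_zero_mismatch_mode(self):
        cfg = FilterConfig(tag="GAC", tag_mismatch=0)
        assert tag_match("GACAAA", cfg)
        assert not tag_match("GATAAA", cfg)

    def test_read_shorter_than_tag_fails_with_inf(self):
        from readforge.filters import tag_distance

        assert tag_distance("GA", self.cfg) == math.inf
        assert not tag_match("GA", self.cfg)


class TestChastity:
    def test_clear_winner_passes(self):
        series = np.tile([10.0, 2.0, 1.0, 0.0], (12, 1))
        assert chastity_pass(series)

    def test_boundary_ratio_inclusive(self):
        series = np.tile([3.0, 2.0, 0.0, 0.0], (12, 1))
        assert chastity_pass(series)  # exactly 1.5x passes

    def test_outlier_modes(self):
        good = [10.0, 1.0, 0.0, 0.0]
        bad = [3.0, 2.5, 0.0, 0.0]  # ratio 1.2
        strict = np.array([good] * 11 + [bad])
        assert not chastity_pass(strict, FilterConfig())
        lenient = np.array([good] * 24 + [bad])
        assert chastity_pass(
            lenient, FilterConfig(chastity_cycles=25, chastity_outliers=1)
        )

    def test_zero_runner_up_needs_positive_max(self):
        ok = np.tile([5.0, 0.0, 0.0, 0.0], (12, 1))
        assert chastity_pass(ok)
        dark = np.zeros((12, 4))
        assert not chastity_pass(dark)

    def test_ratio_one_passes_any_strict_maximum(self, rng):
        series = rng.random((12, 4)) + np.tile([1.0, 0, 0, 0], (12, 1)) * 2
        assert chastity_pass(series, FilterConfig(chastity_ratio=1.0))

    def test_negative_intensity_rejected(self):
        series = np.tile([1.0, -0.1, 0.0, 0.0], (12, 1))
        with pytest.raises(ValueError):
            chastity_pass(series)


class TestChimeraScreen:
    def test_junction_chimera_flagged(self, rng):
        o1 = random_seq(rng, 61)
        o2 = random_seq(rng, 80)
        read = o1[10:40] + o2[0:71]
        cfg = FilterConfig(oligos=(o1, o2))
        flagged, label = chimera_flag(read, cfg)
        assert flagged
        assert "|" in label  # reported as a junction of two oligos

    def test_oligo_with_substitutions_flagged(self, rng):
        o = list(ILLUMINA_PE_ADAPTER)
        for i in (5, 20, 40):
            o[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[o[i]]
        read = "".join(o)  # 3 substitutions in 61nt: identity ~0.95
        cfg = FilterConfig(oligos=(ILLUMINA_PE_ADAPTER,))
        flagged, label = chimera_flag(read, cfg)
        assert flagged

    def test_random_reads_never_flagged(self, rng):
        cfg = FilterConfig(oligos=(ILLUMINA_PE_ADAPTER,))
        screen = ChimeraScreen(cfg)
        flags = sum(
            screen.flag(random_seq(rng, 101))[0] for _ in range(10_000)
        )
        assert flags == 0

    def test_empty_oligo_list_rejected(self):
        with pytest.raises(ValueError):
            chimera_flag("ACGT", FilterConfig(oligos=()))


class TestFilterStream:
    def _reads(self, rng, n=20):
        return [
            ReadRecord(f"r{i}", random_seq(rng, 101), [35] * 101) for i in range(n)
        ]

    def test_no_filters_is_identity(self, rng):
        reads = self._reads(rng)
        passing, table = filter_stream(reads, FilterConfig(), order=())
        assert passing == reads
        assert table["passed"].all()

    def test_order_matters_and_is_reported(self):
        # homopolymer read that matches the tag: entropy-first removes it,
        # tag-only configuration keeps it
        read = ReadRecord("h", "GAC" + "A" * 98, [35] * 101)
        cfg = FilterConfig(tag="GAC")
        passing, table = filter_stream([read], cfg, order=("tag", "entropy"))
        assert not passing
        assert table.loc[0, "failed_filter"] == "entropy"
        passing, table = filter_stream([read], cfg, order=("tag",))
        assert len(passing) == 1

    def test_counts_conserved(self, rng):
        reads = self._reads(rng, 50) + [
            ReadRecord("low", "A" * 101, [35] * 101),
            ReadRecord("badq", random_seq(rng, 101), [5] * 101),
        ]
        cfg = FilterConfig()
        passing, table = filter_stream(reads, cfg, order=("entropy", "quality"))
        assert len(table) == len(reads)
        summary = summarize_verdicts(table)
        assert summary["count"].sum() == len(reads)
        assert len(passing) + (~table["passed"]).sum() == len(reads)

    def test_unknown_filter_rejected(self, rng):
        with pytest.raises(ValueError):
            filter_stream(self._reads(rng, 1), FilterConfig(), order=("bogus",))

    def test_raising_entropy_cutoff_monotone(self, rng):
        reads = self._reads(rng, 100)
        n_pass = []
        for cutoff in (0.5, 0.85, 0.95, 1.0):
            cfg = FilterConfig(entropy_cutoff=cutoff)
            passing, _ = filter_stream(reads, cfg, order=("entropy",))
            n_pass.append(len(passing))
        assert n_pass == sorted(n_pass, reverse=True)
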