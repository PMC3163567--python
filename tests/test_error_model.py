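import numpy as np
import pytest

from readforge.error_model import (
    BASES,
    QualityModel,
    apply_errors,
    apply_errors_batch,
    build_profile_from_truth,
    encode,
    error_count_spectrum,
    load_profile,
    make_synthetic_profile,
    save_profile,
)
from readforge.seqio import ReadRecord

from conftest import random_seq


class TestSyntheticProfile:
    def test_zero_error_gives_max_quality(self):
        prof = make_synthetic_profile(10, 0.0, 0.0)
        assert (prof.rate == 0).all()
        assert (prof.mean_q == 41).all()

    def test_linear_endpoints(self):
        prof = make_synthetic_profile(101, 0.001, 0.1, "linear")
        assert prof.rate[0, 0] == pytest.approx(0.001)
        assert prof.rate[100, 0] == pytest.approx(0.1)

    @pytest.mark.parametrize("shape", ["linear", "exponential"])
    def test_monotone_rates(self, shape):
        prof = make_synthetic_profile(50, 0.002, 0.08, shape)
        assert (np.diff(prof.rate, axis=0) >= -1e-12).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_profile(10, 0.2, 0.1)
        with pytest.raises(ValueError):
            make_synthetic_profile(10, 0.0, 0.9)


class TestApplyErrors:
    def test_zero_profile_is_identity(self, rng):
        prof = make_synthetic_profile(101, 0.0, 0.0)
        truth = random_seq(rng, 101)
        rec = apply_errors(truth, prof, QualityModel(), seed=3)
        assert rec.seq == truth

    def test_mismatch_fraction_matches_binomial(self, rng):
        # constant 1% per cycle over 10,000 101-mers: 4 sigma binomial band
        prof = make_synthetic_profile(101, 0.01, 0.01)
        truth = encode(random_seq(rng, 101))
        mat = np.tile(truth, (10_000, 1))
        obs, _ = apply_errors_batch(mat, prof, QualityModel(), rng)
        frac = (obs != mat).mean()
        n = mat.size
        assert abs(frac - 0.01) < 4 * np.sqrt(0.01 * 0.99 / n)

    def test_position_average_quality_constant_per_cell(self, rng):
        prof = make_synthetic_profile(101, 0.05, 0.05)
        truth = encode(random_seq(rng, 101))
        mat = np.tile(truth, (200, 1))
        _, qual = apply_errors_batch(mat, prof, QualityModel("position_average"), rng)
        expected = np.round(prof.mean_q[np.arange(101), truth])
        assert (qual == expected[None, :]).all()

    def test_informative_quality_uniform_jitter(self, rng):
        prof = make_synthetic_profile(1, 0.0, 0.0)
        prof.mean_q[:] = 30.0
        mat = np.zeros((5000, 1), dtype=np.uint8)
        _, qual = apply_errors_batch(
            mat, prof, QualityModel("error_informative"), rng
        )
        values, counts = np.unique(qual, return_counts=True)
        assert values.min() == 30 and values.max() == 40
        assert counts.min() > 5000 / 11 * 0.7  # roughly uniform over {30..40}

    def test_erroneous_bases_get_lower_quality(self, rng):
        prof = make_synthetic_profile(101, 0.05, 0.05)
        truth = encode(random_seq(rng, 101))
        mat = np.tile(truth, (2000, 1))
        obs, qual = apply_errors_batch(
            mat, prof, QualityModel("error_informative"), rng
        )
        err = obs != mat
        assert qual[err].mean() < qual[~err].mean()

    def test_truth_longer_than_profile_rejected(self):
        prof = make_synthetic_profile(10, 0.01, 0.01)
        with pytest.raises(ValueError):
            apply_errors("A" * 11, prof, QualityModel(), seed=0)


class TestProfileEstimation:
    def test_zero_mismatches_give_zero_rates(self):
        pairs = [
            (ReadRecord(f"r{i}", "ACGT", [30] * 4), "ACGT") for i in range(100)
        ]
        prof = build_profile_from_truth(pairs)
        assert (prof.rate == 0).all()
        assert prof.mean_q[0, 0] == 30

    def test_single_mismatch_direct_count(self):
        # 100 reads, all cycle-5 truth bases are A, exactly one reads C there
        truth = "GGGG" + "A" + "GGGG"
        reads = []
        for i in range(100):
            seq = "GGGG" + ("C" if i == 0 else "A") + "GGGG"
            reads.append((ReadRecord(f"r{i}", seq, [30] * 9), truth))
        prof = build_profile_from_truth(reads)
        assert prof.rate[4, 0] == pytest.approx(0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_profile_from_truth([(ReadRecord("r", "ACG", [30] * 3), "ACGT")])

    def test_parameter_recovery_within_binomial_ci(self, rng, rising_profile):
        # per-cell 4 sigma check at n opportunities per cell
        n = 12_000
        model = QualityModel("error_informative")
        pairs = []
        obs_all = []
        truth_all = []
        truth = encode(random_seq(rng, 101))
        mat = np.tile(truth, (n, 1))
        obs, qual = apply_errors_batch(mat, rising_profile, model, rng)
        from readforge.error_model import decode

        for i in range(n):
            pairs.append(
                (ReadRecord(f"r{i}", decode(obs[i]), qual[i].tolist()),
                 decode(mat[i]))
            )
        est = build_profile_from_truth(pairs)
        opp = np.zeros((101, 4), dtype=int)
        np.add.at(opp, (np.arange(101), truth), n)
        p = rising_profile.rate
        tol = 4 * np.sqrt(p * (1 - p) / np.maximum(opp, 1))
        cells = opp > 0
        assert (np.abs(est.rate - p)[cells] <= tol[cells]).all()


class TestErrorSpectrum:
    def test_zero_error_is_point_mass(self):
        pairs = [(ReadRecord(f"r{i}", "ACGT" * 25, [30] * 100), "ACGT" * 25)
                 for i in range(50)]
        tab = error_count_spectrum(pairs)
        assert tab.loc[0, "observed_fraction"] == 1.0
        assert tab.loc[0, "expected_fraction"] == pytest.approx(1.0)
        assert (tab.loc[1:, "observed_fraction"] == 0).all()

    def test_independent_errors_match_binomial(self, rng):
        prof = make_synthetic_profile(101, 0.01, 0.01)
        truth = encode(random_seq(rng, 101))
        n = 20_000
        mat = np.tile(truth, (n, 1))
        obs, qual = apply_errors_batch(mat, prof, QualityModel(), rng)
        from readforge.error_model import decode

        pairs = [
            (ReadRecord(f"r{i}", decode(obs[i]), qual[i].tolist()), decode(truth))
            for i in range(n)
        ]
        tab = error_count_spectrum(pairs)
        for _, row in tab.iterrows():
            e = row.expected_fraction
            tol = 5 * np.sqrt(max(e, 1 / n) * (1 - e) / n) + 0.005
            assert abs(row.observed_fraction - e) < tol

    def test_clustered_errors_are_overdispersed(self, rng):
        # 90% clean (0.1% per cycle) + 10% noisy (5%): P(2) above extrapolation
        clean = make_synthetic_profile(101, 0.001, 0.001)
        noisy = make_synthetic_profile(101, 0.05, 0.05)
        truth = encode(random_seq(rng, 101))
        from readforge.error_model import decode

        pairs = []
        for prof, n in ((clean, 18_000), (noisy, 2_000)):
            mat = np.tile(truth, (n, 1))
            obs, qual = apply_errors_batch(mat, prof, QualityModel(), rng)
            pairs += [
                (ReadRecord(f"x{len(pairs) + i}", decode(obs[i]), qual[i].tolist()),
                 decode(truth))
                for i in range(n)
            ]
        tab = error_count_spectrum(pairs)
        assert tab.loc[2, "observed_fraction"] > tab.loc[2, "expected_fraction"]

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            error_count_spectrum([])


class TestProfileIO:
    def test_round_trip(self, tmp_path, rising_profile):
        p = tmp_path / "prof.tsv"
        save_profile(rising_profile, p)
        back = load_profile(p)
        np.testing.assert_allclose(back.rate, rising_profile.rate, rtol=1e-9)
        np.testing.assert_allclose(back.mean_q, rising_profile.mean_q, rtol=1e-9)

    def test_missing_row_rejected(self, tmp_path, rising_profile):
        p = tmp_path / "prof.tsv"
        save_profile(rising_profile, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError):
            load_profile(p)

    def test_rate_above_one_rejected(self, tmp_path):
        p = tmp_path / "prof.tsv"
        lines = ["cycle\tbase\trate\tmean_q"]
        for b in BASES:
            lines.append(f"1\t{b}\t1.5\t30")
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError):
            load_profile(p)
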