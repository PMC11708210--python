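import numpy as np
import pandas as pd
import pytest

from urscan.complexity import (
    NullModel,
    WindowConfig,
    calibrate_null,
    classify_unique,
    profile_genome,
    read_profile,
    window_complexity,
    window_starts,
    write_profile,
)
from urscan.seqindex import Factorization, SequenceRecord, build_index, random_residues


def _fact(factors, region):
    starts = np.array([s for s, _ in factors], dtype=np.int64)
    lengths = np.array([l for _, l in factors], dtype=np.int64)
    return Factorization(starts=starts, lengths=lengths, region=region)


class TestWindowConfig:
    def test_default_step_is_tenth(self):
        assert WindowConfig(10_000).step == 1_000

    @pytest.mark.parametrize("w,s", [(1, None), (10, 0), (10, 11)])
    def test_invalid_geometry(self, w, s):
        with pytest.raises(ValueError):
            WindowConfig(w, s)

    def test_last_window_flush_with_end(self):
        starts = window_starts(25, WindowConfig(10, 4))
        assert starts.tolist() == [0, 4, 8, 12, 15]

    def test_short_chromosome_yields_no_windows(self):
        assert len(window_starts(5, WindowConfig(10, 2))) == 0


class TestCalibrateNull:
    def test_determinism_under_fixed_seed(self):
        kw = dict(total_length=3_000, composition=np.full(4, 0.25), cfg=WindowConfig(500, 100))
        a = calibrate_null(replicates=3, seed=9, **kw)
        b = calibrate_null(replicates=3, seed=9, **kw)
        assert a.me == b.me
        np.testing.assert_array_equal(a.null_cm, b.null_cm)

    def test_null_cm_mean_is_one_by_construction(self):
        null = calibrate_null(3_000, np.full(4, 0.25), WindowConfig(500, 100), 3, seed=1)
        assert null.me > 1
        assert np.isclose(null.null_cm.mean(), 1.0, atol=1e-12)

    def test_me_per_window_decreases_with_genome_length(self):
        # longer genomes have longer chance matches, hence fewer factors
        # per fixed-size window: direct simulation at two lengths
        cfg = WindowConfig(1_000, 500)
        short = calibrate_null(50_000, np.full(4, 0.25), cfg, 2, seed=2)
        long = calibrate_null(500_000, np.full(4, 0.25), cfg, 2, seed=2)
        assert long.me < short.me

    def test_input_validation(self):
        with pytest.raises(ValueError):
            calibrate_null(100, np.full(4, 0.25), WindowConfig(500), 1, seed=0)
        with pytest.raises(ValueError):
            calibrate_null(5_000, np.full(4, 0.25), WindowConfig(500), 0, seed=0)

    def test_save_load_roundtrip(self, tmp_path):
        null = calibrate_null(2_000, np.full(4, 0.25), WindowConfig(500, 100), 2, seed=4)
        null.save(tmp_path / "null.txt")
        back = NullModel.load(tmp_path / "null.txt")
        assert back.me == null.me
        np.testing.assert_array_equal(back.null_cm, null.null_cm)
        assert (back.window_length, back.step, back.replicates, back.seed) == (
            null.window_length, null.step, null.replicates, null.seed,
        )


class TestWindowComplexity:
    def test_single_factor_window_has_cm_zero(self, toy_null):
        fact = _fact([(0, 10)], (0, 10))
        prof = window_complexity({"c": fact}, {"c": 10}, WindowConfig(10, 10), toy_null)
        assert prof.loc[0, "mo"] == 1
        assert prof.loc[0, "Cm"] == 0.0

    def test_formula_mo5_me3_gives_2(self, toy_null):
        fact = _fact([(0, 2), (2, 2), (4, 2), (6, 2), (8, 2)], (0, 10))
        prof = window_complexity({"c": fact}, {"c": 10}, WindowConfig(10, 10), toy_null)
        assert prof.loc[0, "mo"] == 5
        assert prof.loc[0, "Cm"] == pytest.approx(2.0)

    def test_window_length_mismatch_rejected(self, toy_null):
        with pytest.raises(ValueError, match="window length"):
            window_complexity({}, {}, WindowConfig(20, 2), toy_null)

    def test_n_rich_windows_missing(self):
        rng = np.random.default_rng(0)
        seq = random_residues(600, None, rng) + "N" * 400 + random_residues(500, None, rng)
        idx = build_index([SequenceRecord("c", seq)])
        cfg = WindowConfig(500, 100)
        null = calibrate_null(1_500, np.full(4, 0.25), cfg, 2, seed=0)
        prof = profile_genome(idx, cfg, null)
        in_gap = prof[(prof.start >= 500) & (prof.end <= 1_100)]
        assert len(in_gap) and in_gap["Cm"].isna().all()
        flagged = classify_unique(prof, null)
        assert not flagged.loc[in_gap.index, "unique"].any()

    def test_floor_no_negative_cm(self):
        rng = np.random.default_rng(5)
        idx = build_index([SequenceRecord("c", random_residues(3_000, None, rng))])
        cfg = WindowConfig(500, 100)
        null = calibrate_null(3_000, np.full(4, 0.25), cfg, 2, seed=5)
        prof = profile_genome(idx, cfg, null)
        assert (prof["Cm"].dropna() >= 0).all()


class TestClassifyUnique:
    def test_threshold_is_empirical_quantile(self, toy_null):
        # sort-and-interpolate by hand: 0.2-quantile of the 5-point null
        # sample {0.8,0.9,1.0,1.05,1.1} is 0.88; Cm=1.02 clears it
        assert toy_null.threshold(0.2) == pytest.approx(0.88)
        prof = pd.DataFrame(
            {"chromosome": "c", "start": [0], "end": [10], "mo": [3], "Cm": [1.02]}
        )
        assert classify_unique(prof, toy_null, alpha=0.2)["unique"].all()

    def test_cm_zero_never_unique(self, toy_null):
        prof = pd.DataFrame(
            {"chromosome": "c", "start": [0], "end": [10], "mo": [1], "Cm": [0.0]}
        )
        assert not classify_unique(prof, toy_null, alpha=0.05)["unique"].any()

    def test_alpha_monotonicity(self):
        # the rejection region (repeat-like) grows with alpha, so a
        # smaller alpha admits at least as many unique windows
        rng = np.random.default_rng(8)
        idx = build_index([SequenceRecord("c", random_residues(5_000, None, rng))])
        cfg = WindowConfig(500, 100)
        null = calibrate_null(5_000, np.full(4, 0.25), cfg, 3, seed=8)
        prof = profile_genome(idx, cfg, null)
        lenient = classify_unique(prof, null, alpha=0.05)["unique"].sum()
        stringent = classify_unique(prof, null, alpha=0.5)["unique"].sum()
        assert lenient >= stringent

    def test_type_one_control_on_random_sequence(self):
        # on pure random sequence the fraction of windows rejected
        # (not unique) at level alpha tracks alpha
        rng = np.random.default_rng(12)
        idx = build_index([SequenceRecord("c", random_residues(60_000, None, rng))])
        cfg = WindowConfig(1_000, 1_000)  # non-overlapping: independent-ish
        null = calibrate_null(60_000, np.full(4, 0.25), cfg, 5, seed=12)
        prof = profile_genome(idx, cfg, null)
        for alpha in (0.05, 0.2):
            rejected = 1.0 - classify_unique(prof, null, alpha)["unique"].mean()
            se = np.sqrt(alpha * (1 - alpha) / len(prof))
            assert abs(rejected - alpha) < 4 * se + 0.02

    def test_alpha_range_enforced(self, toy_null):
        with pytest.raises(ValueError):
            classify_unique(pd.DataFrame({"Cm": []}), toy_null, alpha=0.7)


def test_profile_roundtrip(tmp_path):
    prof = pd.DataFrame(
        {
            "chromosome": ["c", "c"],
            "start": [0, 5],
            "end": [10, 15],
            "mo": [4, 5],
            "Cm": [1.1, np.nan],
        }
    )
    write_profile(prof, tmp_path / "p.tsv", provenance={"window_length": 10})
    back = read_profile(tmp_path / "p.tsv")
    pd.testing.assert_frame_equal(back, prof)
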