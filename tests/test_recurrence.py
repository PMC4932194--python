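"""Cytoband recurrence, model specificity and arm-level calling."""

import numpy as np
import pandas as pd
import pytest

from ekaryo.recurrence import (CytobandCallMatrix, arm_burden, arm_level_calls,
                               frequency_profile, log2ratio_to_relative_copy,
                               recurrence_test, segments_to_cytobands,
                               specificity_scan, specificity_test)
from ekaryo.segmentation import SegmentSet
from ekaryo.synthetic import make_genome, simulate_dna_segments

from oracles import binomial_upper_tail


def _bands(n=4, length=100):
    return pd.DataFrame({
        "cytoband": [f"1q{i + 1}" for i in range(n)],
        "chromosome": "1",
        "start": [i * length for i in range(n)],
        "end": [(i + 1) * length for i in range(n)],
        "arm": "q",
    })


def _matrix(calls: np.ndarray, models=None, n_bands=None):
    n_bands = n_bands or calls.shape[0]
    bands = _bands(n_bands)
    samples = [f"s{i}" for i in range(calls.shape[1])]
    labels = pd.Series(models if models is not None else "m0", index=samples)
    return CytobandCallMatrix(
        calls=pd.DataFrame(calls, index=bands["cytoband"], columns=samples),
        bands=bands, model_labels=labels)


class TestSegmentsToCytobands:
    def _segset(self, segs):
        rows = [{"sample": s, "chromosome": "1", "start_idx": 0, "end_idx": 0,
                 "n_genes": 1, "start_bp": sb, "end_bp": eb, "mean_dev": 0.3 * c,
                 "p_mean": 1e-4, "call": c} for s, sb, eb, c in segs]
        return SegmentSet(segments=pd.DataFrame(rows), total_genes=1)

    def test_full_cover_takes_call(self):
        segset = self._segset([("s0", 1, 400, 1)])
        m = segments_to_cytobands(segset, _bands())
        assert (m.calls["s0"] == 1).all()

    def test_majority_overlap_wins(self):
        # band 1 spans [0,100); gain covers [1,70], neutral [71,100]
        segset = self._segset([("s0", 1, 70, 1), ("s0", 71, 400, 0)])
        m = segments_to_cytobands(segset, _bands())
        assert m.calls.loc["1q1", "s0"] == 1
        assert m.calls.loc["1q2", "s0"] == 0

    def test_exact_tie_resolves_zero(self):
        segset = self._segset([("s0", 1, 50, 1), ("s0", 51, 100, -1)])
        m = segments_to_cytobands(segset, _bands(1))
        assert m.calls.loc["1q1", "s0"] == 0

    def test_uncovered_band_zero(self):
        segset = self._segset([("s0", 1, 100, 1)])
        m = segments_to_cytobands(segset, _bands())
        assert m.calls.loc["1q4", "s0"] == 0

    def test_overlapping_bands_error(self):
        bands = _bands()
        bands.loc[1, "start"] = 50
        with pytest.raises(ValueError, match="overlap"):
            segments_to_cytobands(self._segset([("s0", 1, 100, 0)]), bands)


class TestRecurrenceTest:
    def test_binomial_tail_matches_oracle(self):
        # 10 bands, 20 samples; band 0 gained in 6, scattered gains elsewhere
        rng = np.random.default_rng(0)
        calls = (rng.random((10, 20)) < 0.05).astype(int)
        calls[0, :6] = 1
        out = recurrence_test(_matrix(calls), "gain").set_index("cytoband")
        row = out.loc["1q1"]
        K, N = int(row["K"]), int(row["N"])
        p_c = row["p_background"]
        assert row["p_binomial"] == pytest.approx(
            binomial_upper_tail(K, N, p_c), rel=1e-9)
        assert row["p_bonferroni"] == pytest.approx(
            min(1.0, row["p_binomial"] * 10))

    def test_background_excludes_own_band(self):
        calls = np.zeros((4, 10), int)
        calls[0, :5] = 1   # 5 gains on band 0
        calls[1, :2] = 1   # 2 gains on band 1
        out = recurrence_test(_matrix(calls), "gain").set_index("cytoband")
        assert out.loc["1q1", "p_background"] == pytest.approx(2 / (10 * 3))
        assert out.loc["1q2", "p_background"] == pytest.approx(5 / (10 * 3))

    def test_prevalence_rule_strict(self):
        calls = np.zeros((4, 20), int)
        calls[0, :2] = 1   # exactly 10%: not recurrent by prevalence
        calls[1, :3] = 1   # 15%: recurrent by prevalence
        out = recurrence_test(_matrix(calls), "gain").set_index("cytoband")
        assert not out.loc["1q1", "recurrent_by_prevalence"]
        assert out.loc["1q2", "recurrent_by_prevalence"]

    def test_zero_background_flagged(self):
        calls = np.zeros((4, 10), int)
        calls[0, :3] = 1   # the only gains anywhere
        out = recurrence_test(_matrix(calls), "gain").set_index("cytoband")
        assert out.loc["1q1", "zero_background"]
        assert out.loc["1q1", "p_binomial"] == 0.0
        assert not out.loc["1q2", "zero_background"]
        assert out.loc["1q2", "p_binomial"] == 1.0

    def test_directions_independent(self):
        calls = np.zeros((4, 10), int)
        calls[0, :5] = 1
        calls[1, :5] = -1
        gains = recurrence_test(_matrix(calls), "gain").set_index("cytoband")
        losses = recurrence_test(_matrix(calls), "loss").set_index("cytoband")
        assert gains.loc["1q1", "K"] == 5 and gains.loc["1q2", "K"] == 0
        assert losses.loc["1q2", "K"] == 5 and losses.loc["1q1", "K"] == 0

    def test_single_band_errors(self):
        with pytest.raises(ValueError):
            recurrence_test(_matrix(np.zeros((1, 5), int)), "gain")


class TestSpecificity:
    def test_exclusive_event_flagged_and_attributed(self):
        calls = np.zeros((4, 40), int)
        calls[0, :20] = 1  # all events in the first 20 samples = model mA
        models = ["mA"] * 20 + ["mB"] * 20
        res = specificity_test(_matrix(calls, models), "1q1", "gain")
        assert res["model_specific"]
        assert res["attributed_model"] == "mA"

    def test_uniform_event_not_flagged(self):
        calls = np.zeros((4, 40), int)
        calls[0, ::2] = 1  # every other sample: 10 events in each model
        models = ["mA"] * 20 + ["mB"] * 20
        res = specificity_test(_matrix(calls, models), "1q1", "gain")
        assert not res["model_specific"]
        assert res["p_value"] > 0.5

    def test_no_events_untestable(self):
        calls = np.zeros((4, 20), int)
        models = ["mA"] * 10 + ["mB"] * 10
        res = specificity_test(_matrix(calls, models), "1q1", "gain")
        assert not res["testable"]
        assert np.isnan(res["p_value"])

    def test_single_model_errors(self):
        with pytest.raises(ValueError):
            specificity_test(_matrix(np.zeros((4, 10), int)), "1q1", "gain")

    def test_scan_family_size(self):
        calls = np.zeros((4, 40), int)
        calls[0, :20] = 1
        calls[2, 5] = -1
        models = ["mA"] * 20 + ["mB"] * 20
        out = specificity_scan(_matrix(calls, models))
        assert len(out) == 2  # (1q1, gain) and (1q3, loss)
        row = out.set_index(["cytoband", "direction"]).loc[("1q1", "gain")]
        assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_value"] * 2))


class TestFrequencyProfile:
    def test_frequencies(self):
        calls = np.zeros((4, 10), int)
        calls[0, :4] = 1
        calls[0, 4:6] = -1
        out = frequency_profile(_matrix(calls)).set_index("cytoband")
        assert out.loc["1q1", "gain_frequency"] == pytest.approx(0.4)
        assert out.loc["1q1", "loss_frequency"] == pytest.approx(0.2)

    def test_model_restriction(self):
        calls = np.zeros((2, 4), int)
        calls[0, :2] = 1
        models = ["mA", "mA", "mB", "mB"]
        out = frequency_profile(_matrix(calls, models), model="mA")
        assert out.set_index("cytoband").loc["1q1", "gain_frequency"] == 1.0


def _dna_segments(value_by_arm, chrom_len=200, sample="s0"):
    """One-sample segment frame with p = [1, 100], q = [101, 200]."""
    rows = []
    for (start, end), v in value_by_arm:
        rows.append({"sample": sample, "chromosome": "1",
                     "start": start, "end": end, "value": v})
    return pd.DataFrame(rows)


def _arms(chrom_len=200):
    return pd.DataFrame({"chromosome": ["1", "1"], "arm": ["p", "q"],
                         "start": [0, chrom_len // 2],
                         "end": [chrom_len // 2, chrom_len]})


class TestRelativeCopyConversion:
    def test_median_centred_and_transformed(self):
        seg = _dna_segments([((1, 100), 0.5), ((101, 200), 0.0)])
        seg2 = seg.copy()
        seg2.loc[1, "end"] = 300  # make the 0.0 segment dominate the median
        out = log2ratio_to_relative_copy(seg2)
        # median = 0.0; r=0.5 -> 2*2^0.5-2
        assert out["value"].iloc[0] == pytest.approx(2 * 2 ** 0.5 - 2)
        assert out["value"].iloc[1] == pytest.approx(0.0)

    def test_cap_applied(self):
        seg = _dna_segments([((1, 100), 4.0), ((101, 400), 0.0)])
        out = log2ratio_to_relative_copy(seg)
        assert out["value"].iloc[0] == 1.5

    def test_whole_sample_shift_removed(self):
        seg = _dna_segments([((1, 100), 0.7), ((101, 400), 0.7)])
        out = log2ratio_to_relative_copy(seg)
        assert np.allclose(out["value"].values, 0.0)

    def test_nonfinite_errors(self):
        seg = _dna_segments([((1, 100), np.nan)])
        with pytest.raises(ValueError):
            log2ratio_to_relative_copy(seg)


class TestArmLevelCalls:
    def test_threshold_cases(self):
        """0.25 -> +1; -0.05 -> 0; exactly +0.10 -> 0 (strict inequality)."""
        for value, expected in ((0.25, 1), (-0.05, 0), (0.10, 0), (-0.10, 0),
                                (0.1001, 1), (-0.25, -1)):
            seg = _dna_segments([((1, 100), value), ((101, 200), 0.0)])
            out = arm_level_calls(seg, _arms()).set_index("arm")
            assert out.loc["p", "call"] == expected, value
            assert out.loc["p", "arm_median"] == pytest.approx(value)

    def test_weighted_median_dominant_segment(self):
        # p arm: 80 units at 0.3, 20 units at -1.0 -> median 0.3
        seg = _dna_segments([((1, 80), 0.3), ((81, 100), -1.0),
                             ((101, 200), 0.0)])
        out = arm_level_calls(seg, _arms()).set_index("arm")
        assert out.loc["p", "arm_median"] == pytest.approx(0.3)
        assert out.loc["p", "call"] == 1

    def test_low_coverage_missing(self):
        seg = _dna_segments([((1, 30), 0.5), ((101, 200), 0.0)])
        out = arm_level_calls(seg, _arms()).set_index("arm")
        assert np.isnan(out.loc["p", "call"])
        assert out.loc["q", "call"] == 0

    def test_resegmentation_invariant(self):
        """Splitting segments without changing values leaves calls unchanged."""
        seg = _dna_segments([((1, 100), 0.25), ((101, 200), -0.3)])
        pieces = []
        for _, r in seg.iterrows():
            mid = (r["start"] + r["end"]) // 2
            pieces.append({**r, "end": mid})
            pieces.append({**r, "start": mid + 1})
        split = pd.DataFrame(pieces)
        a = arm_level_calls(seg, _arms()).set_index("arm")["call"]
        b = arm_level_calls(split, _arms()).set_index("arm")["call"]
        pd.testing.assert_series_equal(a, b)

    def test_generator_truth_recovered(self):
        genome = make_genome(3, 60, 4, seed=0)
        events = [("1p", "gain", 1.0, 0.6), ("2q", "loss", 1.0, 0.6)]
        dna = simulate_dna_segments(genome, 5, events, seed=1)
        out = arm_level_calls(dna.segments, genome.arms)
        out["key"] = out["chromosome"].astype(str) + out["arm"]
        by = out.set_index(["sample", "key"])["call"]
        for s in dna.segments["sample"].unique():
            assert by.loc[(s, "1p")] == 1
            assert by.loc[(s, "2q")] == -1
            assert by.loc[(s, "3p")] == 0

    def test_arm_burden(self):
        genome = make_genome(2, 40, 4, seed=0)
        dna = simulate_dna_segments(genome, 4, [("1p", "gain", 1.0, 0.5)],
                                    seed=2)
        calls = arm_level_calls(dna.segments, genome.arms)
        burden = arm_burden(calls)
        assert (burden == 1).all()
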