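"""Donor-paired DE: ratios, tests, BH correction, calibration, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smallrna import de_paired, syndata
from smallrna.annotate import to_cpm
from smallrna.core import CountMatrix
from smallrna.de_paired import (
    bh_adjust, call_de, de_sets, overlap, paired_log2fc, paired_test,
    run_paired_de,
)


def _cpm_matrix(values: dict, donors, treatments):
    samples = list(values)
    meta = pd.DataFrame(
        {"donor": donors, "treatment": treatments, "timepoint": [6] * len(samples)},
        index=samples,
    )
    return CountMatrix(pd.DataFrame(values), meta, "CPM")


class TestPairedLog2fc:
    def test_identical_conditions_give_zero(self):
        m = _cpm_matrix(
            {"a_l": [10.0, 20.0], "a_m": [10.0, 20.0]}, ["a", "a"], ["LPS", "medium"]
        )
        assert (paired_log2fc(m) == 0).all().all()

    def test_label_swap_negates_every_ratio(self, rng):
        vals = {f"s{i}": rng.random(30) * 100 for i in range(6)}
        donors = ["d1", "d1", "d2", "d2", "d3", "d3"]
        trts = ["LPS", "medium"] * 3
        m = _cpm_matrix(vals, donors, trts)
        swapped_meta = m.meta.copy()
        swapped_meta["treatment"] = swapped_meta["treatment"].map(
            {"LPS": "medium", "medium": "LPS"}
        )
        m_sw = CountMatrix(m.values, swapped_meta, "CPM")
        np.testing.assert_allclose(
            paired_log2fc(m, center=False).to_numpy(),
            -paired_log2fc(m_sw, center=False).to_numpy(),
        )

    def test_unpaired_donor_error_lists_donor(self):
        m = _cpm_matrix(
            {"a_l": [1.0], "a_m": [1.0], "b_l": [1.0]},
            ["a", "a", "b"], ["LPS", "medium", "LPS"],
        )
        with pytest.raises(ValueError, match="b"):
            paired_log2fc(m)

    def test_spiked_recovery_at_negligible_dispersion(self):
        spikes = [
            syndata.SpikeSpec("s1", 2000.0, 1.5),
            syndata.SpikeSpec("s2", 3000.0, -1.0),
            syndata.SpikeSpec("s3", 1500.0, 0.0),
        ]
        m = syndata.simulate_paired_counts(
            spikes, n_null=200, n_donors=7, dispersion=1e-4, seed=5,
            null_sd_log=1.0,
        )
        ratios = paired_log2fc(to_cpm(m))
        means = ratios.mean(axis=1)
        for s in spikes:
            assert means[s.feature_id] == pytest.approx(s.log2fc, abs=0.1)


class TestPairedTest:
    def test_all_zero_ratios_give_p_one(self):
        ratios = pd.DataFrame(np.zeros((4, 5)))
        res = paired_test(ratios, moderate=False)
        assert (res.pvalues == 1.0).all()

    def test_degenerate_equal_ratios_give_p_one_unmoderated(self):
        ratios = pd.DataFrame(np.full((3, 5), 0.7))
        res = paired_test(ratios, moderate=False)
        assert (res.pvalues == 1.0).all()

    def test_negation_symmetry(self, rng):
        ratios = pd.DataFrame(rng.normal(0.5, 1.0, size=(20, 7)))
        p_pos = paired_test(ratios, moderate=False).pvalues
        p_neg = paired_test(-ratios, moderate=False).pvalues
        np.testing.assert_allclose(p_pos.to_numpy(), p_neg.to_numpy())

    def test_too_few_donors(self):
        with pytest.raises(ValueError, match="donors"):
            paired_test(pd.DataFrame(np.ones((2, 2))))

    def test_agrees_with_exact_sign_flip_oracle(self, rng):
        # enumerate all 2^7 sign flips of the t statistic per instance
        diffs = []
        flips = np.array(list(itertools.product([1, -1], repeat=7)))
        for _ in range(50):
            x = rng.normal(0.0, 1.0, 7)
            p_t = float(paired_test(pd.DataFrame([x]), moderate=False).pvalues.iloc[0])
            t_obs = abs(stats.ttest_1samp(x, 0).statistic)
            flipped = flips * x
            t_flip = np.abs(
                flipped.mean(1) / (flipped.std(1, ddof=1) / np.sqrt(7))
            )
            p_perm = float((t_flip >= t_obs - 1e-12).mean())
            diffs.append(abs(p_t - p_perm))
        diffs = np.array(diffs)
        assert diffs.mean() < 0.05
        assert diffs.max() < 0.15


class TestBHAdjust:
    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), [1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_against_hand_rolled_step_up_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            m = len(p)
            order = np.argsort(p)
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected)


class TestCallDE:
    def test_empty_results(self):
        res = call_de(pd.DataFrame(columns=["log2fc", "q"]))
        sets = de_sets(res)
        assert sets == {"up": set(), "down": set(), "ns": set()}

    def test_partition_and_overlap(self):
        res = call_de(
            pd.DataFrame(
                {"log2fc": [2.0, -2.0, 0.5], "q": [0.01, 0.01, 0.5]},
                index=["a", "b", "c"],
            )
        )
        sets = de_sets(res)
        assert sets["up"] == {"a"} and sets["down"] == {"b"} and sets["ns"] == {"c"}
        assert overlap({"a", "b"}, {"b", "c"}) == (1, 3)


class TestCalibrationAndErrorControl:
    def test_null_pvalues_uniform(self):
        """With no true effects the raw p distribution is uniform."""
        spikes = [syndata.SpikeSpec(f"f{i}", 500.0, 0.0) for i in range(2000)]
        m = syndata.simulate_paired_counts(spikes, n_null=0, seed=7)
        ratios = paired_log2fc(to_cpm(m))
        for moderate in (False, True):
            p = paired_test(ratios, moderate=moderate).pvalues
            assert stats.kstest(p, "uniform").pvalue > 0.01
            frac = (p < 0.05).mean()
            sigma = np.sqrt(0.05 * 0.95 / len(p))
            assert abs(frac - 0.05) < 3 * sigma

    def test_bh_controls_empirical_fdr(self):
        """Across repeated spiked simulations, realised FDR <= alpha + 3 sigma."""
        alpha = 0.05
        false_calls, total_calls = 0, 0
        for rep in range(10):
            spikes = [syndata.SpikeSpec(f"spike{i}", 800.0, 2.0) for i in range(20)]
            m = syndata.simulate_paired_counts(
                spikes, n_null=300, n_donors=7, dispersion=0.05, seed=50 + rep
            )
            res = run_paired_de(m, alpha=alpha)
            called = res.index[res["direction"] != "ns"]
            false_calls += sum(1 for f in called if f.startswith("null"))
            total_calls += len(called)
        fdr = false_calls / max(total_calls, 1)
        sigma = np.sqrt(alpha * (1 - alpha) / max(total_calls, 1))
        assert fdr <= alpha + 3 * sigma

    def test_strong_spikes_recovered_with_direction(self):
        spikes = [
            syndata.SpikeSpec("up1", 500.0, 2.0),
            syndata.SpikeSpec("down1", 500.0, -2.0),
        ]
        m = syndata.simulate_paired_counts(spikes, n_null=100, n_donors=7, seed=4)
        res = run_paired_de(m)
        assert res.loc["up1", "direction"] == "up"
        assert res.loc["down1", "direction"] == "down"
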