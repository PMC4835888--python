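"""Integer calling: gap partition, anchoring, recovery against truth, QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from c4cnv import (
    CallingConfig, SimConfig, call_integer_cn, cn_distribution_summary,
    dosage_bias_qc, flag_homozygous_deletions, simulate_cohort, simulate_peaks,
    normalize_dosages, impute_total_c4,
)
from c4cnv.calling import FLAG_HOMDEL, FLAG_LOWCONF


def dosage_frame(values, locus_col="d_c4a", study="S1"):
    n = len(values)
    df = pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)], "study": study,
        "d_c4a": np.nan, "d_c4b": np.nan, "d_total": np.nan,
        "total_source": "measured",
    })
    df[locus_col] = values
    return df


SMALL = CallingConfig(min_batch=3)


class TestGapPartition:
    def test_hand_partition_example(self):
        d = dosage_frame([0.49, 0.51, 1.00, 1.01, 0.99, 1.52])
        calls = call_integer_cn(d, "C4A", SMALL).sort_values("sample_id")
        assert list(calls["cn"]) == [1, 1, 2, 2, 2, 3]

    def test_zero_dosage_flags_homozygous_deletion(self):
        d = dosage_frame([0.0, 1.0, 1.01, 0.99, 0.51])
        calls = call_integer_cn(d, "C4A", SMALL).set_index("sample_id")
        assert calls.loc["s000", "cn"] == 0
        assert FLAG_HOMDEL in calls.loc["s000", "flags"]

    def test_most_populous_subgroup_anchored_to_modal(self):
        # most samples cluster at 1.5: with modal anchor 2 they must be
        # called 2 even though an absolute scale would say 3
        vals = [1.5, 1.49, 1.51, 1.5, 1.52, 1.48, 2.0, 1.0]
        calls = call_integer_cn(dosage_frame(vals), "C4A", SMALL)
        at_mode = calls[np.isclose(calls["dosage"], 1.5, atol=0.03)]
        assert (at_mode["cn"] == 2).all()

    def test_monotone_in_dosage_within_batch(self):
        rng = np.random.default_rng(42)
        vals = np.abs(rng.normal(1.0, 0.35, size=200))
        calls = call_integer_cn(dosage_frame(vals), "C4A", CallingConfig())
        srt = calls.sort_values("dosage")
        assert (np.diff(srt["cn"].to_numpy()) >= 0).all()

    def test_small_batch_refused(self):
        with pytest.raises(ValueError, match="calling requires"):
            call_integer_cn(dosage_frame([1.0] * 10), "C4A", CallingConfig())

    def test_structureless_dosages_error(self):
        vals = np.linspace(0.2, 2.2, 100)  # uniform smear, no gaps
        with pytest.raises(ValueError, match="no discernible subgroup"):
            call_integer_cn(dosage_frame(vals), "C4A", CallingConfig())

    def test_midpoint_tie_goes_to_lower_integer_flagged(self):
        vals = [1.0, 1.0, 0.99, 1.01, 1.25]  # 1.25 is exactly between 2 and 3 copies
        calls = call_integer_cn(dosage_frame(vals), "C4A", SMALL).set_index("sample_id")
        assert calls.loc["s004", "cn"] == 2
        assert FLAG_LOWCONF in calls.loc["s004", "flags"]

    def test_range_clamped_and_flagged(self):
        vals = [1.0] * 30 + [3.4]  # 6.8 copies of C4A is outside 0..5
        calls = call_integer_cn(dosage_frame(vals), "C4A", SMALL).set_index("sample_id")
        assert calls.loc["s030", "cn"] == 5
        assert FLAG_LOWCONF in calls.loc["s030", "flags"]


class TestRecovery:
    def test_concordance_against_truth_at_default_noise(self, sim_calls, sim_truth):
        for locus, col in (("C4A", "true_c4a"), ("C4B", "true_c4b")):
            m = sim_calls[sim_calls["locus"] == locus].merge(sim_truth, on="sample_id")
            assert (m["cn"] == m[col]).mean() >= 0.99, locus

    def test_total_c4_high_confidence_calls_concordant(self, sim_calls, sim_truth):
        m = sim_calls[sim_calls["locus"] == "totalC4"].merge(sim_truth, on="sample_id")
        hc = m[~m["flags"].str.contains(FLAG_LOWCONF)]
        assert len(hc) > 0.5 * len(m)
        assert (hc["cn"] == hc["true_total"]).mean() >= 0.99

    def test_consistency_total_equals_sum_for_confident_calls(
        self, sim_calls, sim_dosages
    ):
        cn = sim_calls.pivot(index="sample_id", columns="locus", values="cn")
        fl = sim_calls.pivot(index="sample_id", columns="locus", values="flags")
        measured = (
            sim_dosages.set_index("sample_id")["total_source"] == "measured"
        ).reindex(cn.index)
        confident = ~fl.apply(lambda c: c.str.contains(FLAG_LOWCONF)).any(axis=1)
        sub = cn[measured & confident]
        assert len(sub) >= 100
        assert (sub["totalC4"] == sub["C4A"] + sub["C4B"]).mean() >= 0.99

    def test_graceful_degradation_with_noise(self):
        """More noise produces more flags, not more wrong confident calls."""
        flagged, wrong_hc, wrong_raw = {}, {}, {}
        for cv in (0.04, 0.10):
            cfg = SimConfig(n_cases=300, n_controls=300, seed=21, peak_noise_cv=cv,
                            studies={"S1": (1.0, 1.0)}, batch_scale={"S1": 1.0})
            truth, _ = simulate_cohort(cfg)
            d = impute_total_c4(normalize_dosages(simulate_peaks(truth, cfg)))
            calls = call_integer_cn(d, "C4A").merge(truth, on="sample_id")
            flagged[cv] = calls["flags"].str.contains(FLAG_LOWCONF).mean()
            hc = calls[~calls["flags"].str.contains(FLAG_LOWCONF)]
            wrong_hc[cv] = (hc["cn"] != hc["true_c4a"]).mean()
            wrong_raw[cv] = (calls["cn"] != calls["true_c4a"]).mean()
        assert flagged[0.10] > flagged[0.04]
        assert wrong_hc[0.04] <= 0.005
        # confident calls stay far more reliable than unfiltered ones
        assert wrong_hc[0.10] <= wrong_raw[0.10] / 3.0

    def test_mixture_engine_agrees_with_gap_engine(self, sim_dosages, sim_truth):
        calls = call_integer_cn(sim_dosages, "C4A", CallingConfig(method="mixture"))
        m = calls.merge(sim_truth, on="sample_id")
        assert (m["cn"] == m["true_c4a"]).mean() >= 0.99


class TestDeletionWorklist:
    def test_no_zero_calls_empty_list(self):
        calls = call_integer_cn(dosage_frame([1.0, 0.99, 1.01, 0.5]), "C4A", SMALL)
        assert len(flag_homozygous_deletions(calls)) == 0

    def test_zero_dosage_samples_listed(self):
        calls = call_integer_cn(dosage_frame([0.0, 0.0, 1.0, 1.01, 0.99]), "C4A", SMALL)
        wl = flag_homozygous_deletions(calls)
        assert set(wl["sample_id"]) == {"s000", "s001"}
        assert set(wl.columns) >= {"sample_id", "study", "locus", "dosage"}

    def test_planted_deletion_rate_recovered(self):
        # 10% haploid zero-copy alleles -> 1% homozygous deletions
        cfg = SimConfig(n_cases=500, n_controls=500, seed=13,
                        haplotypes=None, haploid_freqs_c4a=(0.1, 0.8, 0.1),
                        studies={"S1": (1.0, 1.0)}, batch_scale={"S1": 1.0})
        truth, _ = simulate_cohort(cfg)
        d = impute_total_c4(normalize_dosages(simulate_peaks(truth, cfg)))
        wl = flag_homozygous_deletions(call_integer_cn(d, "C4A"))
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.01)
        assert lo <= len(wl) <= hi


class TestBiasQc:
    def make_inputs(self, shift=0.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        n2 = 2 * n
        dosage = np.clip(rng.normal(1.0, 0.04, n2), 0.01, None)
        dosage[:n] += shift  # cases
        df = dosage_frame(dosage)
        calls = call_integer_cn(df, "C4A")
        cohort = pd.DataFrame({
            "sample_id": df["sample_id"],
            "status": ["case"] * n + ["control"] * n,
            "subtype": ["NV"] * n + ["none"] * n,
            "age": 75.0, "sex": "female", "study": "S1",
        })
        return df, calls, cohort

    def test_identical_groups_zero_difference(self):
        df, calls, cohort = self.make_inputs()
        # mirror the case dosages onto the controls exactly
        half = len(df) // 2
        df.loc[half:, "d_c4a"] = df.loc[: half - 1, "d_c4a"].to_numpy()
        calls = call_integer_cn(df, "C4A")
        qc = dosage_bias_qc(df, calls, cohort)
        row = qc[(qc["locus"] == "C4A") & (qc["study"] == "pooled")].iloc[0]
        assert row["difference"] == pytest.approx(0.0, abs=1e-12)

    def test_null_calibration(self):
        """Cases and controls from one distribution: ~5% of QC runs at p<0.05."""
        n = 150
        cohort = pd.DataFrame({
            "sample_id": [f"s{i:03d}" for i in range(2 * n)],
            "status": ["case"] * n + ["control"] * n,
            "subtype": ["NV"] * n + ["none"] * n,
            "age": 75.0, "sex": "female", "study": "S1",
        })
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            calls = pd.DataFrame({
                "sample_id": cohort["sample_id"], "study": "S1", "locus": "C4A",
                "cn": 2, "dosage": rng.normal(1.0, 0.04, 2 * n),
                "confidence": 1.0, "flags": "",
            })
            qc = dosage_bias_qc(pd.DataFrame(), calls, cohort)
            row = qc[(qc["locus"] == "C4A") & (qc["study"] == "pooled")].iloc[0]
            pvals.append(row["p"])
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= frac <= 0.09

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(40):
            df, calls, cohort = self.make_inputs(shift=0.05, n=400, seed=seed)
            qc = dosage_bias_qc(df, calls, cohort)
            row = qc[(qc["locus"] == "C4A") & (qc["study"] == "pooled")].iloc[0]
            hits += row["p"] < 0.01
        assert hits / 40 >= 0.95

    def test_tiny_group_not_testable(self):
        df, calls, cohort = self.make_inputs(n=50)
        cohort.loc[cohort["status"] == "case", "status"] = "control"
        cohort.loc[cohort.index[0], "status"] = "case"
        qc = dosage_bias_qc(df, calls, cohort)
        row = qc[(qc["locus"] == "C4A") & (qc["study"] == "pooled")].iloc[0]
        assert not row["testable"]


class TestDistributionSummary:
    def test_single_class(self):
        df = dosage_frame([1.0, 1.01, 0.99, 1.0])
        calls = call_integer_cn(df, "C4A", SMALL)
        cohort = pd.DataFrame({"sample_id": df["sample_id"], "status": "control",
                               "subtype": "none", "age": 70.0, "sex": "male",
                               "study": "S1"})
        out = cn_distribution_summary(calls, cohort)
        pooled = out[out["study"] == "pooled"]
        assert len(pooled) == 1
        assert pooled["proportion"].iloc[0] == 1.0

    def test_proportions_sum_to_one(self, sim_calls, sim_cohort):
        out = cn_distribution_summary(sim_calls, sim_cohort)
        sums = out.groupby(["locus", "status", "study"])["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_matches_generator_frequencies(self, sim_calls, sim_cohort, sim_truth,
                                           sim_config):
        out = cn_distribution_summary(sim_calls, sim_cohort)
        c4a = out[(out["locus"] == "C4A") & (out["status"] == "control")
                  & (out["study"] == "pooled")]
        called = c4a.set_index("cn")["proportion"]
        truth_ctrl = sim_truth[sim_truth["status"] == "control"]
        expected = truth_ctrl["true_c4a"].value_counts(normalize=True)
        for cn in expected.index:
            assert called.get(cn, 0.0) == pytest.approx(expected[cn], abs=0.03)
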