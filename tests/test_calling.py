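"""Distance-decay background, z-scores, p-values and q-values."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest

import capture3c as c3
from conftest import run_pipeline


def cis_table(distances, signals, vp=None, chrom="chr1"):
    """Region table centered on a viewpoint at position 1e6."""
    center = 1_000_000
    starts = (center + np.asarray(distances) - 500).astype(int)
    n = len(starts)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + 1000,
        "region_id": np.arange(n),
        "raw_count": 1,
        "norm_rpm": signals,
    })
    return df.sort_values("start").reset_index(drop=True)


VP = c3.Viewpoint("chr1", 999_600, 1_000_400)


class TestCisBackground:
    def test_noiseless_decay_reproduced(self):
        rng = np.random.default_rng(0)
        d = np.sort(rng.uniform(2000, 1_500_000, 400)) * rng.choice(
            [-1, 1], 400
        )
        signals = 1000.0 / (1 + np.abs(d) / 10_000)
        df = cis_table(d, signals)
        bg = c3.fit_cis_background(df, VP)
        # region_id i was assigned to signals[i] before coordinate sorting
        exp = bg.expected.loc[np.arange(len(signals))].to_numpy()
        rel = np.abs(exp - signals) / signals
        assert np.median(rel) < 0.02
        assert bg.residual_sd < 0.05 * signals.max()

    def test_constant_signal_is_degenerate(self):
        rng = np.random.default_rng(1)
        d = np.sort(rng.uniform(2000, 1_000_000, 100))
        df = cis_table(d, np.full(100, 5.0))
        with pytest.raises(ValueError, match="degenerate"):
            c3.fit_cis_background(df, VP)

    def test_spar_range_enforced(self):
        rng = np.random.default_rng(2)
        d = np.sort(rng.uniform(2000, 1_000_000, 100))
        df = cis_table(d, 100 / (1 + d / 1e4) + rng.normal(0, 1, 100))
        with pytest.raises(ValueError, match="spar"):
            c3.fit_cis_background(df, VP, spar=0.5)
        c3.fit_cis_background(df, VP, spar=0.5, allow_spar_outside=True)

    def test_too_few_regions_rejected(self):
        df = cis_table([5000, 10000, 20000, 40000], [4.0, 3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="cis regions"):
            c3.fit_cis_background(df, VP)

    def test_smoother_spar_has_larger_residual_variance(self):
        rng = np.random.default_rng(3)
        d = np.sort(rng.uniform(2000, 1_500_000, 500))
        y = 500 / (1 + d / 1e4) + rng.normal(0, 5, 500)
        df = cis_table(d, y)
        sd = {
            spar: c3.fit_cis_background(df, VP, spar=spar).residual_sd
            for spar in (0.06, 0.4)
        }
        assert sd[0.06] <= sd[0.4]

    def test_viewpoint_neighbourhood_excluded(self):
        rng = np.random.default_rng(4)
        d = np.sort(rng.uniform(2000, 1_000_000, 100))
        df = cis_table(np.concatenate([[0.0], d]),
                       np.concatenate([[1e9], 100 / (1 + d / 1e4)]))
        bg = c3.fit_cis_background(df, VP)
        vp_region = df.loc[df["norm_rpm"].idxmax(), "region_id"]
        assert vp_region in bg.excluded_region_ids
        assert vp_region not in bg.fit_region_ids


class TestZScores:
    def test_direct_formula(self):
        rng = np.random.default_rng(5)
        d = np.sort(rng.uniform(2000, 1_000_000, 60))
        df = cis_table(d, rng.uniform(1, 2, 60) + 200 / (1 + d / 1e4))
        bg = c3.fit_cis_background(df, VP)
        z = c3.zscores_cis(df, bg)
        rid = df["region_id"].iloc[30]
        obs = df["norm_rpm"].iloc[30]
        expect = (obs - bg.expected.loc[rid]) / bg.residual_sd
        assert z.loc[rid] == pytest.approx(expect)

    def test_residuals_center_near_zero(self, default_sim):
        cfg, fm, vp = default_sim
        reads, _ = c3.simulate_3cseq(dataclasses.replace(cfg, seed=31), fm)
        counts = c3.count_per_fragment(reads, fm)
        sig = c3.simple_rpm(counts)
        sig = c3.powerlaw_normalize(sig, c3.fit_powerlaw(sig, viewpoint=vp))
        bg = c3.fit_cis_background(sig, vp)
        z = c3.zscores_cis(sig, bg)
        assert abs(z.loc[bg.fit_region_ids].mean()) < 0.1

    def test_trans_global_statistics(self):
        # signals [1,1,1,1,6]: mean 2, sd sqrt(5); z(6) = 4/sqrt(5)
        df = pd.DataFrame({
            "chrom": ["chr2"] * 5,
            "start": np.arange(5) * 1000,
            "end": (np.arange(5) + 1) * 1000,
            "region_id": np.arange(5),
            "norm_rpm": [1.0, 1.0, 1.0, 1.0, 6.0],
        })
        z = c3.zscores_trans(df, VP, min_regions=2)
        assert z.iloc[-1] == pytest.approx(4 / math.sqrt(5))
        assert z.iloc[0] == pytest.approx(-1 / math.sqrt(5))

    def test_trans_constant_signal_rejected(self):
        df = pd.DataFrame({
            "chrom": ["chr2"] * 5, "start": np.arange(5) * 1000,
            "end": (np.arange(5) + 1) * 1000, "region_id": np.arange(5),
            "norm_rpm": [3.0] * 5,
        })
        with pytest.raises(ValueError, match="degenerate"):
            c3.zscores_trans(df, VP, min_regions=2)

    def test_exclusion_zone_does_not_change_trans_z(self):
        trans = pd.DataFrame({
            "chrom": ["chr2"] * 6, "start": np.arange(6) * 1000,
            "end": (np.arange(6) + 1) * 1000, "region_id": np.arange(6),
            "norm_rpm": [1.0, 2.0, 1.0, 3.0, 1.0, 9.0],
        })
        near_vp = pd.DataFrame({
            "chrom": ["chr1"], "start": [1_000_500], "end": [1_001_500],
            "region_id": [99], "norm_rpm": [1e6],
        })
        z_without = c3.zscores_trans(trans, VP, min_regions=2)
        z_with = c3.zscores_trans(
            pd.concat([trans, near_vp], ignore_index=True), VP, min_regions=2
        )
        assert np.allclose(z_without.to_numpy(), z_with.to_numpy())


class TestPValues:
    @pytest.mark.parametrize("z,expect", [
        (0.0, 0.5),
        (3.0, 0.0013498980316301),
        (-2.0, 0.9772498680518208),
    ])
    def test_upper_tail_normal(self, z, expect):
        assert c3.pvalues_from_z([z])[0] == pytest.approx(expect, rel=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            c3.pvalues_from_z([np.nan])


class TestQValues:
    def test_bh_by_hand(self):
        q, sig = c3.qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert sig.tolist() == [True, True, True, True]

    def test_all_ones(self):
        q, sig = c3.qvalues(np.ones(20))
        assert np.allclose(q, 1.0)
        assert not sig.any()

    def test_monotone_in_sorted_p_order(self):
        rng = np.random.default_rng(7)
        p = rng.random(500)
        q, _ = c3.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            c3.qvalues([0.5, 1.5])

    def test_pi0_near_one_on_uniform_null(self):
        rng = np.random.default_rng(9)
        pi0 = c3.estimate_pi0_bootstrap(rng.random(2000))
        assert 0.8 <= pi0 <= 1.0

    def test_degenerate_p_distribution_falls_back_conservatively(self):
        p = np.full(100, 0.6) + np.linspace(0, 0.01, 100)
        with pytest.warns(UserWarning, match="pi0"):
            pi0 = c3.estimate_pi0_bootstrap(p)
        assert pi0 == 1.0


class TestCallInteractions:
    def test_scale_invariance(self, default_sim):
        cfg, fm, vp = default_sim
        reads, _ = c3.simulate_3cseq(
            dataclasses.replace(cfg, seed=41, n_reads=50_000), fm
        )
        counts = c3.count_per_fragment(reads, fm)
        sig = c3.simple_rpm(counts)
        sig = c3.powerlaw_normalize(sig, c3.fit_powerlaw(sig, viewpoint=vp))
        scaled = sig.copy()
        scaled["norm_rpm"] = scaled["norm_rpm"] * 7.3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = c3.call_interactions(sig, vp)
            b = c3.call_interactions(scaled, vp)
        for col in ("z", "p", "q"):
            assert np.allclose(a[col].to_numpy(), b[col].to_numpy())

    def test_cis_only_input_produces_cis_only_output(self):
        rng = np.random.default_rng(11)
        d = np.sort(rng.uniform(2000, 1_500_000, 300)) * rng.choice([-1, 1], 300)
        y = 300 / (1 + np.abs(d) / 1e4) + rng.normal(0, 3, 300)
        df = cis_table(d, np.maximum(y, 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = c3.call_interactions(df, VP)
        assert calls["is_cis"].all()

    def test_sorted_by_q_then_abs_z(self, spiked_calls):
        _, rep1, _ = spiked_calls
        q = rep1["q"].to_numpy()
        assert (np.diff(q) >= -1e-15).all()

    def test_spike_recovery(self, spiked_calls):
        spike_ids, rep1, _ = spiked_calls
        hit = rep1[rep1["region_id"].isin(spike_ids) & rep1["significant"]]
        assert len(hit) >= 18  # >= 90% of 20 spikes

    def test_null_fdr_fraction(self, default_sim):
        cfg, fm, vp = default_sim
        called = total = 0
        for seed in range(3):
            calls = run_pipeline(dataclasses.replace(cfg, seed=60 + seed),
                                 fm, vp)
            cis = calls[calls["is_cis"]]
            called += int(cis["significant"].sum())
            total += len(cis)
        assert called / total <= 0.10
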