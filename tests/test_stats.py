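"""Signed-rank exactness, Bonferroni, spatial classifications and the
random-vs-periodic preference classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from culture_mmr import (
    CultureParams,
    SeparationCategory,
    bonferroni_adjust,
    classify_site_preference,
    make_oddball,
    proximity_analysis,
    ring_analysis,
    separation_analysis,
    simulate_spikes,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank(d, alternative="two-sided"):
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_n5_two_sided(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 32)

    def test_all_zero_differences_undefined(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.method == "undefined"
        assert np.isnan(res.p_value)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_antisymmetry_under_pair_swap(self, alternative):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        swap = {"greater": "less", "less": "greater", "two-sided": "two-sided"}
        a = wilcoxon_signed_rank(x, y, alternative)
        b = wilcoxon_signed_rank(y, x, swap[alternative])
        assert a.p_value == pytest.approx(b.p_value)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_exact_matches_brute_force_all_small_n(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            # half-integer values provoke ties and zeros
            d = np.round(rng.normal(scale=2, size=n) * 2) / 2
            if np.all(d == 0):
                continue
            for alt in ("two-sided", "greater", "less"):
                got = wilcoxon_signed_rank(d, alternative=alt)
                assert got.p_value == pytest.approx(
                    brute_force_signed_rank(d, alt), abs=1e-12
                )

    def test_exact_matches_scipy_without_ties(self):
        # independent reference on tie-free data where scipy is exact
        rng = np.random.default_rng(17)
        for _ in range(30):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            got = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, mode="exact")
            assert got.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_cutoff(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.3, 1.0, size=25)
        exact = wilcoxon_signed_rank(x, exact_cutoff=25)
        approx = wilcoxon_signed_rank(x, exact_cutoff=10)
        assert approx.method == "normal-approx"
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.15)


class TestBonferroni:
    def test_multiplication_and_cap(self):
        assert bonferroni_adjust([0.01], m=3) == [pytest.approx(0.03)]
        assert bonferroni_adjust([0.5], m=3) == [1.0]
        assert bonferroni_adjust([0.2, 0.04]) == [pytest.approx(0.4), pytest.approx(0.08)]

    def test_m_one_is_identity(self):
        assert bonferroni_adjust([0.3, 0.7], m=1) == [0.3, 0.7]

    def test_never_decreases_and_monotone_in_m(self):
        ps = [0.001, 0.02, 0.3]
        for m in (1, 2, 5):
            adj = bonferroni_adjust(ps, m=m)
            assert all(a >= p for a, p in zip(adj, ps))
        a2 = bonferroni_adjust(ps, m=2)
        a5 = bonferroni_adjust(ps, m=5)
        assert all(x <= y for x, y in zip(a2, a5))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.0])
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


class TestSeparationCategories:
    @pytest.mark.parametrize(
        "sep,cat",
        [(30.0, "small"), (40.0, "small"), (41.0, "medium"), (68.0, "medium"),
         (69.0, "large"), (175.0, "large"), (10.0, "out_of_range"),
         (200.0, "out_of_range")],
    )
    def test_band_boundaries(self, sep, cat):
        assert SeparationCategory().classify(sep) == cat

    def test_separation_analysis_runs_tests_per_band(self):
        rng = np.random.default_rng(7)
        seps = np.r_[np.full(8, 30.0), np.full(8, 50.0), np.full(8, 100.0)]
        r_std = rng.uniform(0.5, 1.0, size=24)
        # contrast grows with separation band (small: symmetric noise only)
        boost = np.r_[rng.normal(0, 0.05, 8), np.full(8, 0.3), np.full(8, 0.8)]
        df = pd.DataFrame(
            {"separation_um": seps, "r_std": r_std, "r_dev": r_std + boost}
        )
        out = separation_analysis(df).set_index("category")
        assert out.loc["medium", "p_value"] < 0.05
        assert out.loc["large", "p_value"] < 0.05
        assert out.loc["small", "p_value"] > 0.05

    def test_empty_band_flagged(self):
        df = pd.DataFrame(
            {"separation_um": [30.0, 35.0], "r_std": [1.0, 1.1], "r_dev": [1.2, 1.4]}
        )
        out = separation_analysis(df).set_index("category")
        assert out.loc["medium", "flagged_empty"]


@pytest.fixture(scope="module")
def spatial_sim(grid):
    """Oddball culture with channels spread from 0 to ~70 electrodes."""
    sites = ((60, 60), (75, 60))
    seq = make_oddball(sites, 300, 0.1, 0.5, seed=41)
    channels = [(60 + dc, 60) for dc in range(0, 71, 2)]
    channels += [(60, 60 + dr) for dr in range(2, 50, 4)]
    params = CultureParams(seed=41)
    spikes = simulate_spikes(grid, seq, params, channels)
    return seq, channels, spikes, sites


class TestSpatial:
    def test_proximity_partitions_channels(self, grid, spatial_sim):
        seq, channels, spikes, _ = spatial_sim
        out = proximity_analysis(spikes, seq, grid, channels)
        per_area = out[(out.condition == "standard") & (out.window == "early")]
        assert per_area["n_channels"].sum() == len(channels)

    def test_early_amplitude_larger_proximal(self, grid, spatial_sim):
        seq, channels, spikes, _ = spatial_sim
        out = proximity_analysis(spikes, seq, grid, channels).set_index(
            ["area", "condition", "window"]
        )
        a = out.loc[("standard_proximal", "standard", "early"), "amplitude"]
        b = out.loc[("other", "standard", "early"), "amplitude"]
        assert a > 2 * b

    def test_late_amplitude_distance_independent(self, grid, spatial_sim):
        seq, channels, spikes, _ = spatial_sim
        out = proximity_analysis(spikes, seq, grid, channels).set_index(
            ["area", "condition", "window"]
        )
        a = out.loc[("standard_proximal", "standard", "late"), "amplitude"]
        b = out.loc[("other", "standard", "late"), "amplitude"]
        assert a == pytest.approx(b, rel=0.25)

    def test_rings_partition_channels(self, grid, spatial_sim):
        seq, channels, spikes, _ = spatial_sim
        out = ring_analysis(spikes, seq, grid, channels)
        early_std = out[(out.condition == "standard") & (out.window == "early")]
        assert early_std["n_channels"].sum() == len(channels)

    def test_single_channel_ring_assignment(self, grid):
        sites = ((60, 60), (75, 60))
        seq = make_oddball(sites, 20, 0.1, 0.5, seed=2)
        spikes = simulate_spikes(grid, seq, CultureParams(seed=2), [(80, 60)])
        out = ring_analysis(spikes, seq, grid, [(80, 60)])
        row = out[(out.condition == "standard") & (out.window == "early")]
        ring = row.loc[row.n_channels > 0, "ring"].iloc[0]
        assert ring == "<= 30"  # distance 20 electrodes from (60, 60)

    def test_channel_order_permutation_invariance(self, grid, spatial_sim):
        seq, channels, spikes, _ = spatial_sim
        out1 = ring_analysis(spikes, seq, grid, channels)
        out2 = ring_analysis(spikes, seq, grid, channels[::-1])
        m1 = out1.set_index(["ring", "condition", "window"])["amplitude"]
        m2 = out2.set_index(["ring", "condition", "window"])["amplitude"]
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), equal_nan=True)


class TestPreferenceClassifier:
    def test_identical_values_nonsignificant(self):
        v = np.tile(np.arange(10.0), (3, 1))
        out = classify_site_preference(v, v)
        assert out.counts["nonsignificant"] == 3
        assert sum(out.fractions.values()) == pytest.approx(1.0)

    def test_strong_shift_detected_with_correct_sign(self):
        rng = np.random.default_rng(11)
        vp = rng.poisson(2.0, size=(10, 200)).astype(float)
        vr = rng.poisson(4.0, size=(10, 200)).astype(float)
        out = classify_site_preference(vr, vp)
        assert out.counts["prefers_random"] == 10

    def test_type_i_error_near_alpha_under_null(self):
        # paired iid Poisson counts: fraction significant ~ alpha
        rng = np.random.default_rng(13)
        n_sites = 2000
        vr = rng.poisson(1.5, size=(n_sites, 120)).astype(float)
        vp = rng.poisson(1.5, size=(n_sites, 120)).astype(float)
        out = classify_site_preference(vr, vp, alpha=0.05)
        frac_sig = 1.0 - out.fractions["nonsignificant"]
        assert 0.03 <= frac_sig <= 0.07

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            classify_site_preference(np.zeros((2, 5)), np.zeros((3, 5)))
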