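"""Winner-takes-the-turn simulation: oracles, filters, monotonicity."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_rt_frame
from turntimes.winner import (
    SimConfig,
    enumerate_sets,
    filter_rt_outliers,
    gain_table,
    simulate_winning_times,
    sweep_set_size,
)


class TestEnumerateSets:
    def test_twenty_participants_pair_count(self):
        ids = [f"p{i:02d}" for i in range(20)]
        assert len(enumerate_sets(ids, 2)) == 190

    def test_identity_case(self):
        assert enumerate_sets(["a", "b"], 2) == [("a", "b")]

    def test_matches_exhaustive_enumeration(self):
        ids = [f"p{i}" for i in range(10)]
        expected = sorted(itertools.combinations(sorted(ids), 3))
        assert enumerate_sets(ids, 3) == expected

    @given(n=st.integers(2, 8), k=st.integers(1, 8))
    def test_subset_count_is_binomial(self, n, k):
        ids = [f"p{i}" for i in range(n)]
        if k > n:
            with pytest.raises(ValueError):
                enumerate_sets(ids, k)
        else:
            subsets = enumerate_sets(ids, k)
            assert len(subsets) == math.comb(n, k)
            assert len(set(subsets)) == len(subsets)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            enumerate_sets(["a", "a", "b"], 2)


class TestOutlierFilter:
    def test_hand_computed_bound(self):
        # mean 190, sample sd ~284.6 -> upper bound ~901.5; only 1000 is out
        ds = make_rt_frame({"p1": [100.0] * 9 + [1000.0]})
        kept, removed, report = filter_rt_outliers(ds)
        assert len(removed) == 1
        assert removed["rt_ms"].iloc[0] == 1000.0
        assert report["upper"].iloc[0] == pytest.approx(901.5, abs=0.1)

    def test_identical_values_nothing_removed(self):
        ds = make_rt_frame({"p1": [250.0] * 10})
        kept, removed, _ = filter_rt_outliers(ds)
        assert len(removed) == 0

    def test_incorrect_removed_regardless_of_value(self):
        ds = make_rt_frame({"p1": [300.0, 310.0, 320.0, 305.0]})
        ds.loc[1, "correct"] = False
        kept, removed, _ = filter_rt_outliers(ds)
        assert list(removed["removed_reason"]) == ["incorrect"]
        assert removed["rt_ms"].iloc[0] == 310.0

    @given(
        st.lists(
            st.floats(min_value=-1000, max_value=2000, allow_nan=False),
            min_size=2,
            max_size=40,
        )
    )
    def test_partition_conservation(self, values):
        ds = make_rt_frame({"p1": values})
        kept, removed, _ = filter_rt_outliers(ds)
        assert len(kept) + len(removed) == len(ds)
        assert sorted(kept.index.tolist() + removed.index.tolist()) == list(
            ds.index
        )


class TestSimulateWinningTimes:
    def test_degenerate_pools(self):
        ds = make_rt_frame({"a": [100.0] * 4, "b": [200.0] * 4})
        cfg = SimConfig(set_size=2, trials_per_condition=8, seed=0)
        draws = simulate_winning_times(ds, [("a", "b")], cfg)
        assert (draws["winning_rt_ms"] == 100.0).all()
        assert (draws["winner_id"] == "a").all()

    def test_k1_equals_individual_sampling(self):
        ds = make_rt_frame({"a": [100.0, 150.0, 200.0, 250.0]})
        cfg = SimConfig(
            set_size=1, trials_per_condition=4, seed=0,
            sampling="without_replacement",
        )
        draws = simulate_winning_times(ds, [("a",)], cfg)
        assert sorted(draws["winning_rt_ms"]) == [100.0, 150.0, 200.0, 250.0]

    def test_winning_is_min_of_members(self, toy_rt_dataset):
        cfg = SimConfig(set_size=2, trials_per_condition=16, seed=3,
                        sampling="with_replacement")
        sets = enumerate_sets(["a", "b", "c"], 2)
        draws = simulate_winning_times(toy_rt_dataset, sets, cfg)
        for _, row in draws.iterrows():
            assert row["winning_rt_ms"] == min(row["member_rts"])

    def test_exponential_min_oracle(self):
        # E[min of k iid Exp(mean m)] = m / k
        rng = np.random.default_rng(0)
        pools = {p: rng.exponential(300.0, 30_000) for p in ("a", "b", "c")}
        ds = make_rt_frame(pools)
        cfg = SimConfig(
            set_size=3, trials_per_condition=10_000, seed=1,
            sampling="with_replacement",
        )
        draws = simulate_winning_times(ds, [("a", "b", "c")], cfg)
        win = draws["winning_rt_ms"].to_numpy()
        se = win.std(ddof=1) / np.sqrt(len(win))
        assert abs(win.mean() - 100.0) < 3 * se + 2.0  # + finite-pool slack

    def test_empty_pool_names_participant(self, toy_rt_dataset):
        cfg = SimConfig(set_size=2, trials_per_condition=4, seed=0)
        with pytest.raises(ValueError, match="zz"):
            simulate_winning_times(toy_rt_dataset, [("a", "zz")], cfg)

    def test_exhaustive_matches_brute_force(self, toy_rt_dataset):
        """Winner distribution equals direct enumeration of all
        (member, trial) combinations on the 3-participant toy dataset."""
        cfg = SimConfig(set_size=2, sampling="exhaustive", seed=0)
        sets = enumerate_sets(["a", "b", "c"], 2)
        draws = simulate_winning_times(toy_rt_dataset, sets, cfg)

        pools = {
            pid: grp["rt_ms"].tolist()
            for pid, grp in toy_rt_dataset.groupby("participant_id")
        }
        brute = []
        for members in sets:
            for combo in itertools.product(*(pools[m] for m in members)):
                brute.append(min(combo))
        assert sorted(draws["winning_rt_ms"]) == sorted(brute)


class TestGainTable:
    def test_k1_exhaustive_gains_are_zero(self, toy_rt_dataset):
        cfg = SimConfig(set_size=1, sampling="exhaustive", seed=0)
        draws = simulate_winning_times(
            toy_rt_dataset, [("a",), ("b",), ("c",)], cfg
        )
        table = gain_table(toy_rt_dataset, draws)
        assert table["gain_mean"].iloc[0] == pytest.approx(0.0)
        assert table["gain_median"].iloc[0] == pytest.approx(0.0)

    def test_winner_mean_below_observed(self):
        ds = make_rt_frame({"a": [300.0, 400.0], "b": [300.0, 400.0]})
        cfg = SimConfig(set_size=2, sampling="exhaustive", seed=0)
        draws = simulate_winning_times(ds, [("a", "b")], cfg)
        table = gain_table(ds, draws)
        assert table["winner_mean"].iloc[0] < table["observed_mean"].iloc[0]

    def test_normal_pairs_closed_form(self):
        # E[min of 2 iid N(mu, sigma)] = mu - sigma/sqrt(pi)
        rng = np.random.default_rng(4)
        sigma = 177.0
        pools = {p: rng.normal(417.0, sigma, 50_000) for p in ("a", "b")}
        ds = make_rt_frame(pools)
        cfg = SimConfig(
            set_size=2, trials_per_condition=10_000, seed=2,
            sampling="with_replacement",
        )
        draws = simulate_winning_times(ds, [("a", "b")], cfg)
        table = gain_table(ds, draws)
        win = draws["winning_rt_ms"].to_numpy()
        se_mc = win.std(ddof=1) / np.sqrt(len(win))
        se_obs = sigma / np.sqrt(2 * 50_000)
        tol = 3 * (se_mc + se_obs)
        assert table["gain_mean"].iloc[0] == pytest.approx(
            sigma / np.sqrt(np.pi), abs=tol
        )

    def test_condition_mismatch_raises(self, toy_rt_dataset):
        cfg = SimConfig(set_size=2, sampling="exhaustive", seed=0)
        draws = simulate_winning_times(
            toy_rt_dataset, [("a", "b")], cfg
        )
        other = toy_rt_dataset.copy()
        other["response"] = "affirmative"
        with pytest.raises(ValueError, match="condition mismatch"):
            gain_table(other, draws)


class TestSweep:
    def test_coupled_mean_is_nonincreasing_exactly(self):
        rng = np.random.default_rng(8)
        pools = {f"p{i:02d}": rng.gamma(2.0, 150.0, 64) for i in range(12)}
        ds = make_rt_frame(pools)
        sweep = sweep_set_size(
            ds, k_min=2, k_max=10, config=SimConfig(seed=5), coupled=True
        )
        assert (np.diff(sweep["mean"].to_numpy()) <= 1e-12).all()

    def test_bounded_by_sample_minimum(self):
        rng = np.random.default_rng(9)
        pools = {f"p{i}": rng.normal(400, 100, 32) for i in range(6)}
        ds = make_rt_frame(pools)
        m = ds["rt_ms"].min()
        sweep = sweep_set_size(
            ds, k_min=2, k_max=6, config=SimConfig(seed=1), subset_cap=50
        )
        assert (sweep["mean"] >= m).all()
        assert (sweep["q25"] >= m).all()

    def test_bounded_support_plateaus(self):
        # with a hard floor the mean winning time flattens out:
        # late decrements are an order of magnitude below early ones
        rng = np.random.default_rng(10)
        pools = {f"p{i:02d}": rng.uniform(100, 500, 64) for i in range(12)}
        ds = make_rt_frame(pools)
        sweep = sweep_set_size(
            ds, k_min=2, k_max=10,
            config=SimConfig(seed=6, trials_per_condition=64),
            subset_cap=20_000, coupled=True,
        )
        means = sweep["mean"].to_numpy()
        first_step = means[0] - means[1]
        last_step = means[-2] - means[-1]
        assert last_step < 0.25 * first_step
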