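"""Fastest-responder-wins resampling simulation.

Given trial-level response times for a panel of participants, form k-member
sets, sample one response time per member and condition from that member's
pool, and record the minimum ("winning") time per simulated trial.  The gain
is the drop in mean/median of winning times relative to all observed
responses; sweeping k shows the gain growing and then plateauing as the set
exhausts the fast tail of the pool.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITION_COLS = ["display", "response"]

SAMPLING_POLICIES = ("without_replacement", "with_replacement", "exhaustive")


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the winning-time simulation.

    ``sampling='without_replacement'`` draws each member's trials_per_condition
    samples without replacement when the member's pool is large enough,
    falling back to with-replacement otherwise.  ``'exhaustive'`` enumerates
    every cross-member combination of pool entries (ignores
    trials_per_condition) and is meant for small oracle datasets.
    """

    set_size: int = 2
    trials_per_condition: int = 32
    sd_outlier_factor: float = 2.5
    sampling: str = "without_replacement"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size < 1:
            raise ValueError("SimConfig.set_size must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("SimConfig.trials_per_condition must be >= 1")
        if self.sampling not in SAMPLING_POLICIES:
            raise ValueError(
                f"SimConfig.sampling must be one of {SAMPLING_POLICIES}"
            )


def enumerate_sets(
    participant_ids: Sequence[str], k: int
) -> list[tuple[str, ...]]:
    """All unordered k-subsets of participants, in lexicographic order.

    20 participants at k=2 give C(20,2) = 190 pairs.
    """
    ids = sorted(participant_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("participant_ids must be distinct")
    if not 1 <= k <= len(ids):
        raise ValueError(
            f"k must be in [1, {len(ids)}] (number of participants); got {k}"
        )
    return list(itertools.combinations(ids, k))


def filter_rt_outliers(
    dataset: pd.DataFrame, sd_factor: float = 2.5
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Remove incorrect responses and per-condition +/- sd_factor SD outliers.

    Incorrect trials are removed by flag first; then, per condition cell,
    responses deviating by *more than* ``sd_factor`` sample standard
    deviations (n-1 denominator) from the cell mean of the correct
    responses are removed.  Returns ``(kept, removed, report)`` where
    ``removed`` carries a ``removed_reason`` column (``incorrect`` or
    ``outlier``) and ``report`` the per-condition bounds.  Kept and removed
    partition the input exactly.
    """
    required = set(CONDITION_COLS + ["rt_ms", "correct"])
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")

    correct = dataset[dataset["correct"]].copy()
    incorrect = dataset[~dataset["correct"]].copy()
    incorrect["removed_reason"] = "incorrect"

    kept_parts: list[pd.DataFrame] = []
    outlier_parts: list[pd.DataFrame] = []
    report_rows: list[dict] = []
    for cond, grp in correct.groupby(CONDITION_COLS, sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"condition {cond} has fewer than 2 correct records"
            )
        mean = grp["rt_ms"].mean()
        sd = grp["rt_ms"].std(ddof=1)
        lo, hi = mean - sd_factor * sd, mean + sd_factor * sd
        is_out = (grp["rt_ms"] < lo) | (grp["rt_ms"] > hi)
        kept_parts.append(grp[~is_out])
        out = grp[is_out].copy()
        out["removed_reason"] = "outlier"
        outlier_parts.append(out)
        report_rows.append(
            {
                "display": cond[0],
                "response": cond[1],
                "mean": mean,
                "sd": sd,
                "lower": lo,
                "upper": hi,
                "n_input": len(grp),
                "n_outliers": int(is_out.sum()),
            }
        )

    kept = pd.concat(kept_parts).sort_index()
    removed = pd.concat([incorrect] + outlier_parts).sort_index()
    report = pd.DataFrame(report_rows)
    assert len(kept) + len(removed) == len(dataset)
    return kept, removed, report


def _pools(dataset: pd.DataFrame) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Per-condition, per-participant RT pools."""
    pools: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for (display, response, pid), grp in dataset.groupby(
        CONDITION_COLS + ["participant_id"], sort=True
    ):
        pools.setdefault((display, response), {})[pid] = (
            grp["rt_ms"].to_numpy()
        )
    return pools


def simulate_winning_times(
    dataset: pd.DataFrame,
    sets: Iterable[tuple[str, ...]],
    config: SimConfig,
) -> pd.DataFrame:
    """Simulate winning (minimum) response times per set, condition and trial.

    The dataset should already be outlier-filtered.  Returns a DataFrame
    with one row per simulated trial: ``set_id, set_members, display,
    response, trial, winning_rt_ms, winner_id, member_rts`` (member RTs in
    set-member order).  Deterministic under ``config.seed``.
    """
    sets = [tuple(s) for s in sets]
    rng = np.random.default_rng(config.seed)
    pools = _pools(dataset)

    for cond, by_pid in pools.items():
        for set_members in sets:
            for pid in set_members:
                if pid not in by_pid or len(by_pid[pid]) == 0:
                    raise ValueError(
                        f"participant {pid!r} has no responses in condition "
                        f"{cond}"
                    )

    rows: list[dict] = []
    for set_id, members in enumerate(sets):
        for cond in sorted(pools):
            by_pid = pools[cond]
            if config.sampling == "exhaustive":
                combos = itertools.product(*(by_pid[pid] for pid in members))
                draws = np.array(list(combos), dtype=float)
            else:
                n_tr = config.trials_per_condition
                cols = []
                for pid in members:
                    pool = by_pid[pid]
                    without = (
                        config.sampling == "without_replacement"
                        and len(pool) >= n_tr
                    )
                    cols.append(
                        rng.choice(pool, size=n_tr, replace=not without)
                    )
                draws = np.column_stack(cols)
            win_idx = draws.argmin(axis=1)
            win = draws[np.arange(len(draws)), win_idx]
            for trial, (rts, w, wi) in enumerate(
                zip(draws, win, win_idx), start=1
            ):
                rows.append(
                    {
                        "set_id": set_id,
                        "set_members": members,
                        "display": cond[0],
                        "response": cond[1],
                        "trial": trial,
                        "winning_rt_ms": float(w),
                        # ties attributed to the lexicographically smallest id
                        "winner_id": min(
                            m
                            for m, r in zip(members, rts)
                            if r == w
                        ),
                        "member_rts": tuple(float(r) for r in rts),
                    }
                )
    return pd.DataFrame(rows)


def gain_table(
    observed_dataset: pd.DataFrame, winner_draws: pd.DataFrame
) -> pd.DataFrame:
    """Per-condition observed vs winning central tendencies and their gains.

    Medians use the midpoint convention for even n; MAD is the unscaled
    median absolute deviation.  ``gain_mean = observed_mean - winner_mean``
    and likewise for medians.
    """
    obs_conds = set(map(tuple, observed_dataset[CONDITION_COLS].drop_duplicates().to_numpy()))
    win_conds = set(map(tuple, winner_draws[CONDITION_COLS].drop_duplicates().to_numpy()))
    if obs_conds != win_conds:
        raise ValueError(
            f"condition mismatch: observed {sorted(obs_conds)} vs "
            f"winners {sorted(win_conds)}"
        )

    def mad(x: pd.Series) -> float:
        return float((x - x.median()).abs().median())

    rows = []
    for cond in sorted(obs_conds):
        obs = observed_dataset.loc[
            (observed_dataset["display"] == cond[0])
            & (observed_dataset["response"] == cond[1]),
            "rt_ms",
        ]
        win = winner_draws.loc[
            (winner_draws["display"] == cond[0])
            & (winner_draws["response"] == cond[1]),
            "winning_rt_ms",
        ]
        rows.append(
            {
                "display": cond[0],
                "response": cond[1],
                "observed_mean": obs.mean(),
                "observed_sd": obs.std(ddof=1),
                "observed_median": obs.median(),
                "observed_mad": mad(obs),
                "winner_mean": win.mean(),
                "winner_sd": win.std(ddof=1),
                "winner_median": win.median(),
                "winner_mad": mad(win),
            }
        )
    table = pd.DataFrame(rows)
    table["gain_mean"] = table["observed_mean"] - table["winner_mean"]
    table["gain_median"] = table["observed_median"] - table["winner_median"]
    return table


def _coupled_sweep(
    pools: dict[tuple[str, str], dict[str, np.ndarray]],
    ids: list[str],
    k_min: int,
    k_max: int,
    trials: int,
    n_chains: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sweep with coupled sampling: supersets reuse subset draws.

    Each chain fixes a random participant ordering and one draw per
    participant x condition x trial; the k-set winning time is the cumulative
    minimum over the first k participants, so per-chain winning times are
    non-increasing in k by construction.
    """
    conds = sorted(pools)
    per_k_values: dict[int, list[np.ndarray]] = {k: [] for k in range(k_min, k_max + 1)}
    for _ in range(n_chains):
        order = list(rng.permutation(ids))[:k_max]
        for cond in conds:
            by_pid = pools[cond]
            draws = np.stack(
                [rng.choice(by_pid[pid], size=trials, replace=True) for pid in order]
            )  # (k_max, trials)
            cummin = np.minimum.accumulate(draws, axis=0)
            for k in range(k_min, k_max + 1):
                per_k_values[k].append(cummin[k - 1])
    rows = []
    for k in range(k_min, k_max + 1):
        vals = np.concatenate(per_k_values[k])
        rows.append(_summary_row(k, vals, n_sets=n_chains))
    return pd.DataFrame(rows)


def _summary_row(k: int, vals: np.ndarray, n_sets: int) -> dict:
    return {
        "k": k,
        "n_sets": n_sets,
        "n_draws": len(vals),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "q25": float(np.quantile(vals, 0.25)),
        "q75": float(np.quantile(vals, 0.75)),
    }


def sweep_set_size(
    dataset: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    config: SimConfig | None = None,
    subset_cap: int = 10_000,
    coupled: bool = False,
) -> pd.DataFrame:
    """Winning-time summaries for set sizes k_min..k_max.

    For each k, simulates winning times over all k-subsets (or a uniform
    sample of ``subset_cap`` subsets when the number of combinations
    explodes) and reports mean, median and quartiles of the winning times
    pooled across conditions.  With ``coupled=True``, supersets reuse the
    subsets' draws, which makes the per-k mean non-increasing exactly.
    """
    config = config or SimConfig()
    ids = sorted(dataset["participant_id"].unique())
    n = len(ids)
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds number of participants ({n})")

    rng = np.random.default_rng(config.seed)
    pools = _pools(dataset)
    trials = config.trials_per_condition

    if coupled:
        n_chains = max(1, subset_cap // 100)
        return _coupled_sweep(pools, ids, k_min, k_max, trials, n_chains, rng)

    rows = []
    for k in range(k_min, k_max + 1):
        n_comb = math.comb(n, k)
        if n_comb <= subset_cap:
            sets = enumerate_sets(ids, k)
        else:
            sets = [
                tuple(sorted(rng.choice(ids, size=k, replace=False)))
                for _ in range(subset_cap)
            ]
        # vectorized winning draws, pooled over conditions
        vals_parts = []
        for cond, by_pid in pools.items():
            draws = np.empty((len(sets), k, trials))
            for si, members in enumerate(sets):
                for mi, pid in enumerate(members):
                    pool = by_pid[pid]
                    without = (
                        config.sampling == "without_replacement"
                        and len(pool) >= trials
                    )
                    draws[si, mi] = rng.choice(
                        pool, size=trials, replace=not without
                    )
            vals_parts.append(draws.min(axis=1).ravel())
        vals = np.concatenate(vals_parts)
        rows.append(_summary_row(k, vals, n_sets=len(sets)))
    return pd.DataFrame(rows)
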