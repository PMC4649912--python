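"""Replicate-level statistics for qPCR platforms.

Covers the within-run precision measures used to compare platforms:
coefficient of variation of replicate CTs, replicate range, CT-based
expression tiers, fidelity scoring (fraction of replicate groups whose CT
range stays under 1/2/3-cycle cutoffs), fold-change conversion and
between-run reproducibility.

All summaries are returned as tidy DataFrames; one row per replicate group,
per (platform, cutoff), or per (platform, tier).
"""

from __future__ import annotations

import enum
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CtTable

__all__ = [
    "ExpressionTier",
    "TIER_BOUNDS",
    "assign_tier",
    "fold_change",
    "replicate_stats",
    "fidelity_report",
    "tiered_variation",
    "inter_run_difference",
]

#: CT boundaries between the ultra-high / high / moderate / low tiers.
TIER_BOUNDS = (10.0, 20.0, 30.0)


class ExpressionTier(str, enum.Enum):
    """Abundance bin of a transcript, judged from its mean CT.

    Lower CT means more template: ultra-high is CT < 10, high is 10-20,
    moderate is 20-30 and low is CT > 30.  The boundaries are closed on the
    high-abundance side (CT 20.0 is still "high"), which keeps the four bins
    a partition of (0, inf).
    """

    ULTRA_HIGH = "ultra_high"
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"


_TIER_ORDER = [t.value for t in ExpressionTier]


def assign_tier(
    ct: float, bounds: Sequence[float] = TIER_BOUNDS
) -> ExpressionTier:
    """Map a finite positive CT value to its expression tier.

    Raises
    ------
    ValueError
        If ``ct`` is NaN (undetermined), non-positive or infinite: dropouts
        must be filtered or imputed before tiering.
    """
    if ct is None or not np.isfinite(ct) or ct <= 0:
        raise ValueError(f"cannot tier CT value {ct!r}; need a finite value > 0")
    b1, b2, b3 = bounds
    if ct < b1:
        return ExpressionTier.ULTRA_HIGH
    if ct <= b2:
        return ExpressionTier.HIGH
    if ct <= b3:
        return ExpressionTier.MODERATE
    return ExpressionTier.LOW


def _tier_series(mean_ct: pd.Series, bounds: Sequence[float] = TIER_BOUNDS) -> pd.Series:
    b1, b2, b3 = bounds
    out = pd.Series(pd.NA, index=mean_ct.index, dtype="object")
    ok = mean_ct.notna()
    v = mean_ct[ok]
    out[ok] = np.select(
        [v < b1, v <= b2, v <= b3],
        [ExpressionTier.ULTRA_HIGH.value, ExpressionTier.HIGH.value,
         ExpressionTier.MODERATE.value],
        default=ExpressionTier.LOW.value,
    )
    return out


def fold_change(delta_ct):
    """Convert a CT difference to a fold difference in template abundance.

    Assumes perfect doubling per cycle: a 3-cycle spread corresponds to a
    2**3 = 8-fold difference in transcript abundance.
    """
    return np.power(2.0, delta_ct)


def replicate_stats(table: CtTable, pool_runs: bool = False) -> pd.DataFrame:
    """Per-group replicate statistics.

    Groups are (platform, run, sample, mirna), or (platform, sample, mirna)
    with ``pool_runs=True``.  Undetermined replicates are excluded from the
    mean/sd; groups left with fewer than two determined values carry NaN
    sd/cv/range and are flagged.

    Returns
    -------
    DataFrame with columns ``platform, [run,] sample, mirna, n,
    n_determined, n_undetermined, mean_ct, sd_ct, cv_pct, range_ct, tier,
    flagged``.  ``sd_ct`` uses the n-1 (sample) denominator and
    ``cv_pct = 100 * sd_ct / mean_ct``.
    """
    keys = ["platform", "sample", "mirna"] if pool_runs else [
        "platform", "run", "sample", "mirna"
    ]
    df = table.data
    if df.empty:
        return pd.DataFrame(
            columns=keys + ["n", "n_determined", "n_undetermined", "mean_ct",
                            "sd_ct", "cv_pct", "range_ct", "tier", "flagged"]
        )
    g = df.groupby(keys, sort=True)["ct"]
    stats = g.agg(
        n="size",
        n_determined="count",
        mean_ct="mean",
        sd_ct="std",  # pandas default ddof=1
        min_ct="min",
        max_ct="max",
    )
    stats["n_undetermined"] = stats["n"] - stats["n_determined"]
    stats["cv_pct"] = 100.0 * stats["sd_ct"] / stats["mean_ct"]
    stats["range_ct"] = stats["max_ct"] - stats["min_ct"]
    too_few = stats["n_determined"] < 2
    stats.loc[too_few, ["sd_ct", "cv_pct", "range_ct"]] = np.nan
    stats["tier"] = pd.Categorical(
        _tier_series(stats["mean_ct"]), categories=_TIER_ORDER, ordered=True
    )
    stats["flagged"] = too_few
    stats = stats.drop(columns=["min_ct", "max_ct"]).reset_index()
    cols = keys + ["n", "n_determined", "n_undetermined", "mean_ct", "sd_ct",
                   "cv_pct", "range_ct", "tier", "flagged"]
    return stats[cols]


def fidelity_report(
    table: CtTable,
    cutoffs: Iterable[float] = (1.0, 2.0, 3.0),
    undetermined_policy: str = "fail_all",
    pool_runs: bool = False,
) -> pd.DataFrame:
    """Fidelity score per platform and CT cutoff.

    A replicate group passes a cutoff ``c`` when its CT range (max - min
    over determined replicates) is strictly less than ``c``.  Fidelity is
    the percentage of scorable groups that pass; "deviation from fidelity"
    is its complement.

    Parameters
    ----------
    undetermined_policy
        ``"fail_all"`` (default): a group containing any undetermined
        replicate counts as exceeding every cutoff — a dropout is a
        worse-than-8-fold discordance.  ``"exclude"``: undetermined
        replicates are silently dropped and the group is scored on the
        remaining values (needs >= 2 of them).

    Returns
    -------
    DataFrame with columns ``platform, cutoff, n_groups, fidelity_pct,
    deviation_pct``.  Platforms with no scorable group are omitted with a
    warning.
    """
    if undetermined_policy not in ("fail_all", "exclude"):
        raise ValueError(f"unknown undetermined_policy {undetermined_policy!r}")
    cutoffs = sorted(float(c) for c in cutoffs)
    stats = replicate_stats(table, pool_runs=pool_runs)
    rows = []
    for platform in table.platforms:
        sub = stats[stats["platform"] == platform]
        if undetermined_policy == "fail_all":
            scorable = sub[sub["n"] >= 2]
            dropout = scorable["n_undetermined"] > 0
        else:
            scorable = sub[sub["n_determined"] >= 2]
            dropout = pd.Series(False, index=scorable.index)
        if scorable.empty:
            warnings.warn(
                f"platform {platform!r}: no scorable replicate groups; omitted",
                stacklevel=2,
            )
            continue
        for c in cutoffs:
            passed = (~dropout) & (scorable["range_ct"] < c)
            fidelity = 100.0 * passed.sum() / len(scorable)
            rows.append(
                {
                    "platform": platform,
                    "cutoff": c,
                    "n_groups": len(scorable),
                    "fidelity_pct": fidelity,
                    "deviation_pct": 100.0 - fidelity,
                }
            )
    return pd.DataFrame(rows, columns=["platform", "cutoff", "n_groups",
                                       "fidelity_pct", "deviation_pct"])


def tiered_variation(table: CtTable, pool_runs: bool = False) -> pd.DataFrame:
    """Distribution of replicate CT range per platform and expression tier.

    Groups are binned by the tier of their mean CT; within each
    (platform, tier) cell the median, quartiles and extremes of the range
    are reported.  Tiers with no groups appear with ``n = 0`` and NaN
    summaries so the full grid is always present.
    """
    stats = replicate_stats(table, pool_runs=pool_runs)
    stats = stats[stats["n_determined"] >= 2]
    grid = pd.MultiIndex.from_product(
        [table.platforms, _TIER_ORDER], names=["platform", "tier"]
    )
    if stats.empty:
        out = pd.DataFrame(index=grid,
                           columns=["n", "median", "q1", "q3", "min", "max"])
        out["n"] = 0
        return out.reset_index()
    agg = (
        stats.groupby(["platform", "tier"], observed=False)["range_ct"]
        .agg(
            n="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            min="min",
            max="max",
        )
        .reindex(grid)
    )
    agg["n"] = agg["n"].fillna(0).astype(int)
    return agg.reset_index()


def inter_run_difference(table: CtTable, run_a, run_b) -> pd.DataFrame:
    """Between-run reproducibility per platform and miRNA.

    For every (platform, mirna, sample) cell present in both runs the
    run-mean CTs are differenced (run_a - run_b); per (platform, mirna) the
    mean absolute and mean signed difference over shared samples are
    reported.  The signed mean exposes systematic shifts such as one run
    producing consistently lower CTs.

    miRNAs observed in only one of the two runs on a platform are omitted
    with a warning.
    """
    df = table.data
    present = set(df["run"].unique())
    missing_runs = {run_a, run_b} - present
    if missing_runs:
        raise ValueError(f"run(s) not present in table: {sorted(missing_runs)}")
    sub = df[df["run"].isin([run_a, run_b])]
    means = (
        sub.groupby(["platform", "mirna", "sample", "run"], sort=True)["ct"]
        .mean()
        .unstack("run")
    )
    both = means.dropna(subset=[run_a, run_b])
    dropped = (
        means[means[[run_a, run_b]].isna().any(axis=1)]
        .reset_index()[["platform", "mirna"]]
        .drop_duplicates()
    )
    diff = (both[run_a] - both[run_b]).rename("diff")
    out = (
        diff.groupby(level=["platform", "mirna"])
        .agg(
            n_samples="count",
            mean_abs_diff=lambda s: s.abs().mean(),
            mean_signed_diff="mean",
        )
        .reset_index()
    )
    fully_dropped = dropped.merge(
        out[["platform", "mirna"]], how="left", indicator=True
    )
    fully_dropped = fully_dropped[fully_dropped["_merge"] == "left_only"]
    if not fully_dropped.empty:
        warnings.warn(
            f"{len(fully_dropped)} (platform, mirna) pair(s) present in only one "
            f"of runs {run_a!r}/{run_b!r}; omitted",
            stacklevel=2,
        )
    return out
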