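"""Cross-platform agreement on the z-score scale.

Raw CT values cannot be compared across qPCR platforms (different reaction
volumes, pre-amplification depth and detection chemistry shift the whole
scale), so each platform's values are standardized to z-scores and the
agreement between a comparison platform and a reference ("gold standard")
platform is summarized by Pearson correlation and the slope of the
ordinary-least-squares line.  A slope below the ideal value of 1 indicates
dynamic-range compression on the comparison platform.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.base import BaseEstimator, RegressorMixin

from .io import CtTable, collapse_replicates

__all__ = [
    "ZScoredTable",
    "ConcordanceStats",
    "ConcordanceRegressor",
    "DegenerateDataError",
    "InsufficientDataError",
    "platform_zscores",
    "pairwise_concordance",
    "concordance_table",
]


class DegenerateDataError(ValueError):
    """A platform has zero variance; z-scores are undefined."""


class InsufficientDataError(ValueError):
    """Fewer than three matched cells are available for a comparison."""


@dataclasses.dataclass(frozen=True)
class ZScoredTable:
    """Matched, per-platform standardized expression values.

    ``z`` is indexed by (sample, mirna) with one column per platform; only
    cells determined on every compared platform are retained, and within
    each platform the retained values have mean 0 and sd 1 (sample sd).
    """

    z: pd.DataFrame

    @property
    def platforms(self) -> list:
        return list(self.z.columns)

    @property
    def n_cells(self) -> int:
        return len(self.z)


def platform_zscores(
    table: CtTable,
    platforms: Sequence | None = None,
    sample_groups: Mapping | None = None,
) -> ZScoredTable:
    """Standardize matched expression cells within each platform.

    Replicate CTs are first collapsed to their mean per (platform, sample,
    mirna); cells missing (all replicates undetermined or unmeasured) on any
    of the compared platforms are dropped, so the comparison is
    pairwise-complete for the platform set given.

    Parameters
    ----------
    platforms
        Platforms to match and standardize; default all in the table.
    sample_groups
        Optional mapping sample -> group label (e.g. cellular vs serum).
        When given, z-scores are computed within each (platform, group)
        instead of over all of a platform's values.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 matched cells survive.
    DegenerateDataError
        A platform's matched values have zero variance.
    """
    wide = collapse_replicates(table).unstack("platform")
    wide.index.names = ["sample", "mirna"]
    if platforms is None:
        platforms = list(wide.columns)
    else:
        missing = [p for p in platforms if p not in wide.columns]
        if missing:
            raise KeyError(f"platform(s) not in table: {missing}")
    sub = wide[list(platforms)].dropna()
    if len(sub) < 3:
        raise InsufficientDataError(
            f"only {len(sub)} matched cell(s) across platforms {list(platforms)}; "
            "need >= 3"
        )
    if sample_groups is None:
        mean, sd = sub.mean(), sub.std(ddof=1)
        flat = sd <= 0
        if flat.any():
            raise DegenerateDataError(
                f"zero variance on platform(s) {list(sd.index[flat])}"
            )
        z = (sub - mean) / sd
    else:
        groups = sub.index.get_level_values("sample").map(sample_groups)
        parts = []
        for _, part in sub.groupby(groups.values):
            sd = part.std(ddof=1)
            if (sd <= 0).any():
                raise DegenerateDataError(
                    f"zero variance on platform(s) {list(sd.index[sd <= 0])}"
                )
            parts.append((part - part.mean()) / sd)
        z = pd.concat(parts).loc[sub.index]
    return ZScoredTable(z)


@dataclasses.dataclass(frozen=True)
class ConcordanceStats:
    """OLS summary of one platform against the reference on the z scale."""

    reference: object
    platform: object
    n_pairs: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float


class ConcordanceRegressor(RegressorMixin, BaseEstimator):
    """Simple OLS of comparison-platform z-scores on reference z-scores.

    A thin estimator wrapper so the concordance fit composes with sklearn
    tooling.  Fitted attributes: ``slope_``, ``intercept_``, ``pearson_r_``,
    ``r_squared_``, ``n_``.  The slope's deviation from the ideal value 1
    measures dynamic-range compression (slope < 1) or expansion (> 1).
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("ConcordanceRegressor expects a single feature")
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if x.size < 3:
            raise InsufficientDataError(f"need >= 3 pairs, got {x.size}")
        if np.ptp(x) == 0:
            raise DegenerateDataError("reference values are constant")
        res = _sps.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.pearson_r_ = float(res.rvalue)
        self.r_squared_ = float(res.rvalue**2)
        self.n_ = int(x.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.slope_ * x + self.intercept_


def pairwise_concordance(z: ZScoredTable, reference, other) -> ConcordanceStats:
    """Concordance statistics of ``other`` regressed on ``reference``.

    The reference (gold standard) platform is on x; slope, intercept,
    Pearson r and R^2 come from unweighted OLS over the matched z pairs.
    """
    for p in (reference, other):
        if p not in z.z.columns:
            raise KeyError(f"platform {p!r} not in z-scored table")
    reg = ConcordanceRegressor().fit(z.z[reference].to_numpy(),
                                     z.z[other].to_numpy())
    return ConcordanceStats(
        reference=reference,
        platform=other,
        n_pairs=reg.n_,
        pearson_r=reg.pearson_r_,
        r_squared=reg.r_squared_,
        slope=reg.slope_,
        intercept=reg.intercept_,
    )


def concordance_table(
    table: CtTable,
    reference,
    others: Sequence | None = None,
    sample_groups: Mapping | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons against the reference platform.

    Each pair is matched pairwise-complete (cells determined on both
    platforms of that pair) and standardized over exactly those cells, so
    different comparisons may retain different cell sets.

    Returns a DataFrame with columns ``reference, platform, n, r, r2,
    slope, intercept``.
    """
    if others is None:
        others = [p for p in table.platforms if p != reference]
    rows = []
    for other in others:
        z = platform_zscores(table, [reference, other], sample_groups=sample_groups)
        s = pairwise_concordance(z, reference, other)
        rows.append(
            {
                "reference": s.reference,
                "platform": s.platform,
                "n": s.n_pairs,
                "r": s.pearson_r,
                "r2": s.r_squared,
                "slope": s.slope,
                "intercept": s.intercept,
            }
        )
    return pd.DataFrame(rows)
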