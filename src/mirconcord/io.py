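"""Reading and writing replicate CT tables and tabular analysis reports.

The canonical interchange format is a long (tidy) CSV with one row per
individual qPCR reaction::

    platform,run,user,sample,mirna,replicate,ct

``ct`` holds the cycle-threshold value of that reaction, or the sentinel
string ``"Undetermined"`` (configurable) / an empty cell for reactions that
never crossed the fluorescence threshold.  In memory undetermined reactions
are represented as NaN, so the usual pandas missing-data machinery applies.
Wide per-platform matrices are derived in memory only: four platforms with
unequal replicate structure cannot share one wide layout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "CtTableFormatError",
    "CtTableIntegrityError",
    "read_ct_table",
    "write_ct_table",
    "write_report",
    "UNDETERMINED",
    "REQUIRED_COLUMNS",
    "KEY_COLUMNS",
]

#: Default sentinel used by vendor CSV exports for reactions with no signal.
UNDETERMINED = "Undetermined"

REQUIRED_COLUMNS = ("platform", "run", "sample", "mirna", "replicate", "ct")
KEY_COLUMNS = ("platform", "run", "sample", "mirna", "replicate")
ALL_COLUMNS = ("platform", "run", "user", "sample", "mirna", "replicate", "ct")


class CtTableFormatError(ValueError):
    """A CT table file could not be parsed (missing column, bad cell)."""


class CtTableIntegrityError(ValueError):
    """A CT table violates its invariants (duplicate keys, bad CT values)."""


@dataclasses.dataclass(frozen=True)
class CtTable:
    """Collection of replicate CT measurements.

    Parameters
    ----------
    data
        Long-format frame with columns ``platform, run, user, sample, mirna,
        replicate, ct``.  ``ct`` is float; NaN flags an undetermined reaction.

    Notes
    -----
    The key ``(platform, run, sample, mirna, replicate)`` is unique within a
    table and every determined CT is finite and positive; both are enforced
    at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CtTableFormatError(f"missing required column(s): {missing}")
        if "user" not in df.columns:
            df = df.assign(user=pd.NA)
        df = df.loc[:, list(ALL_COLUMNS)].reset_index(drop=True)
        ct = pd.to_numeric(df["ct"], errors="coerce")
        determined = ct.notna()
        bad = determined & (~np.isfinite(ct.fillna(0.0)) | (ct <= 0))
        if bad.any():
            raise CtTableIntegrityError(
                f"{int(bad.sum())} determined CT value(s) are not finite and > 0 "
                f"(first offending row index {int(bad.idxmax())})"
            )
        df["ct"] = ct.astype(float)
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
        if (df["replicate"] < 1).any():
            raise CtTableIntegrityError("replicate indices must be positive integers")
        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            keys = df.loc[dup, list(KEY_COLUMNS)].drop_duplicates()
            raise CtTableIntegrityError(
                f"duplicate measurement key(s): {keys.to_dict(orient='records')[:3]}"
            )
        object.__setattr__(self, "data", df)

    # -- rosters ---------------------------------------------------------
    @property
    def platforms(self) -> list:
        return sorted(self.data["platform"].unique())

    @property
    def mirnas(self) -> list:
        return sorted(self.data["mirna"].unique())

    @property
    def samples(self) -> list:
        return sorted(self.data["sample"].unique())

    @property
    def runs(self) -> list:
        return sorted(self.data["run"].unique())

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_undetermined(self) -> int:
        return int(self.data["ct"].isna().sum())

    def equals(self, other: "CtTable") -> bool:
        """Order-independent equality on the measurement set."""

        def canon(t: CtTable) -> pd.DataFrame:
            return (
                t.data.sort_values(list(KEY_COLUMNS))
                .reset_index(drop=True)
                .astype({"user": "object"})
            )

        return canon(self).equals(canon(other))


def read_ct_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    undetermined: str = UNDETERMINED,
) -> CtTable:
    """Read a long-format CT table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional mapping from canonical column names (``platform``, ``run``,
        ``user``, ``sample``, ``mirna``, ``replicate``, ``ct``) to the column
        names actually present in the file, so arbitrary vendor layouts can
        be adapted without rewriting them.
    undetermined
        Sentinel string marking reactions with no signal.  Matched after
        whitespace stripping; empty cells are treated the same way.

    Raises
    ------
    CtTableFormatError
        Missing required column, or a CT cell that is neither numeric nor
        the sentinel (the error names the offending row).
    CtTableIntegrityError
        Duplicate (platform, run, sample, mirna, replicate) keys.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        rename = {src: canon for canon, src in dialect.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CtTableFormatError(f"{path.name}: missing required column(s): {missing}")

    ct_raw = raw["ct"].str.strip()
    is_undet = (ct_raw == "") | (ct_raw == undetermined)
    ct = pd.to_numeric(ct_raw.where(~is_undet), errors="coerce")
    unparsable = ~is_undet & ct.isna()
    if unparsable.any():
        row = int(unparsable.idxmax()) + 2  # header + 1-based
        raise CtTableFormatError(
            f"{path.name}: non-numeric CT {ct_raw[unparsable.idxmax()]!r} at row {row} "
            f"(not the sentinel {undetermined!r})"
        )
    df = raw.copy()
    df["ct"] = ct
    if "user" in df.columns:
        df["user"] = df["user"].replace("", pd.NA)
    return CtTable(df)


def write_ct_table(
    table: CtTable, path: str | Path, undetermined: str = UNDETERMINED
) -> None:
    """Write a :class:`CtTable` to CSV, restoring the undetermined sentinel."""
    df = table.data.copy()
    ct = df["ct"].map(lambda v: undetermined if pd.isna(v) else f"{v:.10g}")
    df["ct"] = ct
    df.to_csv(path, index=False)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis report as a flat CSV.

    Numeric columns are written with 6 significant digits, so reading the
    file back reproduces the report to that precision.  An empty report
    produces a header-only file.
    """
    if not isinstance(report, pd.DataFrame):
        report = pd.DataFrame(report)
    df = report.reset_index() if _meaningful_index(report) else report
    df.to_csv(path, index=False, float_format="%.6g")


def _meaningful_index(df: pd.DataFrame) -> bool:
    return not isinstance(df.index, pd.RangeIndex)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(path)


def collapse_replicates(table: CtTable, pool_runs: bool = True) -> pd.Series:
    """Mean determined CT per (platform, sample, mirna) cell.

    Undetermined replicates are skipped; a cell whose replicates are all
    undetermined collapses to NaN.  With ``pool_runs=False`` the run is kept
    as an extra key level.
    """
    keys = ["platform", "sample", "mirna"] if pool_runs else [
        "platform", "run", "sample", "mirna"
    ]
    return table.data.groupby(keys, sort=True)["ct"].mean()
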