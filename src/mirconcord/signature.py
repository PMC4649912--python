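"""Radar-style biomarker signature profiles and their comparison.

A signature profile places a fixed, ordered miRNA panel (>= 3 members) on
equally spaced radar axes and reads each axis at the panel member's value
(CT/CRT cycles, or normalized reads for sequencing data).  The shaded
polygon's area and its shape (correlation of axis values between two
profiles) summarize whether a signature — e.g. a 5-miRNA diabetic
retinopathy panel — retains its profile across platforms.

Because a lower CT means a higher abundance, an inverted radial scale
(max_ct - CT) is available for displays where the polygon should grow with
expression.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CtTable

__all__ = [
    "SignatureProfile",
    "ProfileComparison",
    "extract_signature",
    "radar_area",
    "compare_profiles",
    "plot_radar",
]


@dataclasses.dataclass(frozen=True)
class SignatureProfile:
    """Ordered panel values for one (platform, sample)."""

    panel: tuple
    values: tuple
    platform: object = None
    sample: object = None
    group: object = None  # e.g. "DR" / "NDR"

    def __post_init__(self) -> None:
        if len(self.panel) < 3:
            raise ValueError("a radar profile needs at least 3 axes")
        if len(self.values) != len(self.panel):
            raise ValueError("panel and values lengths differ")
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("profile values must be finite and non-negative")
        object.__setattr__(self, "panel", tuple(self.panel))
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    def inverted(self, max_value: float) -> "SignatureProfile":
        """Profile on the inverted scale ``max_value - v`` (higher =
        more abundant for CT input)."""
        vals = [max_value - v for v in self.values]
        if any(v < 0 for v in vals):
            raise ValueError("max_value smaller than a profile value")
        return dataclasses.replace(self, values=tuple(vals))


def extract_signature(
    table: CtTable, panel: Sequence, platform, sample
) -> SignatureProfile:
    """Panel profile for one platform and sample, replicates collapsed by mean.

    Raises a ``KeyError`` naming the first panel miRNA that is absent or
    entirely undetermined for that (platform, sample).
    """
    df = table.data
    sub = df[(df["platform"] == platform) & (df["sample"] == sample)]
    means = sub.groupby("mirna")["ct"].mean()
    values = []
    for m in panel:
        if m not in means.index or pd.isna(means[m]):
            raise KeyError(
                f"panel miRNA {m!r} missing/undetermined for platform "
                f"{platform!r}, sample {sample!r}"
            )
        values.append(float(means[m]))
    return SignatureProfile(panel=tuple(panel), values=tuple(values),
                            platform=platform, sample=sample)


def radar_area(profile) -> float:
    """Polygon area of a radar profile with axes at equal angles.

    For radii r_1..r_n on axes 2*pi/n apart the shaded polygon has area
    0.5 * sin(2*pi/n) * sum_i r_i * r_{i+1} (cyclically).  Invariant under
    cyclic rotation and reversal of the axis order, and quadratic under
    uniform scaling of the radii.
    """
    r = np.asarray(
        profile.values if isinstance(profile, SignatureProfile) else profile,
        dtype=float,
    )
    n = r.size
    if n < 3:
        raise ValueError("a radar polygon needs at least 3 axes")
    return float(0.5 * math.sin(2.0 * math.pi / n) * np.sum(r * np.roll(r, -1)))


@dataclasses.dataclass(frozen=True)
class ProfileComparison:
    """Area and shape agreement between two profiles on the same panel."""

    area_a: float
    area_b: float
    area_ratio: float
    shape_correlation: float  # NaN when undefined
    shape_correlation_defined: bool


def compare_profiles(a: SignatureProfile, b: SignatureProfile) -> ProfileComparison:
    """Compare two profiles sharing an identical, identically ordered panel.

    ``area_ratio = area_a / area_b`` (1 when both are zero; an error when
    only the denominator vanishes).  ``shape_correlation`` is the Pearson r
    across matched axes; a constant profile makes it undefined, which is
    flagged rather than raised.
    """
    if a.panel != b.panel:
        raise ValueError("profiles have different panels or axis orders")
    area_a, area_b = radar_area(a), radar_area(b)
    if area_b == 0.0:
        if area_a == 0.0:
            ratio = 1.0
        else:
            raise ZeroDivisionError("second profile has zero area")
    else:
        ratio = area_a / area_b
    va, vb = np.asarray(a.values), np.asarray(b.values)
    defined = bool(va.std() > 0 and vb.std() > 0)
    if defined:
        corr = float(np.corrcoef(va, vb)[0, 1])
    else:
        corr = float("nan")
    return ProfileComparison(
        area_a=float(area_a), area_b=float(area_b), area_ratio=float(ratio),
        shape_correlation=corr, shape_correlation_defined=defined,
    )


def plot_radar(profiles: Sequence[SignatureProfile], path=None, labels=None):
    """Optional radar plot of one or more profiles (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panel = profiles[0].panel
    n = len(panel)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for i, p in enumerate(profiles):
        if p.panel != panel:
            raise ValueError("profiles have different panels")
        vals = np.asarray(p.values)
        ang = np.concatenate([angles, angles[:1]])
        v = np.concatenate([vals, vals[:1]])
        lab = labels[i] if labels else str(p.platform)
        ax.plot(ang, v, label=lab)
        ax.fill(ang, v, alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(panel)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1))
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
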