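"""Stochastic simulator of multi-platform miRNA qPCR measurement.

The generator embodies the limiting-dilution physics that drives platform
differences at low template abundance: the number of template copies a
reaction receives is Poisson with mean

    lambda = concentration * reaction_volume / dilution_factor

so shrinking the reaction from microliters to nanoliters shrinks lambda
proportionally and stochastic dropout (zero copies) appears.  At a mean of
one copy per reaction ~37% of reactions receive no copy, ~37% one copy and
~18% two copies.

Measurement follows a log-linear CT model: a reaction with ``c`` copies is
pre-amplified deterministically to N = c * (1+E)^P effective copies
(E = per-cycle efficiency, P = pre-amplification cycles) and crosses
threshold at

    ct = ct_one_copy - log(N) / log(1+E) + run_shift + noise

with platform-specific Gaussian cycle noise, a Gaussian run-level offset
shared by all reactions of a (platform, run), and a hard detection limit:
reactions with zero copies or ct beyond ``max_cycles`` are undetermined.
With E = 1 every copy doubling lowers CT by exactly one cycle.

Defaults mirror a four-platform study: a 5 ul 96-well reference platform, a
1 ul microfluidic card, a 33 nl and a 15 nl nanoliter array (the latter with
16 pre-amplification cycles and a 1:10 dilution instead of 12 and 1:40),
42 miRNAs spanning ultra-high to low abundance in 4 samples, duplicate runs
and 4 replicates.  All randomness flows from one master seed via named
substreams, so identical configs reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import CtTable

__all__ = [
    "PlatformSpec",
    "TruthProfile",
    "SimulationConfig",
    "default_platforms",
    "default_truth_profile",
    "default_config",
    "poisson_pmf",
    "reaction_lambda",
    "simulate_copy_partition",
    "simulate_ct",
    "simulate_study",
]


@dataclasses.dataclass(frozen=True)
class PlatformSpec:
    """Physics of one qPCR platform.

    ``reaction_volume`` is in liters, ``noise_sd`` in cycles.  ``noise_sd``
    defaults were set so the simulated median replicate CVs fall where the
    four real platform classes fall (sub-percent for the 96-well plate,
    a few percent for the 33 nl array, high single digits for the card and
    the 15 nl array).
    """

    name: str
    reaction_volume: float
    preamp_cycles: int = 12
    dilution_factor: float = 40.0
    noise_sd: float = 0.3
    efficiency: float = 0.95

    def __post_init__(self) -> None:
        if self.reaction_volume <= 0:
            raise ValueError("reaction_volume must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_platforms() -> list[PlatformSpec]:
    """The four study platforms, largest to smallest reaction volume."""
    return [
        PlatformSpec("ViiA7", 5e-6, preamp_cycles=12, dilution_factor=40.0,
                     noise_sd=0.10),
        PlatformSpec("TLDA", 1e-6, preamp_cycles=12, dilution_factor=40.0,
                     noise_sd=1.20),
        PlatformSpec("OA", 33e-9, preamp_cycles=12, dilution_factor=40.0,
                     noise_sd=0.30),
        PlatformSpec("DA", 15e-9, preamp_cycles=16, dilution_factor=10.0,
                     noise_sd=1.50),
    ]


@dataclasses.dataclass(frozen=True)
class TruthProfile:
    """Ground-truth template concentrations per (miRNA, sample).

    ``concentrations`` (miRNA rows, sample columns) is in copies per liter
    of the pre-dilution pre-amplification product; each platform dilutes it
    by its own factor before partitioning into reactions.  ``clusters``
    optionally records the planted expression cluster of each miRNA.
    """

    concentrations: pd.DataFrame
    clusters: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.concentrations.to_numpy() < 0).any():
            raise ValueError("concentrations must be >= 0")

    @property
    def mirnas(self) -> list:
        return list(self.concentrations.index)

    @property
    def samples(self) -> list:
        return list(self.concentrations.columns)


def default_truth_profile(
    n_mirnas: int = 42,
    n_samples: int = 4,
    n_clusters: int = 4,
    seed: int = 0,
) -> TruthProfile:
    """Planted-cluster truth spanning ultra-high to low abundance.

    miRNAs are split evenly over ``n_clusters`` abundance bands (log10
    concentration 13-14, 11.5-12.5, 10-11 and 9-10 copies/l for the default
    four), and each cluster carries its own +/-1.5 log2 sample pattern plus
    0.25 log2 per-cell jitter — so samples separate the clusters beyond
    their abundance bands.  The lowest band reaches a mean of a few copies
    per nanoliter-scale reaction, where Poisson dropout becomes visible.
    """
    rng = np.random.default_rng(seed)
    bands = [(13.0, 14.0), (11.5, 12.5), (10.0, 11.0), (9.0, 10.0)]
    if n_clusters > len(bands):
        raise ValueError(f"at most {len(bands)} planted clusters supported")
    clusters = np.arange(n_mirnas) % n_clusters
    base = np.array([rng.uniform(*bands[c]) for c in clusters])
    archetypes = 1.5 * np.array(
        [[1, 1, -1, -1], [-1, -1, 1, 1], [1, -1, 1, -1], [-1, 1, -1, 1]],
        dtype=float,
    )
    reps = int(np.ceil(n_samples / archetypes.shape[1]))
    patterns = np.tile(archetypes, (1, reps))[:, :n_samples]
    jitter = rng.normal(0.0, 0.25, size=(n_mirnas, n_samples))
    conc = 10.0 ** base[:, None] * 2.0 ** (patterns[clusters] + jitter)
    mirnas = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    samples = (["islet1", "islet2", "serum1", "serum2"][:n_samples]
               if n_samples <= 4 else [f"sample{i + 1}" for i in range(n_samples)])
    return TruthProfile(
        concentrations=pd.DataFrame(conc, index=mirnas, columns=samples),
        clusters=pd.Series(clusters + 1, index=mirnas, name="cluster"),
    )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full study design: platforms, truth, replication and the CT model."""

    platforms: Sequence[PlatformSpec]
    truth: TruthProfile
    replicates: int = 4
    runs: int = 2
    run_shift_sd: float = 0.5
    ct_one_copy: float = 45.0
    max_cycles: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be > 0")
        if self.replicates < 1 or self.runs < 1:
            raise ValueError("replicates and runs must be >= 1")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default four-platform study configuration under one master seed."""
    truth = overrides.pop("truth", None)
    if truth is None:
        truth = default_truth_profile(
            n_mirnas=overrides.pop("n_mirnas", 42),
            n_samples=overrides.pop("n_samples", 4),
            seed=seed,
        )
    platforms = overrides.pop("platforms", default_platforms())
    return SimulationConfig(platforms=platforms, truth=truth, seed=seed,
                            **overrides)


# ---------------------------------------------------------------------------
# Poisson partitioning


def poisson_pmf(k, lam):
    """P(copies = k) for Poisson-distributed template with mean ``lam``.

    ``k`` must be a non-negative integer (arrays allowed), ``lam >= 0``.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 0) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must be a non-negative integer")
    if np.any(lam_arr < 0):
        raise ValueError("lam must be >= 0")
    out = _sps.poisson.pmf(k_arr, lam_arr)
    return float(out) if np.isscalar(k) and np.isscalar(lam) else out


def reaction_lambda(concentration, spec: PlatformSpec):
    """Mean template copies per reaction on a platform.

    ``concentration * reaction_volume / dilution_factor``: the shared
    sample has one concentration; each platform dilutes it by its own
    factor and partitions its own reaction volume.
    """
    return np.asarray(concentration, dtype=float) * spec.reaction_volume / spec.dilution_factor


def simulate_copy_partition(lam: float, n_rxn: int, seed) -> np.ndarray:
    """Independent Poisson(lam) copy counts for ``n_rxn`` reactions.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if n_rxn < 1:
        raise ValueError("n_rxn must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(lam, size=int(n_rxn))


def _noiseless_ct(copies, spec: PlatformSpec, ct_one_copy: float) -> np.ndarray:
    """CT of each reaction before noise; NaN where no copies landed."""
    c = np.asarray(copies, dtype=float)
    log_gain = spec.preamp_cycles  # in units of log_(1+E)
    with np.errstate(divide="ignore"):
        ct = ct_one_copy - (np.log(c) / np.log1p(spec.efficiency) + log_gain)
    return np.where(c > 0, ct, np.nan)


def simulate_ct(
    copies,
    spec: PlatformSpec,
    ct_one_copy: float = 45.0,
    rng: np.random.Generator | None = None,
    max_cycles: float = 40.0,
):
    """Measured CT for reaction copy counts on one platform.

    Zero copies are undetermined (NaN); otherwise the log-linear model with
    deterministic pre-amplification gain applies, plus Gaussian cycle noise
    when ``rng`` is given and ``spec.noise_sd > 0``.  CTs beyond
    ``max_cycles`` fall outside the detection window and come back NaN.
    """
    scalar = np.isscalar(copies)
    c = np.atleast_1d(np.asarray(copies))
    if np.any(c < 0):
        raise ValueError("copies must be >= 0")
    ct = _noiseless_ct(c, spec, ct_one_copy)
    if rng is not None and spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, size=ct.shape)
    ct = np.where(ct > max_cycles, np.nan, ct)
    return float(ct[0]) if scalar else ct


def simulate_study(config: SimulationConfig) -> tuple[CtTable, pd.DataFrame]:
    """Simulate the full multi-platform study.

    Returns the measurement table plus a ground-truth ledger with one row
    per reaction recording lambda, the Poisson copy count, the noiseless CT
    and the reported CT (NaN = undetermined).  Identical configs (seed
    included) produce identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_part, rng_noise, rng_shift = (np.random.default_rng(s) for s in ss.spawn(3))
    truth = config.truth
    conc = truth.concentrations.to_numpy()  # (n_mir, n_samp)
    n_mir, n_samp = conc.shape
    reps, runs = config.replicates, config.runs
    frames = []
    for spec in config.platforms:
        lam = reaction_lambda(conc, spec)  # (n_mir, n_samp)
        for run_idx in range(1, runs + 1):
            shift = rng_shift.normal(0.0, config.run_shift_sd) if config.run_shift_sd > 0 else 0.0
            copies = rng_part.poisson(lam[:, :, None], size=(n_mir, n_samp, reps))
            ct0 = _noiseless_ct(copies, spec, config.ct_one_copy)
            noise = rng_noise.normal(0.0, spec.noise_sd, size=ct0.shape) if spec.noise_sd > 0 else 0.0
            ct = ct0 + shift + noise
            ct = np.where(ct > config.max_cycles, np.nan, ct)
            idx = pd.MultiIndex.from_product(
                [truth.mirnas, truth.samples, range(1, reps + 1)],
                names=["mirna", "sample", "replicate"],
            )
            frame = pd.DataFrame(
                {
                    "lam": np.repeat(lam.ravel(), reps),
                    "copies": copies.ravel(),
                    "ct_noiseless": ct0.ravel(),
                    "ct": ct.ravel(),
                },
                index=idx,
            ).reset_index()
            frame.insert(0, "platform", spec.name)
            frame.insert(1, "run", f"run{run_idx}")
            frame.insert(2, "user", f"user{run_idx}")
            frames.append(frame)
    ledger = pd.concat(frames, ignore_index=True)
    table = CtTable(
        ledger[["platform", "run", "user", "sample", "mirna", "replicate", "ct"]]
    )
    return table, ledger
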