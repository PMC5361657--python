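"""Channel arithmetic, replicate aggregation and growth thresholding.

Two-channel processing: the 490 nm read tracks respiration through
irreversible formazan accumulation, the 750 nm read tracks turbidity (hyphal
density). Because hyaline mycelium absorbs evenly from 490 to 750 nm, the
turbidity signal is subtracted from the redox read to give a corrected
respiration value, A_c490 = A_490 - A_750. Growth on a substrate is called
measurable when the day-7 replicate-mean turbidity lies strictly above 0.3
and at most 3.0 (the upper bound is ~99.9% light absorbance; the lower bound
separates cultures still in lag phase from those that reached log phase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plate_data import (
    DEFAULT_TIME_GRID,
    WAVELENGTH_REDOX,
    WAVELENGTH_TURBIDITY,
    KineticDataset,
    PlateLayout,
)

__all__ = [
    "GrowthThresholds",
    "corrected_absorbance",
    "replicate_mean",
    "is_measurable",
    "endpoint_matrix",
    "kendall_tau",
    "channel_correlation",
]


@dataclass(frozen=True)
class GrowthThresholds:
    """Measurable-growth bounds and the endpoint used for inference.

    ``lower`` is strict and ``upper`` inclusive: measurable means
    ``lower < a <= upper``. The endpoint day defaults to 7.0, the time point
    at which the global strain difference is largest; ``alpha`` is the
    significance level applied to adjusted p-values.
    """

    lower: float = 0.3
    upper: float = 3.0
    endpoint_day: float = 7.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ValueError("thresholds must satisfy 0 <= lower < upper")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def corrected_absorbance(a490, a750):
    """Corrected redox absorbance A_c490 = A_490 - A_750.

    Accepts scalars or arrays; negative results are preserved (clamping, where
    a downstream method needs nonnegative input, happens there).
    """
    a490 = np.asarray(a490, dtype=float)
    a750 = np.asarray(a750, dtype=float)
    if not (np.isfinite(a490).all() and np.isfinite(a750).all()):
        raise ValueError("absorbance inputs must be finite")
    out = a490 - a750
    return float(out) if out.ndim == 0 else out


def replicate_mean(
    dataset: KineticDataset, strain: str, well: str, wavelength: int, time: float
) -> float:
    """Mean absorbance over replicate plates at one coordinate."""
    return float(dataset.replicate_values(strain, well, wavelength, time).mean())


def is_measurable(a: float, thresholds: GrowthThresholds = GrowthThresholds()) -> bool:
    """Strict-lower / inclusive-upper measurable-growth test."""
    if not math.isfinite(a):
        raise ValueError("absorbance must be finite")
    return thresholds.lower < a <= thresholds.upper


def endpoint_matrix(
    dataset: KineticDataset,
    layout: PlateLayout,
    wavelength: int = WAVELENGTH_TURBIDITY,
    time: float | None = None,
    include_water: bool = False,
) -> pd.DataFrame:
    """Per-plate substrate profile at one wavelength and time point.

    Returns a table with one row per (strain, replicate) plate and one column
    per non-control substrate (95 columns; 96 with ``include_water``), holding
    the raw per-plate absorbance. This is the sample x substrate matrix the
    distance-based global statistics operate on.
    """
    if time is None:
        time = dataset.time_grid[-1]
    if time not in dataset.time_grid:
        raise ValueError(f"time {time} is not on the read grid {dataset.time_grid}")
    f = dataset.frame
    sel = f[(f["wavelength"] == wavelength) & (f["time_d"] == time)]
    wide = sel.pivot_table(
        index=["strain", "replicate"], columns="well", values="absorbance"
    )
    keep = [w.well_id for w in layout.wells if include_water or not w.is_control]
    wide = wide[keep]
    wide.columns = [layout.substrate_of(w) for w in keep]
    # deterministic row order: strains in dataset order, replicates ascending
    order = [
        (s, r)
        for s in dataset.strains
        for r in range(1, dataset.n_rep + 1)
        if (s, r) in wide.index
    ]
    return wide.loc[order]


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b (mid-ranks for ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs for a correlation")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def channel_correlation(
    dataset: KineticDataset,
    layout: PlateLayout,
    time: float | None = None,
    log: bool = False,
) -> tuple[float, float]:
    """Kendall's tau-b between corrected redox and turbidity channels.

    Pairs are replicate-mean (A_c490, A_750) values per strain x substrate,
    pooled over the whole time course by default (pass ``time`` to restrict
    to one read). ``log`` applies a log transform first, which requires
    strictly positive pairs; being a rank statistic, tau is unchanged by it.

    Returns ``(tau, p_value)``.
    """
    times = dataset.time_grid if time is None else (time,)
    substrates = [w.well_id for w in layout.wells if not w.is_control]
    f = dataset.frame
    sel = f[f["time_d"].isin(times) & f["well"].isin(substrates)]
    means = sel.pivot_table(
        index=["strain", "well", "time_d"], columns="wavelength", values="absorbance",
        aggfunc="mean",
    )
    a750 = means[WAVELENGTH_TURBIDITY].to_numpy(dtype=float)
    ac490 = means[WAVELENGTH_REDOX].to_numpy(dtype=float) - a750
    if len(a750) < 2:
        raise ValueError("need at least 2 channel pairs for a correlation")
    if log:
        if (a750 <= 0).any() or (ac490 <= 0).any():
            raise ValueError("log transform requires strictly positive channel pairs")
        ac490, a750 = np.log(ac490), np.log(a750)
    return kendall_tau(ac490, a750)
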