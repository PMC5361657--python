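"""Seeded generator of two-strain phenotype-array kinetic datasets.

Emulates the study design: five replicate plates per strain, 96 wells (95
substrates + water control), read at two wavelengths every 12 hours for seven
days. Each substrate carries a planted outcome archetype: a logistic growth
curve per strain (baseline + K / (1 + exp(-r (t - t_mid)))) whose carrying
capacities encode the intended endpoint classification, observed through
additive Gaussian noise truncated at zero (plate readers report nonnegative
optical density). The redox channel is modeled as turbidity plus a gain times
cumulative growth, the simplest monotone coupling consistent with
irreversible formazan accumulation; its noiseless corrected value is
therefore nondecreasing in time.

Default condition values: noise SD 0.03 absorbance units, strain effect
(carrying-capacity gap) 0.3 for the directional outcomes -- the average
day-7 difference observed on significantly different substrates -- and a
planted outcome composition of 17 negligible-both, 15 no-difference, 2
infected-only, 5 cured-higher and 56 infected-higher substrates, echoing the
endpoint census of the study this package models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plate_data import (
    DEFAULT_TIME_GRID,
    STRAIN_MINUS,
    STRAIN_PLUS,
    WAVELENGTH_REDOX,
    WAVELENGTH_TURBIDITY,
    KineticDataset,
    PlateLayout,
    ff_plate_layout,
)

__all__ = [
    "SubstrateArchetype",
    "SimulationConfig",
    "DEFAULT_OUTCOME_COMPOSITION",
    "logistic_curve",
    "default_archetypes",
    "null_archetypes",
    "generate_dataset",
    "planted_truth_frame",
]

#: Planted outcome code -> number of substrates, summing to 95.
DEFAULT_OUTCOME_COMPOSITION: dict[int, int] = {1: 17, 2: 15, 3: 2, 4: 5, 5: 56}

#: Carrying capacity at or below which a strain stays negligible
#: (baseline 0.1 + K 0.15 = endpoint 0.25 < 0.3).
NEGLIGIBLE_K = 0.15


@dataclass(frozen=True)
class SubstrateArchetype:
    """Planted growth parameters for one substrate.

    ``outcome`` is the intended endpoint classification code (1..5);
    ``k_plus``/``k_minus`` are the logistic carrying capacities of the
    infected and cured strains (absorbance units), ``r`` the growth rate per
    day, ``t_mid`` the inflection day and ``baseline`` the no-growth optical
    density of the inoculated well.
    """

    outcome: int
    k_plus: float
    k_minus: float
    r: float = 2.0
    t_mid: float = 3.0
    baseline: float = 0.1

    def __post_init__(self) -> None:
        if self.k_plus < 0 or self.k_minus < 0:
            raise ValueError("carrying capacities must be nonnegative")
        if self.r <= 0:
            raise ValueError("growth rate must be positive")

    def k(self, strain: str) -> float:
        return self.k_plus if strain == STRAIN_PLUS else self.k_minus


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic experiment."""

    archetypes: dict[str, SubstrateArchetype]
    n_rep: int = 5
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    noise_sd: float = 0.03
    redox_gain: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("need at least one replicate plate")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.redox_gain < 0:
            raise ValueError("redox gain must be nonnegative")
        if len(self.archetypes) != 96:
            raise ValueError(
                f"archetype map must cover 95 substrates + control, got {len(self.archetypes)}"
            )


def logistic_curve(t, k: float, r: float, t_mid: float, baseline: float):
    """Three-phase growth curve baseline + K / (1 + exp(-r (t - t_mid))).

    The lag, log and stationary phases of the culture correspond to the flat
    start, the rise around ``t_mid`` and the plateau at ``baseline + K``;
    ``K = 0`` gives the constant-baseline control well.
    """
    t = np.asarray(t, dtype=float)
    out = baseline + k / (1.0 + np.exp(-r * (t - t_mid)))
    return float(out) if out.ndim == 0 else out


def _effect_archetype(
    code: int, base_k: float, effect_size: float
) -> SubstrateArchetype:
    if code == 1:
        return SubstrateArchetype(outcome=1, k_plus=0.05, k_minus=0.05)
    if code == 2:
        return SubstrateArchetype(outcome=2, k_plus=base_k, k_minus=base_k)
    if code == 3:
        return SubstrateArchetype(outcome=3, k_plus=0.55, k_minus=0.05)
    if code == 4:
        return SubstrateArchetype(outcome=4, k_plus=base_k, k_minus=base_k + effect_size)
    if code == 5:
        return SubstrateArchetype(outcome=5, k_plus=base_k + effect_size, k_minus=base_k)
    raise ValueError(f"unknown outcome code {code}")


def default_archetypes(
    layout: PlateLayout | None = None,
    effect_size: float = 0.3,
    composition: dict[int, int] = DEFAULT_OUTCOME_COMPOSITION,
    seed: int = 0,
) -> dict[str, SubstrateArchetype]:
    """Planted archetypes for every well of the layout.

    Outcome codes follow ``composition`` (default mix above) and are assigned
    to substrates in a seeded shuffle; measurable base carrying capacities
    are drawn uniformly from [0.6, 1.8] so endpoint densities span the range
    seen on real plates while staying clear of both growth bounds. The water
    control gets K = 0.
    """
    layout = layout or ff_plate_layout()
    if sum(composition.values()) != 95:
        raise ValueError("outcome composition must cover exactly 95 substrates")
    rng = np.random.default_rng(seed)
    codes = [c for c, n in sorted(composition.items()) for _ in range(n)]
    codes = list(rng.permutation(codes))
    archetypes: dict[str, SubstrateArchetype] = {}
    for well in layout.wells:
        if well.is_control:
            archetypes[well.substrate] = SubstrateArchetype(
                outcome=1, k_plus=0.0, k_minus=0.0
            )
            continue
        code = int(codes.pop())
        base_k = float(rng.uniform(0.6, 1.8))
        archetypes[well.substrate] = _effect_archetype(code, base_k, effect_size)
    return archetypes


def null_archetypes(
    layout: PlateLayout | None = None, seed: int = 0
) -> dict[str, SubstrateArchetype]:
    """Archetypes with no strain effect anywhere (k_plus == k_minus).

    Keeps the default mix of growing and negligible substrates so null
    datasets still look like plates, but every apparent strain difference is
    noise. Used for type-I-error calibration of the global scan.
    """
    composition = {
        1: DEFAULT_OUTCOME_COMPOSITION[1],
        2: 95 - DEFAULT_OUTCOME_COMPOSITION[1],
    }
    return default_archetypes(layout, effect_size=0.0, composition=composition, seed=seed)


def generate_dataset(
    config: SimulationConfig, layout: PlateLayout | None = None
) -> tuple[KineticDataset, pd.DataFrame]:
    """Simulate a full two-strain kinetic experiment.

    Per strain/replicate/well series: A_750(t) is the archetype's logistic
    curve plus truncated Gaussian noise; A_490(t) adds the redox coupling
    ``gain * (curve(t) - baseline)`` plus its own noise, so with zero gain
    and zero noise the two channels coincide. Identical seeds give
    bit-identical datasets. Returns the dataset and the planted-truth table.
    """
    layout = layout or ff_plate_layout()
    missing = [w.substrate for w in layout.wells if w.substrate not in config.archetypes]
    if missing:
        raise ValueError(f"archetype map missing substrates, e.g. {missing[:3]}")
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.time_grid, dtype=float)
    records = []
    for strain in (STRAIN_PLUS, STRAIN_MINUS):
        for rep in range(1, config.n_rep + 1):
            for well in layout.wells:
                arch = config.archetypes[well.substrate]
                curve = logistic_curve(t, arch.k(strain), arch.r, arch.t_mid, arch.baseline)
                a750 = np.clip(curve + rng.normal(0, config.noise_sd, t.size), 0, None)
                redox = config.redox_gain * (curve - arch.baseline)
                a490 = np.clip(
                    a750 + redox + rng.normal(0, config.noise_sd, t.size), 0, None
                )
                for lam, series in (
                    (WAVELENGTH_TURBIDITY, a750),
                    (WAVELENGTH_REDOX, a490),
                ):
                    for ti, value in zip(t, series):
                        records.append(
                            (strain, rep, well.well_id, lam, float(ti), float(value))
                        )
    frame = pd.DataFrame(
        records,
        columns=["strain", "replicate", "well", "wavelength", "time_d", "absorbance"],
    )
    dataset = KineticDataset(
        frame=frame,
        time_grid=tuple(float(x) for x in t),
        n_rep=config.n_rep,
    )
    return dataset, planted_truth_frame(config, layout)


def planted_truth_frame(
    config: SimulationConfig, layout: PlateLayout | None = None
) -> pd.DataFrame:
    """Sidecar table of planted outcome codes and growth parameters."""
    layout = layout or ff_plate_layout()
    rows = []
    for well in layout.wells:
        arch = config.archetypes[well.substrate]
        rows.append(
            {
                "well": well.well_id,
                "substrate": well.substrate,
                "is_control": well.is_control,
                "planted_outcome": arch.outcome,
                "k_plus": arch.k_plus,
                "k_minus": arch.k_minus,
                "r": arch.r,
                "t_mid": arch.t_mid,
                "baseline": arch.baseline,
            }
        )
    return pd.DataFrame(rows)
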