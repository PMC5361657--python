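"""Domain types, file I/O and packaged fixtures for FF phenotype-microarray data.

The Biolog FF plate is a 96-well microtiter plate carrying 95 unique carbon
sources plus one water control. Kinetic reads are absorbance values at two
wavelengths (490 nm, respiration via formazan accumulation; 750 nm, turbidity
as a proxy for hyphal density) on a 12-hour grid over seven days, for five
replicate plates of each of two strains: the naturally infected fungus
("EHB+") and its antibiotic-cured clone ("EHB-").
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRAIN_PLUS",
    "STRAIN_MINUS",
    "WAVELENGTH_REDOX",
    "WAVELENGTH_TURBIDITY",
    "DEFAULT_TIME_GRID",
    "Well",
    "PlateLayout",
    "KineticDataset",
    "SubstrateSummary",
    "Outcome",
    "GlobalComparison",
    "ff_plate_layout",
    "read_kinetic_csv",
    "write_kinetic_csv",
    "load_table1_fixture",
    "write_summary_tsv",
    "read_summary_tsv",
]

STRAIN_PLUS = "EHB+"
STRAIN_MINUS = "EHB-"
STRAINS = (STRAIN_PLUS, STRAIN_MINUS)

WAVELENGTH_REDOX = 490
WAVELENGTH_TURBIDITY = 750
WAVELENGTHS = (WAVELENGTH_REDOX, WAVELENGTH_TURBIDITY)

#: 12-hour reads from half a day to seven days: 14 time points.
DEFAULT_TIME_GRID: tuple[float, ...] = tuple(np.arange(1, 15) * 0.5)

#: Highest raw absorbance the instrument can meaningfully report; values above
#: are kept but flagged by :meth:`KineticDataset.flag_saturated`.
SATURATION_BOUND = 3.0

_FIXTURE_NAME = "ff_table1.tsv"
_FIXTURE_SHA256 = "e5722e4824acc7fbe784efcf4f2a293822d7fac7073dbd72975aa736d537f4b3"

_WELL_IDS = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Well:
    """One well of the 96-well array."""

    well_id: str
    substrate: str
    substrate_class: str
    is_control: bool = False


@dataclass(frozen=True)
class PlateLayout:
    """Map from well id to substrate identity for one plate type.

    Exactly 96 wells, of which exactly one is the water control; the 95
    remaining substrate names are unique. Only substrate identity enters any
    downstream computation, so the physical ordering of wells is a packaging
    convention (substrates are laid out A1..H12 in the order of the endpoint
    summary table, water last).
    """

    wells: tuple[Well, ...]

    def __post_init__(self) -> None:
        if len(self.wells) != 96:
            raise ValueError(f"plate layout must have 96 wells, got {len(self.wells)}")
        controls = [w for w in self.wells if w.is_control]
        if len(controls) != 1:
            raise ValueError("plate layout must have exactly one control well")
        names = [w.substrate for w in self.wells if not w.is_control]
        if len(set(names)) != 95:
            raise ValueError("plate layout must have 95 unique substrate names")

    @property
    def well_ids(self) -> tuple[str, ...]:
        return tuple(w.well_id for w in self.wells)

    @property
    def substrates(self) -> tuple[str, ...]:
        """Non-control substrate names in layout order."""
        return tuple(w.substrate for w in self.wells if not w.is_control)

    @property
    def control_well(self) -> Well:
        return next(w for w in self.wells if w.is_control)

    def well(self, well_id: str) -> Well:
        try:
            return next(w for w in self.wells if w.well_id == well_id)
        except StopIteration:
            raise KeyError(f"unknown well id {well_id!r}") from None

    def substrate_of(self, well_id: str) -> str:
        return self.well(well_id).substrate

    def class_of(self, substrate: str) -> str:
        for w in self.wells:
            if w.substrate == substrate:
                return w.substrate_class
        raise KeyError(f"unknown substrate {substrate!r}")


def ff_plate_layout() -> PlateLayout:
    """The packaged FF-plate layout (95 carbon sources + water control).

    Substrates are assigned to wells A1..H12 in the order of the packaged
    endpoint summary fixture, with the water control in H12.
    """
    rows = _read_fixture_frame()
    wells = []
    for well_id, row in zip(_WELL_IDS, rows.itertuples(index=False)):
        wells.append(
            Well(
                well_id=well_id,
                substrate=row.substrate,
                substrate_class=row.substrate_class,
                is_control=row.substrate == "water",
            )
        )
    return PlateLayout(wells=tuple(wells))


# ---------------------------------------------------------------------------
# kinetic dataset
# ---------------------------------------------------------------------------

_KINETIC_COLUMNS = ["strain", "replicate", "well", "wavelength", "time_d", "absorbance"]


@dataclass
class KineticDataset:
    """Long-format kinetic absorbance readings.

    One row of :attr:`frame` per (strain, replicate plate, well, wavelength,
    time point). Every series must cover the full time grid at both
    wavelengths; absorbance is finite and nonnegative, and raw values above
    the saturation bound are retained but can be flagged.
    """

    frame: pd.DataFrame
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    n_rep: int = 5
    strains: tuple[str, ...] = STRAINS

    def __post_init__(self) -> None:
        missing = [c for c in _KINETIC_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"kinetic frame missing columns {missing}")
        if not np.isfinite(self.frame["absorbance"].to_numpy()).all():
            raise ValueError("kinetic frame contains non-finite absorbance values")

    @property
    def wells(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["well"].unique()))

    def validate_complete(self, layout: PlateLayout) -> None:
        """Check that every series covers the full grid; raise listing gaps."""
        known = set(layout.well_ids)
        unknown = set(self.frame["well"].unique()) - known
        if unknown:
            raise ValueError(f"unknown well ids: {sorted(unknown)}")
        expected = {
            (s, r, w, lam, t)
            for s in self.strains
            for r in range(1, self.n_rep + 1)
            for w in layout.well_ids
            for lam in WAVELENGTHS
            for t in self.time_grid
        }
        seen = set(
            zip(
                self.frame["strain"],
                self.frame["replicate"],
                self.frame["well"],
                self.frame["wavelength"],
                self.frame["time_d"],
            )
        )
        gaps = sorted(expected - seen)
        if gaps:
            head = ", ".join(f"{w}/{t:g} ({s} rep {r}, {lam} nm)" for s, r, w, lam, t in gaps[:5])
            raise ValueError(f"{len(gaps)} missing readings, e.g. {head}")

    def value(self, strain: str, replicate: int, well: str, wavelength: int, time: float) -> float:
        f = self.frame
        sel = f[
            (f["strain"] == strain)
            & (f["replicate"] == replicate)
            & (f["well"] == well)
            & (f["wavelength"] == wavelength)
            & (f["time_d"] == time)
        ]
        if sel.empty:
            raise KeyError(f"no reading for {strain} rep {replicate} {well} {wavelength} nm at {time} d")
        return float(sel["absorbance"].iloc[0])

    def replicate_values(
        self, strain: str, well: str, wavelength: int, time: float
    ) -> np.ndarray:
        """All replicate readings at one coordinate, ordered by replicate id."""
        f = self.frame
        sel = f[
            (f["strain"] == strain)
            & (f["well"] == well)
            & (f["wavelength"] == wavelength)
            & (f["time_d"] == time)
        ].sort_values("replicate")
        if len(sel) != self.n_rep:
            raise ValueError(
                f"expected {self.n_rep} replicates for {strain} {well} "
                f"{wavelength} nm at {time} d, found {len(sel)}"
            )
        return sel["absorbance"].to_numpy(dtype=float)

    def flag_saturated(self, bound: float = SATURATION_BOUND) -> pd.DataFrame:
        """Rows whose raw absorbance exceeds the saturation bound."""
        return self.frame[self.frame["absorbance"] > bound]


def read_kinetic_csv(path: str | Path, layout: PlateLayout) -> KineticDataset:
    """Read long-format kinetic CSV and validate it against the plate layout.

    The file must carry the header ``strain,replicate,well,wavelength,time_d,
    absorbance``. Missing cells, unknown well ids and non-numeric absorbance
    values are reported as errors.
    """
    frame = pd.read_csv(
        path, dtype={"strain": str, "well": str}, float_precision="round_trip"
    )
    missing = [c for c in _KINETIC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = pd.to_numeric(frame["absorbance"], errors="coerce")
    if bad.isna().any():
        # +2: header line and 1-based numbering
        lines = (np.flatnonzero(bad.isna().to_numpy()) + 2).tolist()
        raise ValueError(f"{path}: non-numeric absorbance on line(s) {lines[:5]}")
    frame["absorbance"] = bad.astype(float)
    frame["replicate"] = frame["replicate"].astype(int)
    frame["wavelength"] = frame["wavelength"].astype(int)
    frame["time_d"] = frame["time_d"].astype(float)

    time_grid = tuple(sorted(frame["time_d"].unique()))
    n_rep = int(frame["replicate"].max())
    strains = tuple(dict.fromkeys(frame["strain"]))
    ds = KineticDataset(frame=frame, time_grid=time_grid, n_rep=n_rep, strains=strains)
    ds.validate_complete(layout)
    return ds


def write_kinetic_csv(dataset: KineticDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False, columns=_KINETIC_COLUMNS)


# ---------------------------------------------------------------------------
# endpoint summaries (Table-1-style rows)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Outcome:
    """Five-way classification of one substrate's strain comparison.

    Codes: 1 negligible growth by both strains; 2 measurable by both with no
    difference; 3 measurable by the infected (EHB+) strain only; 4 the cured
    (EHB-) strain denser; 5 the infected strain denser. The undefined mirror
    of code 3 (measurable by the cured strain only) is reported as code 4 with
    :attr:`mirror` set.
    """

    code: int
    mirror: bool = False

    def __post_init__(self) -> None:
        if self.code not in (1, 2, 3, 4, 5):
            raise ValueError(f"outcome code must be 1..5, got {self.code}")


@dataclass
class SubstrateSummary:
    """One row of the endpoint comparison table (day-7 turbidity means).

    ``p_adj`` is the Benjamini-Hochberg adjusted two-sided Welch p-value;
    it is absent (None) for substrates that were negligible for both strains
    and therefore never tested. ``p_adj_text`` preserves the printed rendering
    (e.g. ``<0.00001``) when the row comes from the packaged transcription.
    """

    substrate: str
    substrate_class: str
    mean_plus: float
    sd_plus: float
    mean_minus: float
    sd_minus: float
    t: float | None = None
    df: float | None = None
    p_raw: float | None = None
    p_adj: float | None = None
    p_adj_text: str | None = None
    outcome: Outcome | None = None

    def __post_init__(self) -> None:
        if self.sd_plus < 0 or self.sd_minus < 0:
            raise ValueError("standard deviations must be nonnegative")
        for p in (self.p_raw, self.p_adj):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range: {p}")

    @property
    def significant(self) -> bool:
        """Whether the adjusted p-value falls below 0.05 (strict)."""
        return self.p_adj is not None and self.p_adj < 0.05


@dataclass(frozen=True)
class GlobalComparison:
    """Distance-based whole-plate comparison at one time point."""

    time: float
    permanova_F: float
    permanova_R2: float
    permanova_p: float
    anosim_R: float
    anosim_p: float
    mrpp_A: float
    mrpp_p: float
    n_perm: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.permanova_R2 <= 1 + 1e-9:
            raise ValueError("R2 must lie in [0, 1]")
        if not -1 - 1e-9 <= self.anosim_R <= 1 + 1e-9:
            raise ValueError("ANOSIM R must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# packaged Table 1 transcription
# ---------------------------------------------------------------------------

def _fixture_bytes() -> bytes:
    return resources.files("ffpm.fixtures").joinpath(_FIXTURE_NAME).read_bytes()


def _read_fixture_frame() -> pd.DataFrame:
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"packaged fixture {_FIXTURE_NAME} checksum mismatch: {digest}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype=str, keep_default_na=False)


def _parse_p_text(text: str) -> float | None:
    if text == "NA":
        return None
    if text.startswith("<"):
        return float(text[1:])
    return float(text)


def load_table1_fixture() -> list[SubstrateSummary]:
    """Load the packaged transcription of the published day-7 endpoint table.

    96 rows (95 substrates + water control) at printed precision, including
    the rows whose adjusted p is printed as ``NA`` (both strains negligible,
    never tested). ``<x`` entries are parsed as the printed upper bound ``x``
    with the original text preserved in ``p_adj_text``.
    """
    frame = _read_fixture_frame()
    rows: list[SubstrateSummary] = []
    for rec in frame.itertuples(index=False):
        p_adj = _parse_p_text(rec.p_adj)
        rows.append(
            SubstrateSummary(
                substrate=rec.substrate,
                substrate_class=rec.substrate_class,
                mean_plus=float(rec.mean_plus),
                sd_plus=float(rec.sd_plus),
                mean_minus=float(rec.mean_minus),
                sd_minus=float(rec.sd_minus),
                t=float(rec.t),
                df=float(rec.df),
                p_adj=p_adj,
                p_adj_text=rec.p_adj if rec.p_adj != "NA" else None,
                outcome=Outcome(code=int(rec.outcome)),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# summary TSV I/O
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = [
    "substrate",
    "substrate_class",
    "mean_plus",
    "sd_plus",
    "mean_minus",
    "sd_minus",
    "t",
    "df",
    "p_adj",
    "outcome",
]


def _fmt(value: float | None) -> str:
    if value is None:
        return "NA"
    return f"{value:g}"


def write_summary_tsv(rows: Sequence[SubstrateSummary], path: str | Path) -> None:
    """Write endpoint summaries as a TSV mirroring the endpoint-table columns.

    Absent adjusted p-values are rendered as ``NA``; values transcribed as an
    upper bound keep their ``<x`` rendering.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("cannot write an empty summary table")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
        for row in rows:
            if row.p_adj_text is not None:
                p_text = row.p_adj_text
            else:
                p_text = _fmt(row.p_adj)
            fields = [
                row.substrate,
                row.substrate_class,
                _fmt(row.mean_plus),
                _fmt(row.sd_plus),
                _fmt(row.mean_minus),
                _fmt(row.sd_minus),
                _fmt(row.t),
                _fmt(row.df),
                p_text,
                str(row.outcome.code) if row.outcome is not None else "NA",
            ]
            fh.write("\t".join(fields) + "\n")


def read_summary_tsv(path: str | Path) -> list[SubstrateSummary]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows: list[SubstrateSummary] = []
    for rec in frame.itertuples(index=False):
        p_adj = _parse_p_text(rec.p_adj)
        rows.append(
            SubstrateSummary(
                substrate=rec.substrate,
                substrate_class=rec.substrate_class,
                mean_plus=float(rec.mean_plus),
                sd_plus=float(rec.sd_plus),
                mean_minus=float(rec.mean_minus),
                sd_minus=float(rec.sd_minus),
                t=None if rec.t == "NA" else float(rec.t),
                df=None if rec.df == "NA" else float(rec.df),
                p_adj=p_adj,
                p_adj_text=rec.p_adj if rec.p_adj.startswith("<") else None,
                outcome=None if rec.outcome == "NA" else Outcome(code=int(rec.outcome)),
            )
        )
    return rows
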