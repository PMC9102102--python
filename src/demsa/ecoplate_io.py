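"""Reading, validation and blank correction of Biolog EcoPlate data.

A Biolog EcoPlate is a 96-well microplate carrying 31 carbon substrates plus
a water blank, each in triplicate: the plate is divided into three 32-well
blocks (columns 1-4, 5-8 and 9-12), and within a block the substrates run
column-major from row A to row H, starting with water in the top-left well
of the block (A1, A5, A9).  Microbial respiration reduces a tetrazolium dye
and is read as optical density at 590 nm.

This module knows the fixed substrate -> code -> guild catalog, the plate
geometry, the two supported CSV dialects (grid and long), the water-blank
correction, and the choice of the analysis timepoint.  Everything downstream
works on :class:`SampleProfile` objects: one blank-corrected response per
coded substrate.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("demsa")

__all__ = [
    "GUILDS",
    "GUILD_SIZES",
    "WATER_CODE",
    "ValidationError",
    "ParseError",
    "CatalogEntry",
    "SubstrateCatalog",
    "PlateReading",
    "DesignTable",
    "SampleProfile",
    "builtin_catalog",
    "load_catalog",
    "load_plates",
    "blank_correct",
    "select_plateau",
    "load_design",
    "write_profiles",
    "read_profiles",
    "well_layout",
]

#: The five functional guilds (chemical substrate classes).
GUILDS = ("AA", "AM", "CH", "CX", "P")

#: Number of coded substrates per guild on an EcoPlate.
GUILD_SIZES = {"CH": 10, "CX": 9, "AA": 6, "P": 4, "AM": 2}

#: Code of the water blank.
WATER_CODE = "W"


class ValidationError(ValueError):
    """Input data violates a structural invariant (catalog, design, profile)."""


class ParseError(ValueError):
    """A file could not be parsed; message carries file and line context."""


# ---------------------------------------------------------------------------
# Substrate catalog
# ---------------------------------------------------------------------------

# The fixed EcoPlate catalog, in plate order (column-major within a block).
# Codes group substrates into guilds: CH carbohydrates, P polymers,
# CX carboxylic/acetic acids, AA amino acids, AM amines/amides.
_BUILTIN_ROWS: list[tuple[str, str, str]] = [
    ("Water", "W", "W"),
    ("Pyruvic acid methyl ester", "CH1", "CH"),
    ("Tween 40", "P1", "P"),
    ("Tween 80", "P2", "P"),
    ("alpha-Cyclodextrin", "P3", "P"),
    ("Glycogen", "P4", "P"),
    ("d-Cellobiose", "CH2", "CH"),
    ("alpha-d-Lactose", "CH3", "CH"),
    ("beta-Methyl-d-glucoside", "CH4", "CH"),
    ("d-Xylose", "CH5", "CH"),
    ("i-Erythritol", "CH6", "CH"),
    ("d-Mannitol", "CH7", "CH"),
    ("N-Acetyl-d-glucosamine", "CH8", "CH"),
    ("d-Glucosaminic acid", "CX1", "CX"),
    ("Glucose-1-phosphate", "CH9", "CH"),
    ("d,l-alpha-Glycerol phosphate", "CH10", "CH"),
    ("d-Galactonic acid gamma-lactone", "CX2", "CX"),
    ("d-Galacturonic acid", "CX3", "CX"),
    ("2-Hydroxy benzoic acid", "CX4", "CX"),
    ("4-Hydroxy benzoic acid", "CX5", "CX"),
    ("gamma-Hydroxy butyric acid", "CX6", "CX"),
    ("Itaconic acid", "CX7", "CX"),
    ("alpha-Keto butyric acid", "CX8", "CX"),
    ("d-Malic acid", "CX9", "CX"),
    ("l-Arginine", "AA1", "AA"),
    ("l-Asparagine", "AA2", "AA"),
    ("l-Phenylalanine", "AA3", "AA"),
    ("l-Serine", "AA4", "AA"),
    ("l-Threonine", "AA5", "AA"),
    ("Glycyl-l-glutamic acid", "AA6", "AA"),
    ("Phenylethylamine", "AM1", "AM"),
    ("Putrescine", "AM2", "AM"),
]

_ROW_LABELS = "ABCDEFGH"


@dataclass(frozen=True)
class CatalogEntry:
    substrate: str
    code: str
    guild: str


@dataclass(frozen=True)
class SubstrateCatalog:
    """The 31 coded substrates plus the water blank, with guild membership.

    Entries are stored in plate order, so the catalog doubles as the
    well -> substrate map for one 32-well block.
    """

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != 32:
            raise ValidationError(
                f"catalog must have 32 entries (31 substrates + water), got {len(self.entries)}"
            )
        codes = [e.code for e in self.entries]
        seen: set[str] = set()
        for e in self.entries:
            if e.code in seen:
                raise ValidationError(f"duplicate substrate code {e.code!r} ({e.substrate!r})")
            seen.add(e.code)
            if e.guild not in GUILDS and e.guild != WATER_CODE:
                raise ValidationError(
                    f"unknown guild {e.guild!r} for substrate {e.substrate!r}"
                )
        if WATER_CODE not in codes:
            raise ValidationError("catalog is missing the water blank (code W)")
        sizes = {g: sum(1 for e in self.entries if e.guild == g) for g in GUILDS}
        if sizes != GUILD_SIZES:
            raise ValidationError(f"guild sizes {sizes} differ from expected {GUILD_SIZES}")

    @property
    def codes(self) -> tuple[str, ...]:
        """The 31 substrate codes, in plate order (water excluded)."""
        return tuple(e.code for e in self.entries if e.code != WATER_CODE)

    @property
    def guild_of(self) -> dict[str, str]:
        """Map substrate code -> guild (water excluded)."""
        return {e.code: e.guild for e in self.entries if e.code != WATER_CODE}

    def guild_codes(self, guild: str) -> tuple[str, ...]:
        if guild not in GUILDS:
            raise ValidationError(f"unknown guild {guild!r}")
        return tuple(e.code for e in self.entries if e.guild == guild)


def builtin_catalog() -> SubstrateCatalog:
    """The standard EcoPlate substrate catalog shipped with the package."""
    return SubstrateCatalog(tuple(CatalogEntry(*row) for row in _BUILTIN_ROWS))


def load_catalog(source: Union[str, Path, io.TextIOBase]) -> SubstrateCatalog:
    """Load a substrate catalog from CSV with columns substrate, code, guild.

    The catalog must describe a full EcoPlate: 31 coded substrates with the
    standard guild sizes, plus the water blank.
    """
    df = pd.read_csv(source, dtype=str)
    missing = {"substrate", "code", "guild"} - set(df.columns)
    if missing:
        raise ParseError(f"catalog is missing columns: {sorted(missing)}")
    entries = tuple(
        CatalogEntry(r.substrate.strip(), r.code.strip(), r.guild.strip())
        for r in df.itertuples()
    )
    return SubstrateCatalog(entries)


def well_layout(catalog: SubstrateCatalog | None = None) -> dict[str, str]:
    """Map each of the 96 wells (e.g. ``"A1"``) to its substrate code.

    Wells are laid out in three replicate blocks of four columns; within a
    block substrates run column-major from row A to row H in catalog order.
    """
    catalog = catalog or builtin_catalog()
    layout: dict[str, str] = {}
    codes = [e.code for e in catalog.entries]
    for block in range(3):
        for col_off in range(4):
            for row_idx, row in enumerate(_ROW_LABELS):
                well = f"{row}{block * 4 + col_off + 1}"
                layout[well] = codes[col_off * 8 + row_idx]
    return layout


# ---------------------------------------------------------------------------
# Plate readings
# ---------------------------------------------------------------------------

@dataclass
class PlateReading:
    """Raw optical densities of one plate at one timepoint (96 wells)."""

    plate_id: str
    sample_id: str
    timepoint: float  # hours
    od: dict[str, float]  # well -> OD at 590 nm

    def __post_init__(self) -> None:
        if len(self.od) != 96:
            raise ValidationError(f"96 wells expected, {len(self.od)} found")
        if self.timepoint < 0:
            raise ValidationError(f"negative timepoint {self.timepoint}")


def _parse_grid(path: Path) -> list[PlateReading]:
    readings: list[PlateReading] = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    i = 0
    while i < len(rows):
        if not rows[i] or not any(cell.strip() for cell in rows[i]):
            i += 1
            continue
        header = [c.strip().lower() for c in rows[i]]
        if header[:3] != ["plate_id", "sample_id", "time_h"]:
            raise ParseError(
                f"{path}:{i + 1}: expected block header 'plate_id,sample_id,time_h', got {rows[i]!r}"
            )
        meta = rows[i + 1]
        plate_id, sample_id = meta[0].strip(), meta[1].strip()
        try:
            time_h = float(meta[2])
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{i + 2}: non-numeric timepoint in {meta!r}") from None
        od: dict[str, float] = {}
        for r in range(8):
            line_no = i + 3 + r
            try:
                row = rows[i + 2 + r]
            except IndexError:
                raise ParseError(f"{path}:{line_no}: truncated 8x12 grid") from None
            vals = [c for c in row if c.strip() != ""]
            if len(vals) != 12:
                raise ParseError(f"{path}:{line_no}: expected 12 OD values, found {len(vals)}")
            for c, cell in enumerate(vals):
                try:
                    od[f"{_ROW_LABELS[r]}{c + 1}"] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{line_no}: non-numeric OD {cell!r} in column {c + 1}"
                    ) from None
        readings.append(PlateReading(plate_id, sample_id, time_h, od))
        i += 10
    if not readings:
        raise ParseError(f"{path}: no plate blocks found")
    return readings


def _parse_long(path: Path) -> list[PlateReading]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if not {"sample_id", "time_h", "od"} <= cols:
        raise ParseError(f"{path}: long layout needs columns sample_id, time_h, od")
    by_well = "well" in cols
    if not by_well and "substrate_code" not in cols:
        raise ParseError(f"{path}: long layout needs a 'well' or 'substrate_code' column")
    if not np.issubdtype(df["od"].dtype, np.number):
        bad = df[pd.to_numeric(df["od"], errors="coerce").isna()].index[0]
        raise ParseError(f"{path}: non-numeric OD at data row {bad + 1}")

    layout = well_layout()
    code_wells: dict[str, list[str]] = {}
    for well, code in layout.items():
        code_wells.setdefault(code, []).append(well)

    readings = []
    for (sample_id, time_h), grp in df.groupby(["sample_id", "time_h"], sort=True):
        od: dict[str, float] = {}
        if by_well:
            for r in grp.itertuples():
                od[str(r.well)] = float(r.od)
        else:
            # One value per substrate code: replicate it across the code's
            # three wells so blank correction reproduces it exactly.
            for r in grp.itertuples():
                code = str(r.substrate_code)
                if code not in code_wells:
                    raise ParseError(f"{path}: unknown substrate code {code!r}")
                for well in code_wells[code]:
                    od[well] = float(r.od)
        if len(od) != 96:
            raise ParseError(
                f"{path}: sample {sample_id!r} at {time_h} h: 96 wells expected, {len(od)} found"
            )
        readings.append(PlateReading(str(sample_id), str(sample_id), float(time_h), od))
    return readings


def load_plates(path: Union[str, Path], layout: str = "grid") -> list[PlateReading]:
    """Read plate OD data from CSV.

    Parameters
    ----------
    path:
        CSV file.  ``layout="grid"`` expects repeated blocks of a
        ``plate_id,sample_id,time_h`` header row, one metadata row, and an
        8x12 grid of OD values.  ``layout="long"`` expects columns
        ``sample_id``, ``well`` (or ``substrate_code``), ``time_h``, ``od``.
    """
    path = Path(path)
    if layout == "grid":
        readings = _parse_grid(path)
    elif layout == "long":
        readings = _parse_long(path)
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'grid' or 'long')")
    # Timepoints must be strictly increasing within a plate series.
    series: dict[str, list[float]] = {}
    for rd in readings:
        series.setdefault(rd.plate_id, []).append(rd.timepoint)
    for plate_id, times in series.items():
        if sorted(times) != sorted(set(times)):
            raise ParseError(f"{path}: duplicate timepoints for plate {plate_id!r}")
    return readings


# ---------------------------------------------------------------------------
# Design table and sample profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignTable:
    """Maps samples to treatments and replicates, and names the control."""

    rows: tuple[tuple[str, str, int], ...]  # (sample_id, treatment, replicate)
    control: str

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(ids) != len(set(ids)):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise ValidationError(f"duplicate sample_id {dup!r} in design")
        for sid, trt, rep in self.rows:
            if rep < 1:
                raise ValidationError(f"replicate must be a positive integer (sample {sid!r})")
        n_control = sum(1 for r in self.rows if r[1] == self.control)
        if n_control < 2:
            raise ValidationError(
                f"control treatment {self.control!r} needs >= 2 replicates, found {n_control}"
            )
        if n_control < 3:
            warnings.warn(
                f"control treatment {self.control!r} has only {n_control} replicates; "
                "3 or more are recommended for a stable niche range",
                stacklevel=2,
            )

    @property
    def treatments(self) -> tuple[str, ...]:
        out: list[str] = []
        for _, trt, _ in self.rows:
            if trt not in out:
                out.append(trt)
        return tuple(out)

    def treatment_of(self, sample_id: str) -> str:
        for sid, trt, _ in self.rows:
            if sid == sample_id:
                return trt
        raise KeyError(sample_id)

    def samples_of(self, treatment: str) -> tuple[str, ...]:
        return tuple(sid for sid, trt, _ in self.rows if trt == treatment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["sample_id", "treatment", "replicate"])


def load_design(path: Union[str, Path], control: str) -> DesignTable:
    """Read a design CSV with columns sample_id, treatment, replicate."""
    df = pd.read_csv(path)
    missing = {"sample_id", "treatment", "replicate"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: design is missing columns {sorted(missing)}")
    rows = tuple(
        (str(r.sample_id), str(r.treatment), int(r.replicate)) for r in df.itertuples()
    )
    if control not in {r[1] for r in rows}:
        raise ValidationError(f"control treatment {control!r} not found in design")
    return DesignTable(rows, control)


@dataclass
class SampleProfile:
    """One sample's blank-corrected response per coded substrate (OD units)."""

    sample_id: str
    treatment: str
    replicate: int
    responses: dict[str, float]  # substrate code -> response, 31 entries

    def __post_init__(self) -> None:
        if len(self.responses) != 31:
            raise ValidationError(
                f"sample {self.sample_id!r}: 31 substrate responses expected, "
                f"{len(self.responses)} found"
            )
        for code, x in self.responses.items():
            if x < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative response {x} for {code}"
                )

    @property
    def total(self) -> float:
        """Total substrate activity S = sum of the 31 responses."""
        return float(sum(self.responses.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.responses, name=self.sample_id, dtype=float)


def blank_correct(reading: PlateReading, catalog: SubstrateCatalog | None = None,
                  treatment: str = "", replicate: int = 1) -> SampleProfile:
    """Blank-correct a plate reading and average its three replicate blocks.

    For each block, the water well's OD is subtracted from every substrate
    well of that block; negative corrected values are clipped to 0, and the
    substrate's response is the mean over its three block replicates.
    """
    catalog = catalog or builtin_catalog()
    layout = well_layout(catalog)
    corrected: dict[str, list[float]] = {code: [] for code in catalog.codes}
    for block in range(3):
        water_well = f"A{block * 4 + 1}"
        water_od = reading.od[water_well]
        for col_off in range(4):
            for row in _ROW_LABELS:
                well = f"{row}{block * 4 + col_off + 1}"
                code = layout[well]
                if code == WATER_CODE:
                    continue
                corrected[code].append(max(0.0, reading.od[well] - water_od))
    responses = {code: float(np.mean(v)) for code, v in corrected.items()}
    return SampleProfile(reading.sample_id, treatment, replicate, responses)


def select_plateau(series: Sequence[PlateReading], policy: str = "last",
                   catalog: SubstrateCatalog | None = None) -> PlateReading:
    """Pick the analysis timepoint from a plate's reading series.

    Policies: ``last`` (latest timepoint; the incubation runs to the plateau
    phase, so the last reading is the plateau by protocol), ``max_awcd``
    (timepoint with maximal average well color development), ``fixed:T``
    (nearest timepoint to T hours; ties break toward the later reading, and a
    gap above 12 h triggers a warning).
    """
    if not series:
        raise ValidationError("empty reading series")
    ordered = sorted(series, key=lambda r: r.timepoint)
    if policy == "last":
        return ordered[-1]
    if policy == "max_awcd":
        def _awcd(rd: PlateReading) -> float:
            prof = blank_correct(rd, catalog)
            return prof.total / 31.0
        return max(ordered, key=lambda rd: (_awcd(rd), rd.timepoint))
    if policy.startswith("fixed:"):
        try:
            target = float(policy.split(":", 1)[1])
        except ValueError:
            raise ValueError(f"bad fixed policy {policy!r}; use e.g. 'fixed:96'") from None
        # Ties toward the later reading: sort key (distance, -timepoint).
        best = min(ordered, key=lambda rd: (abs(rd.timepoint - target), -rd.timepoint))
        if abs(best.timepoint - target) > 12:
            warnings.warn(
                f"nearest timepoint {best.timepoint} h is more than 12 h from "
                f"requested {target} h",
                stacklevel=2,
            )
        return best
    raise ValueError(f"unknown plateau policy {policy!r}")


# ---------------------------------------------------------------------------
# Canonical long-format profile CSV
# ---------------------------------------------------------------------------

def write_profiles(profiles: Iterable[SampleProfile], path: Union[str, Path]) -> None:
    """Write profiles as canonical long CSV: sample_id, substrate_code, response."""
    records = [
        (p.sample_id, code, resp)
        for p in profiles
        for code, resp in p.responses.items()
    ]
    pd.DataFrame(records, columns=["sample_id", "substrate_code", "response"]).to_csv(
        path, index=False
    )


def read_profiles(path: Union[str, Path], design: DesignTable) -> list[SampleProfile]:
    """Read canonical long-format profiles, attaching design labels."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"sample_id", "substrate_code", "response"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: profile CSV is missing columns {sorted(missing)}")
    rep_of = {sid: rep for sid, _, rep in design.rows}
    profiles = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        sid = str(sample_id)
        responses = {str(r.substrate_code): float(r.response) for r in grp.itertuples()}
        profiles.append(
            SampleProfile(sid, design.treatment_of(sid), rep_of[sid], responses)
        )
    return profiles
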