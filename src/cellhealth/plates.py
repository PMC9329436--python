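"""384-well plate layouts and dilution-series arithmetic for the cell-health screen.

The screen's physical format: each test compound is laid out as a 10-step,
3-fold dilution series (100 µM down to ~5 nM) in duplicate, occupying 20
wells of one plate row, so 16 compounds fit on a 384-well plate.  Every row
also carries one positive-control and one negative-control well, giving 16
replicate control pairs per plate.  Unused positions receive DMSO vehicle
blanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import CapacityError

ROWS = "ABCDEFGHIJKLMNOP"
N_COLUMNS = 24
N_WELLS = len(ROWS) * N_COLUMNS

ROLE_TEST = "test"
ROLE_POSITIVE = "positive_control"
ROLE_NEGATIVE = "negative_control"
ROLE_BLANK = "blank"


@dataclass(frozen=True)
class DoseSeries:
    """A descending geometric dilution series in µM.

    ``concentrations[0]`` is the top concentration and each successive value
    is the previous one divided by ``dilution_factor``.
    """

    top_concentration: float
    n_steps: int
    dilution_factor: float
    concentrations: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.top_concentration <= 0:
            raise ValueError("top concentration must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be a positive integer")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must exceed 1")
        if not self.concentrations:
            concs = tuple(
                self.top_concentration / self.dilution_factor**i
                for i in range(self.n_steps)
            )
            object.__setattr__(self, "concentrations", concs)
        if len(self.concentrations) != self.n_steps:
            raise ValueError("series length does not match n_steps")
        if not math.isclose(self.concentrations[0], self.top_concentration,
                            rel_tol=1e-12):
            raise ValueError("series must start at the top concentration")
        for a, b in zip(self.concentrations, self.concentrations[1:]):
            if not math.isclose(a / b, self.dilution_factor, rel_tol=1e-12):
                raise ValueError("series is not a clean geometric dilution")

    @property
    def lowest(self) -> float:
        return self.concentrations[-1]


def build_dose_series(top_um: float, n_steps: int, factor: float) -> DoseSeries:
    """Build a descending dilution series, e.g. ``(100, 10, 3)`` → 100 µM…5 nM."""
    return DoseSeries(top_concentration=float(top_um), n_steps=int(n_steps),
                      dilution_factor=float(factor))


def nm_to_um(value_nm: float) -> float:
    """Explicit unit tag for nM inputs; internal storage is µM."""
    return value_nm / 1000.0


@dataclass(frozen=True)
class WellSpec:
    role: str
    compound_id: str | None = None
    concentration: float | None = None  # µM
    replicate_index: int | None = None


@dataclass
class PlateMap:
    """Well-address → :class:`WellSpec` assignment for one 384-well plate."""

    plate_id: str
    wells: dict[str, WellSpec]

    def __post_init__(self) -> None:
        expected = {f"{r}{c}" for r in ROWS for c in range(1, N_COLUMNS + 1)}
        if set(self.wells) != expected:
            raise ValueError("a plate map must cover exactly the 384 well addresses")

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, s in self.wells.items() if s.role == role]

    def test_wells_for(self, compound_id: str) -> list[str]:
        return [w for w, s in self.wells.items()
                if s.role == ROLE_TEST and s.compound_id == compound_id]

    @property
    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for addr in sorted(self.wells, key=_well_sort_key):
            spec = self.wells[addr]
            if spec.role == ROLE_TEST and spec.compound_id is not None:
                seen.setdefault(spec.compound_id)
        return list(seen)

    # ---- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for addr in sorted(self.wells, key=_well_sort_key):
            s = self.wells[addr]
            rows.append({"well": addr, "role": s.role,
                         "compound_id": s.compound_id,
                         "concentration_uM": s.concentration,
                         "replicate": s.replicate_index})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        # %.17g keeps enough digits for float64 values to round-trip exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, plate_id: str = "plate") -> "PlateMap":
        wells = {}
        for row in frame.itertuples(index=False):
            comp = None if pd.isna(row.compound_id) else str(row.compound_id)
            conc = None if pd.isna(row.concentration_uM) else float(row.concentration_uM)
            rep = None if pd.isna(row.replicate) else int(row.replicate)
            wells[str(row.well)] = WellSpec(role=str(row.role), compound_id=comp,
                                            concentration=conc, replicate_index=rep)
        return cls(plate_id=plate_id, wells=wells)

    @classmethod
    def from_csv(cls, path, plate_id: str = "plate") -> "PlateMap":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(frame, plate_id=plate_id)

    def to_yaml(self, path) -> None:
        payload = {
            "plate_id": self.plate_id,
            "wells": {
                addr: {"role": s.role, "compound_id": s.compound_id,
                       "concentration_uM": s.concentration,
                       "replicate": s.replicate_index}
                for addr, s in sorted(self.wells.items(), key=lambda kv: _well_sort_key(kv[0]))
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlateMap":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        wells = {
            addr: WellSpec(role=v["role"], compound_id=v.get("compound_id"),
                           concentration=v.get("concentration_uM"),
                           replicate_index=v.get("replicate"))
            for addr, v in payload["wells"].items()
        }
        return cls(plate_id=payload["plate_id"], wells=wells)


def _well_sort_key(addr: str) -> tuple[int, int]:
    return ROWS.index(addr[0]), int(addr[1:])


def build_plate_map(compound_ids: list[str], series: DoseSeries,
                    plate_id: str = "plate") -> PlateMap:
    """Lay out up to 16 compounds, one per row.

    Row layout (columns): replicate 1 of the descending series in columns
    1–10, replicate 2 in columns 11–20, positive control in column 21,
    negative control in column 22, DMSO blanks in columns 23–24.  Rows
    without a compound keep their control pair; their series positions are
    blanks.  The geometric placement within a row is a package convention —
    the format only fixes the well counts.
    """
    compound_ids = list(compound_ids)
    if not 1 <= len(compound_ids):
        raise ValueError("at least one compound is required")
    if len(compound_ids) > len(ROWS):
        raise CapacityError(
            f"{len(compound_ids)} compounds requested but a 384-well plate "
            f"holds at most {len(ROWS)} (one 20-well series per row)")
    if series.n_steps != 10:
        raise ValueError("the screen format uses a 10-step series")

    wells: dict[str, WellSpec] = {}
    for row_idx, row in enumerate(ROWS):
        compound = compound_ids[row_idx] if row_idx < len(compound_ids) else None
        for rep in (1, 2):
            for step, conc in enumerate(series.concentrations):
                col = step + 1 + (rep - 1) * 10
                addr = f"{row}{col}"
                if compound is None:
                    wells[addr] = WellSpec(role=ROLE_BLANK)
                else:
                    wells[addr] = WellSpec(role=ROLE_TEST, compound_id=compound,
                                           concentration=conc, replicate_index=rep)
        wells[f"{row}21"] = WellSpec(role=ROLE_POSITIVE)
        wells[f"{row}22"] = WellSpec(role=ROLE_NEGATIVE)
        wells[f"{row}23"] = WellSpec(role=ROLE_BLANK)
        wells[f"{row}24"] = WellSpec(role=ROLE_BLANK)
    return PlateMap(plate_id=plate_id, wells=wells)


def cells_per_well(density_cells_per_ml: float, volume_ul: float) -> int:
    """Deposited cell count: density (cells/mL) × volume (µL), e.g.
    2.5e6 cells/mL in 40 µL → 100,000 cells."""
    if density_cells_per_ml <= 0 or volume_ul <= 0:
        raise ValueError("density and volume must be positive")
    return round(density_cells_per_ml * volume_ul / 1000.0)
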