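"""Per-well flow cytometry event data: the 12-parameter panel, readers, QC.

The screen derives its phenotype from twelve ungated detection parameters:
forward/side scatter plus fluorescence channels from two non-overlapping
dye mixes applied on replicate plates (mix 1: Calcein AM, SYTOX Red,
MitoSOX Red, monobromobimane; mix 2: JC-9 green/red, propidium iodide,
DyeCycle Violet).  Which dyes occupy two detectors is instrument
configuration, not ground truth, so the panel is declared data:  here JC-9
contributes green and red detectors and PI and DyeCycle Violet contribute
area + pulse-width parameters, giving the canonical 12.

An :class:`EventMatrix` always carries the full 12-parameter panel; the
physical two-plate split is retained as the per-channel dye-mix tag on
:class:`ChannelPanel`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fcs
from .errors import SchemaError

N_CHANNELS = 12

SCATTER = "scatter"
MIX1 = "mix1"
MIX2 = "mix2"

#: canonical channel order: (name, reporter role, dye mix)
DEFAULT_CHANNELS: tuple[tuple[str, str, str], ...] = (
    ("FSC", "FSC", SCATTER),
    ("SSC", "SSC", SCATTER),
    ("CalceinAM", "CalceinAM", MIX1),
    ("SYTOXRed", "SYTOXRed", MIX1),
    ("MitoSOXRed", "MitoSOXRed", MIX1),
    ("Monobromobimane", "Monobromobimane", MIX1),
    ("JC9_green", "JC9_green", MIX2),
    ("JC9_red", "JC9_red", MIX2),
    ("PI", "PI", MIX2),
    ("PI_W", "PI_width", MIX2),
    ("DCV", "DyeCycleViolet", MIX2),
    ("DCV_W", "DyeCycleViolet_width", MIX2),
)

#: the aspiration target for the autosampler; wells under this fail QC
DEFAULT_MIN_EVENTS = 10_000


@dataclass(frozen=True)
class ChannelPanel:
    """Channel name → (reporter role, dye mix) mapping plus name aliases."""

    channels: tuple[tuple[str, str, str], ...] = DEFAULT_CHANNELS
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.channels]
        if len(set(names)) != len(names):
            raise SchemaError("channel names must be unique")
        roles = {c[0]: c[1] for c in self.channels}
        if "FSC" not in roles.values() or "SSC" not in roles.values():
            raise SchemaError("a panel must include FSC and SSC")
        for name, _, mix in self.channels:
            if mix not in (SCATTER, MIX1, MIX2):
                raise SchemaError(
                    f"channel {name!r}: every non-scatter channel belongs to "
                    f"exactly one dye mix (got {mix!r})")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.channels]

    @property
    def scatter_channels(self) -> list[str]:
        return [c[0] for c in self.channels if c[2] == SCATTER]

    def mix_of(self, name: str) -> str:
        for n, _, mix in self.channels:
            if n == name:
                return mix
        raise SchemaError(f"unknown channel {name!r}")

    def canonical_name(self, raw: str) -> str | None:
        """Resolve a raw instrument parameter name to a panel channel."""
        if raw in self.names:
            return raw
        if raw in self.aliases:
            return self.aliases[raw]
        lowered = {n.lower(): n for n in self.names}
        return lowered.get(raw.lower())


DEFAULT_PANEL = ChannelPanel()


@dataclass
class EventMatrix:
    """Ungated events × 12 detection parameters for one well."""

    well: str
    channels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.channels) != N_CHANNELS:
            raise SchemaError(
                f"an event matrix carries exactly {N_CHANNELS} channels, "
                f"got {len(self.channels)}")
        if len(set(self.channels)) != len(self.channels):
            raise SchemaError("channel names must be unique")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise SchemaError("value matrix shape must be events × channels")
        if self.values.shape[0] < 1:
            raise SchemaError("an event matrix needs at least one event")
        if not np.isfinite(self.values).all():
            raise SchemaError("event values must be finite (no missing values)")

    @property
    def n_events(self) -> int:
        return int(self.values.shape[0])

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise SchemaError(f"channel {name!r} absent from event matrix") from None
        return self.values[:, idx]

    def reordered(self, order: list[str]) -> "EventMatrix":
        idx = [self.channels.index(c) for c in order]
        return EventMatrix(well=self.well, channels=list(order),
                           values=self.values[:, idx])


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str
    n_events: int

    def __bool__(self) -> bool:  # allows `if qc_well(...)`
        return self.passed


def read_events(source, panel: ChannelPanel = DEFAULT_PANEL,
                well: str | None = None) -> EventMatrix:
    """Read one well's events from an FCS 3.x file or a headered CSV.

    Columns are reordered to the panel's canonical order; no gating or
    transformation is applied.  A channel the panel expects but the file
    lacks raises :class:`SchemaError` naming it.
    """
    path = os.fspath(source)
    if path.lower().endswith(".fcs"):
        raw_names, values = fcs.read_fcs(path)
    else:
        frame = pd.read_csv(path)
        raw_names = [str(c) for c in frame.columns]
        values = frame.to_numpy(dtype=float)

    resolved: dict[str, int] = {}
    for i, raw in enumerate(raw_names):
        canon = panel.canonical_name(raw)
        if canon is not None and canon not in resolved:
            resolved[canon] = i
    missing = [n for n in panel.names if n not in resolved]
    if missing:
        raise SchemaError(
            "file is missing expected channels: " + ", ".join(missing))
    cols = [resolved[n] for n in panel.names]
    if well is None:
        well = os.path.splitext(os.path.basename(path))[0]
    return EventMatrix(well=well, channels=list(panel.names),
                       values=values[:, cols])


def write_events_csv(events: EventMatrix, path) -> None:
    pd.DataFrame(events.values, columns=events.channels).to_csv(path, index=False)


def write_events_fcs(events: EventMatrix, path) -> None:
    fcs.write_fcs(path, events.channels, events.values)


def qc_well(events: EventMatrix, min_events: int = DEFAULT_MIN_EVENTS) -> QCResult:
    """Pass/fail a well on acquired event count (autosampler target ≥ 10,000)."""
    if min_events < 1:
        raise ValueError("min_events must be at least 1")
    ok = events.n_events >= min_events
    reason = (f"{events.n_events} events acquired"
              if ok else
              f"only {events.n_events} events acquired (minimum {min_events})")
    return QCResult(passed=ok, reason=reason, n_events=events.n_events)
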