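"""Spectral channel scheme: definitions, validation, CSV I/O.

Every other module indexes into the channel table defined here.  Channel
indices are 1-based in all user-facing interfaces ("Channel 3"); use
:func:`to_internal` / :func:`to_user` for conversion to 0-based array axes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "FLUOROPHORE_HINTS",
    "ChannelDefinition",
    "ChannelTable",
    "ChannelTableError",
    "DuplicateChannelIndexError",
    "NonNumericBandError",
    "EmissionBandOrderError",
    "MissingChannelFileError",
    "load_channel_table",
    "write_channel_table",
    "default_channel_table",
    "to_internal",
    "to_user",
]

#: Allowed fluorophore attributions for a channel.
FLUOROPHORE_HINTS = frozenset(
    {"elastin", "lipopigment", "flavins", "PPIX", "NADH", "other", "none"}
)

#: Channel attributions used by the bundled default table.
DEFAULT_HINTED_CHANNELS = {3: "elastin", 12: "lipopigment", 30: "flavins", 52: "PPIX"}

_CSV_COLUMNS = [
    "index",
    "ex_center_nm",
    "ex_halfwidth_nm",
    "em_low_nm",
    "em_high_nm",
    "fluorophore_hint",
]


class ChannelTableError(ValueError):
    """Base class for channel-table validation failures."""


class DuplicateChannelIndexError(ChannelTableError):
    """Two channel rows share the same index."""


class NonNumericBandError(ChannelTableError):
    """A wavelength column could not be parsed as a number."""


class EmissionBandOrderError(ChannelTableError):
    """Emission band has em_low_nm >= em_high_nm."""


class MissingChannelFileError(ChannelTableError, FileNotFoundError):
    """Channel-table file does not exist."""


def to_internal(index: int) -> int:
    """Convert a 1-based user-facing channel index to a 0-based array axis."""
    if index < 1:
        raise IndexError(f"channel indices are 1-based, got {index}")
    return index - 1


def to_user(axis: int) -> int:
    """Convert a 0-based array axis to the 1-based user-facing channel index."""
    if axis < 0:
        raise IndexError(f"array axes are 0-based and nonnegative, got {axis}")
    return axis + 1


@dataclass(frozen=True)
class ChannelDefinition:
    """One excitation/emission band pair of the imaging scheme."""

    index: int
    ex_center_nm: float
    ex_halfwidth_nm: float
    em_low_nm: float
    em_high_nm: float
    fluorophore_hint: str = "none"

    def validate(self) -> None:
        if self.ex_center_nm <= 0:
            raise ChannelTableError(
                f"channel {self.index}: excitation center must be positive"
            )
        if not self.em_low_nm < self.em_high_nm:
            raise EmissionBandOrderError(
                f"channel {self.index}: emission band reversed "
                f"({self.em_low_nm} >= {self.em_high_nm})"
            )
        if self.fluorophore_hint not in FLUOROPHORE_HINTS:
            raise ChannelTableError(
                f"channel {self.index}: unknown fluorophore hint "
                f"{self.fluorophore_hint!r}"
            )


@dataclass(frozen=True)
class ChannelTable:
    """Ordered collection of channel definitions with gap-free 1-based indices."""

    channels: tuple[ChannelDefinition, ...] = field(default_factory=tuple)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def validate(self) -> None:
        seen: set[int] = set()
        for ch in self.channels:
            if ch.index in seen:
                raise DuplicateChannelIndexError(
                    f"duplicate channel index {ch.index}"
                )
            seen.add(ch.index)
            ch.validate()
        expected = set(range(1, self.n_channels + 1))
        if seen != expected:
            missing = sorted(expected - seen)
            raise ChannelTableError(
                f"channel indices must be 1..{self.n_channels} without gaps; "
                f"missing {missing}"
            )

    def __getitem__(self, index: int) -> ChannelDefinition:
        """Look up a channel by its 1-based index."""
        return self.channels[to_internal(index)]

    def hinted_channels(self) -> dict[int, str]:
        """Map of 1-based index -> hint for channels with a real attribution."""
        return {
            ch.index: ch.fluorophore_hint
            for ch in self.channels
            if ch.fluorophore_hint not in ("none", "other")
        }


def _parse_float(value: str, column: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise NonNumericBandError(
            f"row {line}: column {column!r} is not numeric: {value!r}"
        ) from exc


def load_channel_table(path: str | Path, strict: bool = True) -> ChannelTable:
    """Load a channel table from CSV.

    Parameters
    ----------
    path:
        CSV file with header ``index, ex_center_nm, ex_halfwidth_nm,
        em_low_nm, em_high_nm[, fluorophore_hint]``.
    strict:
        When True (default) any invariant violation raises; when False the
        table is returned unvalidated (useful for inspecting broken files).
    """
    path = Path(path)
    if not path.exists():
        raise MissingChannelFileError(f"channel table not found: {path}")
    channels: list[ChannelDefinition] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "index" not in reader.fieldnames:
            raise ChannelTableError(f"{path}: missing header row with 'index'")
        for lineno, row in enumerate(reader, start=2):
            try:
                index = int(row["index"])
            except (TypeError, ValueError) as exc:
                raise NonNumericBandError(
                    f"row {lineno}: non-integer channel index {row['index']!r}"
                ) from exc
            hint = (row.get("fluorophore_hint") or "none").strip() or "none"
            channels.append(
                ChannelDefinition(
                    index=index,
                    ex_center_nm=_parse_float(row["ex_center_nm"], "ex_center_nm", lineno),
                    ex_halfwidth_nm=_parse_float(
                        row["ex_halfwidth_nm"], "ex_halfwidth_nm", lineno
                    ),
                    em_low_nm=_parse_float(row["em_low_nm"], "em_low_nm", lineno),
                    em_high_nm=_parse_float(row["em_high_nm"], "em_high_nm", lineno),
                    fluorophore_hint=hint,
                )
            )
    table = ChannelTable(channels=tuple(channels))
    if strict:
        table.validate()
    return table


def write_channel_table(table: ChannelTable, path: str | Path) -> Path:
    """Write a channel table to CSV (inverse of :func:`load_channel_table`)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CSV_COLUMNS)
        for ch in table.channels:
            writer.writerow(
                [
                    ch.index,
                    ch.ex_center_nm,
                    ch.ex_halfwidth_nm,
                    ch.em_low_nm,
                    ch.em_high_nm,
                    ch.fluorophore_hint,
                ]
            )
    return path


def default_channel_table() -> ChannelTable:
    """The bundled 59-channel default scheme.

    Five excitation groups (one per filter cube) spanning ~340-450 nm with
    ±5 nm excitation bands and stepped 40 nm emission windows.  Channels
    3/12/30/52 carry fluorophore attributions (elastin, lipopigment,
    flavins, PPIX).
    """
    with resources.as_file(
        resources.files("afmi.data").joinpath("default_channels.csv")
    ) as path:
        return load_channel_table(path, strict=True)
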