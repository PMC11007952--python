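"""Tabular domain types: discrete trait matrices and fossil calibration tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["TraitMatrix", "Calibration", "CalibrationTable", "MISSING"]

MISSING = "?"


@dataclass
class TraitMatrix:
    """Taxa x discrete characters, with named state spaces.

    ``data`` is a pandas DataFrame indexed by taxon name with one column per
    character; cells hold state symbols (strings) or the missing symbol "?".
    ``state_spaces`` maps character name -> ordered list of allowed symbols.
    """

    data: pd.DataFrame
    state_spaces: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(str)
        for char in self.data.columns:
            observed = sorted(set(self.data[char]) - {MISSING})
            if char not in self.state_spaces:
                self.state_spaces[char] = observed
            else:
                bad = set(observed) - set(self.state_spaces[char])
                if bad:
                    raise ValueError(
                        f"character {char!r}: symbols {sorted(bad)} outside "
                        f"declared state space {self.state_spaces[char]}"
                    )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def column(self, char: str) -> dict[str, str]:
        """Taxon -> state symbol for one character."""
        return dict(self.data[char])

    def states(self, char: str) -> list[str]:
        return list(self.state_spaces[char])


@dataclass
class Calibration:
    """A single soft-bound node calibration (MRCA of two named tips)."""

    name: str
    tip_a: str
    tip_b: str
    min_age: float | None = None
    max_age: float | None = None
    tail_low: float = 0.025
    tail_high: float = 0.025

    def __post_init__(self) -> None:
        if self.min_age is None and self.max_age is None:
            raise ValueError(f"calibration {self.name!r}: need min and/or max age")
        if (
            self.min_age is not None
            and self.max_age is not None
            and not self.min_age < self.max_age
        ):
            raise ValueError(
                f"calibration {self.name!r}: min {self.min_age} >= max {self.max_age}"
            )
        for t in (self.tail_low, self.tail_high):
            if not 0.0 <= t < 0.5:
                raise ValueError(f"calibration {self.name!r}: tail mass {t} not in [0, 0.5)")

    @property
    def midpoint(self) -> float:
        """Interval midpoint, or the minimum for a min-only calibration."""
        if self.min_age is not None and self.max_age is not None:
            return 0.5 * (self.min_age + self.max_age)
        return self.min_age if self.min_age is not None else self.max_age


@dataclass
class CalibrationTable:
    rows: list[Calibration]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i: int) -> Calibration:
        return self.rows[i]

    def drop(self, name: str) -> "CalibrationTable":
        kept = [r for r in self.rows if r.name != name]
        if len(kept) == len(self.rows):
            raise KeyError(name)
        return CalibrationTable(kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "tip_a": r.tip_a,
                    "tip_b": r.tip_b,
                    "min_age": r.min_age,
                    "max_age": r.max_age,
                    "tail_low": r.tail_low,
                    "tail_high": r.tail_high,
                }
                for r in self.rows
            ]
        )
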