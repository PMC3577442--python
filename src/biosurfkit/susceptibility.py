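"""MIC/MBC determination from replicate broth-microdilution plates.

Growth in each well is a boolean (for sulfate-reducing indicator strains,
blackening of the medium by iron sulfide).  The endpoint rule is the
conservative all-replicates convention: the MIC is the lowest
concentration ``c`` such that *every* replicate at *every* concentration
``>= c`` is growth-free.  A well pattern that is clear below a growth
well ("skipped wells") therefore raises the MIC and is flagged as
non-monotone.  The MBC applies the same rule to the subculture matrix
(growth after transfer to fresh medium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DilutionSeries",
    "PlateAssay",
    "SusceptibilityResult",
    "build_series",
    "determine_mic",
    "determine_mbc",
    "ABOVE_MAX",
    "BELOW_MIN",
]

#: Sentinel: growth everywhere, endpoint above the highest tested concentration.
ABOVE_MAX = ">max"
#: Sentinel: no growth anywhere, endpoint at or below the lowest tested concentration.
BELOW_MIN = "<=min"


@dataclass(frozen=True)
class DilutionSeries:
    """Strictly decreasing concentrations (ug/ml) from serial dilution."""

    concentrations: tuple[float, ...]
    factor: float = 2.0

    def __post_init__(self) -> None:
        c = self.concentrations
        if not c:
            raise ValueError("dilution series must be non-empty")
        if any(b >= a for a, b in zip(c, c[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        if self.factor <= 1:
            raise ValueError("dilution factor must be > 1")
        for a, b in zip(c, c[1:]):
            if abs(a / b - self.factor) > 0.05 * self.factor:
                raise ValueError(
                    f"step {a}->{b} deviates from factor {self.factor} by >5%"
                )

    def __len__(self) -> int:
        return len(self.concentrations)


def build_series(start: float, factor: float = 2.0, lowest: float = 1.2) -> DilutionSeries:
    """Serial-dilution ladder from ``start`` down to ~``lowest`` (ug/ml).

    Values are generated by repeated division by ``factor`` and kept while
    they remain at or above ``lowest`` (with 5% slack so that a printed
    "1.2" admits the exact twofold value 1.25).
    """
    if not start >= lowest > 0:
        raise ValueError("require start >= lowest > 0")
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    concs = []
    c = float(start)
    while c >= lowest * 0.95:
        concs.append(c)
        c /= factor
    return DilutionSeries(tuple(concs), factor)


@dataclass(frozen=True)
class PlateAssay:
    """Growth matrix: one row per concentration, one column per replicate.

    ``True`` marks growth (a blackened well).  ``subculture`` is the
    matching matrix read after transfer to fresh medium, used for the MBC.
    """

    series: DilutionSeries
    growth: tuple[tuple[bool, ...], ...]
    subculture: tuple[tuple[bool, ...], ...] | None = None

    def __post_init__(self) -> None:
        self._check_matrix(self.growth, "growth")
        if self.subculture is not None:
            self._check_matrix(self.subculture, "subculture")

    def _check_matrix(self, m: tuple[tuple[bool, ...], ...], name: str) -> None:
        if len(m) != len(self.series):
            raise ValueError(
                f"{name} matrix has {len(m)} rows for {len(self.series)} concentrations"
            )
        widths = {len(row) for row in m}
        if len(widths) != 1:
            raise ValueError(f"{name} matrix is ragged: row widths {sorted(widths)}")
        if 0 in widths:
            raise ValueError(f"{name} matrix needs at least one replicate")

    @property
    def replicates(self) -> int:
        return len(self.growth[0])

    @classmethod
    def from_arrays(
        cls,
        series: DilutionSeries,
        growth: Sequence[Sequence[bool]] | np.ndarray,
        subculture: Sequence[Sequence[bool]] | np.ndarray | None = None,
    ) -> "PlateAssay":
        to_t = lambda m: tuple(tuple(bool(v) for v in row) for row in m)
        return cls(series, to_t(growth), None if subculture is None else to_t(subculture))


@dataclass(frozen=True)
class SusceptibilityResult:
    mic: float | str
    mbc: float | str | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (
            isinstance(self.mic, float)
            and isinstance(self.mbc, float)
            and self.mbc < self.mic
        ):
            object.__setattr__(
                self, "notes", self.notes + ("MBC below MIC: inconsistent matrices",)
            )


def _endpoint(
    concentrations: Sequence[float], matrix: Sequence[Sequence[bool]]
) -> tuple[float | str, list[str]]:
    """All-replicates endpoint: lowest c with every well at conc >= c clear."""
    any_growth = [any(row) for row in matrix]
    k = 0  # length of the clear prefix in decreasing-concentration order
    while k < len(any_growth) and not any_growth[k]:
        k += 1
    notes = []
    if k < len(any_growth) and any(not g for g in any_growth[k + 1 :]):
        notes.append(
            "non-monotone plate: clear wells below a growth well; "
            "endpoint raised by the all-concentrations-above rule"
        )
    if k == 0:
        return ABOVE_MAX, notes
    if k == len(any_growth):
        return BELOW_MIN, notes
    return float(concentrations[k - 1]), notes


def determine_mic(plate: PlateAssay) -> SusceptibilityResult:
    """MIC by the all-replicates rule on the growth matrix."""
    mic, notes = _endpoint(plate.series.concentrations, plate.growth)
    return SusceptibilityResult(mic=mic, notes=tuple(notes))


def determine_mbc(plate: PlateAssay) -> SusceptibilityResult:
    """MIC and MBC; the MBC applies the same rule to the subculture matrix."""
    if plate.subculture is None:
        raise ValueError("MBC determination requires a subculture matrix")
    mic, notes_a = _endpoint(plate.series.concentrations, plate.growth)
    mbc, notes_b = _endpoint(plate.series.concentrations, plate.subculture)
    notes = tuple(notes_a) + tuple("subculture: " + n for n in notes_b)
    if isinstance(mic, float) and isinstance(mbc, float) and mbc < mic:
        notes = notes + ("MBC below MIC: inconsistent matrices",)
    return SusceptibilityResult(mic=mic, mbc=mbc, notes=notes)
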