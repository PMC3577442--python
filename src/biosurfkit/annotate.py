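"""Annotation of observed ESI-MS peak lists against theoretical ions.

Covers the two interpretation steps for a lipopeptide homologue mixture:
matching observed peaks to theoretical molecular/fragment ions within a
mass tolerance, and detecting the 14-Da-spaced homologue ladder that is
the fingerprint of a fatty-acid chain-length series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .chem import (
    METHYLENE,
    LipopeptideSpecies,
    Polarity,
    TheoreticalIon,
    adduct_mz,
)

__all__ = [
    "Peak",
    "Spectrum",
    "Assignment",
    "HomologueLadder",
    "match_peaks",
    "detect_ladder",
    "assign_homologues",
    "annotation_report",
    "DEFAULT_TOLERANCE_DA",
]

#: Unit-resolution (triple-quadrupole) matching tolerance, Da.
DEFAULT_TOLERANCE_DA = 0.5


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


@dataclass(frozen=True)
class Spectrum:
    """An observed spectrum: peaks sorted by m/z, polarity, MS level.

    ``precursor`` is required exactly when ``level == 2``.
    """

    peaks: tuple[Peak, ...]
    polarity: Polarity = "positive"
    level: int = 1
    precursor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )
        if self.level not in (1, 2):
            raise ValueError(f"MS level must be 1 or 2, got {self.level}")
        if self.level == 2 and self.precursor is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")
        if self.level == 1 and self.precursor is not None:
            raise ValueError("MS1 spectrum must not carry a precursor m/z")

    @classmethod
    def from_arrays(
        cls,
        mz: Sequence[float],
        intensity: Sequence[float] | None = None,
        **kw,
    ) -> "Spectrum":
        if intensity is None:
            intensity = [1.0] * len(mz)
        return cls(
            peaks=tuple(Peak(m, i) for m, i in zip(mz, intensity)), **kw
        )


@dataclass(frozen=True)
class Assignment:
    """One observed peak explained by one theoretical ion."""

    peak: Peak
    ion: TheoreticalIon
    error_da: float

    @property
    def error_ppm(self) -> float:
        return 1e6 * self.error_da / self.ion.mz


@dataclass(frozen=True)
class HomologueLadder:
    """A chain of peaks spaced by ~one methylene mass."""

    members: tuple[Peak, ...]
    spacing: float

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.members]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("ladder members must be strictly increasing in m/z")


def match_peaks(
    spectrum: Spectrum,
    theoretical: Iterable[TheoreticalIon],
    tolerance: float = DEFAULT_TOLERANCE_DA,
) -> list[Assignment]:
    """Match each theoretical ion to its nearest observed peak.

    Each ion matches at most one peak, the one with the smallest absolute
    m/z error within ``tolerance``; ties break toward higher intensity.
    An empty spectrum yields an empty list.  Output is sorted by
    theoretical m/z then label, so it is invariant to peak-list order.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    out: list[Assignment] = []
    for ion in theoretical:
        best: Peak | None = None
        for p in spectrum.peaks:
            err = abs(p.mz - ion.mz)
            if err > tolerance:
                continue
            if best is None:
                best = p
                continue
            best_err = abs(best.mz - ion.mz)
            if err < best_err or (err == best_err and p.intensity > best.intensity):
                best = p
        if best is not None:
            out.append(Assignment(best, ion, best.mz - ion.mz))
    out.sort(key=lambda a: (a.ion.mz, a.ion.label))
    return out


def _grow_chain(
    start: int,
    peaks: Sequence[Peak],
    used: Sequence[bool],
    spacing: float,
    tolerance: float,
) -> list[int]:
    """Greedy arithmetic chain from ``start``: nearest step within tolerance."""
    chain = [start]
    target = peaks[start].mz + spacing
    i = start + 1
    while i < len(peaks):
        best_j, best_err = -1, tolerance
        for j in range(i, len(peaks)):
            if used[j]:
                continue
            err = abs(peaks[j].mz - target)
            if err <= best_err:
                if best_j < 0 or err < best_err or (
                    peaks[j].intensity > peaks[best_j].intensity
                ):
                    best_j, best_err = j, err
            if peaks[j].mz - target > tolerance:
                break
        if best_j < 0:
            break
        chain.append(best_j)
        target = peaks[best_j].mz + spacing
        i = best_j + 1
    return chain


def detect_ladder(
    spectrum: Spectrum,
    spacing: float = METHYLENE,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    min_members: int = 2,
) -> list[HomologueLadder]:
    """Extract maximal ~``spacing``-spaced peak chains from a spectrum.

    Chains are extracted greedily, longest first (ties: lowest starting
    m/z); each peak belongs to at most one ladder.  Chains shorter than
    ``min_members`` are discarded.
    """
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    peaks = spectrum.peaks
    used = [False] * len(peaks)
    ladders: list[HomologueLadder] = []
    while True:
        best_chain: list[int] | None = None
        for s in range(len(peaks)):
            if used[s]:
                continue
            chain = _grow_chain(s, peaks, used, spacing, tolerance)
            if best_chain is None or len(chain) > len(best_chain):
                best_chain = chain
        if best_chain is None or len(best_chain) < min_members:
            break
        members = tuple(peaks[i] for i in best_chain)
        diffs = [b.mz - a.mz for a, b in zip(members, members[1:])]
        est = sum(diffs) / len(diffs) if diffs else spacing
        ladders.append(HomologueLadder(members, est))
        for i in best_chain:
            used[i] = True
    return ladders


def assign_homologues(
    ladders: Iterable[HomologueLadder],
    template: LipopeptideSpecies,
    polarity: Polarity,
    carbons: Iterable[int] = range(8, 25),
    tolerance: float = DEFAULT_TOLERANCE_DA,
) -> list[tuple[int, Assignment]]:
    """Label ladder members with fatty-acid carbon counts.

    Each member peak is compared with the theoretical adduct of the
    template species across candidate chain lengths; the nearest one wins,
    and the member stays unlabeled if even the nearest exceeds the
    tolerance.
    """
    theo = [
        (c, adduct_mz(template.with_carbons(c), polarity)) for c in carbons
    ]
    out: list[tuple[int, Assignment]] = []
    for ladder in ladders:
        for peak in ladder.members:
            c_best, ion_best = min(theo, key=lambda t: abs(peak.mz - t[1].mz))
            err = peak.mz - ion_best.mz
            if abs(err) <= tolerance:
                out.append((c_best, Assignment(peak, ion_best, err)))
    out.sort(key=lambda t: t[0])
    return out


def annotation_report(
    assignments: Iterable[Assignment],
    ladders: Iterable[HomologueLadder] = (),
) -> pd.DataFrame:
    """Tabulate assignments with ladder membership, deterministically ordered.

    Columns: label, span, theoretical_mz, nominal_mz, observed_mz,
    intensity, error_da, error_ppm, ladder.  ``ladder`` is the 0-based
    index of the ladder containing the observed peak, or -1.
    """
    ladder_of: dict[float, int] = {}
    for k, ladder in enumerate(ladders):
        for p in ladder.members:
            ladder_of[p.mz] = k
    rows = []
    for a in assignments:
        rows.append(
            {
                "label": a.ion.label,
                "span": "" if a.ion.span is None else f"{a.ion.span[0]}-{a.ion.span[1]}",
                "theoretical_mz": round(a.ion.mz, 6),
                "nominal_mz": a.ion.nominal,
                "observed_mz": round(a.peak.mz, 6),
                "intensity": a.peak.intensity,
                "error_da": round(a.error_da, 6),
                "error_ppm": round(a.error_ppm, 3),
                "ladder": ladder_of.get(a.peak.mz, -1),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "label",
            "span",
            "theoretical_mz",
            "nominal_mz",
            "observed_mz",
            "intensity",
            "error_da",
            "error_ppm",
            "ladder",
        ],
    )
    return df.sort_values(
        ["theoretical_mz", "label"], kind="mergesort"
    ).reset_index(drop=True)
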