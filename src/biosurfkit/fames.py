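"""Rule-based interpretation of EI-MS spectra of fatty-acid methyl esters.

Hydroxy-FAME electron-ionization spectra carry position-diagnostic ions:
cleavage alpha to the C3 hydroxyl of a beta-hydroxy FAME gives the m/z 103
fragment, while alpha-hydroxy FAMEs undergo a McLafferty rearrangement
yielding m/z 90.  Chain length is read from retention time relative to a
known standard (3-OH-C16:0 methyl ester) under a linear carbon-number
retention model.  Iso/anteiso branching appears as near-co-eluting peak
doublets with identical mass spectra.  A TLC retention-factor helper is
included for bioautography bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

__all__ = [
    "FameSpectrum",
    "FameCall",
    "TlcSpot",
    "classify_hydroxy",
    "assign_chain_length",
    "detect_branching_doublet",
    "compute_rf",
    "BETA_DIAGNOSTIC_MZ",
    "ALPHA_DIAGNOSTIC_MZ",
]

#: C3-hydroxyl alpha-cleavage diagnostic ion of beta-hydroxy FAMEs.
BETA_DIAGNOSTIC_MZ = 103.0
#: McLafferty rearrangement diagnostic ion of alpha-hydroxy FAMEs.
ALPHA_DIAGNOSTIC_MZ = 90.0
#: Half-width of the diagnostic m/z window (Da).
DIAGNOSTIC_WINDOW = 0.5
#: Default presence threshold, % relative intensity.
DEFAULT_THRESHOLD = 10.0

HydroxylCall = Literal["beta", "alpha", "unclassified"]


@dataclass(frozen=True)
class FameSpectrum:
    """One GC peak: retention time plus EI peak list (m/z, rel. int. 0-100)."""

    retention_time: float
    peaks: tuple[tuple[float, float], ...]
    identifier: str = ""

    def __post_init__(self) -> None:
        if not self.retention_time > 0:
            raise ValueError("retention time must be > 0")
        for mz, ri in self.peaks:
            if not 0 <= ri <= 100:
                raise ValueError(f"relative intensity out of [0,100] at m/z {mz}")

    def intensity_near(self, mz: float, window: float = DIAGNOSTIC_WINDOW) -> float:
        """Highest relative intensity within ±window of an m/z, else 0."""
        hits = [ri for m, ri in self.peaks if abs(m - mz) <= window]
        return max(hits, default=0.0)


@dataclass(frozen=True)
class FameCall:
    hydroxyl: HydroxylCall
    carbons: int | None = None
    branching: Literal["possible-iso/anteiso-pair", "single"] = "single"
    reason: str = ""


@dataclass(frozen=True)
class TlcSpot:
    migration: float
    front: float

    def __post_init__(self) -> None:
        if not self.front > 0:
            raise ValueError("solvent front distance must be > 0")
        if not 0 <= self.migration <= self.front:
            raise ValueError("migration must lie in [0, front]")

    @property
    def rf(self) -> float:
        return compute_rf(self.migration, self.front)


def classify_hydroxy(
    spectrum: FameSpectrum,
    threshold: float = DEFAULT_THRESHOLD,
) -> FameCall:
    """Diagnose hydroxyl position from the 103/90 diagnostic ions.

    ``beta`` when m/z 103 is present above threshold and m/z 90 is not;
    ``alpha`` for the converse; ``unclassified`` (with a reason) when both
    or neither diagnostic is present.  The call is invariant to uniform
    intensity rescaling because relative intensities are compared with a
    relative threshold.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    if not spectrum.peaks:
        return FameCall("unclassified", reason="empty peak list")
    base = max(ri for _, ri in spectrum.peaks)
    if base == 0:
        return FameCall("unclassified", reason="all intensities zero")
    scale = 100.0 / base  # normalize to the base peak: rescaling-invariant
    i103 = spectrum.intensity_near(BETA_DIAGNOSTIC_MZ) * scale
    i90 = spectrum.intensity_near(ALPHA_DIAGNOSTIC_MZ) * scale
    has103, has90 = i103 >= threshold, i90 >= threshold
    if has103 and not has90:
        return FameCall("beta", reason=f"m/z 103 at {i103:.1f}%")
    if has90 and not has103:
        return FameCall("alpha", reason=f"m/z 90 at {i90:.1f}%")
    if has103 and has90:
        return FameCall("unclassified", reason="both diagnostics present")
    return FameCall("unclassified", reason="neither diagnostic present")


def assign_chain_length(
    spectrum: FameSpectrum,
    standard: FameSpectrum,
    standard_carbons: int = 16,
    increment: float = 1.0,
) -> int:
    """Carbon count from retention time relative to a known standard.

    Uses the classic linear FAME retention model: one ``increment``
    (minutes, calibration parameter) per carbon.
    """
    if increment <= 0:
        raise ValueError("per-carbon retention increment must be > 0")
    delta = spectrum.retention_time - standard.retention_time
    return standard_carbons + round(delta / increment)


def detect_branching_doublet(
    spectra: Sequence[FameSpectrum],
    window: float = 0.2,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[FameSpectrum, FameSpectrum]]:
    """Flag near-co-eluting pairs with identical hydroxyl classification.

    Such doublets are the GC signature of iso/anteiso branching variants,
    which are mass-identical and separate only slightly in retention.
    Pairs are returned in deterministic order (ascending retention time,
    then pair partner).
    """
    if window <= 0:
        raise ValueError("co-elution window must be > 0")
    ordered = sorted(spectra, key=lambda s: (s.retention_time, s.identifier))
    calls = [classify_hydroxy(s, threshold).hydroxyl for s in ordered]
    pairs = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if ordered[j].retention_time - ordered[i].retention_time > window:
                break
            if calls[i] == calls[j] and calls[i] != "unclassified":
                pairs.append((ordered[i], ordered[j]))
    return pairs


def compute_rf(migration: float, front: float) -> float:
    """TLC retention factor, reported to two decimals."""
    if front <= 0:
        raise ValueError("solvent front distance must be > 0")
    if not 0 <= migration <= front:
        raise ValueError("migration must lie in [0, front]")
    return round(migration / front, 2)
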