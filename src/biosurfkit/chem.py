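"""Mass model for cyclic acyl-heptapeptide biosurfactants (surfactin family).

Surfactin-type lipopeptides consist of a heptapeptide — canonically
Glu-Leu-Leu-Val-Asp-Leu-Leu — whose N-terminal amine is acylated by a
beta-hydroxy fatty acid, and whose C-terminal carboxyl closes a lactone
ring with the fatty-acid hydroxyl.  Natural products are mixtures of
homologues that differ only in the fatty-acid chain length, so both the
molecular adducts and every acyl-bearing fragment form ladders spaced by
one methylene unit (14.0157 Da).

Monoisotopic masses are the internal currency throughout.  Unit-resolution
instruments (triple quadrupoles) print integer m/z; those integers are
reproduced by rounding the monoisotopic m/z half-up (:func:`nominal_mz`).

Fragment enumeration follows the standard b/y nomenclature after opening
the lactone ring at the ester bond, which yields the canonical linear
acyl-peptide FA-Glu-Leu-Leu-Val-Asp-Leu-Leu.  b ions retain the acylated
N-terminal side, y ions the C-terminal side plus water; internal b-type
fragments arise from two backbone cleavages.  Acyl-bearing ions carry the
beta-hydroxyl and therefore show -H2O satellites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from pyteomics import mass as _pt_mass

__all__ = [
    "PROTON",
    "WATER",
    "METHYLENE",
    "UnknownResidueError",
    "ResidueMassTable",
    "FattyAcidVariant",
    "LipopeptideSpecies",
    "TheoreticalIon",
    "nominal_mz",
    "neutral_mass",
    "adduct_mz",
    "enumerate_fragments",
    "homologue_series",
    "SURFACTIN_SEQUENCE",
]

#: Mass of the charge carrier: a proton, not a hydrogen atom (Da).
PROTON = 1.00727646688
#: Monoisotopic mass of H2O (Da).
WATER = 18.0105646863
#: Monoisotopic mass of a CH2 unit — the homologue ladder spacing (Da).
METHYLENE = 14.0156500642

#: Monoisotopic element masses used for fatty-acid formula sums (Da).
_ELEMENT = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
}

#: Heptapeptide of surfactin and its homologues, one-letter codes.
SURFACTIN_SEQUENCE = "ELLVDLL"


def nominal_mz(mz: float) -> int:
    """Round a monoisotopic m/z half-up to the printed integer value."""
    return int(math.floor(mz + 0.5))


class UnknownResidueError(KeyError):
    """Raised when a sequence contains a residue code without a mass entry."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses (Da), keyed by one-letter code.

    Defaults to the standard amino-acid residue table.  Leu and Ile share
    the code ``L`` for mass purposes; L/D stereochemistry is ignored.
    """

    masses: dict[str, float] = field(
        default_factory=lambda: dict(_pt_mass.std_aa_mass)
    )

    def __post_init__(self) -> None:
        bad = [c for c, m in self.masses.items() if not m > 0]
        if bad:
            raise ValueError(f"non-positive residue masses for {bad!r}")

    def mass(self, code: str) -> float:
        try:
            return self.masses[code]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue code {code!r}; known: {sorted(self.masses)}"
            ) from None

    def peptide_residue_sum(self, sequence: str) -> float:
        """Sum of residue masses (no termini) for a sequence."""
        return sum(self.mass(c) for c in sequence)


DEFAULT_RESIDUE_TABLE = ResidueMassTable()

Hydroxyl = Literal["beta", "alpha"]
Branching = Literal["linear", "iso", "anteiso", "unknown"]
Topology = Literal["cyclic-lactone", "linear"]
Polarity = Literal["positive", "negative"]


@dataclass(frozen=True)
class FattyAcidVariant:
    """A (possibly branched) hydroxy fatty acid, e.g. beta-OH-C15:0.

    Branching (iso/anteiso) is metadata only: it never changes the mass,
    which is why iso and anteiso homologues co-elute as mass-identical
    doublets in GC rather than splitting in MS.
    """

    carbons: int
    hydroxyl: Hydroxyl = "beta"
    branching: Branching = "linear"
    double_bonds: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise ValueError(f"carbon count must be >= 4, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double-bond count must be >= 0")
        if self.hydroxyl not in ("beta", "alpha"):
            raise ValueError(f"hydroxyl must be beta|alpha, got {self.hydroxyl!r}")

    def formula(self) -> dict[str, int]:
        """Element counts of the free hydroxy acid (CnH(2n-2d)O3)."""
        n, d = self.carbons, self.double_bonds
        return {"C": n, "H": 2 * n - 2 * d, "O": 3}

    def mass(self) -> float:
        """Monoisotopic mass of the free acid (Da)."""
        return sum(_ELEMENT[el] * k for el, k in self.formula().items())

    def acyl_mass(self) -> float:
        """Monoisotopic mass of the acyl group (acid minus water, Da)."""
        return self.mass() - WATER


@dataclass(frozen=True)
class LipopeptideSpecies:
    """One chemically defined lipopeptide: peptide + fatty acid + topology."""

    sequence: str
    fatty_acid: FattyAcidVariant | None = None
    topology: Topology = "cyclic-lactone"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.topology == "cyclic-lactone":
            if self.fatty_acid is None:
                raise ValueError("cyclic-lactone topology requires a fatty acid")
            if self.fatty_acid.hydroxyl != "beta":
                raise ValueError(
                    "cyclic-lactone topology requires a beta-hydroxy fatty acid"
                )

    @classmethod
    def surfactin(
        cls,
        carbons: int,
        branching: Branching = "linear",
        topology: Topology = "cyclic-lactone",
    ) -> "LipopeptideSpecies":
        """The surfactin scaffold with a beta-OH fatty acid of given length."""
        return cls(
            sequence=SURFACTIN_SEQUENCE,
            fatty_acid=FattyAcidVariant(carbons, "beta", branching),
            topology=topology,
        )

    def with_carbons(self, carbons: int) -> "LipopeptideSpecies":
        if self.fatty_acid is None:
            raise ValueError("species has no fatty acid to vary")
        return replace(self, fatty_acid=replace(self.fatty_acid, carbons=carbons))


@dataclass(frozen=True)
class TheoreticalIon:
    """A theoretical ion: label, residue span (1-based, inclusive), m/z."""

    label: str
    span: tuple[int, int] | None
    mz: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"non-positive m/z for {self.label!r}")

    @property
    def nominal(self) -> int:
        return nominal_mz(self.mz)


def neutral_mass(
    species: LipopeptideSpecies,
    table: ResidueMassTable = DEFAULT_RESIDUE_TABLE,
) -> float:
    """Monoisotopic neutral mass (Da) of a lipopeptide species.

    The linear acyl-peptide is the residue-mass sum plus the intact fatty
    acid minus one water (the amide bond); equivalently residue sum plus
    acid, since peptide termini contribute one water.  Lactone cyclization
    removes one further water.  Without a fatty acid the species is a plain
    peptide (residue sum plus water).
    """
    residues = table.peptide_residue_sum(species.sequence)
    if species.fatty_acid is None:
        return residues + WATER
    m = residues + species.fatty_acid.mass()  # = residues + WATER + acyl
    if species.topology == "cyclic-lactone":
        m -= WATER
    return m


def adduct_mz(
    species: LipopeptideSpecies,
    polarity: Polarity,
    table: ResidueMassTable = DEFAULT_RESIDUE_TABLE,
) -> TheoreticalIon:
    """Singly protonated/deprotonated molecular ion of a species."""
    m = neutral_mass(species, table)
    n = len(species.sequence)
    if polarity == "positive":
        return TheoreticalIon("[M+H]+", (1, n), m + PROTON)
    if polarity == "negative":
        return TheoreticalIon("[M-H]-", (1, n), m - PROTON)
    raise ValueError(f"polarity must be positive|negative, got {polarity!r}")


def enumerate_fragments(
    species: LipopeptideSpecies,
    table: ResidueMassTable = DEFAULT_RESIDUE_TABLE,
    b_ions: bool = True,
    y_ions: bool = True,
    internal: bool = True,
    water_loss: bool = True,
) -> list[TheoreticalIon]:
    """Theoretical singly charged CID fragments of the linearized species.

    The cyclic lactone is first ring-opened at the ester bond, giving the
    canonical linear acyl-peptide (fatty acid amide-linked to residue 1).
    Returned series:

    * ``b1..b(N-1)``: acyl + N-terminal residues (+ proton);
    * ``y1..y(N-1)``: C-terminal residues + water (+ proton);
    * internal b-type ions for every contiguous interior span of length
      >= 2 (+ proton, no water);
    * ``-H2O`` satellites of acyl-bearing (b-series) ions, from loss of
      the beta-hydroxyl water.

    A linear species without fatty acid yields the plain peptide b/y
    series (no satellites).
    """
    seq = species.sequence
    n = len(seq)
    res = [table.mass(c) for c in seq]
    acyl = species.fatty_acid.acyl_mass() if species.fatty_acid else 0.0
    has_acyl = species.fatty_acid is not None

    out: list[TheoreticalIon] = []
    if b_ions:
        running = acyl
        for k in range(1, n):
            running += res[k - 1]
            mz = running + PROTON
            out.append(TheoreticalIon(f"b{k}", (1, k), mz))
            if water_loss and has_acyl:
                out.append(TheoreticalIon(f"b{k}-H2O", (1, k), mz - WATER))
    if y_ions:
        running = WATER
        for k in range(1, n):
            running += res[n - k]
            out.append(TheoreticalIon(f"y{k}", (n - k + 1, n), running + PROTON))
    if internal:
        # spans strictly inside the backbone: start > 1, end < N
        for i in range(2, n):
            running = 0.0
            for j in range(i, n):
                running += res[j - 1]
                if j > i:
                    label = f"internal({i}-{j})"
                    out.append(TheoreticalIon(label, (i, j), running + PROTON))
    return out


def homologue_series(
    species: LipopeptideSpecies,
    carbons: Iterable[int],
    polarity: Polarity,
    table: ResidueMassTable = DEFAULT_RESIDUE_TABLE,
) -> list[tuple[int, TheoreticalIon]]:
    """Molecular-ion ladder over fatty-acid chain lengths.

    Consecutive members differ by exactly one methylene mass; e.g. the
    C13..C16 series in negative mode prints as 1007/1021/1035/1049.
    """
    carbons = list(carbons)
    if not carbons:
        raise ValueError("carbon range must be non-empty")
    if any(b <= a for a, b in zip(carbons, carbons[1:])):
        raise ValueError("carbon range must be strictly ascending")
    return [
        (c, adduct_mz(species.with_carbons(c), polarity, table)) for c in carbons
    ]
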