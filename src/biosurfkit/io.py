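"""Readers/writers for the TSV formats the pipeline exchanges.

Everything tabular is tab-separated text with a header row; lipopeptide
definitions use a small ``key: value`` config format.  Validation is
schema-only (column presence, ranges, duplicates) and reports findings
with row numbers rather than raising, so a run can list every problem at
once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import Peak, Spectrum
from .chem import FattyAcidVariant, LipopeptideSpecies
from .cmc import TensionPoint
from .surface import ProbeLiquid
from .susceptibility import DilutionSeries, PlateAssay

__all__ = [
    "read_peaks",
    "write_peaks",
    "read_species_config",
    "write_species_config",
    "parse_fatty_acid",
    "format_fatty_acid",
    "write_ion_table",
    "read_angles",
    "read_liquids",
    "read_plate",
    "read_tension_curve",
    "write_tension_curve",
    "validate_inputs",
    "Finding",
]

# e.g. "C15:0-3OH,anteiso" — carbons : double bonds - hydroxyl position, branching
_FA_RE = re.compile(
    r"^C(?P<carbons>\d+):(?P<db>\d+)-(?P<pos>[23])OH(?:,(?P<branch>iso|anteiso|linear|unknown))?$"
)
_POS_TO_NAME = {"3": "beta", "2": "alpha"}
_NAME_TO_POS = {"beta": "3", "alpha": "2"}


def parse_fatty_acid(text: str) -> FattyAcidVariant:
    """Parse a fatty-acid shorthand like ``C15:0-3OH,anteiso``."""
    m = _FA_RE.match(text.strip())
    if not m:
        raise ValueError(
            f"cannot parse fatty acid {text!r}; expected e.g. 'C15:0-3OH,anteiso'"
        )
    return FattyAcidVariant(
        carbons=int(m["carbons"]),
        hydroxyl=_POS_TO_NAME[m["pos"]],
        branching=m["branch"] or "linear",
        double_bonds=int(m["db"]),
    )


def format_fatty_acid(fa: FattyAcidVariant) -> str:
    s = f"C{fa.carbons}:{fa.double_bonds}-{_NAME_TO_POS[fa.hydroxyl]}OH"
    if fa.branching != "linear":
        s += f",{fa.branching}"
    return s


def read_species_config(path: str | Path) -> LipopeptideSpecies:
    """Read a lipopeptide definition from a ``key: value`` config file.

    Recognized keys: ``sequence`` (one-letter residue string),
    ``fatty_acid`` (shorthand, optional), ``topology``
    (cyclic-lactone | linear, default cyclic-lactone).
    """
    kv: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key: value', got {line!r}")
        key, _, val = line.partition(":")
        kv[key.strip().lower()] = val.strip()
    if "sequence" not in kv:
        raise ValueError(f"{path}: missing required key 'sequence'")
    fa = parse_fatty_acid(kv["fatty_acid"]) if kv.get("fatty_acid") else None
    return LipopeptideSpecies(
        sequence=kv["sequence"],
        fatty_acid=fa,
        topology=kv.get("topology", "cyclic-lactone"),
    )


def write_species_config(species: LipopeptideSpecies, path: str | Path) -> None:
    lines = [f"sequence: {species.sequence}"]
    if species.fatty_acid is not None:
        lines.append(f"fatty_acid: {format_fatty_acid(species.fatty_acid)}")
    lines.append(f"topology: {species.topology}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaks(
    path: str | Path,
    polarity: str = "positive",
    level: int = 1,
    precursor: float | None = None,
) -> Spectrum:
    """Read a two-column (mz, intensity) TSV into a :class:`Spectrum`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("mz", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: peak list missing column {col!r}")
    peaks = tuple(
        Peak(float(m), float(i)) for m, i in zip(df["mz"], df["intensity"])
    )
    return Spectrum(peaks=peaks, polarity=polarity, level=level, precursor=precursor)


def write_peaks(spectrum: Spectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {"mz": [p.mz for p in spectrum.peaks], "intensity": [p.intensity for p in spectrum.peaks]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_ion_table(ions: Iterable, path: str | Path) -> None:
    """Write theoretical ions as TSV: label, span, monoisotopic_mz, nominal_mz."""
    rows = [
        {
            "label": ion.label,
            "span": "" if ion.span is None else f"{ion.span[0]}-{ion.span[1]}",
            "monoisotopic_mz": f"{ion.mz:.6f}",
            "nominal_mz": ion.nominal,
        }
        for ion in ions
    ]
    pd.DataFrame(rows, columns=["label", "span", "monoisotopic_mz", "nominal_mz"]).to_csv(
        path, sep="\t", index=False
    )


def read_angles(path: str | Path) -> pd.DataFrame:
    """Replicate-level contact-angle table: surface, treatment, liquid, angle_deg."""
    df = pd.read_csv(path, sep="\t")
    required = ["surface", "treatment", "liquid", "angle_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: angle table missing columns {missing}")
    return df


def read_liquids(path: str | Path) -> dict[str, ProbeLiquid]:
    """Probe-liquid constants table: liquid, gamma_tot, gamma_lw, gamma_plus, gamma_minus."""
    df = pd.read_csv(path, sep="\t")
    required = ["liquid", "gamma_tot", "gamma_lw", "gamma_plus", "gamma_minus"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: liquid table missing columns {missing}")
    return {
        r["liquid"]: ProbeLiquid(
            r["liquid"],
            float(r["gamma_tot"]),
            float(r["gamma_lw"]),
            float(r["gamma_plus"]),
            float(r["gamma_minus"]),
        )
        for _, r in df.iterrows()
    }


def read_plate(
    path: str | Path,
    subculture_path: str | Path | None = None,
    factor: float = 2.0,
) -> PlateAssay:
    """Plate TSV: a ``concentration`` column plus rep1..repN 0/1 columns."""

    def _matrix(p: str | Path) -> tuple[list[float], list[list[bool]]]:
        df = pd.read_csv(p, sep="\t")
        if "concentration" not in df.columns:
            raise ValueError(f"{p}: plate missing column 'concentration'")
        reps = [c for c in df.columns if c != "concentration"]
        if not reps:
            raise ValueError(f"{p}: plate has no replicate columns")
        concs = [float(c) for c in df["concentration"]]
        growth = [[bool(int(v)) for v in row] for row in df[reps].to_numpy()]
        return concs, growth

    concs, growth = _matrix(path)
    series = DilutionSeries(tuple(concs), factor)
    sub = None
    if subculture_path is not None:
        sub_concs, sub = _matrix(subculture_path)
        if sub_concs != concs:
            raise ValueError("subculture concentrations differ from plate")
    return PlateAssay.from_arrays(series, growth, sub)


def write_plate(plate: PlateAssay, path: str | Path, which: str = "growth") -> None:
    matrix = plate.growth if which == "growth" else plate.subculture
    if matrix is None:
        raise ValueError("plate has no subculture matrix")
    reps = len(matrix[0])
    df = pd.DataFrame(
        [
            {"concentration": c, **{f"rep{j+1}": int(v) for j, v in enumerate(row)}}
            for c, row in zip(plate.series.concentrations, matrix)
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_tension_curve(path: str | Path) -> list[TensionPoint]:
    df = pd.read_csv(path, sep="\t")
    required = ["concentration_mg_per_L", "tension_mN_per_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: tension curve missing columns {missing}")
    return [
        TensionPoint(float(c), float(t))
        for c, t in zip(df["concentration_mg_per_L"], df["tension_mN_per_m"])
    ]


def write_tension_curve(points: Sequence[TensionPoint], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "concentration_mg_per_L": [p.concentration for p in points],
            "tension_mN_per_m": [p.tension for p in points],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass(frozen=True)
class Finding:
    """One validation finding: file, row (1-based data row, 0 = file level), message."""

    path: str
    row: int
    message: str


_SCHEMAS = {
    "peaks": ["mz", "intensity"],
    "angles": ["surface", "treatment", "liquid", "angle_deg"],
    "plate": ["concentration"],
    "curve": ["concentration_mg_per_L", "tension_mN_per_m"],
    "liquids": ["liquid", "gamma_tot", "gamma_lw", "gamma_plus", "gamma_minus"],
}


def validate_inputs(paths: dict[str, str | Path]) -> list[Finding]:
    """Schema-check a set of input files; returns deterministic findings.

    ``paths`` maps a schema name (peaks | angles | plate | curve | liquids)
    to a file path.  No computation is performed; findings cover missing
    files, missing columns, out-of-range values and duplicated keys.
    """
    findings: list[Finding] = []
    for kind in sorted(paths):
        path = Path(paths[kind])
        if kind not in _SCHEMAS:
            findings.append(Finding(str(path), 0, f"unknown schema {kind!r}"))
            continue
        if not path.exists():
            findings.append(Finding(str(path), 0, "file does not exist"))
            continue
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # malformed file
            findings.append(Finding(str(path), 0, f"unreadable TSV: {exc}"))
            continue
        missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
        if missing:
            findings.append(
                Finding(str(path), 0, f"missing columns {missing}")
            )
            continue
        if kind == "peaks":
            for i, v in enumerate(df["mz"], 1):
                if not v > 0:
                    findings.append(Finding(str(path), i, f"non-positive m/z {v}"))
        elif kind == "angles":
            for i, v in enumerate(df["angle_deg"], 1):
                if not 0 <= v <= 180:
                    findings.append(
                        Finding(str(path), i, f"angle {v} outside [0, 180]")
                    )
        elif kind == "plate":
            seen: dict[float, int] = {}
            for i, v in enumerate(df["concentration"], 1):
                if v in seen:
                    findings.append(
                        Finding(
                            str(path),
                            i,
                            f"duplicated concentration {v} (first at row {seen[v]})",
                        )
                    )
                else:
                    seen[v] = i
        elif kind == "curve":
            for i, (c, t) in enumerate(
                zip(df["concentration_mg_per_L"], df["tension_mN_per_m"]), 1
            ):
                if not c > 0:
                    findings.append(
                        Finding(str(path), i, f"non-positive concentration {c}")
                    )
                if not 0 < t <= 100:
                    findings.append(
                        Finding(str(path), i, f"tension {t} outside (0, 100]")
                    )
    return findings
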