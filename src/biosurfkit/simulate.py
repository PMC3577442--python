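"""Seeded generators for every input the pipeline consumes.

Each generator returns a ``(data, truth)`` pair: the data in exactly the
container the downstream stage expects, and the ground-truth labels that
seeded it.  All randomness flows from an explicit integer seed through a
``numpy`` generator, so identical configurations reproduce identical
outputs byte for byte; changing the seed changes only noise realizations,
never the planted truth.

Noise models are deliberately minimal: Gaussian m/z jitter for peaks,
truncated-Gaussian contact angles, Bernoulli well growth, Gaussian
tension noise.  The defaults mirror the study conditions of the
lipopeptide characterization the package implements: a C13-C16 homologue
ladder read on a unit-resolution instrument, five-replicate twofold
plates from 80 ug/ml, ten-drop contact angles, and a tension curve
plateauing near 27 mN/m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import Peak, Spectrum
from .chem import (
    LipopeptideSpecies,
    Polarity,
    TheoreticalIon,
    adduct_mz,
    enumerate_fragments,
    homologue_series,
)
from .fames import FameSpectrum
from .cmc import TensionPoint
from .surface import (
    DEFAULT_LIQUIDS,
    ProbeLiquid,
    SurfaceComponents,
    forward_contact_angle,
)
from .susceptibility import DilutionSeries, PlateAssay, build_series

__all__ = [
    "gen_ms1",
    "gen_ms2",
    "gen_contact_angles",
    "gen_plate",
    "gen_tension_curve",
    "gen_fame_set",
]


def _decoy_mzs(
    rng: np.random.Generator,
    count: int,
    low: float,
    high: float,
    keepout: Sequence[float],
    min_offset: float,
) -> list[float]:
    """Uniform decoy m/z values at least ``min_offset`` from every keepout."""
    out: list[float] = []
    while len(out) < count:
        mz = float(rng.uniform(low, high))
        if all(abs(mz - k) >= min_offset for k in keepout):
            out.append(mz)
    return out


def gen_ms1(
    template: LipopeptideSpecies | None = None,
    carbons: Iterable[int] = range(13, 17),
    polarity: Polarity = "negative",
    decoys: int = 5,
    jitter_sd: float = 0.1,
    decoy_offset: float = 3.0,
    seed: int = 0,
) -> tuple[Spectrum, dict]:
    """MS1 spectrum with a planted homologue ladder plus off-grid decoys.

    Ladder peaks sit at the theoretical adduct m/z of each chain length
    plus Gaussian jitter (``jitter_sd`` = 0 puts them exactly on theory);
    decoys are uniform over the spectrum range but at least
    ``decoy_offset`` Da from every theoretical ladder position.  The truth
    dict maps carbon count to the planted (theoretical, observed) pair.
    """
    if jitter_sd < 0:
        raise ValueError("jitter sd must be >= 0")
    template = template or LipopeptideSpecies.surfactin(15)
    rng = np.random.default_rng(seed)
    ladder = homologue_series(template, list(carbons), polarity)
    peaks = []
    truth_members = {}
    for c, ion in ladder:
        mz = ion.mz + (rng.normal(0.0, jitter_sd) if jitter_sd else 0.0)
        intensity = float(rng.uniform(50.0, 100.0))
        peaks.append(Peak(mz, intensity))
        truth_members[c] = {"theoretical_mz": ion.mz, "observed_mz": mz}
    lo = min(i.mz for _, i in ladder) - 60.0
    hi = max(i.mz for _, i in ladder) + 60.0
    for mz in _decoy_mzs(
        rng, decoys, lo, hi, [i.mz for _, i in ladder], decoy_offset
    ):
        peaks.append(Peak(mz, float(rng.uniform(1.0, 40.0))))
    spectrum = Spectrum(peaks=tuple(peaks), polarity=polarity, level=1)
    truth = {
        "members": truth_members,
        "polarity": polarity,
        "decoys": decoys,
        "seed": seed,
    }
    return spectrum, truth


def gen_ms2(
    species: LipopeptideSpecies | None = None,
    fragments: Sequence[TheoreticalIon] | None = None,
    noise_peaks: int = 10,
    jitter_sd: float = 0.1,
    noise_offset: float = 1.0,
    seed: int = 0,
) -> tuple[Spectrum, dict]:
    """MS2 spectrum of one homologue: planted fragments plus noise peaks.

    Noise peaks are uniform below the precursor and at least
    ``noise_offset`` Da away from every theoretical fragment.
    """
    species = species or LipopeptideSpecies.surfactin(15)
    all_theo = enumerate_fragments(species)
    planted = list(fragments) if fragments is not None else all_theo
    precursor = adduct_mz(species, "positive")
    rng = np.random.default_rng(seed)
    peaks = []
    truth_frag = {}
    for ion in planted:
        mz = ion.mz + (rng.normal(0.0, jitter_sd) if jitter_sd else 0.0)
        peaks.append(Peak(mz, float(rng.uniform(30.0, 100.0))))
        truth_frag[ion.label] = {"theoretical_mz": ion.mz, "observed_mz": mz}
    keepout = [i.mz for i in all_theo] + [precursor.mz]
    for mz in _decoy_mzs(
        rng, noise_peaks, 60.0, precursor.mz, keepout, noise_offset
    ):
        peaks.append(Peak(mz, float(rng.uniform(1.0, 25.0))))
    spectrum = Spectrum(
        peaks=tuple(peaks), polarity="positive", level=2, precursor=precursor.mz
    )
    return spectrum, {"fragments": truth_frag, "precursor_mz": precursor.mz, "seed": seed}


def gen_contact_angles(
    truth: Mapping[tuple[str, str], SurfaceComponents],
    liquids: Mapping[str, ProbeLiquid] = DEFAULT_LIQUIDS,
    noise_sd: float = 0.5,
    replicates: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Replicate-level contact-angle table from known surface components.

    Angles come from the Young-Dupre forward model plus truncated-Gaussian
    noise confined to [0, 180] degrees.  ``truth`` maps
    (surface, treatment) to the generating components.
    """
    if noise_sd < 0:
        raise ValueError("angle noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for (surf, treat), comp in truth.items():
        for name, liq in liquids.items():
            theta = forward_contact_angle(comp, liq).theta_deg
            for rep in range(1, replicates + 1):
                if noise_sd:
                    a = float(np.clip(rng.normal(theta, noise_sd), 0.0, 180.0))
                else:
                    a = theta
                rows.append(
                    {
                        "surface": surf,
                        "treatment": treat,
                        "liquid": name,
                        "replicate": rep,
                        "angle_deg": a,
                    }
                )
    df = pd.DataFrame(rows)
    return df, {"components": dict(truth), "noise_sd": noise_sd, "seed": seed}


def gen_plate(
    series: DilutionSeries | None = None,
    true_mic: float = 5.0,
    p_growth: float = 1.0,
    p_partial: float | None = None,
    replicates: int = 5,
    with_subculture: bool = True,
    seed: int = 0,
) -> tuple[PlateAssay, dict]:
    """Microdilution plate with a planted MIC.

    Wells at concentrations >= ``true_mic`` are always clear.  Wells below
    grow with probability ``p_growth`` except the well immediately below
    the MIC (the MIC/2 well), which uses ``p_partial`` when given; to keep
    the planted MIC identifiable its first replicate is forced to grow,
    the rest are Bernoulli.  This mirrors plates where sub-MIC wells show
    growth in only some replicates.  The subculture matrix, when
    requested, is clear at and above the MIC and positive below, i.e. a
    bactericidal endpoint equal to the MIC.
    """
    series = series or build_series(80.0, 2.0, 1.2)
    if true_mic not in series.concentrations:
        raise ValueError(f"true MIC {true_mic} not in the dilution series")
    rng = np.random.default_rng(seed)
    concs = series.concentrations
    mic_idx = concs.index(true_mic)
    growth = []
    for i, c in enumerate(concs):
        if c >= true_mic:
            growth.append([False] * replicates)
            continue
        p = p_growth
        forced_first = False
        if i == mic_idx + 1 and p_partial is not None:
            p, forced_first = p_partial, True
        row = [bool(rng.random() < p) for _ in range(replicates)]
        if forced_first:
            row[0] = True
        growth.append(row)
    sub = None
    if with_subculture:
        sub = [[c < true_mic] * replicates for c in concs]
    plate = PlateAssay.from_arrays(series, growth, sub)
    return plate, {"true_mic": true_mic, "true_mbc": true_mic, "seed": seed}


def gen_tension_curve(
    true_cmc: float = 27.6,
    slope_pre: float = -25.0,
    plateau: float = 27.1,
    n_points: int = 20,
    decades: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[list[TensionPoint], dict]:
    """Two-segment tension curve with a planted breakpoint.

    Concentrations are log-spaced ``decades`` decades on each side of the
    true CMC (the CMC itself is always included so the noiseless knot is
    on-grid); tension falls at ``slope_pre`` mN/m per decade below the CMC
    and stays at ``plateau`` above it, plus Gaussian noise.
    """
    if true_cmc <= 0:
        raise ValueError("true CMC must be > 0")
    rng = np.random.default_rng(seed)
    lx = np.log10(true_cmc)
    xs = np.linspace(lx - decades, lx + decades, n_points)
    if not np.any(np.isclose(xs, lx)):
        xs = np.sort(np.append(xs, lx))
    points = []
    for x in xs:
        t = plateau + (slope_pre * (x - lx) if x < lx else 0.0)
        if noise_sd:
            t += rng.normal(0.0, noise_sd)
        points.append(TensionPoint(float(10.0 ** x), float(np.clip(t, 1.0, 100.0))))
    truth = {
        "true_cmc": true_cmc,
        "slope_pre": slope_pre,
        "plateau": plateau,
        "seed": seed,
    }
    return points, truth


def _fame_peaks(
    hydroxyl: str, rng: np.random.Generator
) -> tuple[tuple[float, float], ...]:
    base = [(74.0, float(rng.uniform(20.0, 50.0))), (55.0, float(rng.uniform(10.0, 30.0)))]
    if hydroxyl == "beta":
        base.append((103.0, 100.0))
    elif hydroxyl == "alpha":
        base.append((90.0, 80.0))
    return tuple(sorted(base))


def gen_fame_set(
    chain_lengths: Iterable[int] = range(13, 17),
    hydroxyl: str = "beta",
    rt_increment: float = 1.0,
    rt_standard: float = 20.0,
    rt_noise_sd: float = 0.0,
    branched_doublet: int | None = 15,
    doublet_gap: float = 0.05,
    seed: int = 0,
) -> tuple[list[FameSpectrum], dict]:
    """FAME spectra for a chain-length series plus the C16 standard.

    Retention times follow the linear carbon-number model anchored at the
    C16 standard (``rt_standard`` minutes).  When ``branched_doublet``
    names a chain length, that length is emitted twice ``doublet_gap``
    minutes apart, emulating mass-identical iso/anteiso variants.  The
    truth dict maps spectrum identifier to the planted carbon count.
    """
    rng = np.random.default_rng(seed)
    spectra = [
        FameSpectrum(
            retention_time=rt_standard,
            peaks=_fame_peaks("beta", rng),
            identifier="standard-C16",
        )
    ]
    truth = {"standard-C16": 16}
    for n in chain_lengths:
        rts = [rt_standard + (n - 16) * rt_increment]
        names = [f"C{n}"]
        if n == branched_doublet:
            rts = [rts[0] - doublet_gap / 2.0, rts[0] + doublet_gap / 2.0]
            names = [f"C{n}-iso", f"C{n}-anteiso"]
        for rt, name in zip(rts, names):
            if rt_noise_sd:
                rt += float(rng.normal(0.0, rt_noise_sd))
            spectra.append(
                FameSpectrum(
                    retention_time=rt,
                    peaks=_fame_peaks(hydroxyl, rng),
                    identifier=name,
                )
            )
            truth[name] = n
    return spectra, truth
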