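"""van Oss-Chaudhury-Good acid-base surface energetics from contact angles.

The total surface free energy of a solid is decomposed into an apolar
Lifshitz-van der Waals component gLW and Lewis acid-base electron-acceptor
and electron-donor parameters g+ and g-, with

    gAB  = 2 sqrt(g+ g-),        gTOT = gLW + gAB.

The Young-Dupre relation links the components of a solid ``s`` to the
contact angle theta of a probe liquid ``l`` of known components:

    (1 + cos theta) gl_TOT
        = 2 ( sqrt(gs_LW gl_LW) + sqrt(gs+ gl-) + sqrt(gs- gl+) ).

Measuring theta with three liquids of independent component vectors
(classically water, formamide and ethylene glycol) gives a 3x3 linear
system in the square roots of the unknown solid components.

Hydrophobicity is quantified by the free energy of interaction of two
slabs of the material immersed in water,

    dGiwi = -2 (sqrt(gs_LW) - sqrt(gw_LW))^2
            - 4 ( sqrt(gs+ gs-) + sqrt(gw+ gw-)
                  - sqrt(gs+ gw-) - sqrt(gs- gw+) ),

with dGiwi < 0 hydrophobic and dGiwi > 0 hydrophilic.

The module offers both the functional primitives and a statsmodels-style
``ContactAngleModel`` built from a replicate-level angle table whose
``fit()`` returns a :class:`ContactAngleResults` with per-surface energies
and a summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProbeLiquid",
    "WATER",
    "FORMAMIDE",
    "ETHYLENE_GLYCOL",
    "DEFAULT_LIQUIDS",
    "SurfaceComponents",
    "SurfaceEnergy",
    "ForwardAngle",
    "forward_contact_angle",
    "invert_components",
    "derive_ab_total",
    "compute_deltaG_iwi",
    "classify_wettability",
    "conditioning_delta",
    "surface_energy",
    "ContactAngleModel",
    "ContactAngleResults",
]


@dataclass(frozen=True)
class ProbeLiquid:
    """A probe liquid with known surface-tension components (mJ/m^2)."""

    name: str
    gamma_tot: float
    gamma_lw: float
    gamma_plus: float
    gamma_minus: float

    def __post_init__(self) -> None:
        for v in (self.gamma_tot, self.gamma_lw, self.gamma_plus, self.gamma_minus):
            if v < 0:
                raise ValueError(f"negative component for liquid {self.name!r}")
        # allow rounding slack in published tables
        if self.gamma_tot < self.gamma_lw - 0.5:
            raise ValueError(f"gamma_tot < gamma_lw for liquid {self.name!r}")


# Standard 20 degC probe-liquid constants (mJ/m^2), van Oss convention.
WATER = ProbeLiquid("water", 72.8, 21.8, 25.5, 25.5)
FORMAMIDE = ProbeLiquid("formamide", 58.0, 39.0, 2.28, 39.6)
ETHYLENE_GLYCOL = ProbeLiquid("ethylene glycol", 48.0, 29.0, 1.92, 47.0)

DEFAULT_LIQUIDS: dict[str, ProbeLiquid] = {
    liq.name: liq for liq in (WATER, FORMAMIDE, ETHYLENE_GLYCOL)
}


@dataclass(frozen=True)
class SurfaceComponents:
    """The three independent solid components (mJ/m^2)."""

    gamma_lw: float
    gamma_plus: float
    gamma_minus: float

    def __post_init__(self) -> None:
        for v in (self.gamma_lw, self.gamma_plus, self.gamma_minus):
            if v < 0:
                raise ValueError("surface components must be >= 0")


@dataclass(frozen=True)
class SurfaceEnergy:
    """Full energetic characterization of one surface (mJ/m^2)."""

    gamma_lw: float
    gamma_plus: float
    gamma_minus: float
    gamma_ab: float
    gamma_tot: float
    delta_g_iwi: float
    classification: Literal["hydrophobic", "hydrophilic"]
    boundary: bool = False
    negative_roots: tuple[str, ...] = ()
    condition_number: float = float("nan")

    @property
    def components(self) -> SurfaceComponents:
        return SurfaceComponents(self.gamma_lw, self.gamma_plus, self.gamma_minus)


@dataclass(frozen=True)
class ForwardAngle:
    """Predicted contact angle with physicality flag."""

    theta_deg: float
    cos_theta: float
    flag: Literal["ok", "complete-wetting", "non-physical"] = "ok"


def forward_contact_angle(
    components: SurfaceComponents, liquid: ProbeLiquid
) -> ForwardAngle:
    """Young-Dupre forward model: contact angle of a liquid on a surface.

    ``cos theta > 1`` is reported as complete wetting (theta = 0) with a
    flag; ``cos theta < -1`` is flagged non-physical (theta = 180).
    """
    if liquid.gamma_tot <= 0:
        raise ValueError("liquid gamma_tot must be > 0")
    rhs = 2.0 * (
        math.sqrt(components.gamma_lw * liquid.gamma_lw)
        + math.sqrt(components.gamma_plus * liquid.gamma_minus)
        + math.sqrt(components.gamma_minus * liquid.gamma_plus)
    )
    cos_theta = rhs / liquid.gamma_tot - 1.0
    if cos_theta > 1.0:
        return ForwardAngle(0.0, cos_theta, "complete-wetting")
    if cos_theta < -1.0:
        return ForwardAngle(180.0, cos_theta, "non-physical")
    return ForwardAngle(math.degrees(math.acos(cos_theta)), cos_theta, "ok")


def invert_components(
    angles_deg: Mapping[str, float],
    liquids: Mapping[str, ProbeLiquid] = DEFAULT_LIQUIDS,
    condition_threshold: float = 1e8,
) -> tuple[SurfaceComponents, dict]:
    """Solve the 3x3 Young-Dupre system for the solid components.

    ``angles_deg`` maps liquid name to the (mean) contact angle in
    degrees; exactly three liquids are required.  The system is linear in
    (sqrt(gs_LW), sqrt(gs+), sqrt(gs-)); components are the squared
    solutions.  Negative roots — common with noisy angles — are clamped
    to zero and recorded in the returned diagnostics dict, which also
    carries the condition number of the design matrix.
    """
    if len(angles_deg) != 3:
        raise ValueError("exactly three probe liquids are required")
    names = sorted(angles_deg)
    rows, rhs = [], []
    for name in names:
        try:
            liq = liquids[name]
        except KeyError:
            raise KeyError(f"no component constants for liquid {name!r}") from None
        rows.append(
            [
                math.sqrt(liq.gamma_lw),
                math.sqrt(liq.gamma_minus),
                math.sqrt(liq.gamma_plus),
            ]
        )
        theta = math.radians(angles_deg[name])
        rhs.append((1.0 + math.cos(theta)) * liq.gamma_tot / 2.0)
    a = np.array(rows)
    b = np.array(rhs)
    cond = float(np.linalg.cond(a))
    if not np.isfinite(cond) or cond > condition_threshold:
        raise ValueError(
            f"ill-conditioned liquid set {names} (condition number {cond:.3g}); "
            "choose liquids with independent component vectors"
        )
    roots = np.linalg.solve(a, b)  # sqrt(gLW), sqrt(g+), sqrt(g-)
    labels = ("gamma_lw", "gamma_plus", "gamma_minus")
    negative = tuple(lab for lab, r in zip(labels, roots) if r < 0)
    clamped = np.where(roots < 0, 0.0, roots)
    comp = SurfaceComponents(*(float(r * r) for r in clamped))
    return comp, {"negative_roots": negative, "condition_number": cond}


def derive_ab_total(
    gamma_plus: float, gamma_minus: float, gamma_lw: float
) -> tuple[float, float]:
    """Acid-base component and total surface energy from the parameters.

    gAB = 2 sqrt(g+ g-) is non-negative by construction; published tables
    occasionally print it signed, which is a tabulation convention, not a
    different quantity.
    """
    if min(gamma_plus, gamma_minus, gamma_lw) < 0:
        raise ValueError("components must be >= 0")
    gamma_ab = 2.0 * math.sqrt(gamma_plus * gamma_minus)
    return gamma_ab, gamma_lw + gamma_ab


def compute_deltaG_iwi(
    components: SurfaceComponents, water: ProbeLiquid = WATER
) -> float:
    """Free energy of self-interaction immersed in water (mJ/m^2)."""
    s, w = components, water
    apolar = -2.0 * (math.sqrt(s.gamma_lw) - math.sqrt(w.gamma_lw)) ** 2
    polar = -4.0 * (
        math.sqrt(s.gamma_plus * s.gamma_minus)
        + math.sqrt(w.gamma_plus * w.gamma_minus)
        - math.sqrt(s.gamma_plus * w.gamma_minus)
        - math.sqrt(s.gamma_minus * w.gamma_plus)
    )
    return apolar + polar


def classify_wettability(delta_g_iwi: float) -> tuple[str, bool]:
    """Strict sign rule: negative dGiwi = hydrophobic, positive = hydrophilic.

    Exactly zero is reported as hydrophilic with a boundary flag.
    """
    if not math.isfinite(delta_g_iwi):
        raise ValueError("delta_g_iwi must be finite")
    if delta_g_iwi < 0:
        return "hydrophobic", False
    return "hydrophilic", delta_g_iwi == 0


def surface_energy(
    components: SurfaceComponents,
    water: ProbeLiquid = WATER,
    negative_roots: tuple[str, ...] = (),
    condition_number: float = float("nan"),
) -> SurfaceEnergy:
    """Bundle components into a full :class:`SurfaceEnergy` record."""
    gamma_ab, gamma_tot = derive_ab_total(
        components.gamma_plus, components.gamma_minus, components.gamma_lw
    )
    dg = compute_deltaG_iwi(components, water)
    cls, boundary = classify_wettability(dg)
    return SurfaceEnergy(
        gamma_lw=components.gamma_lw,
        gamma_plus=components.gamma_plus,
        gamma_minus=components.gamma_minus,
        gamma_ab=gamma_ab,
        gamma_tot=gamma_tot,
        delta_g_iwi=dg,
        classification=cls,
        boundary=boundary,
        negative_roots=negative_roots,
        condition_number=condition_number,
    )


def conditioning_delta(
    control: SurfaceEnergy, treated: SurfaceEnergy
) -> dict:
    """Compare a conditioned surface against its control.

    Returns per-component differences (treated - control) plus qualitative
    verdicts: the hydrophobicity verdict follows the dGiwi ordering (a
    higher dGiwi is less hydrophobic), with an explicit note when the
    classification sign changes; the electron-donor verdict follows the
    gamma_minus ordering.
    """
    deltas = {
        k: getattr(treated, k) - getattr(control, k)
        for k in (
            "gamma_lw",
            "gamma_plus",
            "gamma_minus",
            "gamma_ab",
            "gamma_tot",
            "delta_g_iwi",
        )
    }
    if treated.delta_g_iwi > control.delta_g_iwi:
        hydro = "less hydrophobic"
    elif treated.delta_g_iwi < control.delta_g_iwi:
        hydro = "more hydrophobic"
    else:
        hydro = "unchanged"
    sign_change = treated.classification != control.classification
    if deltas["gamma_minus"] > 0:
        donor = "more electron-donating"
    elif deltas["gamma_minus"] < 0:
        donor = "less electron-donating"
    else:
        donor = "unchanged"
    return {
        "deltas": deltas,
        "hydrophobicity": hydro,
        "sign_change": sign_change,
        "classification": f"{control.classification} -> {treated.classification}",
        "electron_donor": donor,
    }


class ContactAngleModel:
    """Surface energetics fitted from a replicate-level contact-angle table.

    Parameters
    ----------
    data
        DataFrame with columns ``surface``, ``treatment``, ``liquid`` and
        ``angle_deg`` (one row per drop).  Replicates are averaged per
        (surface, treatment, liquid) before inversion.
    liquids
        Mapping of liquid name to :class:`ProbeLiquid`.
    water_name
        Which entry of ``liquids`` plays the immersion medium in dGiwi.
    """

    required_columns = ("surface", "treatment", "liquid", "angle_deg")

    def __init__(
        self,
        data: pd.DataFrame,
        liquids: Mapping[str, ProbeLiquid] = DEFAULT_LIQUIDS,
        water_name: str = "water",
    ) -> None:
        missing = [c for c in self.required_columns if c not in data.columns]
        if missing:
            raise ValueError(f"angle table missing columns {missing}")
        bad = data[(data["angle_deg"] < 0) | (data["angle_deg"] > 180)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} contact angle(s) outside [0, 180] degrees"
            )
        self.data = data.copy()
        self.liquids = dict(liquids)
        self.water = self.liquids[water_name]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "ContactAngleModel":
        return cls(data, **kw)

    def fit(self) -> "ContactAngleResults":
        means = (
            self.data.groupby(["surface", "treatment", "liquid"])["angle_deg"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        energies: dict[tuple[str, str], SurfaceEnergy] = {}
        for (surf, treat), grp in means.groupby(["surface", "treatment"]):
            angle_map = dict(zip(grp["liquid"], grp["mean"]))
            comp, diag = invert_components(angle_map, self.liquids)
            energies[(surf, treat)] = surface_energy(
                comp,
                self.water,
                negative_roots=diag["negative_roots"],
                condition_number=diag["condition_number"],
            )
        return ContactAngleResults(self, energies, means)


class ContactAngleResults:
    """Per-(surface, treatment) energies with summary and comparisons."""

    def __init__(
        self,
        model: ContactAngleModel,
        energies: dict[tuple[str, str], SurfaceEnergy],
        angle_means: pd.DataFrame,
    ) -> None:
        self.model = model
        self.energies = energies
        self.angle_means = angle_means

    def summary(self) -> pd.DataFrame:
        """One row per surface x treatment, mirroring published energy tables."""
        rows = []
        for (surf, treat), e in sorted(self.energies.items()):
            rows.append(
                {
                    "surface": surf,
                    "treatment": treat,
                    "gamma_lw": round(e.gamma_lw, 2),
                    "gamma_minus": round(e.gamma_minus, 2),
                    "gamma_plus": round(e.gamma_plus, 2),
                    "gamma_ab": round(e.gamma_ab, 2),
                    "gamma_tot": round(e.gamma_tot, 2),
                    "delta_g_iwi": round(e.delta_g_iwi, 1),
                    "classification": e.classification,
                    "negative_roots": ";".join(e.negative_roots),
                }
            )
        return pd.DataFrame(rows)

    def compare(self, control_label: str = "control") -> pd.DataFrame:
        """Conditioning verdicts of every non-control treatment per surface."""
        rows = []
        for (surf, treat), e in sorted(self.energies.items()):
            if treat == control_label:
                continue
            key = (surf, control_label)
            if key not in self.energies:
                continue
            verdict = conditioning_delta(self.energies[key], e)
            rows.append(
                {
                    "surface": surf,
                    "treatment": treat,
                    "delta_g_change": round(verdict["deltas"]["delta_g_iwi"], 1),
                    "hydrophobicity": verdict["hydrophobicity"],
                    "sign_change": verdict["sign_change"],
                    "classification": verdict["classification"],
                    "electron_donor": verdict["electron_donor"],
                }
            )
        return pd.DataFrame(rows)
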