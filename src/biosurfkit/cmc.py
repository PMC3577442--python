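"""Critical micelle concentration from tension-dilution curves.

Below the CMC the surface tension of a surfactant solution falls roughly
linearly with the logarithm of concentration; above it, added surfactant
goes into micelles and the tension plateaus.  The CMC is therefore
estimated as the knot of a continuous two-segment linear model in
(log10 concentration, tension), fitted by least squares with the knot
chosen by grid search over interior candidates (data abscissae plus a
dense grid), requiring at least two points on each side of the knot.
Ties in residual sum of squares break toward the lower concentration.

The module exposes a statsmodels-style :class:`CmcModel` whose ``fit()``
returns a :class:`CmcResults` carrying the breakpoint, segment slopes,
plateau tension and a seeded bootstrap confidence interval, plus the
functional wrappers ``fit_two_segment`` / ``estimate_cmc``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TensionPoint",
    "CmcFit",
    "CmcModel",
    "CmcResults",
    "fit_two_segment",
    "estimate_cmc",
]


@dataclass(frozen=True)
class TensionPoint:
    """One dilution: concentration (mg/L) and surface tension (mN/m)."""

    concentration: float
    tension: float
    interfacial_tension: float | None = None

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")
        if not 0 < self.tension <= 100:
            raise ValueError("surface tension must lie in (0, 100] mN/m")


@dataclass(frozen=True)
class CmcFit:
    """Two-segment fit summary; ``breakpoint`` is None for collinear data."""

    breakpoint: float | None  # concentration, mg/L
    slope_pre: float  # mN/m per decade, below the knot
    slope_post: float  # mN/m per decade, above the knot
    rss: float
    plateau: float  # mean fitted tension above the knot (mN/m)

    def __post_init__(self) -> None:
        if self.rss < -1e-12:
            raise ValueError("RSS must be >= 0")


def _segment_rss(
    x: np.ndarray, y: np.ndarray, knots: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched least-squares RSS of the continuous two-segment model.

    For each candidate knot ``c`` the design is [1, x, max(x - c, 0)];
    returns (rss, beta) arrays over candidates.
    """
    n = x.size
    hinge = np.maximum(x[None, :] - knots[:, None], 0.0)  # (k, n)
    d = np.empty((knots.size, n, 3))
    d[:, :, 0] = 1.0
    d[:, :, 1] = x[None, :]
    d[:, :, 2] = hinge
    ata = np.einsum("kni,knj->kij", d, d)
    aty = np.einsum("kni,n->ki", d, y)
    try:
        beta = np.linalg.solve(ata, aty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.einsum("kij,kj->ki", np.linalg.pinv(ata), aty)
    resid = np.einsum("kni,ki->kn", d, beta) - y[None, :]
    return np.einsum("kn,kn->k", resid, resid), beta


class CmcModel:
    """Two-segment tension model built from a list of tension points."""

    def __init__(self, points: Sequence[TensionPoint]) -> None:
        if len(points) < 5:
            raise ValueError("need at least 5 tension points")
        concs = [p.concentration for p in points]
        if len(set(concs)) != len(concs):
            raise ValueError("concentrations must be distinct")
        self.points = tuple(sorted(points, key=lambda p: p.concentration))
        self.x = np.log10([p.concentration for p in self.points])
        self.y = np.array([p.tension for p in self.points])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CmcModel":
        return cls(
            [
                TensionPoint(float(c), float(t))
                for c, t in zip(df["concentration_mg_per_L"], df["tension_mN_per_m"])
            ]
        )

    def _candidates(self, grid: int) -> np.ndarray:
        # interior knots leaving >= 2 points on each side
        lo, hi = self.x[1], self.x[-2]
        cands = self.x[(self.x >= lo) & (self.x <= hi)]
        if grid > 0 and hi > lo:
            cands = np.concatenate([cands, np.linspace(lo, hi, grid)])
        return np.unique(cands)

    def fit(self, grid: int = 200, collinear_tol: float = 1e-10) -> "CmcResults":
        """Grid-searched continuous two-segment least squares.

        ``grid`` extra equally spaced candidate knots are searched in
        addition to the interior data abscissae.  If a single straight
        line already fits to within ``collinear_tol`` (RSS relative to
        total variation), the data carry no breakpoint and the result says
        so instead of raising.
        """
        x, y = self.x, self.y
        # single-line reference fit
        d1 = np.column_stack([np.ones_like(x), x])
        beta1, *_ = np.linalg.lstsq(d1, y, rcond=None)
        rss1 = float(np.sum((d1 @ beta1 - y) ** 2))
        scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
        if rss1 <= collinear_tol * scale:
            fit = CmcFit(
                breakpoint=None,
                slope_pre=float(beta1[1]),
                slope_post=float(beta1[1]),
                rss=rss1,
                plateau=float(y[-1]),
            )
            return CmcResults(self, fit)
        knots = self._candidates(grid)
        rss, beta = _segment_rss(x, y, knots)
        best = int(np.argmin(rss))  # ties: argmin keeps the first = lowest knot
        b0, b1, b2 = beta[best]
        knot = float(knots[best])
        xs = x[x >= knot]
        if xs.size:
            plateau = float(np.mean(b0 + b1 * xs + b2 * (xs - knot)))
        else:
            plateau = float(y[-1])
        fit = CmcFit(
            breakpoint=float(10.0 ** knot),
            slope_pre=float(b1),
            slope_post=float(b1 + b2),
            rss=float(rss[best]),
            plateau=plateau,
        )
        return CmcResults(self, fit)


class CmcResults:
    """Fitted two-segment model: CMC estimate, slopes, bootstrap interval."""

    def __init__(self, model: CmcModel, fit: CmcFit) -> None:
        self.model = model
        self.fit_result = fit

    @property
    def cmc(self) -> float | None:
        """The CMC estimate (mg/L): the fitted breakpoint concentration."""
        return self.fit_result.breakpoint

    def bootstrap_ci(
        self,
        n_boot: int = 100,
        seed: int = 0,
        level: float = 0.95,
        grid: int = 60,
    ) -> tuple[float, float]:
        """Seeded residual-bootstrap percentile interval for the CMC.

        The concentration grid is a fixed design, so residuals of the
        fitted two-segment model are resampled with replacement onto the
        fitted values and the knot search is repeated on each replicate.
        Noiseless data have zero residuals, hence a zero-width interval.
        """
        f = self.fit_result
        if f.breakpoint is None:
            raise ValueError("no breakpoint was fitted")
        rng = np.random.default_rng(seed)
        x, y = self.model.x, self.model.y
        knot = np.log10(f.breakpoint)
        # fitted values from the stored segment parameters
        b1 = f.slope_pre
        b2 = f.slope_post - f.slope_pre
        # recover intercept from plateau: plateau is the mean fit over x >= knot
        xs = x[x >= knot]
        b0 = f.plateau - float(np.mean(b1 * xs + b2 * (xs - knot)))
        fitted = b0 + b1 * x + b2 * np.maximum(x - knot, 0.0)
        resid = y - fitted
        knots = self.model._candidates(grid)
        estimates = np.empty(n_boot)
        for i in range(n_boot):
            y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
            rss, _ = _segment_rss(x, y_star, knots)
            estimates[i] = 10.0 ** knots[int(np.argmin(rss))]
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def summary(self) -> str:
        f = self.fit_result
        lines = ["Two-segment tension fit (log10 concentration)"]
        if f.breakpoint is None:
            lines.append("  no breakpoint: data are collinear")
            lines.append(f"  slope          {f.slope_pre:10.4f} mN/m per decade")
        else:
            lines.append(f"  CMC            {f.breakpoint:10.4f} mg/L")
            lines.append(f"  pre-CMC slope  {f.slope_pre:10.4f} mN/m per decade")
            lines.append(f"  post-CMC slope {f.slope_post:10.4f} mN/m per decade")
            lines.append(f"  plateau        {f.plateau:10.4f} mN/m")
        lines.append(f"  RSS            {f.rss:10.6g}")
        return "\n".join(lines)


def fit_two_segment(points: Sequence[TensionPoint], grid: int = 200) -> CmcFit:
    """Functional wrapper: fit the two-segment model, return the fit record."""
    return CmcModel(points).fit(grid=grid).fit_result


def estimate_cmc(fit: CmcFit) -> float:
    """The CMC (mg/L) implied by a fitted breakpoint."""
    if fit.breakpoint is None:
        raise ValueError("fit has no breakpoint")
    return fit.breakpoint
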