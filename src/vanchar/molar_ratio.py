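"""Molar-ratio (continuous-variation style) stoichiometry determination.

Absorbance is measured across mixtures that sweep the metal mole fraction
x = [M]/([M]+[L]) from 0 to 1 at fixed total concentration.  With a
strongly formed ML_q complex the absorbance rises and falls linearly on
either side of the stoichiometric composition, so the intersection of the
two branch lines — the breakpoint — sits at x = 1/(1+q): 0.5 for a 1:1
complex, 1/3 for 1:2 (M:L).

:func:`fit_breakpoint` fits every admissible two-segment split by
ordinary least squares, keeps the split with the smallest total residual
sum of squares, and labels the stoichiometry from the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BreakpointError",
    "MolarRatioSeries",
    "BranchFit",
    "StoichiometryResult",
    "fit_breakpoint",
]


class BreakpointError(ValueError):
    """Raised when no admissible two-segment split exists."""


@dataclass
class MolarRatioSeries:
    """Absorbance against metal mole fraction [M]/([M]+[L])."""

    mole_fraction_metal: np.ndarray  # in [0, 1], strictly increasing
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.mole_fraction_metal = np.asarray(self.mole_fraction_metal, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if self.mole_fraction_metal.shape != self.absorbance.shape:
            raise ValueError("fraction and absorbance lengths differ")
        if self.mole_fraction_metal.size < 5:
            raise ValueError("at least 5 points are required")
        if np.any((self.mole_fraction_metal < 0) | (self.mole_fraction_metal > 1)):
            raise ValueError("mole fractions must lie in [0, 1]")
        if np.any(np.diff(self.mole_fraction_metal) <= 0):
            raise ValueError("mole fractions must be strictly increasing")


@dataclass
class BranchFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class StoichiometryResult:
    breakpoint: Optional[float]     # mole fraction, None when unassigned
    ratio_label: str                # "1:1" | "1:2" | "unassigned"
    branch_fits: tuple[BranchFit, BranchFit]
    split_index: int
    warnings: list[str] = field(default_factory=list)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line; returns slope, intercept, rss, r^2."""
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return float(slope), float(intercept), rss, r2


def fit_breakpoint(
    series: MolarRatioSeries,
    tol: float = 0.05,
    min_points_per_side: int = 3,
) -> StoichiometryResult:
    """Two-segment piecewise-linear fit of a molar-ratio series.

    Every interior split leaving at least ``min_points_per_side`` points
    per branch is fitted; the split minimizing total RSS wins, ties going
    to the smaller breakpoint.  The breakpoint is the intersection of the
    two branch lines and must fall strictly inside (0, 1); the label is
    1:1 when it lies within ``tol`` of 1/2, 1:2 within ``tol`` of 1/3,
    else "unassigned".  Parallel branches yield "unassigned" with a
    warning.
    """
    x = series.mole_fraction_metal
    y = series.absorbance
    n = x.size
    splits = range(min_points_per_side, n - min_points_per_side + 1)
    if not splits:
        raise BreakpointError(
            f"series of {n} points leaves no split with "
            f">= {min_points_per_side} points per side"
        )

    candidates = []  # (rss, breakpoint-or-inf, split, left, right)
    for i in splits:
        sl, il, rssl, r2l = _ols_line(x[:i], y[:i])
        sr, ir, rssr, r2r = _ols_line(x[i:], y[i:])
        rss = rssl + rssr
        if abs(sl - sr) > 1e-12 * max(abs(sl), abs(sr), 1.0):
            bp = (ir - il) / (sl - sr)
        else:
            bp = np.inf  # parallel; sorts after any finite breakpoint
        candidates.append(
            (rss, bp, i, BranchFit(sl, il, r2l), BranchFit(sr, ir, r2r))
        )

    best_rss = min(c[0] for c in candidates)
    scale = max(float(np.sum((y - y.mean()) ** 2)), 1e-30)
    near_best = [c for c in candidates if c[0] <= best_rss + 1e-10 * scale]
    near_best.sort(key=lambda c: (c[1], c[2]))  # tie -> smallest breakpoint
    rss, bp, split, left, right = near_best[0]

    warnings: list[str] = []
    if not np.isfinite(bp):
        warnings.append("branch lines are parallel; no intersection")
        return StoichiometryResult(None, "unassigned", (left, right), split, warnings)
    if not 0.0 < bp < 1.0:
        warnings.append(f"intersection {bp:.3f} outside (0, 1)")
        return StoichiometryResult(None, "unassigned", (left, right), split, warnings)

    if abs(bp - 0.5) <= tol:
        label = "1:1"
    elif abs(bp - 1.0 / 3.0) <= tol:
        label = "1:2"
    else:
        label = "unassigned"
    return StoichiometryResult(float(bp), label, (left, right), split, warnings)
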