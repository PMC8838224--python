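"""Benesi–Hildebrand estimation of DNA binding constants from titrations.

An absorption titration holds the compound concentration fixed and raises
the DNA concentration; for 1:1 association the double-reciprocal
linearization

    A0/(A − A0) = c + (c/K) · 1/[DNA],      c = εG/(εH−G − εG)

is a straight line in 1/[DNA], and the binding constant is the intercept
to slope ratio, K_b = intercept/slope.

The line is fitted by least squares on the transformed variables.  By
default the fit is inverse-variance weighted: under relative
(multiplicative) absorbance error the transformed ordinate has standard
deviation proportional to y·(1+y), which grows steeply toward the
high-1/[DNA] end of the plot, and an unweighted fit lets those noisiest
points dominate the slope.  ``weighted=False`` reproduces the plain
graphical (unweighted) estimator; both are exact on noise-free data.

The direction of the absorbance change classifies the chromism:
hyperchromic (absorbance grows with [DNA], electrostatic/groove binding)
or hypochromic (absorbance falls, intercalation), with a blue/red shift
read from the free vs bound band maxima when both are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FitError",
    "InsufficientDataError",
    "TitrationSeries",
    "BindingFit",
    "benesi_hildebrand_fit",
    "classify_chromism",
]


class FitError(ValueError):
    """Raised when the double-reciprocal fit cannot be carried out."""


class InsufficientDataError(FitError):
    """Raised when fewer than three usable titration points remain."""


@dataclass
class TitrationSeries:
    """Absorbance vs DNA concentration at one analytical wavelength."""

    a0: float
    dna_concentration: np.ndarray  # M, strictly increasing
    absorbance: np.ndarray
    lambda_free: Optional[float] = None   # nm
    lambda_bound: Optional[float] = None  # nm

    def __post_init__(self) -> None:
        self.dna_concentration = np.asarray(self.dna_concentration, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.dna_concentration.shape != self.absorbance.shape:
            raise ValueError("concentration and absorbance lengths differ")
        if self.dna_concentration.size < 3:
            raise ValueError("at least 3 titration points are required")
        if np.any(self.dna_concentration <= 0):
            raise ValueError("DNA concentrations must be strictly positive")
        if np.any(np.diff(self.dna_concentration) <= 0):
            raise ValueError("DNA concentrations must be strictly increasing")


@dataclass
class BindingFit:
    """Result of the Benesi–Hildebrand double-reciprocal fit."""

    k_b: float           # M^-1, intercept/slope
    slope: float
    intercept: float
    r_squared: float
    epsilon_ratio: float  # εG/(εH−G − εG), the fitted intercept
    chromism: str         # hyperchromic | hypochromic | indeterminate
    shift: str            # blue | red | none | unknown
    n_used: int
    excluded_points: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def classify_chromism(
    series: TitrationSeries, threshold: float = 0.01
) -> tuple[str, str]:
    """Label the absorbance response and band shift of a titration.

    Hyperchromic if the final absorbance exceeds A0 by more than
    ``threshold`` (relative), hypochromic if it falls below by more than
    that, else indeterminate.  The shift compares bound vs free band
    maxima ("unknown" when the bound maximum was not recorded).
    """
    rel_change = (series.absorbance[-1] - series.a0) / abs(series.a0)
    if rel_change > threshold:
        chromism = "hyperchromic"
    elif rel_change < -threshold:
        chromism = "hypochromic"
    else:
        chromism = "indeterminate"
    if series.lambda_bound is None or series.lambda_free is None:
        shift = "unknown"
    elif series.lambda_bound < series.lambda_free:
        shift = "blue"
    elif series.lambda_bound > series.lambda_free:
        shift = "red"
    else:
        shift = "none"
    return chromism, shift


def _fit_line(x: np.ndarray, y: np.ndarray, weighted: bool) -> tuple[float, float]:
    """Straight-line fit of the transformed points.

    The weighted branch runs a few reweighting iterations starting from
    the unweighted solution; weights follow the fitted (not observed)
    ordinate so the scheme is stable against single noisy points.
    """
    slope, intercept = np.polyfit(x, y, 1)
    if weighted:
        for _ in range(3):
            y_hat = np.abs(slope * x + intercept)
            w = 1.0 / np.maximum(y_hat * (1.0 + y_hat), 1e-12)  # ~1/sd(y)
            slope, intercept = np.polyfit(x, y, 1, w=w)
    return float(slope), float(intercept)


def benesi_hildebrand_fit(
    series: TitrationSeries,
    delta_floor: float = 1e-3,
    chromism_threshold: float = 0.01,
    weighted: bool = True,
) -> BindingFit:
    """Fit A0/(A−A0) against 1/[DNA] and return K_b = intercept/slope.

    Points with ``|A − A0|`` below ``delta_floor`` are excluded (the
    transform diverges there) and reported in the result.  If the
    remaining points mix signs of (A − A0), the majority-sign subset is
    fitted and the chromism is reported indeterminate with a warning.

    With ``weighted=True`` (default) the line is fitted by iteratively
    reweighted least squares with weights 1/(ŷ·(1+ŷ))², the inverse
    variance of the transform under relative absorbance error;
    ``weighted=False`` gives the plain unweighted graphical fit.
    """
    warnings: list[str] = []
    delta = series.absorbance - series.a0
    usable = np.abs(delta) >= delta_floor
    excluded = [int(i) for i in np.nonzero(~usable)[0]]
    if excluded:
        warnings.append(
            f"excluded {len(excluded)} point(s) with |A - A0| < {delta_floor:g}"
        )
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} usable points (need >= 3)"
        )

    chromism, shift = classify_chromism(series, chromism_threshold)
    signs = np.sign(delta[usable])
    if signs.min() != signs.max():
        majority = 1.0 if (signs > 0).sum() >= (signs < 0).sum() else -1.0
        minority_idx = np.nonzero(usable & (np.sign(delta) != majority))[0]
        usable = usable & (np.sign(delta) == majority)
        excluded.extend(int(i) for i in minority_idx)
        warnings.append(
            "mixed signs of (A - A0); fitted the majority-sign subset, "
            "chromism is indeterminate"
        )
        chromism = "indeterminate"
        if int(usable.sum()) < 3:
            raise InsufficientDataError(
                "fewer than 3 points remain after majority-sign filtering"
            )

    x = 1.0 / series.dna_concentration[usable]
    y = series.a0 / delta[usable]
    slope, intercept = _fit_line(x, y, weighted)
    y_span = max(float(np.ptp(y)), abs(float(np.mean(y))), 1e-30)
    if abs(slope) * float(np.ptp(x)) < 1e-9 * y_span:
        raise FitError("no concentration dependence: slope is zero within tolerance")
    fitted = slope * x + intercept
    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - float(np.sum((y - fitted) ** 2)) / tss if tss > 0 else 1.0
    return BindingFit(
        k_b=intercept / slope,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        epsilon_ratio=intercept,
        chromism=chromism,
        shift=shift,
        n_used=int(usable.sum()),
        excluded_points=sorted(excluded),
        warnings=warnings,
    )
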