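"""Thermogravimetric step segmentation and decomposition kinetics.

A thermogram records remaining mass (% of initial) against temperature at
constant heating rate β.  Segmentation finds mass-loss steps from the
smoothed DTG signal (|dm/dT|): contiguous regions above a noise-scaled
threshold are grown outward to the bounding plateaus, and each step
carries its conversion profile α(T) = (m_start − m)/(m_start − m_end).

Kinetics assume a single first-order decomposition per step.  Two
single-heating-rate linearizations are provided:

* Coats–Redfern:       ln[−ln(1−α)/T²]  vs  1/T,  slope = −E_a/R
* Horowitz–Metzger:    ln[−ln(1−α)]     vs  θ = T − T_s,
                       slope = E_a/(R·T_s²),

with T_s the DTG-peak temperature of the step.  Activation thermodynamics
follow transition-state expressions evaluated at T_s:
ΔH = E_a − R·T_s, ΔS = R·ln(A·h/(k_B·T_s)) with A in s⁻¹, ΔG = ΔH − T_s·ΔS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .constants import BOLTZMANN_K, PLANCK_H, R_GAS
from .formulas import MolecularFormula, mass_loss_percent

__all__ = [
    "ThermogramError",
    "ThermogramCurve",
    "MassLossStep",
    "KineticFit",
    "AssignmentCheck",
    "segment_steps",
    "check_step_assignment",
    "coats_redfern_fit",
    "horowitz_metzger_fit",
]


class ThermogramError(ValueError):
    """Raised for invalid thermogram input or unusable conversion data."""


@dataclass
class ThermogramCurve:
    """Remaining-mass curve at constant heating rate.

    Temperatures are kelvin internally; use :meth:`from_celsius` for
    instrument output in °C.
    """

    temperature: np.ndarray        # K, strictly increasing
    mass_percent: np.ndarray       # % of initial mass
    heating_rate_beta: float       # K/min

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.mass_percent = np.asarray(self.mass_percent, dtype=float)
        if self.temperature.shape != self.mass_percent.shape:
            raise ThermogramError("temperature and mass arrays differ in length")
        if self.temperature.size < 20:
            raise ThermogramError("thermogram too short to analyse (need >= 20 points)")
        if np.any(np.diff(self.temperature) <= 0):
            raise ThermogramError("temperatures must be strictly increasing")
        if not self.heating_rate_beta > 0:
            raise ThermogramError("heating rate must be positive")

    @classmethod
    def from_celsius(
        cls, temperature_c, mass_percent, heating_rate_beta: float
    ) -> "ThermogramCurve":
        return cls(np.asarray(temperature_c, float) + 273.15,
                   mass_percent, heating_rate_beta)


@dataclass
class MassLossStep:
    """One decomposition step cut out of a thermogram."""

    t_start: float                 # K
    t_end: float                   # K
    percent_loss: float            # % of initial mass
    temperature: np.ndarray        # K, within the step
    alpha: np.ndarray              # conversion in [0, 1], non-decreasing
    t_peak: float                  # K, DTG-peak temperature (T_s)
    assigned_fragment: Optional[MolecularFormula] = None


@dataclass
class KineticFit:
    """Kinetic and activation-thermodynamic parameters of one step."""

    method: str                    # coats_redfern | horowitz_metzger
    e_a: float                     # kJ/mol
    pre_exponential_a: float       # min^-1
    r_squared: float
    t_s: float                     # K
    delta_h: float                 # kJ/mol
    delta_s: float                 # J/(mol K)
    delta_g: float                 # kJ/mol


@dataclass
class AssignmentCheck:
    """Comparison of an observed step loss with a fragment's formula mass."""

    passed: bool
    expected_percent: float
    observed_percent: float
    deviation: float


def _smooth(mass: np.ndarray, window: int) -> np.ndarray:
    window = min(window, mass.size if mass.size % 2 else mass.size - 1)
    if window < 5:
        return mass.copy()
    if window % 2 == 0:
        window -= 1
    return savgol_filter(mass, window, 3)


def segment_steps(
    curve: ThermogramCurve,
    min_loss_percent: float = 1.0,
    *,
    window: int = 31,
    gap_K: float = 25.0,
    peak_frac: float = 0.02,
    stop_frac: float = 0.002,
    monotone_tol: float = 0.5,
) -> list[MassLossStep]:
    """Locate mass-loss steps from the smoothed DTG signal.

    Candidate regions are where the loss rate −dm/dT exceeds
    ``max(peak_frac · global peak, 5 · MAD noise)``; regions separated by
    less than ``gap_K`` are merged and each region is grown outward until
    the rate falls below ``stop_frac`` of its own peak (or the midpoint to
    the neighbouring region).  Start/end masses are read as medians of the
    bounding plateaus, which keeps the measured loss robust to point
    noise, and steps losing less than ``min_loss_percent`` are dropped.
    Raw curves that *gain* more than ``monotone_tol`` mass percent beyond
    smoothing noise are rejected.
    """
    if not min_loss_percent > 0:
        raise ValueError("min_loss_percent must be > 0")
    T = curve.temperature
    smoothed = _smooth(curve.mass_percent, window)
    if np.max(smoothed) - smoothed[0] > monotone_tol or np.any(
        np.diff(smoothed) > monotone_tol
    ):
        raise ThermogramError(
            "mass curve increases beyond smoothing tolerance; not a loss curve"
        )
    rate = -np.gradient(smoothed, T)          # %/K, positive when losing mass
    peak_rate = float(rate.max(initial=0.0))
    if peak_rate <= 0:
        return []
    mad = float(np.median(np.abs(rate - np.median(rate)))) * 1.4826
    threshold = max(peak_frac * peak_rate, 5.0 * mad)

    above = rate > threshold
    if not above.any():
        return []
    # contiguous candidate regions [i0, i1] inclusive
    idx = np.nonzero(above)[0]
    regions: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if T[i] - T[regions[-1][1]] <= gap_K:
            regions[-1][1] = int(i)
        else:
            regions.append([int(i), int(i)])

    # grow regions to their own-rate stop threshold, bounded by neighbours
    grown: list[tuple[int, int]] = []
    for k, (i0, i1) in enumerate(regions):
        own_peak = float(rate[i0 : i1 + 1].max())
        stop = max(stop_frac * own_peak, 3.0 * mad)
        lo_limit = 0 if k == 0 else (regions[k - 1][1] + i0) // 2
        hi_limit = T.size - 1 if k == len(regions) - 1 else (i1 + regions[k + 1][0]) // 2
        while i0 > lo_limit and rate[i0 - 1] > stop:
            i0 -= 1
        while i1 < hi_limit and rate[i1 + 1] > stop:
            i1 += 1
        grown.append((i0, i1))

    steps: list[MassLossStep] = []
    for k, (i0, i1) in enumerate(grown):
        left_lo = 0 if k == 0 else grown[k - 1][1] + 1
        right_hi = T.size if k == len(grown) - 1 else grown[k + 1][0]
        left_plateau = smoothed[left_lo:i0]
        right_plateau = smoothed[i1 + 1 : right_hi]
        m_start = float(np.median(left_plateau)) if left_plateau.size else float(smoothed[i0])
        m_end = float(np.median(right_plateau)) if right_plateau.size else float(smoothed[i1])
        loss = m_start - m_end
        if loss < min_loss_percent:
            continue
        seg = slice(i0, i1 + 1)
        alpha = np.clip((m_start - smoothed[seg]) / loss, 0.0, 1.0)
        alpha = np.maximum.accumulate(alpha)
        t_peak = float(T[i0 + int(np.argmax(rate[seg]))])
        steps.append(
            MassLossStep(
                t_start=float(T[i0]),
                t_end=float(T[i1]),
                percent_loss=loss,
                temperature=T[seg].copy(),
                alpha=alpha,
                t_peak=t_peak,
            )
        )
    return steps


def check_step_assignment(
    step: MassLossStep,
    fragment: MolecularFormula,
    parent: MolecularFormula,
    tolerance: float,
) -> AssignmentCheck:
    """Test whether a fragment formula accounts for a step's mass loss."""
    expected = mass_loss_percent(fragment, parent)
    deviation = step.percent_loss - expected
    return AssignmentCheck(
        passed=abs(deviation) <= tolerance,
        expected_percent=expected,
        observed_percent=step.percent_loss,
        deviation=deviation,
    )


def _alpha_window(step: MassLossStep, lo: float, hi: float):
    mask = (step.alpha >= lo) & (step.alpha <= hi)
    if int(mask.sum()) < 5:
        raise ThermogramError(
            f"only {int(mask.sum())} points with conversion in [{lo}, {hi}]; "
            "need >= 5 for a kinetic fit"
        )
    return step.temperature[mask], step.alpha[mask]


def _thermodynamics(e_a: float, a_per_min: float, t_s: float):
    """ΔH, ΔS, ΔG from E_a (J/mol) and A (min⁻¹) at T_s; SI inside."""
    a_per_s = a_per_min / 60.0
    delta_h = e_a - R_GAS * t_s
    delta_s = R_GAS * math.log(a_per_s * PLANCK_H / (BOLTZMANN_K * t_s))
    delta_g = delta_h - t_s * delta_s
    return delta_h, delta_s, delta_g


def coats_redfern_fit(
    step: MassLossStep,
    beta: float,
    alpha_range: tuple[float, float] = (0.05, 0.95),
) -> KineticFit:
    """First-order Coats–Redfern fit of one decomposition step.

    Linear regression of ln[−ln(1−α)/T²] on 1/T gives E_a = −slope·R; the
    intercept ln[A·R/(β·E_a)] yields the pre-exponential factor (the small
    (1 − 2RT/E_a) correction is neglected, as is customary).
    """
    T, alpha = _alpha_window(step, *alpha_range)
    y = np.log(-np.log1p(-alpha) / T**2)
    x = 1.0 / T
    res = linregress(x, y)
    e_a = -res.slope * R_GAS
    if e_a <= 0:
        raise ThermogramError("Coats-Redfern slope implies non-positive E_a")
    a = math.exp(res.intercept) * beta * e_a / R_GAS
    t_s = step.t_peak
    dh, ds, dg = _thermodynamics(e_a, a, t_s)
    return KineticFit(
        method="coats_redfern",
        e_a=e_a / 1e3,
        pre_exponential_a=a,
        r_squared=res.rvalue**2,
        t_s=t_s,
        delta_h=dh / 1e3,
        delta_s=ds,
        delta_g=dg / 1e3,
    )


def horowitz_metzger_fit(
    step: MassLossStep,
    beta: float,
    alpha_range: tuple[float, float] = (0.05, 0.95),
) -> KineticFit:
    """First-order Horowitz–Metzger fit of one decomposition step.

    Linear regression of ln[−ln(1−α)] on θ = T − T_s gives
    E_a = slope·R·T_s²; A follows from the intercept
    ln[A·R·T_s²/(β·E_a)] − E_a/(R·T_s).
    """
    T, alpha = _alpha_window(step, *alpha_range)
    t_s = step.t_peak
    theta = T - t_s
    y = np.log(-np.log1p(-alpha))
    res = linregress(theta, y)
    e_a = res.slope * R_GAS * t_s**2
    if e_a <= 0:
        raise ThermogramError("Horowitz-Metzger slope implies non-positive E_a")
    a = math.exp(res.intercept + e_a / (R_GAS * t_s)) * beta * e_a / (R_GAS * t_s**2)
    dh, ds, dg = _thermodynamics(e_a, a, t_s)
    return KineticFit(
        method="horowitz_metzger",
        e_a=e_a / 1e3,
        pre_exponential_a=a,
        r_squared=res.rvalue**2,
        t_s=t_s,
        delta_h=dh / 1e3,
        delta_s=ds,
        delta_g=dg / 1e3,
    )
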