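"""Synthetic instrument-output generators for every analysis stage.

Each generator is a pure function of its arguments including the seed,
and its zero-noise output is an exact fixed point of the matching
estimator: a noise-free titration transforms to an exact
Benesi–Hildebrand line, a noise-free thermogram yields first-order steps
whose Coats–Redfern fit returns the generating activation energy, an
ideal molar-ratio series breaks exactly at the stoichiometric mole
fraction, and a zero-noise descriptor table is exactly linear.

Noise models: multiplicative Gaussian on absorbances (instrument-like
relative error), additive Gaussian on thermogram mass percent, additive
Gaussian on the QSAR response.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import R_GAS
from .dna_binding import TitrationSeries
from .molar_ratio import MolarRatioSeries
from .tga import ThermogramCurve

import pandas as pd

__all__ = [
    "default_dna_grid",
    "default_mole_fractions",
    "gen_titration",
    "gen_thermogram",
    "gen_molar_ratio",
    "gen_qsar_table",
    "DEFAULT_QSAR_COEFFICIENTS",
    "DEFAULT_QSAR_INTERCEPT",
    "DEFAULT_DESCRIPTOR_RANGES",
]


def default_dna_grid(n: int = 10) -> np.ndarray:
    """Log-spaced DNA concentration grid over [1e-7, 1e-5] M."""
    return np.logspace(-7, -5, n)


def default_mole_fractions() -> np.ndarray:
    """The seven-flask molar-ratio design: mole fractions 0, 1/6, ..., 1."""
    return np.linspace(0.0, 1.0, 7)


def gen_titration(
    true_k: float = 1.40e6,
    a0: float = 0.5,
    epsilon_ratio: float = 1.0,
    dna_grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    lambda_free: float = 265.0,
    lambda_bound: float = 259.0,
) -> TitrationSeries:
    """Simulate a 1:1 binding titration obeying the double-reciprocal law.

    The absorbance at DNA concentration D inverts the Benesi–Hildebrand
    line A0/(A−A0) = c·(1 + 1/(K·D)) with c = ``epsilon_ratio``, so the
    zero-noise series is exactly linear in the transformed variables and
    the fit recovers ``true_k`` exactly.  ``noise_sd`` is the relative
    standard deviation of multiplicative Gaussian noise on A.
    """
    if not true_k > 0:
        raise ValueError("true_k must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = default_dna_grid() if dna_grid is None else np.asarray(dna_grid, float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("dna_grid must be positive and strictly increasing")
    y = epsilon_ratio * (1.0 + 1.0 / (true_k * grid))
    if np.any(y == 0):
        raise ValueError("grid makes A - A0 vanish")
    a = a0 + a0 / y
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a * (1.0 + rng.normal(0.0, noise_sd, size=a.shape))
    return TitrationSeries(
        a0=a0,
        dna_concentration=grid,
        absorbance=a,
        lambda_free=lambda_free,
        lambda_bound=lambda_bound,
    )


def gen_thermogram(
    steps: Sequence[tuple[float, float, float]] = ((9.44, 120.0, 1e10),),
    beta: float = 10.0,
    t_range: tuple[float, float] = (298.15, 1100.0),
    t_step: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ThermogramCurve:
    """Simulate a constant-heating-rate thermogram of first-order steps.

    ``steps`` lists ``(percent_loss, E_a kJ/mol, A min^-1)`` per
    decomposition step.  Each conversion profile integrates the
    first-order non-isothermal rate law
    dα/dT = (A/β)·exp(−E_a/(R·T))·(1−α) numerically (cumulative
    trapezoid on the temperature grid), and the remaining mass is
    100 − Σ fᵢ·αᵢ(T).  ``noise_sd`` is additive Gaussian noise in mass
    percent.
    """
    fractions = [s[0] for s in steps]
    if sum(fractions) >= 100.0:
        raise ValueError("step percents must sum to < 100")
    if any(f <= 0 for f in fractions):
        raise ValueError("step percents must be positive")
    if any(s[1] <= 0 for s in steps):
        raise ValueError("activation energies must be positive")
    T = np.arange(t_range[0], t_range[1] + t_step / 2, t_step)
    mass = np.full_like(T, 100.0)
    alphas = []
    for frac, e_a_kj, a_min in steps:
        e_a = e_a_kj * 1e3
        integral = cumulative_trapezoid(np.exp(-e_a / (R_GAS * T)), T, initial=0.0)
        alpha = 1.0 - np.exp(-(a_min / beta) * integral)
        alphas.append(alpha)
        mass = mass - frac * alpha
    _warn_on_overlap(T, alphas)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mass = mass + rng.normal(0.0, noise_sd, size=mass.shape)
    return ThermogramCurve(T, mass, beta)


def _warn_on_overlap(T: np.ndarray, alphas: list[np.ndarray]) -> None:
    """Warn when consecutive steps' active windows (alpha 1%-99%) merge."""
    import warnings as _warnings

    windows = []
    for alpha in alphas:
        active = (alpha > 0.01) & (alpha < 0.99)
        if active.any():
            idx = np.nonzero(active)[0]
            windows.append((T[idx[0]], T[idx[-1]]))
    windows.sort()
    for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
        if lo2 < hi1:
            _warnings.warn(
                "decomposition step windows overlap; segmentation may merge them",
                stacklevel=3,
            )


def gen_molar_ratio(
    ratio: str = "1:2",
    max_abs: float = 1.0,
    fractions: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MolarRatioSeries:
    """Simulate an ideal-complexation molar-ratio series.

    With an effectively infinite formation constant the complex amount at
    metal mole fraction x is min(x, (1−x)/q) for an ML_q complex, so the
    absorbance is piecewise linear with its break at x = 1/(1+q) and peak
    ``max_abs``.  ``noise_sd`` is the relative sd of multiplicative
    Gaussian noise.
    """
    if ratio not in ("1:1", "1:2"):
        raise ValueError("ratio must be '1:1' or '1:2'")
    q = 1 if ratio == "1:1" else 2
    x = default_mole_fractions() if fractions is None else np.asarray(fractions, float)
    x_break = 1.0 / (1.0 + q)
    a = max_abs * np.minimum(x, (1.0 - x) / q) / x_break
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a * (1.0 + rng.normal(0.0, noise_sd, size=a.shape))
    return MolarRatioSeries(x, a)


DEFAULT_QSAR_COEFFICIENTS = {
    "ASA_P": 0.5,
    "ASA_H": -0.2,
    "h_pkp": 3.0,
    "dipole": 1.0,
}
DEFAULT_QSAR_INTERCEPT = 7.0
DEFAULT_DESCRIPTOR_RANGES = {
    "ASA_P": (50.0, 400.0),    # polar surface area, Angstrom^2
    "ASA_H": (200.0, 800.0),   # hydrophobic surface area, Angstrom^2
    "h_pkp": (2.0, 14.0),      # protonation pKb at pH 7
    "dipole": (1.0, 15.0),     # Debye
}


def gen_qsar_table(
    n: int = 100,
    coefficients: Optional[dict[str, float]] = None,
    intercept: float = DEFAULT_QSAR_INTERCEPT,
    descriptor_ranges: Optional[dict[str, tuple[float, float]]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a descriptor/activity table from a known linear model.

    Descriptors are uniform over their ranges; the response is the exact
    linear combination plus additive Gaussian noise of sd ``noise_sd``
    (response units).  A zero-width descriptor range produces a constant
    column with a warning.
    """
    import warnings as _warnings

    if n <= 5:
        raise ValueError("need n > 5 records")
    coeffs = dict(DEFAULT_QSAR_COEFFICIENTS if coefficients is None else coefficients)
    ranges = dict(DEFAULT_DESCRIPTOR_RANGES if descriptor_ranges is None else descriptor_ranges)
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name, (lo, hi) in ranges.items():
        if hi == lo:
            _warnings.warn(f"descriptor {name!r} has zero-width range; constant column")
            data[name] = np.full(n, float(lo))
        else:
            data[name] = rng.uniform(lo, hi, size=n)
    y = np.full(n, float(intercept))
    for name, b in coeffs.items():
        y = y + b * data[name]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    table = pd.DataFrame({"compound_id": [f"S{i:03d}" for i in range(1, n + 1)]})
    for name in ranges:
        table[name] = data[name]
    table["IC50"] = y
    return table
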