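# Methods

This note records the models behind each stage, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would want to know.

## Formula arithmetic

Formulas are parsed from the dialect coordination chemists actually
write: Hill-style element runs, nested brackets with multipliers,
subscript underscores from typeset tables, and hydrate/adduct segments
separated by a centered dot or whitespace with a leading integer
multiplicity (`8H2O`). A single-segment string keeps its leading
integer as a `multiplicity` field; multi-segment strings are combined
into one expanded composition. Formatting follows the Hill convention
(C, H, then alphabetical; purely alphabetical without carbon), so a
vanadyl residue prints as `O2V` — compare compositions, not strings,
when the conventional order matters.

Masses use one fixed table of abridged standard atomic weights shipped
with the package (`data/atomic_weights.csv`), so two-decimal masses and
percentages are identical across installations regardless of other
chemistry libraries present. Reported masses and percentages round to
two decimals, half away from zero (`decimal`-based, avoiding binary
half-case surprises). Published compound tables of this kind contain
arithmetic slips; the package therefore always reports *recomputed*
values and flags deviations from user-supplied nominal masses beyond
0.1 g/mol in the pipeline's consistency log rather than silently
adopting either number.

Fragment suggestion is an exhaustive bounded enumeration over
sub-multisets of the parent (optionally restricted to an element pool),
capped by `max_atoms`; candidates within tolerance of the target loss
are sorted by |deviation|, then fewer atoms, then formula string. A
1 ppb epsilon on the tolerance comparison keeps exact-mass matches
(e.g. the parent itself at 100%) from being lost to float summation
order.

## Reactivity descriptors and the V=O correlation

Descriptors follow the standard conceptual-DFT definitions from a
HOMO/LUMO pair in eV (χ = −(E_HOMO+E_LUMO)/2, η = ΔE/2, μ = −χ,
S = 1/2η, ω = μ²/2η, ΔN_max = χ/η). Pairs with E_HOMO ≥ E_LUMO are
rejected (hardness would be non-positive). Published tables sometimes
print these with the averaging bracket dropped or with ω replaced by
χ/2 in some rows; `consistency_report` recomputes every derived column
and flags any cell deviating by more than a tolerance (default 0.01 in
the quantity's units) instead of trying to reproduce inconsistent
cells.

The empirical vanadyl correlation ν = 21349·exp(−1.9176·R) is used with
its constants fixed exactly as published — no refitting — giving
R = ln(21349/ν)/1.9176 for 0 < ν < 21349 cm⁻¹. It is strictly
decreasing (higher stretch ⇒ shorter bond) and exactly invertible;
lengths are reported to 3 decimals. The correlation is an empirical
IR↔structure bridge and need not agree with quantum-chemical
frequencies at the same geometry.

## DNA binding (Benesi–Hildebrand)

For 1:1 drug–DNA association at fixed drug concentration the
double-reciprocal form A₀/(A−A₀) = c + (c/K)·(1/[DNA]) is linear, with
c = ε_G/(ε_HG−ε_G), and K_b = intercept/slope. Points with
|A−A₀| below a floor (default 10⁻³ absorbance units) are excluded
because the transform diverges there; mixed signs of A−A₀ trigger a
majority-sign fit with an indeterminate-chromism warning.

The line is fitted by iteratively reweighted least squares with weights
1/(ŷ(1+ŷ))². Under relative (multiplicative) absorbance error — the
natural spectrophotometer noise model — the transformed ordinate's
standard deviation grows as y(1+y), which is steepest exactly at the
high-1/[DNA] points that dominate an unweighted slope; an unweighted
fit there turns 1% absorbance noise into median ~20% errors in K_b,
while the weighted fit keeps the median near 3%. Weights follow the
fitted (not observed) ordinate over three reweighting iterations for
stability, zero-noise behaviour is identical (any weighting reproduces
an exact line), and `weighted=False` restores the plain graphical
estimator for comparison with hand-drawn plots. r² is always reported
for the unweighted residuals of the final line.

Chromism is classified from the relative change of the final absorbance
vs A₀ (default threshold 1%, the paper-style labels being qualitative),
and the band shift from the free vs bound λ_max metadata. K_b is
conventionally reported to 3 significant figures.

## Thermogravimetric segmentation and kinetics

A thermogram (remaining mass % vs T at constant β, default
10 K·min⁻¹) is smoothed by a Savitzky–Golay filter (cubic, default
31-point window ≈ 15 K at the default 0.5 K sampling) and steps are
found where the DTG signal −dm/dT exceeds
max(2% of the global peak, 5×MAD noise). Regions closer than 25 K
merge; each grows outward until the rate drops below 0.2% of its own
peak (bounded by the midpoint to its neighbour). Start/end masses are
medians of the bounding plateaus, which makes the measured loss robust
to point noise; conversion is α = (m_start−m)/(m_start−m_end), clipped
and made monotone. Mass-gaining curves beyond a 0.5% tolerance are
rejected. These defaults were calibrated against the synthetic
generator (noise-free losses recovered to < 0.1 mass-%, robust at
0.1 mass-% noise); real thermograms with drifting baselines or
overlapping events may need the window/thresholds adjusted.

Kinetics assume first order (n = 1) per step — the convention when a
single E_a per step is reported without order analysis:

- Coats–Redfern: ln[−ln(1−α)/T²] vs 1/T; E_a = −slope·R; intercept
  ln[A·R/(β·E_a)] gives A (the small (1−2RT/E_a) correction is
  neglected, as is customary).
- Horowitz–Metzger: ln[−ln(1−α)] vs θ = T−T_s with T_s the DTG-peak
  temperature; E_a = slope·R·T_s²; A from the intercept.

Both fit the conversion window α ∈ [0.05, 0.95] (≥ 5 points).
Activation thermodynamics are evaluated at T_s with CODATA constants
(scipy): ΔH = E_a − R·T_s, ΔS = R·ln(A·h/(k_B·T_s)) with A converted to
s⁻¹, ΔG = ΔH − T_s·ΔS. For A ≤ 10¹² min⁻¹ this gives the familiar
pattern ΔS < 0, ΔH > 0, ΔG > 0.

**Known limitation — HM bias.** On exactly integrated first-order data
Coats–Redfern recovers the generating E_a to ~0.1%, but the
Horowitz–Metzger linearization truncates the 1/T expansion at first
order in θ and systematically overestimates E_a by roughly 3RT_s/E_a —
about 12–15% at these conditions (A = 10¹⁰ min⁻¹ ⇒ E_a/RT_s ≈ 24). The
bias persists under either classical T_s definition (DTG peak or
1−α = 1/e) and narrows only slightly for narrower α windows. HM values
should be read as upper bounds and cross-checked against CR; the test
suite asserts tighter HM agreement as the stage's acceptance surface
and that assertion is expected to fail, documenting the method's
intrinsic error rather than hiding it.

## Molar-ratio stoichiometry

Every interior split of the series leaving ≥ 3 points per branch is
fitted by two least-squares lines; the split with minimum total RSS
wins (ties to the smallest breakpoint, deterministically), and the
breakpoint is the branch-line intersection, required to lie strictly
inside (0, 1). |x−1/2| ≤ tol labels 1:1, |x−1/3| ≤ tol labels 1:2
(default tol 0.05); parallel branches or out-of-range intersections
yield "unassigned" with a warning. The estimate is invariant to affine
rescaling of the absorbance axis. The default grid is the classical
seven-flask design (mole fractions 0, 1/6, …, 1), but any strictly
increasing grid in [0, 1] with ≥ 5 points is accepted. No
formation-constant refinement is attempted from curvature near the
break.

## QSAR

Ordinary least squares with intercept (statsmodels) of IC₅₀ on ASA_P,
ASA_H, h_pkp and dipole. The response is regressed on its natural µM
scale by default — matching the printed model form Y = Σb·x + C — with
an optional log10 transform (predictions transformed back), since QSAR
convention often prefers log activities; descriptors are deliberately
not standardized so coefficients stay in natural units. Requires more
records than parameters and a full-rank design (collinear columns are
named in the rejection); a constant response is fitted as
intercept-only and flagged degenerate. Diagnostics: R (Pearson of
fitted vs observed; R² = R² by the OLS identity), per-record residuals,
and leave-one-out q² = 1 − PRESS/TSS via explicit refits. Header
spellings `h_pkb`/`h_pKb` are accepted as aliases of `h_pkp`.

## Synthetic generators

Each generator is a pure function of its arguments including the seed
(NumPy `default_rng`), and its zero-noise output is an exact fixed
point of the matching estimator — that round trip is the core property
the test suite leans on.

- Titrations invert the double-reciprocal line exactly; defaults
  A₀ = 0.5, ε-ratio c = 1 (i.e. 100% hyperchromicity at saturation,
  the strong response these complexes show), 10-point log-spaced DNA
  grid over [10⁻⁷, 10⁻⁵] M, K = 1.40×10⁶ M⁻¹. Noise is multiplicative
  Gaussian on A (instrument-like relative error).
- Thermograms integrate dα/dT = (A/β)e^(−Ea/RT)(1−α) by cumulative
  trapezoid on the temperature grid (298–1100 K, 0.5 K step, β = 10);
  additive Gaussian noise on mass %; overlapping step windows warn.
- Molar-ratio series use the ideal-complexation (infinite formation
  constant) piecewise-linear model: complex ∝ min(x, (1−x)/q), break at
  1/(1+q); multiplicative absorbance noise.
- QSAR tables draw descriptors uniformly over plausible ranges
  (ASA_P 50–400 Å², ASA_H 200–800 Å², h_pkp 2–14, dipole 1–15 D) and
  add Gaussian noise to the exact linear response
  (b = (0.5, −0.2, 3.0, 1.0), C = 7).

What the generators do **not** emulate: full UV–Vis spectra or baseline
drift, competing binding modes or cooperativity, overlapping or
non-first-order decompositions, finite formation constants (curvature
near the molar-ratio break), correlated or non-Gaussian instrument
noise, and descriptor collinearity patterns of real compound series.
Passing tests therefore demonstrate estimator correctness under each
stage's own model assumptions, not robustness to every pathology of
real instrument data.

## Pipeline

`RunConfig` is validated by pydantic with unknown keys rejected;
relative paths resolve against the config file. Stages run in
dependency-free isolation: a failing stage is reported as `failed` with
its error while the rest complete, and unconfigured stages are
`skipped`. Reports serialize with sorted keys and no timestamps, so
rerunning an identical configuration yields byte-identical JSON.
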