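# Methods

## The photosynthesis model and its assumptions

Net CO₂ assimilation of a C3 leaf is modelled as the minimum of two
potential rates minus day respiration:

    Ac = Vcmax · (Ci − Γ*) / (Ci + Kc·(1 + O/Ko))
    Aj = J · (Ci − Γ*) / (4·Ci + 8·Γ*)
    A  = min(Ac, Aj) − Rd

with Ci the intercellular CO₂ mole fraction (µmol mol⁻¹), Γ* the
photorespiratory compensation point, Kc/Ko the Rubisco Michaelis constants
and O = 210 mmol mol⁻¹ oxygen. Assumptions baked into the implementation:

- **Saturating light.** Curves are measured at PPFD 1500 µmol m⁻² s⁻¹, so
  the electron-transport rate is taken at its maximum, J = Jmax. A
  non-rectangular-hyperbola light dependence exists in the code but is off
  by default.
- **Infinite mesophyll conductance.** The model operates on Ci; chloroplast
  CO₂ equals Ci.
- **No triose-phosphate limitation.** The two-branch model covers the
  measured Ci range; an optional cleaning rule can trim trailing
  high-CO₂ points where A declines with rising Ci.
- **Rubisco kinetics** default to the Bernacchi-2001 temperature response
  (Kc 404.9 µmol mol⁻¹, Ko 278.4 mmol mol⁻¹, Γ* 42.75 µmol mol⁻¹ at 25°C,
  with activation energies 79.43, 36.38, 37.83 kJ mol⁻¹), the de-facto
  standard of A/Ci fitting tools. The constants bundle is an argument, so
  an alternative parameterization is a one-line swap.

## Curve fitting

For a fixed assignment of points to the Rubisco and RuBP branches, both
branch equations are *linear* in (Vcmax, J, Rd). The fitter therefore:

1. sorts usable points by Ci and searches every admissible transition
   (at least 3 points below, 2 above) exhaustively;
2. solves each candidate by bounded linear least squares (Rd confined to
   [0, 5] µmol m⁻² s⁻¹ — Rd is never reported by the measurement protocol
   and otherwise trades off against Vcmax);
3. seeds a bounded trust-region refinement of the full min-rule model with
   the best candidate.

Step 3 matters: below Γ* (the Ca = 50 step sits at Ci ≈ 35 < Γ* ≈ 42.8)
the minimum rule makes the RuBP branch limiting *regardless of the Ci
ordering*, so no contiguous partition reproduces the forward model
exactly; the refinement removes the resulting ~5% bias and makes the
noise-free round trip exact to better than 1e-3 relative. SSE ties in the
transition search break toward the larger Rubisco-limited segment, making
the search deterministic. Points are labelled rubisco/rubp by the limiting
branch at the fitted parameters.

The repeated Ca = 380 step is a protocol stability check, not an
independent observation, and is excluded from fitting by default
(`FitOptions.use_duplicate_380`). A_sat is read from the first
(acclimated) 380 step; a mean-of-both mode exists.

## Temperature normalization

Rates are projected between leaf temperature and 25°C with the pure
exponential Arrhenius form `f(Tk)/k25 = exp(c − ΔHa/(R·Tk))`,
R = 0.008314 kJ mol⁻¹ K⁻¹, with (c, ΔHa) = (26.355, 65.33 kJ mol⁻¹) for
Vcmax and (17.710, 43.90) for Jmax. The constants are mutually consistent:
the factor is 1 at 298.15 K to within 3e-4. No peaked (deactivation) term
is added — the cuvette range here never approaches the optimum-temperature
rolloff, and the 25°C estimate is unchanged by construction. Day
respiration in the generator uses ΔHa = 46.39 kJ mol⁻¹ with c chosen for
exact unity at 25°C.

## Leaf biochemistry

Pigment concentrations (µg mL⁻¹) come from 95%-ethanol extract absorbances
at 665/649/470 nm:

    Chl a = 13.95·A665 − 6.88·A649
    Chl b = 24.96·A649 − 7.32·A665
    Car   = (1000·A470 − 2.05·Chl a − 114.8·Chl b) / 245

These coefficients are the single source of truth for every pigment value
in the package; negative concentrations near the detection limit are
clipped to zero with a logged warning. Area contents scale by extract
volume × dilution / leaf area.

Nitrogen partitioning uses the classical pool model with fixed constants
V_cr = 20.5 µmol CO₂ (g Rubisco)⁻¹ s⁻¹, J_mc = 156 µmol electrons
(µmol cyt f)⁻¹ s⁻¹, C_B = 2.15 mmol g⁻¹, 6.25 g Rubisco (g N)⁻¹ and the
bioenergetics factor 8.06. Because V_cr and J_mc are 25°C values, the
fractions are computed from 25°C-normalized capacities by default.
Area-based chlorophyll converts to C_c (mmol per g dry mass) through M_A
and a mean chlorophyll molar mass of 901 g mol⁻¹ (≈3:1 a:b mixture of
893.5 and 907.5). Fractions outside (0, 1) flag implausible inputs with a
warning naming the leaf; they never abort a run.

Unit conventions: area contents in µg cm⁻² (1 g m⁻² = 100 µg cm⁻²), SLA in
cm² g⁻¹ with M_A = 10⁴/SLA in g m⁻². The regression battery takes N_area
in g m⁻² — the scale at which its coefficients are meaningful — and the
pigments in µg cm⁻²; each fitted model records its predictor units in
metadata rather than assuming them silently.

## The synthetic season

The generator emulates a single winter-wheat season: 8 sampling days
(DOY 92, 96, 105, 119, 126, 133, 140, 147), n = 4/4/3/3/3/4/4/4 (29
leaves), stages bounded at DOY 95/117/131/161. Each trait follows a
piecewise-linear trajectory through (season start, flowering peak at DOY
126, season end); defaults anchor Vcmax25 at 82.4 → 133.46 → 46.0
µmol m⁻² s⁻¹ (a 62% rise to the peak and a fall to roughly a third),
N_area at 160 → 201.6 → 110 µg cm⁻², Car_area at 9.0 → 13.3 → 10.0
µg cm⁻², Jmax25 at 1.7× Vcmax25. Chlorophyll is derived by default from
the nitrogen trajectory times a Chl/N ratio curve (0.23 at DOY 92, 0.32 at
96, plateau 0.36 from DOY 105) — the constant-allocation signature of the
mid/late season; explicit Chl anchors are available via
`chl_mode="anchors"`. Rd25 defaults to 1.5% of Vcmax25; SLA declines
linearly 230 → 160 cm² g⁻¹.

Leaf-to-leaf variation within a day is multivariate lognormal: one
correlated standard-normal vector per leaf (Cholesky of a 6×6 coupling
matrix over Vcmax25, Jmax25, Chl, Car, N, SLA), scaled per trait by
σ = sqrt(ln(1+CV²)) and mean-corrected so the per-day expectation equals
the trajectory exactly. The default couplings and CVs were calibrated,
together with the trajectory amplitudes, so the season-pooled correlation
structure matches the field pattern this design mimics: r(Vcmax25, Chl) ≈
0.84, r(Vcmax25, Car) ≈ 0.67, r(Vcmax25, N) ≈ 0.61. Two facts shaped this
calibration and are worth knowing:

- The pooled correlation mixes the shared seasonal trajectory with the
  within-day couplings. Any trait that rises to the same flowering peak
  and falls after is almost perfectly correlated with Vcmax25 *between*
  days; nitrogen's modest pooled correlation therefore requires a weak
  direct V–N coupling (0.15) plus a comparatively large leaf-to-leaf N
  CV (0.20).
- The field pattern's full correlation set is jointly near-infeasible: a
  V–Chl correlation of 0.83 together with a Chl–N correlation of 0.95
  forces r(V, N) ≥ 0.61 by the correlation-matrix positivity constraint.
  The generator honours the capacity–trait row; its Chl–N correlation
  settles near 0.64 rather than 0.9+.

A second factory, `season.ordered_coupling_config()`, produces a season
whose coupling strengths are *strictly ordered* Chl > Car > N > SLA
(0.85/0.75/0.50/0.0, chlorophyll's trajectory affine to Vcmax25's, SLA
flat with purely idiosyncratic variation). Its gaps are sized so the
ordering is statistically resolvable at the 29-leaf design — the point of
ranking analyses is to detect a known ordering, and gaps of ~0.07 in
pooled correlation are below the resolution of n = 29. Measured before
freezing: the joint R²-ladder + importance-ranking ordering holds in ≈97%
of seasons.

Gas exchange: Ci is derived from each Ca setpoint with a constant
operating ratio Ci/Ca = 0.7 (typical C3 value; the fitter consumes Ci
directly, so the coupling rule only shapes where points land on the
curve), A comes from the forward model at leaf temperature (cuvette
25°C) plus additive Gaussian noise, default sd 0.3 µmol m⁻² s⁻¹.

What the generator does **not** emulate: instrument drift, leaks or
humidity excursions; within-leaf spatial heterogeneity; the early-season
excess of inorganic nitrogen (its ratio trajectory is the smooth
idealization); non-wheat canopies; multi-year or multi-site designs.
Passing recovery tests therefore demonstrate correctness of the inference
chain under idealized measurement conditions, not robustness to every
field pathology.

## Randomness and reproducibility

One master seed governs a run. Per-leaf streams derive from
`SeedSequence([seed, leaf_index])`; curve noise keys on
`[seed, crc32(leaf_id)]` — stable across processes (Python's string hash
is not). The bagged-tree importance uses a single generator for bootstrap,
tree seeds and permutations. Identical config + seed ⇒ byte-identical
CSVs: floats are written at 6 significant digits, the manifest carries no
timestamps (stage timing goes to the log instead).

## Statistical layer

- Pearson r by direct summation of centred cross-products; p from the
  two-sided t-test with n−2 df; significance stars at 0.05/0.01/0.001.
- OLS via statsmodels; model significance is the overall ANOVA F-test;
  p-values reported to 3 significant figures; no multiple-testing
  correction (a handful of pre-specified models, not a screen);
  complete-case analysis per model.
- %IncMSE: for each of 500 bagged regression trees (max_features ⌈p/3⌉),
  the out-of-bag MSE is recomputed after permuting one predictor's OOB
  values; the per-tree percent increases are averaged. This is the
  out-of-bag permutation form, not test-set permutation. Implemented over
  scikit-learn decision trees with an explicit bootstrap loop because the
  stock forest class does not expose per-tree OOB permutation.
- Seasonal percent changes are reported under both conventions,
  100·(b−a)/a and 100·(b−a)/b, explicitly labelled: a "190% decline" is
  only expressible relative to the later mean, and seasonal narratives in
  the literature mix the two freely.

## Problem sizes used by the test suite

Noise-recovery uses 200 replicate curves; regression recovery 500
replicates at n = 29; importance orderings 10 seeds × 500 trees; the
plateau check 200 replicate seasons. The full suite runs in well under a
minute on one core.

## Known limitations

- Equivalence with any specific third-party A/Ci spreadsheet tool cannot
  be asserted — kinetics and algorithms of such tools vary; the package's
  guarantees are internal (forward/inverse consistency, oracle
  equivalence, recovery under known noise).
- Rd is weakly identified from A/Ci data measured at a single light level;
  the [0, 5] bound regularizes it, and Rd estimates should not be
  interpreted physiologically.
- The generator's Chl–N correlation is structurally lower than the field
  pattern's printed value (see calibration note above).
- With 3–4 leaves per day, per-day means are noisy; single-season
  statistics at n = 29 carry wide sampling bands, which is precisely why
  ranking checks are run across replicate seasons.
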