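# Methods

## Scope and model

`sorbfit` analyses single-solute batch adsorption equilibria. One vial
holds a volume V (dm³) of solution at initial concentration C0
(mg/dm³) and a sorbent mass m (g); at equilibrium the mass balance
gives the adsorbed amount Qe = (C0 − Ce)·V/m (mg/g) and the removal
efficiency E_ads = 100·(C0 − Ce)/C0. Six isotherm families relate Qe
to Ce at fixed temperature (see the README table): the hyperbolic
monolayer model (Langmuir), the empirical power law (Freundlich), the
three-parameter hybrid interpolating between them (Redlich–Peterson),
the logarithmic decreasing-heat model (Temkin), and the two
pore-filling models in the Polanyi potential ε = RT·ln(Cs/Ce) with
Gaussian (Dubinin–Radushkevich) or free-exponent (Dubinin–Astakhov)
energy distributions.

Units are fixed package-wide — concentrations mg/dm³, amounts mg/g,
ε J/mol, energies reported in kJ/mol, temperature stored in kelvin
(config accepts °C and adds 273.15) — matching how such studies print
their tables. The gas constant is R = 8.314 J/(mol·K).

Assumptions worth stating explicitly:

* Temkin predictions are negative wherever K_T·Ce < 1. They are
  returned unclamped; the linear form (Qe vs ln Ce) is unaffected, and
  the equilibrium solver still works because the mass-balance function
  remains monotone.
* The Polanyi families require the adsorbate solubility Cs with
  Cs > max(Ce) strictly. Cs has no authoritative value for 18β-GA in
  2-propanol; it is therefore a **required** input with no default for
  fitting. Simulation fixtures use Cs = 69 000 mg/dm³ (10× the largest
  initial concentration of the reference design) — admissible,
  explicit, and recorded in every simulation sidecar. Consequence:
  fitted K_DR/K_DA values are only comparable between runs that share
  a Cs convention.

## Estimation

**Linearized least squares.** Each family's exact straight-line form
is fitted by unweighted OLS (`scipy.stats.linregress`); slope and
intercept map back to the physical parameters. The Langmuir dialect is
the double-reciprocal (1/Qe vs 1/Ce) form; alternative dialects are
deliberately not offered, because mixing dialects changes the implied
error weighting and breaks cross-family comparability. Out-of-domain
points (Ce ≤ 0, Qe ≤ 0, or K_RP·Ce/Qe ≤ 1 for Redlich–Peterson) raise
an error naming the offending indices; an explicit `allow_drop=True`
excludes them and records the surviving indices, so no silent subset
bias can creep in.

For the two three-parameter families the linear form exists only
conditional on one parameter (K_RP, or the exponent n_DA). That
parameter is profiled: a 64-point log-spaced pre-scan brackets the r²
maximum, then a bounded Brent refinement (`minimize_scalar`,
`method="bounded"`) polishes it to ~1e-10 relative. Two numerical
choices matter here:

* The feasible K_RP region is bounded below by
  (1 + 1e-6)·max(Qe/Ce) — below that, some point has
  K_RP·Ce/Qe ≤ 1 and the logarithm is undefined. The default upper
  bound is 10⁴× that floor; both are overridable.
* The profile objective is computed as 1 − SS_res/SS_tot rather than as
  the squared Pearson correlation. The two are algebraically identical,
  but the correlation form saturates at 1 − 1e-16 on noiseless data and
  flattens the profile; the residual form keeps curvature down to
  machine precision, which is what lets the profiled parameter be
  recovered to ~1e-8 relative in round-trip tests.
* If the pre-scan finds several local maxima, a warning is issued,
  every bracket is refined, and the best r² wins.

**Nonlinear MPSD minimization.** MPSD (Marquardt's percent standard
deviation) is 100·√(Σ rel² /(n − p)) with p = 2 or 3 per family.
Minimizing it is least squares on relative residuals, so the optimizer
is `scipy.optimize.least_squares` (trust-region reflective) on the
relative-residual vector, with strictly positive parameters fitted as
log10 (β additionally bounded in (0, 1], n_DA in [1, 6]). Multistart is
deterministic: the linearized estimate seeds the first start (a crude
moment-based heuristic replaces it if the linear fit is infeasible),
followed by 8 seeded perturbed starts — one decade of jitter on rate
constants, ±50 % on capacities, exponents redrawn inside their bounds.
The multistart matters in practice for Redlich–Peterson at small β,
where the objective has a secondary valley. Tolerances (1e-12 on the
objective, 1e-12 step, configurable) sit well below the 1e-6 round-trip
acceptance used in the tests.

Because the first start is the linear estimate, the optimized MPSD can
never exceed the linear solution's MPSD on the same data — a property
the test suite asserts on every noisy replicate rather than trusting.

## Derived quantities

* E_DR = 1/√(2·K_DR), reported in kJ/mol. All sixteen published
  (K_DR → E_DR) pairs across both sorbent series and both methods are
  reproduced to the printed 2 decimals.
* E_DA: the generalization of the Gaussian formula is taken as
  E_DA = (2·K_DA)^(−1/n_DA), which reduces exactly to E_DR at
  n_DA = 2. The source tables' E_DA column is **not** reproducible
  under this (or any standard) closed form — e.g. K_DA = 5.448e-12,
  n_DA = 2.733 gives 10.27 kJ/mol here vs 9.35 printed, a 1–10 %
  family-wide mismatch — so printed E_DA values are documented but
  excluded from acceptance checks.
* Molar site ratio n_GA/n_FG = (Q_max·10⁻³/M)/Q_FG with the adsorbate
  molar mass defaulting to 470.68 g/mol (C₃₀H₄₆O₄, overridable) and
  Q_FG the functional-group content (mol/g) from thermogravimetry.
* Surface-normalized capacity Q_s = Q_max/S_BET (mg/m²).
* Rankings: families sort by the method's own score (descending r² or
  ascending MPSD); an adjacent pair is rendered "≈" when the MPSD ratio
  is ≤ 1.5 or |Δr²| ≤ 0.01, else ">". The 1.5 default reproduces the
  published nonlinear comparison row for the aminopropyl-SBA-15
  sorbent; reproducing every published row is not promised, since those
  "≈" judgments were editorial. Exactly equal scores order
  alphabetically for determinism. The 8 kJ/mol
  physisorption/chemisorption convention is reported as an annotation
  in summaries, never baked into any decision.

## Synthetic data generator

The generator emulates the reference batch protocol: 12 geometrically
spaced C0 over 120–6900 mg/dm³, V = 0.010 dm³, m = 0.100 g, 298.15 K,
one vial per level (replicates exposed as a knob). For each C0 the true
equilibrium is the root of f(Ce) = Ce + (m/V)·Qe(Ce) − C0 on (0, C0],
bracketed (f < 0 near 0, f ≥ 0 at C0) and solved by Brent to 1e-14;
non-adsorbing parameter regimes that leave no root raise instead of
returning nonsense.

Noise enters on the measured concentration, not the derived amount:
Ce_obs = Ce_true·(1 + cv·z), z standard normal from one seeded
generator per dataset, resampled until 0 < Ce_obs < C0. Qe_obs is then
derived through the mass balance, so conservation holds exactly for
every generated record and the relative-error structure matches what a
spectrophotometric measurement chain induces — the structure the MPSD
objective is designed for. The default cv of 0.05 in the noise studies
is a realistic dilution-plus-absorbance error figure.

What the generator does **not** emulate: calibration drift, replicate
correlation, solubility limits binding at high C0, or competitive
adsorption. Passing round-trip tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to structured
instrument error.

## Problem sizes and determinism

The test and acceptance workloads are sized so the whole pipeline runs
in seconds: 12-point datasets (the reference design), 200 replicates
for the noise study, 10 + 10 random datasets for the profile-oracle
comparison with a 1000-point dense grid. Every stochastic step draws
from `numpy.random.default_rng` with an explicit seed; the acceptance
script derives all of its seeds from its single `--seed` argument.

## Known limitations

* Parameters of the published study cannot be re-estimated from
  scratch: its raw isotherm points were published only as figures, and
  its Cs is unstated. All checks against it are therefore arithmetic
  on printed constants plus properties on synthetic data.
* Linearized estimates carry the usual transformation bias under
  noise; the package surfaces both routes side by side rather than
  correcting for it.
* No parameter uncertainties (confidence intervals, bootstrap) are
  computed; the comparison vocabulary is goodness-of-fit only.
* Weighted OLS variants and alternative nonlinear error functions
  (SSE, HYBRID, ARE) are out of scope.
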