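# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic validation does and does
not demonstrate.

## Pipeline overview

1. **Trade reconstruction** (`trade_history`). Transported mass (kg) is
   observed directly only in a recent window (default 1995–2019); earlier
   years carry monetary flows (default through 2014). For every ordered
   country pair a zero-intercept regression `mass = c₁·money + c₂·money²`
   is fitted by least squares on the overlap years and used to predict
   mass for the historical years. Predictions are clamped at zero (mass
   cannot be negative) and an observed value is never overwritten by a
   prediction. Pairs with fewer than three overlap years are left unfit
   and contribute zero pre-window mass, with a warning — no pooling or
   borrowing across pairs, which keeps every prediction auditable. `R²` is
   computed against the centred total sum of squares, so a zero-intercept
   model that underperforms the mean can go negative. Yearly masses are
   then cumulated at decade endpoints `{start+9, start+19, …}`; with the
   default 1870–2019 range that gives exactly 15 endpoints (1879 … 2019),
   the first covering the 10 calendar years 1870–1879.

2. **Species flows** (`species_flows`). A country's species pool in year
   *y* is its native set plus every alien first-recorded there by *y*
   (bridgehead effect). A first record of species *s* in importer *i* at
   year *y* is credited in full to every country that held *s* in its pool
   at year *y−1* — one year earlier, so a same-year arrival elsewhere
   cannot be its own source. Multi-crediting is intentional: when several
   exporters could have supplied a species, each plausible route carries
   the introduction, which inflates the attributed total relative to the
   number of records. Records of a species in a country where it is
   native are dropped with a warning; records with no candidate exporter
   are logged and counted nowhere. Attributed counts are aggregated into
   the 15 decade intervals; the exporter pool size `S_e` is evaluated at
   each decade's first year (no future information), the importer's
   native count `S_i` is constant.

3. **Count model** (`nbglmm`). `AS ~ NB(μ, θ)` with
   `log μ = β₀ + β₁ z(log(1+TR)) + β₂ D + β₃ log S_e + β₄ log S_i
   + u_{i:period} + u_{e:period}`, independent Gaussian intercepts per
   grouping factor. Log-trade uses `log(1+x)` because pre-trade decades
   contain zeros; richness terms are always ≥ 1 and use plain logs.
   **Scaling:** only log-trade is z-scored. Scaling every predictor was
   considered and rejected: the distance effect is a per-km rate of order
   10⁻⁵ and the richness effects are per-log-unit elasticities of order
   10⁻¹–1, and keeping those units makes the coefficients directly
   interpretable and comparable across data sets; the scaling constants
   actually used are stored inside the fit and re-applied at prediction
   time, so any other convention is a reparametrisation, not a different
   model.

## Fitting the NB GLMM

No maintained Python package fits a negative-binomial mixed model, so the
marginal-likelihood machinery is implemented here.

* **Inner problem.** For trial `(θ, σ)`, the joint penalised
  log-likelihood in `(β, u)` is strictly concave (the observed-information
  weight for the NB log link, `w = (y+θ)θμ/(θ+μ)²`, is positive), and is
  maximised by damped Newton iterations stopped on the Newton decrement.
* **Laplace correction.** The marginal log-likelihood is the joint maximum
  plus `−½ log|Z'WZ + Σ⁻¹| − ½ log|Σ|`; as σ→0 the terms cancel and the
  objective reduces continuously to the plain NB GLM likelihood.
* **Outer search.** A Nelder–Mead pass over `(log θ, log σ₁, log σ₂)` from
  the fixed starting values (β=0, θ=1, σ²=0.1) profiles β at the joint
  mode; a subsequent L-BFGS-B polish re-optimises *all* parameters in the
  full Laplace objective. The polish matters: profiling β at the joint
  mode ignores how β moves the curvature term, which attenuates
  group-level coefficients (the exporter-pool effect) by ~1–2%; with the
  polish the fit agrees with R's `glmmTMB` to ~10⁻⁵ in every coefficient
  on a 9000-row panel. Covariate columns are centred and scaled
  internally for conditioning only (the km-scale distance column otherwise
  makes the outer problem numerically singular); reported coefficients are
  mapped back to natural units, with the covariance transformed
  accordingly. Everything is deterministic: fixed starts, no restarts.
* **Edge handling.** σ estimates pinned near the lower box edge are
  flagged as boundary fits; non-convergence is flagged, never silent.
  AICc counts fixed effects (incl. intercept) + θ + one variance per
  grouping factor, and candidates with `n ≤ k+1` are excluded from model
  selection with a note.
* **Predictions** default to population mode (random effects at zero) so
  fate factors generalise beyond the training levels; conditional mode
  (adding the estimated intercept modes) is available. The Nakagawa-style
  R² decomposes latent-scale variance with the lognormal
  distribution-specific term `ln(1 + 1/λ + 1/θ)`,
  `λ = exp(mean η + ½(σ²_f + σ²_re))`.

## Fate factors

For each eligible pair: **average** FF contrasts the model's expectation
at the full cumulative quantity with the expectation at `TR = 0`, divides
by the importer's total species count and by the mean transport rate
(cumulative kg over 150 years); **marginal** FF perturbs by one extra year
at the final decade's mean annual rate. Both denominators are rates
(kg/yr), making the two variants dimensionally identical (ASF·yr/kg) — the
only reading under which they can share one effect factor. The weighting
count `S_total,i` defaults to natives plus all recorded aliens ("all
species present"); a natives-only flag exists. Pairs below 100 kg/yr on
the 150-year mean rate are excluded; exactly 100 is eligible. Concavity
of the fitted response in `TR` guarantees marginal ≤ average, which the
tests verify pairwise rather than assume.

## Effect factor

Country PDF = (assessed native amphibians/birds/mammals that are
threatened — VU/EN/CR/EX/EW, with three bracketing options for
data-deficient species — *and* have a documented decline caused by the
invasive-alien threat class) / (assessed natives whose threat severity is
known). The stressor–response slope of PDF on ASF is fitted through a low
quantile (τ = 0.05 headline; 0.10 and 0.15 as sensitivity) because
confounding threats can only add to a country's PDF: the lower envelope of
the scatter is where the alien-species signal is least contaminated. The
weighted check-loss minimisation is solved exactly as a linear program
(HiGHS); weights are log₁₀ of country area with a floor of 1 below
10 km², and the CI is a weighted pairs bootstrap (countries resampled with
replacement, 1000 draws, seeded) — the bracketing method had to be chosen
here, and resampling countries respects the country-level sampling unit.
Countries missing from any input table are excluded, as are countries
with no comparably assessed species (logged).

## Synthetic worlds

The generator (`synthetic_world`) produces every input stream from one
seeded config and echoes the truth:

* Trade: per-pair gravity-like base rates (lognormal, damped by distance)
  with exponential growth toward the present and lognormal yearly noise;
  money = mass × price × lognormal price noise, so the back-casting stage
  has real signal (with price noise off, every pair back-casts with
  R² = 1). Mass is exposed only in the recent window, money only in the
  historical one, mirroring the asymmetry the reconstruction exists for.
* Introductions: drawn decade-by-decade from the same NB/log-link/
  random-intercept model the fitter assumes, with covariates built by the
  same transforms. Only log-trade is z-scored and trade is exogenous, so
  the generator computes the scaling constants from the full pair×decade
  grid upfront and the fitter recomputes identical ones from the same
  rows — generator and fitter are exactly conjugate. Latent counts are
  realised by sampling species from the exporter's decade-start pool not
  yet present in the importer; arrival years avoid each decade's first
  year so pool-at-decade-start is unambiguous; draws exceeding the
  available pool are truncated *and logged*, and the recovery studies run
  in regimes where no truncation occurs (the tests assert this rather
  than assume it).
* Impacts: `PDF = ef_slope·ASF + ε`, ε half-normal — one-sided, because
  a symmetric confounder would invalidate the low-quantile estimand — and
  discretised into per-species threat rows with the threatened count
  rounded *up* (again one-sided). Distractor rows exercise every
  exclusion rule (wrong threat class, non-threatened categories, unknown
  severity, DD labels with and without a threatened prediction).
* Species are native to exactly one country, so exporter attribution is
  unique until bridgehead spread creates genuine multi-candidate records.
  The generator logs its own forward prediction of the attribution rule's
  output, and the tests require `species_flows` to reproduce it exactly
  from the CSVs.

**What passing does and does not show.** Recovery of planted coefficients
demonstrates that the estimation chain is unbiased under its own
assumptions at realistic panel sizes; it does not validate those
assumptions against real trade or Red-List data, where attribution error,
reporting lags, commodity structure and spatial autocorrelation are all
live issues the model ignores. Reconstructed panels differ from latent
ones wherever multi-crediting fires (~30–40% count inflation on dense
bridgehead worlds): that is the attribution rule working as specified,
not an estimation failure, and is why the recovery studies fit the
generator's own table.

## Simulation sizes

The coefficient-recovery study uses 25 countries × 15 decades (9000 panel
rows, 750 random-effect levels) over 20 seeds in the test suite and 12 in
the reproduction script: per fit the scaled-log-trade SE is ≈1.5×10⁻²,
so 12–20 seeds put the Monte-Carlo SE of the mean at ≈3–4×10⁻³ against a
plant of 9.3×10⁻³ — small enough for a sharp sign and location test,
while a single fit cannot reliably sign that coefficient (the original
analysis needed tens of thousands of real pairs for that). Sign checks
therefore apply to the mean across seeds. The effect-factor study uses
140 countries and 20 seeds; the mean fitted τ=0.05 slope lands within a
few percent of the 0.038 plant, with the mild upward drift expected from
ceiling discretisation. Quadrature oracles run on 60-row instances with
two levels per factor and high counts (μ≈90, θ=20), where the genuine
Laplace error (~6×10⁻⁴) is small enough to expose any formula mistake,
which would show up orders of magnitude larger.

## Known limitations

* The attribution rule multi-credits; no fractional splitting is offered.
* Heteroscedasticity and spatial autocorrelation in the count model are
  neither modelled nor corrected, only observable in residuals.
* The Laplace approximation is a first-order method; on very low-count
  panels (mean AS ≪ 1) the variance components are weakly identified and
  may legitimately hit the boundary.
* Commodity- and transport-mode structure is out of scope: one aggregate
  flow per pair.
* Real-data accession (trade databases, first-record databases, Red-List
  APIs, GIS border distances) is out of scope; all inputs enter as CSV in
  the documented dialects, with a haversine centroid fallback when a
  distance is missing from the matrix.
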