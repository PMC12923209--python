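# Methods

## The targeted-yield procedure

The package implements the inductive soil-test crop response (STCR)
calibration chain. Its inputs are plot-level records of a main test-crop
experiment laid over a deliberately created fertility gradient: per plot,
applied N/P₂O₅/K₂O (kg ha⁻¹), farmyard manure (FYM, t ha⁻¹), pre-sowing
soil-test values (kg ha⁻¹), green-foliage yield (t ha⁻¹) and total
nutrient uptakes (kg ha⁻¹). Its outputs are the basic parameters
(NR, CS%, CF%, COM%), the linear dose equations per nutrient and regime
(mineral-only "alone" vs mineral + FYM "integrated"), ready-reckoner
tables, and validation metrics.

### Estimators

All estimators are means of per-plot ratios, run in dependency order; all
eligibility is per nutrient X:

1. **CS%** = 100 · mean(U_X / STV_X) over no-FYM plots with no mineral X.
   A plot unfertilized in X is a control *for X* even if it received other
   nutrients, which roughly doubles the usable control set relative to
   all-zero plots.
2. **CF% (alone)** = 100 · mean((U_X − CS·STV_X/100) / F_X) over no-FYM
   plots with F_X > 0.
3. **COM%** = 100 · mean((U_X − CS·STV_X/100 − CF_alone·F_X/100) /
   (1000·FYM)) over FYM plots; plots with F_X = 0 identify COM cleanly
   (the fertilizer term vanishes) and are preferred when present.
4. **CF% (integrated)** = as step 2 over FYM plots. By default the FYM
   share is *not* debited first: the organic–mineral synergy is credited
   to the fertilizer, which is why CF rises sharply under integration
   while COM stays tiny (fractions of a percent of manure mass). This
   "lumped" convention is what the calibrated parameter tables of the
   methodology report; a `strict_ledger` alternative that subtracts the
   COM share first is available via configuration.
5. **NR (kg t⁻¹)** = mean(U_X / Y) over the regime's fertilized plots.

Negative per-plot contribution terms are retained, never clipped, keeping
the estimators unbiased under symmetric noise.

**Unit note.** Parameter tables in this literature often label NR
"kg q⁻¹" (per quintal), but the quantity that makes the dose equation
dimensionally coherent with T in t ha⁻¹ — and that matches observed
uptake:yield ratios (≈ 50 kg / 7.6 t ≈ 6.5) — is kg per tonne. NR is
computed, stored and serialized in kg t⁻¹, with the unit embedded in the
parameters file.

### Prescription equations and dose policy

`a_T = 100·NR/CF` (kg fertilizer per t of target), `b = CS/CF`
(dimensionless), and the FYM term. The FYM term has two published
conventions that disagree: the symbolic statement (COM/CF)·OM versus the
dose tables' direct COM·OM with OM in t ha⁻¹. Only the latter reproduces
the published reckoner columns and the printed OM coefficients
(−0.08/−0.09/−0.07), so it is the default; the symbolic variant sits
behind `om_term_convention: symbolic`. Coefficients are kept at full
precision internally; reckoner display rounds N doses to 1 decimal and
P/K to 2, mirroring the published layout. A raw dose ≤ 0 triggers the
maintenance policy: final dose = fraction (default 0.25, from the
methodology's "25–30 percent" guidance) × a user-supplied reference dose,
with the raw value always reported alongside.

Because the integrated dose rule deducts COM·OM *in addition to* the FYM
effect already inside CF-integrated, integrated prescriptions undershoot
their target by a fraction of a percent even in a noise-free world; the
two conventions cannot both be exact. This residual (~0.7% at 7.5 t FYM)
is far inside the ±10% validity band used for validation trials.

### Validation metrics

Percent deviation = 100·(achieved − target)/target. Response yardstick =
yield response over the absolute control per kg of total nutrient applied.
Value:cost ratio = value of the yield gain / cost of fertilizer + FYM
(prices are always user-supplied; the default config carries illustrative
placeholders only). Efficiency indices per nutrient, with yields in
kg ha⁻¹: PFP = Y/F, AE = (Y−Y₀)/F, PNB = U/F, IUE = Y/U. Indices are
computed on treatment means (replicates averaged before the ratio), the
convention validation tables in this literature use; the identities
PFP − AE = Y₀/F and PNB·IUE = PFP hold exactly and are property-tested.

## The synthetic trial generator

The generator exists so that the full chain is testable end-to-end with
known truth. It emulates the three-phase design: three 24-plot fertility
strips (low/medium/high) whose soil tests come from zero-truncated
normals; a 24-treatment main experiment (four levels each of N, P₂O₅,
K₂O; three FYM levels rotated systematically over treatments and strips so
each strip carries all three manure regimes, 72 plots); and a 7-treatment
× 3-replicate validation trial.

**Uptake.** Strictly additive: soil share CS·STV/100, plus fertilizer
share CF_R·F/100 where a mineral dose was applied, plus manure share
COM·(1000·FYM)/100 for nutrients receiving FYM but no mineral fertilizer.
The FYM credit is piecewise on purpose: in fertilized plots the manure
effect is expressed as the larger integrated CF (exactly how the
calibration attributes it), so the estimator chain inverts the generator
identically.

**Pre-sowing soil tests.** Gradient-phase strip means describe the
post-harvest state of the gradient year; the main experiment re-samples
before sowing. A calibratable trial needs soil supplies commensurate with
the crop's stoichiometry — a soil whose P supply alone would feed twice
the yield its N supply can carries no information about NR_P in a
ratio-based calibration. The generator therefore re-centres the P and K
columns (N anchored, strip gradient and relative spread preserved) so a
fertilized plot's mean supply sits on the NR ray; with the default truth
this puts pre-sowing P at ≈ 52 and K at ≈ 241 kg ha⁻¹, close to a typical
Alfisol baseline.

**Yield.** Starts from the plain average of the nutrient-implied yields
mean_X(S_X/NR_X); a minimal relative per-plot adjustment (projection of
1/Y onto the three moment constraints mean(S_X/Y) = NR_X per regime) then
makes the finite-sample uptake:yield moments exactly equal the specified
NR. The adjustments (typically 5–13%) play the role of plot-level yield
efficiency heterogeneity, and they are what makes zero-noise calibration
recover the generative truth to machine precision. For designs too small
or skewed for the projection (fewer than three fertilized plots, or an
infeasible supply composition) yields fall back to the plain average with
a logged warning. A Liebig alternative (Y = min_X S_X/NR_X) is available
as `yield_model: liebig` for sensitivity work.

**Noise.** Multiplicative Gaussian, truncated at zero, independently on
each uptake and on yield; default relative SD 0.05 for both. Multiplicative
noise reflects the large, mean-scaled coefficients of variation such
trials report. One root seed drives deterministic per-phase child seeds.

**What the generator does *not* emulate.** Real uptake is biomass-driven:
all three uptakes co-move with plant vigour, which is why field data show
yield–uptake r² of 0.7–0.96 for every nutrient. Here uptake is pinned to
the additive supply (that is what makes calibration exactly invertible),
so yield–uptake correlation is structural only: strong for K (~0.8),
moderate for P (~0.73), weak for N (~0.4), because yield variance is
dominated by the P/K dose structure of the design. Passing tests therefore
demonstrate the correctness of the estimation chain, not that the
generator reproduces field-data correlation patterns. There is no
weather, spatial layout, nutrient carryover or mechanistic soil-process
component.

**Parameter recovery limits.** At the default 72-plot design and 5%
relative noise, NR and CS are recovered within 5% relative in ≳95% of
runs, but CF for nitrogen is not (≈50–55% of runs): the fertilizer
contribution to N uptake (~12 kg of ~42) is small relative to the uptake
noise, and the estimator inherits the control-derived CS error amplified
by STV/F ≈ 8. This is an information floor of the design, not an
estimator defect — the Cramér–Rao bound for any unbiased estimator under
these conditions is ≈3.5% SD. Reliable CF_N calibration needs either more
replication, lower-noise uptake assays, or larger N dose contrasts.

## Numerical choices

* Truncated normals via `scipy.stats.truncnorm`; OLS with t/p statistics
  via `statsmodels`; the moment projection is a closed-form weighted
  least-squares step (`numpy.linalg.lstsq` on a 3×3 Gram matrix).
* Yields are floored at 0.05 t ha⁻¹ after noise.
* Sample SD uses the n−1 denominator; a single-plot stratum reports NaN
  markers for SD and CV rather than an error.
* Undefined metric ratios (zero dose, zero uptake, zero cost) are NaN
  markers so reports can still be assembled; upstream invalid *inputs*
  (negative doses, missing uptake on a yielding plot) raise typed errors.
* Equation coefficients are never rounded internally; display rounding is
  applied only in reckoner output (N: 1 decimal; P, K: 2 decimals).
* Config files are YAML over defaults; unknown keys warn, invalid values
  raise, and a nested `seed` key is hoisted with last-wins semantics.

## Known limitations

* The estimator forms are the classical inductive ones (means of per-plot
  ratios in dependency order); origin-paper spreadsheets in this
  literature are not published, so fidelity beyond reproducing the
  published parameter tables cannot be verified.
* ANOVA/Tukey letter groupings and SEm/CD reporting of validation tables
  are out of scope; treatment comparison is by relative differences.
* GRD (blanket) and SFR (fertility-rating) dose sets are inputs, not
  defaults; the shipped config carries values inferred from published
  efficiency-index arithmetic and should be replaced for real use.
* The multivariate yield-vs-soil-test regression and the yield–uptake
  correlations are generic tools; on synthetic data their r² reflects the
  generator's structure, not any field result.
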