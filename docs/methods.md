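# Methods

This note documents the models, numerical choices and limitations behind
`ghostpeat`. It covers what each stage computes, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and where genuinely open design decisions were made.

## Radiocarbon calibration

A calibration curve is a tabulated mapping from calendar age `t` (cal yr BP,
BP = AD 1950) to radiocarbon age `mu(t)` with 1-sigma uncertainty
`sigma(t)`. Sites under mixed north/south tropical air masses are calibrated
against a weighted mixture of the two hemisphere curves. On the union grid of
the overlap, the mixture is treated as a two-component normal mixture with
exact moments:

    mu_mix    = w mu_N + (1-w) mu_S
    sigma_mix^2 = w sigma_N^2 + (1-w) sigma_S^2 + w(1-w)(mu_N - mu_S)^2

The default weight is 0.5. The variance inflation term `w(1-w)(mu_N-mu_S)^2`
matters: dropping it understates the mixed-curve uncertainty wherever the
hemispheres disagree.

Single-date calibration evaluates, on the curve's calendar grid, a density
proportional to `N(y; mu(t), err^2 + sigma(t)^2)` and normalises it with the
trapezoid rule. The posterior is exact up to the grid resolution; tests
check it against a brute-force evaluation normalised on a 10x finer grid.

## Bayesian age-depth model

The age-depth model is the gamma-autoregressive accumulation family used by
the standard Bayesian peat-chronology tools. The core from `depth_top` to
`depth_bottom` is divided into `K` equal sections of thickness `dc` (cm).
The parameters are the top age `x0`, per-section accumulation rates
`alpha_j` (yr/cm) and a memory `w in [0,1)`:

    age(d) = x0 + sum_{j above d} alpha_j dc + alpha_{j(d)} (d - edge_{j(d)})

Priors: `alpha_1 ~ Gamma(shape a_acc, mean m_acc)`; for `j > 1`
`alpha_j | alpha_{j-1} ~ Gamma(a_acc, mean = w alpha_{j-1} + (1-w) m_acc)`;
`w ~ Beta(mean 0.7, strength 4)`. Because every `alpha_j > 0`, each
posterior draw is a strictly monotone age-depth function by construction —
age reversals in the data cannot produce reversed models.

Observation model: each date `y_i +/- s_i` at depth `d_i` enters in
radiocarbon space through a Student-t likelihood with the conventional
robustness parameters `a = 3, b = 4`,

    log L_i = -0.5 log(s2_i) - (a + 0.5) log(b + (y_i - mu(age(d_i)))^2 / (2 s2_i)),

with `s2_i = s_i^2 + sigma(age(d_i))^2`. The heavy tails keep single
outlying dates from dragging the whole model. The core top can be anchored
by a pseudo-date `x0 ~ N(1950 - collection_year, 1 yr)`.

Defaults: section thickness 5 cm, accumulation shape 1.5 with prior mean
20 yr/cm, memory mean 0.7 / strength 4 — the documented defaults of the
tool this model family comes from, all configurable.

### Sampling

Metropolis-within-Gibbs on `(x0, log alpha_j, logit w)` with per-parameter
random-walk steps adapted toward ~40% acceptance during burn-in. Two
correlated moves supplement the single-site updates each iteration: an
adjacent-pair exchange (`log alpha_j += delta`, `log alpha_{j+1} -= delta`),
which re-partitions rate between neighbouring sections while nearly fixing
their combined age span, and a global shift of all `log alpha_j`. Both are
symmetric proposals, so plain Metropolis acceptance applies.

Defaults: 1,000 burn-in + 4,000 kept iterations thinned by 5 (800 draws).
Convergence is monitored by single-chain split-R-hat on `x0` and three
`alpha_j` spread along the core; values above 1.05 raise a warning, never a
silent pass. Individual section rates inside a slow interval are only
weakly identified (the data constrain their sum), so their R-hat can
trip the warning even when ages, bands and interval-mean rates are stable;
the warning is informative rather than fatal by design.

Summaries (median, 2.5/97.5 percentiles) are computed per cm from the full
ensemble. Depth intervals are half-open `[top, bottom)`; depths are cm below
surface on the restored (decompacted) scale, where each coring drive is
linearly stretched from its recovered length back to its driven length.

## Accumulation rates, slow-interval detection, peat loss

`rate_profile` converts the ensemble into interval rates: the point rate is
interval thickness over the difference of median ages (mm/yr); the sd is the
spread of per-draw rates. `detect_ghost` flags an interior interval whose
rate is at least `ratio_threshold` (default 5) times slower than **both**
neighbours — the operational definition of a decomposition ("ghost")
interval. When the interval bounds are not known stratigraphically,
`scan_ghost_breakpoints` scores every admissible 3-interval partition of the
section edges by the smaller of the two neighbour/middle rate ratios and
returns the best pair.

Peat loss over a slow interval of duration `T` (yr) with remaining thickness
`R` (mm), had peat kept accumulating at the neighbouring rate `r` (mm/yr):
`max(rT - R, 0)/1000` metres. With the bracketing rates 0.50 and
0.74 mm/yr, `T = 5,500 yr`, `R = 390 mm`, this gives 2.36 and 3.68 m.

Rate-profile caveat: the memory prior smooths section-to-section rates, so
interval rates adjacent to a strong contrast are biased a few percent toward
their neighbours; the contrast ratio itself remains well above the detection
threshold in the study-like geometry.

## Proxy envelopes

Proxy records are measured on depth; interpretation happens on age.
`proxy_envelope` propagates both error sources by Monte Carlo: each draw
perturbs values by their analytical 1-sigma, takes one posterior age-depth
draw to map depths to ages, and interpolates onto a common age grid. The
68%/95% envelopes are pointwise quantiles. Pollen envelopes
(`count_envelope`) work the same way but resample counts multinomially at
the observed proportions, so envelope width scales like 1/sqrt(pollen sum).

## Rock-Eval S2 indices

The S2 thermogram (hydrocarbon yield vs pyrolysis temperature) is split into
five pools: 200-340 C (A1, highly labile), 340-400 (A2, labile), 400-460
(A3, resistant), 460-520 (A4, refractory), 520-650 C (A5, highly
refractory). Integration is trapezoidal with linear interpolation at band
boundaries (half-open bands); areas are expressed as percent of the
200-650 C total, which makes

    I = log10((A1 + A2) / A3)        R = (A3 + A4 + A5) / 100

with `R in (0,1)`. `I` is a pure ratio, identical under any common
normalisation; `R` requires the percent convention, which is therefore the
default and exposed as configuration. Fresh organic matter typically has
`I` in 0.2-0.5; negative `I` marks intense decomposition. Rock-Eval organic
carbon is corrected to elemental-analyser-comparable TOC by the immature
organic-matter factor 1.166256; corrected values above 100 wt% warn about
oxidation-phase signal saturation.

The decomposition classifier flags depths where `I < 0` **and** TOC and C/N
both exceed thresholds (default: profile median + 1 robust sd, i.e.
1.4826 MAD). The ~2 permil delta13C shift of decomposed intervals is
reported descriptively (baseline median minus interval median), not used by
the classifier.

## Plant-wax metrics

CPI uses the double-window odd/even formula over C25-C35:
`[(C25+C27+C29+C31+C33) + (C27+C29+C31+C33+C35)] / [2 (C26+...+C34)]`.
It is scale invariant; missing chains count as zero with a warning.
Dominant-homologue ties break toward the longer chain. Replicate isotope
statistics use sample sd (n-1); single replicates fall back to instrument
precision (deltaD 3 permil, delta13C 0.3 permil). No vegetation or
ice-volume corrections are applied to deltaD; hooks exist but default off.

## deltaD -> precipitation-regime inversion

Step 1 — wax to precipitation: the soil calibration has slope ~1, so the
transfer is an additive offset and only *relative* changes are
interpretable; the package works in offsets against the core-top (modern)
sample throughout, and the unknown apparent fractionation cancels.

Step 2 — amount effect and annual averaging: station regressions
`dD = a + b P` (P in mm/month) are unweighted OLS on monthly aggregates.
The precipitation-weighted annual value of a monthly climatology `P_m` is

    dD_ann = sum P_m (a + b P_m) / sum P_m = a + b (sum P_m^2 / sum P_m),

an exact closed form used directly.

Seasonality index: with `p_m = P_m / MAP`,
`D = sum p_m log2(12 p_m)` (relative entropy vs uniform, `0 <= D <= log2 12
~ 3.585`) and `SI = D * MAP / r_max`, `r_max` being the maximum MAP in the
gridded data. SI is zero iff rainfall is uniform and linear in MAP at fixed
shape.

Step 3 — solution curves: a reconstructed annual deltaD target constrains a
one-parameter family of regimes. The monthly shape family is
circular-exponential, `w_m(kappa) ∝ exp(kappa cos(2 pi (m - m0)/12))`,
chosen because it spans SI from 0 (kappa=0, uniform) to near-maximal
concentration, is smooth in kappa, and makes the inversion analytic:
with `P_m = MAP w_m`, `dD_ann = a + b MAP sum w_m^2`, so

    MAP(kappa) = (target - a) / (b sum w_m(kappa)^2).

The (MAP(kappa), SI(kappa)) locus is the solution curve; differencing two
curves on a shared kappa grid brackets the precipitation change between two
epochs, and spread across the three station regressions widens the bracket.
The family is a declared stand-in: real monthly distributions are not
circular-exponential, so solution curves are exact for the family and
approximate for nature. An alternative (power-transformed observed
climatology) gives similar loci but no closed form; it was not adopted.

## Climate-space KDE

Each grid cell contributes one (MAP, SI) point. The density is a
product-Gaussian KDE with per-axis bandwidths chosen by the diffusion
fixed-point selector (Botev-Grotowski-Kroese 2010), implemented via DCT
with a Silverman fallback for degenerate samples. Evaluation is by binned
Gaussian smoothing on a 256x256 grid — equivalent to the exact KDE up to
binning resolution and O(grid) rather than O(n·grid). Contour levels are
highest-density-region thresholds: the density value whose superlevel set
contains 68% (resp. 95%) of total mass. "68% from the peak density" is
interpreted as this mass convention, the common one; a level-ratio
interpretation would give different, less calibratable contours.

## Synthetic worlds

The generator emulates the statistical structure of the study inputs with
known truth, at a problem size chosen for fast, well-identified inference:

- **Core geometry**: 300 cm with a slow interval at 190-150 cm and true
  rates 0.50 / 0.09 / 0.74 mm/yr (below / within / above), core top
  AD 2014. The interval's implied ages are ~6.4 and ~2.0 ka. Twenty
  radiocarbon dates (~1 per 15 cm) with 40 14C yr errors, measured against
  a seeded wiggly monotone curve pair (hemispheres offset by 40 14C yr).
- **Thermograms**: two-Gaussian labile (330 C) / resistant (445 C)
  mixtures; labile fraction 0.45 outside the interval (I ~ 0.34, inside the
  fresh band) and 0.10 within (I ~ -0.15).
- **Bulk geochemistry**: TOC 55 -> 65 wt%, C/N 45 -> 80, delta13C
  -29 -> -27 permil inside the interval, with analytical noise.
- **Wax deltaD**: piecewise-linear in age with the 5,000- and 2,000-yr
  levels offset -20.3 / +5.6 permil from the core top; duplicate
  replicates with 2 permil scatter; odd-dominated chain profiles with CPI
  ~5-10 (mean ~7.3).
- **Stations**: monthly series whose deltaD follows the configured lines
  (slopes -2.5 / -4.6 / -3.2) with noise variance set analytically from the
  target R^2 (0.73 / 0.81 / 0.65).
- **Climatology grid**: 400 cells with MAP uniform on 900-3,200 mm/yr and
  kappa uniform on 0-3 expanded through the circular-exponential family.
- **Pollen**: Dirichlet-multinomial counts (sum 350) with swamp taxa
  (Pandanus, Pycnanthus) dropping from 30% to 8% inside the interval;
  charcoal Poisson and flat (no fire signal).

What it does **not** emulate: curve plateaus and reversals of the real
calibration record (wiggles are gentle), laboratory blank/background
structure, spatially correlated rainfall, non-stationary amount-effect
relationships, taphonomic pollen degradation, or real monthly precipitation
shapes. Passing tests therefore demonstrate correctness of the algorithms
and their uncertainty accounting under the stated generating assumptions,
not field performance on any particular real core.

## Problem sizes and determinism

Default analysis sizes: 10-cm sections (30 per core) for synthetic-world
fits, 4,000 kept iterations, 800 posterior draws, 200-400 Monte-Carlo
envelope draws, 256-grid KDEs. These were chosen so a full multi-seed
recovery study completes in minutes on one CPU while leaving all recovery
margins comfortable. Every stochastic routine takes an explicit seed;
identical seeds give identical output to the byte.

## Known limitations

- Single-chain split-R-hat is a weak diagnostic for multimodal posteriors;
  it warns on slow within-interval mixing that does not affect the reported
  summaries (see above).
- The standalone-calibration posterior uses a plain normal observation
  model; the age-depth model uses Student-t. The two are deliberately
  different (robustness matters only where multiple dates interact).
- `peat_loss` assumes the neighbouring rate would have held throughout the
  slow interval — an accounting convention, not a process model.
- Solution-curve numbers inherit the circular-exponential family; treat
  cross-epoch MAP differences as order-of-magnitude brackets, not point
  estimates.
- Reservoir corrections, 210Pb chronologies and post-bomb calibration are
  out of scope.
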