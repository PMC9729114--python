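# ghostpeat

Palaeoenvironmental analysis of tropical peat cores: radiocarbon chronology
with mixed-hemisphere calibration, Bayesian age-depth modelling with
slow-interval ("ghost interval") detection, Rock-Eval S2 thermogram indices,
plant-wax n-alkane metrics, a leaf-wax deltaD inversion to precipitation
regimes, pollen/charcoal quantification, and peat-loss accounting — plus a
synthetic-data generator that emulates every input with known ground truth.

It is written for palaeoecologists and biogeochemists working on peat-core
records, in particular records where an interval of anomalously slow
apparent accumulation may mark peat that decomposed (or was lost) after
deposition, and where leaf-wax hydrogen isotopes are used to ask whether a
drying climate drove that loss.

## The models in brief

**Chronology.** Dates are calibrated against a mixture of the two
hemisphere calibration curves (for sites under mixed north/south air
masses): on a common grid, mu = w·mu_N + (1−w)·mu_S and
sigma² = w·sigma_N² + (1−w)·sigma_S² + w(1−w)(mu_N − mu_S)². The age-depth
model is the gamma-autoregressive accumulation family: per-section rates
alpha_j (yr/cm) with an autoregressive gamma prior (memory w), a Student-t
(a=3, b=4) observation model in radiocarbon space, and Metropolis-within-
Gibbs sampling — every posterior draw is strictly monotone in depth.
Interval rates from the posterior feed a dual-sided ratio test: an interior
interval ≥ 5× slower than both neighbours is flagged as a ghost interval,
and the thickness deficit `max(r·T − R, 0)` converts to metres of peat lost.

**Geochemistry.** The S2 pyrolysis thermogram is integrated over five
thermal pools (200–340, 340–400, 400–460, 460–520, 520–650 °C, as % of the
total), giving I = log10((A1+A2)/A3) and R = (A3+A4+A5)/100. Fresh organic
matter has I ≈ 0.2–0.5; negative I plus elevated TOC and C/N classifies
decomposed peat.

**Hydroclimate.** Wax deltaD maps to precipitation deltaD by a slope-1
calibration (offsets cancel in differences). Station amount-effect lines
dD = a + b·P give the precipitation-weighted annual value
a + b·ΣP²/ΣP for any monthly climatology; the seasonality index is
SI = D·MAP/r_max with D the relative entropy (bits) of monthly rainfall
versus uniform. A reconstructed annual deltaD target then defines a
solution curve MAP(kappa) = (target − a)/(b·Σw_m(kappa)²) over a
circular-exponential family of monthly shapes, and differencing two epochs'
curves brackets the precipitation change. Regional (MAP, SI) climate
spaces are bivariate KDEs with diffusion-optimised bandwidths and
highest-density-region 68/95% contours.

## Worked example

Generate a synthetic world whose truth mirrors the study conditions — a
300-cm core with a slow interval at 190–150 cm (true rates
0.50/0.09/0.74 mm/yr) — and run the full pipeline:

```python
from ghostpeat.synthetic import WorldConfig, write_world
from ghostpeat.pipeline import run_pipeline

write_world(WorldConfig(seed=7), "world")
report = run_pipeline({
    "input_dir": "world", "out_dir": "out", "seed": 7,
    "section_thickness": 10.0, "ghost_breakpoints": [150.0, 190.0],
})
c = report["chronology"]
print([round(r, 3) for r in c["rates_mm_yr"]])  # [0.724, 0.093, 0.486]
print(c["ghost_flagged"])                       # True
print([round(x, 2) for x in c["peat_loss_m"]])  # [1.7, 2.73]
```

The fitted interval rates recover the generating truth (0.74/0.09/0.50) to
within a few percent; the middle interval is 5–8× slower than its
neighbours, so it is flagged, and the peat-loss accounting converts its
~4,300-yr fitted duration and 400-mm remaining thickness into roughly
1.7–2.7 m of peat missing relative to the bracketing rates. With the published interval
parameters (rates 0.50 and 0.74 mm/yr, 5,500 yr, 390 mm remaining) the same
arithmetic gives:

```python
from ghostpeat.chronology import peat_loss
peat_loss(0.50, 5500, 390), peat_loss(0.74, 5500, 390)   # (2.36, 3.68) metres
```

A matching command-line surface exists for every stage
(`ghostpeat synth world`, `ghostpeat chronology fit`, `ghostpeat chronology
ghost`, `ghostpeat rockeval`, `ghostpeat wax`, `ghostpeat pollen`,
`ghostpeat climate space`, `ghostpeat climate solve`, `ghostpeat run`).

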