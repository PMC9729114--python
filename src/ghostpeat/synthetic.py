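"""Synthetic peat-core worlds with known ground truth.

Generates every input the pipeline reads — calibration curves, radiocarbon
dates, Rock-Eval S2 thermograms, bulk geochemistry, plant-wax records,
pollen/charcoal counts, station isotope series and gridded climatologies —
from a single seeded configuration, with the generating truth attached so
every stage can be tested by parameter recovery.

The default world mirrors the geometry of a central-African interfluvial
peat core: a slow ("ghost") interval at 190-150 cm with accumulation
0.09 mm/yr between faster peat below (0.50 mm/yr) and above (0.74 mm/yr),
a drying ramp in wax deltaD between 5,000 and 2,000 cal yr BP whose offsets
against the core top are -20.3 and +5.6 permil, station amount-effect lines
with slopes -2.5 / -4.6 / -3.2, and swamp-taxon pollen declining inside the
slow interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ghostpeat.chronology import CalibrationCurve, RadiocarbonDate
from ghostpeat.hydroclimate import monthly_weights


@dataclass
class WorldConfig:
    """Ground truth and sampling design for a synthetic world."""

    seed: int = 0
    # core geometry (cm, restored scale) and true accumulation (mm/yr)
    core_depth: float = 300.0
    ghost_top: float = 150.0
    ghost_bottom: float = 190.0
    rate_above: float = 0.74
    rate_ghost: float = 0.09
    rate_below: float = 0.50
    collection_year: int = 2014
    # dating design
    n_dates: int = 20
    date_error: float = 40.0  # 14C yr, 1 sigma
    # thermal-pool truth: fraction of S2 mass in the labile pool
    labile_fresh: float = 0.45
    labile_decomposed: float = 0.10
    # bulk geochemistry truth (fresh matrix vs decomposed interval)
    toc_fresh: float = 55.0
    toc_decomposed: float = 65.0
    cn_fresh: float = 45.0
    cn_decomposed: float = 80.0
    d13c_fresh: float = -29.0
    d13c_decomposed: float = -27.0
    # wax deltaD trajectory: (age cal yr BP, dD_wax permil) knots; offsets of
    # the 5,000 and 2,000 cal yr BP levels vs the core top are -20.3 / +5.6
    dD_knots: tuple[tuple[float, float], ...] = (
        (-100.0, -150.0),
        (900.0, -150.0),
        (2000.0, -144.4),
        (5000.0, -170.3),
        (25000.0, -170.3),
    )
    wax_noise: float = 2.0  # replicate scatter, permil
    # amount-effect truth per station: intercept a (permil), slope b
    # (permil per mm/month), and the R^2 the noise is tuned to produce
    stations: dict = field(
        default_factory=lambda: {
            "Bangui": {"a": -2.0, "b": -2.5, "r2": 0.73},
            "Kinshasa": {"a": 5.0, "b": -4.6, "r2": 0.81},
            "Kisangani": {"a": 0.0, "b": -3.2, "r2": 0.65},
        }
    )
    station_months: int = 120
    # climatology grid
    n_cells: int = 400
    map_range: tuple[float, float] = (900.0, 3200.0)
    kappa_range: tuple[float, float] = (0.0, 3.0)
    peak_month: int = 1
    # pollen truth
    pollen_sum: int = 350
    swamp_fresh: float = 0.30
    swamp_decomposed: float = 0.08
    arboreal_fresh: float = 0.88

    def __post_init__(self) -> None:
        if min(self.rate_above, self.rate_ghost, self.rate_below) <= 0:
            raise ValueError("true accumulation rates must be positive")
        if not 0 <= self.ghost_top < self.ghost_bottom <= self.core_depth:
            raise ValueError("ghost interval must lie inside the core")

    # -- true age-depth function ------------------------------------------
    @property
    def top_age(self) -> float:
        return 1950.0 - self.collection_year

    def true_age(self, depths: np.ndarray) -> np.ndarray:
        """True age (cal yr BP) at restored depths (cm); piecewise linear."""
        d = np.atleast_1d(np.asarray(depths, dtype=float))
        yr_per_cm = np.where(
            d <= self.ghost_top,
            10.0 / self.rate_above,
            np.where(d <= self.ghost_bottom, 10.0 / self.rate_ghost, 10.0 / self.rate_below),
        )
        # integrate piecewise-constant gradient from the surface
        knots = np.array([0.0, self.ghost_top, self.ghost_bottom, self.core_depth])
        grads = np.array(
            [10.0 / self.rate_above, 10.0 / self.rate_ghost, 10.0 / self.rate_below]
        )
        knot_ages = self.top_age + np.concatenate(([0.0], np.cumsum(grads * np.diff(knots))))
        return np.interp(d, knots, knot_ages)

    def true_dD(self, ages: np.ndarray) -> np.ndarray:
        knots = np.asarray(self.dD_knots, dtype=float)
        return np.interp(np.asarray(ages, dtype=float), knots[:, 0], knots[:, 1])

    def labile_fraction(self, depths: np.ndarray) -> np.ndarray:
        d = np.atleast_1d(np.asarray(depths, dtype=float))
        inside = (d >= self.ghost_top) & (d < self.ghost_bottom)
        return np.where(inside, self.labile_decomposed, self.labile_fresh)


# ---------------------------------------------------------------------------
# Calibration curves
# ---------------------------------------------------------------------------


def synth_curve(
    cal_min: float = -70.0,
    cal_max: float = 25000.0,
    seed: int = 0,
    step: float = 5.0,
    slope: float = 1.0,
    offset: float = 0.0,
    wiggle_amp: float = 0.3,
    sigma: float = 15.0,
    name: str = "synth",
) -> CalibrationCurve:
    """A smooth monotone synthetic calibration curve with optional wiggles.

    The radiocarbon-vs-calendar gradient is slope * (1 + wiggles) with the
    wiggle amplitude strictly below 1, so monotonicity holds by
    construction; ``offset`` shifts the whole curve (useful for building a
    hemisphere pair differing by a constant).
    """
    if slope <= 0:
        raise ValueError("curve slope must be positive: the curve must be monotone")
    if not 0 <= wiggle_amp < 1:
        raise ValueError("wiggle amplitude must lie in [0, 1) to keep the curve monotone")
    rng = np.random.default_rng(seed)
    cal = np.arange(cal_min, cal_max + step / 2, step)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    periods = np.array([800.0, 2300.0, 5100.0])
    wig = sum(
        np.sin(2 * np.pi * cal / p + ph) / len(periods) for p, ph in zip(periods, phase)
    )
    grad = slope * (1.0 + wiggle_amp * wig)
    c14 = offset + np.concatenate(([0.0], np.cumsum(0.5 * (grad[1:] + grad[:-1]) * np.diff(cal))))
    return CalibrationCurve(cal, c14, np.full_like(cal, float(sigma)), name=name)


def synth_curve_pair(
    seed: int = 0, hemispheric_offset: float = 40.0, **kwargs
) -> tuple[CalibrationCurve, CalibrationCurve]:
    """A north/south curve pair differing by a constant radiocarbon offset."""
    north = synth_curve(seed=seed, name="north", **kwargs)
    south = CalibrationCurve(
        north.cal_age, north.c14_age + hemispheric_offset, north.sigma, name="south"
    )
    return north, south


# ---------------------------------------------------------------------------
# Core: dates, thermograms, bulk geochem, wax, pollen, charcoal
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCore:
    dates: pd.DataFrame
    thermograms: pd.DataFrame
    bulk: pd.DataFrame
    wax: pd.DataFrame
    pollen: pd.DataFrame
    markers: pd.DataFrame
    charcoal: pd.DataFrame
    truth: dict
    config: WorldConfig

    def radiocarbon_dates(self) -> list[RadiocarbonDate]:
        return [
            RadiocarbonDate(
                depth=row.depth_cm,
                c14_age=row.c14_age,
                error=row.error,
                fraction=row.fraction,
                label=row.id,
            )
            for row in self.dates.itertuples()
        ]


def _two_pool_signal(temp: np.ndarray, labile_frac: float) -> np.ndarray:
    """Two-Gaussian S2 shape: labile pool near 330 degC, resistant near 445."""
    lab = np.exp(-0.5 * ((temp - 330.0) / 38.0) ** 2) / 38.0
    res = np.exp(-0.5 * ((temp - 445.0) / 52.0) ** 2) / 52.0
    return labile_frac * lab + (1.0 - labile_frac) * res


def synth_core(
    world: WorldConfig, curve: CalibrationCurve | None = None
) -> SyntheticCore:
    """Generate a full synthetic core consistent with the world's truth.

    Radiocarbon dates are the calibration curve evaluated at the true ages
    of evenly spread depths plus normal measurement noise; thermograms are
    two-Gaussian labile/resistant mixtures whose labile fraction drops
    inside the slow interval; bulk geochemistry, wax deltaD, pollen and
    charcoal follow the configured trajectories with realistic noise.
    """
    cfg = world
    rng = np.random.default_rng(cfg.seed)
    if curve is None:
        north, south = synth_curve_pair(seed=cfg.seed)
        from ghostpeat.chronology import mix_calibration_curves

        curve = mix_calibration_curves(north, south, 0.5)

    # --- radiocarbon dates ---
    depths = np.linspace(cfg.core_depth / cfg.n_dates, cfg.core_depth - 2.0, cfg.n_dates)
    depths += rng.uniform(-3.0, 3.0, size=cfg.n_dates)
    depths = np.clip(np.sort(depths), 1.0, cfg.core_depth)
    true_ages = cfg.true_age(depths)
    mu, _ = curve.interp(true_ages)
    c14 = mu + rng.normal(0.0, cfg.date_error, size=len(depths))
    dates = pd.DataFrame(
        {
            "id": [f"SYN-{i:02d}" for i in range(len(depths))],
            "depth_cm": depths,
            "c14_age": c14,
            "error": np.full(len(depths), cfg.date_error),
            "fraction": "fine",
        }
    )

    # --- thermograms (every 10 cm) ---
    tg_depths = np.arange(5.0, cfg.core_depth, 10.0)
    temp = np.arange(200.0, 650.0 + 1e-9, 2.0)
    frames = []
    for d in tg_depths:
        frac = float(cfg.labile_fraction(d)[0])
        sig = _two_pool_signal(temp, frac)
        sig = sig * rng.uniform(0.8, 1.2) * (1.0 + rng.normal(0.0, 0.01, size=temp.size))
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": f"TG-{d:05.1f}",
                    "depth_cm": d,
                    "temperature_C": temp,
                    "signal": np.clip(sig, 0.0, None),
                }
            )
        )
    thermograms = pd.concat(frames, ignore_index=True)

    # --- bulk geochemistry (every 5 cm) ---
    bk_depths = np.arange(2.5, cfg.core_depth, 5.0)
    inside = (bk_depths >= cfg.ghost_top) & (bk_depths < cfg.ghost_bottom)
    toc = np.where(inside, cfg.toc_decomposed, cfg.toc_fresh) + rng.normal(0, 1.0, bk_depths.size)
    cn = np.where(inside, cfg.cn_decomposed, cfg.cn_fresh) + rng.normal(0, 2.0, bk_depths.size)
    d13c = np.where(inside, cfg.d13c_decomposed, cfg.d13c_fresh) + rng.normal(
        0, 0.15, bk_depths.size
    )
    bulk = pd.DataFrame(
        {
            "depth_cm": bk_depths,
            "toc_ea": toc,
            "total_n": toc / cn,
            "d13c_toc": d13c,
        }
    )

    # --- plant-wax record (every 5 cm, duplicate replicates) ---
    wax_depths = np.arange(2.5, cfg.core_depth, 5.0)
    wax_true_dD = cfg.true_dD(cfg.true_age(wax_depths))
    rows = []
    chains = np.arange(25, 36)
    for d, dd in zip(wax_depths, wax_true_dD):
        odd_level = rng.uniform(6.0, 9.0)
        for rep in (1, 2):
            for c in chains:
                if c % 2 == 1:
                    peak = {29: 1.0, 31: 0.85, 27: 0.55, 33: 0.3, 25: 0.15, 35: 0.1}[c]
                    ab = odd_level * peak * rng.uniform(0.95, 1.05)
                else:
                    ab = 0.58 * rng.uniform(0.9, 1.1)  # even-chain level sets CPI ~5-10, mean ~7.3
                rows.append(
                    {
                        "depth_cm": d,
                        "chain": c,
                        "abundance": ab,
                        "dD": dd + rng.normal(0, cfg.wax_noise) if c in (27, 29, 31) else np.nan,
                        "d13C": -32.0 + rng.normal(0, 0.2) if c in (27, 29, 31) else np.nan,
                        "replicate": rep,
                    }
                )
    wax = pd.DataFrame(rows)

    # --- pollen and charcoal (every 10 cm) ---
    pn_depths = np.arange(5.0, cfg.core_depth, 10.0)
    taxa_base = {
        "Pandanus": 0.6,
        "Pycnanthus": 0.4,
        "Uapaca": 0.30,
        "Alchornea": 0.20,
        "Macaranga": 0.08,
        "Poaceae": 0.12,
    }
    rows, mrows, crows = [], [], []
    for d in pn_depths:
        inside = cfg.ghost_top <= d < cfg.ghost_bottom
        swamp = cfg.swamp_decomposed if inside else cfg.swamp_fresh
        arboreal_rest = cfg.arboreal_fresh - swamp
        nonarb = 1.0 - cfg.arboreal_fresh
        p = {
            "Pandanus": swamp * taxa_base["Pandanus"],
            "Pycnanthus": swamp * taxa_base["Pycnanthus"],
            "Uapaca": arboreal_rest * 0.52,
            "Alchornea": arboreal_rest * 0.34,
            "Macaranga": arboreal_rest * 0.14,
            "Poaceae": nonarb,
        }
        probs = np.array(list(p.values()))
        probs = rng.dirichlet(probs * 120.0)  # sample-to-sample compositional noise
        counts = rng.multinomial(cfg.pollen_sum, probs)
        for (taxon, _), c in zip(p.items(), counts):
            rows.append({"depth_cm": d, "taxon": taxon, "count": int(c)})
        mrows.append(
            {
                "depth_cm": d,
                "marker_counted": int(rng.integers(80, 300)),
                "tablets": 2,
                "spores_per_tablet": 11267,
                "volume_cm3": 1.0,
            }
        )
        crows.append(
            {"depth_cm": d, "particle_count": int(rng.poisson(3.0)), "volume_cm3": 1.0}
        )
    pollen = pd.DataFrame(rows)
    markers = pd.DataFrame(mrows)
    charcoal = pd.DataFrame(crows)

    truth = {
        "top_age": cfg.top_age,
        "ghost_interval": [cfg.ghost_top, cfg.ghost_bottom],
        "rates_mm_yr": {
            "above": cfg.rate_above,
            "ghost": cfg.rate_ghost,
            "below": cfg.rate_below,
        },
        "age_knots": {
            "depth_cm": [0.0, cfg.ghost_top, cfg.ghost_bottom, cfg.core_depth],
            "age": cfg.true_age(
                np.array([0.0, cfg.ghost_top, cfg.ghost_bottom, cfg.core_depth])
            ).tolist(),
        },
        "labile_fraction": {
            "fresh": cfg.labile_fresh,
            "decomposed": cfg.labile_decomposed,
        },
        "dD_knots": [list(k) for k in cfg.dD_knots],
        "swamp_fraction": {"fresh": cfg.swamp_fresh, "decomposed": cfg.swamp_decomposed},
    }
    return SyntheticCore(
        dates=dates,
        thermograms=thermograms,
        bulk=bulk,
        wax=wax,
        pollen=pollen,
        markers=markers,
        charcoal=charcoal,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Climate: station series and climatology grid
# ---------------------------------------------------------------------------


@dataclass
class SyntheticClimate:
    stations: pd.DataFrame  # station, month_index, P_mm, dD
    grid: pd.DataFrame  # cell, month (1-12), P_mm columns wide
    site_climatology: np.ndarray  # (12,)
    r_max: float
    truth: dict


def synth_climate(world: WorldConfig) -> SyntheticClimate:
    """Station isotope series and a regional climatology grid.

    Station monthly deltaD follows the configured linear amount effect with
    gaussian noise whose variance is tuned analytically to the target R^2;
    grid cells draw (MAP, kappa) from the configured ranges and expand to
    monthly amounts through the circular-exponential weight family.
    """
    cfg = world
    rng = np.random.default_rng(cfg.seed + 1)
    srows = []
    for name, st in cfg.stations.items():
        months = np.arange(cfg.station_months)
        seasonal = 120.0 + 100.0 * np.cos(2 * np.pi * (months % 12 - cfg.peak_month + 1) / 12.0)
        P = np.clip(seasonal + rng.normal(0, 35.0, size=months.size), 0.0, None)
        sd_signal = abs(st["b"]) * P.std(ddof=1)
        noise_sd = sd_signal * np.sqrt(1.0 / st["r2"] - 1.0)
        dD = st["a"] + st["b"] * P + rng.normal(0, noise_sd, size=months.size)
        for m, (pp, dd) in enumerate(zip(P, dD)):
            srows.append({"station": name, "month_index": m, "P_mm": pp, "dD": dd})
    stations = pd.DataFrame(srows)

    maps = rng.uniform(*cfg.map_range, size=cfg.n_cells)
    kappas = rng.uniform(*cfg.kappa_range, size=cfg.n_cells)
    cells = np.array(
        [m * monthly_weights(k, cfg.peak_month) for m, k in zip(maps, kappas)]
    )
    grid = pd.DataFrame(cells, columns=[f"P{m:02d}" for m in range(1, 13)])
    grid.insert(0, "cell", np.arange(cfg.n_cells))
    r_max = float(maps.max())

    site_map = float(np.median(maps))
    site_kappa = 1.2
    site = site_map * monthly_weights(site_kappa, cfg.peak_month)

    truth = {
        "stations": cfg.stations,
        "map_range": list(cfg.map_range),
        "kappa_range": list(cfg.kappa_range),
        "r_max": r_max,
        "site_map": site_map,
        "site_kappa": site_kappa,
        "peak_month": cfg.peak_month,
    }
    return SyntheticClimate(
        stations=stations,
        grid=grid,
        site_climatology=site,
        r_max=r_max,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk world
# ---------------------------------------------------------------------------


def write_world(world: WorldConfig, out_dir: str | Path) -> Path:
    """Write every synthetic input file plus truth.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    north, south = synth_curve_pair(seed=world.seed)
    from ghostpeat import io as gio

    gio.write_calibration_curve(north, out / "north.14c")
    gio.write_calibration_curve(south, out / "south.14c")
    core = synth_core(world)
    core.dates.to_csv(out / "dates.csv", index=False)
    core.thermograms.to_csv(out / "thermograms.csv", index=False)
    core.bulk.to_csv(out / "bulk.csv", index=False)
    core.wax.to_csv(out / "wax.csv", index=False)
    core.pollen.to_csv(out / "pollen.csv", index=False)
    core.markers.to_csv(out / "markers.csv", index=False)
    core.charcoal.to_csv(out / "charcoal.csv", index=False)
    climate = synth_climate(world)
    climate.stations.to_csv(out / "stations.csv", index=False)
    climate.grid.to_csv(out / "climatology_grid.csv", index=False)
    truth = {"core": core.truth, "climate": climate.truth, "seed": world.seed}
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
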