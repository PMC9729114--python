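"""End-to-end orchestration: inputs -> chronology -> proxies -> inversion.

``run_pipeline`` consumes a directory of input files (the formats
``ghostpeat.synthetic.write_world`` produces and ``ghostpeat.io`` reads),
runs the requested stages in dependency order and writes a JSON + CSV
bundle plus an effective-config snapshot, so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ghostpeat import io as gio
from ghostpeat.biomarker import summarize_wax
from ghostpeat.chronology import (
    AgeDepthConfig,
    ProxySeries,
    detect_ghost,
    fit_age_depth,
    mix_calibration_curves,
    peat_loss,
    proxy_envelope,
    rate_profile,
)
from ghostpeat.geochem import Thermogram, classify_decomposed, rock_eval
from ghostpeat.hydroclimate import (
    build_climate_space,
    fit_amount_effect,
    precip_change_range,
    reconstruct_offsets,
    solution_curve,
)
from ghostpeat.palynology import PollenSample, concentration, count_envelope, percentages

log = logging.getLogger("ghostpeat.pipeline")

DEFAULT_CONFIG: dict = {
    "input_dir": ".",
    "out_dir": "ghostpeat_out",
    "seed": 0,
    "mix_weight": 0.5,
    "top_year": 2014,
    "section_thickness": 10.0,
    "mcmc_iter": 4000,
    "mcmc_burn": 1000,
    "ghost_breakpoints": None,  # [top, bottom] cm; None -> scan
    "ghost_ratio": 5.0,
    "offset_times": [5000.0, 2000.0],
    "kappa_max": 5.0,
    "n_draws": 500,
    "stages": ["chronology", "geochem", "biomarker", "palynology", "hydroclimate"],
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict) -> dict:
    """Run the configured stages and return (and write) the report bundle."""
    cfg = {**DEFAULT_CONFIG, **config}
    indir = Path(cfg["input_dir"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.json").write_text(json.dumps(cfg, indent=1, default=str))
    report: dict = {"seed": cfg["seed"], "stages": list(cfg["stages"])}
    state: dict = {}

    order = ["chronology", "geochem", "biomarker", "palynology", "hydroclimate"]
    runners = {
        "chronology": _stage_chronology,
        "geochem": _stage_geochem,
        "biomarker": _stage_biomarker,
        "palynology": _stage_palynology,
        "hydroclimate": _stage_hydroclimate,
    }
    for stage in order:
        if stage not in cfg["stages"]:
            log.info("stage %s disabled", stage)
            continue
        log.info("running stage %s", stage)
        try:
            runners[stage](cfg, indir, out, state, report)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - named-stage abort contract
            raise StageError(stage, exc) from exc
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def _require(state: dict, key: str, stage: str, needed_by: str) -> object:
    if key not in state:
        raise StageError(
            needed_by, RuntimeError(f"requires output of stage {stage!r}, which did not run")
        )
    return state[key]


def _stage_chronology(cfg, indir, out, state, report) -> None:
    north = gio.read_calibration_curve(indir / "north.14c")
    south = gio.read_calibration_curve(indir / "south.14c")
    curve = mix_calibration_curves(north, south, cfg["mix_weight"])
    dates = gio.read_dates(indir / "dates.csv")
    mcfg = AgeDepthConfig(
        section_thickness=cfg["section_thickness"],
        n_iter=cfg["mcmc_iter"],
        burn=cfg["mcmc_burn"],
        seed=cfg["seed"],
    )
    model = fit_age_depth(dates, curve, top_age=1950.0 - cfg["top_year"], config=mcfg)
    model.summaries.to_csv(out / "age_model.csv", index=False)
    gio.write_model(model, out / "model.json")
    state["model"] = model
    state["curve"] = curve

    if cfg["ghost_breakpoints"]:
        bps = list(cfg["ghost_breakpoints"])
    else:
        from ghostpeat.chronology import scan_ghost_breakpoints

        bps = list(scan_ghost_breakpoints(model))
    profile = rate_profile(model, bps)
    ghost = detect_ghost(profile, cfg["ghost_ratio"])
    state["profile"], state["ghost"] = profile, ghost
    report["chronology"] = {
        "n_dates": len(dates),
        "breakpoints_cm": bps,
        "rates_mm_yr": [iv.rate for iv in profile.intervals],
        "rate_sds": [iv.rate_sd for iv in profile.intervals],
        "ghost_flagged": ghost is not None,
    }
    if ghost is not None:
        ages = np.median(model.ages_at([ghost.depth_top, ghost.depth_bottom]), axis=0)
        duration = float(ages[1] - ages[0])
        remaining_mm = (ghost.depth_bottom - ghost.depth_top) * 10.0
        rates = [iv.rate for iv in profile.intervals]
        i = profile.intervals.index(ghost)
        losses = [
            peat_loss(r, duration, remaining_mm) for r in (rates[i - 1], rates[i + 1])
        ]
        report["chronology"].update(
            {
                "ghost_interval_cm": [ghost.depth_top, ghost.depth_bottom],
                "ghost_duration_yr": duration,
                "peat_loss_m": [min(losses), max(losses)],
            }
        )


def _stage_geochem(cfg, indir, out, state, report) -> None:
    tg = pd.read_csv(indir / "thermograms.csv")
    results = []
    for sid, g in tg.groupby("sample_id"):
        g = g.sort_values("temperature_C")
        res = rock_eval(
            Thermogram(
                g["temperature_C"].to_numpy(),
                g["signal"].to_numpy(),
                sample_id=str(sid),
                depth=float(g["depth_cm"].iloc[0]),
            )
        )
        results.append(
            {
                "sample_id": res.sample_id,
                "depth_cm": res.depth,
                **{f"A{i+1}": a for i, a in enumerate(res.areas)},
                "i_index": res.i_index,
                "r_index": res.r_index,
            }
        )
    rockeval = pd.DataFrame(results).sort_values("depth_cm")
    rockeval.to_csv(out / "rockeval.csv", index=False)

    bulk = pd.read_csv(indir / "bulk.csv")
    bulk["cn"] = bulk["toc_ea"] / bulk["total_n"]
    profile = pd.DataFrame(
        {
            "depth": bulk["depth_cm"],
            "i_index": np.interp(bulk["depth_cm"], rockeval["depth_cm"], rockeval["i_index"]),
            "toc": bulk["toc_ea"],
            "cn": bulk["cn"],
        }
    )
    flags, intervals = classify_decomposed(profile)
    state["rockeval"], state["decomposed_intervals"] = rockeval, intervals
    report["geochem"] = {
        "n_thermograms": len(rockeval),
        "i_index_range": [float(rockeval["i_index"].min()), float(rockeval["i_index"].max())],
        "decomposed_intervals_cm": [list(iv) for iv in intervals],
    }


def _stage_biomarker(cfg, indir, out, state, report) -> None:
    wax = pd.read_csv(indir / "wax.csv").rename(columns={"depth_cm": "depth"})
    summary = summarize_wax(wax)
    summary.to_csv(out / "wax_summary.csv", index=False)
    state["wax_summary"] = summary
    report["biomarker"] = {
        "n_samples": len(summary),
        "cpi_mean": float(summary["cpi"].mean()),
        "dominant_chains": sorted(summary["dominant_chain"].unique().tolist()),
    }


def _stage_palynology(cfg, indir, out, state, report) -> None:
    model = _require(state, "model", "chronology", "palynology")
    pollen = pd.read_csv(indir / "pollen.csv")
    markers = pd.read_csv(indir / "markers.csv")
    samples = []
    for depth, g in pollen.groupby("depth_cm"):
        m = markers[markers["depth_cm"] == depth].iloc[0]
        samples.append(
            PollenSample(
                depth=float(depth),
                counts=dict(zip(g["taxon"], g["count"])),
                marker_counted=int(m["marker_counted"]),
                marker_added=int(m["tablets"] * m["spores_per_tablet"]),
                volume=float(m["volume_cm3"]),
            )
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-300 sums are reported, not fatal
        for s in samples:
            _, groups = percentages(s)
            rows.append(
                {
                    "depth_cm": s.depth,
                    "swamp_pct": groups.get("swamp", 0.0),
                    "other_pct": groups.get("other", 0.0),
                    "concentration": concentration(s),
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "pollen_summary.csv", index=False)
    env = count_envelope(
        samples, model, taxa=["Pandanus", "Pycnanthus"], n_draws=cfg["n_draws"], seed=cfg["seed"]
    )
    for taxon, df in env.items():
        df.to_csv(out / f"pollen_envelope_{taxon}.csv", index=False)
    charcoal = pd.read_csv(indir / "charcoal.csv")
    charcoal["concentration"] = charcoal["particle_count"] / charcoal["volume_cm3"]
    state["pollen_summary"] = summary
    report["palynology"] = {
        "n_samples": len(samples),
        "swamp_pct_range": [float(summary["swamp_pct"].min()), float(summary["swamp_pct"].max())],
        "charcoal_mean_per_cm3": float(charcoal["concentration"].mean()),
    }


def _stage_hydroclimate(cfg, indir, out, state, report) -> None:
    model = _require(state, "model", "chronology", "hydroclimate")
    wax_summary = _require(state, "wax_summary", "biomarker", "hydroclimate")

    stations = pd.read_csv(indir / "stations.csv")
    regs = {
        name: fit_amount_effect(g["P_mm"].to_numpy(), g["dD"].to_numpy(), station=name)
        for name, g in stations.groupby("station")
    }
    grid = gio.read_climatology_grid(indir / "climatology_grid.csv")
    space = build_climate_space(grid)

    # wax deltaD on the age scale; offsets at the configured times vs core top
    series = ProxySeries(
        depth=wax_summary["depth"].to_numpy(),
        value=wax_summary["dD_C29"].to_numpy(),
        analytical_sd=wax_summary["dD_C29_sd"].to_numpy(),
    )
    env = proxy_envelope(series, model, n_draws=cfg["n_draws"], seed=cfg["seed"])
    env.to_csv(out / "dD_envelope.csv", index=False)
    med_ages = np.median(model.ages_at(series.depth), axis=0)
    offsets = reconstruct_offsets(med_ages, series.value, np.asarray(cfg["offset_times"]))

    kappa_grid = np.linspace(0.0, cfg["kappa_max"], 101)
    curves, ranges = {}, {}
    for name, reg in regs.items():
        # anchor the modern annual deltaD on the region's median climatology
        modern = np.median(space.points[:, 0])
        from ghostpeat.hydroclimate import monthly_weights, weighted_annual_dD

        site_P = modern * monthly_weights(1.2)
        base_dD = weighted_annual_dD(site_P, reg)
        c1 = solution_curve(base_dD + offsets[0], reg, space.r_max, kappa_grid)
        c2 = solution_curve(base_dD + offsets[1], reg, space.r_max, kappa_grid)
        curves[name] = (c1, c2)
        ranges[name] = precip_change_range(c1, c2)
        pd.DataFrame(
            {"kappa": c1.kappa, "map_t1": c1.map_mm_yr, "si_t1": c1.si,
             "map_t2": c2.map_mm_yr, "si_t2": c2.si}
        ).to_csv(out / f"solution_{name}.csv", index=False)

    all_mins = [r[0] for r in ranges.values()]
    all_maxs = [r[1] for r in ranges.values()]
    report["hydroclimate"] = {
        "station_slopes": {n: r.slope for n, r in regs.items()},
        "station_r2": {n: r.r2 for n, r in regs.items()},
        "offsets_permil": offsets.tolist(),
        "offset_times": list(cfg["offset_times"]),
        "r_max": space.r_max,
        "delta_map_range_mm_yr": [float(min(all_mins)), float(max(all_maxs))],
    }
    state["climate_space"] = space
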