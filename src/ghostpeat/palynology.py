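"""Pollen and charcoal quantification.

Percentages against the terrestrial pollen sum (exotic markers, spores and
indeterminables excluded), exotic-marker (Lycopodium tablet) concentrations,
taxon-group curves, and Monte-Carlo confidence envelopes that combine
counting (multinomial) and age-model uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ghostpeat.chronology import AgeDepthModel

#: Lycopodium marker batch constants: 2 tablets of 11,267 +/- 370 spores
#: against 1 cm^3 of peat
SPORES_PER_TABLET = 11_267
DEFAULT_TABLETS = 2

#: default swamp-forest indicator taxa for central-African peatlands
DEFAULT_GROUPS: dict[str, str] = {
    "Pandanus": "swamp",
    "Pycnanthus": "swamp",
}

#: minimum terrestrial pollen sum below which percentages are flagged
MIN_POLLEN_SUM = 300


@dataclass
class PollenSample:
    """Counted pollen at one depth plus the exotic-marker bookkeeping."""

    depth: float
    counts: dict[str, int]
    marker_counted: int = 0
    marker_added: int = DEFAULT_TABLETS * SPORES_PER_TABLET
    volume: float = 1.0  # cm^3
    groups: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("pollen counts must be non-negative")
        if self.volume <= 0:
            raise ValueError("sample volume must be positive")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def percentages(sample: PollenSample) -> tuple[dict[str, float], dict[str, float]]:
    """Per-taxon and per-group percentages of the terrestrial pollen sum.

    Markers are never part of the sum; a sum below 300 grains (the usual
    counting minimum) triggers a warning, a zero sum is an error. Group
    percentages are sums of member-taxon percentages.
    """
    total = sample.total
    if total < 1:
        raise ValueError("zero pollen sum: percentages undefined")
    if total < MIN_POLLEN_SUM:
        warnings.warn(
            f"pollen sum {total} below the {MIN_POLLEN_SUM}-grain counting minimum",
            stacklevel=2,
        )
    taxon_pct = {t: 100.0 * c / total for t, c in sample.counts.items()}
    group_pct: dict[str, float] = {}
    for taxon, pct in taxon_pct.items():
        group = sample.groups.get(taxon, "other")
        group_pct[group] = group_pct.get(group, 0.0) + pct
    return taxon_pct, group_pct


def concentration(sample: PollenSample) -> float:
    """Pollen concentration (grains/cm^3) by the exotic-marker method.

    total_pollen * (marker_added / marker_counted) / volume.
    """
    if sample.marker_counted <= 0:
        raise ValueError("no marker grains counted: concentration undefined")
    return sample.total * (sample.marker_added / sample.marker_counted) / sample.volume


def charcoal_concentration(particle_count: float, volume: float) -> float:
    """Macro-charcoal concentration (particles/cm^3); particles >= 150 um."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    if particle_count < 0:
        raise ValueError("particle count must be non-negative")
    return particle_count / volume


def count_envelope(
    samples: list[PollenSample],
    model: AgeDepthModel,
    taxa: list[str] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    age_grid: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-taxon percentage curves on the age scale with 68/95% envelopes.

    Counting error is propagated by resampling each sample's counts
    multinomially at its observed proportions and total; age error by
    assigning depths to ages from a random posterior age-depth draw.
    Envelope width therefore shrinks like 1/sqrt(pollen sum).
    """
    if n_draws < 100:
        warnings.warn("n_draws < 100 gives unstable envelope quantiles", stacklevel=2)
    rng = np.random.default_rng(seed)
    samples = sorted(samples, key=lambda s: s.depth)
    depths = np.array([s.depth for s in samples])
    if depths.min() < model.depth_top or depths.max() > model.depth_bottom:
        raise ValueError("sample depths fall outside the age-depth model range")
    if taxa is None:
        taxa = sorted({t for s in samples for t in s.counts})
    counts = np.array([[s.counts.get(t, 0) for t in taxa] for s in samples], dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals < 1):
        raise ValueError("every sample needs a positive pollen sum")
    probs = counts / totals[:, None]

    ages_all = model.ages_at(depths)
    med_ages = np.median(ages_all, axis=0)
    if age_grid is None:
        age_grid = np.linspace(med_ages.min(), med_ages.max(), 200)

    sims = np.empty((n_draws, len(age_grid), len(taxa)))
    idx = rng.integers(0, model.n_draws, size=n_draws)
    for k in range(n_draws):
        ages = ages_all[idx[k]]
        pct = np.empty_like(probs)
        for i in range(len(samples)):
            draw = rng.multinomial(int(totals[i]), probs[i])
            pct[i] = 100.0 * draw / totals[i]
        for j in range(len(taxa)):
            sims[k, :, j] = np.interp(age_grid, ages, pct[:, j])

    out: dict[str, pd.DataFrame] = {}
    for j, taxon in enumerate(taxa):
        qs = np.percentile(sims[:, :, j], [2.5, 16, 50, 84, 97.5], axis=0)
        out[taxon] = pd.DataFrame(
            {
                "age": age_grid,
                "lo95": qs[0],
                "lo68": qs[1],
                "median": qs[2],
                "hi68": qs[3],
                "hi95": qs[4],
            }
        )
    return out
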