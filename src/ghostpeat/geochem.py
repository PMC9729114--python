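"""Rock-Eval S2 thermogram indices and bulk organic geochemistry.

The S2 thermogram (hydrocarbons released during pyrolysis as a function of
oven temperature) is split into five thermal pools: highly labile
(200-340 degC, A1), labile (340-400, A2), resistant (400-460, A3),
refractory (460-520, A4) and highly refractory (520-650, A5). Two indices
summarise organic-matter quality: I = log10((A1+A2)/A3), the balance of
thermally labile vs resistant pools (fresh organic matter typically 0.2-0.5,
negative values indicating intense decomposition), and R = (A3+A4+A5)/100
with areas as percent of the S2 total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: thermal-pool bounds in degC, half-open [lo, hi)
S2_BANDS: tuple[tuple[float, float], ...] = (
    (200.0, 340.0),
    (340.0, 400.0),
    (400.0, 460.0),
    (460.0, 520.0),
    (520.0, 650.0),
)

#: multiplicative correction from mature-kerogen-standardised Rock-Eval
#: carbon to TOC of immature organic samples
TOC_CORRECTION: float = 1.166256


@dataclass(frozen=True)
class Thermogram:
    """An S2 pyrolysis signal on an ascending temperature grid (degC)."""

    temperature: np.ndarray
    signal: np.ndarray
    sample_id: str = ""
    depth: float = np.nan

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("temperature and signal must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if t[0] > S2_BANDS[0][0] or t[-1] < S2_BANDS[-1][1]:
            raise ValueError("thermogram must cover at least [200, 650] degC")
        if np.any(s < 0):
            raise ValueError("signal must be non-negative")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class RockEvalResult:
    """Thermal-pool areas (percent of S2 total) and derived indices."""

    areas: np.ndarray  # A1..A5, %
    i_index: float
    r_index: float
    toc_re: float = np.nan
    sample_id: str = ""
    depth: float = np.nan

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        if a.shape != (5,):
            raise ValueError("areas must hold the five pools A1..A5")
        if abs(a.sum() - 100.0) > 1e-6:
            raise ValueError("areas must sum to 100%")
        object.__setattr__(self, "areas", a)


def integrate_s2(tg: Thermogram) -> np.ndarray:
    """Integrate the S2 signal over the five thermal pools.

    Trapezoid rule with linear interpolation at band boundaries; bands are
    half-open [lo, hi) so a boundary belongs to the upper band (boundary
    ordinates carry zero width, making the convention observable only in the
    sense that the five areas exactly tile the [200, 650] total). Returns
    areas as percent of that total.
    """
    t, s = tg.temperature, tg.signal
    areas = np.empty(5)
    for k, (lo, hi) in enumerate(S2_BANDS):
        grid = t[(t > lo) & (t < hi)]
        grid = np.concatenate(([lo], grid, [hi]))
        vals = np.interp(grid, t, s)
        areas[k] = np.trapezoid(vals, grid)
    total = areas.sum()
    if total <= 0:
        raise ValueError("total S2 area over [200, 650] degC is zero")
    return 100.0 * areas / total


def indices(areas: np.ndarray, normalized: bool = True) -> tuple[float, float]:
    """I-index and R-index from the five pool areas.

    ``I = log10((A1 + A2) / A3)`` and ``R = (A3 + A4 + A5) / 100`` with areas
    in percent of the S2 total. Raw (un-normalised) areas are accepted with
    ``normalized=False`` and rescaled first — I is a pure ratio either way,
    R requires the percent convention.
    """
    a = np.asarray(areas, dtype=float)
    if a.shape != (5,):
        raise ValueError("expected the five pool areas A1..A5")
    if not normalized:
        a = 100.0 * a / a.sum()
    if a[2] <= 0:
        raise ValueError("A3 = 0: I-index log ratio undefined")
    i_index = float(np.log10((a[0] + a[1]) / a[2]))
    r_index = float((a[2] + a[3] + a[4]) / 100.0)
    return i_index, r_index


def rock_eval(tg: Thermogram) -> RockEvalResult:
    """Full S2 workup of one thermogram: pool areas plus I and R indices."""
    areas = integrate_s2(tg)
    i_idx, r_idx = indices(areas)
    return RockEvalResult(
        areas=areas, i_index=i_idx, r_index=r_idx, sample_id=tg.sample_id, depth=tg.depth
    )


def toc_from_rockeval(
    pyrolysed_c: float, residual_c: float, factor: float = TOC_CORRECTION
) -> float:
    """Rock-Eval TOC (wt%) from pyrolysed plus residual organic carbon.

    The instrument's organic carbon is standardised for mature kerogens;
    the default factor 1.166256 corrects to immature organic matter so the
    result is comparable with elemental-analyser TOC. Values above 100 wt%
    indicate oxidation-phase signal saturation and trigger a warning.
    """
    if pyrolysed_c < 0 or residual_c < 0:
        raise ValueError("carbon fractions must be non-negative")
    toc = (pyrolysed_c + residual_c) * factor
    if toc > 100.0:
        warnings.warn(
            f"TOC_RE = {toc:.1f} wt% exceeds 100%: probable signal saturation "
            "(highly organic samples may saturate the oxidation phase)",
            stacklevel=2,
        )
    return toc


def cn_ratio(toc: float, n: float) -> float:
    """Mass C/N ratio from TOC and total nitrogen (both wt%)."""
    if n <= 0:
        raise ValueError("total nitrogen must be positive for a C/N ratio")
    return toc / n


def _robust_sd(x: np.ndarray) -> float:
    med = np.nanmedian(x)
    return 1.4826 * float(np.nanmedian(np.abs(x - med)))


def classify_decomposed(
    profile: pd.DataFrame,
    toc_threshold: float | None = None,
    cn_threshold: float | None = None,
) -> tuple[pd.Series, list[tuple[float, float]]]:
    """Flag decomposed peat from co-registered I-index, TOC and C/N profiles.

    A depth is flagged where the I-index is negative AND TOC and C/N both
    exceed their thresholds (default: profile median plus one robust sd),
    the operational signature of intensely decomposed peat. Contiguous
    flagged runs are merged into depth intervals [top, bottom).

    ``profile`` needs columns ``depth``, ``i_index``, ``toc``, ``cn``.
    """
    for col in ("depth", "i_index", "toc", "cn"):
        if col not in profile.columns:
            raise ValueError(f"profile is missing column {col!r}")
        if profile[col].isna().all():
            raise ValueError(f"column {col!r} holds no data")
    df = profile.sort_values("depth").reset_index(drop=True)
    if toc_threshold is None:
        toc_threshold = float(df["toc"].median() + _robust_sd(df["toc"].to_numpy()))
    if cn_threshold is None:
        cn_threshold = float(df["cn"].median() + _robust_sd(df["cn"].to_numpy()))
    flag = (df["i_index"] < 0) & (df["toc"] > toc_threshold) & (df["cn"] > cn_threshold)
    intervals: list[tuple[float, float]] = []
    depths = df["depth"].to_numpy()
    in_run = False
    start = 0.0
    for i, f in enumerate(flag.to_numpy()):
        if f and not in_run:
            in_run, start = True, depths[i]
        elif not f and in_run:
            in_run = False
            intervals.append((float(start), float(depths[i])))
    if in_run:
        intervals.append((float(start), float(depths[-1])))
    flag.index = df.index
    return flag, intervals


def d13c_anomaly(
    profile: pd.DataFrame, interval: tuple[float, float]
) -> float:
    """Descriptive delta13C_TOC shift: baseline median minus interval median.

    ``profile`` needs columns ``depth`` and ``d13c``; the interval is
    [top, bottom) in cm. Reported descriptively, not used for classification.
    """
    top, bottom = interval
    inside = (profile["depth"] >= top) & (profile["depth"] < bottom)
    if inside.sum() == 0 or (~inside).sum() == 0:
        raise ValueError("interval must split the profile into non-empty parts")
    return float(profile.loc[~inside, "d13c"].median() - profile.loc[inside, "d13c"].median())
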