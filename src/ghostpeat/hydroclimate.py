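"""Leaf-wax deltaD -> precipitation-regime inversion and climate spaces.

The inversion is a three-step empirical chain: (1) wax deltaD translates to
precipitation deltaD via a soil calibration with slope ~1, so only an
additive offset is involved and relative changes are offset-invariant;
(2) station-scale amount-effect regressions (monthly deltaD_precip vs
precipitation amount, negative slopes in convective tropics) convert a
monthly precipitation distribution into a precipitation-weighted annual
deltaD_precip; (3) a reconstructed annual deltaD target then defines a
one-parameter locus of (mean annual precipitation, seasonality index)
solutions.

Seasonality index: SI = D * MAP / r_max where D is the relative entropy (in
bits) of the monthly precipitation distribution against uniform and r_max
the maximum MAP in the gridded data; SI = 0 iff rainfall is uniform, and
D <= log2(12) ~ 3.585.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.fft import dct

_LOG2_12 = np.log2(12.0)


# ---------------------------------------------------------------------------
# Step 1-2: calibration, amount effect, annual deltaD, seasonality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeRegression:
    """Station amount-effect fit: deltaD_precip = a + b * P (P in mm/month)."""

    station: str
    slope: float  # b, permil per (mm/month)
    intercept: float  # a, permil
    r2: float
    n: int
    pvalue: float = np.nan


def wax_to_precip(dD_wax: float | np.ndarray, offset: float = 0.0) -> float | np.ndarray:
    """Translate wax deltaD to precipitation deltaD via a slope-1 calibration.

    With slope fixed at 1 the transfer is a pure additive offset (apparent
    fractionation), so differences between samples do not depend on it.
    """
    return np.asarray(dD_wax, dtype=float) + offset if np.ndim(dD_wax) else dD_wax + offset


def fit_amount_effect(
    P: np.ndarray, dD: np.ndarray, station: str = ""
) -> IsotopeRegression:
    """OLS fit of monthly deltaD_precip on precipitation amount.

    Expects >= 12 months; a non-negative slope is legal but triggers a
    warning since the tropical amount effect is negative.
    """
    P = np.asarray(P, dtype=float)
    dD = np.asarray(dD, dtype=float)
    if P.shape != dD.shape or P.ndim != 1:
        raise ValueError("P and dD must be equal-length 1-d arrays")
    if len(P) < 12:
        raise ValueError("need at least 12 monthly observations")
    if np.ptp(P) == 0:
        raise ValueError("precipitation amounts have zero variance")
    res = stats.linregress(P, dD)
    if res.slope >= 0:
        warnings.warn(
            f"amount-effect slope {res.slope:.3g} is non-negative for station "
            f"{station or '<unnamed>'}",
            stacklevel=2,
        )
    return IsotopeRegression(
        station=station,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(P),
        pvalue=float(res.pvalue),
    )


def weighted_annual_dD(P_monthly: np.ndarray, reg: IsotopeRegression) -> float:
    """Precipitation-weighted annual deltaD_precip from a monthly climatology.

    sum P_m (a + b P_m) / sum P_m = a + b * (sum P_m^2 / sum P_m).
    """
    P = np.asarray(P_monthly, dtype=float)
    if np.any(P < 0):
        raise ValueError("monthly precipitation must be non-negative")
    total = P.sum()
    if total <= 0:
        raise ValueError("mean annual precipitation is zero")
    return float(reg.intercept + reg.slope * np.sum(P**2) / total)


def relative_entropy(P_monthly: np.ndarray) -> float:
    """Relative entropy D (bits) of monthly precipitation against uniform."""
    P = np.asarray(P_monthly, dtype=float)
    total = P.sum()
    if total <= 0:
        raise ValueError("mean annual precipitation is zero")
    p = P / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(12.0 * p[nz])))


def seasonality_index(P_monthly: np.ndarray, r_max: float) -> float:
    """SI = D * MAP / r_max: relative entropy scaled by normalised MAP."""
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    P = np.asarray(P_monthly, dtype=float)
    MAP = P.sum()
    if MAP > r_max * (1 + 1e-9):
        warnings.warn(f"MAP {MAP:.0f} exceeds r_max {r_max:.0f}", stacklevel=2)
    return relative_entropy(P) * MAP / r_max


# ---------------------------------------------------------------------------
# Climate spaces: bivariate KDE with diffusion bandwidth
# ---------------------------------------------------------------------------


def botev_bandwidth(x: np.ndarray, n_grid: int = 1024) -> float:
    """1-d kernel bandwidth by the diffusion fixed-point of Botev et al. (2010).

    Solves t = xi * gamma^[5](t) on a DCT representation of the binned data;
    falls back to Silverman's rule when the fixed point cannot be bracketed
    (small n or near-degenerate samples).
    """
    x = np.asarray(x, dtype=float)
    n = len(np.unique(x))
    lo, hi = x.min(), x.max()
    span = hi - lo
    if span == 0:
        raise ValueError("degenerate sample: zero range")
    lo -= span / 10
    hi += span / 10
    R = hi - lo
    hist, _ = np.histogram(x, bins=n_grid, range=(lo, hi))
    a = dct(hist / hist.sum(), norm=None)
    I = np.arange(1, n_grid, dtype=float) ** 2
    a2 = (a[1:] / 2.0) ** 2

    def fixed_point(t: float) -> float:
        ell = 7
        f = 2.0 * np.pi ** (2 * ell) * np.sum(I**ell * a2 * np.exp(-I * np.pi**2 * t))
        for s in range(ell - 1, 1, -1):
            k0 = np.prod(np.arange(1, 2 * s, 2)) / np.sqrt(2.0 * np.pi)
            const = (1.0 + 0.5 ** (s + 0.5)) / 3.0
            time = (2.0 * const * k0 / (n * f)) ** (2.0 / (3.0 + 2.0 * s))
            f = 2.0 * np.pi ** (2 * s) * np.sum(I**s * a2 * np.exp(-I * np.pi**2 * time))
        return t - (2.0 * n * np.sqrt(np.pi) * f) ** (-2.0 / 5.0)

    try:
        t_star = optimize.brentq(fixed_point, 1e-12, 0.1)
        bw = np.sqrt(t_star) * R
    except (ValueError, RuntimeError):
        bw = 1.06 * x.std(ddof=1) * n ** (-1.0 / 5.0)
    if not np.isfinite(bw) or bw <= 0:
        bw = 1.06 * x.std(ddof=1) * n ** (-1.0 / 5.0)
    return float(bw)


@dataclass
class ClimateSpace:
    """Bivariate KDE of (MAP, seasonality index) over a gridded region."""

    points: np.ndarray  # (n, 2): MAP mm/yr, SI
    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray  # (ny, nx), integrates to ~1
    level68: float
    level95: float
    r_max: float
    bandwidth: tuple[float, float] = (np.nan, np.nan)

    def density_at(self, pts: np.ndarray) -> np.ndarray:
        """Nearest-cell density lookup for points (n, 2)."""
        pts = np.atleast_2d(pts)
        ix = np.clip(np.searchsorted(self.grid_x, pts[:, 0]) - 1, 0, len(self.grid_x) - 2)
        iy = np.clip(np.searchsorted(self.grid_y, pts[:, 1]) - 1, 0, len(self.grid_y) - 2)
        return self.density[iy, ix]

    def mass_within(self, level: float) -> float:
        dx = self.grid_x[1] - self.grid_x[0]
        dy = self.grid_y[1] - self.grid_y[0]
        return float(self.density[self.density >= level].sum() * dx * dy)


def _hdr_level(density: np.ndarray, cell_area: float, mass: float) -> float:
    """Density threshold whose highest-density region holds ``mass``."""
    d = np.sort(density.ravel())[::-1]
    cum = np.cumsum(d) * cell_area
    idx = np.searchsorted(cum, mass)
    idx = min(idx, len(d) - 1)
    return float(d[idx])


def build_climate_space(
    climatologies: np.ndarray,
    r_max: float | None = None,
    n_grid: int = 256,
    contour_masses: tuple[float, float] = (0.68, 0.95),
) -> ClimateSpace:
    """Climate space of a region: (MAP, SI) per cell with a bivariate KDE.

    ``climatologies`` is (n_cells, 12) monthly precipitation in mm/month.
    Each cell contributes one (MAP, SI) point; the joint density is a
    product-Gaussian KDE with per-axis bandwidths from the diffusion
    optimiser, evaluated by binned Gaussian smoothing on a regular grid.
    Contour levels are highest-density-region thresholds enclosing 68% and
    95% of the probability mass.
    """
    C = np.asarray(climatologies, dtype=float)
    if C.ndim != 2 or C.shape[1] != 12:
        raise ValueError("climatologies must be (n_cells, 12)")
    if C.shape[0] < 100:
        raise ValueError("need at least 100 grid cells for a climate space")
    MAP = C.sum(axis=1)
    if r_max is None:
        r_max = float(MAP.max())
    SI = np.array([seasonality_index(c, r_max) for c in C])
    pts = np.column_stack([MAP, SI])
    if np.ptp(MAP) == 0 and np.ptp(SI) == 0:
        raise ValueError("degenerate climate space: all cells identical")
    return _kde_space(pts, r_max, n_grid, contour_masses)


def _kde_space(
    pts: np.ndarray,
    r_max: float,
    n_grid: int = 256,
    contour_masses: tuple[float, float] = (0.68, 0.95),
) -> ClimateSpace:
    x, y = pts[:, 0], pts[:, 1]
    bx = botev_bandwidth(x)
    by = botev_bandwidth(y)
    pad = 4.0
    gx = np.linspace(x.min() - pad * bx, x.max() + pad * bx, n_grid)
    gy = np.linspace(y.min() - pad * by, y.max() + pad * by, n_grid)
    dx, dy = gx[1] - gx[0], gy[1] - gy[0]
    hist, _, _ = np.histogram2d(y, x, bins=[len(gy), len(gx)], range=[(gy[0], gy[-1]), (gx[0], gx[-1])])
    dens = ndimage.gaussian_filter(hist, sigma=(by / dy, bx / dx), mode="constant")
    dens /= dens.sum() * dx * dy
    cell = dx * dy
    lo_mass, hi_mass = sorted(contour_masses)
    level68 = _hdr_level(dens, cell, lo_mass)
    level95 = _hdr_level(dens, cell, hi_mass)
    return ClimateSpace(
        points=pts,
        grid_x=gx,
        grid_y=gy,
        density=dens,
        level68=level68,
        level95=level95,
        r_max=r_max,
        bandwidth=(bx, by),
    )


# ---------------------------------------------------------------------------
# Step 3: solution curves and precipitation change
# ---------------------------------------------------------------------------


@dataclass
class SolutionCurve:
    """Locus of (MAP, SI) pairs whose annual deltaD equals a target.

    Parameterised by the concentration kappa of a circular-exponential
    monthly weight profile w_m proportional to exp(kappa cos(2 pi (m - m0)/12));
    kappa = 0 is uniform rainfall (SI = 0) and large kappa concentrates rain
    into one peak month.
    """

    kappa: np.ndarray
    map_mm_yr: np.ndarray
    si: np.ndarray
    target_dD: float
    station: str = ""


def monthly_weights(kappa: float, peak_month: int = 1) -> np.ndarray:
    """Normalised circular-exponential monthly weights (12,)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    m = np.arange(1, 13)
    w = np.exp(kappa * np.cos(2.0 * np.pi * (m - peak_month) / 12.0))
    return w / w.sum()


def solution_curve(
    target_dD: float,
    reg: IsotopeRegression,
    r_max: float,
    kappa_grid: np.ndarray | None = None,
    peak_month: int = 1,
) -> SolutionCurve:
    """All (MAP, SI) precipitation regimes consistent with an annual deltaD.

    For monthly amounts P_m = MAP * w_m(kappa), the weighted annual deltaD is
    a + b * MAP * sum(w_m^2), so MAP(kappa) = (target - a) / (b * sum w_m^2);
    SI follows from the seasonality index of MAP * w. kappa values admitting
    no positive MAP are dropped with a warning.
    """
    if reg.slope >= 0:
        raise ValueError("solution curves require a negative amount-effect slope")
    if kappa_grid is None:
        kappa_grid = np.linspace(0.0, 5.0, 101)
    kappas, maps, sis = [], [], []
    for k in np.asarray(kappa_grid, dtype=float):
        w = monthly_weights(k, peak_month)
        sw2 = float(np.sum(w**2))
        MAP = (target_dD - reg.intercept) / (reg.slope * sw2)
        if MAP <= 0:
            continue
        kappas.append(k)
        maps.append(MAP)
        with warnings.catch_warnings():
            # solution MAPs may legitimately exceed the observed r_max
            warnings.simplefilter("ignore")
            sis.append(seasonality_index(MAP * w, r_max))
    if len(kappas) < len(np.atleast_1d(kappa_grid)):
        warnings.warn(
            f"{len(np.atleast_1d(kappa_grid)) - len(kappas)} kappa values admit "
            "no positive-MAP solution and were dropped",
            stacklevel=2,
        )
    return SolutionCurve(
        kappa=np.array(kappas),
        map_mm_yr=np.array(maps),
        si=np.array(sis),
        target_dD=target_dD,
        station=reg.station,
    )


def reconstruct_offsets(
    ages: np.ndarray,
    dD: np.ndarray,
    times: np.ndarray,
    reference_age: float | None = None,
) -> np.ndarray:
    """deltaD offsets at requested times relative to a modern reference.

    The record (age in cal yr BP, deltaD) is linearly interpolated at each
    time and the reference value (default: the record's youngest sample)
    subtracted. Times outside the record raise rather than extrapolate.
    """
    ages = np.asarray(ages, dtype=float)
    dD = np.asarray(dD, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    order = np.argsort(ages)
    ages, dD = ages[order], dD[order]
    if np.any(times < ages[0]) or np.any(times > ages[-1]):
        raise ValueError(
            f"requested times extend beyond the record [{ages[0]:.0f}, {ages[-1]:.0f}] cal yr BP"
        )
    if reference_age is None:
        ref = dD[0]  # youngest sample = core top
    else:
        if not ages[0] <= reference_age <= ages[-1]:
            raise ValueError("reference age outside the record")
        ref = np.interp(reference_age, ages, dD)
    return np.interp(times, ages, dD) - ref


def precip_change_range(
    curve_t1: SolutionCurve, curve_t2: SolutionCurve
) -> tuple[float, float]:
    """Min and max MAP difference (t1 minus t2) over the shared kappa grid.

    With the wetter (more negative deltaD) period as t1 and the drier as t2,
    every kappa gives a positive MAP drop; the spread over kappa (and over
    station regressions, when called per station) brackets the
    precipitation-change range.
    """
    if len(curve_t1.kappa) != len(curve_t2.kappa) or not np.allclose(
        curve_t1.kappa, curve_t2.kappa
    ):
        raise ValueError("solution curves must share the same kappa grid")
    d = curve_t1.map_mm_yr - curve_t2.map_mm_yr
    return float(d.min()), float(d.max())
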