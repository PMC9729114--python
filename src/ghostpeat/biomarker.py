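"""n-Alkane plant-wax metrics: chain-length statistics and replicate isotopes.

Long-chain n-alkanes (C25-C35) from epicuticular waxes of higher plants show
a strong odd-over-even chain-length preference, quantified by the Carbon
Preference Index (CPI); compound-specific deltaD and delta13C are measured
in replicate, so per-sample means carry a replicate-based 1-sigma (or the
instrument precision when only one replicate exists).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: default 1-sigma instrument precision when a sample has a single replicate
INSTRUMENT_PRECISION = {"dD": 3.0, "d13C": 0.3}

_ODD_FIRST = (25, 27, 29, 31, 33)
_ODD_SECOND = (27, 29, 31, 33, 35)
_EVEN = (26, 28, 30, 32, 34)


def _get(abundances: Mapping[int, float], chain: int) -> float:
    if chain not in abundances:
        warnings.warn(f"chain C{chain} missing; treated as zero abundance", stacklevel=3)
        return 0.0
    a = float(abundances[chain])
    if a < 0:
        raise ValueError(f"negative abundance for C{chain}")
    return a


def cpi(abundances: Mapping[int, float]) -> float:
    """Carbon Preference Index of long-chain n-alkanes.

    CPI = [(C25+C27+C29+C31+C33) + (C27+C29+C31+C33+C35)]
          / [2 (C26+C28+C30+C32+C34)].

    Values well above 1 (typically 5-10 in peat) indicate fresh higher-plant
    waxes; the index is invariant under uniform scaling of all abundances.
    """
    odd = sum(_get(abundances, c) for c in _ODD_FIRST) + sum(
        _get(abundances, c) for c in _ODD_SECOND
    )
    even = 2.0 * sum(_get(abundances, c) for c in _EVEN)
    if even <= 0:
        raise ValueError("even-chain abundance sum is zero: CPI undefined")
    return odd / even


def dominant_homologue(abundances: Mapping[int, float]) -> int:
    """Most abundant chain length; ties break toward the longer chain."""
    if not abundances:
        raise ValueError("empty abundance mapping")
    items = [(int(c), float(a)) for c, a in abundances.items()]
    if all(a <= 0 for _, a in items):
        raise ValueError("all abundances zero: no dominant homologue")
    best = max(items, key=lambda ca: (ca[1], ca[0]))
    return best[0]


def replicate_stats(
    values: Sequence[float], instrument_precision: float | None = None, kind: str = "dD"
) -> tuple[float, float]:
    """Mean and 1-sigma of replicate isotope measurements.

    Sample sd (ddof=1) when n >= 2; with a single replicate the sd falls back
    to the configured instrument precision (deltaD 3 permil, delta13C
    0.3 permil by default).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise ValueError("need at least one replicate")
    if instrument_precision is None:
        instrument_precision = INSTRUMENT_PRECISION[kind]
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else float(instrument_precision)
    return mean, sd


def summarize_wax(
    wax: pd.DataFrame, isotope_chains: Sequence[int] = (27, 29, 31)
) -> pd.DataFrame:
    """Per-depth wax summary from a long-format table.

    ``wax`` columns: depth, chain, abundance, dD, d13C, replicate. Returns
    one row per depth with CPI, the dominant homologue, and replicate
    mean +/- sd of deltaD and delta13C for each requested chain.
    """
    rows = []
    for depth, g in wax.groupby("depth"):
        ab = g.groupby("chain")["abundance"].mean().to_dict()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # missing chains are expected here
            row = {"depth": depth, "cpi": cpi(ab), "dominant_chain": dominant_homologue(ab)}
        for chain in isotope_chains:
            gc = g[g["chain"] == chain]
            for col, kind in (("dD", "dD"), ("d13C", "d13C")):
                vals = gc[col].dropna().to_numpy()
                if vals.size:
                    m, s = replicate_stats(vals, kind=kind)
                else:
                    m, s = np.nan, np.nan
                row[f"{col}_C{chain}"] = m
                row[f"{col}_C{chain}_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows).sort_values("depth").reset_index(drop=True)
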