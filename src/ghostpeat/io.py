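"""Readers and writers for the pipeline's plain-text formats.

Calibration curves use the standard 3-column ".14c" dialect
(cal BP, 14C BP, error), comma- or whitespace-separated, with '#' comment
headers. Everything else is CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ghostpeat.chronology import AgeDepthModel, CalibrationCurve, RadiocarbonDate


def read_calibration_curve(path: str | Path, name: str | None = None) -> CalibrationCurve:
    """Read a 3+-column calibration-curve table (cal BP, 14C BP, error).

    Tolerates '#' header lines and either comma or whitespace separation;
    extra columns beyond the first three are ignored. Rows are sorted into
    ascending calendar age.
    """
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise ValueError(f"{path}: expected >= 3 columns, got {line!r}")
        rows.append([float(p) for p in parts[:3]])
    arr = np.asarray(rows)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    # collapse duplicate calendar ages (some published tables repeat endpoints)
    _, keep = np.unique(arr[:, 0], return_index=True)
    arr = arr[keep]
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2], name=name or path.stem)


def write_calibration_curve(curve: CalibrationCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# cal BP, 14C BP, error (1 sigma)\n")
        for c, m, s in zip(curve.cal_age, curve.c14_age, curve.sigma):
            fh.write(f"{c:.1f},{m:.2f},{s:.2f}\n")


def read_dates(path: str | Path) -> list[RadiocarbonDate]:
    """Read radiocarbon dates from CSV (id, depth_cm, c14_age, error, fraction)."""
    df = pd.read_csv(path)
    required = {"depth_cm", "c14_age", "error"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dates file is missing columns: {sorted(missing)}")
    return [
        RadiocarbonDate(
            depth=row["depth_cm"],
            c14_age=row["c14_age"],
            error=row["error"],
            fraction=str(row.get("fraction", "fine")),
            label=str(row.get("id", "")),
        )
        for _, row in df.iterrows()
    ]


def write_model(model: AgeDepthModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def read_model(path: str | Path) -> AgeDepthModel:
    return AgeDepthModel.from_dict(json.loads(Path(path).read_text()))


def read_climatology_grid(path: str | Path) -> np.ndarray:
    """Read a climatology-cell CSV (columns P01..P12, mm/month) -> (n, 12)."""
    df = pd.read_csv(path)
    cols = [f"P{m:02d}" for m in range(1, 13)]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"climatology grid is missing columns: {sorted(missing)}")
    return df[cols].to_numpy(dtype=float)
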