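"""Readers and writers: puncta CSV dialect, TIFF images, configs.

Puncta CSV dialect: header
``channel,id,x_um,y_um,area_um2,feret_um,total_intensity,mean_intensity``,
one row per punctum, UTF-8, "." decimal.  One file may carry all channels.
Coordinate tables from other tools may record positions in pixels; the
reader sniffs the unit (values bounded by the ROI extent in µm vs in
pixels) and records the decision in provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Punctum, PunctaSet, RoiSpec

PUNCTA_COLUMNS = [
    "channel",
    "id",
    "x_um",
    "y_um",
    "area_um2",
    "feret_um",
    "total_intensity",
    "mean_intensity",
]


def puncta_to_frame(sets: Union[PunctaSet, List[PunctaSet]]) -> pd.DataFrame:
    if isinstance(sets, PunctaSet):
        sets = [sets]
    rows = []
    for s in sets:
        for p in s:
            rows.append(
                {
                    "channel": p.channel,
                    "id": p.id,
                    "x_um": p.centroid_xy[0],
                    "y_um": p.centroid_xy[1],
                    "area_um2": p.area,
                    "feret_um": p.feret_diameter,
                    "total_intensity": p.total_intensity,
                    "mean_intensity": p.mean_intensity,
                }
            )
    return pd.DataFrame(rows, columns=PUNCTA_COLUMNS)


def write_puncta_csv(sets: Union[PunctaSet, List[PunctaSet]], path: Union[str, Path]) -> None:
    puncta_to_frame(sets).to_csv(path, index=False)


def _sniff_units(df: pd.DataFrame, roi: RoiSpec) -> str:
    """Decide whether coordinates are µm or pixels from their range."""
    xmax = df["x_um"].max() if len(df) else 0.0
    ymax = df["y_um"].max() if len(df) else 0.0
    if xmax <= roi.width_um + 1e-6 and ymax <= roi.height_um + 1e-6:
        return "um"
    n_rows, n_cols = roi.shape
    if xmax <= n_cols and ymax <= n_rows:
        return "pixel"
    raise ValueError(
        f"coordinates (max x={xmax:g}, y={ymax:g}) exceed the ROI in both µm "
        f"({roi.width_um} x {roi.height_um}) and pixel ({n_cols} x {n_rows}) units"
    )


def read_puncta_csv(
    path: Union[str, Path], roi: RoiSpec, channels: Optional[List[str]] = None
) -> Dict[str, PunctaSet]:
    """Read the puncta CSV dialect into per-channel sets.

    Unit sniffing converts pixel-recorded tables to µm; the choice is
    recorded in each set's provenance.
    """
    df = pd.read_csv(path)
    missing = set(PUNCTA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"puncta CSV missing columns: {sorted(missing)}")
    unit = _sniff_units(df, roi)
    if unit == "pixel":
        s = roi.pixel_scale
        df = df.assign(
            x_um=df.x_um / s,
            y_um=df.y_um / s,
            area_um2=df.area_um2 / s**2,
            feret_um=df.feret_um / s,
        )
    out: Dict[str, PunctaSet] = {}
    for name, grp in df.groupby("channel", sort=False):
        if channels is not None and name not in channels:
            continue
        puncta = [
            Punctum(
                id=int(r.id),
                channel=str(name),
                centroid_xy=(float(r.x_um), float(r.y_um)),
                area=float(r.area_um2),
                feret_diameter=float(r.feret_um),
                total_intensity=float(r.total_intensity),
                mean_intensity=float(r.mean_intensity),
            )
            for r in grp.itertuples()
        ]
        out[str(name)] = PunctaSet(
            str(name), roi, puncta, provenance=f"external table (units sniffed: {unit})"
        )
    return out


def write_truth_csv(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, index=False)


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Single-channel 8/16-bit TIFF as a 2D intensity array.

    Multi-page stacks are rejected; run them through :func:`max_project`
    first.  RGB TIFFs are rejected.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(f"{path}: RGB TIFF; expected single-channel intensity data")
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: {arr.ndim}-dimensional stack; max-project it first "
            "(puncta.io.max_project)"
        )
    return arr


def write_image(image: np.ndarray, path: Union[str, Path]) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the planes of a z-stack."""
    arr = np.asarray(stack)
    if arr.ndim < 3:
        if arr.ndim == 2:
            return arr
        raise ValueError("stack must have at least one plane")
    return arr.max(axis=0)


def read_config(path: Union[str, Path]) -> dict:
    """Flat key-value run configuration (YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg


def write_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
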