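"""Reading and writing the pipeline's text and image formats.

CDE tables and layouts travel as tab-separated text; plate images as
16-bit grayscale PNG/TIFF (any raster imageio can read is accepted on
input, RGB is collapsed downstream); thresholds as YAML.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from lightscreen.imaging import ArrayLayout, PlateImage
from lightscreen.scoring import ScreenThresholds

CDE_COLUMNS = [
    "plate", "row", "col", "strain", "control_flag", "dubious_flag",
    "condition", "day", "cde",
]
LAYOUT_COLUMNS = ["plate", "row", "col", "strain", "control_flag", "dubious_flag"]


def write_cde_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CDE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


def read_cde_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"plate", "row", "col", "strain", "condition", "day", "cde"} - set(table.columns)
    if missing:
        raise ValueError(f"CDE table {path} lacks columns {sorted(missing)}")
    for flag in ("control_flag", "dubious_flag"):
        if flag not in table.columns:
            table[flag] = False
        table[flag] = table[flag].astype(bool)
    return table


def write_layout(layout: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in LAYOUT_COLUMNS if c in layout.columns]
    layout[cols].to_csv(path, sep="\t", index=False)


def read_layout(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path, sep="\t")
    for flag in ("control_flag", "dubious_flag"):
        if flag not in layout.columns:
            layout[flag] = False
        layout[flag] = layout[flag].astype(bool)
    return layout


def layout_for_plate(layout: pd.DataFrame, plate: str, **kwargs) -> ArrayLayout:
    """ArrayLayout restricted to one plate of a multi-plate layout table."""
    sel = layout[layout["plate"] == plate]
    if sel.empty:
        raise ValueError(f"plate {plate!r} absent from layout")
    return ArrayLayout(strain_map=sel.reset_index(drop=True), **kwargs)


def write_plate_image(image: PlateImage, path: str | Path) -> None:
    """Write as 16-bit grayscale; intensities are clipped to the uint16 range."""
    px = np.clip(np.round(image.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    iio.imwrite(path, px)


def read_plate_image(
    path: str | Path, plate_id: str | None = None, condition: str = "light", day: int = 0
) -> PlateImage:
    px = np.asarray(iio.imread(path))
    return PlateImage(
        pixels=px.astype(float),
        plate_id=plate_id or Path(path).stem,
        condition=condition,
        day=day,
    )


def read_thresholds(path: str | Path) -> ScreenThresholds:
    """Thresholds from YAML; a bare ``variant: <name>`` selects a named set,
    and any other keys override individual cutoffs."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    variant = cfg.pop("variant", "primary")
    base = ScreenThresholds.variant(variant)
    if cfg:
        from dataclasses import replace

        base = replace(base, **cfg)
    return base


def write_thresholds(thresholds: ScreenThresholds, path: str | Path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(thresholds), fh, sort_keys=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Two-column gene/term table (SGD go_slim_mapping-style), tab-separated."""
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(table.columns):
        raise ValueError(f"annotation {path} needs 'gene' and 'term' columns")
    return table
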