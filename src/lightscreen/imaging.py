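"""Per-colony cell-density estimation (CDE) from plate photographs.

A plate photograph of a pinned 16x24 colony array is cut into horizontal
bands of 30 pixels, one band per colony row.  Each band is reduced to a
one-dimensional intensity profile by summing the 25 brightest pixels of
every column; the profile is then split into 60-pixel colony windows
(60 px is the colony center-to-center spacing).  Within a window the
colony intensity is the median of the 10 largest values among the central
20 positions, and the background is the mean of the two flank minima
(1-based positions 5-20 and 40-55).  The CDE of the colony is colony
intensity minus background; it is not clipped at zero, so an empty
position with a bright flank may legitimately score negative.

All pixel ranges quoted in docstrings are 1-based inclusive; the code
uses 0-based half-open slices internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Geometry of the standard 384-array photograph.
BAND_HEIGHT_PX = 30
SPACING_PX = 60
TOP_K = 25

# 1-based inclusive ranges of the colony window (length 60)
_CENTRAL = (21, 40)  # colony core
_LEFT_FLANK = (5, 20)
_RIGHT_FLANK = (40, 55)


@dataclass
class PlateImage:
    """One photographed plate with its acquisition metadata.

    RGB input is collapsed to grayscale with an unweighted channel mean
    on construction; pixel intensities must be nonnegative.
    """

    pixels: np.ndarray
    plate_id: str = "plate1"
    condition: str = "light"
    day: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:
            px = px.mean(axis=2)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D (or RGB 3-D) image, got ndim={px.ndim}")
        if px.size and px.min() < 0:
            raise ValueError("plate image contains negative intensities")
        if self.condition not in ("light", "dark"):
            raise ValueError(f"condition must be 'light' or 'dark', got {self.condition!r}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ArrayLayout:
    """Grid geometry and strain map of a colony array.

    ``strain_map`` is a DataFrame with columns ``row``, ``col`` (0-based),
    ``strain``, ``control_flag`` and ``dubious_flag``; it must cover every
    grid position.  ``offset`` is a (row_px, col_px) registration crop
    applied before banding; automatic grid detection is out of scope.
    """

    rows: int = 16
    cols: int = 24
    band_height_px: int = BAND_HEIGHT_PX
    spacing_px: int = SPACING_PX
    top_k: int = TOP_K
    strain_map: pd.DataFrame | None = None
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.top_k > self.band_height_px:
            raise ValueError(
                f"top_k={self.top_k} exceeds band height {self.band_height_px}"
            )
        if self.strain_map is not None:
            need = {(r, c) for r in range(self.rows) for c in range(self.cols)}
            have = set(zip(self.strain_map["row"], self.strain_map["col"]))
            if need - have:
                missing = sorted(need - have)[:3]
                raise ValueError(f"strain_map misses positions, e.g. {missing}")

    def position_info(self, row: int, col: int) -> tuple[str, bool, bool]:
        """(strain, control_flag, dubious_flag) for a grid position."""
        if self.strain_map is None:
            return (f"r{row:02d}c{col:02d}", False, False)
        sel = self.strain_map[
            (self.strain_map["row"] == row) & (self.strain_map["col"] == col)
        ].iloc[0]
        return (str(sel["strain"]), bool(sel["control_flag"]), bool(sel["dubious_flag"]))


def band_profile(band: np.ndarray, top_k: int = TOP_K) -> np.ndarray:
    """Column profile of a 30-px band: per-column sum of the ``top_k`` largest pixels.

    Summing the brightest pixels rather than all of them boosts the
    signal-to-background ratio for the faint colonies present right after
    pinning.  Ties are multiset-counted.  Integer input yields an exact
    integer profile.
    """
    band = np.asarray(band)
    if band.ndim != 2:
        raise ValueError("band must be a 2-D matrix")
    if band.shape[0] < top_k:
        raise ValueError(f"band has {band.shape[0]} rows, fewer than top_k={top_k}")
    return np.sort(band, axis=0)[-top_k:, :].sum(axis=0)


def colony_windows(profile: np.ndarray, spacing_px: int = SPACING_PX) -> list[np.ndarray]:
    """Split a band profile into consecutive colony windows of ``spacing_px`` values.

    Window *i* (1-based) holds profile positions (i-1)*60+1 .. i*60; the
    concatenation of the windows reproduces the profile exactly.
    """
    profile = np.asarray(profile)
    if profile.ndim != 1:
        raise ValueError("profile must be 1-D")
    if profile.size % spacing_px != 0:
        raise ValueError(
            f"profile length {profile.size} is not a multiple of spacing {spacing_px}"
        )
    n = profile.size // spacing_px
    return [profile[i * spacing_px : (i + 1) * spacing_px] for i in range(n)]


def _check_window(window: np.ndarray) -> np.ndarray:
    window = np.asarray(window)
    if window.ndim != 1 or window.size != SPACING_PX:
        raise ValueError(f"colony window must have exactly {SPACING_PX} values")
    return window


def colony_intensity(window: np.ndarray) -> float:
    """Median of the top 10 values among the central 20 window positions (21-40, 1-based).

    The median of 10 values is the mean of the 5th and 6th order statistics.
    """
    window = _check_window(window)
    central = window[_CENTRAL[0] - 1 : _CENTRAL[1]]
    top10 = np.sort(central)[-10:]
    return float(np.median(top10))


def background_intensity(window: np.ndarray) -> float:
    """Mean of the two flank minima (1-based positions 5-20 and 40-55)."""
    window = _check_window(window)
    left = window[_LEFT_FLANK[0] - 1 : _LEFT_FLANK[1]].min()
    right = window[_RIGHT_FLANK[0] - 1 : _RIGHT_FLANK[1]].min()
    return float((left + right) / 2)


def colony_cde(window: np.ndarray) -> float:
    """Cell-density estimate: colony intensity minus background, unclipped."""
    return colony_intensity(window) - background_intensity(window)


def quantify_plate(image: PlateImage, layout: ArrayLayout) -> pd.DataFrame:
    """Quantify a plate photograph into one CDE record per grid position.

    Returns a table with columns ``plate``, ``row``, ``col``, ``strain``,
    ``control_flag``, ``dubious_flag``, ``condition``, ``day``, ``cde``.

    Raises on a geometry mismatch after applying the registration offset.
    """
    r0, c0 = layout.offset
    need_h = layout.rows * layout.band_height_px
    need_w = layout.cols * layout.spacing_px
    px = image.pixels[r0:, c0:]
    if px.shape[0] < need_h or px.shape[1] < need_w:
        raise ValueError(
            f"plate {image.plate_id}: image {image.pixels.shape} too small for "
            f"{layout.rows}x{layout.cols} grid needing {need_h}x{need_w} px "
            f"after offset {layout.offset}"
        )
    px = px[:need_h, :need_w]

    if layout.strain_map is not None:
        smap = layout.strain_map.set_index(["row", "col"])

    records = []
    for r in range(layout.rows):
        band = px[r * layout.band_height_px : (r + 1) * layout.band_height_px, :]
        profile = band_profile(band, layout.top_k)
        for c, window in enumerate(colony_windows(profile, layout.spacing_px)):
            if layout.strain_map is None:
                strain, ctrl, dub = f"r{r:02d}c{c:02d}", False, False
            else:
                row = smap.loc[(r, c)]
                strain = str(row["strain"])
                ctrl = bool(row["control_flag"])
                dub = bool(row["dubious_flag"])
            records.append(
                {
                    "plate": image.plate_id,
                    "row": r,
                    "col": c,
                    "strain": strain,
                    "control_flag": ctrl,
                    "dubious_flag": dub,
                    "condition": image.condition,
                    "day": image.day,
                    "cde": colony_cde(window),
                }
            )
    return pd.DataFrame.from_records(records)
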