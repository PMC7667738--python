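"""Quantitative serial-dilution drop-test analysis.

Each strain is spotted as a tenfold dilution series (dilution 1 at
OD610 ~ 1) on light-exposed and dark plates.  Because growth is slower
under illumination, the scored light/dark ratio compares the *first*
light dilution against the *second* dark dilution, and uses intensity
per unit area after background subtraction (INT/mm^2) so that spot size
differences do not bias the ratio.  Strain ratios are compared to the
wild type's with a pooled-variance two-sided Student t-test; a strain is
significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
LIGHT_DILUTION = 1
DARK_DILUTION = 2
SCORING_DAY = 3
FALLBACK_DAY = 5


@dataclass(frozen=True)
class SpotRegion:
    """Circular spot region with a surrounding background annulus (pixel units)."""

    center_row: float
    center_col: float
    radius: float
    annulus_width: float = 5.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.annulus_width <= 0:
            raise ValueError("radius and annulus width must be positive")


def spot_intensity(
    image: np.ndarray, region: SpotRegion, mm_per_px: float = 1.0
) -> float:
    """Background-subtracted spot intensity per unit area (INT/mm^2).

    The spot is the disk of ``region.radius`` around the center; the
    local background level is the median pixel intensity of the annulus
    between ``radius`` and ``radius + annulus_width``.  Returns
    (sum(disk) - area * background) / area in mm^2 units.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    h, w = image.shape
    yy = np.arange(h)[:, None] - region.center_row
    xx = np.arange(w)[None, :] - region.center_col
    dist2 = yy**2 + xx**2
    disk = dist2 <= region.radius**2
    annulus = (dist2 > region.radius**2) & (
        dist2 <= (region.radius + region.annulus_width) ** 2
    )
    if not disk.any():
        raise ValueError("spot region contains no pixels")
    if not annulus.any():
        raise ValueError("background annulus contains no pixels")
    area_px = int(disk.sum())
    background = float(np.median(image[annulus]))
    total = float(image[disk].sum())
    area_mm2 = area_px * mm_per_px**2
    return (total - area_px * background) / area_mm2


def light_dark_ratio(
    records: pd.DataFrame, day5_fallback: bool = False
) -> float:
    """Light/dark growth ratio of one strain in one experiment.

    Divides the light dilution-1 INT/mm^2 by the dark dilution-2 value,
    both at day 3; ``day5_fallback`` reads the light value at day 5
    instead (used for slow growers where day 3 is unreliable).  Raises
    when the required cells are absent and on a non-positive dark value.
    """
    light_day = FALLBACK_DAY if day5_fallback else SCORING_DAY

    def cell(cond: str, dil: int, day: int) -> float:
        sel = records[
            (records["condition"] == cond)
            & (records["dilution"] == dil)
            & (records["day"] == day)
        ]
        if sel.empty:
            raise ValueError(f"missing {cond} dilution {dil} day {day} record")
        return float(sel["intensity_per_area"].iloc[0])

    light = cell("light", LIGHT_DILUTION, light_day)
    dark = cell("dark", DARK_DILUTION, SCORING_DAY)
    if dark <= 0:
        raise ValueError("dark reference intensity is non-positive; ratio undefined")
    return light / dark


def droptest_significance(
    strain_ratios: list[float] | np.ndarray,
    wt_ratios: list[float] | np.ndarray,
    alpha: float = ALPHA,
) -> dict:
    """Pooled-variance two-sided t-test of strain vs wild-type light/dark ratios.

    Requires >= 2 ratios per group; df = n1 + n2 - 2.  Two identical
    zero-spread groups give t = 0, p = 1.  Returns a dict with the mean
    ratio, SD, t, two-sided p and the significance flag at ``alpha``.
    """
    x = np.asarray(strain_ratios, dtype=float)
    y = np.asarray(wt_ratios, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 ratios per group for the t-test")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    # zero-spread groups are detected by range, not computed variance, so
    # that identical constant groups give t=0, p=1 despite mean round-off
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        same = x[0] == y[0]
        t = 0.0 if same else math_inf_signed(x[0] - y[0])
        p = 1.0 if same else 0.0
    else:
        t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), df)
    return {
        "mean_ratio": float(x.mean()),
        "sd_ratio": float(x.std(ddof=1)),
        "t": float(t),
        "p": float(p),
        "df": int(df),
        "significant": bool(p < alpha),
    }


def math_inf_signed(diff: float) -> float:
    return float(np.inf) if diff > 0 else float(-np.inf)


def run_droptest(
    table: pd.DataFrame,
    wt_strain: str = "wt",
    day5_strains: set[str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Score every strain in a spot table against the wild type.

    ``table`` follows the SpotRecord schema (strain, experiment,
    condition, dilution, day, intensity_per_area).  Per experiment the
    light/dark ratio is formed, then each strain's ratios are tested
    against the wild type's.  Returns one row per non-wild-type strain
    with mean ratio, SD, t, p and significance at ``alpha``.
    """
    day5_strains = day5_strains or set()
    if wt_strain not in set(table["strain"]):
        raise ValueError(f"wild-type strain {wt_strain!r} absent from table")

    def ratios(strain: str) -> list[float]:
        out = []
        grp = table[table["strain"] == strain]
        for _, exp_grp in grp.groupby("experiment"):
            out.append(light_dark_ratio(exp_grp, day5_fallback=strain in day5_strains))
        return out

    wt = ratios(wt_strain)
    rows = []
    for strain in sorted(set(table["strain"]) - {wt_strain}):
        res = droptest_significance(ratios(strain), wt, alpha=alpha)
        res["strain"] = strain
        rows.append(res)
    cols = ["strain", "mean_ratio", "sd_ratio", "t", "p", "df", "significant"]
    return pd.DataFrame.from_records(rows)[cols]
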