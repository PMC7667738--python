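"""Calling light-sensitive and light-resistant strains from CDE tables.

The screen scores each deletion strain from four measurements: light
day-0 and day-6 CDE, and dark day-0 and day-1 CDE.  Because light
toxicity depends strongly on initial cell density, strains are first
banded by day-0 CDE (discarded < 61; moderate 61-120; high >= 121) and
each band gets its own day-6 cutoff (criterium I: day-6 light CDE < 400
moderate / < 900 high).  Criterium II normalizes light growth twice —
first to the strain's own dark growth, then to the plate-and-band median
of the same ratio over the his3-delta control colonies:

    LGnorm = (LG / DG) / median_controls(LGctr / DGctr)

with LG the day-6 light CDE and DG the day-1 dark CDE.  A strain is
called sensitive only when both criteria hold (LGnorm < 0.75 by
default).  Strains with < 1.5-fold dark growth over the first day are
excluded as generic slow growers, and strains with day-0 CDE >= 61 but
day-6 light CDE > 1642 are called light-resistant.

Control colonies calibrate everything: the plate/band control median
anchors LGnorm at 1, and the fraction of in-band controls passing
criterium I estimates the false-positive rate of the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BAND_DISCARDED = "discarded"
BAND_MODERATE = "moderate"
BAND_HIGH = "high"

VERDICTS = (
    "sensitive_high",
    "sensitive_moderate",
    "resistant",
    "not_called",
    "excluded_low_density",
    "excluded_slow_growth",
    "excluded_missing_data",
)


@dataclass(frozen=True)
class ScreenThresholds:
    """All calling cutoffs; defaults are the primary genome-wide screen's.

    ``moderate_min`` may be ``None`` for assay variants that define no
    moderate band (then any day-0 CDE below ``high_min`` is discarded).
    Day-6 cutoffs are strict (<); band entry is inclusive (>=); the
    resistance cutoff is strict (>).
    """

    moderate_min: float | None = 61.0
    moderate_max: float | None = 120.0
    high_min: float = 121.0
    day6_cutoff_high: float = 900.0
    day6_cutoff_moderate: float | None = 400.0
    lgnorm_cutoff: float = 0.75
    slow_growth_fold: float = 1.5
    resistant_day6_cutoff: float = 1642.0
    resistant_day0_min: float = 61.0
    assay_variant: str = "primary"

    def __post_init__(self) -> None:
        if self.moderate_min is not None:
            if self.moderate_max is None or self.day6_cutoff_moderate is None:
                raise ValueError("moderate band needs moderate_max and its day-6 cutoff")
            if not (self.moderate_min <= self.moderate_max < self.high_min):
                raise ValueError("bands must be ordered and non-overlapping")

    @classmethod
    def variant(cls, name: str) -> "ScreenThresholds":
        """Named threshold sets: ``primary``, ``confirm_haploid``, ``confirm_diploid``.

        The confirmation assays recalibrate band boundaries on their own
        control distributions: the haploid set has a single high band
        from day-0 CDE 13 (all controls grew well even when faint); the
        diploid set uses high >= 105 / moderate 45-104 with a 500 cutoff.
        """
        if name == "primary":
            return cls()
        if name == "confirm_haploid":
            return cls(
                moderate_min=None,
                moderate_max=None,
                day6_cutoff_moderate=None,
                high_min=13.0,
                assay_variant=name,
            )
        if name == "confirm_diploid":
            return cls(
                moderate_min=45.0,
                moderate_max=104.0,
                high_min=105.0,
                day6_cutoff_moderate=500.0,
                assay_variant=name,
            )
        raise ValueError(f"unknown assay variant {name!r}")


def density_band(cde_day0: float, thresholds: ScreenThresholds) -> str:
    """Band of a day-0 CDE: ``discarded``, ``moderate`` or ``high`` (inclusive bounds)."""
    if cde_day0 >= thresholds.high_min:
        return BAND_HIGH
    if (
        thresholds.moderate_min is not None
        and thresholds.moderate_min <= cde_day0 <= thresholds.moderate_max
    ):
        return BAND_MODERATE
    return BAND_DISCARDED


def _band_cutoff(band: str, thresholds: ScreenThresholds) -> float:
    if band == BAND_HIGH:
        return thresholds.day6_cutoff_high
    if band == BAND_MODERATE:
        return float(thresholds.day6_cutoff_moderate)
    raise ValueError("criterium I is undefined for the discarded band")


def criterium1(cde_day0: float, cde_day6_light: float, thresholds: ScreenThresholds) -> bool:
    """Density-band day-6 cutoff: day-6 light CDE strictly below the band's cutoff."""
    band = density_band(cde_day0, thresholds)
    return cde_day6_light < _band_cutoff(band, thresholds)


def lgnorm(lg_day6_light: float, dg_day1_dark: float, ctrl_median: float) -> float:
    """Double-normalized light growth (LG/DG)/ctrl_median; denominators must be positive."""
    if dg_day1_dark <= 0:
        raise ValueError("dark day-1 CDE must be positive")
    if ctrl_median <= 0:
        raise ValueError("control median must be positive")
    return (lg_day6_light / dg_day1_dark) / ctrl_median


def slow_growth_excluded(
    dark_day0: float, dark_day1: float, thresholds: ScreenThresholds
) -> bool:
    """True when dark growth over the first day is below the slow-growth fold (default 1.5)."""
    if dark_day0 <= 0:
        raise ValueError("dark day-0 CDE must be positive for the fold-change filter")
    return dark_day1 / dark_day0 < thresholds.slow_growth_fold


# ---------------------------------------------------------------------------
# table assembly


def _wide_table(light: pd.DataFrame, dark: pd.DataFrame) -> pd.DataFrame:
    """One row per colony position with columns ld0, ld6, dd0, dd1 (NaN if missing)."""
    keys = ["plate", "row", "col", "strain", "control_flag"]
    if "dubious_flag" in light.columns:
        keys.append("dubious_flag")

    def pivot(df: pd.DataFrame, cond: str, day: int, name: str) -> pd.DataFrame:
        sel = df[(df["condition"] == cond) & (df["day"] == day)]
        return sel[keys + ["cde"]].rename(columns={"cde": name})

    wide = pivot(light, "light", 0, "ld0")
    for df, cond, day, name in (
        (light, "light", 6, "ld6"),
        (dark, "dark", 0, "dd0"),
        (dark, "dark", 1, "dd1"),
    ):
        wide = wide.merge(pivot(df, cond, day, name), on=keys, how="outer")
    return wide


def control_band_medians(
    light: pd.DataFrame,
    dark: pd.DataFrame,
    thresholds: ScreenThresholds,
    strict: bool = True,
) -> dict[tuple[str, str], float]:
    """Per (plate, band) median control light/dark growth ratio, with neighbor fallback.

    The ratio is day-6 light CDE over day-1 dark CDE of each control
    colony, banded by the control's own day-0 light CDE.  A (plate, band)
    with no usable in-band control takes the median from the nearest
    plate by index (lower index preferred on ties).  A band with no
    control value on any plate raises when ``strict``; otherwise it is
    simply absent from the result (strains in it are then unscorable).
    """
    wide = _wide_table(light, dark)
    ctrl = wide[wide["control_flag"].astype(bool)].copy()
    ctrl = ctrl.dropna(subset=["ld0", "ld6", "dd1"])
    ctrl = ctrl[ctrl["dd1"] > 0]
    ctrl["band"] = [density_band(v, thresholds) for v in ctrl["ld0"]]
    ctrl = ctrl[ctrl["band"] != BAND_DISCARDED]
    ctrl["ratio"] = ctrl["ld6"] / ctrl["dd1"]

    plates = sorted(pd.unique(wide["plate"]))
    bands = [BAND_HIGH] if thresholds.moderate_min is None else [BAND_MODERATE, BAND_HIGH]
    raw = ctrl.groupby(["plate", "band"])["ratio"].median()

    medians: dict[tuple[str, str], float] = {}
    for band in bands:
        have = {p: raw.loc[(p, band)] for p in plates if (p, band) in raw.index}
        if not have:
            if strict:
                raise ValueError(f"no control colonies in band {band!r} on any plate")
            continue
        order = {p: i for i, p in enumerate(plates)}
        for p in plates:
            if p in have:
                medians[(p, band)] = float(have[p])
            else:
                src = min(have, key=lambda q: (abs(order[q] - order[p]), order[q]))
                medians[(p, band)] = float(have[src])
    return medians


def control_band_median(
    light: pd.DataFrame,
    dark: pd.DataFrame,
    thresholds: ScreenThresholds,
    plate: str,
    band: str,
) -> float:
    """Control light/dark median for one (plate, band), after fallback resolution."""
    medians = control_band_medians(light, dark, thresholds, strict=False)
    try:
        return medians[(plate, band)]
    except KeyError:
        raise ValueError(
            f"no control colonies in band {band!r} on any plate"
        ) from None


def call_strains(
    light: pd.DataFrame,
    dark: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """Assemble a per-colony verdict table from light and dark CDE tables.

    Pipeline per colony: density band -> criterium I -> slow-growth
    exclusion -> criterium II (LGnorm), then the resistance gate.  A
    sensitive verdict requires BOTH criteria; every exclusion carries a
    machine-readable reason; every layout position appears exactly once.

    Returns columns ``plate, row, col, strain, control_flag,
    dubious_flag, band, lgnorm, verdict, reasons``.
    """
    thresholds = thresholds or ScreenThresholds()
    wide = _wide_table(light, dark)
    medians = control_band_medians(light, dark, thresholds, strict=False)

    out = []
    for rec in wide.itertuples(index=False):
        reasons: list[str] = []
        lgn = np.nan
        band = BAND_DISCARDED

        missing = [
            name
            for name, v in (("light_day0", rec.ld0), ("light_day6", rec.ld6),
                            ("dark_day0", rec.dd0), ("dark_day1", rec.dd1))
            if v is None or (isinstance(v, float) and np.isnan(v))
        ]
        if missing:
            verdict = "excluded_missing_data"
            reasons.append("missing:" + ",".join(missing))
        else:
            band = density_band(rec.ld0, thresholds)
            if band == BAND_DISCARDED:
                verdict = "excluded_low_density"
                reasons.append(f"day0_cde={rec.ld0:g} below band minimum")
            elif rec.dd0 <= 0 or rec.dd1 <= 0:
                verdict = "excluded_missing_data"
                reasons.append("non-positive dark CDE")
            elif slow_growth_excluded(rec.dd0, rec.dd1, thresholds):
                verdict = "excluded_slow_growth"
                reasons.append(
                    f"dark fold {rec.dd1 / rec.dd0:.2f} < {thresholds.slow_growth_fold:g}"
                )
            elif (rec.plate, band) not in medians:
                verdict = "excluded_missing_data"
                reasons.append(f"no control median available for band {band}")
            else:
                crit1 = criterium1(rec.ld0, rec.ld6, thresholds)
                lgn = lgnorm(rec.ld6, rec.dd1, medians[(rec.plate, band)])
                crit2 = lgn < thresholds.lgnorm_cutoff
                if crit1 and crit2:
                    verdict = f"sensitive_{band}"
                    reasons.append("criterium I and II satisfied")
                elif (
                    rec.ld0 >= thresholds.resistant_day0_min
                    and rec.ld6 > thresholds.resistant_day6_cutoff
                ):
                    verdict = "resistant"
                    reasons.append(
                        f"day6_cde={rec.ld6:g} > {thresholds.resistant_day6_cutoff:g}"
                    )
                else:
                    verdict = "not_called"
                    if not crit1:
                        reasons.append("criterium I failed")
                    if not crit2:
                        reasons.append("criterium II failed")

        out.append(
            {
                "plate": rec.plate,
                "row": rec.row,
                "col": rec.col,
                "strain": rec.strain,
                "control_flag": bool(rec.control_flag),
                "dubious_flag": bool(getattr(rec, "dubious_flag", False)),
                "band": band,
                "lgnorm": lgn,
                "verdict": verdict,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame.from_records(out)


def call_resistant(
    light: pd.DataFrame, thresholds: ScreenThresholds | None = None
) -> set[str]:
    """Strains with day-0 CDE >= 61 and day-6 light CDE > 1642 (defaults).

    Applies only the density gate and the resistance cutoff the screen
    defines; the slow-growth filter does not apply here.
    """
    thresholds = thresholds or ScreenThresholds()
    keys = ["plate", "row", "col", "strain"]
    d0 = light[(light["condition"] == "light") & (light["day"] == 0)]
    d6 = light[(light["condition"] == "light") & (light["day"] == 6)]
    wide = d0[keys + ["cde"]].rename(columns={"cde": "ld0"}).merge(
        d6[keys + ["cde"]].rename(columns={"cde": "ld6"}), on=keys
    )
    hit = wide[
        (wide["ld0"] >= thresholds.resistant_day0_min)
        & (wide["ld6"] > thresholds.resistant_day6_cutoff)
    ]
    return set(hit["strain"])


def estimate_false_positive_rate(
    control_records: pd.DataFrame,
    thresholds: ScreenThresholds,
    band: str,
) -> float:
    """Fraction of in-band control colonies whose day-6 light CDE passes criterium I.

    Controls are genetically neutral, so any control satisfying the
    sensitivity cutoff of its band is a false positive by construction.
    ``control_records`` is a light CDE table restricted to controls, with
    days 0 and 6 present.  Raises if the band holds no control.
    """
    d0 = control_records[
        (control_records["condition"] == "light") & (control_records["day"] == 0)
    ]
    d6 = control_records[
        (control_records["condition"] == "light") & (control_records["day"] == 6)
    ]
    keys = ["plate", "row", "col"]
    wide = d0[keys + ["cde"]].rename(columns={"cde": "ld0"}).merge(
        d6[keys + ["cde"]].rename(columns={"cde": "ld6"}), on=keys
    )
    in_band = wide[[density_band(v, thresholds) == band for v in wide["ld0"]]]
    if in_band.empty:
        raise ValueError(f"no control colonies in band {band!r}")
    cutoff = _band_cutoff(band, thresholds)
    return float((in_band["ld6"] < cutoff).mean())


def aggregate_calls(calls: pd.DataFrame, how: str = "any") -> pd.DataFrame:
    """Collapse replicate colony calls to one verdict per strain.

    ``how='any'`` flags a strain sensitive if any scoreable replicate
    is; ``how='majority'`` requires more than half.  Replicates excluded
    for low density or missing data do not vote; a strain with no voting
    replicate is excluded.
    """
    if how not in ("any", "majority"):
        raise ValueError("how must be 'any' or 'majority'")
    rows = []
    for strain, grp in calls.groupby("strain"):
        voting = grp[~grp["verdict"].isin(["excluded_low_density", "excluded_missing_data"])]
        if voting.empty:
            rows.append({"strain": strain, "verdict": "excluded_missing_data",
                         "n_replicates": len(grp), "n_voting": 0})
            continue
        sens = voting["verdict"].str.startswith("sensitive")
        hit = sens.any() if how == "any" else sens.sum() * 2 > len(voting)
        if hit:
            verdict = voting.loc[sens, "verdict"].iloc[0]
        elif (voting["verdict"] == "excluded_slow_growth").all():
            verdict = "excluded_slow_growth"
        else:
            verdict = "not_called"
        rows.append({"strain": strain, "verdict": verdict,
                     "n_replicates": len(grp), "n_voting": int(len(voting))})
    return pd.DataFrame.from_records(rows)
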