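"""Synthetic plates, screen tables and drop tests with known ground truth.

The generator emulates the statistical structure a visible-light
sensitivity screen produces, not the photochemistry behind it:

* **Plate images** — 16x24 colony grids rendered as radially symmetric
  Gaussian spots on a constant-plus-gradient background, 30-px row
  bands, 60-px center spacing, optional additive Gaussian pixel noise.

* **Screen tables** — per-colony CDE values for light day 0/6 and dark
  day 0/1.  Initial (day-0) density is right-skewed (lognormal), and
  expected day-6 light growth follows a logistic curve in initial
  density multiplied by a strain effect, reproducing the near-binary
  control behavior of the real screen: colonies pinned dense grow out
  under illumination, faint ones fail variably.  Sensitive, resistant
  and slow-growing mutants are planted with known effects; his3-delta
  controls are spread over every plate.

* **Drop tests** — per-strain, per-experiment spot intensities for the
  light/dark serial-dilution assay, with multiplicative lognormal noise.

All randomness flows through explicit integer seeds; identical
(spec, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lightscreen.imaging import BAND_HEIGHT_PX, SPACING_PX, PlateImage


# ---------------------------------------------------------------------------
# plate images


@dataclass
class SyntheticPlateImageSpec:
    """Geometry and photometry of one rendered plate.

    ``amplitudes`` is a rows x cols array of nonnegative peak colony
    intensities (zeros render an empty position).  Colony centers sit at
    1-based column 30 + 60*(i-1) of their band and row 15 of the band.
    """

    rows: int = 16
    cols: int = 24
    band_height_px: int = BAND_HEIGHT_PX
    spacing_px: int = SPACING_PX
    amplitudes: np.ndarray | None = None
    kernel_sigma_px: float = 6.0
    background: float = 100.0
    gradient: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.band_height_px < 25:
            raise ValueError("band height must be >= 25 px (top-25 column sum)")
        if self.amplitudes is None:
            self.amplitudes = np.zeros((self.rows, self.cols))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (self.rows, self.cols):
            raise ValueError("amplitudes must be rows x cols")
        if np.any(self.amplitudes < 0):
            raise ValueError("colony amplitudes must be nonnegative")


def simulate_plate_image(
    spec: SyntheticPlateImageSpec,
    plate_id: str = "plate1",
    condition: str = "light",
    day: int = 0,
) -> tuple[PlateImage, pd.DataFrame]:
    """Render a plate and return it with the true per-position amplitude table.

    The image is ``rows*band_height`` by ``cols*spacing`` pixels.  Each
    colony is an isotropic Gaussian of the given sigma, truncated at
    4 sigma for speed; intensities are clipped at zero after noise.
    """
    h = spec.rows * spec.band_height_px
    w = spec.cols * spec.spacing_px
    gy, gx = spec.gradient
    img = spec.background + gy * np.arange(h)[:, None] + gx * np.arange(w)[None, :]
    img = np.broadcast_to(img, (h, w)).astype(float).copy()

    radius = int(math.ceil(4 * spec.kernel_sigma_px))
    truth = []
    for r in range(spec.rows):
        cy = r * spec.band_height_px + 14  # 1-based row 15 of the band
        for c in range(spec.cols):
            cx = c * spec.spacing_px + 29  # 1-based column 30 of the window
            amp = spec.amplitudes[r, c]
            truth.append({"row": r, "col": c, "amplitude": amp,
                          "center_row": cy, "center_col": cx})
            if amp == 0:
                continue
            y0, y1 = max(0, cy - radius), min(h, cy + radius + 1)
            x0, x1 = max(0, cx - radius), min(w, cx + radius + 1)
            yy = np.arange(y0, y1)[:, None] - cy
            xx = np.arange(x0, x1)[None, :] - cx
            img[y0:y1, x0:x1] += amp * np.exp(
                -(yy**2 + xx**2) / (2 * spec.kernel_sigma_px**2)
            )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)
    image = PlateImage(pixels=img, plate_id=plate_id, condition=condition, day=day)
    return image, pd.DataFrame.from_records(truth)


# ---------------------------------------------------------------------------
# screen tables


@dataclass
class SyntheticScreenSpec:
    """Study conditions of a simulated genome-wide light screen.

    Defaults model the real screen's scale: 76 control colonies per
    384-position plate, a lognormal day-0 CDE law putting roughly a
    fifth of colonies under the 61-CDE discard line, and a logistic
    light-response curve saturating at 1500 CDE with midpoint 60 so
    densely pinned colonies grow out under light while faint ones fail.
    Planted mutants scale the curve (sensitive 0.1x, resistant 2.5x);
    slow growers get a 1.1-fold first-day dark growth (vs 3.0 normal)
    and grow poorly in light too (0.25x), so only the dark-growth filter
    keeps them from being miscalled sensitive.  Planted strains draw
    their initial density from the same lognormal truncated at >= 100
    CDE, guaranteeing they land in a scoreable band.  Measurement noise
    is additive Gaussian per measurement (sd 15 CDE, about 1% of the
    dynamic range).
    """

    n_plates: int = 7
    rows: int = 16
    cols: int = 24
    controls_per_plate: int = 76
    n_strains: int | None = None
    planted_sensitive: dict[str, float] = field(default_factory=dict)
    planted_resistant: dict[str, float] = field(default_factory=dict)
    planted_slow: frozenset[str] = field(default_factory=frozenset)
    day0_log_mean: float = math.log(100.0)
    day0_log_sd: float = 0.6
    planted_day0_min: float = 100.0
    curve_max: float = 1500.0
    curve_midpoint: float = 60.0
    curve_scale: float = 15.0
    normal_dark_fold: float = 3.0
    slow_dark_fold: float = 1.1
    slow_light_factor: float = 0.25
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        cap = self.n_plates * (self.rows * self.cols - self.controls_per_plate)
        if self.n_strains is None:
            self.n_strains = cap
        if self.n_strains > cap:
            raise ValueError(f"{self.n_strains} strains exceed capacity {cap}")
        self.planted_slow = frozenset(self.planted_slow)
        sets = [set(self.planted_sensitive), set(self.planted_resistant),
                set(self.planted_slow)]
        if len(set().union(*sets)) != sum(len(s) for s in sets):
            raise ValueError("planted strain sets must be disjoint")
        for sid, eff in self.planted_sensitive.items():
            if not 0 < eff < 1:
                raise ValueError(
                    f"sensitive effect for {sid} must be in (0, 1), got {eff}"
                )
        for sid, eff in self.planted_resistant.items():
            if eff <= 1:
                raise ValueError(
                    f"resistant effect for {sid} must exceed 1, got {eff}"
                )

    @classmethod
    def with_counts(
        cls,
        n_strains: int = 2000,
        n_sensitive: int = 200,
        n_resistant: int = 50,
        n_slow: int = 50,
        sensitive_effect: float = 0.1,
        resistant_effect: float = 2.5,
        **kwargs,
    ) -> "SyntheticScreenSpec":
        """Spec with auto-named planted strains and enough plates to hold them."""
        if n_sensitive + n_resistant + n_slow > n_strains:
            raise ValueError("planted counts exceed total strains")
        rows = kwargs.get("rows", 16)
        cols = kwargs.get("cols", 24)
        controls = kwargs.get("controls_per_plate", 76)
        per_plate = rows * cols - controls
        kwargs.setdefault("n_plates", math.ceil(n_strains / per_plate))
        return cls(
            n_strains=n_strains,
            planted_sensitive={f"sens{i:04d}": sensitive_effect for i in range(n_sensitive)},
            planted_resistant={f"res{i:04d}": resistant_effect for i in range(n_resistant)},
            planted_slow=frozenset(f"slow{i:04d}" for i in range(n_slow)),
            **kwargs,
        )

    def light_response(self, day0: np.ndarray | float) -> np.ndarray | float:
        """Expected day-6 light CDE of a neutral strain at the given initial density."""
        return self.curve_max / (1.0 + np.exp(-(np.asarray(day0, dtype=float)
                                                - self.curve_midpoint) / self.curve_scale))


def _truth_class(spec: SyntheticScreenSpec, strain: str) -> str:
    if strain in spec.planted_sensitive:
        return "sensitive"
    if strain in spec.planted_resistant:
        return "resistant"
    if strain in spec.planted_slow:
        return "slow"
    return "normal"


def simulate_screen_tables(
    spec: SyntheticScreenSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one full screen: (light_table, dark_table, layout, truth).

    Light table holds days 0 and 6, dark table days 0 and 1, one record
    per plate/position/condition/day in the common CDE-table schema.
    ``layout`` maps positions to strains and control flags; ``truth``
    gives each mutant strain's class and effect.  With ``noise_sd = 0``
    the output is a deterministic function of (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_positions = spec.rows * spec.cols
    per_plate = n_positions - spec.controls_per_plate

    planted = (
        list(spec.planted_sensitive) + list(spec.planted_resistant) + sorted(spec.planted_slow)
    )
    n_fill = spec.n_strains - len(planted)
    strains = planted + [f"mut{i:04d}" for i in range(n_fill)]
    order = rng.permutation(len(strains))
    strains = [strains[i] for i in order]

    layout_rows = []
    value_rows = []
    truth_rows = [
        {
            "strain": s,
            "truth_class": _truth_class(spec, s),
            "effect": spec.planted_sensitive.get(s, spec.planted_resistant.get(s, 1.0)),
        }
        for s in strains
    ]

    def draw_day0(planted_strain: bool) -> float:
        if not planted_strain:
            return float(rng.lognormal(spec.day0_log_mean, spec.day0_log_sd))
        while True:  # truncated draw keeps planted strains scoreable
            v = float(rng.lognormal(spec.day0_log_mean, spec.day0_log_sd))
            if v >= spec.planted_day0_min:
                return v

    cursor = 0
    for p in range(spec.n_plates):
        plate = f"plate{p + 1:02d}"
        ctrl_pos = set(rng.choice(n_positions, size=spec.controls_per_plate, replace=False))
        mutants_here = strains[cursor : cursor + per_plate]
        cursor += len(mutants_here)
        mut_iter = iter(mutants_here)
        for pos in range(n_positions):
            r, c = divmod(pos, spec.cols)
            if pos in ctrl_pos:
                strain, ctrl = "his3", True
            else:
                strain = next(mut_iter, "his3")  # spare slots become extra controls
                ctrl = strain == "his3"
            cls = "control" if ctrl else _truth_class(spec, strain)
            d0 = draw_day0(not ctrl and cls != "normal")

            light_eff = {
                "sensitive": spec.planted_sensitive.get(strain, 1.0),
                "resistant": spec.planted_resistant.get(strain, 1.0),
                "slow": spec.slow_light_factor,
            }.get(cls, 1.0)
            dark_fold = spec.slow_dark_fold if cls == "slow" else spec.normal_dark_fold

            true_vals = {
                ("light", 0): d0,
                ("light", 6): float(spec.light_response(d0)) * light_eff,
                ("dark", 0): d0,
                ("dark", 1): d0 * dark_fold,
            }
            layout_rows.append(
                {"plate": plate, "row": r, "col": c, "strain": strain,
                 "control_flag": ctrl, "dubious_flag": False}
            )
            for (cond, day), v in true_vals.items():
                if spec.noise_sd > 0:
                    v = v + rng.normal(0.0, spec.noise_sd)
                # real CDEs derive from integer pixel sums; emitting whole
                # CDE units keeps the integer-complete density bands gapless
                v = float(np.rint(v))
                value_rows.append(
                    {"plate": plate, "row": r, "col": c, "strain": strain,
                     "control_flag": ctrl, "dubious_flag": False,
                     "condition": cond, "day": day, "cde": v}
                )

    values = pd.DataFrame.from_records(value_rows)
    light = values[values["condition"] == "light"].reset_index(drop=True)
    dark = values[values["condition"] == "dark"].reset_index(drop=True)
    layout = pd.DataFrame.from_records(layout_rows)
    truth = pd.DataFrame.from_records(truth_rows)
    return light, dark, layout, truth


# ---------------------------------------------------------------------------
# drop tests


def simulate_droptest(
    n_strains: int,
    n_experiments: int,
    effect_map: dict[str, float] | None = None,
    seed: int = 0,
    base_intensity: float = 1000.0,
    wt_ratio: float = 0.6,
    noise_log_sd: float = 0.15,
    n_dilutions: int = 6,
) -> pd.DataFrame:
    """Simulate a serial-dilution drop-test intensity table.

    Emits per-strain, per-experiment INT/mm^2 values for both conditions
    and all dilutions at day 3 in the SpotRecord schema; a wild-type
    strain ``wt`` is always present.  ``effect_map`` multiplies a
    strain's light/dark ratio (1.0 = wild-type behavior).  Noise is
    multiplicative lognormal per spot; with ``noise_log_sd = 0`` every
    strain's ratio is exactly ``wt_ratio * effect``.
    """
    if n_experiments < 2:
        raise ValueError("need >= 2 experiments for the t-test")
    effect_map = dict(effect_map or {})
    rng = np.random.default_rng(seed)
    strains = ["wt"] + [f"strain{i:03d}" for i in range(n_strains)]
    for s in effect_map:
        if s not in strains:
            raise ValueError(f"effect_map names unknown strain {s!r}")

    rows = []
    for exp in range(1, n_experiments + 1):
        for strain in strains:
            effect = effect_map.get(strain, 1.0)
            for cond in ("dark", "light"):
                for dil in range(1, n_dilutions + 1):
                    # dark dil-2 and light dil-1 are the scored pair; the
                    # 10x dilution ladder offsets slower growth in light
                    base = base_intensity * 10.0 ** (-(dil - 2) if cond == "dark"
                                                     else -(dil - 1))
                    if cond == "light":
                        base *= wt_ratio * effect
                    noise = math.exp(rng.normal(0.0, noise_log_sd)) if noise_log_sd > 0 else 1.0
                    rows.append(
                        {"strain": strain, "experiment": exp, "condition": cond,
                         "dilution": dil, "day": 3, "intensity_per_area": base * noise}
                    )
    return pd.DataFrame.from_records(rows)
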