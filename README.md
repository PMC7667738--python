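# lightscreen

Scoring pipeline for genome-wide **visible-light sensitivity screens** of
pinned yeast colony arrays.  Given photographs (or tabulated intensities)
of 384-format deletion-collection plates grown under white light and in
the dark, `lightscreen` quantifies each colony, calls light-sensitive and
light-resistant gene deletions with control-calibrated thresholds,
quantifies serial-dilution drop tests, and tests GO-slim term enrichment
among the hits.  A synthetic-data module simulates whole screens with
known ground truth, so the entire pipeline is testable without any
laboratory data.

## The measurement and the model

Each colony's growth is summarized as a **cell-density estimate (CDE)**:
within the colony's 60-px window of its 30-px band profile (per-column
top-25 pixel sums), the colony intensity is the median of the top 10 of
the central 20 values and the background is the mean of the two flank
minima; CDE is their difference.  The construction is exactly invariant
under uniform illumination offsets.

Because light toxicity depends sharply on initial cell density, strains
are banded by day-0 CDE (moderate 61–120, high ≥ 121; lower densities are
discarded) and called sensitive only when **both** criteria hold:

* **Criterium I** — day-6 light CDE below the band cutoff
  (400 moderate / 900 high);
* **Criterium II** — double-normalized light growth

  `LGnorm_j = (LG_j / DG_j) / median_ctr(LGctr / DGctr) < 0.75`,

  i.e. light growth normalized to the strain's own dark growth and then
  to the plate-and-band median of the neutral *his3Δ* controls.

Strains with < 1.5-fold dark growth over day 1 are excluded as generic
slow growers; strains with day-0 CDE ≥ 61 and day-6 light CDE > 1642 are
called light-resistant.  The in-plate controls also calibrate per-band
false-positive rates.  Drop-test spots are scored as background-subtracted
intensity per area (INT/mm²), forming a light/dark ratio (light dilution 1
vs dark dilution 2) tested against wild type with a pooled-variance
two-sided t-test; enrichment uses the hypergeometric upper tail with
Benjamini–Hochberg FDR (q < 0.06, terms with ≥ 25 reference genes,
dubious ORFs excluded).  See `docs/methods.md` for the full account.

## Worked example

Simulate a 600-strain screen with 60 planted light-sensitive, 15
resistant and 15 slow-growing mutants, then score it:

```python
import lightscreen as ls

spec = ls.SyntheticScreenSpec.with_counts(
    n_strains=600, n_sensitive=60, n_resistant=15, n_slow=15, seed=0
)
light, dark, layout, truth = ls.simulate_screen_tables(spec)
calls = ls.call_strains(light, dark)
print(calls["verdict"].value_counts().to_string())
```

```
not_called              533
excluded_low_density    141
sensitive_high           42
sensitive_moderate       22
excluded_slow_growth     15
resistant                15
```

The 64 sensitive colony calls split by confidence band; 141 colonies
were pinned too thin to score (day-0 CDE < 61), and the 15 planted slow
growers were caught by the dark-growth filter rather than miscalled
sensitive.  Each call carries its LGnorm value and an audit trail:

```python
print(calls[calls["verdict"] == "sensitive_high"].head(3)
      [["plate", "strain", "band", "lgnorm", "verdict"]].to_string(index=False))
```

```
  plate   strain band   lgnorm        verdict
plate01 sens0036 high 0.072251 sensitive_high
plate01 sens0045 high 0.071417 sensitive_high
plate01 sens0058 high 0.050442 sensitive_high
```

An LGnorm of 0.07 means the strain retained 7% of the control's
dark-normalized light growth.  The resistant set and the control-based
false-positive estimate come from the same tables:

```python
print(len(ls.call_resistant(light)))                      # 15
ctrl = light[light["control_flag"]]
ls.estimate_false_positive_rate(ctrl, ls.ScreenThresholds(), "moderate")
# 0.0127  -> 1.3% of moderate-band controls pass criterium I
```

The same operations are exposed on the command line:

```sh
lightscreen simulate-screen --strains 600 --sensitive 60 --seed 0 --outdir sim/
lightscreen score --light sim/light.tsv --dark sim/dark.tsv --out calls.tsv
lightscreen quantify --image plate01.png --layout sim/layout.tsv --out cde.tsv
lightscreen droptest --table spots.tsv --wt wt --out droptest.tsv
lightscreen enrich --hits hits.txt --reference ref.txt --annotation go_slim.tsv --out enr.tsv
```

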