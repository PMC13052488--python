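# oximc

Pulsatile Monte Carlo simulation of reflectance pulse oximetry, and
melanin-corrected ratio-of-ratios calibration models that remove the
resulting skin-tone bias.

Pulse oximeters estimate arterial oxygen saturation from the pulsatile
part of reflected light at two wavelengths via the ratio of ratios

    R = (AC/DC at 655 nm) / (AC/DC at 940 nm),
    AC/DC = (R_diastolic - R_systolic) / R_diastolic,

mapped to SpO2 by a calibration curve SpO2 = aR² + bR + c. Because
epidermal melanin absorbs and scatters red light more strongly than
near-infrared, R shifts with skin tone, and devices calibrated
predominantly on light skin overestimate SpO2 in darker-skinned patients.
`oximc` reproduces this bias *in silico* — a six-layer skin model
(epidermis through subcutis, with vessel self-shielding and systolic blood
volume increase) swept over melanin volume fraction f_m ∈ [0.01, 0.43]
and SaO2 ∈ [0.5, 1.0] by a weighted-photon Monte Carlo engine — and then
fits corrected calibration families such as

    SpO2 = aR² + (b + c₁m²)R + c,

where m is the melanin volume fraction, so that a single calibration holds
across all skin tones. It is intended for researchers studying pulse
oximetry bias and correction models who need full control over melanin and
saturation — conditions that are hard to set independently *in vivo*.

## A worked example

```python
import warnings
from oximc import (SweepGrid, MCConfig, build_dataset,
                   fit_conventional, fit_corrected, get_model)

grid = SweepGrid(melanin_values=(0.01, 0.15, 0.29, 0.43),
                 sao2_values=(0.5, 0.75, 1.0))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")          # desk-scale MC noise warnings
    ds = build_dataset(grid, cfg=MCConfig(n_photons=50_000, rng_seed=0))

print(ds.table.pivot(index="f_m", columns="sao2", values="R").round(3))

conv = fit_conventional(ds, calibration_melanin=0.01)
corr = fit_corrected(get_model("quad_b_m2"), ds)
print(f"conventional max error {conv.max_abs_error:.1f} pts -> "
      f"corrected {corr.max_abs_error:.1f} pts")
```

Output (16 Monte Carlo runs, ~30 s):

    sao2   0.50   0.75   1.00
    f_m
    0.01  1.491  0.950  0.250
    0.15  0.755  0.506  0.140
    0.29  0.171  0.142  0.039
    0.43  0.085  0.061  0.021
    conventional max error 54.7 pts -> corrected 13.2 pts

Each R column falls as melanin rises — the same true saturation produces a
smaller ratio of ratios in darker skin, so a light-skin calibration
(top row) overestimates SpO2 everywhere below it, by tens of saturation
points on this coarse grid. Refitting with the single quadratic melanin
term shrinks the worst-case error about four-fold; higher-order melanin
corrections (see `oximc.model_zoo`) shrink it further.

The `examples/` directory holds short narrative scripts, one per
capability: reflectance spectra, the pulsatile sweep, the correction-model
zoo, and melanin-estimation sensitivity. A thin CLI wraps the same
library calls:

    oximc sweep --melanin 0.01:0.43:9 --sao2 0.5:1.0:6 --seed 1 --out ds.csv
    oximc fit --dataset ds.csv --all --out models.csv
    oximc report --dataset ds.csv --out-dir reports/

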