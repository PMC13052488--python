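"""Quantify skin-tone bias and remove it with melanin-corrected models.

Uses a synthetic SaO2-R-melanin surface (milliseconds instead of a Monte
Carlo sweep) to show the calibration workflow: fit the conventional
quadratic on the light-skin slice only, observe the error growing with
melanin, then fit corrected models over the full grid.
"""
import numpy as np

from oximc import (SurfaceSpec, fit_conventional, fit_corrected, generate,
                   get_model)

# surface generated from the single-quadratic-term correction model
ds = generate(SurfaceSpec(noise_sigma=0.002, seed=1))

conv = fit_conventional(ds, calibration_melanin=0.01, form="quadratic")
print("conventional quadratic, calibrated on f_m = 0.01 only:")
print(f"  max |SaO2 - SpO2| = {conv.max_abs_error:.2f} percentage points")
print("  mean error by melanin fraction:")
per_m = conv.error_map.groupby("f_m")["abs_error_pct"].mean()
for fm, err in per_m.items():
    print(f"    f_m = {fm:.3f}: {err:6.2f} pts")

for name in ("quad_b_m2", "quad_b_cubic", "quad_abc_cubic"):
    fr = fit_corrected(get_model(name), ds)
    print(f"\n{name} ({fr.spec.n_coefficients} coefficients), "
          "fitted over all melanin values:")
    print(f"  max error  {fr.max_abs_error:6.3f} pts   "
          f"avg error {fr.avg_abs_error:6.3f} pts")
    print(f"  Bland-Altman bias {fr.bland.bias * 100:+.3f} pts, "
          f"95% LoA [{fr.bland.loa_lower * 100:+.3f}, "
          f"{fr.bland.loa_upper * 100:+.3f}] pts")

print("\nThe conventional error climbs steadily with melanin (the "
      "simulated skin-tone\nbias); the corrected fits hold the error flat "
      "across all skin tones.")
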