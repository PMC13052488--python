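"""Closed-form SaO2-R-melanin surfaces for fast calibration testing.

A generating calibration model (any ModelSpec with coefficients) is
inverted numerically — for each (melanin, SaO2) cell the R solving
SpO2(R, m) = SaO2 is found by monotone bisection — and optional Gaussian
noise is added to R.  The result is packaged as a RoRDataset
interchangeable with the Monte Carlo-built one, so parameter recovery and
model selection can be exercised in milliseconds without photon transport.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ModelSpec, get_model
from .sweep import RoRDataset

__all__ = ["SurfaceSpec", "generate"]

#: Coefficients reported for the single-quadratic-term correction
#: SpO2 = a*R^2 + (b + c1*m^2)*R + c.
REFERENCE_COEFFS = dict(a=-0.0462, b=-0.2795, c1=-5.4755, c=1.1026)


@dataclass
class SurfaceSpec:
    """Recipe for one synthetic SaO2-R-melanin surface."""
    model: ModelSpec = field(
        default_factory=lambda: get_model("quad_b_m2"))
    coefficients: tuple = (-0.0462, -0.2795, 1.1026, -5.4755)  # a, b, c, c1
    melanin_values: tuple = tuple(np.round(np.linspace(0.01, 0.43, 9), 6))
    sao2_values: tuple = tuple(np.round(np.linspace(0.50, 1.00, 6), 6))
    noise_sigma: float = 0.0
    seed: int = 0
    r_bracket: tuple = (1e-9, 6.0)
    tol: float = 1e-12


def _bisect_monotone(f, lo, hi, tol):
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < tol or fm == 0.0:
            return mid
        if np.sign(fm) == np.sign(flo):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(spec: SurfaceSpec) -> RoRDataset:
    """Invert the generating model on the grid and emit a RoRDataset.

    Raises if the model is not strictly monotone in R (hence not uniquely
    invertible) over the bracket for some cell, naming that cell.
    """
    coeffs = np.asarray(spec.coefficients, dtype=float)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.r_bracket
    rows = []
    for m in spec.melanin_values:
        # monotonicity check on a probe grid at this melanin value
        rr = np.linspace(lo, hi, 64)
        vals = spec.model.evaluate(coeffs, rr, np.full_like(rr, m))
        dv = np.diff(vals)
        if not (np.all(dv < 0) or np.all(dv > 0)):
            raise ValueError(
                f"generating model {spec.model.name} not monotone in R over "
                f"{spec.r_bracket} at melanin={m}")
        for s in spec.sao2_values:
            root = _bisect_monotone(
                lambda r: float(spec.model.evaluate(coeffs, r, m)) - s,
                lo, hi, spec.tol)
            if root is None:
                raise ValueError(
                    f"SpO2(R, m)={s} has no solution in {spec.r_bracket} "
                    f"at cell (melanin={m}, sao2={s})")
            rows.append(dict(f_m=float(m), sao2=float(s), R=float(root)))
    table = pd.DataFrame(rows)
    if spec.noise_sigma > 0:
        table["R"] = table["R"] + rng.normal(
            0.0, spec.noise_sigma, size=len(table))
    # populate AC/DC columns consistently with R (synthetic placeholders:
    # a flat 5% NIR pulse amplitude)
    table["acdc940_raw"] = 0.05
    table["acdc655_raw"] = table["R"] * 0.05
    table["acdc940_smooth"] = table["acdc940_raw"]
    table["acdc655_smooth"] = table["acdc655_raw"]
    table = table[["f_m", "sao2", "acdc655_raw", "acdc940_raw",
                   "acdc655_smooth", "acdc940_smooth", "R"]]
    meta = dict(kind="synthetic_surface", model=spec.model.name,
                coefficients=list(map(float, coeffs)),
                noise_sigma=spec.noise_sigma, seed=spec.seed)
    return RoRDataset(table=table, meta=meta)
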