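"""Wavelength-resolved chromophore absorption and layer absorption assembly.

Absorption coefficients of a tissue layer are volume-fraction-weighted sums
of pure-chromophore spectra, mu_a = sum_i f_i * mu_a_i.  Spectra are bundled
as plain CSV anchor tables (one per chromophore) and resampled onto a common
wavelength grid by piecewise-linear interpolation; queries outside the
tabulated 400-1000 nm range are rejected rather than extrapolated.

All coefficients are stored and returned in mm^-1 (layer geometry is
specified in mm throughout the skin model).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ChromophoreLibrary",
    "EPIDERMAL_BASELINE",
    "epidermal_baseline",
]

#: Constants of the epidermal background absorption term
#: B(lambda) = k0 + k1 * exp(-(lambda - k2) / k3), lambda in nm, B in mm^-1.
EPIDERMAL_BASELINE = (0.122, 42.65, 154.0, 66.2)

_CHROMOPHORES = ("hb", "hbo2", "water", "fat", "melanin")


def epidermal_baseline(wavelength, unit: str = "mm"):
    """Baseline (chromophore-free) epidermal absorption B(lambda), mm^-1.

    ``unit`` selects how the published constants are read: ``"mm"`` (default)
    takes them as mm^-1 directly; ``"cm"`` reads them as cm^-1 and converts.
    """
    k0, k1, k2, k3 = EPIDERMAL_BASELINE
    wavelength = np.asarray(wavelength, dtype=float)
    b = k0 + k1 * np.exp(-(wavelength - k2) / k3)
    if unit == "cm":
        b = b / 10.0
    elif unit != "mm":
        raise ValueError(f"unknown baseline unit {unit!r}")
    return b if b.ndim else float(b)


def _read_fixture(name: str):
    """Read a bundled chromophore CSV -> (wavelengths, mu_a, provenance)."""
    ref = resources.files("oximc.data").joinpath(f"mu_a_{name}.csv")
    wl, mu, provenance, unit = [], [], "", "mm^-1"
    with ref.open("r") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            if "provenance:" in line:
                provenance = line.split("provenance:", 1)[1].strip()
            elif "unit:" in line:
                unit = line.split("unit:", 1)[1].strip()
        elif line.strip():
            data_lines.append(line)
    for row in csv.DictReader(data_lines):
        wl.append(float(row["wavelength_nm"]))
        mu.append(float(row["mu_a"]))
    wl = np.asarray(wl)
    mu = np.asarray(mu)
    if unit == "cm^-1":
        mu = mu / 10.0
    elif unit != "mm^-1":
        raise ValueError(f"fixture {name}: unknown unit {unit!r}")
    order = np.argsort(wl)
    return wl[order], mu[order], provenance


@dataclass
class ChromophoreLibrary:
    """Tabulated absorption spectra of all skin chromophores on a common grid.

    Attributes
    ----------
    wavelengths : ndarray
        Wavelength grid in nm (default 400-1000 nm at 1 nm).
    spectra : dict of str -> ndarray
        mu_a in mm^-1 per chromophore ("hb", "hbo2", "water", "fat",
        "melanin") resampled onto ``wavelengths``.
    provenance : dict of str -> str
        Source string recorded for each bundled spectrum.
    baseline_unit : str
        How the epidermal-baseline constants are interpreted ("mm" or "cm").
    """

    wavelengths: np.ndarray
    spectra: dict = field(repr=False)
    provenance: dict = field(default_factory=dict, repr=False)
    baseline_unit: str = "mm"

    @classmethod
    def default(cls, wavelength_step: float = 1.0, baseline_unit: str = "mm"):
        """Load the bundled fixture tables onto a 400-1000 nm grid."""
        grid = np.arange(400.0, 1000.0 + 0.5 * wavelength_step,
                         wavelength_step)
        spectra, prov = {}, {}
        for name in _CHROMOPHORES:
            wl, mu, p = _read_fixture(name)
            spectra[name] = np.interp(grid, wl, mu)
            prov[name] = p
        lib = cls(wavelengths=grid, spectra=spectra, provenance=prov,
                  baseline_unit=baseline_unit)
        lib._validate()
        return lib

    def _validate(self):
        for name, mu in self.spectra.items():
            if not np.all(mu > 0):
                raise ValueError(f"spectrum {name} not strictly positive")
            if not np.all(np.isfinite(mu)):
                raise ValueError(f"spectrum {name} not finite")

    # -- low-level lookup ---------------------------------------------------

    def mu_a(self, chromophore: str, wavelength) -> float:
        """mu_a of a pure chromophore at ``wavelength`` (nm), mm^-1."""
        wavelength = float(wavelength)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside tabulated range "
                f"[{lo}, {hi}] nm")
        return float(np.interp(wavelength, self.wavelengths,
                               self.spectra[chromophore]))

    def baseline(self, wavelength) -> float:
        """Epidermal background absorption B(lambda) in mm^-1."""
        self.mu_a("melanin", wavelength)  # range check
        return float(epidermal_baseline(wavelength, self.baseline_unit))

    # -- mixture rules ------------------------------------------------------

    def blood_mu_a(self, sao2: float, wavelength) -> float:
        """Whole-blood absorption at arterial saturation ``sao2``.

        (1 - sao2) * mu_a_Hb + sao2 * mu_a_HbO2, in mm^-1.
        """
        if not 0.0 <= sao2 <= 1.0:
            raise ValueError(f"sao2 {sao2} outside [0, 1]")
        return ((1.0 - sao2) * self.mu_a("hb", wavelength)
                + sao2 * self.mu_a("hbo2", wavelength))

    def epidermis_mu_a(self, wavelength, f_m: float, f_w: float) -> float:
        """Epidermal absorption: melanin + water + residual baseline."""
        if f_m < 0 or f_w < 0 or f_m + f_w > 1.0 + 1e-12:
            raise ValueError(
                f"epidermal fractions f_m={f_m}, f_w={f_w} invalid")
        return (f_m * self.mu_a("melanin", wavelength)
                + f_w * self.mu_a("water", wavelength)
                + (1.0 - f_m - f_w) * self.baseline(wavelength))

    def generic_layer_baseline(self, layer, wavelength) -> float:
        """Non-blood absorption of a dermal/subcutaneous layer.

        f_w * mu_a_water + f_f * mu_a_fat + (1 - f_b - f_w - f_f) * B.
        ``layer`` provides volume fractions f_b, f_w, f_f.
        """
        total = layer.f_b + layer.f_w + layer.f_f
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"layer {getattr(layer, 'name', '?')}: fractions sum {total} > 1")
        return (layer.f_w * self.mu_a("water", wavelength)
                + layer.f_f * self.mu_a("fat", wavelength)
                + (1.0 - total) * self.baseline(wavelength))
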