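"""Pulsatile sweep: diastole/systole pairs -> AC/DC -> ratio-of-ratios.

For every (melanin fraction, SaO2) grid point and each of the two oximetry
wavelengths (655 and 940 nm) a diastolic and a systolic reflectance run are
performed with a *shared* photon seed (common random numbers), so the small
AC/DC difference is estimated with far lower variance than independent runs
would give.  AC/DC over melanin is then smoothed by an exponential fit
A*exp(B*m)+C at each (wavelength, SaO2), and the ratio-of-ratios

    R = (AC/DC at 655 nm) / (AC/DC at 940 nm)

is tabulated on the grid.  The resulting SaO2-R-melanin table is the input
of the calibration stage.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .mc import MCConfig, ProbeGeometry, run_mc
from .tissue import DIASTOLE, SYSTOLE, PhysiologyState, SkinStack

__all__ = ["SweepGrid", "SmoothingFit", "RoRDataset",
           "ac_dc", "ratio_of_ratios", "plan_sweep", "smooth_acdc",
           "build_dataset"]


def ac_dc(r_diastolic: float, r_systolic: float) -> float:
    """Pulsatile amplitude over baseline: (Rd - Rs) / Rd.

    Negative values (systolic brighter than diastolic — physically
    anomalous, possible at low photon counts) are returned as-is with a
    warning.
    """
    if r_diastolic <= 0:
        raise ValueError("diastolic reflectance must be positive")
    val = (r_diastolic - r_systolic) / r_diastolic
    if val < 0:
        warnings.warn("negative AC/DC (systolic reflectance exceeds "
                      "diastolic); physically anomalous", stacklevel=2)
    return val


def ratio_of_ratios(acdc_655: float, acdc_940: float) -> float:
    """R = AC/DC(655 nm) / AC/DC(940 nm)."""
    if acdc_940 == 0:
        raise ValueError("AC/DC at 940 nm is zero")
    return acdc_655 / acdc_940


@dataclass(frozen=True)
class SweepGrid:
    """Melanin x SaO2 x wavelength x phase grid of the pulsatile sweep."""
    melanin_values: tuple = tuple(np.round(np.arange(0.01, 0.431, 0.01), 4))
    sao2_values: tuple = tuple(np.round(np.arange(0.50, 1.001, 0.05), 4))
    wavelengths: tuple = (655.0, 940.0)

    def __post_init__(self):
        for name, vals in (("melanin", self.melanin_values),
                           ("sao2", self.sao2_values),
                           ("wavelengths", self.wavelengths)):
            arr = np.asarray(vals)
            if arr.size == 0:
                raise ValueError(f"{name} grid is empty")
            if not (np.all(np.diff(arr) > 0)):
                raise ValueError(f"{name} values must be sorted, unique")

    @classmethod
    def reduced(cls, n_melanin: int = 9, n_sao2: int = 6):
        """Desk-scale grid spanning the same ranges with fewer points."""
        return cls(
            melanin_values=tuple(np.round(
                np.linspace(0.01, 0.43, n_melanin), 6)),
            sao2_values=tuple(np.round(
                np.linspace(0.50, 1.00, n_sao2), 6)))

    @property
    def n_runs(self) -> int:
        return (len(self.wavelengths) * len(self.melanin_values)
                * len(self.sao2_values) * 2)


def plan_sweep(grid: SweepGrid, master_seed: int = 0) -> pd.DataFrame:
    """Enumerate all (wavelength, f_m, sao2, phase) runs with seeds.

    The diastole and systole runs of a pair share their seed (common
    random numbers); seeds are derived deterministically from the master.
    """
    rows = []
    pair_idx = 0
    for wl in grid.wavelengths:
        for fm in grid.melanin_values:
            for s in grid.sao2_values:
                ss = np.random.SeedSequence(
                    [int(master_seed) & 0x7FFFFFFF, pair_idx])
                seed = int(ss.generate_state(1, dtype=np.uint64)[0])
                for phase in (DIASTOLE, SYSTOLE):
                    rows.append(dict(wavelength=wl, f_m=fm, sao2=s,
                                     phase=phase, seed=seed))
                pair_idx += 1
    manifest = pd.DataFrame(rows)
    assert len(manifest) == grid.n_runs
    return manifest


@dataclass
class SmoothingFit:
    """Exponential AC/DC(m) = A*exp(B*m) + C fit at one (wavelength, SaO2)."""
    A: float
    B: float
    C: float
    converged: bool
    rmse: float

    def __call__(self, m):
        return self.A * np.exp(self.B * np.asarray(m, dtype=float)) + self.C


def smooth_acdc(melanin: np.ndarray, acdc: np.ndarray) -> SmoothingFit:
    """Fit AC/DC versus melanin with A*exp(B*m)+C.

    The fit minimises *relative* residuals (weights 1/|y|): AC/DC decays
    over one to two decades across the melanin range, and unweighted least
    squares would fit the bright light-skin points only, badly overshooting
    the dark-skin tail that dominates the ratio-of-ratios there.

    Needs at least 4 melanin points.  Nearly constant data falls back to a
    constant fit; non-convergence falls back to pass-through of the raw
    values (rmse reported against that fallback) with a warning.
    """
    m = np.asarray(melanin, dtype=float)
    y = np.asarray(acdc, dtype=float)
    if m.size < 4:
        raise ValueError("smoothing needs at least 4 melanin points")
    if np.std(y) < 1e-14:
        c = float(np.mean(y))
        return SmoothingFit(0.0, 0.0, c, True, 0.0)
    p0 = (y[0] - y[-1], -1.0, y[-1])
    sigma = np.maximum(np.abs(y), 1e-12 * np.max(np.abs(y)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(lambda x, a, b, c: a * np.exp(b * x) + c,
                                m, y, p0=p0, sigma=sigma, maxfev=20000)
        fit = SmoothingFit(*map(float, popt), True, 0.0)
        fit.rmse = float(np.sqrt(np.mean((fit(m) - y) ** 2)))
        return fit
    except RuntimeError:
        warnings.warn("exponential smoothing did not converge; raw AC/DC "
                      "passed through", stacklevel=2)
        return SmoothingFit(0.0, 0.0, float(np.mean(y)), False,
                            float(np.std(y)))


@dataclass
class RoRDataset:
    """SaO2-R-melanin table with raw and smoothed AC/DC columns.

    ``table`` columns: f_m, sao2, acdc655_raw, acdc940_raw, acdc655_smooth,
    acdc940_smooth, R (plus the raw per-phase detected reflectances when
    built by Monte Carlo).  ``meta`` carries provenance: seed, photon count
    and every model switch.
    """
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    CORE_COLUMNS = ("f_m", "sao2", "acdc655_raw", "acdc940_raw",
                    "acdc655_smooth", "acdc940_smooth", "R")

    def __len__(self):
        return len(self.table)

    @property
    def melanin_values(self):
        return np.sort(self.table["f_m"].unique())

    @property
    def sao2_values(self):
        return np.sort(self.table["sao2"].unique())

    def columns_for(self, smoothed: bool = True):
        return (("acdc655_smooth", "acdc940_smooth") if smoothed
                else ("acdc655_raw", "acdc940_raw"))

    def to_csv(self, path, sidecar: bool = True):
        self.table.to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.meta, fh, indent=2, default=str)

    @classmethod
    def from_csv(cls, path):
        table = pd.read_csv(path)
        meta = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(table=table, meta=meta)


def build_dataset(grid: SweepGrid,
                  stack: SkinStack | None = None,
                  probe: ProbeGeometry | None = None,
                  cfg: MCConfig | None = None,
                  smoothing: bool = True,
                  p: float = 0.5, E: float = 0.79,
                  progress: bool = False) -> RoRDataset:
    """Execute the sweep manifest and assemble the SaO2-R dataset.

    Smoothing (exponential in melanin, per wavelength and SaO2) replaces the
    raw AC/DC in the R computation by default; both are stored.
    """
    stack = stack or SkinStack.default()
    probe = probe or ProbeGeometry()
    cfg = cfg or MCConfig()
    manifest = plan_sweep(grid, cfg.rng_seed)

    refl = {}
    it = manifest.itertuples()
    for run in it:
        state = PhysiologyState(f_m=run.f_m, sao2=run.sao2,
                                phase=run.phase, p=p, E=E)
        slab = stack.build_slab(state, run.wavelength)
        res = run_mc(slab, probe, replace(cfg, rng_seed=run.seed),
                     wavelength=run.wavelength)
        refl[(run.wavelength, run.f_m, run.sao2, run.phase)] = \
            res.detected_reflectance
        if progress:
            print(f"  run {len(refl)}/{len(manifest)}", end="\r")

    rows = []
    for fm in grid.melanin_values:
        for s in grid.sao2_values:
            row = dict(f_m=fm, sao2=s)
            for wl in grid.wavelengths:
                rd = refl[(wl, fm, s, DIASTOLE)]
                rs = refl[(wl, fm, s, SYSTOLE)]
                key = int(round(wl))
                row[f"r_diastolic_{key}"] = rd
                row[f"r_systolic_{key}"] = rs
                row[f"acdc{key}_raw"] = ac_dc(rd, rs)
            rows.append(row)
    table = pd.DataFrame(rows)

    can_smooth = smoothing and len(grid.melanin_values) >= 4
    for wl in grid.wavelengths:
        key = int(round(wl))
        smooth_col = np.empty(len(table))
        for s in grid.sao2_values:
            mask = table["sao2"] == s
            m = table.loc[mask, "f_m"].to_numpy()
            y = table.loc[mask, f"acdc{key}_raw"].to_numpy()
            smooth_col[mask.to_numpy()] = smooth_acdc(m, y)(m) if can_smooth \
                else y
        table[f"acdc{key}_smooth"] = smooth_col

    suffix = "smooth" if can_smooth else "raw"
    table["R"] = table[f"acdc655_{suffix}"] / table[f"acdc940_{suffix}"]

    meta = dict(
        master_seed=cfg.rng_seed, n_photons=cfg.n_photons,
        smoothing=bool(can_smooth), p=p, E=E,
        pulsatile_mode=stack.pulsatile_mode,
        systolic_fb_in_mu_a=stack.systolic_fb_in_mu_a,
        systole_geometry=stack.systole_geometry,
        baseline_unit=stack.library.baseline_unit,
        scattering=dict(C1=stack.scattering.C1,
                        k_alpha=stack.scattering.k_alpha,
                        k_beta=stack.scattering.k_beta),
        probe=dict(source_radius=probe.source_radius,
                   detector_radius=probe.detector_radius,
                   lateral_bound=probe.lateral_bound,
                   max_depth=probe.max_depth),
        wavelengths=list(grid.wavelengths),
    )
    return RoRDataset(table=table, meta=meta)
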