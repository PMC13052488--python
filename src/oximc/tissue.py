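"""Six-layer skin stack resolved into per-wavelength optical slabs.

The model covers the epidermis, capillary loops, upper vascular plexus,
reticular dermis, deep vascular plexus and subcutis.  For a given melanin
volume fraction, arterial saturation and cardiac phase it produces, per
layer, the absorption coefficient mu_a, scattering coefficient mu_s,
anisotropy g, refractive index n and thickness d — the inputs of the
Monte Carlo transport engine.

Physics implemented here:

* vessel self-shielding (pigment packaging): blood confined to vessels of
  finite diameter absorbs less than homogeneously distributed blood; the
  effective blood fraction is scaled by
  S(x) = 1 / (1 + 1.007 * (x/2)**1.228) with x = mu_a_blood * vessel_diameter;
* pulsatile dynamics: during systole the arterial blood fraction of the
  vascular plexus layers rises by the pulsatile constant p and the layer
  expands by 1/E, with the absorption coefficient diluted by E;
* a power-law reduced scattering spectrum mu_s' = mu_s0 * (577/lambda**C1) * C2
  with C2 = 400**(C1-1) chosen so mu_s'(400 nm) is independent of C1; the
  epidermis additionally steepens and amplifies its scattering with melanin
  through calibration functions alpha(f_m) and beta(f_m).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .chromophores import ChromophoreLibrary

__all__ = [
    "LayerSpec", "PhysiologyState", "ScatteringParams", "OpticalSlab",
    "SkinStack", "self_shield", "mu_s_from_reduced",
    "load_layer_table", "DIASTOLE", "SYSTOLE",
]

DIASTOLE = "diastole"
SYSTOLE = "systole"

#: Default pulsatile layers: the dense vascular plexuses.
DEFAULT_PULSATILE = ("capillary_loops", "upper_plexus", "deep_plexus")


def self_shield(mu_a_blood: float, vd: float) -> float:
    """Vessel self-shielding factor S in (0, 1].

    S = 1 / (1 + 1.007 * (mu_a_blood * vd / 2) ** 1.228); S = 1 when the
    product vanishes (no vessels, or transparent blood).
    """
    if mu_a_blood < 0 or vd < 0:
        raise ValueError("mu_a_blood and vd must be non-negative")
    x = mu_a_blood * vd / 2.0
    if x == 0.0:
        return 1.0
    return 1.0 / (1.0 + 1.007 * x ** 1.228)


def mu_s_from_reduced(mu_s_prime: float, g: float) -> float:
    """Similarity relation mu_s = mu_s' / (1 - g)."""
    if g >= 1.0:
        raise ValueError("anisotropy g must be < 1")
    return mu_s_prime / (1.0 - g)


@dataclass(frozen=True)
class LayerSpec:
    """Structural and compositional description of one skin layer."""
    name: str
    f_m: float = 0.0   # melanin volume fraction (epidermis only)
    f_b: float = 0.0   # blood volume fraction
    f_w: float = 0.0   # water volume fraction
    f_f: float = 0.0   # fat volume fraction
    d: float = 1.0     # thickness, mm
    n: float = 1.4     # refractive index
    vd: float = 0.0    # mean vessel diameter, mm
    pulsatile: bool = False
    mu_s0: float = 2.5  # scattering scale at 577 nm, mm^-1
    # affine anisotropy model g(lambda) = g0 + g1 * lambda, clipped to [0, .99]
    anisotropy_params: tuple = (0.62, 0.00029)

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError(f"layer {self.name}: thickness must be > 0")
        if self.n < 1:
            raise ValueError(f"layer {self.name}: refractive index < 1")
        if self.vd < 0:
            raise ValueError(f"layer {self.name}: vessel diameter < 0")
        for frac in (self.f_m, self.f_b, self.f_w, self.f_f):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"layer {self.name}: fraction {frac} "
                                 "outside [0, 1]")


@dataclass(frozen=True)
class PhysiologyState:
    """Melanin content, arterial saturation and cardiac phase.

    p is the pulsatile constant (relative systolic increase in arterial
    blood volume); E the systolic layer expansion factor.
    """
    f_m: float
    sao2: float
    phase: str = DIASTOLE
    p: float = 0.5
    E: float = 0.79

    def __post_init__(self):
        if not 0.01 <= self.f_m <= 0.43:
            raise ValueError(f"f_m {self.f_m} outside [0.01, 0.43]")
        if not 0.0 <= self.sao2 <= 1.0:
            raise ValueError(f"sao2 {self.sao2} outside [0, 1]")
        if self.phase not in (DIASTOLE, SYSTOLE):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not 0.0 < self.E <= 1.0:
            raise ValueError("expansion factor E must be in (0, 1]")
        if self.p < 0:
            raise ValueError("pulsatile constant p must be >= 0")


@dataclass(frozen=True)
class ScatteringParams:
    """Power-law scattering constants and melanin calibration slopes.

    The global spectrum uses curvature C1 and offset C2 = 400**(C1-1);
    the epidermis replaces (C1, C2) by (alpha(f_m)*C1, beta(f_m)*400**(C1'-1))
    with alpha(f_m) = 1 + (f_m - f_m_ref) * k_alpha and
    beta(f_m) = 1 + (f_m - f_m_ref) * k_beta, so both reduce to the global
    law at the light-skin reference f_m_ref.
    """
    C1: float = 0.5
    k_alpha: float = 22.0 / 3.0
    k_beta: float = 20.0
    f_m_ref: float = 0.01

    @property
    def C2(self) -> float:
        return 400.0 ** (self.C1 - 1.0)

    def alpha(self, f_m: float) -> float:
        return 1.0 + (f_m - self.f_m_ref) * self.k_alpha

    def beta(self, f_m: float) -> float:
        return 1.0 + (f_m - self.f_m_ref) * self.k_beta


@dataclass(frozen=True)
class OpticalSlab:
    """Per-wavelength optical properties of the resolved layer stack."""
    mu_a: np.ndarray       # mm^-1, top-down
    mu_s: np.ndarray       # mm^-1
    g: np.ndarray
    n: np.ndarray
    thickness: np.ndarray  # mm
    ambient_index: float = 1.0
    names: tuple = ()

    def __post_init__(self):
        for arr, label, lo in ((self.mu_a, "mu_a", 0.0),
                               (self.mu_s, "mu_s", 0.0),
                               (self.thickness, "thickness", None)):
            a = np.asarray(arr, dtype=float)
            if label == "thickness":
                if np.any(a <= 0):
                    raise ValueError("thickness must be > 0")
            elif np.any(a < lo):
                raise ValueError(f"{label} must be >= {lo}")
        if np.any(np.asarray(self.g) < 0) or np.any(np.asarray(self.g) >= 1):
            raise ValueError("anisotropy must be in [0, 1)")

    @property
    def n_layers(self) -> int:
        return len(self.mu_a)

    @property
    def total_thickness(self) -> float:
        return float(np.sum(self.thickness))


def load_layer_table(path=None) -> list[LayerSpec]:
    """Read a layer table CSV (bundled six-layer stack by default)."""
    if path is None:
        ref = resources.files("oximc.data").joinpath("skin_layers.csv")
        with ref.open("r") as fh:
            lines = fh.readlines()
    else:
        with open(path) as fh:
            lines = fh.readlines()
    rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    layers = []
    for row in csv.DictReader(rows):
        layers.append(LayerSpec(
            name=row["name"],
            f_m=float(row["Cm"]), f_b=float(row["Cb"]),
            f_w=float(row["Cw"]), f_f=float(row["Cf"]),
            d=float(row["d_mm"]), n=float(row["n"]),
            vd=float(row["vd_mm"]),
            pulsatile=bool(int(row.get("pulsatile", 0))),
            mu_s0=float(row.get("mu_s0", 2.5)),
        ))
    return layers


@dataclass
class SkinStack:
    """The layer stack plus the model switches that resolve it into slabs.

    Switches (all default to the readings adopted in docs/methods.md):

    * ``pulsatile_mode``: "relative" (f_b_sys = (1+p) * f_b_dia) or
      "additive" (f_b_sys = f_b_dia + p * S);
    * ``systolic_fb_in_mu_a``: use the systolic blood fraction inside the
      systolic absorption coefficient (True) or the literal diastolic one;
    * ``systole_geometry``: how the systolic expansion of pulsatile layers
      is realised.  "equivalent" (default) keeps the geometry fixed and
      drops the dilution factor E from the coefficients — the exact
      first-order equivalent of expansion, since plane-parallel transport
      depends on the optical depths mu*d, and it preserves the
      common-random-numbers pairing of diastole/systole runs.  "expand"
      scales pulsatile-layer thickness by 1/E and dilutes both mu_a and
      mu_s by E (scatterers and baseline absorbers are conserved, so their
      optical depths stay fixed while blood optical depth grows).
    """
    layers: Sequence[LayerSpec]
    library: ChromophoreLibrary
    scattering: ScatteringParams = field(default_factory=ScatteringParams)
    ambient_index: float = 1.0
    pulsatile_mode: str = "relative"
    systolic_fb_in_mu_a: bool = True
    systole_geometry: str = "equivalent"

    @classmethod
    def default(cls, library: ChromophoreLibrary | None = None, **kwargs):
        if library is None:
            library = ChromophoreLibrary.default()
        return cls(layers=load_layer_table(), library=library, **kwargs)

    # -- per-layer quantities ------------------------------------------------

    def diastolic_blood_fraction(self, layer: LayerSpec,
                                 state: PhysiologyState,
                                 wavelength) -> float:
        """Self-shielded diastolic blood volume fraction (wavelength
        dependent through the shielding factor)."""
        if layer.f_b == 0.0:
            return 0.0
        mu_b = self.library.blood_mu_a(state.sao2, wavelength)
        return layer.f_b * self_shield(mu_b, layer.vd)

    def systolic_blood_fraction(self, layer: LayerSpec,
                                state: PhysiologyState,
                                wavelength) -> float:
        """Systolic blood fraction of a pulsatile layer; non-pulsatile
        layers keep their diastolic value."""
        fbd = self.diastolic_blood_fraction(layer, state, wavelength)
        if not layer.pulsatile:
            return fbd
        if self.pulsatile_mode == "relative":
            return (1.0 + state.p) * fbd
        if self.pulsatile_mode == "additive":
            mu_b = self.library.blood_mu_a(state.sao2, wavelength)
            return fbd + state.p * self_shield(mu_b, layer.vd) * layer.f_b
        raise ValueError(f"unknown pulsatile_mode {self.pulsatile_mode!r}")

    def layer_mu_a(self, layer: LayerSpec, state: PhysiologyState,
                   wavelength) -> float:
        """Layer absorption coefficient for the state's cardiac phase."""
        if layer.f_m > 0.0 or layer.name == "epidermis":
            # phase-invariant: the epidermis carries no blood
            return self.library.epidermis_mu_a(wavelength, state.f_m,
                                               layer.f_w)
        base = self.library.generic_layer_baseline(layer, wavelength)
        mu_b = self.library.blood_mu_a(state.sao2, wavelength)
        fbd = self.diastolic_blood_fraction(layer, state, wavelength)
        if state.phase == DIASTOLE or not layer.pulsatile:
            return fbd * mu_b + base
        fbs = (self.systolic_blood_fraction(layer, state, wavelength)
               if self.systolic_fb_in_mu_a else fbd)
        dilution = state.E if self.systole_geometry == "expand" else 1.0
        return dilution * (fbs * mu_b + base)

    def reduced_scattering(self, layer: LayerSpec, state: PhysiologyState,
                           wavelength) -> float:
        """Power-law reduced scattering; melanin-dependent in the epidermis."""
        wavelength = float(wavelength)
        if wavelength <= 0:
            raise ValueError("wavelength must be positive")
        sp = self.scattering
        if layer.name == "epidermis":
            c1 = sp.alpha(state.f_m) * sp.C1
            c2 = sp.beta(state.f_m) * 400.0 ** (c1 - 1.0)
        else:
            c1, c2 = sp.C1, sp.C2
        return layer.mu_s0 * (577.0 / wavelength ** c1) * c2

    def anisotropy(self, layer: LayerSpec, wavelength) -> float:
        """Affine anisotropy model, clipped to [0, 0.99]."""
        g0, g1 = layer.anisotropy_params
        return float(np.clip(g0 + g1 * float(wavelength), 0.0, 0.99))

    def _is_expanded(self, layer: LayerSpec, state: PhysiologyState) -> bool:
        return (state.phase == SYSTOLE and layer.pulsatile
                and self.systole_geometry == "expand")

    def layer_thickness(self, layer: LayerSpec, state: PhysiologyState
                        ) -> float:
        if self._is_expanded(layer, state):
            return layer.d / state.E
        return layer.d

    # -- slab assembly -------------------------------------------------------

    def build_slab(self, state: PhysiologyState, wavelength) -> OpticalSlab:
        """Resolve the stack into an OpticalSlab at one wavelength."""
        mu_a, mu_s, g, n, d = [], [], [], [], []
        for layer in self.layers:
            gi = self.anisotropy(layer, wavelength)
            msp = self.reduced_scattering(layer, state, wavelength)
            ms = mu_s_from_reduced(msp, gi)
            if self._is_expanded(layer, state):
                ms *= state.E  # scatterer dilution in the expanded layer
            mu_a.append(self.layer_mu_a(layer, state, wavelength))
            mu_s.append(ms)
            g.append(gi)
            n.append(layer.n)
            d.append(self.layer_thickness(layer, state))
        return OpticalSlab(
            mu_a=np.array(mu_a), mu_s=np.array(mu_s), g=np.array(g),
            n=np.array(n), thickness=np.array(d),
            ambient_index=self.ambient_index,
            names=tuple(layer.name for layer in self.layers))

    def with_config(self, **kwargs) -> "SkinStack":
        return replace(self, **kwargs)
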