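"""Key-value configuration files for the simulation switches.

Format: one ``key = value`` pair per line; ``#`` starts a comment; values
are parsed as bool/int/float/tuple-of-strings where possible.  Recognised
keys (all optional) and their defaults:

    baseline_unit        = mm        # epidermal baseline constants unit (mm|cm)
    pulsatile_mode       = relative  # systolic blood fraction rule (relative|additive)
    systolic_fb_in_mu_a  = true      # systolic mu_a uses the systolic blood fraction
    systole_geometry     = equivalent # systolic expansion: equivalent|expand
    C1                   = 0.5       # global scattering curvature
    k_alpha              = 7.3333333 # melanin slope of the epidermal curvature
    k_beta               = 20.0      # melanin slope of the epidermal magnitude
    p                    = 0.5       # pulsatile constant
    E                    = 0.79      # systolic layer expansion factor
    smoothing            = true      # exponential AC/DC smoothing over melanin
    n_photons            = 100000
    source_radius        = 0.2       # mm
    detector_radius      = 0.0667    # mm
    lateral_bound        = 3.0       # mm
    max_depth            = 8.0       # mm
    layer_table          =           # path to a CSV overriding the bundled stack
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .chromophores import ChromophoreLibrary
from .mc import MCConfig, ProbeGeometry
from .tissue import ScatteringParams, SkinStack, load_layer_table

__all__ = ["Settings", "load_config", "parse_kv"]

_BOOL = {"true": True, "false": False, "yes": True, "no": False,
         "1": True, "0": False}


def _coerce(value: str):
    v = value.strip()
    low = v.lower()
    if low in _BOOL:
        return _BOOL[low]
    try:
        return int(v)
    except ValueError:
        pass
    try:
        return float(v)
    except ValueError:
        pass
    return v


def parse_kv(text: str) -> dict:
    out = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key = value")
        key, value = line.split("=", 1)
        out[key.strip()] = _coerce(value)
    return out


@dataclass
class Settings:
    """All model switches resolved; factory for the configured objects."""
    baseline_unit: str = "mm"
    pulsatile_mode: str = "relative"
    systolic_fb_in_mu_a: bool = True
    systole_geometry: str = "equivalent"
    C1: float = 0.5
    k_alpha: float = 22.0 / 3.0
    k_beta: float = 20.0
    p: float = 0.5
    E: float = 0.79
    smoothing: bool = True
    n_photons: int = 100_000
    source_radius: float = 0.2
    detector_radius: float = 0.0667
    lateral_bound: float = 3.0
    max_depth: float = 8.0
    layer_table: str = ""

    def make_stack(self) -> SkinStack:
        library = ChromophoreLibrary.default(
            baseline_unit=self.baseline_unit)
        layers = load_layer_table(self.layer_table or None)
        return SkinStack(
            layers=layers, library=library,
            scattering=ScatteringParams(C1=self.C1, k_alpha=self.k_alpha,
                                        k_beta=self.k_beta),
            pulsatile_mode=self.pulsatile_mode,
            systolic_fb_in_mu_a=self.systolic_fb_in_mu_a,
            systole_geometry=self.systole_geometry)

    def make_probe(self) -> ProbeGeometry:
        return ProbeGeometry(source_radius=self.source_radius,
                             detector_radius=self.detector_radius,
                             lateral_bound=self.lateral_bound,
                             max_depth=self.max_depth)

    def make_mc_config(self, seed: int = 0, n_photons: int | None = None
                       ) -> MCConfig:
        return MCConfig(n_photons=n_photons or self.n_photons,
                        rng_seed=seed)


def load_config(path=None, **overrides) -> Settings:
    values = {}
    if path:
        with open(path) as fh:
            values.update(parse_kv(fh.read()))
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(Settings.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Settings(**values)
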