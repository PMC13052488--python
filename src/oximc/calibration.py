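"""SpO2 calibration models: conventional and melanin-corrected ratio-of-ratios.

The conventional clinical mapping is linear or quadratic in the ratio of
ratios R:

    SpO2 = b*R + c            (linear)
    SpO2 = a*R^2 + b*R + c    (quadratic)

calibrated on light-skin data only.  The corrected families add melanin
polynomials (m = melanin volume fraction) to one or more coefficient slots,
e.g. the single-quadratic-term correction

    SpO2 = a*R^2 + (b + c1*m^2)*R + c,

or vertex-form variants alpha*(R - h + P(m))^2 + k + Q(m).  Every
non-vertex family is linear in its coefficients and is fitted by exact
least squares over the whole melanin x SaO2 grid; vertex forms use
deterministic multi-start nonlinear least squares.

Error metrics follow the percentage-point convention:
|SaO2_true - SpO2_predicted| * 100.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["ModelSpec", "FitResult", "BlandAltman",
           "model_zoo", "corrected_models", "conventional_models",
           "evaluate_model", "fit_conventional", "fit_corrected",
           "bland_altman", "melanin_sensitivity", "fit_all"]

_CUBIC = (3, 2, 1)
_BASE_SLOTS = {"linear": ("b", "c"), "quadratic": ("a", "b", "c"),
               "vertex": ("alpha", "h", "k")}


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one calibration model.

    ``slots`` maps coefficient slots to the melanin powers added there,
    e.g. ``(("b", (2,)),)`` for SpO2 = a*R^2 + (b + c1*m^2)*R + c.
    ``shared`` re-uses the same melanin coefficients in every listed slot.
    """
    name: str
    base: str = "quadratic"                 # linear | quadratic | vertex
    slots: tuple = ()                        # ((slot, (powers...)), ...)
    shared: bool = False

    def __post_init__(self):
        if self.base not in _BASE_SLOTS:
            raise ValueError(f"unknown base {self.base!r}")
        valid = {"a", "b", "c"} if self.base != "vertex" else {"h", "k"}
        for slot, powers in self.slots:
            if slot not in valid:
                raise ValueError(f"slot {slot!r} invalid for base "
                                 f"{self.base!r}")
            if not powers:
                raise ValueError("empty power list")

    # -- bookkeeping ---------------------------------------------------------

    @property
    def base_names(self) -> tuple:
        return _BASE_SLOTS[self.base]

    @property
    def melanin_coeff_count(self) -> int:
        if not self.slots:
            return 0
        if self.shared:
            return len(self.slots[0][1])
        return sum(len(p) for _, p in self.slots)

    @property
    def n_coefficients(self) -> int:
        return len(self.base_names) + self.melanin_coeff_count

    @property
    def is_vertex(self) -> bool:
        return self.base == "vertex"

    def coefficient_names(self) -> list:
        names = list(self.base_names)
        if self.shared:
            names += [f"c{i + 1}" for i in range(len(self.slots[0][1]))]
        else:
            k = 0
            for _, powers in self.slots:
                for _ in powers:
                    k += 1
                    names.append(f"c{k}")
        return names

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(dict(name=self.name, base=self.base,
                               slots=[[s, list(p)] for s, p in self.slots],
                               shared=self.shared))

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(name=d["name"], base=d["base"],
                   slots=tuple((s, tuple(p)) for s, p in d["slots"]),
                   shared=bool(d["shared"]))

    # -- evaluation ----------------------------------------------------------

    def _melanin_terms(self, coeffs, m):
        """Per-slot melanin polynomial values, dict slot -> array."""
        m = np.asarray(m, dtype=float)
        out = {}
        base_n = len(self.base_names)
        if self.shared and self.slots:
            powers = self.slots[0][1]
            cs = coeffs[base_n:base_n + len(powers)]
            poly = sum(ci * m ** p for ci, p in zip(cs, powers))
            for slot, _ in self.slots:
                out[slot] = poly
        else:
            k = base_n
            for slot, powers in self.slots:
                cs = coeffs[k:k + len(powers)]
                k += len(powers)
                out[slot] = sum(ci * m ** p for ci, p in zip(cs, powers))
        return out

    def evaluate(self, coeffs, R, m):
        """SpO2 (fraction) at ratio-of-ratios R and melanin fraction m."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.size != self.n_coefficients:
            raise ValueError(f"{self.name}: expected {self.n_coefficients} "
                             f"coefficients, got {coeffs.size}")
        R = np.asarray(R, dtype=float)
        m = np.asarray(m, dtype=float)
        terms = self._melanin_terms(coeffs, m)
        zero = np.zeros(np.broadcast(R, m).shape)
        if self.base == "vertex":
            alpha, h, k = coeffs[:3]
            shift = terms.get("h", zero)
            lift = terms.get("k", zero)
            return alpha * (R - h + shift) ** 2 + k + lift
        if self.base == "linear":
            b, c = coeffs[:2]
            return ((b + terms.get("b", zero)) * R
                    + c + terms.get("c", zero))
        a, b, c = coeffs[:3]
        return ((a + terms.get("a", zero)) * R ** 2
                + (b + terms.get("b", zero)) * R
                + c + terms.get("c", zero))

    def design_matrix(self, R, m):
        """Least-squares design matrix (linear-in-coefficients bases only)."""
        if self.is_vertex:
            raise ValueError("vertex forms are not linear in coefficients")
        R = np.asarray(R, dtype=float)
        m = np.asarray(m, dtype=float)
        basis = {"a": R ** 2, "b": R, "c": np.ones_like(R)}
        cols = ([basis["a"], basis["b"], basis["c"]]
                if self.base == "quadratic" else [basis["b"], basis["c"]])
        if self.shared and self.slots:
            slot_sum = sum(basis[s] for s, _ in self.slots)
            for p in self.slots[0][1]:
                cols.append(m ** p * slot_sum)
        else:
            for slot, powers in self.slots:
                for p in powers:
                    cols.append(m ** p * basis[slot])
        return np.column_stack(cols)


def evaluate_model(spec: ModelSpec, coeffs, R, m):
    """Functional alias for ``spec.evaluate``."""
    return spec.evaluate(coeffs, R, m)


# -- the zoo -----------------------------------------------------------------

def conventional_models() -> list:
    return [ModelSpec("conventional_linear", base="linear"),
            ModelSpec("conventional_quadratic", base="quadratic")]


def corrected_models() -> list:
    """The 25 melanin-corrected candidate forms, grouped by coefficient
    count: one 12-coefficient, four 9-coefficient, five 6-coefficient and
    five single-term 4-coefficient models for each of cubic, quadratic and
    linear melanin terms."""
    zoo = [ModelSpec("quad_abc_cubic",
                     slots=(("a", _CUBIC), ("b", _CUBIC), ("c", _CUBIC)))]
    zoo += [
        ModelSpec("quad_ab_cubic", slots=(("a", _CUBIC), ("b", _CUBIC))),
        ModelSpec("quad_ac_cubic", slots=(("a", _CUBIC), ("c", _CUBIC))),
        ModelSpec("quad_bc_cubic", slots=(("b", _CUBIC), ("c", _CUBIC))),
        ModelSpec("vertex_hk_cubic", base="vertex",
                  slots=(("h", _CUBIC), ("k", _CUBIC))),
    ]
    zoo += [
        ModelSpec("quad_a_cubic", slots=(("a", _CUBIC),)),
        ModelSpec("quad_b_cubic", slots=(("b", _CUBIC),)),
        ModelSpec("quad_c_cubic", slots=(("c", _CUBIC),)),
        ModelSpec("quad_shared_cubic", shared=True,
                  slots=(("a", _CUBIC), ("b", _CUBIC), ("c", _CUBIC))),
        ModelSpec("vertex_h_cubic", base="vertex", slots=(("h", _CUBIC),)),
    ]
    for p, tag in ((3, "m3"), (2, "m2"), (1, "m1")):
        zoo += [
            ModelSpec(f"quad_a_{tag}", slots=(("a", (p,)),)),
            ModelSpec(f"quad_b_{tag}", slots=(("b", (p,)),)),
            ModelSpec(f"quad_c_{tag}", slots=(("c", (p,)),)),
            ModelSpec(f"quad_shared_{tag}", shared=True,
                      slots=(("a", (p,)), ("b", (p,)), ("c", (p,)))),
            ModelSpec(f"vertex_h_{tag}", base="vertex", slots=(("h", (p,)),)),
        ]
    return zoo


def model_zoo() -> list:
    """All candidate correction forms plus the two conventional baselines."""
    return corrected_models() + conventional_models()


def get_model(name: str) -> ModelSpec:
    for spec in model_zoo():
        if spec.name == name:
            return spec
    raise KeyError(f"no model named {name!r}")


#: The single-quadratic-term correction recommended for clinical use
#: (4-coefficient, melanin term on the R-linear slot).
RECOMMENDED = "quad_b_m2"


# -- agreement statistics ------------------------------------------------------

@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means,
                             "difference": self.differences})


def bland_altman(truth, predicted) -> BlandAltman:
    """Bias and 95% limits of agreement of predicted vs truth.

    bias = mean(predicted - truth); LoA = bias +/- 1.96 * SD(differences)
    (sample SD, ddof=1).
    """
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    diff = predicted - truth
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    return BlandAltman(bias=bias, sd=sd,
                       loa_lower=bias - 1.96 * sd,
                       loa_upper=bias + 1.96 * sd,
                       n=diff.size,
                       means=(truth + predicted) / 2.0,
                       differences=diff)


# -- fitting -------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted coefficients of one model plus its grid error metrics."""
    spec: ModelSpec
    coefficients: np.ndarray
    loss: float                      # sum of squared SpO2 residuals
    avg_abs_error: float             # percentage points
    max_abs_error: float             # percentage points
    error_map: pd.DataFrame          # long form: f_m, sao2, abs_error_pct
    bland: BlandAltman
    converged: bool = True
    calibration_subset: str = "full grid"

    @property
    def coef_dict(self) -> dict:
        return dict(zip(self.spec.coefficient_names(),
                        map(float, self.coefficients)))

    def predict(self, R, m):
        return self.spec.evaluate(self.coefficients, R, m)

    def to_json(self, path=None) -> str:
        payload = dict(model=self.spec.name, spec=self.spec.to_json(),
                       coefficients=self.coef_dict, loss=self.loss,
                       avg_abs_error=self.avg_abs_error,
                       max_abs_error=self.max_abs_error,
                       bland_altman=dict(bias=self.bland.bias,
                                         sd=self.bland.sd,
                                         loa_lower=self.bland.loa_lower,
                                         loa_upper=self.bland.loa_upper),
                       converged=self.converged,
                       calibration_subset=self.calibration_subset)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _dataset_arrays(dataset):
    t = dataset.table
    return (t["R"].to_numpy(dtype=float), t["f_m"].to_numpy(dtype=float),
            t["sao2"].to_numpy(dtype=float))


def _make_result(spec, coeffs, dataset, converged=True,
                 calibration_subset="full grid") -> FitResult:
    R, m, truth = _dataset_arrays(dataset)
    pred = spec.evaluate(coeffs, R, m)
    resid = pred - truth
    err = np.abs(resid) * 100.0
    emap = pd.DataFrame({"f_m": m, "sao2": truth, "abs_error_pct": err})
    return FitResult(spec=spec, coefficients=np.asarray(coeffs, dtype=float),
                     loss=float(np.sum(resid ** 2)),
                     avg_abs_error=float(np.mean(err)),
                     max_abs_error=float(np.max(err)),
                     error_map=emap,
                     bland=bland_altman(truth, pred),
                     converged=converged,
                     calibration_subset=calibration_subset)


def fit_conventional(dataset, calibration_melanin: float = 0.01,
                     form: str = "quadratic") -> FitResult:
    """Fit the conventional model on a single melanin slice, evaluate on all.

    Calibrating only at the minimum melanin fraction reproduces the clinical
    practice of over-sampling light skin; the full-grid error map then
    exposes the skin-tone bias.
    """
    spec = ModelSpec(f"conventional_{form}", base=form)
    t = dataset.table
    mask = np.isclose(t["f_m"].to_numpy(dtype=float), calibration_melanin,
                      rtol=0, atol=1e-9)
    if not mask.any():
        raise ValueError(f"dataset has no melanin slice at "
                         f"{calibration_melanin}")
    R = t.loc[mask, "R"].to_numpy(dtype=float)
    truth = t.loc[mask, "sao2"].to_numpy(dtype=float)
    X = spec.design_matrix(R, np.zeros_like(R))
    coeffs, *_ = np.linalg.lstsq(X, truth, rcond=None)
    return _make_result(spec, coeffs, dataset,
                        calibration_subset=f"f_m={calibration_melanin}")


def _vertex_starts(dataset):
    """Deterministic starts for vertex-form fits, seeded by the conventional
    quadratic fit (a,b,c -> alpha=a, h=-b/2a, k=c-b^2/4a)."""
    R, m, truth = _dataset_arrays(dataset)
    X = np.column_stack([R ** 2, R, np.ones_like(R)])
    (a, b, c), *_ = np.linalg.lstsq(X, truth, rcond=None)
    if abs(a) < 1e-12:
        a = -0.05
    h = -b / (2 * a)
    k = c - b ** 2 / (4 * a)
    starts = []
    for dh, fa in product((0.0, 0.5, -0.5, 1.0), (1.0, 0.5)):
        starts.append((a * fa, h + dh, k))
    return starts


def fit_corrected(spec: ModelSpec, dataset, min_melanin_values: int = 2
                  ) -> FitResult:
    """Least-squares fit of SpO2(R, m) against SaO2 over the whole grid.

    Linear-in-coefficient forms are solved exactly; vertex forms by
    multi-start nonlinear least squares (best of 8 deterministic starts).
    """
    if len(np.unique(dataset.table["f_m"])) < min_melanin_values:
        raise ValueError("dataset must cover at least "
                         f"{min_melanin_values} melanin values")
    R, m, truth = _dataset_arrays(dataset)
    if not spec.is_vertex:
        X = spec.design_matrix(R, m)
        coeffs, *_ = np.linalg.lstsq(X, truth, rcond=None)
        return _make_result(spec, coeffs, dataset)

    n_mel = spec.melanin_coeff_count
    best, best_cost, ok = None, np.inf, False
    for start in _vertex_starts(dataset):
        x0 = np.concatenate([start, np.zeros(n_mel)])
        res = least_squares(
            lambda x: spec.evaluate(x, R, m) - truth, x0,
            method="lm", max_nfev=20000)
        if res.cost < best_cost:
            best, best_cost, ok = res.x, res.cost, bool(res.success)
    return _make_result(spec, best, dataset, converged=ok)


def fit_all(dataset, include_conventional: bool = True) -> pd.DataFrame:
    """Fit every zoo member; summary table sorted like the candidate list."""
    rows = []
    for spec in corrected_models():
        fr = fit_corrected(spec, dataset)
        rows.append(dict(model=spec.name, n_coefficients=spec.n_coefficients,
                         avg_error_pct=fr.avg_abs_error,
                         max_error_pct=fr.max_abs_error,
                         bias=fr.bland.bias, converged=fr.converged))
    if include_conventional:
        for form in ("linear", "quadratic"):
            fr = fit_conventional(dataset, form=form)
            rows.append(dict(model=fr.spec.name,
                             n_coefficients=fr.spec.n_coefficients,
                             avg_error_pct=fr.avg_abs_error,
                             max_error_pct=fr.max_abs_error,
                             bias=fr.bland.bias, converged=fr.converged))
    return pd.DataFrame(rows)


def melanin_sensitivity(fit: FitResult, dataset, delta_m_grid=None,
                        max_added_error: float = 4.0) -> dict:
    """Propagate melanin-estimation error into SpO2 error.

    Re-evaluates the fitted model at m + delta for each perturbation delta
    and reports the added (above the delta=0 floor) max/avg absolute error
    in percentage points, plus the largest |delta| that keeps the added max
    error below ``max_added_error``.
    """
    if delta_m_grid is None:
        delta_m_grid = np.round(np.arange(-0.10, 0.1001, 0.01), 4)
    R, m, truth = _dataset_arrays(dataset)
    base_pred = fit.predict(R, m)
    base_max = float(np.max(np.abs(base_pred - truth)) * 100.0)
    base_avg = float(np.mean(np.abs(base_pred - truth)) * 100.0)
    rows = []
    for d in np.asarray(delta_m_grid, dtype=float):
        pred = fit.predict(R, m + d)
        err = np.abs(pred - truth) * 100.0
        rows.append(dict(delta_m=float(d),
                         max_error_pct=float(np.max(err)),
                         avg_error_pct=float(np.mean(err)),
                         added_max_error_pct=float(np.max(err)) - base_max,
                         added_avg_error_pct=float(np.mean(err)) - base_avg))
    curve = pd.DataFrame(rows)
    tol = curve[curve["added_max_error_pct"] <= max_added_error]
    largest = float(np.max(np.abs(tol["delta_m"]))) if len(tol) else 0.0
    return dict(curve=curve, base_max_error_pct=base_max,
                base_avg_error_pct=base_avg,
                max_tolerable_abs_delta_m=largest)
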