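"""Semi-empirical density-based solubility models and their regression.

Four classical correlations of solid solubility y2 in a supercritical fluid
against the pure-solvent density rho1 [kg/m3] and temperature T [K]:

* Chrastil (solvato-complex):      ln(y2/(1-y2)) = (k-1) ln rho1 + A1 + B1/T
* modified (dimensionless) Chrastil:
      y2 = (R T rho1 / (M_scf f0))^(k'-1) exp(A2 + B2/T)
* Mendez-Santiago & Teja (MT):     T ln(y2 P) = A3 + B3 rho1 + C3 T
* Bartle:   ln(y2 P / P_ref) = A4 + B4/T + C4 (rho1 - rho_ref)

Pressure is in MPa throughout (this is the convention under which the MT and
Bartle parameter magnitudes of the validation fixture reproduce); Bartle
references are P_ref = 0.1 MPa and rho_ref = 700 kg/m3.

Each model is a Model class constructed from a :class:`SolubilityDataset`;
``fit()`` minimizes the sum of absolute relative deviations (Nelder-Mead,
started from an exact linearized least-squares solution) and returns a
:class:`DensityResults` with parameters, AARD%, R2 and a ``summary()``.

The 1/T coefficients carry van 't Hoff information: -B1*R (or -B2*R) is the
total dissolution enthalpy, -B4*R the sublimation enthalpy, and their
difference the (exothermic) solvation enthalpy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq, minimize

from .dataset import GAS_CONSTANT, SolubilityDataset
from . import stats as fs

__all__ = [
    "ChrastilParams",
    "ModifiedChrastilParams",
    "MTParams",
    "BartleParams",
    "DissolutionEnthalpies",
    "chrastil_predict",
    "modified_chrastil_predict",
    "mt_predict",
    "mt_lhs",
    "bartle_predict",
    "ChrastilModel",
    "ModifiedChrastilModel",
    "MTModel",
    "BartleModel",
    "DensityResults",
    "fit_density_model",
    "dissolution_enthalpies",
    "crossover_pressure",
    "FitError",
    "NoCrossoverError",
    "DENSITY_MODELS",
]


class FitError(RuntimeError):
    """Optimizer failed to converge; ``.best`` carries the best-so-far result."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class NoCrossoverError(ValueError):
    """The two isotherms do not intersect inside the pressure bracket."""


# ---------------------------------------------------------------------------
# Parameter records and pointwise predictors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChrastilParams:
    kappa: float   # association number
    A1: float
    B1: float      # K; negative for endothermic overall dissolution


@dataclass(frozen=True)
class ModifiedChrastilParams:
    kappa_prime: float
    A2: float
    B2: float                       # K
    f_std: float = 1.0              # reference fugacity f0 (numeric convention)
    solvent_molar_mass: float = 44.01

    def __post_init__(self):
        if not self.f_std > 0:
            raise ValueError("f_std must be > 0")


@dataclass(frozen=True)
class MTParams:
    A3: float  # K
    B3: float  # K m3/kg
    C3: float


@dataclass(frozen=True)
class BartleParams:
    A4: float
    B4: float               # K
    C4: float               # m3/kg
    P_ref: float = 0.1      # MPa
    rho_ref: float = 700.0  # kg/m3

    def __post_init__(self):
        if not (self.P_ref > 0 and self.rho_ref > 0):
            raise ValueError("P_ref and rho_ref must be > 0")


@dataclass(frozen=True)
class DissolutionEnthalpies:
    """kJ/mol; solvation = total - sublimation (negative: exothermic)."""

    total: float
    sublimation: float

    @property
    def solvation(self) -> float:
        return self.total - self.sublimation


def chrastil_predict(params: ChrastilParams, T, rho1):
    """y2 = g/(1+g), g = rho1^(k-1) exp(A1 + B1/T); evaluated in log domain."""
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    if np.any(T <= 0) or np.any(rho1 <= 0):
        raise ValueError("T and rho1 must be > 0")
    ln_g = (params.kappa - 1.0) * np.log(rho1) + params.A1 + params.B1 / T
    y = np.where(ln_g < 0,
                 np.exp(ln_g) / (1.0 + np.exp(ln_g)),
                 1.0 / (1.0 + np.exp(-ln_g)))
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite Chrastil prediction")
    return y if y.ndim else float(y)


def modified_chrastil_predict(params: ModifiedChrastilParams, T, rho1):
    """y2 = (R T rho1 / (M_scf f0))^(k'-1) exp(A2 + B2/T), R = 8.314."""
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    if np.any(T <= 0) or np.any(rho1 <= 0):
        raise ValueError("T and rho1 must be > 0")
    g = GAS_CONSTANT * T * rho1 / (params.solvent_molar_mass * params.f_std)
    ln_y = (params.kappa_prime - 1.0) * np.log(g) + params.A2 + params.B2 / T
    y = np.exp(ln_y)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite modified-Chrastil prediction")
    return y if y.ndim else float(y)


def mt_predict(params: MTParams, T, P, rho1):
    """y2 = (1/P) exp((A3 + B3 rho1)/T + C3), P in MPa."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0) or np.any(rho1 <= 0):
        raise ValueError("T, P and rho1 must be > 0")
    y = np.exp((params.A3 + params.B3 * rho1) / T + params.C3) / P
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite MT prediction")
    return y if y.ndim else float(y)


def mt_lhs(T, P, y2):
    """Self-consistency ordinate T ln(y2 P) [K], P in MPa."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if np.any((y2 <= 0) | (y2 >= 1)) or np.any(P <= 0) or np.any(T <= 0):
        raise ValueError("require T, P > 0 and 0 < y2 < 1")
    v = T * np.log(y2 * P)
    return v if v.ndim else float(v)


def bartle_predict(params: BartleParams, T, P, rho1):
    """y2 = (P_ref/P) exp(A4 + B4/T + C4 (rho1 - rho_ref))."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0) or np.any(rho1 <= 0):
        raise ValueError("T, P and rho1 must be > 0")
    y = (params.P_ref / P) * np.exp(
        params.A4 + params.B4 / T + params.C4 * (rho1 - params.rho_ref)
    )
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite Bartle prediction")
    return y if y.ndim else float(y)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class DensityModel:
    """Base class: holds the dataset arrays and the common fit machinery."""

    model_name: str = "density"
    k_params: int = 3

    def __init__(self, dataset: SolubilityDataset):
        if len(dataset) < self.k_params + 1:
            raise ValueError(
                f"{self.model_name}: need at least {self.k_params + 1} records, "
                f"got {len(dataset)}"
            )
        self.dataset = dataset
        self.T = np.array(dataset.temperatures)
        self.P = np.array(dataset.pressures)
        self.rho = np.array(dataset.densities)
        self.y = np.array(dataset.mole_fractions)

    # subclasses implement --------------------------------------------------
    def _init_theta(self) -> np.ndarray:
        raise NotImplementedError

    def _theta_predict(self, theta: np.ndarray, T, P, rho):
        raise NotImplementedError

    def params_from_theta(self, theta: np.ndarray):
        raise NotImplementedError

    #: regression loss minimized by default: "sar" = sum of absolute relative
    #: deviations; "ssr" = sum of squared relative deviations.  The per-model
    #: defaults mirror the regressions behind the reference parameter sets of
    #: the built-in fixture; either loss can be requested explicitly.
    default_loss: str = "sar"

    # ------------------------------------------------------------------------
    def _objective(self, theta: np.ndarray, loss: str = "sar") -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                pred = self._theta_predict(theta, self.T, self.P, self.rho)
            except FloatingPointError:
                return 1e6
        pred = np.asarray(pred)
        if not np.all(np.isfinite(pred)):
            return 1e6
        rel = (self.y - pred) / self.y
        if loss == "sar":
            return float(np.sum(np.abs(rel)))
        if loss == "ssr":
            return float(np.sum(rel**2))
        raise ValueError(f"unknown loss {loss!r}")

    def fit(
        self,
        init: np.ndarray | None = None,
        loss: str | None = None,
        n_restarts: int = 3,
        seed: int = 0,
        fatol: float = 1e-10,
        maxiter: int = 5000,
    ) -> "DensityResults":
        """Nelder-Mead minimization of the relative-deviation loss.

        Started from the exact linearized least-squares solution (``init``
        overrides); on non-convergence, up to ``n_restarts`` perturbed
        restarts are attempted before raising :class:`FitError` carrying the
        best result found.  ``loss`` is "sar" or "ssr" (class default).
        """
        loss = loss or self.default_loss
        theta0 = np.asarray(init, dtype=float) if init is not None \
            else self._init_theta()
        scale = np.maximum(1.0, np.abs(theta0))

        def obj_scaled(u):
            return self._objective(u * scale, loss)

        rng = np.random.default_rng(seed)
        best = None
        start = theta0 / scale
        for attempt in range(n_restarts + 1):
            res = minimize(
                obj_scaled, start, method="Nelder-Mead",
                options={"fatol": fatol, "xatol": 1e-10,
                         "maxiter": maxiter, "maxfev": 2 * maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
            start = (theta0 / scale) * (1.0 + 0.05 * rng.standard_normal(
                theta0.size))
        theta = best.x * scale
        result = DensityResults(self, theta, loss=loss)
        if not best.success and best.fun >= 1e6:
            raise FitError(
                f"{self.model_name}: optimizer failed to converge", best=result
            )
        return result


class ChrastilModel(DensityModel):
    """Chrastil solvato-complex model; k is the association number."""

    model_name = "chrastil"
    default_loss = "ssr"

    def _init_theta(self) -> np.ndarray:
        # exact linearization: logit(y) = (k-1) ln rho + A1 + B1/T
        z = np.log(self.y / (1.0 - self.y))
        X = np.column_stack([np.log(self.rho), 1.0 / self.T,
                             np.ones_like(self.T)])
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        return np.array([coef[0] + 1.0, coef[2], coef[1]])  # kappa, A1, B1

    def _theta_predict(self, theta, T, P, rho):
        return chrastil_predict(ChrastilParams(*theta), T, rho)

    def params_from_theta(self, theta) -> ChrastilParams:
        return ChrastilParams(*theta)


class ModifiedChrastilModel(DensityModel):
    """Dimensionally consistent Chrastil variant (dimensionless density group)."""

    model_name = "mchrastil"
    default_loss = "ssr"

    def __init__(self, dataset: SolubilityDataset, f_std: float = 1.0,
                 solvent_molar_mass: float = 44.01):
        super().__init__(dataset)
        self.f_std = f_std
        self.solvent_molar_mass = solvent_molar_mass

    def _group(self, T, rho):
        return GAS_CONSTANT * T * rho / (self.solvent_molar_mass * self.f_std)

    def _init_theta(self) -> np.ndarray:
        z = np.log(self.y)
        X = np.column_stack([np.log(self._group(self.T, self.rho)),
                             1.0 / self.T, np.ones_like(self.T)])
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        return np.array([coef[0] + 1.0, coef[2], coef[1]])  # kappa', A2, B2

    def _theta_predict(self, theta, T, P, rho):
        params = ModifiedChrastilParams(
            *theta, f_std=self.f_std, solvent_molar_mass=self.solvent_molar_mass
        )
        return modified_chrastil_predict(params, T, rho)

    def params_from_theta(self, theta) -> ModifiedChrastilParams:
        return ModifiedChrastilParams(
            *theta, f_std=self.f_std, solvent_molar_mass=self.solvent_molar_mass
        )


class MTModel(DensityModel):
    """Mendez-Santiago & Teja model (data self-consistency check)."""

    model_name = "mt"

    def _init_theta(self) -> np.ndarray:
        z = self.T * np.log(self.y * self.P)
        X = np.column_stack([np.ones_like(self.T), self.rho, self.T])
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        return coef  # A3, B3, C3

    def _theta_predict(self, theta, T, P, rho):
        return mt_predict(MTParams(*theta), T, P, rho)

    def params_from_theta(self, theta) -> MTParams:
        return MTParams(*theta)


class BartleModel(DensityModel):
    """Bartle model; -B4*R estimates the sublimation enthalpy."""

    model_name = "bartle"

    def __init__(self, dataset: SolubilityDataset, P_ref: float = 0.1,
                 rho_ref: float = 700.0):
        super().__init__(dataset)
        self.P_ref = P_ref
        self.rho_ref = rho_ref

    def _init_theta(self) -> np.ndarray:
        z = np.log(self.y * self.P / self.P_ref)
        X = np.column_stack([np.ones_like(self.T), 1.0 / self.T,
                             self.rho - self.rho_ref])
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        return coef  # A4, B4, C4

    def _theta_predict(self, theta, T, P, rho):
        params = BartleParams(*theta, P_ref=self.P_ref, rho_ref=self.rho_ref)
        return bartle_predict(params, T, P, rho)

    def params_from_theta(self, theta) -> BartleParams:
        return BartleParams(*theta, P_ref=self.P_ref, rho_ref=self.rho_ref)


DENSITY_MODELS: dict[str, type[DensityModel]] = {
    "chrastil": ChrastilModel,
    "mchrastil": ModifiedChrastilModel,
    "mt": MTModel,
    "bartle": BartleModel,
}


def fit_density_model(variant: str, dataset: SolubilityDataset,
                      init=None, **fit_kwargs) -> "DensityResults":
    """Convenience: build the model named ``variant`` and fit it."""
    try:
        cls = DENSITY_MODELS[variant]
    except KeyError:
        raise ValueError(
            f"unknown model {variant!r}; choose from {sorted(DENSITY_MODELS)}"
        ) from None
    return cls(dataset).fit(init=init, **fit_kwargs)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

class DensityResults:
    """Fitted density-based model: parameters, diagnostics, prediction."""

    def __init__(self, model: DensityModel, theta: np.ndarray,
                 loss: str | None = None):
        self.model = model
        self.loss = loss or model.default_loss
        self.theta = np.asarray(theta, dtype=float)
        self.params = model.params_from_theta(self.theta)
        self.observed = model.y.copy()
        self.fittedvalues = np.asarray(
            model._theta_predict(self.theta, model.T, model.P, model.rho)
        )
        self.resid_rel = (self.observed - self.fittedvalues) / self.observed
        self.nobs = self.observed.size
        self.k_params = model.k_params
        self.of = fs.objective_of(self.observed, self.fittedvalues)
        self.aard_percent = fs.aard_percent(self.observed, self.fittedvalues)
        self.sse = float(np.sum((self.observed - self.fittedvalues) ** 2))
        self.r2 = fs.r_squared(self.observed, self.fittedvalues)
        self.r2_adj = fs.adjusted_r_squared(self.r2, self.nobs, self.k_params)

    @property
    def model_name(self) -> str:
        return self.model.model_name

    def predict(self, T, P=None, rho=None):
        """Predict y2 at new conditions.

        ``rho`` may be omitted when the conditions lie on a tabulated
        isotherm of the training dataset (density interpolated in P)."""
        if rho is None:
            if P is None:
                raise ValueError("need P (and rho, unless on a fixture isotherm)")
            rho = self.model.dataset.isotherm_density(float(T), float(P))
        return self.model._theta_predict(self.theta, T, P, rho)

    # -- van 't Hoff enthalpies ---------------------------------------------
    @property
    def total_enthalpy(self) -> float:
        """dH_total = -B*R [kJ/mol] (Chrastil-type fits only)."""
        if isinstance(self.params, ChrastilParams):
            b = self.params.B1
        elif isinstance(self.params, ModifiedChrastilParams):
            b = self.params.B2
        else:
            raise AttributeError(
                "total enthalpy is defined for Chrastil-type fits only"
            )
        return -b * GAS_CONSTANT / 1000.0

    @property
    def sublimation_enthalpy(self) -> float:
        """dH_sub = -B4*R [kJ/mol] (Bartle fits only)."""
        if not isinstance(self.params, BartleParams):
            raise AttributeError("sublimation enthalpy requires a Bartle fit")
        return -self.params.B4 * GAS_CONSTANT / 1000.0

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"{self.model_name} model fit "
            f"({self.model.dataset.solute_name}/{self.model.dataset.solvent_name})",
            "-" * 58,
            f"N = {self.nobs}, Q = {self.k_params}",
        ]
        for name, value in asdict(self.params).items():
            lines.append(f"  {name:<22s} {value:.6g}")
        lines += [
            f"  {'AARD%':<22s} {self.aard_percent:.3f}",
            f"  {'R2':<22s} {self.r2:.4f}",
            f"  {'R2_adj':<22s} {self.r2_adj:.4f}",
            f"  {'SSE':<22s} {self.sse:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": self.model_name,
            "params": asdict(self.params),
            "aard_percent": self.aard_percent,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "sse": self.sse,
            "n": self.nobs,
            "predictions": self.fittedvalues.tolist(),
            "residuals_rel": self.resid_rel.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def dissolution_enthalpies(
    chrastil_fit: DensityResults, bartle_fit: DensityResults
) -> DissolutionEnthalpies:
    """Total, sublimation and solvation enthalpies [kJ/mol].

    Total from the Chrastil-type 1/T coefficient (-B*R), sublimation from
    the Bartle 1/T coefficient (-B4*R), solvation as the difference.
    """
    return DissolutionEnthalpies(
        total=chrastil_fit.total_enthalpy,
        sublimation=bartle_fit.sublimation_enthalpy,
    )


def crossover_pressure(
    fit: DensityResults,
    T_low: float,
    T_high: float,
    dataset: SolubilityDataset | None = None,
) -> float:
    """Pressure [MPa] where the fitted isotherms at T_low and T_high cross.

    Densities along each isotherm come from the training dataset (or
    ``dataset``), linearly interpolated in pressure; the root is bracketed on
    the common tabulated pressure range and found by bisection (Brent).
    """
    ds = dataset or fit.model.dataset
    iso = ds.isotherms()
    for t in (T_low, T_high):
        if t not in iso:
            raise KeyError(f"no isotherm at T={t} K in the dataset")
    p_lo = max(iso[T_low][0].pressure, iso[T_high][0].pressure)
    p_hi = min(iso[T_low][-1].pressure, iso[T_high][-1].pressure)

    def diff(p: float) -> float:
        y_lo = fit.model._theta_predict(
            fit.theta, T_low, p, ds.isotherm_density(T_low, p))
        y_hi = fit.model._theta_predict(
            fit.theta, T_high, p, ds.isotherm_density(T_high, p))
        return float(y_lo) - float(y_hi)

    f_lo, f_hi = diff(p_lo), diff(p_hi)
    if f_lo == 0.0:
        return p_lo
    if f_hi == 0.0:
        return p_hi
    if f_lo * f_hi > 0:
        raise NoCrossoverError(
            f"isotherms at {T_low} K and {T_high} K do not cross in "
            f"[{p_lo}, {p_hi}] MPa"
        )
    return float(brentq(diff, p_lo, p_hi, xtol=1e-10))
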