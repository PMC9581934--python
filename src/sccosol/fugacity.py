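"""Solute fugacity coefficients and the EoS solid-solubility model.

The solubility of a solid solute (component 2) in supercritical CO2 follows
from equating the solid fugacity with its fugacity in the fluid:

    y2 = (P_sub/P) * exp((P - P_sub) v_s / (RT)) / phi2_hat(T, P, y2),

with the saturation fugacity coefficient taken as unity and the Poynting
factor using the solid molar volume v_s.  phi2_hat, the solute fugacity
coefficient in the mixture, comes from the cubic EoS with Kwak-Mansoori
mixing rules via

    ln phi_i = (1/RT) * integral_v^inf [(dP/dn_i)_{T,V,n_j} - RT/V] dV - ln Z.

The integral is carried out analytically for each variant (the analytic
expressions below); :func:`fugacity_coeff_numeric` evaluates it by finite
differences + quadrature and serves as an independent oracle in the tests.

Because y2 ~ 1e-5, phi2_hat is nearly independent of y2 and the successive
substitution on the solubility relation converges in a few evaluations.

The binary interaction parameters (k_ij, l_ij[, m_ij[, n_ij]]) are
temperature-independent and regressed over all isotherms at once by
multi-start Nelder-Mead on the sum of absolute relative deviations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize

from .dataset import GAS_CONSTANT as R
from .dataset import ComponentProperties, SolubilityDataset
from . import stats as fs
from .eos import (
    INTERACTION_NAMES,
    KMInteraction,
    MixtureConstants,
    PureKMConstants,
    RootError,
    cross_terms,
    km_mix,
    pure_constants,
    solve_Z,
)

__all__ = [
    "SolubilitySolveSettings",
    "fugacity_coeff",
    "fugacity_coeff_numeric",
    "solve_solubility",
    "EoSSolubilityModel",
    "EoSResults",
    "fit_interaction",
    "ConvergenceError",
]

_SQRT2 = math.sqrt(2.0)


class ConvergenceError(RuntimeError):
    """Fixed-point solubility iteration failed; ``.trace`` holds iterates."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class SolubilitySolveSettings:
    """Controls for the successive-substitution solution of the solubility
    relation.  ``damping`` in (0, 1]; 1.0 is plain substitution (the map is
    nearly constant in y2 at these dilutions), and the solver halves the
    step automatically if it detects oscillation."""

    rel_tolerance: float = 1e-10
    max_iterations: int = 200
    damping: float = 1.0
    initial_y2: float | None = None

    def __post_init__(self):
        if not self.rel_tolerance > 0:
            raise ValueError("rel_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Analytic fugacity coefficients
# ---------------------------------------------------------------------------

def _lnphi_from_cross(
    variant: str, x, i: int, T: float, P: float, cross
) -> float:
    """ln phi_i with precomputed cross-term matrices (the hot path)."""
    amat, bmat, cmat, dmat = cross
    n = len(x)
    b = sum(x[j] * x[k] * bmat[j][k] for j in range(n) for k in range(n))
    sb_i = sum(x[j] * bmat[i][j] for j in range(n))
    bhat = 2.0 * sb_i - b

    if variant == "RK":
        if any(amat[j][k] < 0 or bmat[j][k] <= 0
               for j in range(n) for k in range(n)):
            raise ValueError(
                "RK conformal mixing needs non-negative a_ij and positive b_ij"
            )
        abmat = [[amat[j][k] ** (2.0 / 3.0) * bmat[j][k] ** (1.0 / 3.0)
                  for k in range(n)] for j in range(n)]
        s1 = sum(x[j] * x[k] * abmat[j][k] for j in range(n) for k in range(n))
        a = s1**1.5 / math.sqrt(b)
        sab_i = sum(x[j] * abmat[i][j] for j in range(n))
        # (1/n) d(n^2 a)/dn_i for the conformal-solution mixing rule
        ratio = s1 / b
        da_i = 3.0 * math.sqrt(ratio) * sab_i - ratio**1.5 * sb_i
        mix = MixtureConstants("RK", a=a, b=b)
        z, v = solve_Z("RK", mix, T, P)
        ln1 = math.log1p(b / v)
        rt32 = R * T**1.5
        return (
            math.log(v / (v - b))
            + bhat / (v - b)
            - math.log(z)
            + (a * bhat / b**2 * (ln1 - b / (v + b)) - da_i / b * ln1) / rt32
        )

    a = sum(x[j] * x[k] * amat[j][k] for j in range(n) for k in range(n))
    c = sum(x[j] * x[k] * cmat[j][k] for j in range(n) for k in range(n))
    ahat = 2.0 * sum(x[j] * amat[i][j] for j in range(n))
    chat = 2.0 * sum(x[j] * cmat[i][j] for j in range(n))
    rt = R * T
    if variant == "SRK4":
        d = sum(x[j] * x[k] * dmat[j][k] for j in range(n) for k in range(n))
        dhat = 2.0 * sum(x[j] * dmat[i][j] for j in range(n))
        sqt = math.sqrt(T)
        E = a + c * rt - d * R * sqt
        Ehat = ahat + chat * rt - dhat * R * sqt
        mix = MixtureConstants("SRK4", a=a, b=b, c=c, d=d)
    else:
        acrt = a * c * rt
        if acrt < 0:
            raise ValueError("negative a*c*RT under square root")
        root = math.sqrt(acrt)
        E = a + c * rt - 2.0 * root
        # (1/n) d(n^2 E)/dn_i; symmetric form, safe while a, c > 0
        Ehat = ahat + chat * rt - (ahat * c * rt + a * chat * rt) / root
        mix = MixtureConstants(variant, a=a, b=b, c=c)

    z, v = solve_Z(variant, mix, T, P)
    base = bhat / b * (z - 1.0) - math.log(z * (1.0 - b / v))
    if variant == "PR":
        lam = math.log(
            (v + (1.0 + _SQRT2) * b) / (v + (1.0 - _SQRT2) * b)
        )
        return base + (E * bhat / b - Ehat) * lam / (2.0 * _SQRT2 * b * rt)
    ln1 = math.log1p(b / v)
    return base + (E * bhat / b - Ehat) * ln1 / (b * rt)


def fugacity_coeff(
    variant: str,
    x,
    T: float,
    P: float,
    pure: tuple[PureKMConstants, PureKMConstants],
    inter: KMInteraction,
    i: int = 1,
) -> float:
    """Fugacity coefficient of component ``i`` in the mixture at (T, P [Pa]).

    Uses the analytic expression for the variant (derived from the
    dP/dn_i volume integral); raises on log-domain violations, which signal
    an inconsistent root or unphysical constants.
    """
    x = tuple(float(v) for v in x)
    cross = cross_terms(variant, pure, inter)
    lnphi = _lnphi_from_cross(variant, x, i, T, P, cross)
    return math.exp(lnphi)


# ---------------------------------------------------------------------------
# Numeric oracle (finite differences + quadrature of the volume integral)
# ---------------------------------------------------------------------------

def _pressure_total(
    variant: str, T: float, V: float, moles, pure, inter
) -> float:
    """P(T, V, n) for a total mole vector ``moles`` and total volume V [m3]."""
    ntot = sum(moles)
    x = tuple(ni / ntot for ni in moles)
    mix = km_mix(variant, x, pure, inter)
    v = V / ntot
    from .eos import attraction_E, _attr_denominator

    return R * T / (v - mix.b) - attraction_E(mix, T) / _attr_denominator(
        variant, v, mix.b
    )


def fugacity_coeff_numeric(
    variant: str,
    x,
    T: float,
    P: float,
    pure: tuple[PureKMConstants, PureKMConstants],
    inter: KMInteraction,
    i: int = 1,
    rel_step: float = 1e-6,
) -> float:
    """Oracle: ln phi_i from the volume integral of (dP/dn_i - RT/V).

    dP/dn_i by central finite differences on the mole numbers (relative step
    ``rel_step`` of the total moles), the integral by adaptive quadrature to
    infinity.  Test/cross-validation use only - orders of magnitude slower
    than the analytic path.
    """
    x = tuple(float(v) for v in x)
    mix = km_mix(variant, x, pure, inter)
    z, v = solve_Z(variant, mix, T, P)
    h = rel_step  # total moles = 1

    def dp_dni(V: float) -> float:
        plus = list(x)
        minus = list(x)
        plus[i] += h
        minus[i] -= h
        return (
            _pressure_total(variant, T, V, plus, pure, inter)
            - _pressure_total(variant, T, V, minus, pure, inter)
        ) / (2.0 * h)

    integrand = lambda V: dp_dni(V) - R * T / V
    import warnings
    from scipy.integrate import IntegrationWarning

    with warnings.catch_warnings():
        # roundoff-level warnings at these tolerances; accuracy is checked
        # against the returned error estimate below
        warnings.simplefilter("ignore", IntegrationWarning)
        val, err = quad(integrand, v, np.inf, limit=400,
                        epsabs=1e-10, epsrel=1e-10)
    if err > 1e-4 * max(1.0, abs(val)):
        raise RuntimeError(f"quadrature did not converge (err={err:.2e})")
    return math.exp(val / (R * T) - math.log(z))


# ---------------------------------------------------------------------------
# Solid solubility
# ---------------------------------------------------------------------------

def _solve_y2(
    phi_fn,
    T: float,
    P: float,
    p_sub: float,
    v_solid: float,
    settings: SolubilitySolveSettings,
) -> float:
    """Damped successive substitution on y = ideal/phi(y)."""
    ideal = (p_sub / P) * math.exp((P - p_sub) * v_solid / (R * T))
    y = settings.initial_y2 if settings.initial_y2 is not None else p_sub / P
    damping = settings.damping
    prev_update = 0.0
    trace = [y]
    for _ in range(settings.max_iterations):
        phi = phi_fn(y)
        if not (phi > 0.0 and math.isfinite(phi)):
            raise ConvergenceError(
                f"non-positive/overflowed fugacity coefficient {phi}",
                trace=trace,
            )
        rhs = ideal / phi
        if not (0.0 < rhs < 1.0) or not math.isfinite(rhs):
            raise ConvergenceError(
                f"solubility iterate left (0, 1): {rhs}", trace=trace
            )
        update = rhs - y
        if abs(update) <= settings.rel_tolerance * max(y, 1e-300):
            return rhs
        if update * prev_update < 0 and abs(update) >= abs(prev_update):
            damping *= 0.5  # oscillating without contraction
        y += damping * update
        prev_update = update
        trace.append(y)
    raise ConvergenceError(
        f"no convergence in {settings.max_iterations} iterations "
        f"(last relative update {abs(update)/max(y,1e-300):.2e}); "
        "a stronger damping may help",
        trace=trace,
    )


def solve_solubility(
    variant: str,
    T: float,
    P: float,
    solute: ComponentProperties,
    solvent: ComponentProperties,
    inter: KMInteraction,
    settings: SolubilitySolveSettings | None = None,
) -> float:
    """Equilibrium y2 of the solid solute at (T [K], P [Pa])."""
    settings = settings or SolubilitySolveSettings()
    p_sub = solute.sublimation_pressure(T)
    if not P > p_sub:
        raise ValueError("system pressure must exceed the sublimation pressure")
    if solute.solid_molar_volume is None:
        raise ValueError("solute needs a solid molar volume")
    pure = (pure_constants(variant, solvent), pure_constants(variant, solute))
    cross = cross_terms(variant, pure, inter)

    def phi2(y: float) -> float:
        return math.exp(
            _lnphi_from_cross(variant, (1.0 - y, y), 1, T, P, cross)
        )

    return _solve_y2(phi2, T, P, p_sub, solute.solid_molar_volume, settings)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class EoSSolubilityModel:
    """Cubic-EoS solubility model for one solute/solvent pair and dataset.

    ``fit`` regresses the Kwak-Mansoori binary interaction parameters on the
    dataset by multi-start Nelder-Mead over the sum of absolute relative
    deviations; trial points where the EoS has no fluid root or the
    solubility iteration diverges incur a large finite penalty so the
    simplex can recover.
    """

    PENALTY = 1e6

    def __init__(
        self,
        dataset: SolubilityDataset,
        variant: str,
        solute: ComponentProperties,
        solvent: ComponentProperties,
        settings: SolubilitySolveSettings | None = None,
    ):
        if variant not in INTERACTION_NAMES:
            raise ValueError(f"unknown EoS variant {variant!r}")
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        if solute.solid_molar_volume is None or not solute.sublimation_pressures:
            raise ValueError(
                "solute needs solid molar volume and sublimation pressures"
            )
        self.dataset = dataset
        self.variant = variant
        self.solute = solute
        self.solvent = solvent
        self.settings = settings or SolubilitySolveSettings()
        self.k_params = len(INTERACTION_NAMES[variant])
        self.pure = (
            pure_constants(variant, solvent),
            pure_constants(variant, solute),
        )
        self.y = np.array(dataset.mole_fractions)
        self._conditions = [
            (r.temperature, r.pressure * 1e6,
             solute.sublimation_pressure(r.temperature))
            for r in dataset
        ]

    def predict(self, inter: KMInteraction) -> np.ndarray:
        """y2 at every dataset condition for the given interaction set."""
        cross = cross_terms(self.variant, self.pure, inter)
        vs = self.solute.solid_molar_volume
        out = np.empty(len(self._conditions))
        for k, (T, P, p_sub) in enumerate(self._conditions):
            phi2 = lambda y: math.exp(
                _lnphi_from_cross(self.variant, (1.0 - y, y), 1, T, P, cross)
            )
            out[k] = _solve_y2(phi2, T, P, p_sub, vs, self.settings)
        return out

    def objective(self, vector) -> float:
        """Sum of absolute relative deviations; PENALTY on failures."""
        try:
            inter = KMInteraction.from_vector(self.variant, vector)
            pred = self.predict(inter)
        except (RootError, ConvergenceError, ValueError, OverflowError,
                FloatingPointError):
            return self.PENALTY
        return float(np.sum(np.abs(self.y - pred) / self.y))

    def fit(
        self,
        n_starts: int = 32,
        seed: int = 1,
        init: KMInteraction | None = None,
        maxiter: int | None = None,
    ) -> "EoSResults":
        """Multi-start Nelder-Mead over the interaction parameters.

        Starts: the origin, ``init`` if given, plus uniform draws in
        [-1, 1]^Q from ``seed``.  The best start is polished with tighter
        tolerances.
        """
        q = self.k_params
        rng = np.random.default_rng(seed)
        starts = [np.zeros(q)]
        if init is not None:
            starts.append(np.array(init.to_vector(self.variant)))
        while len(starts) < max(n_starts, 1) + (init is not None):
            starts.append(rng.uniform(-1.0, 1.0, size=q))
        best = None
        n_failed = 0
        for s in starts:
            res = minimize(
                self.objective, s, method="Nelder-Mead",
                options={"fatol": 1e-6, "xatol": 1e-6,
                         "maxiter": maxiter or 200 * q},
            )
            if res.fun >= self.PENALTY:
                n_failed += 1
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise ConvergenceError(
                f"{self.variant}: all {len(starts)} starts failed "
                f"({n_failed} penalized)"
            )
        polished = minimize(
            self.objective, best.x, method="Nelder-Mead",
            options={"fatol": 1e-10, "xatol": 1e-9, "maxiter": 2000},
        )
        if polished.fun < best.fun:
            best = polished
        inter = KMInteraction.from_vector(self.variant, best.x)
        return EoSResults(self, inter, n_starts=len(starts), seed=seed)


class EoSResults:
    """Fitted EoS solubility model: interaction set, AARD%, diagnostics."""

    def __init__(self, model: EoSSolubilityModel, interaction: KMInteraction,
                 n_starts: int | None = None, seed: int | None = None):
        self.model = model
        self.interaction = interaction
        self.n_starts = n_starts
        self.seed = seed
        self.observed = model.y.copy()
        self.fittedvalues = model.predict(interaction)
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
        return self.model.variant

    def predict(self, T: float, P_MPa: float) -> float:
        """y2 at a new condition (P in MPa, matching the dataset units)."""
        return solve_solubility(
            self.model.variant, T, P_MPa * 1e6, self.model.solute,
            self.model.solvent, self.interaction, self.model.settings,
        )

    def summary(self) -> str:
        names = INTERACTION_NAMES[self.model.variant]
        lines = [
            f"{self.model.variant} EoS + Kwak-Mansoori mixing rules "
            f"({self.model.dataset.solute_name}/"
            f"{self.model.dataset.solvent_name})",
            "-" * 58,
            f"N = {self.nobs}, Q = {self.k_params}"
            + (f", starts = {self.n_starts}, seed = {self.seed}"
               if self.n_starts else ""),
        ]
        for name in names:
            lines.append(f"  {name:<22s} {getattr(self.interaction, name):.6g}")
        lines += [
            f"  {'AARD%':<22s} {self.aard_percent:.3f}",
            f"  {'R2':<22s} {self.r2:.4f}",
            f"  {'R2_adj':<22s} {self.r2_adj:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": self.model.variant,
            "interaction": {
                n: getattr(self.interaction, n)
                for n in INTERACTION_NAMES[self.model.variant]
            },
            "aard_percent": self.aard_percent,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "sse": self.sse,
            "n": self.nobs,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "predictions": self.fittedvalues.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def fit_interaction(
    variant: str,
    dataset: SolubilityDataset,
    solute: ComponentProperties,
    solvent: ComponentProperties,
    n_starts: int = 32,
    seed: int = 1,
    **kwargs,
) -> EoSResults:
    """Convenience wrapper: build the model and fit the interaction set."""
    model = EoSSolubilityModel(dataset, variant, solute, solvent)
    return model.fit(n_starts=n_starts, seed=seed, **kwargs)
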