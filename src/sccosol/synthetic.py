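"""Synthetic solubility datasets with known ground truth.

The generator emulates the structure of the embedded crizotinib fixture
(a rectangular temperature x pressure grid with a tabulated CO2 density at
each node) so that parameter-recovery and robustness tests can run against
a truth model whose parameters are known exactly.  Noise is multiplicative
Gaussian — ``y2 = truth * (1 + eps)`` with ``eps ~ N(0, noise_cv)`` — because
the fixture's reported standard deviations scale roughly with y2; the
coefficient-of-variation parameterization makes that explicit.  Draws that
would produce a non-positive mole fraction are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import crizotinib_fixture
from .dataset import SolubilityDataset, SolubilityRecord

__all__ = [
    "GenerationError",
    "GeneratorSpec",
    "fixture_density_table",
    "generate",
]

#: Safety cap on redraws per grid point before giving up.
_MAX_REDRAWS = 1000


class GenerationError(RuntimeError):
    """Raised when the truth model cannot produce a valid dataset."""


def fixture_density_table() -> dict[tuple[float, float], float]:
    """The 24 tabulated (T [K], P [MPa]) -> rho1 [kg/m3] fixture densities."""
    return {
        (r.temperature, r.pressure): r.co2_density
        for r in crizotinib_fixture()
    }


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    Parameters
    ----------
    truth_model : callable or fitted result
        Either a callable ``f(T, P, rho) -> y2`` or any fitted result
        exposing ``predict(T, P, rho)`` (density-model results do; EoS
        results are adapted automatically from their ``predict(T, P_MPa)``).
    temperatures, pressures : sequences
        Grid axes, K and MPa.  Default: the fixture's 4 x 6 grid.
    density_model : mapping or callable, optional
        ``(T, P) -> rho1`` in kg/m3.  Default: the 24 fixture densities.
    noise_cv : float
        Coefficient of variation of the multiplicative Gaussian noise.
    seed : int
        Seed for the random generator; same seed => identical dataset.
    """

    truth_model: object
    temperatures: Sequence[float] = (308.0, 318.0, 328.0, 338.0)
    pressures: Sequence[float] = (12.0, 15.0, 18.0, 21.0, 24.0, 27.0)
    density_model: Mapping[tuple[float, float], float] | Callable | None = None
    noise_cv: float = 0.0
    seed: int = 0
    solute_name: str = "synthetic solute"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.temperatures or not self.pressures:
            raise ValueError("temperature and pressure grids must be nonempty")

    # -- helpers -------------------------------------------------------------
    def density_at(self, T: float, P: float) -> float:
        table = self.density_model
        if table is None:
            table = fixture_density_table()
        if callable(table):
            return float(table(T, P))
        try:
            return float(table[(T, P)])
        except KeyError:
            raise GenerationError(
                f"no density tabulated at (T={T} K, P={P} MPa); supply a "
                "density_model covering the requested grid"
            ) from None

    def truth_at(self, T: float, P: float, rho: float) -> float:
        model = self.truth_model
        if callable(model) and not hasattr(model, "predict"):
            return float(model(T, P, rho))
        try:  # density-model results: predict(T, P, rho)
            return float(model.predict(T, P, rho))
        except TypeError:  # EoS results: predict(T, P_MPa)
            return float(model.predict(T, P))


def generate(spec: GeneratorSpec) -> SolubilityDataset:
    """Draw one synthetic dataset according to ``spec``.

    Deterministic under ``spec.seed``; negative/zero noisy draws are
    redrawn so every record satisfies the dataset invariants.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for T in spec.temperatures:
        for P in spec.pressures:
            rho = spec.density_at(T, P)
            truth = spec.truth_at(T, P, rho)
            if not (np.isfinite(truth) and 0.0 < truth < 1.0):
                raise GenerationError(
                    f"truth model returned invalid y2={truth!r} at "
                    f"(T={T} K, P={P} MPa, rho={rho} kg/m3)"
                )
            y2 = truth
            if spec.noise_cv > 0:
                for _ in range(_MAX_REDRAWS):
                    y2 = truth * (1.0 + rng.normal(0.0, spec.noise_cv))
                    if 0.0 < y2 < 1.0:
                        break
                else:
                    raise GenerationError(
                        f"could not draw a positive y2 at (T={T}, P={P}) "
                        f"after {_MAX_REDRAWS} attempts (noise_cv too large?)"
                    )
            records.append(
                SolubilityRecord(
                    temperature=float(T),
                    pressure=float(P),
                    co2_density=rho,
                    mole_fraction=float(y2),
                )
            )
    return SolubilityDataset(records, solute_name=spec.solute_name)
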