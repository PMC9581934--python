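"""Solubility data model, unit conventions and mole-fraction conversions.

The universal input of every model in this package is an isothermal table of
solid-solute solubility in supercritical CO2: temperature (K), pressure (MPa),
CO2 density (kg/m3, an *input*, e.g. from the NIST correlation) and solute
mole fraction y2.  Everything internal is SI (K, Pa, m3, mol) with the two
interface conveniences the source tables use: pressure in MPa and density in
kg/m3 (numerically equal to g/L).

Conversions between the sampling-loop concentration C_s, the equilibrium
solubility S (g solute per litre of saturated fluid) and the mole fraction y2
follow from the loop geometry:

    n_drug = C_s * V_s / M_s,   n_CO2 = V_1 * rho / M_CO2,
    y2 = n_drug / (n_drug + n_CO2),   S = C_s * V_s / V_1,
    S = (rho * M_s / M_CO2) * y2 / (1 - y2).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GAS_CONSTANT",
    "SolubilityRecord",
    "SolubilityDataset",
    "SamplingGeometry",
    "ComponentProperties",
    "SchemaError",
    "mole_fraction_from_concentration",
    "equilibrium_solubility_S",
    "S_from_y2",
    "y2_from_S",
    "load_dataset",
    "write_dataset",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

CSV_COLUMNS = (
    "temperature_K",
    "pressure_MPa",
    "co2_density_kg_m3",
    "y2",
    "sd_y2",
    "S_g_L",
    "U",
)
_REQUIRED_COLUMNS = CSV_COLUMNS[:4]


class SchemaError(ValueError):
    """Raised when a dataset file violates the documented schema."""


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium measurement: (T, P, rho1, y2) plus optional metadata.

    Parameters
    ----------
    temperature : float
        Kelvin, > 0.
    pressure : float
        MPa, > 0.
    co2_density : float
        Pure-CO2 density rho1 at (T, P), kg/m3.
    mole_fraction : float
        Solute mole fraction y2, in (0, 1).
    std_dev : float, optional
        Experimental standard deviation of y2 (same scale as y2).
    equilibrium_solubility : float, optional
        S in g/L; when present must be consistent with y2 at the printed
        rounding (checked to 5% relative by :class:`SolubilityDataset`).
    expanded_uncertainty : float, optional
        Expanded uncertainty U of y2 (coverage factor k=2).
    """

    temperature: float
    pressure: float
    co2_density: float
    mole_fraction: float
    std_dev: float | None = None
    equilibrium_solubility: float | None = None
    expanded_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.pressure > 0:
            raise ValueError(f"pressure must be > 0 MPa, got {self.pressure}")
        if not self.co2_density > 0:
            raise ValueError(f"co2_density must be > 0, got {self.co2_density}")
        if not 0.0 < self.mole_fraction < 1.0:
            raise ValueError(
                f"mole_fraction must lie in (0, 1), got {self.mole_fraction}"
            )


@dataclass(frozen=True)
class SamplingGeometry:
    """Sampling-loop geometry and molar masses used by the conversions.

    Volumes in m3; molar masses in g/mol.  The defaults are the 600 uL loop /
    5 mL collection-vial geometry of the crizotinib measurements.
    """

    loop_volume: float = 600e-9       # V_1, m3 (600 uL)
    vial_volume: float = 5e-6         # V_s, m3 (5 mL)
    solute_molar_mass: float = 450.3  # M_s, g/mol
    solvent_molar_mass: float = 44.01  # M_CO2, g/mol

    def __post_init__(self) -> None:
        for name in ("loop_volume", "vial_volume", "solute_molar_mass",
                     "solvent_molar_mass"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ComponentProperties:
    """Critical and physical pure-component properties.

    Attributes
    ----------
    name : str
    tc : float
        Critical temperature, K.
    pc : float
        Critical pressure, Pa.
    omega : float
        Acentric factor.
    molar_mass : float
        g/mol.
    solid_molar_volume : float, optional
        Molar volume of the pure solid, m3/mol (solutes only).
    sublimation_pressures : mapping, optional
        Tabulated sublimation pressures {T [K]: P_sub [Pa]} (solutes only).
    """

    name: str
    tc: float
    pc: float
    omega: float
    molar_mass: float
    solid_molar_volume: float | None = None
    sublimation_pressures: Mapping[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.tc > 0 and self.pc > 0 and self.molar_mass > 0):
            raise ValueError("tc, pc and molar_mass must be positive")

    def sublimation_pressure(self, temperature: float) -> float:
        """P_sub at ``temperature`` [K], in Pa.

        Exact at tabulated temperatures; elsewhere log-linear in 1/T
        (Clausius-Clapeyron interpolation/extrapolation).
        """
        tab = self.sublimation_pressures
        if not tab:
            raise ValueError(f"no sublimation pressures tabulated for {self.name}")
        if temperature in tab:
            return tab[temperature]
        ts = sorted(tab)
        if len(ts) == 1:
            raise ValueError("need >= 2 tabulated points to interpolate")
        # pick the bracketing (or nearest) pair in 1/T
        lo = max((t for t in ts if t <= temperature), default=ts[0])
        hi = min((t for t in ts if t >= temperature), default=ts[-1])
        if lo == hi:  # extrapolating beyond the table
            lo, hi = (ts[0], ts[1]) if temperature < ts[0] else (ts[-2], ts[-1])
        slope = (math.log(tab[hi]) - math.log(tab[lo])) / (1.0 / hi - 1.0 / lo)
        return math.exp(math.log(tab[lo]) + slope * (1.0 / temperature - 1.0 / lo))

    def to_json(self) -> str:
        d = asdict(self)
        if d["sublimation_pressures"] is not None:
            d["sublimation_pressures"] = {
                str(k): v for k, v in d["sublimation_pressures"].items()
            }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ComponentProperties":
        d = json.loads(text)
        if d.get("sublimation_pressures") is not None:
            d["sublimation_pressures"] = {
                float(k): float(v) for k, v in d["sublimation_pressures"].items()
            }
        return cls(**d)


class SolubilityDataset:
    """Ordered, validated collection of :class:`SolubilityRecord`.

    Records are sorted by (temperature, pressure) on construction; duplicate
    (T, P) pairs are rejected.  When a record carries both y2 and S the pair
    must satisfy S = (rho*M_s/M_CO2) * y2/(1-y2) within 5% relative (printed
    tables are rounded).
    """

    def __init__(
        self,
        records: Iterable[SolubilityRecord],
        solute_name: str = "solute",
        solvent_name: str = "CO2",
        geometry: SamplingGeometry | None = None,
    ) -> None:
        recs = sorted(records, key=lambda r: (r.temperature, r.pressure))
        seen: set[tuple[float, float]] = set()
        for r in recs:
            key = (r.temperature, r.pressure)
            if key in seen:
                raise ValueError(f"duplicate (T, P) pair {key}")
            seen.add(key)
        geom = geometry or SamplingGeometry()
        for r in recs:
            if r.equilibrium_solubility is not None:
                s_calc = S_from_y2(r.mole_fraction, r.co2_density, geom)
                if abs(s_calc - r.equilibrium_solubility) > 0.05 * s_calc:
                    raise ValueError(
                        f"inconsistent (y2, S) at T={r.temperature}, "
                        f"P={r.pressure}: S={r.equilibrium_solubility} vs "
                        f"computed {s_calc:.4g}"
                    )
        self.records: tuple[SolubilityRecord, ...] = tuple(recs)
        self.solute_name = solute_name
        self.solvent_name = solvent_name
        self.geometry = geom

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SolubilityDataset)
            and self.records == other.records
            and self.solute_name == other.solute_name
            and self.solvent_name == other.solvent_name
        )

    # -- column accessors ----------------------------------------------------
    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(r.temperature for r in self.records)

    @property
    def pressures(self) -> tuple[float, ...]:
        return tuple(r.pressure for r in self.records)

    @property
    def densities(self) -> tuple[float, ...]:
        return tuple(r.co2_density for r in self.records)

    @property
    def mole_fractions(self) -> tuple[float, ...]:
        return tuple(r.mole_fraction for r in self.records)

    def isotherms(self) -> dict[float, tuple[SolubilityRecord, ...]]:
        """Group records by temperature, preserving pressure order."""
        out: dict[float, list[SolubilityRecord]] = {}
        for r in self.records:
            out.setdefault(r.temperature, []).append(r)
        return {t: tuple(v) for t, v in out.items()}

    def isotherm_density(self, temperature: float, pressure: float) -> float:
        """CO2 density at ``pressure`` on the ``temperature`` isotherm,
        linearly interpolated in P between the tabulated grid points."""
        iso = self.isotherms().get(temperature)
        if iso is None:
            raise KeyError(f"no isotherm at T={temperature} K")
        ps = [r.pressure for r in iso]
        rhos = [r.co2_density for r in iso]
        if not ps[0] <= pressure <= ps[-1]:
            raise ValueError(
                f"pressure {pressure} outside tabulated range [{ps[0]}, {ps[-1]}]"
            )
        for k in range(len(ps) - 1):
            if ps[k] <= pressure <= ps[k + 1]:
                w = (pressure - ps[k]) / (ps[k + 1] - ps[k])
                return rhos[k] + w * (rhos[k + 1] - rhos[k])
        return rhos[-1]


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def mole_fraction_from_concentration(
    conc_g_per_L: float, co2_density: float, geom: SamplingGeometry
) -> float:
    """Mole fraction y2 from the vial concentration C_s [g/L].

    y2 = n_drug / (n_drug + n_CO2) with n_drug = C_s*V_s/M_s and
    n_CO2 = V_1*rho/M_CO2.  ``co2_density`` in kg/m3 (== g/L).
    """
    if conc_g_per_L < 0:
        raise ValueError("concentration must be >= 0")
    if not co2_density > 0:
        raise ValueError("co2_density must be > 0")
    # volumes in m3; g/L * m3 * 1000 L/m3 = g -> cancel the common factor 1000
    n_drug = conc_g_per_L * geom.vial_volume / geom.solute_molar_mass
    n_co2 = geom.loop_volume * co2_density / geom.solvent_molar_mass
    return n_drug / (n_drug + n_co2)


def equilibrium_solubility_S(conc_g_per_L: float, geom: SamplingGeometry) -> float:
    """Equilibrium solubility S = C_s * V_s / V_1, in g/L."""
    if conc_g_per_L < 0:
        raise ValueError("concentration must be >= 0")
    return conc_g_per_L * geom.vial_volume / geom.loop_volume


def S_from_y2(y2: float, co2_density: float, geom: SamplingGeometry) -> float:
    """S [g/L] from the mole fraction: S = (rho*M_s/M_CO2) * y2/(1-y2)."""
    if not 0.0 <= y2 < 1.0:
        raise ValueError("y2 must lie in [0, 1)")
    if not co2_density > 0:
        raise ValueError("co2_density must be > 0")
    return (co2_density * geom.solute_molar_mass / geom.solvent_molar_mass) * (
        y2 / (1.0 - y2)
    )


def y2_from_S(S: float, co2_density: float, geom: SamplingGeometry) -> float:
    """Inverse of :func:`S_from_y2`."""
    if S < 0:
        raise ValueError("S must be >= 0")
    if not co2_density > 0:
        raise ValueError("co2_density must be > 0")
    g = S * geom.solvent_molar_mass / (co2_density * geom.solute_molar_mass)
    return g / (1.0 + g)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_dataset(
    path: str | Path,
    solute_name: str = "solute",
    solvent_name: str = "CO2",
    geometry: SamplingGeometry | None = None,
) -> SolubilityDataset:
    """Read a dataset CSV (schema: temperature_K, pressure_MPa,
    co2_density_kg_m3, y2[, sd_y2, S_g_L, U])."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        records = []
        for i, row in enumerate(reader, start=2):
            try:
                rec = SolubilityRecord(
                    temperature=float(row["temperature_K"]),
                    pressure=float(row["pressure_MPa"]),
                    co2_density=float(row["co2_density_kg_m3"]),
                    mole_fraction=float(row["y2"]),
                    std_dev=_opt_float(row.get("sd_y2")),
                    equilibrium_solubility=_opt_float(row.get("S_g_L")),
                    expanded_uncertainty=_opt_float(row.get("U")),
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path} row {i}: {exc}") from exc
            records.append(rec)
    try:
        return SolubilityDataset(records, solute_name, solvent_name, geometry)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_dataset(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write ``dataset`` in the documented CSV schema (repr-precision floats,
    so write -> load round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in dataset:
            writer.writerow(
                [
                    repr(r.temperature),
                    repr(r.pressure),
                    repr(r.co2_density),
                    repr(r.mole_fraction),
                    "" if r.std_dev is None else repr(r.std_dev),
                    "" if r.equilibrium_solubility is None
                    else repr(r.equilibrium_solubility),
                    "" if r.expanded_uncertainty is None
                    else repr(r.expanded_uncertainty),
                ]
            )


def _opt_float(value: str | None) -> float | None:
    if value is None or value == "":
        return None
    return float(value)
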