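"""Built-in validation fixture: crizotinib solubility in supercritical CO2.

24 equilibrium measurements (4 isotherms at 308/318/328/338 K, 6 pressures
from 12 to 27 MPa) of crystalline crizotinib, an ALK-inhibitor anticancer
drug, in scCO2, together with the pure-component property records the cubic
equations of state need.  CO2 densities are NIST values at the stated (T, P).

The crizotinib critical constants are group-contribution estimates (Fedors /
Joback / Lee-Kesler chain) and the sublimation pressures a Lee-Kesler vapour
pressure correlation; they are consumed here as given constants.
"""

from __future__ import annotations

from .dataset import (
    ComponentProperties,
    SamplingGeometry,
    SolubilityDataset,
    SolubilityRecord,
)

__all__ = [
    "crizotinib_fixture",
    "crizotinib_properties",
    "co2_properties",
    "crizotinib_geometry",
]

# T [K], P [MPa], rho_CO2 [kg/m3], y2*1e5, S(ybar)*1e5, S [g/L], U*1e5
_CRIZOTINIB_TABLE = (
    (308, 12, 769, 0.483, 0.005, 0.038, 0.025),
    (308, 15, 817, 0.515, 0.009, 0.043, 0.029),
    (308, 18, 849, 0.556, 0.003, 0.048, 0.025),
    (308, 21, 875, 0.686, 0.014, 0.061, 0.043),
    (308, 24, 896, 0.730, 0.015, 0.067, 0.042),
    (308, 27, 914, 0.791, 0.021, 0.074, 0.056),
    (318, 12, 661, 0.315, 0.011, 0.021, 0.026),
    (318, 15, 744, 0.566, 0.015, 0.043, 0.039),
    (318, 18, 791, 0.650, 0.011, 0.053, 0.038),
    (318, 21, 824, 0.799, 0.016, 0.067, 0.046),
    (318, 24, 851, 0.899, 0.020, 0.078, 0.055),
    (318, 27, 872, 0.958, 0.041, 0.085, 0.090),
    (328, 12, 509, 0.260, 0.010, 0.013, 0.022),
    (328, 15, 656, 0.629, 0.015, 0.042, 0.042),
    (328, 18, 725, 0.749, 0.012, 0.056, 0.043),
    (328, 21, 769, 0.918, 0.019, 0.072, 0.056),
    (328, 24, 802, 0.995, 0.021, 0.082, 0.061),
    (328, 27, 829, 1.057, 0.032, 0.089, 0.079),
    (338, 12, 388, 0.156, 0.005, 0.006, 0.011),
    (338, 15, 557, 0.675, 0.022, 0.038, 0.051),
    (338, 18, 652, 0.870, 0.032, 0.058, 0.074),
    (338, 21, 710, 0.993, 0.035, 0.072, 0.088),
    (338, 24, 751, 1.083, 0.012, 0.083, 0.053),
    (338, 27, 783, 1.219, 0.054, 0.098, 0.123),
)


def crizotinib_geometry() -> SamplingGeometry:
    """600 uL sampling loop, 5 mL collection vial, crizotinib/CO2 masses."""
    return SamplingGeometry(
        loop_volume=600e-9,
        vial_volume=5e-6,
        solute_molar_mass=450.3,
        solvent_molar_mass=44.01,
    )


def crizotinib_fixture() -> SolubilityDataset:
    """The 24-point crizotinib/scCO2 dataset."""
    records = [
        SolubilityRecord(
            temperature=float(t),
            pressure=float(p),
            co2_density=float(rho),
            mole_fraction=y2e5 * 1e-5,
            std_dev=sd * 1e-5,
            equilibrium_solubility=s,
            expanded_uncertainty=u * 1e-5,
        )
        for (t, p, rho, y2e5, sd, s, u) in _CRIZOTINIB_TABLE
    ]
    return SolubilityDataset(
        records,
        solute_name="crizotinib",
        solvent_name="CO2",
        geometry=crizotinib_geometry(),
    )


def crizotinib_properties() -> ComponentProperties:
    """Crizotinib critical/physical constants (group-contribution estimates)."""
    return ComponentProperties(
        name="crizotinib",
        tc=485.25,
        pc=14.102e6,
        omega=0.4394,
        molar_mass=450.3,
        solid_molar_volume=32.12e-6,
        sublimation_pressures={308.0: 1072.0, 318.0: 1628.0,
                               328.0: 2398.0, 338.0: 3433.0},
    )


def co2_properties() -> ComponentProperties:
    return ComponentProperties(
        name="CO2",
        tc=304.18,
        pc=7.38e6,
        omega=0.225,
        molar_mass=44.01,
    )
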