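"""cubic_eos_km: pure constants, KM mixing, compressibility roots."""

import math

import pytest

from sccosol.data import co2_properties, crizotinib_properties
from sccosol.dataset import GAS_CONSTANT as R
from sccosol.eos import (
    EOS_VARIANTS,
    INTERACTION_NAMES,
    KMInteraction,
    PureKMConstants,
    RootError,
    attraction_E,
    cross_terms,
    km_mix,
    pure_constants,
    solve_Z,
)

CO2 = co2_properties()
DRUG = crizotinib_properties()


# ---------------------------------------------------------------------------
# Pure constants
# ---------------------------------------------------------------------------

def test_rk_pure_constants_formulas():
    p = pure_constants("RK", CO2)
    assert p.a == pytest.approx(0.42748 * R**2 * 304.18**2.5 / 7.38e6)
    assert p.b == pytest.approx(0.08664 * R * 304.18 / 7.38e6)
    assert p.c == 0.0 and p.d == 0.0


def test_pr_pure_constants_formulas():
    p = pure_constants("PR", CO2)
    a_tc = 0.45724 * R**2 * 304.18**2 / 7.38e6
    m = 0.37464 + 1.5422 * 0.225 - 0.26992 * 0.225**2
    assert p.a == pytest.approx(a_tc * (1 + m) ** 2)
    assert p.b == pytest.approx(0.07780 * R * 304.18 / 7.38e6)
    assert p.c == pytest.approx(a_tc * m**2 / (R * 304.18))


def test_srk3_pure_constants_formulas():
    p = pure_constants("SRK3", DRUG)
    a_tc = 0.42748 * R**2 * 485.25**2 / 14.102e6
    m = 0.48 + 1.574 * 0.4394 - 0.176 * 0.4394**2
    assert p.a == pytest.approx(a_tc * (1 + m) ** 2)
    assert p.c == pytest.approx(a_tc * m**2 / (R * 485.25))


def test_srk4_pure_constants_formulas():
    p = pure_constants("SRK4", CO2)
    a_tc = 0.42748 * R**2 * 304.18**2 / 7.38e6
    m = 0.484 + 1.515 * 0.225 - 0.044 * 0.225**2
    n = 2.756 * m - 0.7
    assert p.a == pytest.approx(a_tc * (1 + m + n))
    assert p.c == pytest.approx(a_tc * (n - m) / (R * 304.18))
    assert p.d == pytest.approx(2 * n * a_tc / (R * math.sqrt(304.18)))


def test_pure_constants_unknown_variant():
    with pytest.raises(ValueError):
        pure_constants("VDW", CO2)
    with pytest.raises(ValueError):
        PureKMConstants(a=-1.0, b=1e-5)


def test_srk_alpha_recomposition():
    """The KM decomposition recomposes the Soave alpha-function exactly:
    a + cRT - 2 sqrt(acRT) = a_tc (1 + m(1 - sqrt(Tr)))^2."""
    p = pure_constants("SRK3", CO2)
    a_tc = 0.42748 * R**2 * 304.18**2 / 7.38e6
    m = 0.48 + 1.574 * 0.225 - 0.176 * 0.225**2
    from sccosol.eos import MixtureConstants
    for T in (280.0, 308.0, 338.0, 400.0):
        e = attraction_E(MixtureConstants("SRK3", a=p.a, b=p.b, c=p.c), T)
        soave = a_tc * (1 + m * (1 - math.sqrt(T / 304.18))) ** 2
        assert e == pytest.approx(soave, rel=1e-12)


# ---------------------------------------------------------------------------
# Interaction records
# ---------------------------------------------------------------------------

def test_interaction_vector_roundtrip():
    for variant, names in INTERACTION_NAMES.items():
        vec = [0.1 * (i + 1) for i in range(len(names))]
        inter = KMInteraction.from_vector(variant, vec)
        assert inter.to_vector(variant) == tuple(vec)
    with pytest.raises(ValueError):
        KMInteraction.from_vector("RK", [0.1, 0.2, 0.3])


# ---------------------------------------------------------------------------
# Mixing rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant", EOS_VARIANTS)
def test_km_mix_reduces_to_pure_at_simplex_vertices(variant):
    pure = (pure_constants(variant, CO2), pure_constants(variant, DRUG))
    inter = KMInteraction(k_ij=0.3, l_ij=-0.2, m_ij=0.1, n_ij=0.05)
    for idx, x in ((0, (1.0, 0.0)), (1, (0.0, 1.0))):
        mix = km_mix(variant, x, pure, inter)
        p = pure[idx]
        assert mix.a == pytest.approx(p.a, rel=1e-12)
        assert mix.b == pytest.approx(p.b, rel=1e-12)
        assert mix.c == pytest.approx(p.c, rel=1e-12)
        assert mix.d == pytest.approx(p.d, rel=1e-12)


def test_cross_terms_symmetric_combining():
    pure = (pure_constants("PR", CO2), pure_constants("PR", DRUG))
    inter = KMInteraction(k_ij=0.2, l_ij=-0.1, m_ij=0.4)
    a, b, c, d = cross_terms("PR", pure, inter)
    assert a[0][1] == a[1][0]
    assert a[0][1] == pytest.approx(
        (1 - 0.2) * math.sqrt(pure[0].a * pure[1].a))
    cbrt = ((pure[0].b ** (1 / 3) + pure[1].b ** (1 / 3)) / 2) ** 3
    assert b[0][1] == pytest.approx((1 + 0.1) * cbrt)
    assert d is None


def test_km_mix_validates_composition():
    pure = (pure_constants("PR", CO2), pure_constants("PR", DRUG))
    inter = KMInteraction()
    with pytest.raises(ValueError):
        km_mix("PR", (0.7, 0.7), pure, inter)
    with pytest.raises(ValueError):
        km_mix("PR", (1.2, -0.2), pure, inter)


def test_km_mix_quadratic_composition_dependence():
    """For PR/SRK, a(x) is exactly quadratic in composition."""
    pure = (pure_constants("PR", CO2), pure_constants("PR", DRUG))
    inter = KMInteraction(k_ij=0.1)
    a, *_ = cross_terms("PR", pure, inter)
    for x2 in (0.0, 0.25, 0.5, 1.0):
        x = (1 - x2, x2)
        mix = km_mix("PR", x, pure, inter)
        expect = (x[0] ** 2 * a[0][0] + 2 * x[0] * x[1] * a[0][1]
                  + x[1] ** 2 * a[1][1])
        assert mix.a == pytest.approx(expect, rel=1e-12)


# ---------------------------------------------------------------------------
# Compressibility roots
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant", EOS_VARIANTS)
def test_ideal_gas_limit(variant):
    pure = (pure_constants(variant, CO2), pure_constants(variant, DRUG))
    mix = km_mix(variant, (1.0, 0.0), pure, KMInteraction())
    z, v = solve_Z(variant, mix, 308.0, 100.0)  # 100 Pa
    assert z == pytest.approx(1.0, abs=1e-3)
    assert v == pytest.approx(z * R * 308.0 / 100.0, rel=1e-12)


@pytest.mark.parametrize("variant", EOS_VARIANTS)
def test_z_root_satisfies_eos(variant):
    """The returned (Z, v) satisfies P = RT/(v-b) - E/denominator."""
    from sccosol.eos import _attr_denominator
    pure = (pure_constants(variant, CO2), pure_constants(variant, DRUG))
    mix = km_mix(variant, (1.0 - 1e-5, 1e-5), pure, KMInteraction())
    for T, P in ((308.0, 12e6), (318.0, 20e6), (338.0, 27e6)):
        z, v = solve_Z(variant, mix, T, P)
        assert v > mix.b
        p_back = R * T / (v - mix.b) - attraction_E(mix, T) / _attr_denominator(
            variant, v, mix.b)
        assert p_back == pytest.approx(P, rel=1e-8)


def test_z_dense_supercritical_regime():
    """At fixture conditions the CO2-rich phase is liquid-like (Z well below 1)."""
    pure = (pure_constants("PR", CO2), pure_constants("PR", DRUG))
    mix = km_mix("PR", (1.0, 0.0), pure, KMInteraction())
    z, v = solve_Z("PR", mix, 308.0, 12e6)
    assert 0.05 < z < 0.6
    # molar volume of the same order as NIST's M/rho at 769 kg/m3
    assert v == pytest.approx(0.04401 / 769.0, rel=0.25)


def test_solve_z_input_validation():
    pure = (pure_constants("RK", CO2), pure_constants("RK", DRUG))
    mix = km_mix("RK", (1.0, 0.0), pure, KMInteraction())
    with pytest.raises(ValueError):
        solve_Z("RK", mix, -1.0, 1e7)
    with pytest.raises(ValueError):
        solve_Z("RK", mix, 308.0, 0.0)


def test_fluid_root_always_above_covolume():
    """f(B) = -2B^2 < 0 for every variant's Z-cubic, so a fluid root with
    v > b exists across the whole fixture regime (RootError is reserved for
    residual failures)."""
    for variant in EOS_VARIANTS:
        pure = (pure_constants(variant, CO2), pure_constants(variant, DRUG))
        mix = km_mix(variant, (0.999, 0.001), pure, KMInteraction())
        for T in (308.0, 338.0):
            for P in (1e5, 12e6, 27e6, 5e7):
                z, v = solve_Z(variant, mix, T, P)
                assert v > mix.b
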