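"""density_models: predictors, fits, enthalpies, crossover."""

import math

import numpy as np
import pytest

from sccosol.data import crizotinib_fixture
from sccosol.dataset import GAS_CONSTANT, SolubilityDataset, SolubilityRecord
from sccosol.density import (
    BartleModel,
    BartleParams,
    ChrastilModel,
    ChrastilParams,
    MTModel,
    MTParams,
    ModifiedChrastilModel,
    ModifiedChrastilParams,
    NoCrossoverError,
    bartle_predict,
    chrastil_predict,
    crossover_pressure,
    dissolution_enthalpies,
    fit_density_model,
    modified_chrastil_predict,
    mt_lhs,
    mt_predict,
)

TABLE_CHRASTIL = ChrastilParams(kappa=4.0042, A1=-20.368, B1=-3677.8)
TABLE_MCHRASTIL = ModifiedChrastilParams(kappa_prime=4.0048, A2=-35.727,
                                         B2=-2709.0)


# ---------------------------------------------------------------------------
# Pointwise predictors
# ---------------------------------------------------------------------------

def test_chrastil_degenerate_half():
    p = ChrastilParams(kappa=1.0, A1=0.0, B1=0.0)
    for T, rho in ((250.0, 100.0), (400.0, 900.0)):
        assert chrastil_predict(p, T, rho) == pytest.approx(0.5)


def test_chrastil_reference_point():
    y = chrastil_predict(TABLE_CHRASTIL, 308.0, 769.0)
    assert y == pytest.approx(4.3e-6, rel=0.05)
    # consistent with the measured 4.83e-6 at the fitted AARD level
    assert abs(y - 4.83e-6) / 4.83e-6 < 0.15


def test_chrastil_monotone_in_density():
    rho = np.linspace(300.0, 950.0, 40)
    y = chrastil_predict(TABLE_CHRASTIL, 308.0, rho)
    assert np.all(np.diff(y) > 0)


def test_chrastil_input_validation():
    with pytest.raises(ValueError):
        chrastil_predict(TABLE_CHRASTIL, -1.0, 700.0)
    with pytest.raises(ValueError):
        chrastil_predict(TABLE_CHRASTIL, 308.0, 0.0)


def test_modified_chrastil_density_independent_when_kprime_one():
    p = ModifiedChrastilParams(kappa_prime=1.0, A2=-12.0, B2=-100.0)
    vals = [modified_chrastil_predict(p, 308.0, rho)
            for rho in (400.0, 700.0, 900.0)]
    assert vals[0] == pytest.approx(math.exp(-12.0 - 100.0 / 308.0))
    assert max(vals) == pytest.approx(min(vals))


def test_modified_chrastil_cross_model_consistency():
    y_mc = modified_chrastil_predict(TABLE_MCHRASTIL, 308.0, 769.0)
    y_c = chrastil_predict(TABLE_CHRASTIL, 308.0, 769.0)
    assert abs(y_mc - y_c) / y_c < 0.15


def test_modified_chrastil_fstd_reparameterization_invariance():
    """Scaling f0 by 10 and refitting shifts only A2; predictions unchanged."""
    ds = crizotinib_fixture()
    base = ModifiedChrastilModel(ds, f_std=1.0).fit()
    scaled = ModifiedChrastilModel(ds, f_std=10.0).fit()
    assert scaled.params.kappa_prime == pytest.approx(
        base.params.kappa_prime, abs=1e-4)
    rel = np.abs(scaled.fittedvalues - base.fittedvalues) / base.fittedvalues
    assert rel.max() < 1e-6
    # A2 absorbs (kappa'-1) ln 10
    shift = (base.params.kappa_prime - 1.0) * math.log(10.0)
    assert scaled.params.A2 - base.params.A2 == pytest.approx(shift, abs=1e-3)


def test_mt_predict_and_lhs_consistency():
    p = MTParams(A3=-7921.4, B3=2.5303, C3=9.6455)
    T, P, rho = 318.0, 18.0, 791.0
    y = mt_predict(p, T, P, rho)
    assert 0 < y < 1
    # T ln(y2 P) reproduces the affine form exactly
    assert mt_lhs(T, P, y) == pytest.approx(p.A3 + p.B3 * rho + p.C3 * T)
    with pytest.raises(ValueError):
        mt_lhs(T, P, 0.0)


def test_bartle_reference_convention():
    p = BartleParams(A4=11.249, B4=-5918.3, C4=7.4427e-3)
    assert p.P_ref == 0.1 and p.rho_ref == 700.0
    y = bartle_predict(p, 308.0, 12.0, 769.0)
    expect = (0.1 / 12.0) * math.exp(
        11.249 - 5918.3 / 308.0 + 7.4427e-3 * 69.0)
    assert y == pytest.approx(expect, rel=1e-12)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def test_fit_chrastil_reproduces_reference():
    res = fit_density_model("chrastil", crizotinib_fixture())
    assert res.aard_percent == pytest.approx(6.97, abs=0.05)
    assert res.params.kappa == pytest.approx(4.00, abs=0.01)
    assert res.params.B1 == pytest.approx(-3677.8, rel=5e-4)
    assert res.r2_adj <= res.r2
    assert res.sse == pytest.approx(1.034e-11, rel=0.02)


def test_fit_unknown_variant():
    with pytest.raises(ValueError, match="unknown model"):
        fit_density_model("nope", crizotinib_fixture())


def test_fit_underdetermined_dataset():
    recs = [SolubilityRecord(308.0, 12.0, 769.0, 1e-5),
            SolubilityRecord(308.0, 15.0, 817.0, 2e-5)]
    with pytest.raises(ValueError, match="at least"):
        ChrastilModel(SolubilityDataset(recs))


def test_fit_loss_switch():
    """The absolute-relative loss is available; it never has a larger OF than
    the squared-loss solution under its own objective."""
    ds = crizotinib_fixture()
    res_ssr = fit_density_model("chrastil", ds, loss="ssr")
    res_sar = fit_density_model("chrastil", ds, loss="sar")
    assert res_sar.of <= res_ssr.of + 1e-9
    assert res_sar.aard_percent <= res_ssr.aard_percent + 1e-9


def test_results_predict_matches_fittedvalues():
    ds = crizotinib_fixture()
    res = fit_density_model("chrastil", ds)
    r = ds[5]
    direct = res.predict(r.temperature, r.pressure, r.co2_density)
    assert float(direct) == pytest.approx(res.fittedvalues[5], rel=1e-12)
    # density omitted -> interpolated from the training isotherm
    assert float(res.predict(r.temperature, r.pressure)) == pytest.approx(
        res.fittedvalues[5], rel=1e-12)


def test_results_serialization_roundtrip():
    res = fit_density_model("mt", crizotinib_fixture())
    d = res.to_dict()
    assert d["variant"] == "mt"
    assert len(d["predictions"]) == 24
    assert d["aard_percent"] == pytest.approx(res.aard_percent)
    assert "summary" not in d  # payload is pure data
    assert "mt model fit" in res.summary()


# ---------------------------------------------------------------------------
# Enthalpies
# ---------------------------------------------------------------------------

def test_enthalpy_identities():
    ds = crizotinib_fixture()
    chr_fit = fit_density_model("chrastil", ds)
    bar_fit = fit_density_model("bartle", ds)
    ent = dissolution_enthalpies(chr_fit, bar_fit)
    assert ent.total == pytest.approx(
        -chr_fit.params.B1 * GAS_CONSTANT / 1000.0)
    assert ent.sublimation == pytest.approx(
        -bar_fit.params.B4 * GAS_CONSTANT / 1000.0)
    assert ent.solvation == pytest.approx(ent.total - ent.sublimation)
    assert ent.solvation < 0  # exothermic solvation step


def test_enthalpy_wrong_model_type():
    ds = crizotinib_fixture()
    mt_fit = fit_density_model("mt", ds)
    with pytest.raises(AttributeError):
        _ = mt_fit.total_enthalpy
    with pytest.raises(AttributeError):
        _ = mt_fit.sublimation_enthalpy


# ---------------------------------------------------------------------------
# Crossover
# ---------------------------------------------------------------------------

def test_crossover_bracketed_on_fixture():
    ds = crizotinib_fixture()
    res = fit_density_model("chrastil", ds)
    p = crossover_pressure(res, 308.0, 338.0)
    assert 12.0 < p < 27.0
    # the fitted isotherms really do cross there
    d = ds.isotherm_density
    lo = res.predict(308.0, p, d(308.0, p))
    hi = res.predict(338.0, p, d(338.0, p))
    assert float(lo) == pytest.approx(float(hi), rel=1e-8)


def test_crossover_requires_known_isotherms():
    res = fit_density_model("chrastil", crizotinib_fixture())
    with pytest.raises(KeyError):
        crossover_pressure(res, 300.0, 338.0)


def test_no_crossover_for_temperature_independent_model():
    """A fit with B1 = 0 and kappa fixed has isotherms that never cross."""
    from sccosol.density import DensityResults
    ds = crizotinib_fixture()
    model = ChrastilModel(ds)
    # B1 = 0: y2 depends on density only, and the cooler isotherm is denser
    # at every pressure, so the isotherms never intersect
    flat = DensityResults(model, np.array([4.0, -20.0, 0.0]))
    with pytest.raises(NoCrossoverError):
        crossover_pressure(flat, 308.0, 318.0)
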