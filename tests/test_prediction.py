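import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pomarch.errors import ConfigError, DataError, ParameterError, RankError
from pomarch.prediction import (
    CalibratedModel,
    VegShootParams,
    calibrate_alpha,
    default_internode_params,
    default_models,
    default_vs_params,
    predict_leaf_area,
    predict_total_leaf_area,
    predict_vs_leaf_area,
    reconstruct_spur,
)
from pomarch.profile import ProfileParams


@pytest.fixture
def bs_model():
    return CalibratedModel(
        shoot_type="BS",
        genotype_group=("AR", "FU"),
        params=ProfileParams(beta=0.67, s=0.36, x0=0.0),
        k=0.64,
        alpha=1.0,
    )


def test_bs_peak_leaf_value(bs_model):
    # peak leaf (rank 2): alpha * (pi/4) * k * Lmax^2
    assert predict_leaf_area(2, 5, 10.0, bs_model) == pytest.approx(
        math.pi / 4 * 0.64 * 100.0, abs=0.01
    )


def test_bs_offpeak_leaf_value(bs_model):
    expected = (math.pi / 4 * 0.64 * 100.0) / (1 + 4.0 / (25 * 0.36**2))
    assert predict_leaf_area(4, 5, 10.0, bs_model) == pytest.approx(expected, abs=0.01)
    assert expected == pytest.approx(22.49, abs=0.01)


def test_ro_peak_leaf_hits_maximum():
    model = CalibratedModel(
        shoot_type="RO",
        genotype_group=("AR", "FU", "RB"),
        params=ProfileParams(beta=0.69, s=0.38, x0=0.5),
        k=0.74,
        alpha=1.0,
    )
    # nl * x0 = 5: the peak rank is an integer here
    assert predict_leaf_area(5, 10, 8.0, model) == pytest.approx(
        math.pi / 4 * 0.74 * 64.0, rel=1e-12
    )


def test_leaf_area_input_validation(bs_model):
    with pytest.raises(RankError):
        predict_leaf_area(0, 5, 10.0, bs_model)
    with pytest.raises(RankError):
        predict_leaf_area(6, 5, 10.0, bs_model)
    with pytest.raises(ParameterError):
        predict_leaf_area(2, 5, -1.0, bs_model)


def test_vs_known_values():
    vs = VegShootParams(p=0.95, k=0.56)
    apical = predict_vs_leaf_area(10, 10, 8.0, vs)
    assert apical == pytest.approx(0.95 * math.pi / 4 * 0.56 * 64.0, abs=0.01)
    assert apical == pytest.approx(26.74, abs=0.01)
    assert predict_vs_leaf_area(5, 10, 8.0, vs) == pytest.approx(apical / 2, rel=1e-12)


def test_vs_p_one_apical_leaf_is_ellipse_maximum():
    vs = VegShootParams(p=1.0, k=0.56)
    assert predict_vs_leaf_area(10, 10, 8.0, vs) == pytest.approx(
        math.pi / 4 * 0.56 * 64.0, rel=1e-12
    )


def test_total_single_leaf(bs_model):
    assert predict_total_leaf_area(1, 10.0, bs_model) == pytest.approx(
        predict_leaf_area(1, 1, 10.0, bs_model), rel=1e-12
    )


def test_total_equals_brute_force_sum(bs_model):
    """Independent per-rank evaluation of the calibrated Lorentz chain for
    nl = 5, Lmax = 10, k = 0.64, s = 0.36: frozen brute-force total."""
    peak = math.pi / 4 * 0.64 * 100.0
    brute = sum(peak / (1 + (R - 2) ** 2 / (25 * 0.36**2)) for R in range(1, 6))
    assert brute == pytest.approx(162.89, abs=0.01)
    assert predict_total_leaf_area(5, 10.0, bs_model) == pytest.approx(brute, rel=1e-12)


@pytest.mark.parametrize("nl, tol", [(8, 0.04), (12, 0.03), (18, 0.025)])
def test_total_over_peak_ratio_approaches_beta(nl, tol):
    """TLA / (nl * alpha * (pi/4) * k * Lmax^2) tends to beta as the rank
    sum approaches the profile integral (finite-rank gap peaks near nl=8)."""
    m = default_models()[("BS", "FU")]
    tla = predict_total_leaf_area(nl, 10.0, m)
    peak = m.alpha * math.pi / 4 * m.k * 100.0
    assert abs(tla / (nl * peak) - m.params.beta) < tol


def test_calibrate_alpha_identity_and_bias():
    calc = [10.0, 20.0, 30.0]
    assert calibrate_alpha(calc, calc) == pytest.approx(1.0, rel=1e-12)
    assert calibrate_alpha([2 * c for c in calc], calc) == pytest.approx(2.0, rel=1e-12)


def test_calibrate_alpha_recovers_known_bias():
    rng = np.random.default_rng(12)
    calc = rng.uniform(20, 200, 100)
    measured = 1.2 * calc * (1 + 0.05 * rng.standard_normal(100))
    assert calibrate_alpha(measured, calc) == pytest.approx(1.2, abs=0.03)


def test_calibrate_alpha_input_validation():
    with pytest.raises(DataError):
        calibrate_alpha([], [])
    with pytest.raises(DataError):
        calibrate_alpha([1.0, 2.0], [1.0])
    with pytest.raises(DataError):
        calibrate_alpha([1.0], [0.0])


@pytest.mark.parametrize("genotype", ["AR", "FU", "RB"])
@pytest.mark.parametrize("nl", [2, 5, 9, 14, 18])
def test_bs_profile_peaks_at_rank_two(genotype, nl):
    m = default_models()[("BS", genotype)]
    areas = [predict_leaf_area(R, nl, 9.0, m) for R in range(1, nl + 1)]
    assert int(np.argmax(areas)) + 1 == 2


def test_bs_profile_symmetric_about_peak(bs_model):
    nl = 9
    areas = [predict_leaf_area(R, nl, 9.0, bs_model) for R in range(1, nl + 1)]
    # ranks equidistant from the peak rank 2 have equal areas
    assert areas[0] == pytest.approx(areas[2], rel=1e-12)  # ranks 1 and 3
    assert areas[1] > max(a for i, a in enumerate(areas) if i != 1)


def test_vs_areas_strictly_increase_with_rank():
    vs = default_vs_params()
    areas = [predict_vs_leaf_area(R, 12, 8.0, vs) for R in range(1, 13)]
    assert np.all(np.diff(areas) > 0)


@given(c=st.floats(0.2, 5.0), nl=st.integers(2, 18), R=st.integers(1, 18))
def test_areas_scale_with_lmax_squared(c, nl, R):
    if R > nl:
        R = nl
    m = default_models()[("BS", "AR")]
    a1 = predict_leaf_area(R, nl, 7.0, m)
    a2 = predict_leaf_area(R, nl, 7.0 * c, m)
    assert a2 == pytest.approx(a1 * c * c, rel=1e-9)


def test_reconstruct_spur_table_structure():
    models = default_models()
    internode = default_internode_params()
    table = reconstruct_spur(5, 6.0, 8, 9.0, 3.0, 14.0, models, internode, "FU")
    assert len(table) == 13
    assert list(table["rank_continuum"]) == list(range(1, 14))
    assert (table["shoot"].iloc[:5] == "RO").all()
    assert (table["shoot"].iloc[5:] == "BS").all()
    d = table["distance_cm"].to_numpy()
    assert np.all(np.diff(d) > 0)
    assert d.max() < 3.0 + 14.0  # logistic < 1 keeps distances inside the spur


def test_reconstruct_spur_total_area_is_additive():
    models = default_models()
    internode = default_internode_params()
    table = reconstruct_spur(5, 6.0, 8, 9.0, 3.0, 14.0, models, internode, "AR")
    expected = predict_total_leaf_area(
        5, 6.0, models[("RO", "AR")]
    ) + predict_total_leaf_area(8, 9.0, models[("BS", "AR")])
    assert table["area_cm2"].sum() == pytest.approx(expected, rel=1e-12)


def test_reconstruct_spur_degenerate_and_missing_params():
    models = default_models()
    internode = default_internode_params()
    with pytest.raises(DataError):
        reconstruct_spur(0, 6.0, 8, 9.0, 3.0, 14.0, models, internode, "FU")
    partial = {("RO", "FU"): models[("RO", "FU")]}
    with pytest.raises(ConfigError):
        reconstruct_spur(5, 6.0, 8, 9.0, 3.0, 14.0, partial, internode, "FU")
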