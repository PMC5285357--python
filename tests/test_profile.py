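import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import pomarch as pm
from pomarch.errors import DataError, ParameterError, RankError
from pomarch.profile import (
    beta_closed_form,
    bs_bounds,
    bs_s_table,
    estimate_x0,
    fit_beta,
    fit_profile_x0,
    lorentz,
    normalized_area,
    normalized_rank,
    solve_s,
)
from pomarch.records import LeafRecord, ShootRecord


@pytest.mark.parametrize(
    "R, nl, stype, expected",
    [
        (2, 7, "BS", 0.0),  # biggest bourse-shoot leaf aligns at zero
        (1, 4, "BS", -0.25),
        (4, 4, "RO", 1.0),
        (3, 6, "VS", 0.5),
    ],
)
def test_normalized_rank(R, nl, stype, expected):
    assert normalized_rank(R, nl, stype) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("R, nl", [(0, 5), (6, 5), (-1, 3)])
def test_normalized_rank_out_of_range(R, nl):
    with pytest.raises(RankError):
        normalized_rank(R, nl, "RO")


def test_normalized_area_bounds_and_degenerate():
    assert normalized_area(50.0, 50.0) == 1.0
    assert normalized_area(0.0, 50.0) == 0.0
    assert normalized_area(12.5, 50.0) == pytest.approx(0.25)
    with pytest.raises(DataError):
        normalized_area(1.0, 0.0)


@given(x0=st.floats(-1, 1), s=st.floats(0.05, 5.0), d=st.floats(0.0, 3.0))
def test_lorentz_peak_halfwidth_and_symmetry(x0, s, d):
    assert lorentz(x0, x0, s) == 1.0
    assert lorentz(x0 + s, x0, s) == pytest.approx(0.5, abs=1e-12)
    assert lorentz(x0 + d, x0, s) == pytest.approx(lorentz(x0 - d, x0, s), rel=1e-12)


def test_lorentz_rejects_nonpositive_scale():
    with pytest.raises(ParameterError):
        lorentz(0.0, 0.0, 0.0)


@pytest.mark.parametrize("s", [0.05, 0.2, 0.36, 1.0, 5.0])
@pytest.mark.parametrize(
    "lower, upper, x0",
    [(-0.4, 0.6, 0.0), (0.0, 1.0, 0.63), (-2.0, -1.0, 0.0), (-1.0, 2.0, 0.3)],
)
def test_closed_form_agrees_with_quadrature(s, lower, upper, x0):
    """The arctan closed form equals adaptive quadrature of the profile."""
    ref, _ = quad(lambda x: lorentz(x, x0, s), lower, upper, epsabs=1e-12)
    assert beta_closed_form(s, lower, upper, x0) == pytest.approx(ref, abs=1e-8)


def test_closed_form_monotone_in_s_and_bounded():
    grid = np.logspace(-3, 3, 200)
    vals = [beta_closed_form(s, -0.4, 0.6, 0.0) for s in grid]
    assert np.all(np.diff(vals) > 0)
    assert vals[-1] < 1.0
    assert beta_closed_form(1e6, 0.0, 1.0, 0.5) == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize(
    "beta, nl, expected",
    [(0.67, 1, 2.13), (0.67, 5, 0.36), (0.50, 18, 0.32)],
)
def test_solve_s_matches_printed_bourse_shoot_cells(beta, nl, expected):
    lo, up = bs_bounds(nl)
    assert solve_s(beta, lower=lo, upper=up) == pytest.approx(expected, abs=0.01)


def test_solve_s_rosette_value():
    s = solve_s(0.69, lower=0.0, upper=1.0, x0=0.63)
    assert s == pytest.approx(0.38, abs=0.01)


@pytest.mark.parametrize("beta", [0.1, 0.3, 0.5, 0.67, 0.8, 0.9])
@pytest.mark.parametrize("bounds", [(-0.4, 0.6, 0.0), (0.0, 1.0, 0.63)])
def test_solve_then_evaluate_round_trips(beta, bounds):
    lo, up, x0 = bounds
    s = solve_s(beta, lower=lo, upper=up, x0=x0)
    assert beta_closed_form(s, lo, up, x0) == pytest.approx(beta, abs=1e-9)


def test_solve_s_rejects_unattainable_beta():
    with pytest.raises(ParameterError):
        solve_s(1.0, lower=0.0, upper=1.0)  # equals the interval width
    with pytest.raises(ParameterError):
        solve_s(-0.2, lower=0.0, upper=1.0)


@pytest.mark.parametrize("nl", [8, 10, 14, 18])
def test_rank_sum_approaches_the_integral(nl):
    """The Riemann property tying the per-rank sum to beta: the gap is
    largest (~0.034) around nl = 8 and shrinks as leaves get denser."""
    beta = 0.67
    table = bs_s_table(beta)

    def gap(n):
        ranks = np.arange(1, n + 1)
        return float(np.sum(lorentz((ranks - 2) / n, 0.0, table[n]))) / n - beta

    assert abs(gap(nl)) < 0.04
    assert abs(gap(18)) < abs(gap(8))


def _shoot(areas, stype="RO", geno="FU", sid="S1"):
    leaves = []
    for i, a in enumerate(areas):
        L = math.sqrt(4 * a / math.pi)  # circular blade, W = L
        leaves.append(LeafRecord(rank=i + 1, blade_length=L, blade_width=L, area=a))
    return ShootRecord(sid, stype, geno, leaves)


def test_fit_beta_equal_leaves_gives_one():
    shoots = [_shoot([30.0] * 6, sid=f"S{i}") for i in range(4)]
    beta, r2 = fit_beta(shoots)
    assert beta == pytest.approx(1.0, abs=1e-12)


def test_fit_beta_empty_is_an_error():
    with pytest.raises(DataError):
        fit_beta([])


def test_fit_beta_on_exact_profile_matches_integral_within_riemann_gap():
    """Shoots lying exactly on the Lorentz curve at nl = 10 give a slope
    within the finite-rank Riemann gap (~0.03) of the integral beta."""
    nl = 10
    s = bs_s_table(0.67)[nl]
    areas = 50.0 * lorentz((np.arange(1, nl + 1) - 2) / nl, 0.0, s)
    shoots = [_shoot(list(areas), stype="BS", geno="AR", sid=f"B{i}") for i in range(5)]
    beta, _ = fit_beta(shoots)
    assert beta == pytest.approx(0.67, abs=0.04)


def test_fit_beta_recovers_truth_from_noisy_synthetic_shoots():
    """200 AR/FU-like bourse shoots with default multiplicative area noise:
    the through-origin slope recovers beta = 0.67 within 0.02."""
    from pomarch.synthetic import SyntheticConfig, generate_leaf_dataset

    cfg = SyntheticConfig(n_bs={"AR": 100, "FU": 100}, n_ro={}, n_vs={})
    df, _ = generate_leaf_dataset(cfg, seed=5)
    shoots = pm.shoots_from_frame(df)
    beta, _ = fit_beta(shoots)
    assert beta == pytest.approx(0.67, abs=0.02)


def test_estimate_x0_single_rosette():
    areas = [10, 20, 30, 40, 55, 40, 30, 20]  # biggest at rank 5 of 8
    assert estimate_x0([_shoot(areas)]) == pytest.approx(0.625)


def test_estimate_x0_consistent_rosettes():
    shoots = []
    for i, nl in enumerate([100] * 3):  # RAmax/nl = 0.63 exactly
        areas = [1.0] * nl
        areas[62] = 2.0
        shoots.append(_shoot(areas, sid=f"R{i}"))
    assert estimate_x0(shoots) == pytest.approx(0.63)


def test_estimate_x0_empty_is_an_error():
    with pytest.raises(DataError):
        estimate_x0([])


def test_x0_recovery_from_noisy_rosettes():
    """80 synthetic rosettes generated around x0 = 0.63 with default noise:
    both x0 estimators land within 0.03."""
    from pomarch.synthetic import SyntheticConfig, generate_leaf_dataset

    cfg = SyntheticConfig(n_bs={}, n_ro={"FU": 80}, n_vs={})
    df, _ = generate_leaf_dataset(cfg, seed=6)
    shoots = pm.shoots_from_frame(df)
    assert fit_profile_x0(shoots) == pytest.approx(0.63, abs=0.03)
    assert estimate_x0(shoots) == pytest.approx(0.63, abs=0.03)
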