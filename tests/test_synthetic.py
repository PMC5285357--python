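import numpy as np
import pytest

import pomarch as pm
from pomarch.errors import ConfigError
from pomarch.internode import InternodeModel
from pomarch.profile import fit_beta, fit_profile_x0, lorentz
from pomarch.synthetic import (
    BS_PEAK_RANK_DIST,
    SyntheticConfig,
    generate_internode_dataset,
    generate_leaf_dataset,
    generate_temperature_series,
    truth_models,
)

from conftest import zero_noise_config


def test_generation_is_deterministic_per_seed():
    cfg = SyntheticConfig(n_bs={"AR": 10}, n_ro={"FU": 10}, n_vs={"AR": 4})
    a, _ = generate_leaf_dataset(cfg, seed=33)
    b, _ = generate_leaf_dataset(cfg, seed=33)
    c, _ = generate_leaf_dataset(cfg, seed=34)
    assert a.to_csv(index=False) == b.to_csv(index=False)
    assert a.to_csv(index=False) != c.to_csv(index=False)
    ia, _ = generate_internode_dataset(cfg, seed=33)
    ib, _ = generate_internode_dataset(cfg, seed=33)
    assert ia.to_csv(index=False) == ib.to_csv(index=False)
    ta = generate_temperature_series(cfg, seed=33)
    tb = generate_temperature_series(cfg, seed=33)
    assert ta.to_csv(index=False) == tb.to_csv(index=False)


def test_config_validation():
    with pytest.raises(ConfigError):
        SyntheticConfig(profile_mode="exact")
    with pytest.raises(ConfigError):
        SyntheticConfig(leaf_area_noise_cv=-0.1)


def test_modal_biggest_leaf_rank_is_two():
    """500 bourse shoots: the empirical modal biggest-leaf rank matches the
    strong rank-2 concentration of the observed distribution."""
    cfg = SyntheticConfig(n_bs={"RB": 500}, n_ro={}, n_vs={})
    df, _ = generate_leaf_dataset(cfg, seed=1)
    shoots = pm.shoots_from_frame(df)
    ranks = np.array([sh.RAmax for sh in shoots])
    values, counts = np.unique(ranks, return_counts=True)
    assert values[np.argmax(counts)] == 2
    # RB concentrates ~87.5% of peaks at rank 2
    assert (ranks == 2).mean() > 0.75


def test_zero_noise_slope_exact_mode_satisfies_the_allometry():
    df, truth = generate_leaf_dataset(zero_noise_config(), seed=11)
    shoots = pm.shoots_from_frame(df)
    for sh in shoots:
        if sh.shoot_type == "VS":
            continue
        beta = truth.models[(sh.shoot_type, sh.genotype)].params.beta
        assert sh.TLA / (sh.nl * sh.Amax) == pytest.approx(beta, abs=1e-9)


def test_zero_noise_shape_exact_mode_lies_on_the_lorentz_curve():
    cfg = zero_noise_config(profile_mode="shape-exact", ro_peak_mode="continuous")
    df, truth = generate_leaf_dataset(cfg, seed=12)
    shoots = [sh for sh in pm.shoots_from_frame(df) if sh.shoot_type == "RO"]
    per_shoot = truth.per_shoot.set_index("shoot_id")
    for sh in shoots[:20]:
        center = per_shoot.loc[sh.shoot_id, "peak_center"]
        s = per_shoot.loc[sh.shoot_id, "s"]
        f = lorentz(np.arange(1, sh.nl + 1) / sh.nl, center / sh.nl, s)
        areas = np.array([lf.area for lf in sh.leaves])
        np.testing.assert_allclose(areas / areas.max(), f / f.max(), rtol=1e-9)


def test_internode_dataset_respects_physical_bounds():
    df, _ = generate_internode_dataset(SyntheticConfig(), seed=13)
    for _, grp in df.groupby("spur_id"):
        grp = grp.sort_values("rank_continuum")
        total = grp["bourse_length_cm"].iloc[0] + grp["bourse_shoot_length_cm"].iloc[0]
        d = grp["cum_length_cm"].to_numpy()
        assert (d >= 0).all() and (d <= total).all()
        assert np.all(np.diff(d) >= 0)


def test_peak_rank_distributions_are_normalized():
    for geno, dist in BS_PEAK_RANK_DIST.items():
        assert sum(dist.values()) == pytest.approx(1.0, abs=0.05)
        assert max(dist, key=dist.get) == 2


def test_estimators_are_unbiased_across_seeds():
    """Monte-Carlo bias check over 50 seeds at the study's sample sizes.

    The slope estimators (beta) are exactly unbiased by construction of the
    noise model; the curved estimators (k through eccentricity noise, the
    logistic qi/si, the pooled x0 fit) carry second-order biases well below
    the 2-decimal resolution at which the parameters are reported, so the
    tolerance is max(3 Monte-Carlo s.e., 0.01)."""
    n_seeds = 50
    est = {"beta": [], "k": [], "x0": [], "qi": [], "si": []}
    cfg = SyntheticConfig(
        n_bs={"AR": 40, "FU": 40}, n_ro={"FU": 60}, n_vs={}, n_spurs=24
    )
    for seed in range(n_seeds):
        df, _ = generate_leaf_dataset(cfg, seed=seed)
        shoots = pm.shoots_from_frame(df)
        bs = [sh for sh in shoots if sh.shoot_type == "BS"]
        ro = [sh for sh in shoots if sh.shoot_type == "RO"]
        est["beta"].append(fit_beta(bs)[0])
        est["k"].append(
            pm.fit_k([lf for sh in bs if sh.genotype == "FU" for lf in sh.leaves]).k
        )
        est["x0"].append(fit_profile_x0(ro))
        dfi, _ = generate_internode_dataset(cfg, seed=seed)
        res = InternodeModel.from_dataframe(dfi).fit()
        est["qi"].append(res.qi)
        est["si"].append(res.si)
    truths = {"beta": 0.67, "k": 0.64, "x0": 0.63, "qi": 0.62, "si": 0.12}
    for name, values in est.items():
        values = np.asarray(values)
        bias = values.mean() - truths[name]
        mc_se = values.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(bias) < max(3 * mc_se, 0.01), (
            f"{name}: bias {bias:.4f} exceeds max(3*{mc_se:.4f}, 0.01)"
        )


def test_temperature_series_shape_and_cycle():
    cfg = SyntheticConfig(n_days=5, temp_mean=17.0, temp_amplitude=6.0)
    df = generate_temperature_series(cfg, seed=0)
    assert len(df) == 5 * 24
    temps = df["temp_C"].to_numpy()
    assert temps.max() == pytest.approx(23.0, abs=1e-9)
    assert temps.min() == pytest.approx(11.0, abs=1e-9)
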