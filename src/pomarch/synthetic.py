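"""Synthetic orchard-like datasets with recorded ground truth.

The generator emulates the statistical structure the allometric analysis
assumes — shoots whose normalized leaf areas follow a Lorentz profile over
normalized rank, elliptical blades with a genotype-specific width/length
ratio, the biggest bourse-shoot leaf concentrated at rank 2, and logistic
cumulative internode length along the spur continuum — so that every
fitting stage can be exercised, with known parameters, without any orchard
measurement.

Two zero-noise idealisations are available, because at finite leaf number a
shoot cannot simultaneously lie exactly on the Lorentz curve and satisfy
the integral allometry TLA = beta * nl * Amax (the rank sum of the profile
differs from its integral by the Riemann gap):

* ``profile_mode="slope-exact"`` (default): non-peak leaf areas are rescaled
  per shoot so that TLA = beta * nl * Amax holds exactly; the slope
  estimators (beta, and through it the scale table s) close exactly.
* ``profile_mode="shape-exact"``: leaf areas sit exactly on the Lorentz
  curve; the profile-shape estimators (x0) and the calibration slope alpha
  close exactly.

The calibration slope alpha (and the vegetative-shoot slope p) is embedded
as a uniform blade-area-to-ellipse-model ratio: recorded areas equal
alpha times the (pi/4)*k*L^2 chain evaluated from the recorded blade
lengths, which is how a systematic deviation of real blades from the
ellipse model surfaces in the data.

All randomness flows from a single seed through named substreams per stage,
so the leaf, internode and temperature generators are independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .errors import ConfigError
from .internode import InternodeParams, logistic_ndi
from .prediction import CalibratedModel, VegShootParams, default_models
from .profile import bs_s_table, solve_s
from . import prediction as _pred

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "truth_models",
    "generate_leaf_dataset",
    "generate_internode_dataset",
    "generate_temperature_series",
]

#: Observed distribution of the biggest-leaf rank on bourse shoots, per
#: genotype (probabilities over ranks 1..6; renormalized).
BS_PEAK_RANK_DIST: dict[str, dict[int, float]] = {
    "AR": {1: 0.0065, 2: 0.5000, 3: 0.2662, 4: 0.1558, 5: 0.0584, 6: 0.0130},
    "FU": {1: 0.0808, 2: 0.6869, 3: 0.1414, 4: 0.0357, 5: 0.0089},
    "RB": {2: 0.8750, 3: 0.0804, 4: 0.0357, 5: 0.0089},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults emulate the study's orchard data
    (sample sizes per genotype, leaf counts, blade sizes, noise levels)."""

    n_bs: Mapping[str, int] = field(
        default_factory=lambda: {"AR": 60, "FU": 60, "RB": 60}
    )
    n_ro: Mapping[str, int] = field(
        default_factory=lambda: {"AR": 78, "FU": 77, "RB": 77}
    )
    n_vs: Mapping[str, int] = field(default_factory=lambda: {"AR": 20, "FU": 20})
    #: truncated-Poisson leaf-count means and inclusive ranges per shoot type
    nl_mean: Mapping[str, float] = field(
        default_factory=lambda: {"BS": 6.0, "RO": 5.0, "VS": 12.0}
    )
    nl_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"BS": (2, 18), "RO": (2, 18), "VS": (3, 18)}
    )
    lmax_median: float = 8.0  # cm
    lmax_sigma_log: float = 0.2
    #: per-leaf multiplicative lognormal noise on non-peak areas (CV)
    leaf_area_noise_cv: float = 0.10
    #: per-shoot lognormal deviation of the TLA allometry around beta (CV)
    beta_noise_cv: float = 0.05
    #: Gaussian noise on blade eccentricity
    ecc_noise_sd: float = 0.03
    #: Gaussian noise on normalized cumulative internode length
    internode_noise_sd: float = 0.05
    profile_mode: str = "slope-exact"  # or "shape-exact"
    bs_peak_mode: str = "table1"  # or "fixed2"
    ro_peak_mode: str = "quantized"  # or "continuous"
    # spur continuum
    n_spurs: int = 24
    spur_nl_mean: float = 13.0
    spur_nl_range: tuple[int, int] = (8, 18)
    bourse_length_median: float = 2.5  # cm
    bourse_length_sigma_log: float = 0.25
    bourse_shoot_length_median: float = 12.0  # cm
    bourse_shoot_length_sigma_log: float = 0.3
    # temperature series
    n_days: int = 30
    start_date: str = "2014-04-10"
    temp_mean: float = 17.0
    temp_amplitude: float = 6.0
    temp_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.profile_mode not in ("slope-exact", "shape-exact"):
            raise ConfigError(f"unknown profile_mode {self.profile_mode!r}")
        if self.bs_peak_mode not in ("table1", "fixed2"):
            raise ConfigError(f"unknown bs_peak_mode {self.bs_peak_mode!r}")
        if self.ro_peak_mode not in ("quantized", "continuous"):
            raise ConfigError(f"unknown ro_peak_mode {self.ro_peak_mode!r}")
        for cv in (self.leaf_area_noise_cv, self.beta_noise_cv,
                   self.ecc_noise_sd, self.internode_noise_sd):
            if cv < 0:
                raise ConfigError("noise levels must be nonnegative")


@dataclass
class SyntheticTruth:
    """The exact generating parameters attached to every synthetic dataset."""

    models: dict[tuple[str, str], CalibratedModel]
    vs: VegShootParams
    internode: InternodeParams
    config: SyntheticConfig
    seed: int
    per_shoot: pd.DataFrame | None = None


def truth_models() -> dict[tuple[str, str], CalibratedModel]:
    """The shipped parameter sets with solver-exact scale parameters.

    Identical to :func:`pomarch.prediction.default_models` except that s is
    recomputed from beta via the closed form to full precision (the shipped
    table is printed at 2 decimals), so generator->fitter closure can be
    checked at solver tolerance.
    """
    models = {}
    for (stype, g), m in default_models().items():
        if stype == "BS":
            s = bs_s_table(m.params.beta)
            params = replace(m.params, s=s)
        else:
            s = solve_s(m.params.beta, lower=0.0, upper=1.0, x0=m.params.x0)
            params = replace(m.params, s=s)
        models[(stype, g)] = replace(m, params=params)
    return models


def _lognormal_mean1(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size)


def _trunc_poisson(rng: np.random.Generator, mean: float, lo: int, hi: int, n: int):
    support = np.arange(lo, hi + 1)
    pmf = poisson.pmf(support, mean)
    pmf = pmf / pmf.sum()
    return rng.choice(support, size=n, p=pmf)


def _draw_peak_rank_bs(rng: np.random.Generator, genotype: str, nl: int) -> int:
    dist = BS_PEAK_RANK_DIST[genotype]
    ranks = np.array([r for r in dist if r <= nl])
    probs = np.array([dist[r] for r in ranks])
    probs = probs / probs.sum()
    return int(rng.choice(ranks, p=probs))


def _rescale_to_sum(f: np.ndarray, peak_idx: int, target: float) -> np.ndarray:
    """Scale the non-peak profile values so that sum(f)/f[peak] = target
    exactly, keeping every non-peak value strictly below the peak.

    A single multiplicative factor can push near-peak leaves above the peak
    (end-of-shoot peaks), so capped leaves are frozen at 0.9995 * peak and
    the remainder redistributed until the target is met.
    """
    f = f.copy()
    fpeak = f[peak_idx]
    cap = 0.9995 * fpeak
    remaining = (target - 1.0) * fpeak
    free = np.ones(len(f), dtype=bool)
    free[peak_idx] = False
    if remaining <= 0 or not free.any():
        return f
    for _ in range(len(f)):
        total_free = f[free].sum()
        if total_free <= 0:
            break
        c = remaining / total_free
        over = free & (f * c > cap)
        if not over.any():
            f[free] *= c
            return f
        f[over] = cap
        remaining -= cap * over.sum()
        free &= ~over
        if remaining <= 0:
            f[free] = 0.0
            break
    return f


def _stochastic_round(rng: np.random.Generator, x: float) -> int:
    """Round x to an adjacent integer with probability equal to proximity,
    so the expectation of the result is exactly x."""
    lo = math.floor(x)
    return lo + (1 if rng.random() < (x - lo) else 0)


def generate_leaf_dataset(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    models: Mapping[tuple[str, str], CalibratedModel] | None = None,
    vs: VegShootParams | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a leaf table (the leaf CSV dialect) plus its ground truth.

    For each shoot: draw the leaf count and the longest-leaf length, place
    the size peak (bourse shoots: rank drawn from the observed biggest-leaf
    rank distribution; rosettes: at the normalized position x0), lay the
    Lorentz (or linear, for vegetative shoots) profile over the ranks,
    apply the configured noise, and back-compute blade lengths and widths
    from areas through the eccentricity model.
    """
    config = config or SyntheticConfig()
    models = dict(models) if models is not None else truth_models()
    vs = vs or _pred.default_vs_params()
    rng = np.random.default_rng([seed, 1])
    rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit_shoot(sid, stype, geno, ranks, areas, ell_areas):
        """Append leaf rows; lengths/widths derive from the ellipse areas."""
        e0 = math.sqrt(max(0.0, 1.0 - _k_of(stype, geno) ** 2))
        for i, R in enumerate(ranks):
            e = float(np.clip(e0 + rng.normal(0.0, config.ecc_noise_sd), 0.02, 0.98))
            k_leaf = math.sqrt(1.0 - e * e)
            L = math.sqrt(4.0 * ell_areas[i] / (math.pi * k_leaf))
            W = k_leaf * L
            rows.append(
                {
                    "shoot_id": sid,
                    "genotype": geno,
                    "shoot_type": stype,
                    "rank": int(R),
                    "blade_length_cm": L,
                    "blade_width_cm": W,
                    "area_cm2": float(areas[i]),
                }
            )

    def _k_of(stype, geno):
        if stype == "VS":
            return vs.k
        return models[(stype, geno)].k

    for stype, counts in (("BS", config.n_bs), ("RO", config.n_ro)):
        lo, hi = config.nl_range[stype]
        for geno, n in counts.items():
            m = models[(stype, geno)]
            nls = _trunc_poisson(rng, config.nl_mean[stype], lo, hi, n)
            lmaxs = np.exp(
                rng.normal(math.log(config.lmax_median), config.lmax_sigma_log, n)
            )
            for i in range(n):
                nl = int(nls[i])
                lmax = float(lmaxs[i])
                s = m.params.s_for(nl)
                if stype == "BS":
                    peak = (
                        2
                        if config.bs_peak_mode == "fixed2"
                        else _draw_peak_rank_bs(rng, geno, nl)
                    )
                    center = float(peak)
                else:
                    target = nl * m.params.x0
                    if config.ro_peak_mode == "quantized":
                        center = float(
                            min(max(_stochastic_round(rng, target), 1), nl)
                        )
                    else:
                        center = target
                ranks = np.arange(1, nl + 1)
                f = 1.0 / (1.0 + ((ranks - center) / (nl * s)) ** 2)
                peak_idx = int(np.argmax(f))
                if config.profile_mode == "slope-exact":
                    # rescale non-peak leaves so TLA = beta * nl * Amax holds
                    # exactly (up to the per-shoot allometry deviation delta)
                    delta = float(_lognormal_mean1(rng, config.beta_noise_cv))
                    target = max(m.params.beta * delta * nl, 1.02)
                    f = _rescale_to_sum(f, peak_idx, target)
                # per-leaf noise on non-peak leaves, clamped below the peak
                if config.leaf_area_noise_cv > 0:
                    eps = _lognormal_mean1(rng, config.leaf_area_noise_cv, nl)
                    eps[peak_idx] = 1.0
                    f = np.minimum(f * eps, 0.9995 * f[peak_idx])
                amax_nom = m.alpha * (math.pi / 4.0) * m.k * lmax**2
                areas = amax_nom * f
                ell_areas = areas / m.alpha  # ellipse-model part of the area
                sid = f"{stype}-{geno}-{i:04d}"
                emit_shoot(sid, stype, geno, ranks, areas, ell_areas)
                truth_rows.append(
                    {
                        "shoot_id": sid,
                        "shoot_type": stype,
                        "genotype": geno,
                        "nl": nl,
                        "lmax_cm": lmax,
                        "peak_center": center,
                        "s": s,
                    }
                )

    lo, hi = config.nl_range["VS"]
    for geno, n in config.n_vs.items():
        nls = _trunc_poisson(rng, config.nl_mean["VS"], lo, hi, n)
        lmaxs = np.exp(
            rng.normal(math.log(config.lmax_median), config.lmax_sigma_log, n)
        )
        for i in range(n):
            nl = int(nls[i])
            lmax = float(lmaxs[i])
            ranks = np.arange(1, nl + 1)
            f = ranks / nl  # linear profile; apex is the biggest leaf
            if config.leaf_area_noise_cv > 0:
                eps = _lognormal_mean1(rng, config.leaf_area_noise_cv, nl)
                eps[-1] = 1.0
                f = np.minimum(f * eps, 0.9995)
                f[-1] = 1.0
            amax_nom = vs.p * (math.pi / 4.0) * vs.k * lmax**2
            areas = amax_nom * f
            ell_areas = areas / vs.p
            sid = f"VS-{geno}-{i:04d}"
            emit_shoot(sid, "VS", geno, ranks, areas, ell_areas)
            truth_rows.append(
                {
                    "shoot_id": sid,
                    "shoot_type": "VS",
                    "genotype": geno,
                    "nl": nl,
                    "lmax_cm": lmax,
                    "peak_center": float(nl),
                    "s": np.nan,
                }
            )

    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        models=models,
        vs=vs,
        internode=_pred.default_internode_params(),
        config=config,
        seed=seed,
        per_shoot=pd.DataFrame(truth_rows),
    )
    return df, truth


def generate_internode_dataset(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    params: InternodeParams | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a spur-continuum internode table plus its ground truth.

    Per spur: draw the continuum leaf count, the bourse length BL and the
    bourse-shoot length BSL; normalized cumulative lengths follow the
    logistic curve with clamped Gaussian noise, made monotone by isotonic
    projection (cumulative length is physically nondecreasing).
    """
    from sklearn.isotonic import IsotonicRegression

    config = config or SyntheticConfig()
    params = params or _pred.default_internode_params()
    rng = np.random.default_rng([seed, 2])
    rows = []
    lo, hi = config.spur_nl_range
    nls = _trunc_poisson(rng, config.spur_nl_mean, lo, hi, config.n_spurs)
    for i in range(config.n_spurs):
        nl = int(nls[i])
        bl = float(
            np.exp(
                rng.normal(
                    math.log(config.bourse_length_median),
                    config.bourse_length_sigma_log,
                )
            )
        )
        bsl = float(
            np.exp(
                rng.normal(
                    math.log(config.bourse_shoot_length_median),
                    config.bourse_shoot_length_sigma_log,
                )
            )
        )
        ranks = np.arange(1, nl + 1)
        ndi = logistic_ndi(ranks / nl, params)
        if config.internode_noise_sd > 0:
            ndi = ndi + rng.normal(0.0, config.internode_noise_sd, nl)
            ndi = np.clip(ndi, 1e-4, 1.0 - 1e-4)
            iso = IsotonicRegression(y_min=1e-4, y_max=1.0 - 1e-4)
            ndi = iso.fit_transform(ranks, ndi)
        d = ndi * (bl + bsl)
        for R, dist in zip(ranks, d):
            rows.append(
                {
                    "spur_id": f"SP-{i:03d}",
                    "rank_continuum": int(R),
                    "cum_length_cm": float(dist),
                    "bourse_length_cm": bl,
                    "bourse_shoot_length_cm": bsl,
                }
            )
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        models=truth_models(),
        vs=_pred.default_vs_params(),
        internode=params,
        config=config,
        seed=seed,
    )
    return df, truth


def generate_temperature_series(
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly temperature table with a sinusoidal daily cycle (24 readings
    per day), deterministic for a given seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng([seed, 3])
    start = pd.Timestamp(config.start_date)
    stamps = pd.date_range(start, periods=config.n_days * 24, freq="h")
    hours = stamps.hour.to_numpy()
    temps = config.temp_mean - config.temp_amplitude * np.cos(
        2.0 * math.pi * (hours - 14) / 24.0
    )
    if config.temp_noise_sd > 0:
        temps = temps + rng.normal(0.0, config.temp_noise_sd, temps.size)
    return pd.DataFrame(
        {"timestamp_iso": stamps.strftime("%Y-%m-%dT%H:%M:%S"), "temp_C": temps}
    )
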