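"""Parameterization / calibration / testing workflow and the top-level
Model/Results classes.

The workflow mirrors how the allometric models are built from orchard data:

1. grouping tests — compare the per-shoot slope TLA/(nl*Amax) across
   genotypes (Shapiro-Wilk on residuals routes to one-way ANOVA or
   Kruskal-Wallis) and pool genotypes that do not differ;
2. random 2/3 : 1/3 train/test split per genotype;
3. parameterization on the training set — beta (through-origin slope of TLA
   on nl*Amax), the Lorentz scale s from the arctan closed form (per leaf
   count for bourse shoots), the rosette peak position x0, and the blade
   ratio k per genotype;
4. calibration — alpha, the through-origin slope of measured on calculated
   total leaf area on the training set;
5. testing — R^2 / slope / RMSE of measured against predicted areas on the
   held-out set.

``ShootLeafAreaModel`` packages steps 2-5 for one shoot type and genotype
group; ``run_parameterization`` orchestrates the whole workflow across
groups and emits a parameter file plus a :class:`FitReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DataError, FitError
from .geometry import ShapeParams, fit_k
from .internode import InternodeModel, InternodeParams
from .prediction import (
    CalibratedModel,
    VegShootParams,
    calibrate_alpha,
    predict_leaf_area,
    predict_total_leaf_area,
    predict_vs_leaf_area,
)
from .profile import (
    ProfileParams,
    bs_s_table,
    estimate_x0,
    fit_beta,
    fit_profile_x0,
    solve_s,
)
from .records import ShootRecord, shoots_from_frame

__all__ = [
    "PipelineConfig",
    "EvalStats",
    "GroupComparison",
    "FitReport",
    "split_train_test",
    "compare_groups",
    "evaluate_fit",
    "ShootLeafAreaModel",
    "ShootLeafAreaResults",
    "VegetativeShootModel",
    "VegetativeShootResults",
    "run_parameterization",
]

DEFAULT_GROUPING: dict[str, tuple[tuple[str, ...], ...]] = {
    "BS": (("AR", "FU"), ("RB",)),
    "RO": (("AR", "FU", "RB"),),
    "VS": (("AR", "FU"),),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Workflow configuration: split fraction, seed, genotype grouping and
    the significance level of the grouping tests."""

    split_fraction: float = 2.0 / 3.0
    seed: int = 0
    grouping: Mapping[str, tuple[tuple[str, ...], ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPING)
    )
    significance_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise DataError(
                f"split fraction must be in (0, 1), got {self.split_fraction}"
            )


def split_train_test(
    shoots: Sequence, fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[list, list]:
    """Random, reproducible, disjoint and exhaustive train/test split with
    |train| = round(fraction * n)."""
    shoots = list(shoots)
    n = len(shoots)
    if n < 3:
        raise DataError(f"need at least 3 shoots to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = set(order[:n_train].tolist())
    train = [shoots[i] for i in range(n) if i in train_idx]
    test = [shoots[i] for i in range(n) if i not in train_idx]
    return train, test


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the normality-routed omnibus comparison between groups."""

    route: str  # "anova" or "kruskal"
    normality_p: float
    omnibus_p: float
    significant: bool
    pooled: tuple[tuple[str, ...], ...]
    pairwise_p: dict[tuple[str, str], float]


def _route_test(groups: list[np.ndarray], route: str) -> float:
    if np.ptp(np.concatenate(groups)) == 0:
        return 1.0
    if route == "anova":
        return float(_stats.f_oneway(*groups).pvalue)
    return float(_stats.kruskal(*groups).pvalue)


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    significance_level: float = 0.05,
) -> GroupComparison:
    """Decide which groups may be pooled for a shared parameter.

    Shapiro-Wilk on the within-group residuals routes to one-way ANOVA
    (residuals normal) or Kruskal-Wallis.  Groups are pooled transitively
    over pairwise non-significant differences.
    """
    names = list(samples)
    if len(names) < 2:
        raise DataError("need at least 2 groups to compare")
    groups = [np.asarray(samples[n], dtype=float) for n in names]
    for n, g in zip(names, groups):
        if g.size < 3:
            raise DataError(f"group {n!r} has fewer than 3 observations")
    resid = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(resid) == 0:
        normality_p = 1.0
    else:
        normality_p = float(_stats.shapiro(resid).pvalue)
    route = "anova" if normality_p > significance_level else "kruskal"
    omnibus_p = _route_test(groups, route)
    significant = omnibus_p < significance_level

    # pairwise pooling via union-find over non-significant pairs
    parent = {n: n for n in names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if not significant:
                p = 1.0
            else:
                p = _route_test([groups[i], groups[j]], route)
            pairwise[(names[i], names[j])] = p
            if p >= significance_level:
                parent[find(names[i])] = find(names[j])
    pools: dict[str, list[str]] = {}
    for n in names:
        pools.setdefault(find(n), []).append(n)
    pooled = tuple(tuple(sorted(v)) for v in sorted(pools.values()))
    return GroupComparison(
        route=route,
        normality_p=normality_p,
        omnibus_p=omnibus_p,
        significant=significant,
        pooled=pooled,
        pairwise_p=pairwise,
    )


@dataclass(frozen=True)
class EvalStats:
    """Agreement between observed and predicted values.

    ``slope`` is the through-origin regression slope of observed on
    predicted; ``slope_intercept``/``intercept`` come from the ordinary
    with-intercept regression (both are reported because testing
    regressions can be read either way); ``r2`` is the squared Pearson
    correlation; RMSE is on the original scale.
    """

    r2: float
    slope: float
    rmse: float
    slope_intercept: float
    intercept: float
    n: int


def evaluate_fit(observed, predicted) -> EvalStats:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise DataError(f"shape mismatch or empty: {obs.shape} vs {pred.shape}")
    if np.ptp(obs) == 0:
        raise DataError("degenerate evaluation: observed values have no variance")
    denom = float(np.sum(pred * pred))
    if denom <= 0:
        raise DataError("predicted values are all zero")
    slope = float(np.sum(pred * obs) / denom)
    if np.ptp(pred) == 0:
        r2, b1, b0 = 0.0, 0.0, float(obs.mean())
    else:
        r = float(_stats.pearsonr(obs, pred).statistic)
        r2 = r * r
        b1, b0 = np.polyfit(pred, obs, 1)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return EvalStats(
        r2=r2,
        slope=slope,
        rmse=rmse,
        slope_intercept=float(b1),
        intercept=float(b0),
        n=int(obs.size),
    )


# ---------------------------------------------------------------------------
# Model / Results classes


class ShootLeafAreaModel:
    """Lorentz leaf-area model for one shoot type and genotype group.

    Parameters
    ----------
    shoots
        :class:`ShootRecord` objects of a single shoot type ("BS" or "RO"),
        restricted to the genotypes of the group.
    shoot_type
        "BS" or "RO".
    genotypes
        The genotype group sharing one beta (e.g. ("AR", "FU")).  The blade
        ratio k and the calibration slope alpha remain genotype specific.
    """

    def __init__(
        self,
        shoots: Sequence[ShootRecord],
        shoot_type: str,
        genotypes: tuple[str, ...],
    ):
        if shoot_type not in ("BS", "RO"):
            raise DataError(f"ShootLeafAreaModel covers BS/RO, got {shoot_type!r}")
        self.shoot_type = shoot_type
        self.genotypes = tuple(genotypes)
        self.shoots = [
            sh
            for sh in shoots
            if sh.shoot_type == shoot_type and sh.genotype in self.genotypes
        ]
        if not self.shoots:
            raise DataError(
                f"no {shoot_type} shoots for genotypes {self.genotypes}"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        shoot_type: str,
        genotypes: tuple[str, ...] | None = None,
    ) -> "ShootLeafAreaModel":
        sub = df[df["shoot_type"] == shoot_type]
        if genotypes is None:
            genotypes = tuple(sorted(sub["genotype"].unique()))
        sub = sub[sub["genotype"].isin(genotypes)]
        return cls(shoots_from_frame(sub), shoot_type, genotypes)

    def fit(
        self,
        split_fraction: float = 2.0 / 3.0,
        seed: int = 0,
    ) -> "ShootLeafAreaResults":
        """Run parameterization, calibration and testing for this group."""
        train: list[ShootRecord] = []
        test: list[ShootRecord] = []
        for g in self.genotypes:
            sub = [sh for sh in self.shoots if sh.genotype == g]
            if not sub:
                continue
            if len(sub) < 3:
                train.extend(sub)
                continue
            tr, te = split_train_test(sub, split_fraction, seed=seed)
            train.extend(tr)
            test.extend(te)

        beta, beta_r2 = fit_beta(train)
        if not beta < 1.0:
            raise FitError(
                f"fitted beta={beta:.4f} >= 1: the closed form has no solution"
            )
        if self.shoot_type == "BS":
            x0 = 0.0
            s: float | dict[int, float] = bs_s_table(beta)
        else:
            if any(sh.RAmax is None for sh in train):  # pragma: no cover
                raise FitError("x0 stage: rosette ranks missing")
            x0 = fit_profile_x0(train)
            s = solve_s(beta, lower=0.0, upper=1.0, x0=x0)
        params = ProfileParams(beta=beta, s=s, x0=x0, beta_r2=beta_r2)

        shape: dict[str, ShapeParams] = {}
        alpha: dict[str, float] = {}
        models: dict[str, CalibratedModel] = {}
        train_eval: dict[str, EvalStats] = {}
        test_eval: dict[str, EvalStats] = {}
        leaf_eval: dict[str, EvalStats] = {}
        for g in self.genotypes:
            tr = [sh for sh in train if sh.genotype == g]
            if not tr:
                continue
            shape[g] = fit_k([lf for sh in tr for lf in sh.leaves])
            uncal = CalibratedModel(
                shoot_type=self.shoot_type,
                genotype_group=self.genotypes,
                params=params,
                k=shape[g].k,
                alpha=1.0,
            )
            measured = [sh.TLA for sh in tr]
            calculated = [
                predict_total_leaf_area(sh.nl, sh.Lmax, uncal) for sh in tr
            ]
            alpha[g] = calibrate_alpha(measured, calculated)
            models[g] = CalibratedModel(
                shoot_type=self.shoot_type,
                genotype_group=self.genotypes,
                params=params,
                k=shape[g].k,
                alpha=alpha[g],
            )
            cal = [c * alpha[g] for c in calculated]
            if len(tr) >= 2 and np.ptp(measured) > 0:
                train_eval[g] = evaluate_fit(measured, cal)
            te = [sh for sh in test if sh.genotype == g]
            if len(te) >= 2:
                obs = [sh.TLA for sh in te]
                pred = [
                    predict_total_leaf_area(sh.nl, sh.Lmax, models[g]) for sh in te
                ]
                if np.ptp(obs) > 0:
                    test_eval[g] = evaluate_fit(obs, pred)
                lobs = [lf.area for sh in te for lf in sh.leaves]
                lpred = [
                    predict_leaf_area(lf.rank, sh.nl, sh.Lmax, models[g])
                    for sh in te
                    for lf in sh.leaves
                ]
                if len(lobs) >= 2 and np.ptp(lobs) > 0:
                    leaf_eval[g] = evaluate_fit(lobs, lpred)

        return ShootLeafAreaResults(
            model=self,
            params=params,
            shape=shape,
            alpha=alpha,
            calibrated=models,
            n_train=len(train),
            n_test=len(test),
            train_eval=train_eval,
            test_eval=test_eval,
            leaf_eval=leaf_eval,
            seed=seed,
        )


@dataclass
class ShootLeafAreaResults:
    """Estimates, calibration and testing diagnostics for one shoot group."""

    model: ShootLeafAreaModel
    params: ProfileParams
    shape: dict[str, ShapeParams]
    alpha: dict[str, float]
    calibrated: dict[str, CalibratedModel]
    n_train: int
    n_test: int
    train_eval: dict[str, EvalStats]
    test_eval: dict[str, EvalStats]
    leaf_eval: dict[str, EvalStats]
    seed: int

    @property
    def beta(self) -> float:
        return self.params.beta

    @property
    def x0(self) -> float:
        return self.params.x0

    def s_for(self, nl: int) -> float:
        return self.params.s_for(nl)

    def k(self, genotype: str) -> float:
        return self.shape[genotype].k

    def to_calibrated(self, genotype: str) -> CalibratedModel:
        return self.calibrated[genotype]

    def predict(self, genotype: str, nl: int, Lmax: float) -> pd.DataFrame:
        """Per-rank predicted areas and the shoot total, as a table."""
        m = self.calibrated[genotype]
        rows = [
            {
                "rank": R,
                "area_cm2": predict_leaf_area(R, nl, Lmax, m),
            }
            for R in range(1, nl + 1)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Leaf-area model: shoot type {m.shoot_type}, "
            f"genotype group {'|'.join(m.genotypes)}",
            f"  shoots      : {len(m.shoots)} ({self.n_train} train / "
            f"{self.n_test} test, seed {self.seed})",
            f"  beta        : {self.beta:.4f}  (R^2 = {self.params.beta_r2:.3f})",
        ]
        if m.shoot_type == "BS":
            s5 = self.params.s_for(5)
            lines.append(f"  s           : per-nl table (e.g. s(5) = {s5:.3f}); x0 = 0")
        else:
            lines.append(
                f"  s, x0       : {self.params.s_for(1):.4f}, {self.x0:.4f}"
            )
        for g in sorted(self.shape):
            lines.append(
                f"  {g}: k = {self.shape[g].k:.3f} "
                f"(R^2 = {self.shape[g].fit_r2:.2f}), alpha = {self.alpha[g]:.3f}"
            )
            if g in self.test_eval:
                ev = self.test_eval[g]
                lines.append(
                    f"      test TLA  : slope = {ev.slope:.3f}, R^2 = {ev.r2:.3f}, "
                    f"RMSE = {ev.rmse:.1f} cm^2 (n = {ev.n})"
                )
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Normalized observed scatter with the fitted Lorentz profile."""
        import matplotlib.pyplot as plt

        from .profile import lorentz, normalized_area, normalized_rank

        if ax is None:
            _, ax = plt.subplots()
        xs, ys = [], []
        for sh in self.model.shoots:
            for lf in sh.leaves:
                xs.append(normalized_rank(lf.rank, sh.nl, sh.shoot_type))
                ys.append(normalized_area(lf.area, sh.Amax))
        ax.scatter(xs, ys, s=8, alpha=0.4, label="observed")
        grid = np.linspace(min(xs), max(xs), 300)
        nl_ref = int(np.median([sh.nl for sh in self.model.shoots]))
        ax.plot(
            grid,
            lorentz(grid, self.x0 if self.model.shoot_type == "RO" else 0.0,
                    self.params.s_for(nl_ref)),
            "k-",
            label=f"Lorentz (nl = {nl_ref})",
        )
        ax.set_xlabel("normalized rank")
        ax.set_ylabel("normalized leaf area")
        ax.legend()
        return ax


class VegetativeShootModel:
    """Descriptive linear leaf-area model for vegetative shoots.

    Fits the blade ratio k (pooled over the genotypes present) and the
    profile slope p of normalized area on normalized rank, against the
    ellipse-based maximum (pi/4) * k * Lmax^2.
    """

    def __init__(self, shoots: Sequence[ShootRecord]):
        self.shoots = [sh for sh in shoots if sh.shoot_type == "VS"]
        if not self.shoots:
            raise DataError("no vegetative shoots supplied")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VegetativeShootModel":
        return cls(shoots_from_frame(df[df["shoot_type"] == "VS"]))

    def fit(self) -> "VegetativeShootResults":
        shape = fit_k([lf for sh in self.shoots for lf in sh.leaves])
        x, y = [], []
        for sh in self.shoots:
            amax_nom = (math.pi / 4.0) * shape.k * sh.Lmax**2
            for lf in sh.leaves:
                x.append((lf.rank / sh.nl) * amax_nom)
                y.append(lf.area)
        x = np.asarray(x)
        y = np.asarray(y)
        denom = float(np.sum(x * x))
        if denom <= 0:
            raise FitError("degenerate vegetative-shoot design")
        p = float(np.sum(x * y) / denom)
        if not 0.0 < p <= 1.05:
            raise FitError(f"fitted p={p:.3f} outside the sanity bound (0, 1.05]")
        ev = evaluate_fit(y, p * x) if np.ptp(y) > 0 else None
        return VegetativeShootResults(
            model=self, vs=VegShootParams(p=p, k=shape.k), shape=shape, leaf_eval=ev
        )


@dataclass
class VegetativeShootResults:
    model: VegetativeShootModel
    vs: VegShootParams
    shape: ShapeParams
    leaf_eval: EvalStats | None

    @property
    def p(self) -> float:
        return self.vs.p

    @property
    def k(self) -> float:
        return self.vs.k

    def predict(self, nl: int, Lmax: float) -> pd.DataFrame:
        rows = [
            {"rank": R, "area_cm2": predict_vs_leaf_area(R, nl, Lmax, self.vs)}
            for R in range(1, nl + 1)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Vegetative-shoot linear leaf-area model",
            f"  shoots : {len(self.model.shoots)}",
            f"  k      : {self.k:.3f} (R^2 = {self.shape.fit_r2:.2f})",
            f"  p      : {self.p:.3f}",
        ]
        if self.leaf_eval is not None:
            lines.append(
                f"  leaves : slope = {self.leaf_eval.slope:.3f}, "
                f"R^2 = {self.leaf_eval.r2:.3f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Full workflow


@dataclass
class FitReport:
    """Everything the workflow produced: per-group results, grouping tests,
    the internode fit, and a flat diagnostics table."""

    results: dict[tuple[str, tuple[str, ...]], ShootLeafAreaResults]
    vs_results: VegetativeShootResults | None
    internode: InternodeParams | None
    grouping_tests: dict[str, GroupComparison]
    config: PipelineConfig

    def calibrated_models(self) -> dict[tuple[str, str], CalibratedModel]:
        out: dict[tuple[str, str], CalibratedModel] = {}
        for (stype, _), res in self.results.items():
            for g, m in res.calibrated.items():
                out[(stype, g)] = m
        return out

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for (stype, group), res in self.results.items():
            for g in sorted(res.alpha):
                ev = res.test_eval.get(g)
                rows.append(
                    {
                        "shoot_type": stype,
                        "group": "|".join(group),
                        "genotype": g,
                        "beta": res.beta,
                        "beta_r2": res.params.beta_r2,
                        "x0": res.x0,
                        "k": res.shape[g].k,
                        "k_r2": res.shape[g].fit_r2,
                        "alpha": res.alpha[g],
                        "n_train": res.n_train,
                        "n_test": res.n_test,
                        "test_slope": ev.slope if ev else np.nan,
                        "test_r2": ev.r2 if ev else np.nan,
                        "test_rmse": ev.rmse if ev else np.nan,
                    }
                )
        if self.vs_results is not None:
            rows.append(
                {
                    "shoot_type": "VS",
                    "group": "|".join(
                        sorted({sh.genotype for sh in self.vs_results.model.shoots})
                    ),
                    "genotype": "pooled",
                    "k": self.vs_results.k,
                    "alpha": self.vs_results.p,
                }
            )
        if self.internode is not None:
            rows.append(
                {
                    "shoot_type": "spur",
                    "group": "internode",
                    "genotype": "pooled",
                    "beta": self.internode.qi,
                    "x0": self.internode.si,
                    "test_r2": self.internode.fit_r2,
                    "test_rmse": self.internode.rmse,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        parts = [res.summary() for res in self.results.values()]
        if self.vs_results is not None:
            parts.append(self.vs_results.summary())
        if self.internode is not None:
            parts.append(
                f"Internode logistic: qi = {self.internode.qi:.3f}, "
                f"si = {self.internode.si:.3f}, R^2 = {self.internode.fit_r2:.3f}, "
                f"RMSE = {self.internode.rmse:.3f}"
            )
        return "\n\n".join(parts)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, FitError):
                raise FitError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, FitError) and not str(exc).startswith("stage"):
                raise FitError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_parameterization(
    leaves: pd.DataFrame,
    config: PipelineConfig | None = None,
    internodes: pd.DataFrame | None = None,
) -> FitReport:
    """Execute the full workflow on a validated leaf table.

    Stages run in order: grouping tests -> beta per group -> s (per nl for
    BS; with x0 for RO) -> k per genotype -> training predictions -> alpha
    calibration -> testing metrics.  Any stage failure raises a
    stage-tagged :class:`FitError`.
    """
    config = config or PipelineConfig()
    grouping_tests: dict[str, GroupComparison] = {}

    with _stage("grouping"):
        for stype in ("BS", "RO"):
            sub = leaves[leaves["shoot_type"] == stype]
            if sub.empty:
                continue
            if stype == "RO" and sub["rank"].isna().any():
                raise FitError("stage 'x0' failed: rosette ranks missing")
            shoots = shoots_from_frame(sub)
            by_geno: dict[str, list[float]] = {}
            for sh in shoots:
                by_geno.setdefault(sh.genotype, []).append(
                    sh.TLA / (sh.nl * sh.Amax)
                )
            if len(by_geno) >= 2 and all(len(v) >= 3 for v in by_geno.values()):
                grouping_tests[stype] = compare_groups(
                    by_geno, config.significance_level
                )

    results: dict[tuple[str, tuple[str, ...]], ShootLeafAreaResults] = {}
    for stype in ("BS", "RO"):
        sub = leaves[leaves["shoot_type"] == stype]
        if sub.empty:
            continue
        present = set(sub["genotype"].unique())
        for group in config.grouping.get(stype, ((tuple(sorted(present))),)):
            group_present = tuple(g for g in group if g in present)
            if not group_present:
                continue
            with _stage(f"{stype} {'|'.join(group_present)}"):
                model = ShootLeafAreaModel.from_dataframe(
                    leaves, stype, group_present
                )
                results[(stype, group_present)] = model.fit(
                    split_fraction=config.split_fraction, seed=config.seed
                )

    vs_results = None
    vs_df = leaves[leaves["shoot_type"] == "VS"]
    if not vs_df.empty:
        with _stage("VS"):
            vs_results = VegetativeShootModel.from_dataframe(vs_df).fit()

    internode_params = None
    if internodes is not None and not internodes.empty:
        with _stage("internode"):
            internode_params = InternodeModel.from_dataframe(internodes).fit().params

    return FitReport(
        results=results,
        vs_results=vs_results,
        internode=internode_params,
        grouping_tests=grouping_tests,
        config=config,
    )
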