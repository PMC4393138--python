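"""Logistic survival-selectivity analysis.

The workflow mirrors standard extinction-selectivity practice: each
candidate predictor is screened in a bivariate logistic regression of
the 0/1 survival label (slope kept when its Wald p < 0.1), the screened
predictors enter an exhaustive set of multivariate logistic models
ranked by small-sample AICc with Akaike weights, and effect sizes are
summarized by Tjur's coefficient of discrimination D and percent
deviance explained.

`SurvivalSelectivityModel` is the front door: build it from a
species-level predictor table (rows = species, columns = predictors
plus a 0/1 ``survival`` column), call :meth:`fit`, and read the
returned :class:`SelectivityResults`.  Missing predictor values are
handled by complete-case culling per fit, so the effective n varies by
model exactly as it does when species lack defined statistics.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from paleosel.core_data import PREDICTOR_COLUMNS

SEPARATION_BETA = 15.0  # |β| beyond this flags (quasi-)complete separation


@dataclass
class LogisticFit:
    """A maximum-likelihood logit fit with Wald inference and fit metrics.

    ``beta`` etc. are ordered intercept-first, matching ``predictors``
    prefixed with "intercept".  ``separation`` flags fits whose
    likelihood is maximized at infinite slopes.
    """

    predictors: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    loglik: float
    null_deviance: float
    resid_deviance: float
    tjur_d: float
    aicc: float
    k: int
    separation: bool = False
    fitted: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    @property
    def slope_p(self) -> float:
        """Wald p of the (single) slope; only defined for bivariate fits."""
        if len(self.predictors) != 1:
            raise ValueError("slope_p is defined for single-predictor fits only")
        return float(self.p[1])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "p": self.p},
            index=["intercept", *self.predictors],
        )


def fit_logistic(y, X, names: tuple[str, ...] | None = None) -> LogisticFit:
    """ML logit fit of a 0/1 response on one or more predictor columns.

    Rows with any missing value are dropped (complete-case).  Requires
    both classes present and at least k+2 complete cases.  Perfect or
    quasi-complete separation does not raise: the fit is returned with
    ``separation=True`` and its (diverging) estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[keep], X[keep]
    n, m = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("response contains a single class")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("a predictor column is constant")
    if n < m + 2:
        raise ValueError(f"too few complete cases (n={n}) for {m} predictors")
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = model.fit(method="bfgs", disp=0, maxiter=200)
            separation = True
    beta = np.asarray(res.params, dtype=float)
    if np.any(np.abs(beta[1:]) > SEPARATION_BETA):
        separation = True
    phat = np.asarray(res.predict(design), dtype=float)
    loglik = float(res.llf)
    k = len(beta)
    null_dev = -2.0 * float(res.llnull)
    fit = LogisticFit(
        predictors=names,
        beta=beta,
        se=np.asarray(res.bse, dtype=float),
        p=np.asarray(res.pvalues, dtype=float),
        n=n,
        loglik=loglik,
        null_deviance=null_dev,
        resid_deviance=-2.0 * loglik,
        tjur_d=_tjur(y, phat),
        aicc=aicc(loglik, k, n),
        k=k,
        separation=separation,
        fitted=phat,
        y=y,
    )
    return fit


def _tjur(y: np.ndarray, phat: np.ndarray) -> float:
    return float(phat[y == 1].mean() - phat[y == 0].mean())


def tjur_d(fit: LogisticFit) -> float:
    """Tjur's coefficient of discrimination D.

    Mean fitted survival probability among survivors minus that among
    victims; an r²-like effect size for binary models.
    """
    return _tjur(fit.y, fit.fitted)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = −2·loglik + 2k + 2k(k+1)/(n−k−1), with k counting the
    intercept.  Undefined (error) when n ≤ k+1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights ω_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc list")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def deviance_explained(fit: LogisticFit) -> float:
    """Percent deviance explained, 100·(1 − residual/null deviance)."""
    return 100.0 * (1.0 - fit.resid_deviance / fit.null_deviance)


@dataclass
class ScreenResult:
    """Bivariate screen output: every per-predictor fit plus the keepers."""

    fits: dict[str, LogisticFit]
    candidates: list[str]
    alpha: float

    def table(self) -> pd.DataFrame:
        rows = []
        for name, f in self.fits.items():
            rows.append(
                {
                    "predictor": name,
                    "beta": f.beta[1],
                    "se": f.se[1],
                    "p": f.p[1],
                    "n": f.n,
                    "tjur_d": f.tjur_d,
                    "candidate": name in self.candidates,
                }
            )
        return pd.DataFrame(rows).set_index("predictor")


def bivariate_screen(
    table: pd.DataFrame,
    alpha: float = 0.1,
    predictors: list[str] | None = None,
    response: str = "survival",
) -> ScreenResult:
    """Fit survival on each predictor separately; keep slopes with p < alpha.

    Each fit uses that predictor's complete cases, so n varies across
    predictors.  Predictors that cannot be fit (constant after culling,
    single class, too few cases) are recorded as non-candidates and
    omitted from the fit map.  No multiple-testing correction is
    applied, matching standard screening practice at this stage; treat
    the candidate set as exploratory.
    """
    if predictors is None:
        predictors = [c for c in PREDICTOR_COLUMNS if c in table.columns]
    fits: dict[str, LogisticFit] = {}
    candidates: list[str] = []
    for name in predictors:
        try:
            f = fit_logistic(table[response], table[name], names=(name,))
        except ValueError:
            continue
        fits[name] = f
        if not f.separation and f.p[1] < alpha:
            candidates.append(name)
    return ScreenResult(fits=fits, candidates=candidates, alpha=alpha)


@dataclass
class ModelRanking:
    """AICc ranking of an exhaustive multivariate model set.

    One row per fitted subset model, sorted by AICc ascending, with
    Akaike weights renormalized over the models actually fitted.
    """

    table: pd.DataFrame
    fits: dict[tuple[str, ...], LogisticFit]
    n: int  # complete cases in the culled set
    skipped: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def best(self) -> LogisticFit:
        return self.fits[self.table.index[0]]


def model_selection(
    candidates: list[str],
    table: pd.DataFrame,
    response: str = "survival",
    min_size: int = 2,
) -> ModelRanking:
    """Exhaustive AICc comparison of all candidate-predictor subsets.

    The table is first culled to rows complete in *all* candidates, so
    every model sees the same n and the AICc values are comparable.
    All subsets of size ≥ ``min_size`` are fitted; a subset too large
    for the culled n is skipped with a warning and the weights are
    renormalized over the fitted models.
    """
    if len(candidates) < 2:
        raise ValueError("model selection needs at least 2 candidate predictors")
    culled = table[[response, *candidates]].dropna()
    n = len(culled)
    fits: dict[tuple[str, ...], LogisticFit] = {}
    skipped: list[tuple[str, ...]] = []
    for size in range(min_size, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            try:
                fits[combo] = fit_logistic(
                    culled[response], culled[list(combo)].to_numpy(), names=combo
                )
            except ValueError as exc:
                warnings.warn(f"model {combo} skipped: {exc}", stacklevel=2)
                skipped.append(combo)
    if not fits:
        raise ValueError("no multivariate model could be fitted")
    keys = list(fits)
    w = akaike_weights([fits[k].aicc for k in keys])
    rows = []
    for key, weight in zip(keys, w):
        f = fits[key]
        rows.append(
            {
                "model": key,
                "k": f.k,
                "aicc": f.aicc,
                "weight": weight,
                "loglik": f.loglik,
                "deviance_explained": deviance_explained(f),
                "tjur_d": f.tjur_d,
            }
        )
    tab = pd.DataFrame(rows).set_index("model").sort_values("aicc")
    return ModelRanking(table=tab, fits=fits, n=n, skipped=skipped)


def group_mean_test(values, survival) -> tuple[float, float]:
    """Two-sample Student's t (pooled variance): survivors vs victims.

    Pairwise-complete; raises on zero pooled variance or an empty group.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(survival, dtype=float)
    keep = ~(np.isnan(v) | np.isnan(s))
    v, s = v[keep], s[keep]
    g1, g0 = v[s == 1], v[s == 0]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(g0) == 0 and np.ptp(g1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(g1, g0, equal_var=True)
    return float(t), float(p)


def predictor_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p and n over pairwise-complete cases."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


class SurvivalSelectivityModel:
    """Survival-selectivity model over a species-level predictor table.

    Parameters
    ----------
    table : DataFrame
        Rows = species; must contain a 0/1 ``survival`` column and the
        predictor columns (NaN = undefined).
    alpha : float
        Bivariate screening level on the slope Wald p (default 0.1).
    predictors : list of str, optional
        Predictor columns to consider; defaults to the ten standard ones
        present in the table.
    tree_control : dict, optional
        Regression-tree controls (minsplit, minbucket, cp).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        alpha: float = 0.1,
        predictors: list[str] | None = None,
        tree_control: dict | None = None,
        response: str = "survival",
    ):
        if response not in table.columns:
            raise ValueError(f"table lacks the {response!r} column")
        self.table = table
        self.alpha = alpha
        self.response = response
        self.predictors = predictors or [c for c in PREDICTOR_COLUMNS if c in table.columns]
        self.tree_control = tree_control or {}

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SurvivalSelectivityModel":
        from paleosel.core_data import load_predictor_table

        return cls(load_predictor_table(path), **kwargs)

    def fit(self) -> "SelectivityResults":
        from paleosel.tree import fit_tree, tree_deviance_explained

        screen = bivariate_screen(
            self.table, alpha=self.alpha, predictors=self.predictors, response=self.response
        )
        ranking = None
        if len(screen.candidates) >= 2:
            ranking = model_selection(screen.candidates, self.table, response=self.response)
        tree = fit_tree(
            self.table,
            response=self.response,
            predictors=self.predictors,
            **self.tree_control,
        )
        tree_dev = tree_deviance_explained(tree, self.table, response=self.response)
        return SelectivityResults(
            model=self, screen=screen, ranking=ranking, tree=tree, tree_deviance=tree_dev
        )


@dataclass
class SelectivityResults:
    """Fitted selectivity analysis: screen, model ranking and tree."""

    model: SurvivalSelectivityModel
    screen: ScreenResult
    ranking: ModelRanking | None
    tree: "RegressionTree"  # noqa: F821 (import cycle avoided)
    tree_deviance: float

    def summary(self) -> str:
        lines = ["Survival selectivity analysis", "=" * 30, ""]
        lines.append(f"Bivariate screen (slope p < {self.screen.alpha}):")
        lines.append(
            self.screen.table()
            .round({"beta": 3, "se": 3, "p": 3, "tjur_d": 3})
            .to_string()
        )
        lines.append("")
        if self.ranking is not None:
            lines.append(f"Model ranking (culled complete-case n = {self.ranking.n}):")
            tab = self.ranking.table.copy()
            tab.index = [" + ".join(m) for m in tab.index]
            lines.append(
                tab.round(
                    {
                        "aicc": 2,
                        "weight": 2,
                        "loglik": 2,
                        "deviance_explained": 1,
                        "tjur_d": 2,
                    }
                ).to_string()
            )
            lines.append("")
            best = self.ranking.best
            lines.append("Best model coefficients:")
            lines.append(best.coef_table().round(3).to_string())
        else:
            lines.append("Fewer than 2 screened candidates: multivariate stage skipped.")
        lines.append("")
        lines.append(f"Regression tree ({self.tree_deviance:.1f}% deviance explained):")
        lines.append(self.tree.to_text())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "alpha": self.screen.alpha,
            "bivariate": {
                name: {
                    "beta": float(f.beta[1]),
                    "se": float(f.se[1]),
                    "p": float(f.p[1]),
                    "n": f.n,
                    "tjur_d": f.tjur_d,
                    "separation": f.separation,
                }
                for name, f in self.screen.fits.items()
            },
            "candidates": self.screen.candidates,
            "tree": self.tree.to_dict(),
            "tree_deviance_explained": self.tree_deviance,
        }
        if self.ranking is not None:
            out["ranking"] = [
                {
                    "model": list(model),
                    "k": int(row.k),
                    "aicc": float(row.aicc),
                    "weight": float(row.weight),
                    "loglik": float(row.loglik),
                    "deviance_explained": float(row.deviance_explained),
                    "tjur_d": float(row.tjur_d),
                }
                for model, row in self.ranking.table.iterrows()
            ]
            best = self.ranking.best
            out["best_model"] = {
                "predictors": list(best.predictors),
                "beta": best.beta.tolist(),
                "se": best.se.tolist(),
                "p": best.p.tolist(),
                "n": best.n,
                "aicc": best.aicc,
                "tjur_d": best.tjur_d,
            }
            out["culled_n"] = self.ranking.n
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
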