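"""Probability machines and logistic comparators.

A *probability machine* (PM) is any consistent nonparametric regression
applied to a {0,1} outcome: its fitted regression function is the
conditional success probability P(Y=1 | X).  The implementation shipped
here is the random-forest probability machine (RFPM): a forest of
*regression* trees whose per-tree probability estimates are averaged —
not the classifier vote fraction.  The tuning contract is fixed:
minimum terminal-node size equal to a fraction (default 5%) of the
training-set size handed to the fit, and every feature a candidate at
every split (mtry = p).

Two logistic comparators are provided: LR1 (intercept + main effects)
and LR2 (intercept + mains + all pairwise interactions), fitted by
maximum likelihood through statsmodels.  Perfect separation or
non-convergence is recorded on the fit, not raised, so that replicate
studies can flag and filter degenerate comparator fits.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import RandomForestRegressor
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .models import BinaryDataset

__all__ = [
    "PMConfig",
    "FittedPM",
    "FittedLogit",
    "fit_pm",
    "predict_pm",
    "fit_logistic",
    "predict_logistic",
    "clip_probability",
    "save_pm",
    "load_pm",
]


@dataclass(frozen=True)
class PMConfig:
    """Random-forest probability machine tuning contract.

    n_trees: trees per forest (default 100).
    nodesize_fraction: the forest's node-size parameter as a fraction of
        the training-set size actually handed to the fit (default 0.05),
        so subgroup machines smooth proportionately to their own n.
        Following the classic Fortran/R random-forest convention, a node
        whose size is at or below the resolved value is not split
        further (children may be smaller); set ``nodesize_is_min_leaf``
        to instead enforce it as a hard minimum leaf size.
    mtry_policy: "all-features" (every used feature considered at every
        split) or an explicit positive count.
    seed: base seed for the forest's bootstrap randomness.
    """

    n_trees: int = 100
    nodesize_fraction: float = 0.05
    mtry_policy: str | int = "all-features"
    seed: int | None = None
    nodesize_is_min_leaf: bool = False

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.nodesize_fraction < 1.0:
            raise ValueError("nodesize_fraction must lie in (0, 1)")
        if isinstance(self.mtry_policy, int) and self.mtry_policy < 1:
            raise ValueError("explicit mtry must be >= 1")
        if isinstance(self.mtry_policy, str) and self.mtry_policy != "all-features":
            raise ValueError('mtry_policy must be "all-features" or a positive int')

    def resolved_nodesize(self, n_train: int) -> int:
        return max(1, math.ceil(self.nodesize_fraction * n_train))


@dataclass
class FittedPM:
    """A trained probability machine: predict(X) -> success probabilities."""

    forest: RandomForestRegressor
    feature_names: tuple[str, ...]
    nodesize: int
    config: PMConfig
    seed: int | None

    def predict(self, X) -> np.ndarray:
        X = self._conform(X)
        return np.clip(self.forest.predict(X), 0.0, 1.0)

    def _conform(self, X) -> np.ndarray:
        if isinstance(X, BinaryDataset):
            X = X.to_frame()
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise ValueError(f"input is missing fitted features: {sorted(missing)}")
            return X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected an (n, {len(self.feature_names)}) matrix over features "
                f"{list(self.feature_names)}, got shape {X.shape}"
            )
        return X


def fit_pm(
    data: BinaryDataset,
    config: PMConfig | None = None,
    exclude_features: set[str] | None = None,
    seed: int | None = None,
    nodesize: int | None = None,
) -> FittedPM:
    """Fit an RFPM to ``data``, optionally excluding named features.

    Conditioning features that are constant within a subgroup (as in the
    two- and four-machine methods) should be excluded here so they never
    enter the design.  ``seed`` overrides ``config.seed`` when given.
    ``nodesize`` overrides the fraction-resolved node size with an
    absolute count — the counterfactual machines use this to keep the
    node-size parameter anchored to the *total* study size rather than
    each training subgroup's size.
    """
    config = config or PMConfig()
    exclude = set(exclude_features or ())
    unknown = exclude - set(data.feature_names)
    if unknown:
        raise ValueError(f"exclude_features not in dataset: {sorted(unknown)}")
    used = tuple(f for f in data.feature_names if f not in exclude)
    if not used:
        raise ValueError("no features left after exclusion")
    if nodesize is None:
        nodesize = config.resolved_nodesize(data.n)
        if data.n < nodesize:
            raise ValueError(
                f"n={data.n} is below the resolved minimum node size {nodesize}"
            )
    elif nodesize < 1:
        raise ValueError("nodesize override must be >= 1")
    if config.mtry_policy == "all-features":
        mtry = len(used)
    else:
        mtry = min(int(config.mtry_policy), len(used))
    rs = seed if seed is not None else config.seed
    cols = [data.feature_names.index(f) for f in used]
    if config.nodesize_is_min_leaf:
        size_kw = {"min_samples_leaf": nodesize}
    else:
        size_kw = {"min_samples_split": nodesize + 1, "min_samples_leaf": 1}
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=mtry,
        bootstrap=True,
        n_jobs=1,
        random_state=rs,
        **size_kw,
    )
    forest.fit(data.X[:, cols].astype(float), data.y.astype(float))
    return FittedPM(forest=forest, feature_names=used, nodesize=nodesize, config=config, seed=rs)


def predict_pm(model: FittedPM, X) -> np.ndarray:
    """Probabilities in [0, 1]; deterministic given the fitted machine."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# Logistic comparators


@dataclass
class FittedLogit:
    """Maximum-likelihood logistic fit: LR1 (mains) or LR2 (+ pairwise)."""

    design: str
    feature_names: tuple[str, ...]
    params: pd.Series
    converged: bool = True
    term_names: tuple[str, ...] = field(default_factory=tuple)

    def coef(self, term: str) -> float:
        """Log-odds coefficient of a term: "X3" or "X2:X3"."""
        if ":" in term:
            a, b = term.split(":")
            term = f"{a}:{b}" if f"{a}:{b}" in self.params.index else f"{b}:{a}"
        return float(self.params[term])

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.coef(term)))

    def predict(self, X) -> np.ndarray:
        return predict_logistic(self, X)


def _design_matrix(X: np.ndarray, names: tuple[str, ...], design: str):
    cols = [np.ones(X.shape[0])]
    terms = ["const"]
    for j, name in enumerate(names):
        cols.append(X[:, j].astype(float))
        terms.append(name)
    if design == "LR2":
        for (i, a), (j, b) in combinations(enumerate(names), 2):
            cols.append((X[:, i] * X[:, j]).astype(float))
            terms.append(f"{a}:{b}")
    return np.column_stack(cols), terms


def fit_logistic(data: BinaryDataset, design: str = "LR1") -> FittedLogit:
    """Fit LR1 (intercept + mains) or LR2 (+ all pairwise products).

    Non-convergence or perfect separation is recorded on ``converged``
    rather than raised; such fits still carry (possibly degenerate)
    parameter estimates.
    """
    if design not in ("LR1", "LR2"):
        raise ValueError('design must be "LR1" or "LR2"')
    D, terms = _design_matrix(data.X, data.feature_names, design)
    if data.n < D.shape[1]:
        raise ValueError(
            f"n={data.n} is below the {D.shape[1]} parameters of the {design} design"
        )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("error", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.GLM(data.y.astype(float), D, family=sm.families.Binomial()).fit()
            params = np.asarray(res.params, dtype=float)
            converged = bool(getattr(res, "converged", True))
        except (PerfectSeparationWarning, ConvergenceWarning, Exception):
            # refit permissively and flag the result
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.GLM(
                        data.y.astype(float), D, family=sm.families.Binomial()
                    ).fit(maxiter=200)
                    params = np.asarray(res.params, dtype=float)
                except Exception:
                    params = np.zeros(D.shape[1])
            converged = False
    # very large coefficients are a separation signature even when IRLS "converges"
    if np.any(np.abs(params[1:]) > 15):
        converged = False
    return FittedLogit(
        design=design,
        feature_names=data.feature_names,
        params=pd.Series(params, index=terms),
        converged=converged,
        term_names=tuple(terms),
    )


def predict_logistic(model: FittedLogit, X) -> np.ndarray:
    """expit of the fitted linear predictor; values in (0, 1)."""
    if isinstance(X, BinaryDataset):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        missing = set(model.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"input is missing fitted features: {sorted(missing)}")
        X = X[list(model.feature_names)].to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected an (n, {len(model.feature_names)}) matrix, got shape {X.shape}"
        )
    D, _ = _design_matrix(X, model.feature_names, model.design)
    return expit(D @ model.params.to_numpy())


def clip_probability(p, eps: float) -> np.ndarray:
    """Order-preserving clamp of probabilities into [eps, 1 - eps]."""
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    return np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# Fitted-machine persistence


def save_pm(model: FittedPM, path: str | Path) -> None:
    """Persist a fitted machine (joblib binary + JSON metadata sidecar)."""
    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "feature_names": list(model.feature_names),
        "nodesize": model.nodesize,
        "n_trees": model.config.n_trees,
        "nodesize_fraction": model.config.nodesize_fraction,
        "mtry_policy": model.config.mtry_policy,
        "seed": model.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_pm(path: str | Path) -> FittedPM:
    return joblib.load(path)
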