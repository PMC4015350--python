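"""Synthetic data generation from logistic and saturated binary-outcome laws.

The generating laws used throughout the package's simulation studies are
logit-linear models over binary features,

    logit P(Y=1 | x) = logit(b0) + sum_i x_i log(OR_i)
                       + sum_{i<j} x_i x_j log(OR_ij),

optionally replaced by a *saturated* stratum table that assigns an
arbitrary success probability to every combination of a designated
feature subset (a fully saturated model including the highest-order
interaction among those features).  Features not named in any effect
have odds ratio exactly 1 and act as noise predictors, emulating the
sparse-signal structure of genomic association studies.

Five built-in models are provided (``model1`` .. ``model5``), plus a
100-feature sparse-coefficient law for the high-dimensional attenuation
study.  :func:`true_probability` exposes the exact conditional success
probability of any covariate pattern and serves as the oracle for tests
and bias computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._seeds import spawn_seeds

__all__ = [
    "LogisticModelSpec",
    "BinaryDataset",
    "SparseCoefficientSpec",
    "BUILTIN_MODELS",
    "builtin_model",
    "true_probability",
    "simulate",
    "simulate_sparse_100",
    "spec_to_json",
    "spec_from_json",
]

DEFAULT_MARGINAL = 0.3


def _feature_names(p: int) -> tuple[str, ...]:
    return tuple(f"X{i + 1}" for i in range(p))


def _as_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered feature pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LogisticModelSpec:
    """A binary-outcome data-generating law.

    Parameters
    ----------
    n_features
        Number of binary features p; names are ``X1`` .. ``Xp``.
    baseline_prob
        Success probability when every modeled feature is 0.
    feature_marginals
        Per-feature P(X_i = 1); a scalar broadcasts to all features.
    main_or
        Map feature name -> conditional odds ratio (1.0 = null).
        Unnamed features are null.
    interaction_or
        Map unordered feature pair -> interaction odds ratio.
    stratum_features / stratum_table
        When present, ``stratum_table`` maps every 0/1 combination of
        the designated ``stratum_features`` (in order) to a success
        probability, overriding the logit-linear form.  Features outside
        the designated set remain noise.
    label
        Human-readable model name.
    """

    n_features: int
    baseline_prob: float = 0.3
    feature_marginals: tuple[float, ...] | float = DEFAULT_MARGINAL
    main_or: dict[str, float] = field(default_factory=dict)
    interaction_or: dict[tuple[str, str], float] = field(default_factory=dict)
    stratum_features: tuple[str, ...] = ()
    stratum_table: dict[tuple[int, ...], float] = field(default_factory=dict)
    label: str = "custom"

    def __post_init__(self):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0.0 < self.baseline_prob < 1.0:
            raise ValueError("baseline_prob must lie strictly in (0, 1)")
        names = set(self.feature_names)
        for name, or_ in self.main_or.items():
            if name not in names:
                raise ValueError(f"unknown feature in main_or: {name!r}")
            if or_ <= 0:
                raise ValueError(f"odds ratio for {name} must be > 0")
        canon = {}
        for (a, b), or_ in self.interaction_or.items():
            if a not in names or b not in names or a == b:
                raise ValueError(f"invalid interaction pair ({a}, {b})")
            if or_ <= 0:
                raise ValueError(f"interaction odds ratio for ({a}, {b}) must be > 0")
            canon[_as_pair(a, b)] = or_
        object.__setattr__(self, "interaction_or", canon)
        m = self.marginals
        if m.shape != (self.n_features,) or not np.all((m > 0) & (m < 1)):
            raise ValueError("feature_marginals must be probabilities in (0, 1), one per feature")
        object.__setattr__(self, "feature_marginals", tuple(float(v) for v in m))
        if self.stratum_table or self.stratum_features:
            k = len(self.stratum_features)
            if k == 0:
                raise ValueError("stratum_table requires stratum_features")
            want = set(product((0, 1), repeat=k))
            got = {tuple(int(v) for v in key) for key in self.stratum_table}
            if got != want:
                raise ValueError(
                    f"stratum_table must cover all {2 ** k} combinations of {self.stratum_features}"
                )
            for key, pr in self.stratum_table.items():
                if not 0.0 < pr < 1.0:
                    raise ValueError(f"stratum probability for {key} must lie in (0, 1)")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return _feature_names(self.n_features)

    @property
    def marginals(self) -> np.ndarray:
        m = self.feature_marginals
        if np.isscalar(m):
            return np.full(self.n_features, float(m))
        return np.asarray(m, dtype=float)

    def main_or_vector(self) -> np.ndarray:
        """Per-feature conditional odds ratio, 1.0 for noise features."""
        return np.array([self.main_or.get(name, 1.0) for name in self.feature_names])

    def true_interaction_or(self, feat_a: str, feat_b: str) -> float:
        """The interaction odds ratio parameter for an unordered pair."""
        if self.stratum_table:
            idx = {f: i for i, f in enumerate(self.stratum_features)}
            if feat_a in idx and feat_b in idx:
                raise ValueError(
                    "saturated models have stratum-specific interactions; "
                    "derive them from the stratum table directly"
                )
            return 1.0
        return self.interaction_or.get(_as_pair(feat_a, feat_b), 1.0)


@dataclass(frozen=True)
class BinaryDataset:
    """n subjects with a {0,1} outcome and p {0,1} features."""

    y: np.ndarray
    X: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        y = np.asarray(self.y, dtype=np.int8)
        X = np.asarray(self.X, dtype=np.int8)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("y must be length n and X must be n x p")
        if y.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("need n >= 1 subjects and p >= 1 features")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match X's column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        for arr, what in ((y, "y"), (X, "X")):
            bad = ~np.isin(arr, (0, 1))
            if bad.any():
                raise ValueError(f"{what} contains values outside {{0, 1}}")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}; have {list(self.feature_names)}") from None
        return self.X[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "y", self.y)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryDataset":
        if "y" not in df.columns:
            raise ValueError('dataset must contain an outcome column named "y"')
        feats = [c for c in df.columns if c != "y"]
        return cls(y=df["y"].to_numpy(), X=df[feats].to_numpy(), feature_names=tuple(feats))


@dataclass(frozen=True)
class SparseCoefficientSpec:
    """The 100-feature sparse logistic law for the attenuation study.

    A fixed fraction of features carry non-zero log-odds-ratio
    coefficients drawn from N(coef_mean, coef_sd^2) and randomly signed;
    the rest are exactly zero.  The intercept is ``logit(baseline_prob)``.
    """

    n_features: int = 100
    nonzero_fraction: float = 0.2
    coef_mean: float = 0.7
    coef_sd: float = 0.2
    sign_prob: float = 0.5
    baseline_prob: float = 0.5
    feature_marginals: float = DEFAULT_MARGINAL
    coefficients: tuple[float, ...] | None = None

    @property
    def feature_names(self) -> tuple[str, ...]:
        return _feature_names(self.n_features)

    @property
    def n_nonzero(self) -> int:
        return int(round(self.nonzero_fraction * self.n_features))

    def realize(self, seed: int | None) -> "SparseCoefficientSpec":
        """Draw the coefficient vector; returns a spec with it filled in."""
        rng = np.random.default_rng(seed)
        coefs = np.zeros(self.n_features)
        k = self.n_nonzero
        if k > 0:
            idx = rng.choice(self.n_features, size=k, replace=False)
            vals = rng.normal(self.coef_mean, self.coef_sd, size=k)
            signs = np.where(rng.random(k) < self.sign_prob, -1.0, 1.0)
            coefs[idx] = vals * signs
        return replace(self, coefficients=tuple(coefs))

    def to_logistic_spec(self) -> LogisticModelSpec:
        if self.coefficients is None:
            raise ValueError("coefficients not realized; call realize(seed) first")
        main = {
            name: float(np.exp(c))
            for name, c in zip(self.feature_names, self.coefficients)
            if c != 0.0
        }
        return LogisticModelSpec(
            n_features=self.n_features,
            baseline_prob=self.baseline_prob,
            feature_marginals=self.feature_marginals,
            main_or=main,
            label="sparse100",
        )


# ---------------------------------------------------------------------------
# Built-in models

# Saturated three-feature stratum probabilities, ordered (X1, X2, X3)
_MODEL3_TABLE = {
    (0, 0, 0): 0.300,
    (1, 0, 0): 0.176,
    (0, 1, 0): 0.563,
    (0, 0, 1): 0.391,
    (1, 1, 0): 0.563,
    (1, 0, 1): 0.096,
    (0, 1, 1): 0.794,
    (1, 1, 1): 0.836,
}


def _builtins() -> dict[str, LogisticModelSpec]:
    common = dict(n_features=10, baseline_prob=0.3, feature_marginals=DEFAULT_MARGINAL)
    model1 = LogisticModelSpec(
        main_or={"X1": 1.2, "X2": 1.5, "X3": 2.0}, label="model1", **common
    )
    return {
        "model1": model1,
        # variant with the alternative main-effect odds ratios (1.3, 1.7, 2.5)
        "model1_table1": LogisticModelSpec(
            main_or={"X1": 1.3, "X2": 1.7, "X3": 2.5}, label="model1_table1", **common
        ),
        "model2": replace(
            model1,
            interaction_or={("X1", "X2"): 2.0, ("X2", "X3"): 5.0},
            label="model2",
        ),
        "model3": LogisticModelSpec(
            stratum_features=("X1", "X2", "X3"),
            stratum_table=dict(_MODEL3_TABLE),
            label="model3",
            **common,
        ),
        "model4": LogisticModelSpec(
            main_or={"X1": 1.3, "X2": 2.0}, label="model4", **common
        ),
        "model5": LogisticModelSpec(
            main_or={"X1": 1.3, "X2": 2.0},
            interaction_or={("X1", "X2"): 2.0},
            label="model5",
            **common,
        ),
    }


BUILTIN_MODELS = tuple(sorted(_builtins()))


def builtin_model(name: str) -> LogisticModelSpec:
    """Return one of the built-in generating laws by name.

    ``model1``: three main effects (OR 1.2, 1.5, 2 on X1..X3), 7 noise
    features.  ``model2``: model1 plus interaction ORs 2 on (X1,X2) and
    5 on (X2,X3).  ``model3``: saturated stratum table over (X1,X2,X3).
    ``model4``: two main effects (OR 1.3, 2 on X1,X2).  ``model5``:
    model4 plus interaction OR 2 on (X1,X2).  ``model1_table1``: the
    (1.3, 1.7, 2.5) variant of model1.
    """
    table = _builtins()
    try:
        return table[name]
    except KeyError:
        raise ValueError(
            f"unknown builtin model {name!r}; valid names: {sorted(table)}"
        ) from None


# ---------------------------------------------------------------------------
# Probability oracle and simulation


def true_probability(spec: LogisticModelSpec, x: np.ndarray) -> float | np.ndarray:
    """Exact conditional success probability of covariate pattern(s) ``x``.

    ``x`` may be a single length-p vector or an (n, p) matrix; a scalar
    or a length-n vector is returned accordingly.  For saturated specs
    the tabulated stratum probability is returned; otherwise the
    logit-linear law is evaluated.
    """
    x = np.asarray(x)
    single = x.ndim == 1
    X = np.atleast_2d(x).astype(float)
    if X.shape[1] != spec.n_features:
        raise ValueError(f"x has {X.shape[1]} features, spec has {spec.n_features}")
    names = spec.feature_names
    if spec.stratum_table:
        idx = [names.index(f) for f in spec.stratum_features]
        keys = X[:, idx].astype(int)
        out = np.array([spec.stratum_table[tuple(row)] for row in keys])
    else:
        eta = np.full(X.shape[0], logit(spec.baseline_prob))
        for name, or_ in spec.main_or.items():
            eta += X[:, names.index(name)] * np.log(or_)
        for (a, b), or_ in spec.interaction_or.items():
            eta += X[:, names.index(a)] * X[:, names.index(b)] * np.log(or_)
        out = expit(eta)
    return float(out[0]) if single else out


def simulate(spec: LogisticModelSpec, n: int, seed: int | None) -> BinaryDataset:
    """Draw n subjects: features independent Bernoulli(marginal), outcome
    Bernoulli(true_probability).  Identical seed -> identical dataset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    X = (rng.random((n, spec.n_features)) < spec.marginals).astype(np.int8)
    p = true_probability(spec, X)
    y = (rng.random(n) < p).astype(np.int8)
    return BinaryDataset(y=y, X=X, feature_names=spec.feature_names)


def simulate_sparse_100(
    spec: SparseCoefficientSpec, n: int, seed: int | None
) -> tuple[BinaryDataset, SparseCoefficientSpec]:
    """Simulate from the sparse high-dimensional law.

    The coefficient vector is realized first (unless already present on
    the spec), then the dataset is drawn from the implied logit-linear
    law; the realized spec is returned for truth comparisons.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    coef_seed, data_seed = spawn_seeds(seed, 2)
    realized = spec if spec.coefficients is not None else spec.realize(coef_seed)
    data = simulate(realized.to_logistic_spec(), n, data_seed)
    return data, realized


# ---------------------------------------------------------------------------
# JSON serialization


def spec_to_json(spec: LogisticModelSpec) -> str:
    d = {
        "n_features": spec.n_features,
        "baseline_prob": spec.baseline_prob,
        "feature_marginals": spec.marginals.tolist(),
        "main_or": dict(spec.main_or),
        "interaction_or": {f"{a},{b}": v for (a, b), v in spec.interaction_or.items()},
        "stratum_features": list(spec.stratum_features),
        "stratum_table": {
            "".join(str(b) for b in key): v for key, v in spec.stratum_table.items()
        },
        "label": spec.label,
    }
    return json.dumps(d, indent=2)


def spec_from_json(text: str) -> LogisticModelSpec:
    d = json.loads(text)
    return LogisticModelSpec(
        n_features=d["n_features"],
        baseline_prob=d["baseline_prob"],
        feature_marginals=tuple(d["feature_marginals"]),
        main_or=d.get("main_or", {}),
        interaction_or={
            tuple(k.split(",")): v for k, v in d.get("interaction_or", {}).items()
        },
        stratum_features=tuple(d.get("stratum_features", ())),
        stratum_table={
            tuple(int(c) for c in k): v for k, v in d.get("stratum_table", {}).items()
        },
        label=d.get("label", "custom"),
    )
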