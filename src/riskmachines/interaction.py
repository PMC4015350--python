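"""Interaction estimation and model-free interaction detection.

Two complementary tools for a pair of binary features (A, B):

*The 4-machine method* (estimation).  One probability machine is
trained on each of the four cells of (A, B); scoring every subject with
all four machines gives per-subject (p00, p01, p10, p11) — one observed
and three counterfactual probabilities.  The per-subject interaction
ratio is the ratio of the two conditional odds ratios for A at B = 1
versus B = 0,

    ior = [p11 (1 - p10) / ((1 - p11) p10)]
        / [p01 (1 - p00) / ((1 - p01) p00)],

the nonparametric analogue of the exponentiated interaction coefficient
of a logistic model.  An additive-scale contrast
p11 - p10 - p01 + p00 on the probability scale is exposed alongside.

*Single-run detection*.  From one machine fitted to all features, the
predictions are averaged within the four OBSERVED (A, B) subgroups — on
the logit scale for multiplicative interaction, on the probability
scale for additive — and the classical contrast

    T = m11 - m10 - m01 + m00

is computed.  T is near 0 when the two interaction-plot lines are
parallel (no interaction on that scale).  These are subgroup averages
from a single run, not counterfactual quantities, so T is a fast
detection screen, not an estimator.  ``scan`` evaluates T over all
feature pairs from a single fit for heat-map triage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .machines import FittedPM, PMConfig, clip_probability
from .models import BinaryDataset
from .risk import MIN_SUBGROUP, default_eps, multi_machine

__all__ = [
    "FourMachineResult",
    "DetectionSummary",
    "ScanMatrix",
    "four_machine",
    "interaction_ratio",
    "detect",
    "scan",
    "plot_data",
    "permutation_reference",
]

_CELLS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class FourMachineResult:
    """Per-subject four-cell probabilities and interaction ratios."""

    p00: np.ndarray
    p01: np.ndarray
    p10: np.ndarray
    p11: np.ndarray
    ior: np.ndarray
    additive: np.ndarray  # per-subject p11 - p10 - p01 + p00
    aggregate_ior: float
    aggregate_additive: float
    stat: str
    pair: tuple[str, str]
    cell_sizes: dict[tuple[int, int], int]
    eps: float


@dataclass
class DetectionSummary:
    """Observed-subgroup cell means and the linear contrast T."""

    m00: float
    m01: float
    m10: float
    m11: float
    T: float
    cell_counts: dict[tuple[int, int], int]
    scale: str
    pair: tuple[str, str]


@dataclass
class ScanMatrix:
    """Symmetric matrix of T over scanned feature pairs (diagonal NaN)."""

    values: pd.DataFrame
    scale: str

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def top_pairs(self, k: int = 5) -> list[tuple[str, str, float]]:
        """Pairs ranked by |T|, largest first."""
        out = []
        feats = self.features
        for i, a in enumerate(feats):
            for b in feats[i + 1 :]:
                t = self.values.loc[a, b]
                if np.isfinite(t):
                    out.append((a, b, float(t)))
        return sorted(out, key=lambda r: abs(r[2]), reverse=True)[:k]


def interaction_ratio(p00, p01, p10, p11) -> np.ndarray:
    """Ratio of the odds ratio for A at B=1 to the odds ratio at B=0."""
    p00, p01, p10, p11 = (np.asarray(v, dtype=float) for v in (p00, p01, p10, p11))
    or_b1 = (p11 * (1.0 - p10)) / ((1.0 - p11) * p10)
    or_b0 = (p01 * (1.0 - p00)) / ((1.0 - p01) * p00)
    return or_b1 / or_b0


def four_machine(
    data: BinaryDataset,
    feat_a: str,
    feat_b: str,
    config: PMConfig | None = None,
    seed: int | None = None,
    stat: str = "median",
    eps: float | None = None,
    min_subgroup: int = MIN_SUBGROUP,
) -> FourMachineResult:
    """Estimate the (feat_a, feat_b) interaction by four counterfactual machines."""
    if feat_a == feat_b:
        raise ValueError("the two interaction features must differ")
    table = multi_machine(
        data, [feat_a, feat_b], config, seed=seed, min_subgroup=min_subgroup, max_k=2
    )
    if eps is None:
        eps = default_eps(min(table.cell_sizes.values()))
    p = {c: clip_probability(table.column(c), eps) for c in _CELLS}
    ior = interaction_ratio(p[(0, 0)], p[(0, 1)], p[(1, 0)], p[(1, 1)])
    additive = p[(1, 1)] - p[(1, 0)] - p[(0, 1)] + p[(0, 0)]
    if stat == "median":
        agg_i, agg_a = float(np.median(ior)), float(np.median(additive))
    elif stat == "mean":
        agg_i, agg_a = float(np.mean(ior)), float(np.mean(additive))
    else:
        raise ValueError('stat must be "median" or "mean"')
    return FourMachineResult(
        p00=p[(0, 0)],
        p01=p[(0, 1)],
        p10=p[(1, 0)],
        p11=p[(1, 1)],
        ior=ior,
        additive=additive,
        aggregate_ior=agg_i,
        aggregate_additive=agg_a,
        stat=stat,
        pair=(feat_a, feat_b),
        cell_sizes={c: table.cell_sizes[c] for c in _CELLS},
        eps=eps,
    )


def _cell_means(
    predictions: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    scale: str,
    eps: float,
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], int]]:
    means, counts = {}, {}
    for cell in _CELLS:
        mask = (a == cell[0]) & (b == cell[1])
        counts[cell] = int(mask.sum())
        if counts[cell] == 0:
            means[cell] = np.nan
            continue
        vals = predictions[mask]
        if scale == "multiplicative":
            vals = logit(clip_probability(vals, eps))
        means[cell] = float(np.mean(vals))
    return means, counts


def detect(
    model,
    data: BinaryDataset,
    feat_a: str,
    feat_b: str,
    scale: str = "multiplicative",
    eps: float | None = None,
) -> DetectionSummary:
    """Single-run interaction screen for one feature pair.

    ``model`` is any fitted predictor exposing ``predict`` over the
    dataset's features — normally a :class:`FittedPM` fitted to all
    features (including the pair); subjects contribute to exactly the
    cell of their OBSERVED (feat_a, feat_b) values.
    """
    if scale not in ("multiplicative", "additive"):
        raise ValueError('scale must be "multiplicative" or "additive"')
    if isinstance(model, FittedPM):
        fitted = set(model.feature_names)
        missing = {feat_a, feat_b} - fitted
        if missing:
            raise ValueError(f"machine was not fitted on feature(s) {sorted(missing)}")
    if eps is None:
        eps = default_eps(data.n)
    preds = np.asarray(model.predict(data.to_frame().drop(columns=["y"])), dtype=float)
    a, b = data.column(feat_a), data.column(feat_b)
    means, counts = _cell_means(preds, a, b, scale, eps)
    empty = [c for c, k in counts.items() if k == 0]
    if empty:
        raise ValueError(
            f"observed ({feat_a}, {feat_b}) cell(s) empty: {empty}; T is undefined"
        )
    T = means[(1, 1)] - means[(1, 0)] - means[(0, 1)] + means[(0, 0)]
    return DetectionSummary(
        m00=means[(0, 0)],
        m01=means[(0, 1)],
        m10=means[(1, 0)],
        m11=means[(1, 1)],
        T=T,
        cell_counts=counts,
        scale=scale,
        pair=(feat_a, feat_b),
    )


def scan(
    model,
    data: BinaryDataset,
    features: list[str] | None = None,
    scale: str = "multiplicative",
    eps: float | None = None,
) -> ScanMatrix:
    """T for every unordered feature pair from ONE fitted machine.

    Pairs whose observed 2x2 cells are not all populated are recorded as
    NaN (not applicable) rather than failing the scan.
    """
    feats = list(features) if features is not None else list(data.feature_names)
    if len(feats) < 2:
        raise ValueError("need at least 2 features to scan")
    if eps is None:
        eps = default_eps(data.n)
    preds = np.asarray(model.predict(data.to_frame().drop(columns=["y"])), dtype=float)
    mat = pd.DataFrame(np.nan, index=feats, columns=feats)
    for i, fa in enumerate(feats):
        for fb in feats[i + 1 :]:
            means, counts = _cell_means(
                preds, data.column(fa), data.column(fb), scale, eps
            )
            if any(k == 0 for k in counts.values()):
                continue
            t = means[(1, 1)] - means[(1, 0)] - means[(0, 1)] + means[(0, 0)]
            mat.loc[fa, fb] = t
            mat.loc[fb, fa] = t
    return ScanMatrix(values=mat, scale=scale)


def plot_data(summary: DetectionSummary) -> pd.DataFrame:
    """Interaction-plot lines: cell means against the first feature's level.

    Two lines over x in {0, 1}: B = 0 joins (m00, m10) and B = 1 joins
    (m01, m11); the difference of the two slopes equals T.
    """
    a, b = summary.pair
    rows = [
        {"x_level": 0, "line": f"{b}=0", "mean": summary.m00},
        {"x_level": 1, "line": f"{b}=0", "mean": summary.m10},
        {"x_level": 0, "line": f"{b}=1", "mean": summary.m01},
        {"x_level": 1, "line": f"{b}=1", "mean": summary.m11},
    ]
    df = pd.DataFrame(rows)
    df.attrs["x_feature"] = a
    df.attrs["scale"] = summary.scale
    return df


def permutation_reference(
    model,
    data: BinaryDataset,
    feat_a: str,
    feat_b: str,
    n_permutations: int = 0,
    scale: str = "multiplicative",
    eps: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Optional null reference for T: permute feat_b's column and recompute.

    Off by default (``n_permutations=0``); an exploratory extension —
    no formal significance test for T is defined by the method itself.
    """
    if n_permutations <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    if eps is None:
        eps = default_eps(data.n)
    preds = np.asarray(model.predict(data.to_frame().drop(columns=["y"])), dtype=float)
    a = data.column(feat_a)
    b = data.column(feat_b).copy()
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(b)
        means, counts = _cell_means(preds, a, perm, scale, eps)
        if any(k == 0 for k in counts.values()):
            out[i] = np.nan
            continue
        out[i] = means[(1, 1)] - means[(1, 0)] - means[(0, 1)] + means[(0, 0)]
    return out
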