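"""Counterfactual risk machines: the two-machine and 2^k-machine methods.

For a binary target feature, the dataset is split into the subgroups
D0 (target = 0) and D1 (target = 1) and one probability machine is
trained on each, with the target excluded from the design (it is
constant within each subgroup).  Scoring every subject with both
machines yields per-subject probabilities (p0, p1): the prediction from
the machine matching the subject's observed target value is the
"observed" probability, the other the counterfactual one.  From each
(p0, p1) any risk-effect function follows directly:

    RD = p1 - p0,   RR = p1 / p0,   OR = p1 (1 - p0) / (p0 (1 - p1)),

and group or whole-study effects are the mean or median of the
per-subject values.  The generalization to k target features trains one
machine per observed cell of the 2^k target combinations and scores all
subjects with all machines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from ._seeds import spawn_seeds
from .machines import FittedPM, PMConfig, clip_probability, fit_pm
from .models import BinaryDataset

__all__ = [
    "CounterfactualPair",
    "CounterfactualTable",
    "EffectEstimates",
    "two_machine",
    "multi_machine",
    "effect_functions",
    "aggregate",
    "default_eps",
    "MIN_SUBGROUP",
]

#: minimum training-subgroup size accepted for any counterfactual machine
MIN_SUBGROUP = 25


def default_eps(min_subgroup_size: int) -> float:
    """Probability clip level scaled to the smallest machine's resolution:
    1 / (2 * subgroup size), never below 1e-6."""
    return max(1e-6, 1.0 / (2.0 * max(1, min_subgroup_size)))


@dataclass
class CounterfactualTable:
    """Per-subject success probabilities under every target combination."""

    probs: np.ndarray  # (n, 2^k), columns ordered by combos
    combos: tuple[tuple[int, ...], ...]  # lexicographic 0/1 tuples over targets
    observed_combo: np.ndarray  # (n,) index into combos of each subject's cell
    targets: tuple[str, ...]
    cell_sizes: dict[tuple[int, ...], int]
    machines: dict[tuple[int, ...], FittedPM]

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def column(self, combo: tuple[int, ...]) -> np.ndarray:
        return self.probs[:, self.combos.index(tuple(combo))]


@dataclass
class CounterfactualPair:
    """Per-subject (p0, p1) for one binary target feature."""

    p0: np.ndarray
    p1: np.ndarray
    observed_arm: np.ndarray  # the subject's observed target value (0/1)
    target: str
    n0: int
    n1: int

    @property
    def n(self) -> int:
        return self.p0.shape[0]

    @property
    def observed_prob(self) -> np.ndarray:
        return np.where(self.observed_arm == 1, self.p1, self.p0)

    @property
    def counterfactual_prob(self) -> np.ndarray:
        return np.where(self.observed_arm == 1, self.p0, self.p1)


@dataclass
class EffectEstimates:
    """Per-subject and aggregated risk-effect functions."""

    rd: np.ndarray
    rr: np.ndarray
    or_: np.ndarray
    eps: float
    stat: str = "median"
    aggregate_rd: float = float("nan")
    aggregate_rr: float = float("nan")
    aggregate_or: float = float("nan")
    subgroup_label: str | None = None


def multi_machine(
    data: BinaryDataset,
    targets: list[str] | tuple[str, ...],
    config: PMConfig | None = None,
    seed: int | None = None,
    min_subgroup: int = MIN_SUBGROUP,
    max_k: int = 3,
    seeds: dict[tuple[int, ...], int] | None = None,
) -> CounterfactualTable:
    """Train one machine per observed cell of the targets; score everyone.

    The target features are excluded from every machine's design (they
    are constant within each training cell).  The node-size parameter is
    resolved against the TOTAL study size, not each cell's size, and
    applied identically to every cell machine; a cell smaller than the
    resolved node size yields a legitimately coarse (near-constant)
    machine.  Child seeds are derived per cell from ``seed`` in
    lexicographic cell order unless explicit per-cell ``seeds`` are
    supplied.
    """
    config = config or PMConfig()
    targets = tuple(targets)
    if not 1 <= len(targets) <= max_k:
        raise ValueError(f"number of targets must be between 1 and {max_k}")
    if len(set(targets)) != len(targets):
        raise ValueError("targets must be distinct")
    cols = np.column_stack([data.column(t) for t in targets])
    combos = tuple(product((0, 1), repeat=len(targets)))
    cell_sizes = {c: int(np.sum(np.all(cols == c, axis=1))) for c in combos}
    bad = {c: s for c, s in cell_sizes.items() if s < min_subgroup}
    if bad:
        cells = ", ".join(f"{dict(zip(targets, c))}: {s}" for c, s in bad.items())
        raise ValueError(
            f"target cell(s) below the minimum subgroup size {min_subgroup}: {cells}"
        )
    if seeds is None:
        child = spawn_seeds(seed if seed is not None else config.seed, len(combos))
        seeds = {c: s for c, s in zip(combos, child)}
    exclude = set(targets)
    nodesize = config.resolved_nodesize(data.n)
    probs = np.empty((data.n, len(combos)))
    machines: dict[tuple[int, ...], FittedPM] = {}
    eval_X = data.to_frame().drop(columns=["y"])
    for j, combo in enumerate(combos):
        mask = np.all(cols == combo, axis=1)
        sub = BinaryDataset(
            y=data.y[mask], X=data.X[mask], feature_names=data.feature_names
        )
        pm = fit_pm(
            sub, config, exclude_features=exclude, seed=seeds[combo], nodesize=nodesize
        )
        machines[combo] = pm
        probs[:, j] = pm.predict(eval_X)
    observed = np.array([combos.index(tuple(row)) for row in cols.astype(int)])
    return CounterfactualTable(
        probs=probs,
        combos=combos,
        observed_combo=observed,
        targets=targets,
        cell_sizes=cell_sizes,
        machines=machines,
    )


def two_machine(
    data: BinaryDataset,
    target: str,
    config: PMConfig | None = None,
    seed: int | None = None,
    min_subgroup: int = MIN_SUBGROUP,
    seeds: tuple[int, int] | None = None,
) -> CounterfactualPair:
    """The two-machine method: PM0 on D0, PM1 on D1, everyone scored twice."""
    vals = data.column(target)
    if vals.min() == vals.max():
        raise ValueError(
            f"target {target!r} is constant in the data: no counterfactual contrast"
        )
    table = multi_machine(
        data,
        [target],
        config,
        seed=seed,
        min_subgroup=min_subgroup,
        seeds=None if seeds is None else {(0,): seeds[0], (1,): seeds[1]},
        max_k=1,
    )
    return CounterfactualPair(
        p0=table.column((0,)),
        p1=table.column((1,)),
        observed_arm=vals.astype(int),
        target=target,
        n0=table.cell_sizes[(0,)],
        n1=table.cell_sizes[(1,)],
    )


def effect_functions(pair: CounterfactualPair, eps: float | None = None) -> EffectEstimates:
    """Per-subject RD, RR and OR after clipping (p0, p1) away from {0, 1}."""
    if eps is None:
        eps = default_eps(min(pair.n0, pair.n1))
    p0 = clip_probability(pair.p0, eps)
    p1 = clip_probability(pair.p1, eps)
    rd = p1 - p0
    rr = p1 / p0
    or_ = (p1 * (1.0 - p0)) / (p0 * (1.0 - p1))
    return EffectEstimates(rd=rd, rr=rr, or_=or_, eps=eps)


def aggregate(
    est: EffectEstimates,
    stat: str = "median",
    subgroup: np.ndarray | None = None,
) -> EffectEstimates:
    """Summarize per-subject effects over the study or a subgroup mask.

    Odds and risk ratios are aggregated on the ratio scale (the study's
    mean-or-median convention), not the log scale.
    """
    if stat not in ("median", "mean", "geometric_mean"):
        raise ValueError('stat must be "median", "mean" or "geometric_mean"')
    if subgroup is None:
        mask = np.ones(est.rd.shape[0], dtype=bool)
    else:
        mask = np.asarray(subgroup, dtype=bool)
        if not mask.any():
            raise ValueError("subgroup mask selects no subjects")

    def _agg(v: np.ndarray) -> float:
        v = v[mask]
        if stat == "median":
            return float(np.median(v))
        if stat == "mean":
            return float(np.mean(v))
        return float(np.exp(np.mean(np.log(v))))

    return EffectEstimates(
        rd=est.rd,
        rr=est.rr,
        or_=est.or_,
        eps=est.eps,
        stat=stat,
        aggregate_rd=float(np.median(est.rd[mask]) if stat == "median" else np.mean(est.rd[mask])),
        aggregate_rr=_agg(est.rr),
        aggregate_or=_agg(est.or_),
    )
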