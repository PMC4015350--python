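"""Replicate-level simulation studies.

Four designs, each simulating fresh training data per replicate from a
specified generating law and comparing methods head-to-head:

- ``probability_study``: bias and efficiency of conditional-probability
  estimation.  A fixed evaluation set is drawn once; every replicate's
  fitted models score it.  Bias is the mean prediction across replicates
  minus the true probability; efficiency is the width of the 5th-95th
  percentile interval of the per-subject prediction distribution.
- ``effect_study``: distribution of main-effect conditional odds
  ratios — exponentiated coefficients for the logistic comparators,
  two-machine aggregated per-subject odds ratios for the RFPM.
- ``interaction_study``: distribution of interaction odds ratios — the
  LR2 interaction coefficient versus the 4-machine interaction ratio.
- ``attenuation_study``: the 100-feature sparse regime, contrasting the
  direction of bias of RFPM (attenuation toward the null) and logistic
  regression (away from the null) per feature.

Degenerate comparator replicates (separation or non-convergence) are
flagged and excluded from distribution summaries, with the exclusion
count reported, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import spawn_seeds
from .machines import PMConfig, fit_logistic, fit_pm
from .models import (
    BinaryDataset,
    LogisticModelSpec,
    SparseCoefficientSpec,
    builtin_model,
    simulate,
    true_probability,
)
from .risk import aggregate, effect_functions, two_machine
from .interaction import four_machine

__all__ = [
    "StudyConfig",
    "ProbabilityStudyResult",
    "EffectStudyResult",
    "AttenuationResult",
    "probability_study",
    "effect_study",
    "interaction_study",
    "detection_study",
    "attenuation_study",
    "export",
    "read_exported",
]

METHODS = ("LR1", "LR2", "RFPM")


@dataclass(frozen=True)
class StudyConfig:
    """Shared configuration for the replicate studies."""

    model: str | LogisticModelSpec = "model1"
    n: int = 1000
    reps: int = 200
    methods: tuple[str, ...] = METHODS
    pm: PMConfig = field(default_factory=PMConfig)
    seed: int = 0
    eval_n: int = 500
    stat: str = "median"

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.methods:
            raise ValueError("at least one method must be selected")
        for m in self.methods:
            if m not in METHODS + ("oracle",):
                raise ValueError(f"unknown method {m!r}; valid: {METHODS + ('oracle',)}")

    def spec(self) -> LogisticModelSpec:
        return builtin_model(self.model) if isinstance(self.model, str) else self.model


def _active_features(spec: LogisticModelSpec) -> tuple[str, ...]:
    """Features the true probability actually depends on."""
    if spec.stratum_features:
        return spec.stratum_features
    names = set(n for n, v in spec.main_or.items() if v != 1.0)
    for (a, b), v in spec.interaction_or.items():
        if v != 1.0:
            names.update((a, b))
    order = {f: i for i, f in enumerate(spec.feature_names)}
    return tuple(sorted(names, key=order.get)) or spec.feature_names[:1]


@dataclass
class ProbabilityStudyResult:
    """Per-evaluation-subject and per-stratum bias/efficiency summaries."""

    per_unit: pd.DataFrame  # unit, method, true, mean_pred, bias, q5, q95, width
    per_stratum: pd.DataFrame  # stratum, method, true, mean_pred, bias, mean_width, n_units
    reps: int
    failures: pd.DataFrame  # rep, method, seed rows for non-converged fits
    kind: str = "probability"

    def to_tidy(self) -> pd.DataFrame:
        df = self.per_stratum.melt(
            id_vars=["stratum", "method"], var_name="statistic", value_name="value"
        )
        df.insert(0, "kind", self.kind)
        return df

    def headline(self) -> dict:
        out = {"kind": self.kind, "reps": self.reps, "n_failures": int(len(self.failures))}
        for method, grp in self.per_stratum.groupby("method"):
            out[method] = {
                "max_abs_bias": float(grp["bias"].abs().max()),
                "mean_width": float(grp["mean_width"].mean()),
            }
        return out


def probability_study(config: StudyConfig) -> ProbabilityStudyResult:
    """Bias / 5th-95th-width study of conditional-probability estimation."""
    spec = config.spec()
    eval_seed, *rep_seeds = spawn_seeds(config.seed, config.reps + 1)
    eval_data = simulate(spec, config.eval_n, eval_seed)
    eval_X = eval_data.to_frame().drop(columns=["y"])
    truth = np.asarray(true_probability(spec, eval_data.X))

    preds = {m: np.empty((config.reps, config.eval_n)) for m in config.methods}
    failures = []
    for r, rseed in enumerate(rep_seeds):
        data_seed, pm_seed = spawn_seeds(rseed, 2)
        train = simulate(spec, config.n, data_seed)
        for m in config.methods:
            if m == "oracle":
                preds[m][r] = truth
            elif m == "RFPM":
                pm = fit_pm(train, config.pm, seed=pm_seed)
                preds[m][r] = pm.predict(eval_X)
            else:
                fit = fit_logistic(train, design=m)
                if not fit.converged:
                    failures.append({"rep": r, "method": m, "seed": data_seed})
                preds[m][r] = fit.predict(eval_X)

    active = _active_features(spec)
    strata = ["".join(str(v) for v in row) for row in
              eval_data.to_frame()[list(active)].to_numpy()]
    unit_rows = []
    for m in config.methods:
        mean_pred = preds[m].mean(axis=0)
        q5 = np.percentile(preds[m], 5, axis=0)
        q95 = np.percentile(preds[m], 95, axis=0)
        for i in range(config.eval_n):
            unit_rows.append(
                {
                    "unit": i,
                    "stratum": strata[i],
                    "method": m,
                    "true": truth[i],
                    "mean_pred": mean_pred[i],
                    "bias": mean_pred[i] - truth[i],
                    "q5": q5[i],
                    "q95": q95[i],
                    "width": q95[i] - q5[i],
                }
            )
    per_unit = pd.DataFrame(unit_rows)
    per_stratum = (
        per_unit.groupby(["stratum", "method"], as_index=False)
        .agg(
            true=("true", "mean"),
            mean_pred=("mean_pred", "mean"),
            bias=("bias", "mean"),
            mean_width=("width", "mean"),
            n_units=("unit", "size"),
        )
        .sort_values(["method", "stratum"], ignore_index=True)
    )
    return ProbabilityStudyResult(
        per_unit=per_unit.drop(columns=["stratum"]),
        per_stratum=per_stratum,
        reps=config.reps,
        failures=pd.DataFrame(failures, columns=["rep", "method", "seed"]),
    )


@dataclass
class EffectStudyResult:
    """Replicate-wise effect estimates and their summaries."""

    estimates: pd.DataFrame  # rep, method, target, estimate, converged
    summary: pd.DataFrame  # method, target, truth, median, q5, q95, n_used, n_excluded
    kind: str = "effect"

    def to_tidy(self) -> pd.DataFrame:
        df = self.summary.melt(
            id_vars=["method", "target"], var_name="statistic", value_name="value"
        )
        df.insert(0, "kind", self.kind)
        return df

    def headline(self) -> dict:
        out = {"kind": self.kind}
        for (method, target), grp in self.summary.groupby(["method", "target"]):
            out[f"{method}:{target}"] = {
                "median": float(grp["median"].iloc[0]),
                "truth": float(grp["truth"].iloc[0]),
            }
        return out


def _summarize_effects(rows: list[dict], truths: dict[str, float]) -> EffectStudyResult:
    est = pd.DataFrame(rows)
    summaries = []
    for (method, target), grp in est.groupby(["method", "target"]):
        ok = grp[grp["converged"]]
        vals = ok["estimate"].to_numpy()
        summaries.append(
            {
                "method": method,
                "target": target,
                "truth": truths[target],
                "median": float(np.median(vals)) if len(vals) else np.nan,
                "q5": float(np.percentile(vals, 5)) if len(vals) else np.nan,
                "q95": float(np.percentile(vals, 95)) if len(vals) else np.nan,
                "n_used": int(len(vals)),
                "n_excluded": int(len(grp) - len(vals)),
            }
        )
    return EffectStudyResult(estimates=est, summary=pd.DataFrame(summaries))


def effect_study(config: StudyConfig, targets: list[str]) -> EffectStudyResult:
    """Distribution of main-effect conditional odds ratios per method."""
    spec = config.spec()
    if any(t not in spec.feature_names for t in targets):
        raise ValueError("targets must be features of the model spec")
    rep_seeds = spawn_seeds(config.seed, config.reps)
    rows = []
    for r, rseed in enumerate(rep_seeds):
        child = spawn_seeds(rseed, 1 + len(targets))
        train = simulate(spec, config.n, child[0])
        for m in config.methods:
            if m in ("LR1", "LR2"):
                fit = fit_logistic(train, design=m)
                for t in targets:
                    rows.append(
                        {
                            "rep": r,
                            "method": m,
                            "target": t,
                            "estimate": fit.odds_ratio(t),
                            "converged": fit.converged,
                        }
                    )
            elif m == "RFPM":
                for t, tseed in zip(targets, child[1:]):
                    pair = two_machine(train, t, config.pm, seed=tseed)
                    est = aggregate(effect_functions(pair), stat=config.stat)
                    rows.append(
                        {
                            "rep": r,
                            "method": m,
                            "target": t,
                            "estimate": est.aggregate_or,
                            "converged": True,
                        }
                    )
    truths = {t: float(spec.main_or_vector()[spec.feature_names.index(t)]) for t in targets}
    return _summarize_effects(rows, truths)


def interaction_study(config: StudyConfig, pair: tuple[str, str]) -> EffectStudyResult:
    """Distribution of the interaction odds ratio: LR2 versus 4-machine."""
    spec = config.spec()
    feat_a, feat_b = pair
    rep_seeds = spawn_seeds(config.seed, config.reps)
    rows = []
    label = f"{feat_a}:{feat_b}"
    for r, rseed in enumerate(rep_seeds):
        data_seed, fm_seed = spawn_seeds(rseed, 2)
        train = simulate(spec, config.n, data_seed)
        for m in config.methods:
            if m == "LR2":
                fit = fit_logistic(train, design="LR2")
                rows.append(
                    {
                        "rep": r,
                        "method": m,
                        "target": label,
                        "estimate": fit.odds_ratio(label),
                        "converged": fit.converged,
                    }
                )
            elif m == "RFPM":
                res = four_machine(
                    train, feat_a, feat_b, config.pm, seed=fm_seed, stat=config.stat
                )
                rows.append(
                    {
                        "rep": r,
                        "method": m,
                        "target": label,
                        "estimate": res.aggregate_ior,
                        "converged": True,
                    }
                )
    truths = {label: spec.true_interaction_or(feat_a, feat_b)}
    return _summarize_effects(rows, truths)


def detection_study(
    config: StudyConfig, pair: tuple[str, str], scale: str = "multiplicative"
) -> EffectStudyResult:
    """Distribution of the single-run detection contrast T across replicates.

    Each replicate simulates a fresh dataset, fits ONE machine on all
    features and computes T for the pair from observed-subgroup cell
    means.  The reference truth is the log interaction odds ratio on the
    multiplicative scale (0 under no interaction).
    """
    from .interaction import detect

    spec = config.spec()
    feat_a, feat_b = pair
    label = f"{feat_a}:{feat_b}"
    rows = []
    for r, rseed in enumerate(spawn_seeds(config.seed, config.reps)):
        data_seed, pm_seed = spawn_seeds(rseed, 2)
        train = simulate(spec, config.n, data_seed)
        pm = fit_pm(train, config.pm, seed=pm_seed)
        summary = detect(pm, train, feat_a, feat_b, scale=scale)
        rows.append(
            {
                "rep": r,
                "method": "RFPM-T",
                "target": label,
                "estimate": summary.T,
                "converged": True,
            }
        )
    truths = {label: float(np.log(spec.true_interaction_or(feat_a, feat_b)))}
    result = _summarize_effects(rows, truths)
    result.kind = "detection"
    return result


@dataclass
class AttenuationResult:
    """Per-feature estimated vs. true log odds ratios in the sparse regime."""

    per_feature: pd.DataFrame  # feature, method, true_log_or, median_log_or
    attenuation_index: dict[str, float]  # method -> median |est| / |true| over non-null
    reps: int
    kind: str = "attenuation"

    def to_tidy(self) -> pd.DataFrame:
        df = self.per_feature.melt(
            id_vars=["feature", "method"], var_name="statistic", value_name="value"
        )
        df.insert(0, "kind", self.kind)
        return df

    def headline(self) -> dict:
        return {
            "kind": self.kind,
            "reps": self.reps,
            "attenuation_index": dict(self.attenuation_index),
        }


def attenuation_study(
    spec: SparseCoefficientSpec,
    n: int = 2000,
    reps: int = 10,
    config: PMConfig | None = None,
    seed: int = 0,
    targets: list[str] | None = None,
    stat: str = "median",
) -> AttenuationResult:
    """High-dimensional attenuation study (sparse 100-feature regime).

    The sparse coefficient vector is realized once; each replicate draws
    a fresh dataset from that fixed law.  Logistic main-effect odds
    ratios come from a single LR1 fit per replicate; RFPM odds ratios
    from the two-machine method per target feature.  ``targets``
    restricts the (expensive) RFPM arm; default: the non-null features.
    """
    config = config or PMConfig()
    coef_seed, *rep_seeds = spawn_seeds(seed, reps + 1)
    realized = spec if spec.coefficients is not None else spec.realize(coef_seed)
    law = realized.to_logistic_spec()
    coefs = dict(zip(realized.feature_names, realized.coefficients))
    if targets is None:
        targets = [f for f, c in coefs.items() if c != 0.0]
    est: dict[tuple[str, str], list[float]] = {}
    for r, rseed in enumerate(rep_seeds):
        child = spawn_seeds(rseed, 1 + len(targets))
        train = simulate(law, n, child[0])
        lr = fit_logistic(train, design="LR1")
        for f in realized.feature_names:
            if lr.converged:
                est.setdefault((f, "LR1"), []).append(lr.coef(f))
        for f, fseed in zip(targets, child[1:]):
            pair = two_machine(train, f, config, seed=fseed)
            agg = aggregate(effect_functions(pair), stat=stat)
            est.setdefault((f, "RFPM"), []).append(float(np.log(agg.aggregate_or)))
    rows = [
        {
            "feature": f,
            "method": m,
            "true_log_or": coefs[f],
            "median_log_or": float(np.median(v)),
        }
        for (f, m), v in est.items()
    ]
    per_feature = pd.DataFrame(rows).sort_values(["method", "feature"], ignore_index=True)
    index = {}
    for m, grp in per_feature.groupby("method"):
        nz = grp[(grp["true_log_or"] != 0.0) & grp["feature"].isin(targets)]
        if len(nz):
            ratios = np.abs(nz["median_log_or"]) / np.abs(nz["true_log_or"])
            index[m] = float(np.median(ratios))
    return AttenuationResult(per_feature=per_feature, attenuation_index=index, reps=reps)


# ---------------------------------------------------------------------------
# Export


def export(result, path: str | Path) -> tuple[Path, Path]:
    """Write a study result as tidy CSV plus a JSON headline summary.

    ``path`` is a prefix; ``<path>.csv`` and ``<path>.json`` are
    written.  The CSV round-trips losslessly through
    :func:`read_exported`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    try:
        result.to_tidy().to_csv(csv_path, index=False, float_format="%.17g")
        json_path.write_text(json.dumps(result.headline(), indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing study export to {path}: {exc}") from exc
    return csv_path, json_path


def read_exported(csv_path: str | Path) -> pd.DataFrame:
    """Read back a tidy CSV written by :func:`export`."""
    return pd.read_csv(csv_path)
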