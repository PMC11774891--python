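"""Repeated random-split evaluation harness.

The lot of n labeled seeds is randomly divided into M training and n − M test
seeds (plain uniform partition, no stratification); a model is fit on the
training side, test predictions are scored as recognition accuracies —
yellow RA (correct yellow / true yellow), non-yellow RA, and average RA
(overall fraction correct) — and the whole split-fit-score cycle is repeated,
by default 100 times per M over the grid M ∈ {150, 160, …, 240}. Reported per
(model, M): mean and SD of the three RAs across repetitions plus the pooled
confusion matrix (yellow = positive class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from . import models as mdl
from .indices import SpectralIndexSpec, correlation_surface, select_best_pair, FAMILIES
from .labeling import RGBThresholds, DEFAULT_THRESHOLDS
from .synthetic import SampleSet, CHANNELS
from .trilateral import rank_trilateral, top_parameters, trilateral_table

MODEL_KINDS = ("plsr", "logit", "rf", "svc", "majority")


@dataclass
class SplitPlan:
    M_grid: tuple[int, ...] = tuple(range(150, 241, 10))
    n_reps: int = 100
    seed: int = 0

    def validate(self, n: int) -> None:
        for m in self.M_grid:
            if not 0 < m < n:
                raise ValueError(f"training size M={m} out of range (0, {n})")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")


@dataclass
class SelectionResult:
    """Fixed feature definitions used by the harness: the 9 channel-optimized
    index specs, the top-3 trilateral parameters, and (for RF/SVC) the
    lasso-selected pool columns."""

    index_specs: tuple[SpectralIndexSpec, ...]
    top3_trilateral: tuple[str, ...]
    lasso_selected: tuple[str, ...] = ()
    lasso_lambda: float | None = None

    @classmethod
    def from_reference(cls) -> "SelectionResult":
        return cls(feat.REFERENCE_INDEX_SPECS, feat.REFERENCE_TOP3_TRILATERAL)


def select_features(samples: SampleSet, index_reps: int = 10,
                    trilateral_reps: int = 100, trilateral_subset: int = 150,
                    lasso: bool = True, cv_folds: int = 10,
                    seed: int | None = None) -> SelectionResult:
    """Run all three selection procedures on a labeled sample set."""
    rng = np.random.default_rng(seed)
    specs = []
    for channel in CHANNELS:
        for family in FAMILIES:
            surf = correlation_surface(family, samples, channel, n_reps=index_reps,
                                       seed=int(rng.integers(2**31)))
            specs.append(select_best_pair(surf))
    subset = min(trilateral_subset, samples.n)
    ranking = rank_trilateral(samples, "R", n_reps=trilateral_reps,
                              subset_size=subset, seed=int(rng.integers(2**31)))
    top3 = tuple(top_parameters(ranking, 3))
    selected: tuple[str, ...] = ()
    lam = None
    if lasso:
        pool = feat.assemble_pool(samples, tuple(specs))
        sel = mdl.lasso_select(pool, samples.label, cv_folds=cv_folds,
                               seed=int(rng.integers(2**31)))
        selected, lam = tuple(sel.selected_names), sel.lam
    return SelectionResult(tuple(specs), top3, selected, lam)


def split(samples: SampleSet, M: int, seed) -> tuple[SampleSet, SampleSet]:
    """Uniform random partition into M training and n − M test seeds."""
    if not 0 < M < samples.n:
        raise ValueError(f"M={M} out of range (0, {samples.n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(samples.n)
    return samples.subset(perm[:M]), samples.subset(perm[M:])


@dataclass
class RAResult:
    average: float
    yellow: float
    nonyellow: float


def recognition_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> RAResult:
    """Per-class and overall recognition accuracies in percent.

    Average RA is the overall fraction correct. A class absent from y_true
    yields NaN for that class RA (reported missing, never 0).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise ValueError(f"{name} must be binary 0/1")
    correct = y_true == y_pred
    avg = 100.0 * correct.mean()
    yellow = 100.0 * correct[y_true == 1].mean() if (y_true == 1).any() else np.nan
    nonyellow = 100.0 * correct[y_true == 0].mean() if (y_true == 0).any() else np.nan
    return RAResult(avg, yellow, nonyellow)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    """TP/FN/FP/TN with yellow (1) as the positive class."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return {
        "tp": int(((y_true == 1) & (y_pred == 1)).sum()),
        "fn": int(((y_true == 1) & (y_pred == 0)).sum()),
        "fp": int(((y_true == 0) & (y_pred == 1)).sum()),
        "tn": int(((y_true == 0) & (y_pred == 0)).sum()),
    }


REPORT_COLUMNS = ("model", "M", "avg_ra_mean", "avg_ra_sd", "yellow_ra_mean",
                  "yellow_ra_sd", "nonyellow_ra_mean", "nonyellow_ra_sd",
                  "tp", "fn", "fp", "tn")


class _MajorityStub:
    """Deterministic baseline: always predicts the training-majority class."""

    def __init__(self, labels: np.ndarray):
        self.majority = int(np.asarray(labels).sum() * 2 >= len(labels))

    def predict(self, features) -> np.ndarray:
        return np.full(len(features), self.majority, dtype=int)


def _fit_predict(model_kind: str, train: SampleSet, test: SampleSet,
                 selection: SelectionResult, thresholds: RGBThresholds,
                 tri_all: pd.DataFrame, pool_all: pd.DataFrame | None,
                 train_idx: np.ndarray, test_idx: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    if model_kind == "plsr":
        preds = np.empty((test.n, 3))
        for c, channel in enumerate(CHANNELS):
            xtr = feat.fused_features(train, channel, selection.index_specs,
                                      selection.top3_trilateral,
                                      trilateral=tri_all.iloc[train_idx])
            xte = feat.fused_features(test, channel, selection.index_specs,
                                      selection.top3_trilateral,
                                      trilateral=tri_all.iloc[test_idx])
            model = mdl.fit_plsr(xtr, train.rgb[:, c])
            preds[:, c] = model.predict(xte).ravel()
        from .labeling import label_rgb
        return label_rgb(np.clip(preds, 0.0, 255.0), thresholds)
    if model_kind == "logit":
        specs = [s for s in selection.index_specs if s.channel == "R"]
        from .indices import compute_index_matrix
        model = mdl.fit_logit(compute_index_matrix(train, specs), train.label)
        return model.classify(compute_index_matrix(test, specs))
    if model_kind in ("rf", "svc"):
        cols = list(selection.lasso_selected)
        if not cols:
            raise ValueError("rf/svc require a non-empty lasso-selected feature set")
        xtr, xte = pool_all.iloc[train_idx][cols], pool_all.iloc[test_idx][cols]
        fit = mdl.fit_rf if model_kind == "rf" else mdl.fit_svc
        model = fit(xtr, train.label, seed=int(rng.integers(2**31)))
        return model.predict(xte)
    if model_kind == "majority":
        return _MajorityStub(train.label).predict(np.empty((test.n, 0)))
    raise ValueError(f"unknown model kind '{model_kind}'")


def run_experiment(samples: SampleSet, model_kinds, plan: SplitPlan,
                   selection: SelectionResult | None = None,
                   thresholds: RGBThresholds = DEFAULT_THRESHOLDS,
                   reselect_per_split: bool = False) -> pd.DataFrame:
    """The full repeated-split experiment; one report row per (model, M).

    By default the feature definitions in ``selection`` are fixed across
    splits (each model is still refit per split on its training half).
    ``reselect_per_split=True`` re-runs band-pair search (single repetition),
    trilateral ranking and lasso selection inside every training split.
    """
    if isinstance(model_kinds, str):
        model_kinds = [model_kinds]
    for kind in model_kinds:
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind '{kind}'")
    lab = samples.label
    if np.isnan(lab).any():
        raise ValueError("run_experiment requires fully labeled samples")
    if np.unique(lab).size < 2:
        raise ValueError("run_experiment requires both classes present")
    plan.validate(samples.n)
    if selection is None:
        selection = SelectionResult.from_reference()
    need_pool = any(k in ("rf", "svc") for k in model_kinds) or reselect_per_split
    tri_all = trilateral_table(samples)
    pool_all = feat.assemble_pool(samples, selection.index_specs, tri_all) if need_pool else None

    rows = []
    for kind in model_kinds:
        for M in plan.M_grid:
            rng = np.random.default_rng(
                np.random.SeedSequence(plan.seed, spawn_key=(MODEL_KINDS.index(kind), M)))
            ras = np.empty((plan.n_reps, 3))
            conf = {k: 0 for k in ("tp", "fn", "fp", "tn")}
            for rep in range(plan.n_reps):
                perm = rng.permutation(samples.n)
                train_idx, test_idx = perm[:M], perm[M:]
                train, test = samples.subset(train_idx), samples.subset(test_idx)
                sel = selection
                if reselect_per_split and kind != "majority":
                    sel = select_features(train, index_reps=1, trilateral_reps=10,
                                          trilateral_subset=min(150, train.n),
                                          lasso=kind in ("rf", "svc"),
                                          seed=int(rng.integers(2**31)))
                    if kind in ("rf", "svc"):
                        tri_split = trilateral_table(samples)
                        pool_split = feat.assemble_pool(samples, sel.index_specs, tri_split)
                    else:
                        tri_split, pool_split = tri_all, pool_all
                else:
                    tri_split, pool_split = tri_all, pool_all
                y_pred = _fit_predict(kind, train, test, sel, thresholds,
                                      tri_split, pool_split, train_idx, test_idx, rng)
                ra = recognition_accuracy(test.label, y_pred)
                ras[rep] = (ra.average, ra.yellow, ra.nonyellow)
                for key, v in confusion_counts(test.label, y_pred).items():
                    conf[key] += v
            rows.append({
                "model": kind, "M": M,
                "avg_ra_mean": np.nanmean(ras[:, 0]), "avg_ra_sd": np.nanstd(ras[:, 0]),
                "yellow_ra_mean": np.nanmean(ras[:, 1]), "yellow_ra_sd": np.nanstd(ras[:, 1]),
                "nonyellow_ra_mean": np.nanmean(ras[:, 2]), "nonyellow_ra_sd": np.nanstd(ras[:, 2]),
                **conf,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
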