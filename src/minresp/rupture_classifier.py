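"""Minimal-response marker classification on rupture windows.

A random forest (500 trees, 6 variables tried at each split) predicts
whether a 10-s rupture window belongs to a rupture carrying the
minimal-response marker, from the 44 per-dyad z-scored switching-pattern
pause features (four patterns at offsets 0, +-1..5 windows).  Training
uses rupture windows only; 2/3 of the rupture *episodes* go to training,
stratified by dyad and marker presence and weighted by episode length in
seconds, so that no episode contributes windows to both sides.  Reported
metrics: out-of-bag error, permutation importance (mean decrease
accuracy), and ROC/AUC on the rupture-only validation set and on the
validation set enriched with all non-rupture windows (negatives by
definition).  No decision threshold is calibrated; the AUC is the
probability that a random positive scores above a random negative, with
half credit for ties.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .windowing import feature_columns

N_TREES = 500
MTRY = 6


@dataclass
class SplitSpec:
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    window_seconds: float = 10.0


@dataclass
class ClassifierReport:
    oob_error: float  # percent
    n_trees: int
    mtry: int
    auc_ruptures_only: float = None
    auc_with_nonruptures: float = None
    roc_ruptures_only: pd.DataFrame = field(default=None, repr=False)
    roc_with_nonruptures: pd.DataFrame = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "oob_error_pct": self.oob_error,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "auc_ruptures_only": self.auc_ruptures_only,
            "auc_with_nonruptures": self.auc_with_nonruptures,
        }


# ---------------------------------------------------------------------------
# AUC / ROC primitives

def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """P(score of a random positive > score of a random negative), ties
    counted half — the rank (Mann-Whitney) definition."""
    y = np.asarray(y, bool)
    scores = np.asarray(scores, float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positives and negatives")
    r = rankdata(scores)
    return (r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_points(y: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC by sweeping the decision threshold over the observed scores
    (descending); both coordinates are monotone non-decreasing."""
    y = np.asarray(y, bool)
    scores = np.asarray(scores, float)
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    ss = scores[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(~ys)
    # collapse tied thresholds
    last = np.concatenate([ss[1:] != ss[:-1], [True]])
    tpr = np.concatenate([[0.0], tp[last] / max(ys.sum(), 1)])
    fpr = np.concatenate([[0.0], fp[last] / max((~ys).sum(), 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def trapezoid_auc(roc: pd.DataFrame) -> float:
    return float(np.trapezoid(roc["tpr"].to_numpy(), roc["fpr"].to_numpy()))


# ---------------------------------------------------------------------------
# episode-level split

def split_ruptures(rows: pd.DataFrame, spec: SplitSpec):
    """Allocate whole rupture episodes to training/validation.

    Within each (dyad, minimal-response) stratum, episodes are shuffled
    and assigned to training while the training side holds less than
    ``train_fraction`` of the stratum's rupture seconds; all of an
    episode's windows land on the same side.  Single-episode strata go
    to training with a warning.
    """
    if rows.empty:
        raise ValueError("no rupture rows to split")
    rows = rows[rows["in_rupture"]]
    if rows.empty:
        raise ValueError("input contains no rupture windows")
    rng = np.random.default_rng(spec.seed)
    key = ["dyad_id", "session_id", "rupture_id"]
    episodes = (
        rows.groupby(key, dropna=False)
        .agg(n_windows=("window_index", "size"),
             minimal_response=("minimal_response", "first"))
        .reset_index()
    )
    episodes["seconds"] = episodes["n_windows"] * spec.window_seconds
    train_keys = []
    for (dyad, mr), grp in episodes.groupby(["dyad_id", "minimal_response"]):
        if len(grp) == 1:
            warnings.warn(
                f"stratum (dyad={dyad}, minimal_response={mr}) has a single "
                "episode; assigned to training"
            )
        grp = grp.iloc[rng.permutation(len(grp))]
        target = spec.train_fraction * grp["seconds"].sum()
        cum = 0.0
        for _, ep in grp.iterrows():
            w = ep["seconds"]
            if cum >= target:
                continue
            # take the stratum-target-crossing episode only when doing so
            # lands closer to the 2/3 mark than leaving it out
            if cum + w <= target or (cum + w - target) <= (target - cum):
                train_keys.append(tuple(ep[key]))
                cum += w
    keyframe = rows.set_index(key)
    train_mask = keyframe.index.isin(train_keys)
    train = keyframe[train_mask].reset_index()
    val = keyframe[~train_mask].reset_index()
    shared = set(map(tuple, train[key].drop_duplicates().to_numpy())) & set(
        map(tuple, val[key].drop_duplicates().to_numpy())
    )
    assert not shared, "episode leaked across the split"
    return train, val


# ---------------------------------------------------------------------------
# forest

def train(train_rows: pd.DataFrame, n_trees: int = N_TREES, mtry: int = MTRY,
          seed: int = 0, max_lag: int = 5):
    """Fit the forest on the training rupture windows; returns
    (model, oob_error_percent)."""
    cols = feature_columns(max_lag)
    y = train_rows["minimal_response"].to_numpy(bool)
    if y.all() or not y.any():
        raise ValueError("training set contains a single class")
    X = train_rows[cols].to_numpy()
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(mtry, len(cols)),
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    votes = clf.oob_decision_function_
    have = ~np.isnan(votes[:, 0])
    pred = votes[have, 1] > 0.5
    oob_error = 100.0 * float((pred != y[have]).mean())
    return clf, oob_error


def importance(model, validation: pd.DataFrame, seed: int = 0,
               n_repeats: int = 5, max_lag: int = 5) -> pd.DataFrame:
    """Permutation importance (mean decrease accuracy, percent) on the
    validation set, ranked most important first."""
    cols = feature_columns(max_lag)
    res = permutation_importance(
        model,
        validation[cols].to_numpy(),
        validation["minimal_response"].to_numpy(bool),
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    out = pd.DataFrame({
        "feature": cols,
        "mean_decrease_accuracy_pct": 100.0 * res.importances_mean,
        "sd_pct": 100.0 * res.importances_std,
    })
    return out.sort_values("mean_decrease_accuracy_pct", ascending=False).reset_index(drop=True)


def evaluate(model, validation: pd.DataFrame, nonrupture_rows: pd.DataFrame = None,
             oob_error: float = float("nan"), max_lag: int = 5) -> ClassifierReport:
    """ROC/AUC on the validation rupture windows and, when non-rupture
    windows are supplied, on the validation set enriched with them (all
    negatives: non-rupture windows contain no minimal-response marker by
    definition)."""
    cols = feature_columns(max_lag)
    y = validation["minimal_response"].to_numpy(bool)
    if y.all() or not y.any():
        raise ValueError("validation set lacks positives or negatives")
    scores = model.predict_proba(validation[cols].to_numpy())[:, 1]
    roc1 = roc_points(y, scores)
    rep = ClassifierReport(
        oob_error=oob_error,
        n_trees=model.n_estimators,
        mtry=model.max_features,
        auc_ruptures_only=rank_auc(y, scores),
        roc_ruptures_only=roc1,
    )
    if nonrupture_rows is not None and len(nonrupture_rows):
        s2 = model.predict_proba(nonrupture_rows[cols].to_numpy())[:, 1]
        y2 = np.concatenate([y, np.zeros(len(nonrupture_rows), bool)])
        sc2 = np.concatenate([scores, s2])
        rep.auc_with_nonruptures = rank_auc(y2, sc2)
        rep.roc_with_nonruptures = roc_points(y2, sc2)
    return rep
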