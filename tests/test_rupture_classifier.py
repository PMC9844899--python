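"""Episode-level splitting, the forest, and the ROC/AUC primitives."""
import numpy as np
import pandas as pd
import pytest

from minresp.rupture_classifier import (
    SplitSpec,
    evaluate,
    importance,
    rank_auc,
    roc_points,
    split_ruptures,
    train,
    trapezoid_auc,
)
from minresp.windowing import feature_columns


def test_auc_perfect_separation():
    assert rank_auc([True, True, False, False], [0.9, 0.8, 0.1, 0.2]) == 1.0


def test_auc_reversal_symmetry():
    rng = np.random.default_rng(0)
    y = rng.random(50) < 0.4
    s = rng.random(50)
    assert rank_auc(y, s) == pytest.approx(1.0 - rank_auc(y, -s))


def test_auc_ties_get_half_credit():
    assert rank_auc([True, False], [0.5, 0.5]) == pytest.approx(0.5)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        rank_auc([True, True], [0.1, 0.2])


def test_rank_auc_equals_trapezoidal_roc_area():
    """Two-oracle agreement on random scores (with ties) to 1e-9."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        y = rng.random(200) < 0.3
        if not y.any() or y.all():
            continue
        s = np.round(rng.random(200), 2)  # rounding forces ties
        roc = roc_points(y, s)
        assert abs(rank_auc(y, s) - trapezoid_auc(roc)) < 1e-9


def test_roc_monotone():
    rng = np.random.default_rng(2)
    y = rng.random(100) < 0.5
    roc = roc_points(y, rng.random(100))
    assert (np.diff(roc.fpr) >= 0).all()
    assert (np.diff(roc.tpr) >= 0).all()


# --- splitting ---------------------------------------------------------------

def _episode_rows(episodes):
    """rows for a list of (dyad, session, rupture_id, n_windows, mr)."""
    cols = feature_columns()
    rows = []
    for dyad, sess, rid, n, mr in episodes:
        for w in range(n):
            rows.append({
                "dyad_id": dyad, "session_id": sess, "rupture_id": rid,
                "window_index": w, "in_rupture": True, "minimal_response": mr,
                "pause_pct": 30.0, **{c: 0.0 for c in cols},
            })
    return pd.DataFrame(rows)


def test_three_equal_ruptures_two_in_training():
    rows = _episode_rows([("d0", "s0", f"r{i}", 4, True) for i in range(3)]
                         + [("d0", "s0", "r9", 4, False)])
    with pytest.warns(UserWarning):
        train_df, val_df = split_ruptures(rows, SplitSpec(seed=1))
    mr_train = train_df[train_df.minimal_response].rupture_id.nunique()
    mr_val = val_df[val_df.minimal_response].rupture_id.nunique() if len(val_df) else 0
    assert mr_train == 2 and mr_val == 1


def test_no_episode_on_both_sides():
    eps = [("d%d" % (i % 3), "s0", "r%d" % i, 3 + i % 4, i % 2 == 0) for i in range(20)]
    train_df, val_df = split_ruptures(_episode_rows(eps), SplitSpec(seed=2))
    key = ["dyad_id", "session_id", "rupture_id"]
    shared = set(map(tuple, train_df[key].values)) & set(map(tuple, val_df[key].values))
    assert not shared


def test_training_share_of_seconds_around_two_thirds():
    rng = np.random.default_rng(3)
    eps = [("d%d" % (i % 4), "s%d" % i, "r0", int(rng.integers(2, 30)), bool(rng.random() < 0.5))
           for i in range(60)]
    rows = _episode_rows(eps)
    shares = []
    for seed in range(20):
        train_df, val_df = split_ruptures(rows, SplitSpec(seed=seed))
        shares.append(len(train_df) / (len(train_df) + len(val_df)))
    assert abs(np.mean(shares) - 2 / 3) < 0.05


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        split_ruptures(_episode_rows([]).reindex(columns=["in_rupture"]), SplitSpec())


# --- forest ------------------------------------------------------------------

def _labelled_features(n=300, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    cols = feature_columns()
    y = rng.random(n) < 0.5
    X = rng.normal(size=(n, len(cols)))
    if informative:
        X[:, cols.index("T_T_lag0")] += 2.5 * y
    df = pd.DataFrame(X, columns=cols)
    df["minimal_response"] = y
    df["in_rupture"] = True
    df["dyad_id"] = "d0"
    df["session_id"] = "s0"
    df["rupture_id"] = [f"r{i}" for i in range(n)]
    df["window_index"] = np.arange(n)
    return df


def test_separable_toy_data_near_zero_oob():
    df = _labelled_features(informative=True, seed=4)
    cols = feature_columns()
    df[cols] = 0.0
    df["T_T_lag0"] = np.where(df.minimal_response, 5.0, -5.0)
    _, oob = train(df, n_trees=100, seed=0)
    assert oob <= 2.0


def test_single_class_training_rejected():
    df = _labelled_features(seed=5)
    df["minimal_response"] = True
    with pytest.raises(ValueError, match="single class"):
        train(df, n_trees=10, seed=0)


def test_shuffled_labels_give_chance_auc():
    df = _labelled_features(n=500, informative=True, seed=6)
    rng = np.random.default_rng(7)
    df["minimal_response"] = rng.permutation(df["minimal_response"].to_numpy())
    tr, val = df.iloc[:300], df.iloc[300:]
    model, _ = train(tr, n_trees=200, seed=1)
    rep = evaluate(model, val)
    assert abs(rep.auc_ruptures_only - 0.5) < 0.08


def test_pure_noise_feature_importance_near_zero():
    df = _labelled_features(n=400, informative=True, seed=8)
    tr, val = df.iloc[:250], df.iloc[250:]
    model, _ = train(tr, n_trees=200, seed=2)
    imp = importance(model, val, seed=0, n_repeats=3)
    top = imp.iloc[0]
    assert top.feature == "T_T_lag0"
    noise = imp[imp.feature == "P_P_lag-5"].mean_decrease_accuracy_pct.iloc[0]
    assert abs(noise) < 1.5


def test_importance_invariant_to_duplicated_useless_feature():
    """Permuting a feature the forest never splits on cannot change
    accuracy: its mean decrease accuracy is exactly zero."""
    df = _labelled_features(n=300, informative=True, seed=9)
    df["P_P_lag5"] = df["P_P_lag4"].to_numpy()  # duplicated useless column
    tr, val = df.iloc[:200], df.iloc[200:]
    model, _ = train(tr, n_trees=100, seed=3)
    imp = importance(model, val, seed=1, n_repeats=3)
    dup = imp[imp.feature == "P_P_lag5"].mean_decrease_accuracy_pct.iloc[0]
    assert abs(dup) < 1.5


def test_evaluate_requires_both_classes():
    df = _labelled_features(n=100, seed=10)
    tr = df.iloc[:60]
    model, _ = train(tr, n_trees=20, seed=0)
    val = df.iloc[60:].copy()
    val["minimal_response"] = True
    with pytest.raises(ValueError, match="lacks"):
        evaluate(model, val)


def test_evaluate_reports_both_variants():
    df = _labelled_features(n=300, informative=True, seed=11)
    tr, val = df.iloc[:200], df.iloc[200:]
    nonrupture = _labelled_features(n=100, informative=False, seed=12)
    nonrupture["minimal_response"] = False
    model, oob = train(tr, n_trees=100, seed=0)
    rep = evaluate(model, val, nonrupture, oob_error=oob)
    assert 0.0 <= rep.auc_ruptures_only <= 1.0
    assert 0.0 <= rep.auc_with_nonruptures <= 1.0
    assert rep.n_trees == 100 and rep.mtry == 6
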