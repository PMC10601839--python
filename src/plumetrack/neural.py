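"""Population-level analysis of hidden-state traces.

Covers: PCA dimensionality of the 64-unit population activity; regression of
hidden states onto candidate represented variables with an
exponentially-weighted-moving-average window scan; and a random-forest
classifier predicting discretized actions, with permutation feature
importance.

The EWMA window convention: a window of ``w`` steps maps to the exponential
decay ``alpha = 2 / (w + 1)`` (the "span" convention), so ``w = 1`` is the
identity smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import randint
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, train_test_split

from .behaviour import encounters, time_since_last

__all__ = [
    "ewma",
    "represented_features",
    "window_scan",
    "WindowScanResult",
    "pca_cumvar",
    "discretize_actions",
    "fit_action_classifier",
    "ClassifierReport",
    "permutation_importance",
    "DEFAULT_WINDOWS",
]

#: Candidate window grid, steps (covers the observed 6-62 step range).
DEFAULT_WINDOWS = tuple(range(2, 81, 2))

INSTANT_FEATURES = ("wx_ego", "wy_ego", "odour")
MEMORY_FEATURES = ("heading_cos", "heading_sin", "t_last",
                   "odour_ewma", "odour_enc")


def ewma(series, window_steps: int) -> np.ndarray:
    """Causal exponential smoothing with span ``window_steps``.

    ``y[0] = x[0]``, then ``y[t] = alpha x[t] + (1 - alpha) y[t-1]`` with
    ``alpha = 2 / (window_steps + 1)``.
    """
    if window_steps < 1:
        raise ValueError("window_steps must be >= 1")
    x = np.asarray(series, dtype=float)
    alpha = 2.0 / (window_steps + 1.0)
    out = np.empty_like(x)
    acc = x[0]
    out[0] = acc
    for t in range(1, x.size):
        acc = alpha * x[t] + (1.0 - alpha) * acc
        out[t] = acc
    return out


def represented_features(episodes: pd.DataFrame,
                         ewma_window: int = 8,
                         enc_window: int = 46) -> pd.DataFrame:
    """Derive the candidate represented variables for every step.

    Per episode: head direction (as cos/sin), steps since odour was last
    perceptible (T_last), the EWMA of sensed concentration and the EWMA of
    the binary encounter signal, plus the instantaneous observations.
    """
    parts = []
    for _, g in episodes.groupby("episode_id", sort=False):
        odour = g["odour"].to_numpy()
        heading = np.radians(g["heading_deg"].to_numpy())
        part = pd.DataFrame({
            "episode_id": g["episode_id"].to_numpy(),
            "step": g["step"].to_numpy(),
            "heading_cos": np.cos(heading),
            "heading_sin": np.sin(heading),
            "t_last": time_since_last(odour > 0),
            "odour_ewma": ewma(odour, ewma_window),
            "odour_enc": ewma(encounters(odour), enc_window),
            "wx_ego": g["wx_ego"].to_numpy(),
            "wy_ego": g["wy_ego"].to_numpy(),
            "odour": odour,
        })
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


@dataclass
class WindowScanResult:
    windows: np.ndarray
    r2: np.ndarray
    best_window: int
    best_r2: float


def _linear_r2(H, y):
    """In-sample R^2 of an ordinary linear map from the hidden state
    (64 predictors + intercept) to a scalar target."""
    X = np.column_stack([H, np.ones(H.shape[0])])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return np.nan
    return 1.0 - (resid ** 2).sum() / tss


def window_scan(hidden, target_signal, windows=DEFAULT_WINDOWS,
                episode_ids=None) -> WindowScanResult:
    """Scan EWMA window lengths: for each candidate window, smooth the target
    signal and regress it on the hidden state; report R^2 per window and the
    best-fitting window.

    If ``episode_ids`` is given, the EWMA is computed within episodes.
    A constant target yields nan (sentinel) R^2 values.
    """
    windows = np.asarray(list(windows), dtype=int)
    if windows.size < 2:
        raise ValueError("need at least two candidate windows")
    H = np.asarray(hidden, dtype=float)
    sig = np.asarray(target_signal, dtype=float)
    if H.shape[0] != sig.shape[0]:
        raise ValueError("hidden trace and target signal are misaligned")
    r2 = np.empty(windows.size)
    for i, w in enumerate(windows):
        if episode_ids is None:
            y = ewma(sig, int(w))
        else:
            y = np.empty_like(sig)
            for eid in pd.unique(np.asarray(episode_ids)):
                m = np.asarray(episode_ids) == eid
                y[m] = ewma(sig[m], int(w))
        r2[i] = _linear_r2(H, y)
    if np.all(np.isnan(r2)):
        return WindowScanResult(windows, r2, -1, np.nan)
    best = int(np.nanargmax(r2))
    return WindowScanResult(windows, r2, int(windows[best]),
                            float(r2[best]))


def circular_r2(hidden, angle_deg) -> float:
    """Fit quality for a circular target: the head-direction angle is encoded
    as (cos, sin) and the reported R^2 is the average over the two
    components."""
    a = np.radians(np.asarray(angle_deg, dtype=float))
    H = np.asarray(hidden, dtype=float)
    return float(np.mean([_linear_r2(H, np.cos(a)), _linear_r2(H, np.sin(a))]))


def pca_cumvar(traces) -> np.ndarray:
    """Cumulative explained-variance curve of the centred hidden-state
    covariance (eigendecomposition); nondecreasing, ends at 1."""
    H = np.asarray(traces, dtype=float)
    n, d = H.shape
    if n < d:
        raise ValueError(f"need at least {d} rows, got {n}")
    Hc = H - H.mean(0)
    cov = Hc.T @ Hc / (n - 1)
    ev = np.linalg.eigvalsh(cov)[::-1]
    ev = np.clip(ev, 0.0, None)
    return np.cumsum(ev) / ev.sum()


def discretize_actions(turn, move) -> np.ndarray:
    """Map continuous actions to 6 classes: the turn axis is split into 3
    equal-width bins over [-1, 1] (left/centre/right) and the move axis into
    2 over [0, 1] (slow/fast); class = 2 * turn_bin + move_bin."""
    turn = np.asarray(turn, dtype=float)
    move = np.asarray(move, dtype=float)
    if np.any((turn < -1) | (turn > 1)) or np.any((move < 0) | (move > 1)):
        raise ValueError("action out of range")
    turn_bin = np.minimum(((turn + 1.0) * 1.5).astype(int), 2)
    move_bin = np.minimum((move * 2.0).astype(int), 1)
    return 2 * turn_bin + move_bin


@dataclass
class ClassifierReport:
    """Action-prediction accuracies and permutation importances."""

    accuracy_full: float
    accuracy_instant: float
    accuracy_majority: float
    best_n_estimators: int
    importances: pd.DataFrame | None = None
    model: object | None = None
    feature_names: tuple = ()
    X_test: np.ndarray | None = None
    y_test: np.ndarray | None = None


def fit_action_classifier(features: pd.DataFrame, classes,
                          strata=None, test_size: float = 0.2,
                          seed: int = 0,
                          feature_names=MEMORY_FEATURES + INSTANT_FEATURES,
                          n_iter: int = 20) -> ClassifierReport:
    """Random-forest prediction of discretized actions.

    An 80/20 randomized split (stratified on the supplied strata, e.g.
    regime x outcome) feeds a 20-trial three-fold cross-validated randomized
    search over the number of estimators in [10, 50]; the best model is
    refit on the whole training set.  Reports test accuracy for the full
    feature set, for instantaneous sensory features only, and for the
    majority-class baseline.
    """
    y = np.asarray(classes)
    present = np.unique(y)
    X = features.loc[:, list(feature_names)].to_numpy(dtype=float)
    idx = np.arange(y.size)
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=None if strata is None
                              else np.asarray(strata))
    if np.unique(y[tr]).size < present.size:
        raise ValueError("a class is absent from the training set")

    def _search(cols):
        rf = RandomForestClassifier(random_state=seed)
        search = RandomizedSearchCV(
            rf, {"n_estimators": randint(10, 51)}, n_iter=n_iter, cv=3,
            random_state=seed, n_jobs=1)
        search.fit(X[np.ix_(tr, cols)], y[tr])
        model = RandomForestClassifier(
            n_estimators=search.best_params_["n_estimators"],
            random_state=seed)
        model.fit(X[np.ix_(tr, cols)], y[tr])
        acc = model.score(X[np.ix_(te, cols)], y[te])
        return model, acc, search.best_params_["n_estimators"]

    all_cols = list(range(len(feature_names)))
    inst_cols = [i for i, f in enumerate(feature_names)
                 if f in INSTANT_FEATURES]
    model, acc_full, best_n = _search(all_cols)
    _, acc_inst, _ = _search(inst_cols)
    majority = np.bincount(pd.factorize(y[tr])[0]).argmax()
    maj_label = pd.unique(y[tr])[majority]
    acc_major = float((y[te] == maj_label).mean())
    return ClassifierReport(float(acc_full), float(acc_inst), acc_major,
                            int(best_n), model=model,
                            feature_names=tuple(feature_names),
                            X_test=X[te], y_test=y[te])


def permutation_importance(model, X_test, y_test, feature_names=None,
                           n_reps: int = 30, seed: int = 0) -> pd.DataFrame:
    """Per-feature mean accuracy drop over ``n_reps`` independent
    within-column shuffles of the test set, with quartiles for box plots."""
    rng = np.random.default_rng(seed)
    base = model.score(X_test, y_test)
    rows = []
    n_feat = X_test.shape[1]
    names = feature_names if feature_names is not None else [
        f"f{i}" for i in range(n_feat)]
    for j in range(n_feat):
        drops = np.empty(n_reps)
        for r in range(n_reps):
            Xp = X_test.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[r] = base - model.score(Xp, y_test)
        rows.append({
            "feature": names[j],
            "importance_mean": float(drops.mean()),
            "importance_median": float(np.median(drops)),
            "q1": float(np.quantile(drops, 0.25)),
            "q3": float(np.quantile(drops, 0.75)),
        })
    return pd.DataFrame(rows)
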