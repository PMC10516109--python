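"""Pseudopopulation decoding and the error-trial projection analysis.

Decoding follows the standard population pipeline: assemble a
pseudopopulation across sessions by resampling trials within matched
conditions, z-score and PCA (99% variance) fit on the training set only, and
train a linear support-vector classifier to discriminate high from low value
in one context.  Standard accuracy comes from repeated 10% holdouts of the
training context; cross-condition generalization performance (CCGP) from
testing on all trials of the other context.

The error-trial projection analysis asks whether misbinding-like signals
precede suboptimal choices: decoders for "left offer higher" vs "right offer
higher" (spatial) and "first higher" vs "second higher" (temporal) are
trained only on optimal-choice trials, and the signed, toward-correct
distance from the decision boundary is compared between held-out optimal
trials and suboptimal trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .neuron_models import SessionTable

__all__ = [
    "Pseudopopulation",
    "DecoderReport",
    "build_pseudopopulation",
    "preprocess",
    "decode_value",
    "error_trial_projection",
    "error_projection_summary",
]

MIN_TRIALS = {"broad": 160, "narrow": 80}


@dataclass
class Pseudopopulation:
    """Per-condition response tensors assembled across sessions.

    ``data`` maps condition -> (n_trials, n_features) with features =
    included neurons (x time bins when sessions carry binned rates).
    """

    data: dict
    included_neurons: list  # (session_index, neuron_index) pairs
    min_trials: int
    seed: int

    @property
    def conditions(self) -> list:
        return list(self.data)


def build_pseudopopulation(
    sessions: list[SessionTable],
    conditions: list,
    split: str = "broad",
    seed: int = 0,
    condition_col: str = "condition",
    n_trials: int | None = None,
) -> Pseudopopulation:
    """Assemble a condition-aligned pseudopopulation from many sessions.

    A neuron is included iff its session has at least the split's minimum
    trial count (160 broad / 80 narrow) in *every* requested condition.  Each
    included neuron contributes ``n_trials`` independently resampled trials
    per condition (default: the split minimum), so simultaneity across
    neurons within a pseudotrial is deliberately destroyed, as in any
    across-session pseudopopulation.
    """
    if split not in MIN_TRIALS:
        raise ValueError(f"split must be one of {list(MIN_TRIALS)}")
    floor = MIN_TRIALS[split]
    if n_trials is None:
        n_trials = floor
    rng = np.random.default_rng(seed)
    cols: dict = {c: [] for c in conditions}
    included = []
    for si, sess in enumerate(sessions):
        labels = list(sess.labels[condition_col])
        idx = {c: [i for i, x in enumerate(labels) if x == c] for c in conditions}
        if min(len(v) for v in idx.values()) < floor:
            continue
        for ni in range(sess.n_neurons):
            included.append((si, ni))
            for c in conditions:
                take = rng.choice(idx[c], size=n_trials, replace=True)
                cols[c].append(sess.rates[take, ni])
    if not included:
        raise ValueError("no neurons meet the per-condition trial threshold")
    data = {c: np.column_stack(cols[c]) for c in conditions}
    return Pseudopopulation(
        data=data, included_neurons=included, min_trials=floor, seed=seed
    )


class preprocess:
    """Train-fit z-score + 99%-variance PCA transform.

    Fit on the training features only; test data are passed through the
    training means, scales, and components.  Zero-variance training features
    are dropped (with a warning).
    """

    def __init__(self, variance: float = 0.99):
        self.variance = variance

    def fit(self, train: np.ndarray) -> "preprocess":
        train = np.asarray(train, dtype=float)
        if train.size == 0:
            raise ValueError("empty training set")
        self.mean_ = train.mean(axis=0)
        sd = train.std(axis=0)
        self.keep_ = sd > 0
        if not self.keep_.all():
            warnings.warn(f"dropping {int((~self.keep_).sum())} zero-variance features")
        self.scale_ = sd[self.keep_]
        z = (train[:, self.keep_] - self.mean_[self.keep_]) / self.scale_
        k = min(z.shape)
        pca = PCA(n_components=k, svd_solver="full").fit(z)
        csum = np.cumsum(pca.explained_variance_ratio_)
        self.n_components_ = int(np.searchsorted(csum, self.variance - 1e-12) + 1)
        self.pca_ = pca
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = (X[:, self.keep_] - self.mean_[self.keep_]) / self.scale_
        return self.pca_.transform(z)[:, : self.n_components_]

    def fit_transform(self, train: np.ndarray) -> np.ndarray:
        return self.fit(train).transform(train)


@dataclass
class DecoderReport:
    standard_accuracy: float
    standard_accuracy_sd: float
    generalization_accuracy: float
    train_context: str
    test_context: str
    n_components: int
    n_repeats: int
    seed: int
    C: float | str = "auto"


def _balance(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Resample the larger class down to the smaller one."""
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    keep = np.concatenate(
        [rng.choice(np.flatnonzero(y == c), size=m, replace=False) for c in classes]
    )
    return X[keep], y[keep]


def decode_value(
    pseudo: Pseudopopulation,
    train_context: str,
    test_context: str,
    seed: int = 0,
    n_repeats: int = 10,
    holdout: float = 0.1,
    C: float | str = "auto",
) -> DecoderReport:
    """Linear-SVM value decoding with cross-condition generalization.

    Conditions are keyed ``(value_level, context)`` with value_level in
    {"low", "high"}.  Standard accuracy averages ``n_repeats`` random 10%
    holdouts within the training context; generalization accuracy is measured
    on all trials of the held-out context (never seen in training).

    ``C="auto"`` sets the soft-margin constant to ``1 / n_train``: because
    the hinge loss is summed over samples, this keeps the effective
    regularization strength independent of trial count.  With trial counts
    comparable to the feature count an unregularized margin overfits noise
    directions and its generalization stops reflecting the representational
    geometry; any float can still be passed to override.
    """
    if train_context == test_context:
        raise ValueError("train and generalization contexts must differ")
    rng = np.random.default_rng(seed)

    def _xy(context: str):
        X = np.vstack([pseudo.data[("low", context)], pseudo.data[("high", context)]])
        y = np.concatenate(
            [
                np.zeros(len(pseudo.data[("low", context)]), dtype=int),
                np.ones(len(pseudo.data[("high", context)]), dtype=int),
            ]
        )
        return X, y

    X_tr_all, y_tr_all = _xy(train_context)
    X_ge, y_ge = _xy(test_context)
    accs, gen_accs, n_comp = [], [], 0
    for r in range(n_repeats):
        Xb, yb = _balance(X_tr_all, y_tr_all, rng)
        n = len(yb)
        perm = rng.permutation(n)
        n_hold = max(int(round(holdout * n)), 2)
        test_idx, train_idx = perm[:n_hold], perm[n_hold:]
        prep = preprocess().fit(Xb[train_idx])
        C_eff = 1.0 / len(train_idx) if C == "auto" else C
        clf = LinearSVC(C=C_eff, random_state=int(rng.integers(2**31)))
        clf.fit(prep.transform(Xb[train_idx]), yb[train_idx])
        accs.append(clf.score(prep.transform(Xb[test_idx]), yb[test_idx]))
        gen_accs.append(clf.score(prep.transform(X_ge), y_ge))
        n_comp = prep.n_components_
    return DecoderReport(
        standard_accuracy=float(np.mean(accs)),
        standard_accuracy_sd=float(np.std(accs)),
        generalization_accuracy=float(np.mean(gen_accs)),
        train_context=train_context,
        test_context=test_context,
        n_components=n_comp,
        n_repeats=n_repeats,
        seed=seed,
    )


@dataclass
class ProjectionReport:
    """Per-session toward-correct boundary projections, one decoder axis."""

    axis: str  # "spatial" | "temporal"
    optimal_mean: float
    suboptimal_mean: float
    n_optimal: int
    n_suboptimal: int
    applicable: bool = True


def error_trial_projection(
    session: SessionTable,
    seed: int = 0,
    holdout: float = 0.2,
    C: float | str = "auto",
    min_neurons: int = 10,
) -> dict[str, ProjectionReport]:
    """Signed decoder projections on optimal vs suboptimal-choice trials.

    Requires label columns ``higher_side`` ("left"/"right"), ``higher_order``
    ("first"/"second") and boolean ``optimal``.  For each axis the linear SVM
    is trained only on optimal trials (minus a holdout); projections are the
    signed distances to the boundary, normalized by the weight norm and
    sign-flipped so that positive means "toward the correct classification".
    Misbound-looking activity on suboptimal trials shows up as a lower mean
    projection than on held-out optimal trials.
    """
    if session.n_neurons < min_neurons:
        raise ValueError(f"need >= {min_neurons} neurons")
    rng = np.random.default_rng(seed)
    out = {}
    for axis, col, pos_label in (
        ("spatial", "higher_side", "left"),
        ("temporal", "higher_order", "first"),
    ):
        lab = session.labels
        valid = lab[col].notna().to_numpy()
        y = (lab[col].to_numpy() == pos_label).astype(int)
        optimal = lab["optimal"].to_numpy().astype(bool)
        X = session.rates
        opt_idx = np.flatnonzero(valid & optimal)
        sub_idx = np.flatnonzero(valid & ~optimal)
        if len(sub_idx) == 0:
            out[axis] = ProjectionReport(axis, np.nan, np.nan, len(opt_idx), 0, False)
            continue
        perm = rng.permutation(opt_idx)
        n_hold = max(int(round(holdout * len(opt_idx))), 1)
        hold, train = perm[:n_hold], perm[n_hold:]
        Xb, yb = _balance(X[train], y[train], rng)
        prep = preprocess().fit(Xb)
        C_eff = 1.0 / len(yb) if C == "auto" else C
        clf = LinearSVC(C=C_eff, random_state=int(rng.integers(2**31)))
        clf.fit(prep.transform(Xb), yb)
        w_norm = np.linalg.norm(clf.coef_)

        def proj(idx: np.ndarray) -> np.ndarray:
            d = clf.decision_function(prep.transform(X[idx])) / w_norm
            sign = np.where(y[idx] == 1, 1.0, -1.0)
            return d * sign

        out[axis] = ProjectionReport(
            axis=axis,
            optimal_mean=float(proj(hold).mean()),
            suboptimal_mean=float(proj(sub_idx).mean()),
            n_optimal=len(hold),
            n_suboptimal=len(sub_idx),
        )
    return out


def error_projection_summary(
    sessions: list[SessionTable], seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Across-session paired comparison of optimal vs suboptimal projections.

    One row per axis with the mean projection difference (optimal minus
    suboptimal) and the paired one-sided t-test p-value across sessions.
    """
    rows = {"spatial": [], "temporal": []}
    for i, sess in enumerate(sessions):
        reports = error_trial_projection(sess, seed=seed + i, **kwargs)
        for axis, rep in reports.items():
            if rep.applicable:
                rows[axis].append(rep.optimal_mean - rep.suboptimal_mean)
    out = []
    for axis, diffs in rows.items():
        diffs = np.asarray(diffs)
        if len(diffs) < 2:
            out.append({"axis": axis, "n_sessions": len(diffs), "mean_diff": np.nan,
                        "t": np.nan, "p": np.nan})
            continue
        t, p_two = stats.ttest_1samp(diffs, 0.0)
        p = p_two / 2 if t > 0 else 1 - p_two / 2  # one-sided: optimal > suboptimal
        out.append(
            {
                "axis": axis,
                "n_sessions": len(diffs),
                "mean_diff": float(diffs.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(out)
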