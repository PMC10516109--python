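"""Per-neuron encoding models and selectivity statistics.

Fits three nested ordinary-least-squares models to each neuron's windowed
firing rates — noise (intercept only), linear (value + side), and interaction
(value + side + value*side) — and compares them with a stacking analysis that
weights the models to maximize leave-one-out predictive density.  Also
provides a permutation ANOVA for selectivity classification and the
fourth-power participation score used to rank neurons' contributions to a
coding subspace.

The regression design follows the recording analyses: subjective value
min-max normalized to [0, 1], offer side effects-coded -1/+1, and their
product for the interaction term.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "SessionTable",
    "RegressionFit",
    "MODEL_TERMS",
    "fit_neuron_models",
    "stack_models",
    "permutation_anova",
    "subspace_contribution",
]

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "noise": (),
    "linear": ("value", "side"),
    "interaction": ("value", "side", "value_x_side"),
}


@dataclass
class SessionTable:
    """Trial-by-neuron firing rates plus per-trial labels.

    ``rates`` is (n_rows, n_neurons); ``labels`` is a DataFrame aligned with
    the rows, carrying at minimum ``value`` (normalized to [0, 1]) and
    ``side`` (-1/+1); an ``epoch`` column selects analysis windows.  ``meta``
    is free-form sidecar metadata (ground truth for synthetic sessions).
    """

    rates: np.ndarray
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2 or len(self.labels) != self.rates.shape[0]:
            raise ValueError("rates must be 2-D and aligned with labels rows")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    def window(self, epoch: str) -> "SessionTable":
        """Rows belonging to one analysis window."""
        mask = (self.labels["epoch"] == epoch).to_numpy()
        if not mask.any():
            raise ValueError(f"no trials in epoch {epoch!r}")
        return SessionTable(
            self.rates[mask], self.labels.loc[mask].reset_index(drop=True), self.meta
        )

    def zscore(self) -> "SessionTable":
        """Per-neuron z-scored copy (zero-variance neurons left centered)."""
        mu = self.rates.mean(axis=0)
        sd = self.rates.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return SessionTable((self.rates - mu) / sd, self.labels.copy(), dict(self.meta))

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        path = Path(path)
        rate_cols = pd.DataFrame(
            self.rates, columns=[f"n{i}" for i in range(self.n_neurons)]
        )
        pd.concat([self.labels.reset_index(drop=True), rate_cols], axis=1).to_csv(
            path, index=False
        )
        if meta_path is None:
            meta_path = path.with_suffix(".json")
        Path(meta_path).write_text(json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def from_csv(cls, path: str | Path, meta_path: str | Path | None = None) -> "SessionTable":
        path = Path(path)
        df = pd.read_csv(path)
        rate_cols = [c for c in df.columns if c.startswith("n") and c[1:].isdigit()]
        meta = {}
        if meta_path is None:
            meta_path = path.with_suffix(".json")
        if Path(meta_path).exists():
            meta = json.loads(Path(meta_path).read_text())
        return cls(df[rate_cols].to_numpy(), df.drop(columns=rate_cols), meta)


@dataclass
class RegressionFit:
    """OLS fit of one model structure for every neuron (vectorized)."""

    model: str  # "noise" | "linear" | "interaction"
    beta0: np.ndarray  # (n_neurons,)
    betaValue: np.ndarray | None
    betaSpace: np.ndarray | None
    betaInteraction: np.ndarray | None
    resid_var: np.ndarray  # unbiased residual variance per neuron
    rss: np.ndarray
    n_trials: int
    n_params: int
    hat_diag: np.ndarray  # (n_trials,) leverage of the shared design
    residuals: np.ndarray  # (n_trials, n_neurons)
    _xtx_inv: np.ndarray | None = None

    def coef_se(self, term_index: int) -> np.ndarray:
        """Standard error of one coefficient (0 = intercept) per neuron."""
        return np.sqrt(self.resid_var * self._xtx_inv[term_index, term_index])


def _design(labels: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(labels))]
    value = labels["value"].to_numpy(dtype=float)
    side = labels["side"].to_numpy(dtype=float)
    for t in terms:
        if t == "value":
            cols.append(value)
        elif t == "side":
            cols.append(side)
        elif t == "value_x_side":
            cols.append(value * side)
        else:
            raise ValueError(f"unknown term {t!r}")
    return np.column_stack(cols)


def fit_neuron_models(
    session: SessionTable, window: str | None = None
) -> dict[str, RegressionFit]:
    """Fit noise, linear, and interaction models to every neuron.

    All three structures are fit by OLS on identical trials, so residual sums
    of squares are nested: RSS(interaction) <= RSS(linear) <= RSS(noise).
    """
    tbl = session.window(window) if window is not None else session
    y = tbl.rates
    n = y.shape[0]
    if n < 50:
        raise ValueError(f"need at least 50 trials in window, got {n}")
    if tbl.labels["value"].nunique() < 2:
        raise ValueError("rank-deficient design: value is constant")
    fits: dict[str, RegressionFit] = {}
    for model, terms in MODEL_TERMS.items():
        X = _design(tbl.labels, terms)
        p = X.shape[1]
        xtx = X.T @ X
        xtx_inv = np.linalg.pinv(xtx)
        beta = xtx_inv @ X.T @ y  # (p, n_neurons)
        resid = y - X @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        names = ("beta0",) + terms
        get = lambda t: beta[names.index(t)] if t in names else None
        fit = RegressionFit(
            model=model,
            beta0=beta[0],
            betaValue=get("value"),
            betaSpace=get("side"),
            betaInteraction=get("value_x_side"),
            resid_var=rss / max(n - p, 1),
            rss=rss,
            n_trials=n,
            n_params=p,
            hat_diag=hat,
            residuals=resid,
        )
        fit._xtx_inv = xtx_inv
        fits[model] = fit
    return fits


def _loo_log_densities(fit: RegressionFit) -> np.ndarray:
    """Leave-one-out log predictive density per (trial, neuron).

    For a Gaussian linear model the deleted residual is ``e_i / (1 - h_ii)``
    and the predictive variance is ``s^2 / (1 - h_ii)`` with ``s^2`` the
    within-sample residual variance — exact hat-matrix identities, no
    refitting.
    """
    h = np.clip(fit.hat_diag, 0.0, 1.0 - 1e-8)[:, None]
    e_loo = fit.residuals / (1.0 - h)
    var = np.maximum(fit.resid_var[None, :], 1e-12) / (1.0 - h)
    return norm.logpdf(e_loo, scale=np.sqrt(var))


def stack_models(fits: dict[str, RegressionFit]) -> pd.DataFrame:
    """Stacking weights over {noise, linear, interaction} per neuron.

    Finds the simplex weights maximizing the summed log of the weight-mixed
    leave-one-out predictive density.  Returns a DataFrame with one row per
    neuron and one column per model; rows sum to 1.
    """
    models = list(MODEL_TERMS)
    lpd = np.stack([_loo_log_densities(fits[m]) for m in models])  # (M, T, N)
    n_neurons = lpd.shape[2]
    out = np.zeros((n_neurons, len(models)))
    for j in range(n_neurons):
        ld = lpd[:, :, j]  # (M, T)
        # stabilize: work with densities relative to the rowwise max
        mx = ld.max(axis=0, keepdims=True)
        dens = np.exp(ld - mx)  # (M, T)

        def neg_score(z: np.ndarray) -> float:
            w = np.exp(z - z.max())
            w = w / w.sum()
            mix = w @ dens
            return -float(np.sum(np.log(np.maximum(mix, 1e-300))))

        res = minimize(neg_score, np.zeros(len(models)), method="Nelder-Mead")
        if not res.success and not np.isfinite(res.fun):
            warnings.warn("stacking optimization failed; using uniform weights")
            out[j] = 1.0 / len(models)
            continue
        w = np.exp(res.x - res.x.max())
        out[j] = w / w.sum()
    return pd.DataFrame(out, columns=models)


def _discretize_value(value: np.ndarray, n_levels: int = 7) -> np.ndarray:
    """Equally spaced value levels; merges to fewer levels if some are empty."""
    for k in range(n_levels, 1, -1):
        edges = np.linspace(value.min(), value.max(), k + 1)
        lev = np.clip(np.digitize(value, edges[1:-1]), 0, k - 1)
        if len(np.unique(lev)) == k:
            if k < n_levels:
                warnings.warn(f"empty value level; re-binned to {k} levels")
            return lev
    raise ValueError("value cannot be discretized into 2 levels")


def permutation_anova(
    session: SessionTable,
    window: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    n_levels: int = 7,
) -> pd.DataFrame:
    """Permutation ANOVA selectivity per neuron.

    Value is discretized to ``n_levels`` equally spaced levels and treated as
    categorical; effects are value, side, and their interaction.  F statistics
    compare the full model against the model with the effect's columns
    removed; the null is built by permuting firing rates, and
    ``p = (#(F_perm >= F_obs) + 1) / (n_perm + 1)`` so p is never 0.

    Returns per-neuron columns ``p_value, p_side, p_interaction, selectivity``
    with classes none / linear-selective / linear-mixed / nonlinear (an
    interaction effect trumps the linear classes).
    """
    tbl = session.window(window) if window is not None else session
    y = tbl.rates
    n = y.shape[0]
    lev = _discretize_value(tbl.labels["value"].to_numpy(dtype=float), n_levels)
    side = tbl.labels["side"].to_numpy(dtype=float)
    k = lev.max() + 1
    # deviation-coded categorical value (k-1 columns), side, interaction
    V = np.zeros((n, k - 1))
    for j in range(k - 1):
        V[:, j] = (lev == j).astype(float) - (lev == k - 1).astype(float)
    S = side[:, None]
    VS = V * S
    groups = {"value": V, "side": S, "interaction": VS}
    full = np.column_stack([np.ones(n), V, S, VS])

    def _q(X: np.ndarray) -> np.ndarray:
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10
        return q[:, keep]

    q_full = _q(full)
    p_full = q_full.shape[1]
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    results = {}
    for name, G in groups.items():
        reduced = np.column_stack(
            [np.ones(n)] + [g for gn, g in groups.items() if gn != name]
        )
        q_red = _q(reduced)
        df1 = p_full - q_red.shape[1]
        df2 = n - p_full

        # RSS via orthonormal projections
        def rss(q: np.ndarray, Y: np.ndarray) -> np.ndarray:
            proj = q.T @ Y
            return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", proj, proj)

        rss_f = rss(q_full, y)
        rss_r = rss(q_red, y)
        f_obs = ((rss_r - rss_f) / df1) / (rss_f / df2)
        count = np.zeros_like(f_obs)
        for perm in perms:
            yp = y[perm]
            rf = rss(q_full, yp)
            rr = rss(q_red, yp)
            fp = ((rr - rf) / df1) / (rf / df2)
            count += fp >= f_obs
        results[f"p_{name}"] = (count + 1.0) / (n_perm + 1.0)
    out = pd.DataFrame(results)
    alpha = 0.05
    sig_v = out["p_value"] < alpha
    sig_s = out["p_side"] < alpha
    sig_i = out["p_interaction"] < alpha
    cls = np.full(len(out), "none", dtype=object)
    cls[sig_v ^ sig_s] = "linear-selective"
    cls[sig_v & sig_s] = "linear-mixed"
    cls[sig_i] = "nonlinear"
    out["selectivity"] = cls
    return out


def subspace_contribution(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fourth-power participation share of each neuron in a subspace vector.

    ``contribution_i = w_i**4 / sum_j w_j**4`` (sums to 1).  Returns the
    contributions and the indices of the smallest set of neurons covering 95%
    cumulative contribution, in descending order of contribution.
    """
    w = np.asarray(weights, dtype=float)
    denom = np.sum(w**4)
    if denom == 0.0:
        raise ValueError("zero weight vector has no subspace contribution")
    contrib = w**4 / denom
    order = np.argsort(contrib)[::-1]
    csum = np.cumsum(contrib[order])
    top = order[: int(np.searchsorted(csum, 0.95) + 1)]
    return contrib, top
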