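"""Crossnobis distances and their linear/nonlinear decomposition.

The pipeline estimates the geometry of a recorded (or synthetic) population:

1. ``crossnobis_rdm`` — cross-validated squared Euclidean distances between
   condition means.  Fold-wise mean differences are multiplied across
   independent folds, which cancels the noise bias of the plain Euclidean
   estimator (entries can legitimately be negative).  No noise-whitening is
   applied, so this is the unwhitened member of the crossnobis family.
2. ``decompose_rdm`` — non-negative least squares split of the 2x2
   (value x side-or-time) RDM into ``dLV^2``, ``dLA^2`` and the per-condition
   conjunctive length ``m^2``.  Every pair of conditions differs by two
   orthogonal conjunctive columns, so the third design coefficient is always
   2 and the reported nonlinear distance is ``dN = sqrt(2)*m``.
3. ``estimate_noise_and_sem`` — noise s.d. along the value decoding direction
   and the standard-error distance ``epsilon`` from finite-trial centroids.
4. ``predicted_error_rates`` — plugs the estimates into the closed-form
   binding and generalization error rates, and sweeps the fixed-total-power
   linear/nonlinear tradeoff curve.
5. ``misbinding_distance_contrasts`` — the temporal / spatial /
   spatio-temporal misbinding distances over the eight order-by-value
   conditions, with trial-bootstrap uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import theory
from .neuron_models import SessionTable
from .theory import CodeParams, StimulusSpec

__all__ = [
    "RDM",
    "DecompositionResult",
    "crossnobis_rdm",
    "decompose_rdm",
    "decompose_session",
    "estimate_noise_and_sem",
    "predicted_error_rates",
    "misbinding_distance_contrasts",
]


@dataclass
class RDM:
    """Squared cross-validated distances between labelled conditions."""

    conditions: list
    distances: np.ndarray  # (C, C), symmetric, zero diagonal, may be negative
    n_folds: int = 0

    def pair(self, a, b) -> float:
        i, j = self.conditions.index(a), self.conditions.index(b)
        return float(self.distances[i, j])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.distances,
            index=[str(c) for c in self.conditions],
            columns=[str(c) for c in self.conditions],
        ).to_csv(path)


@dataclass
class DecompositionResult:
    """Linear/nonlinear split of a 2x2-condition RDM (squared units)."""

    dLV2: float
    dLA2: float
    m2: float
    sigma_hat: float | None = None
    epsilon_hat: float | None = None
    residual: float = 0.0
    bootstrap: pd.DataFrame | None = None  # columns dLV, dLA, dN per resample
    dN2: float = field(init=False)

    def __post_init__(self) -> None:
        self.dN2 = 2.0 * self.m2

    @property
    def dLV(self) -> float:
        return float(np.sqrt(self.dLV2))

    @property
    def dLA(self) -> float:
        return float(np.sqrt(self.dLA2))

    @property
    def dN(self) -> float:
        return float(np.sqrt(self.dN2))

    @property
    def subspace_correlation(self) -> float:
        return theory.subspace_correlation_from_distances(self.dLV, self.dN)

    def code_params(self) -> CodeParams:
        return CodeParams(
            dLV=self.dLV,
            dLA=self.dLA,
            dN=self.dN,
            sigma=self.sigma_hat if self.sigma_hat else 1.0,
            epsilon=self.epsilon_hat or 0.0,
        )


def _condition_indices(labels: pd.Series, conditions: list) -> dict:
    idx = {}
    items = list(labels)
    for c in conditions:
        rows = np.array([i for i, x in enumerate(items) if x == c], dtype=int)
        if len(rows) == 0:
            raise ValueError(f"empty condition cell: {c!r}")
        idx[c] = rows
    return idx


def crossnobis_rdm(
    rates: np.ndarray | SessionTable,
    condition_labels=None,
    conditions: list | None = None,
    n_folds: int = 5,
    seed: int = 0,
    condition_col: str = "condition",
) -> RDM:
    """Unbiased squared condition distances from fold-crossed mean differences.

    For conditions a, b the estimate is the average over ordered fold pairs
    (k != l) of ``(m_a^k - m_b^k) . (m_a^l - m_b^l)``.  Because the two
    factors carry independent noise, the expectation is the true squared
    distance.  Folds are stratified by condition and seeded.
    """
    if isinstance(rates, SessionTable):
        condition_labels = rates.labels[condition_col]
        rates = rates.rates
    labels = pd.Series(list(condition_labels))
    if conditions is None:
        conditions = sorted(set(labels), key=str)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    idx = _condition_indices(labels, conditions)
    means = _fold_means(rates, [idx[c] for c in conditions], n_folds, rng)
    return RDM(
        conditions=list(conditions),
        distances=_crossnobis_from_means(means),
        n_folds=n_folds,
    )


def _fold_means(
    rates: np.ndarray,
    cond_rows: list[np.ndarray],
    n_folds: int,
    rng: np.random.Generator,
    resample: bool = False,
) -> np.ndarray:
    """Fold-wise condition means, (C, F, N).

    With ``resample=True`` trials are bootstrap-resampled *within* each fold,
    keeping folds disjoint in original trials: resampling across fold
    boundaries would let duplicated trials share noise between folds and
    destroy the estimator's unbiasedness.
    """
    C = len(cond_rows)
    means = np.empty((C, n_folds, rates.shape[1]))
    for ci, rows in enumerate(cond_rows):
        folds = np.array_split(rng.permutation(rows), n_folds)
        if min(len(f) for f in folds) < 2:
            raise ValueError(f"condition #{ci} has fewer than 2 trials in some fold")
        for fi, f in enumerate(folds):
            take = rng.choice(f, size=len(f), replace=True) if resample else f
            means[ci, fi] = rates[take].mean(axis=0)
    return means


def _crossnobis_from_means(means: np.ndarray) -> np.ndarray:
    C, n_folds, _ = means.shape
    dist = np.zeros((C, C))
    offdiag = ~np.eye(n_folds, dtype=bool)
    for i in range(C):
        for j in range(i + 1, C):
            diff = means[i] - means[j]  # (F, N)
            cross = diff @ diff.T  # (F, F)
            dist[i, j] = dist[j, i] = cross[offdiag].mean()
    return dist


def _design_rows(conditions: list) -> np.ndarray:
    """6x3 design: [value differs, side differs, 2] per unordered pair.

    Conditions must be (value_level, side_level) tuples.  Any two distinct
    conditions differ by two orthogonal conjunctive columns, hence the
    constant 2 multiplying ``m^2``.
    """
    rows = []
    C = len(conditions)
    for i in range(C):
        for j in range(i + 1, C):
            vi, ai = conditions[i]
            vj, aj = conditions[j]
            rows.append([float(vi != vj), float(ai != aj), 2.0])
    return np.array(rows)


def decompose_rdm(rdm: RDM, spec: StimulusSpec | None = None) -> DecompositionResult:
    """Non-negative least squares split of a 4-condition RDM.

    Solves ``d_empirical = A [dLV^2, dLA^2, m^2]^T`` with the solution
    constrained non-negative; negative crossnobis entries enter the solver
    unclipped.
    """
    if len(rdm.conditions) != 4:
        raise ValueError("decomposition needs the 4 value x side conditions")
    A = _design_rows(rdm.conditions)
    iu = np.triu_indices(4, k=1)
    d_emp = rdm.distances[iu]
    sol, res = nnls(A, d_emp)
    return DecompositionResult(dLV2=sol[0], dLA2=sol[1], m2=sol[2], residual=float(res))


def estimate_noise_and_sem(
    rates: np.ndarray,
    condition_labels,
    train_pair: tuple | None = None,
) -> tuple[float, float]:
    """Noise s.d. and standard-error distance along the value decoding axis.

    The direction is the unit vector between the two training-condition
    centroids (low vs high value in the training context).  ``sigma_hat^2``
    pools the variance of single-trial residual projections across all
    conditions.  ``epsilon_hat`` is the standard-error *distance*: the root
    expected squared norm, across the full response space, of the estimation
    error of the two training centroids combined,
    ``epsilon^2 = sum_c sum_i var_i(c) / n_c``.  A centroid estimated from
    finitely many trials is displaced by a random vector of roughly this
    length, which degrades cross-condition generalization exactly like an
    extra nonlinear perturbation — hence it joins ``dN`` in quadrature
    downstream.
    """
    labels = pd.Series(list(condition_labels))
    conditions = sorted(set(labels), key=str)
    idx = _condition_indices(labels, conditions)
    if any(len(v) < 2 for v in idx.values()):
        raise ValueError("need at least 2 trials per condition")
    if train_pair is None:
        train_pair = (conditions[0], conditions[1])
    c0 = rates[idx[train_pair[0]]].mean(axis=0)
    c1 = rates[idx[train_pair[1]]].mean(axis=0)
    v = c1 - c0
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("degenerate training centroids: zero decoding direction")
    v = v / nv
    proj_res = []
    eps2 = 0.0
    for c in conditions:
        r = rates[idx[c]]
        centered = r - r.mean(axis=0)
        proj_res.append(centered @ v)
        if c in train_pair:
            eps2 += centered.var(axis=0, ddof=1).sum() / len(r)
    sigma2 = np.concatenate(proj_res).var(ddof=1)
    return float(np.sqrt(sigma2)), float(np.sqrt(eps2))


def decompose_session(
    rates: np.ndarray,
    condition_labels,
    n_folds: int = 5,
    n_boot: int = 200,
    seed: int = 0,
    train_pair: tuple | None = None,
) -> DecompositionResult:
    """Full decomposition with noise/SEM estimates and trial-bootstrap CIs."""
    labels = pd.Series(list(condition_labels))
    rdm = crossnobis_rdm(rates, labels, n_folds=n_folds, seed=seed)
    result = decompose_rdm(rdm)
    result.sigma_hat, result.epsilon_hat = estimate_noise_and_sem(
        rates, labels, train_pair
    )
    if n_boot:
        rng = np.random.default_rng(seed + 1)
        conditions = rdm.conditions
        idx = _condition_indices(labels, conditions)
        cond_rows = [idx[c] for c in conditions]
        rows = []
        for _ in range(n_boot):
            means = _fold_means(rates, cond_rows, n_folds, rng, resample=True)
            sub_rdm = RDM(conditions, _crossnobis_from_means(means), n_folds)
            d = decompose_rdm(sub_rdm)
            rows.append({"dLV": d.dLV, "dLA": d.dLA, "dN": d.dN})
        result.bootstrap = pd.DataFrame(rows)
    return result


def predicted_error_rates(
    decomp: DecompositionResult,
    spec: StimulusSpec | None = None,
    n_power_steps: int = 21,
) -> dict:
    """Predicted binding / generalization rates and the power-tradeoff curve.

    Plugs the decomposed distances and noise estimates into the closed forms.
    The tradeoff curve re-allocates the total of value-linear and nonlinear
    power across splits at fixed total, reporting both error rates and the
    implied subspace correlation at each split; a code with ``m^2 = 0`` is
    pinned at the chance binding rate.
    """
    if spec is None:
        spec = StimulusSpec(K=2, n=2, S=2)
    if not decomp.sigma_hat:
        raise ValueError("decomposition lacks a noise estimate (sigma_hat)")
    params = decomp.code_params()
    binding = theory.binding_error_rate(params, spec)
    generalization = theory.generalization_error_rate(params)
    # fixed-total-power sweep over the linear/nonlinear split
    value_spec = StimulusSpec(K=1, n=spec.n, S=spec.S)
    P_total = theory.linear_power_from_distance(params.dLV, value_spec) + (
        theory.nonlinear_power_from_distance(params.dN, spec)
    )
    rows = []
    for f in np.linspace(0.0, 1.0, n_power_steps):
        dLV = theory.linear_distance_from_power(f * P_total, value_spec)
        dN = theory.nonlinear_distance_from_power((1 - f) * P_total, spec)
        p = CodeParams(
            dLV=dLV,
            dLA=params.dLA,
            dN=dN,
            sigma=params.sigma,
            epsilon=params.epsilon,
        )
        rows.append(
            {
                "linear_fraction": f,
                "dLV": dLV,
                "dN": dN,
                "subspace_correlation": (
                    theory.subspace_correlation_from_distances(dLV, dN)
                    if dLV + dN > 0
                    else np.nan
                ),
                "binding_error": theory.binding_error_rate(p, spec),
                "generalization_error": theory.generalization_error_rate(p),
            }
        )
    return {
        "binding_error": binding,
        "generalization_error": generalization,
        "subspace_correlation": decomp.subspace_correlation,
        "tradeoff": pd.DataFrame(rows),
    }


# the eight order x value conditions are (value_first, value_second, order)
# with values in {"low", "high"} and order in {"LR", "RL"} (first-offer side)
_CONTRAST_PAIRS = {
    # same high side, different presentation time
    "temporal": [
        (("high", "low", "LR"), ("low", "high", "RL")),
        (("low", "high", "LR"), ("high", "low", "RL")),
    ],
    # different high side, same presentation time
    "spatial": [
        (("high", "low", "LR"), ("high", "low", "RL")),
        (("low", "high", "LR"), ("low", "high", "RL")),
    ],
    # both side and time of the high offer differ
    "spatiotemporal": [
        (("high", "low", "LR"), ("low", "high", "LR")),
        (("high", "low", "RL"), ("low", "high", "RL")),
    ],
    "low-low": [(("low", "low", "LR"), ("low", "low", "RL"))],
    "high-high": [(("high", "high", "LR"), ("high", "high", "RL"))],
}


def misbinding_distance_contrasts(
    rates: np.ndarray,
    condition_labels,
    n_folds: int = 5,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Misbinding-relevant distances over the eight order x value conditions.

    Conditions are (value_first, value_second, order) tuples.  For each
    contrast class the mean squared crossnobis distance over its condition
    pairs is reported with a trial-bootstrap CI and a one-sided bootstrap
    p-value against zero.  Pairs confusable by a temporal (same side, other
    presentation time), spatial (other side, same time), or spatio-temporal
    swap of the high offer quantify the corresponding misbinding protection;
    the low-low and high-high pairs measure the residual order signal when
    both offers share a value.
    """
    labels = pd.Series(list(condition_labels))
    conditions = sorted(set(labels), key=str)
    needed = {c for pairs in _CONTRAST_PAIRS.values() for p in pairs for c in p}
    missing = needed - set(conditions)
    if missing:
        raise ValueError(f"missing conditions: {sorted(missing, key=str)}")

    def _contrasts(r: np.ndarray, lab: pd.Series, sd: int) -> dict[str, float]:
        rdm = crossnobis_rdm(r, lab, conditions=conditions, n_folds=n_folds, seed=sd)
        return {
            name: float(np.mean([rdm.pair(a, b) for a, b in pairs]))
            for name, pairs in _CONTRAST_PAIRS.items()
        }

    obs = _contrasts(rates, labels, seed)
    rng = np.random.default_rng(seed + 1)
    idx = _condition_indices(labels, conditions)
    cond_rows = [idx[c] for c in conditions]
    boot: dict[str, list[float]] = {k: [] for k in obs}
    for _ in range(n_boot):
        means = _fold_means(rates, cond_rows, n_folds, rng, resample=True)
        rdm = RDM(conditions, _crossnobis_from_means(means), n_folds)
        bs = {
            name: float(np.mean([rdm.pair(a, b) for a, b in pairs]))
            for name, pairs in _CONTRAST_PAIRS.items()
        }
        for k, v in bs.items():
            boot[k].append(v)
    rows = []
    for name, value in obs.items():
        bvals = np.array(boot[name])
        rows.append(
            {
                "contrast": name,
                "distance2": value,
                "ci_low": float(np.percentile(bvals, 2.5)),
                "ci_high": float(np.percentile(bvals, 97.5)),
                "p_vs_zero": (int(np.sum(bvals <= 0)) + 1) / (n_boot + 1),
            }
        )
    return pd.DataFrame(rows)
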