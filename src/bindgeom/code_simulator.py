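"""Explicit linear-nonlinear population codes and empirical error rates.

Builds concrete ``N``-dimensional realizations of the codes described
analytically in :mod:`bindgeom.theory` — a linear transform ``L`` whose
columns span the lattice scaffold and a conjunctive transform ``M`` with one
orthogonal column per lattice point — then generates noisy trials, decodes
them by maximum likelihood, and measures empirical overall / misbinding /
generalization error rates for comparison with the closed forms.

Columns of ``L`` and ``M`` are orthogonalized exactly (QR), so the analytic
identities hold to machine precision rather than only in the large-``N``
random-vector limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import theory
from .theory import CodeParams, StimulusSpec, _lattice

__all__ = [
    "PopulationCode",
    "DecodedSet",
    "build_code",
    "encode_trials",
    "candidate_sets",
    "ml_decode_sets",
    "simulate_error_curves",
    "prototype_ccgp",
    "measure_binding_rate",
]

_CANDIDATE_CAP = 10**6
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PopulationCode:
    """A realized code: ``L`` (N x K) and ``M`` (N x n^K) with exact geometry."""

    L: np.ndarray
    M: np.ndarray
    spec: StimulusSpec
    params: CodeParams
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.L.shape[0]

    def stimulus_coords(self) -> np.ndarray:
        """Integer lattice coordinates of all stimuli, shape (n^K, K)."""
        return _lattice(self.spec.K, self.spec.n)

    def coords_z(self) -> np.ndarray:
        """Centered unit-spacing feature coding (lattice mean subtracted)."""
        coords = self.stimulus_coords().astype(float)
        return coords - (self.spec.n - 1) / 2.0

    def noiseless(self) -> np.ndarray:
        """Mean responses of all ``n^K`` stimuli, shape (n^K, N)."""
        return self.coords_z() @ self.L.T + self.M.T


@dataclass(frozen=True)
class DecodedSet:
    """One maximum-likelihood set decode and its outcome classification."""

    true_set: tuple[int, ...]
    decoded_set: tuple[int, ...]
    outcome: str  # "correct" | "misbinding" | "other-error"
    margin: float  # log-likelihood margin to the runner-up candidate


def build_code(
    N: int, spec: StimulusSpec, params: CodeParams, seed: int = 0
) -> PopulationCode:
    """Draw a random code with exactly orthogonal ``L`` and ``M`` columns.

    The first column of ``L`` (the value axis) is scaled to ``dLV``, the
    remaining ``K-1`` columns to ``dLA``; every column of ``M`` is scaled to
    ``m = dN/sqrt(2)`` so that the nonlinear parts of any two stimuli sit at
    distance ``dN``.
    """
    P = spec.n_stimuli
    if N < spec.K + P:
        raise ValueError(f"N={N} too small; need at least K + n^K = {spec.K + P}")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((N, spec.K + P))
    q, _ = np.linalg.qr(raw)
    scales = np.concatenate(
        [
            [params.dLV],
            np.full(spec.K - 1, params.dLA),
            np.full(P, params.m),
        ]
    )
    cols = q * scales
    return PopulationCode(
        L=cols[:, : spec.K], M=cols[:, spec.K :], spec=spec, params=params, seed=seed
    )


def _set_means(code: PopulationCode, sets: list[tuple[int, ...]]) -> np.ndarray:
    base = code.noiseless()
    return np.stack([base[list(s)].sum(axis=0) for s in sets])


def encode_trials(
    code: PopulationCode,
    sets: list[tuple[int, ...]],
    sigma: float,
    n_trials: int,
    seed: int = 0,
) -> np.ndarray:
    """Noisy responses to stimulus sets, shape (len(sets), n_trials, N).

    Each trial is the sum of the set members' noiseless encodings plus
    isotropic Gaussian noise of s.d. ``sigma`` per response dimension.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    means = _set_means(code, sets)
    noise = rng.standard_normal((len(sets), n_trials, code.n_neurons)) * sigma
    return means[:, None, :] + noise


def candidate_sets(spec: StimulusSpec) -> list[tuple[int, ...]]:
    """All multisets of ``S`` stimulus indices (responses are order-invariant sums)."""
    n_cand = 1
    P, S = spec.n_stimuli, spec.S
    for i in range(S):
        n_cand = n_cand * (P + i) // (i + 1)
    if n_cand > _CANDIDATE_CAP:
        raise ValueError(f"candidate space {n_cand} exceeds cap {_CANDIDATE_CAP}")
    return list(itertools.combinations_with_replacement(range(P), S))


def _linear_sum_key(code: PopulationCode, s: tuple[int, ...]) -> tuple:
    return tuple(code.stimulus_coords()[list(s)].sum(axis=0))


def ml_decode_sets(
    code: PopulationCode,
    responses: np.ndarray,
    true_sets: list[tuple[int, ...]],
    seed: int = 0,
) -> list[DecodedSet]:
    """Nearest-mean (Gaussian maximum-likelihood) decoding of stimulus sets.

    ``responses`` has shape (n_responses, N) with ``true_sets`` giving the
    ground-truth multiset per row.  Exact ties are broken uniformly at random
    with the given seed.  An error is classified as a *misbinding* when the
    decoded multiset differs from the truth but has the same per-feature value
    sums (a chimera, indistinguishable to the linear part of the code).
    """
    rng = np.random.default_rng(seed)
    cands = candidate_sets(code.spec)
    means = _set_means(code, cands)
    cand_keys = [_linear_sum_key(code, c) for c in cands]
    # squared distances to every candidate mean
    d2 = (
        np.einsum("ij,ij->i", responses, responses)[:, None]
        - 2.0 * responses @ means.T
        + np.einsum("ij,ij->i", means, means)[None, :]
    )
    out: list[DecodedSet] = []
    for row, truth in zip(d2, true_sets, strict=True):
        lo = row.min()
        tied = np.flatnonzero(row <= lo + _TIE_RTOL * max(lo, 1.0))
        k = int(tied[0] if len(tied) == 1 else rng.choice(tied))
        rest = np.delete(row, k)
        margin = float((rest.min() - row[k]) / 2.0) if len(rest) else np.inf
        truth_m = tuple(sorted(truth))
        dec = cands[k]
        if dec == truth_m:
            outcome = "correct"
        elif cand_keys[k] == _linear_sum_key(code, truth_m):
            outcome = "misbinding"
        else:
            outcome = "other-error"
        out.append(
            DecodedSet(true_set=truth_m, decoded_set=dec, outcome=outcome, margin=margin)
        )
    return out


def measure_binding_rate(
    code: PopulationCode,
    sigma: float,
    n_trials: int,
    seed: int = 0,
    mode: str = "preferred",
) -> tuple[float, float]:
    """Empirical misbinding frequency over uniform ordered stimulus draws.

    ``mode="preferred"`` counts trials on which some chimera of the true set
    has higher likelihood than the truth — the pairwise comparison the union
    bound sums, exactly independent of the linear geometry.  ``mode="decoded"``
    counts trials on which the maximum-likelihood decoder's final answer is a
    chimera; that frequency is slightly lower whenever overall errors are
    common, because competing wrong sets absorb would-be misbinding trials.
    Returns ``(rate, standard_error)``.
    """
    spec = code.spec
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, spec.n_stimuli, size=(n_trials, spec.S))
    sets = [tuple(d) for d in draws]
    means = code.noiseless()
    resp = np.stack([means[list(s)].sum(axis=0) for s in sets])
    resp += rng.standard_normal(resp.shape) * sigma
    if mode == "decoded":
        decoded = ml_decode_sets(code, resp, sets, seed=seed + 1)
        hits = np.array([d.outcome == "misbinding" for d in decoded], dtype=float)
    elif mode == "preferred":
        cands = candidate_sets(spec)
        cand_means = _set_means(code, cands)
        cand_keys = [_linear_sum_key(code, c) for c in cands]
        hits = np.zeros(n_trials)
        for t, s in enumerate(sets):
            truth = tuple(sorted(s))
            key = _linear_sum_key(code, truth)
            chimeras = [
                i for i, c in enumerate(cands) if c != truth and cand_keys[i] == key
            ]
            if not chimeras:
                continue
            true_mean = means[list(truth)].sum(axis=0)
            d_truth = np.sum((resp[t] - true_mean) ** 2)
            d_chim = np.sum((resp[t] - cand_means[chimeras]) ** 2, axis=1)
            hits[t] = float((d_chim < d_truth).any())
    else:
        raise ValueError("mode must be 'preferred' or 'decoded'")
    return float(hits.mean()), float(hits.std(ddof=1) / np.sqrt(n_trials))


def _measure_overall_rate(
    code: PopulationCode, sigma: float, n_trials: int, seed: int
) -> tuple[float, float]:
    spec = code.spec
    rng = np.random.default_rng(seed)
    stims = rng.integers(0, spec.n_stimuli, size=n_trials)
    means = code.noiseless()
    resp = means[stims] + rng.standard_normal((n_trials, code.n_neurons)) * sigma
    d2 = (
        np.einsum("ij,ij->i", resp, resp)[:, None]
        - 2.0 * resp @ means.T
        + np.einsum("ij,ij->i", means, means)[None, :]
    )
    err = (d2.argmin(axis=1) != stims).astype(float)
    return float(err.mean()), float(err.std(ddof=1) / np.sqrt(n_trials))


def prototype_ccgp(
    code: PopulationCode, sigma: float, n_trials: int, seed: int = 0
) -> tuple[float, float]:
    """Empirical generalization error of the nearest-centroid (prototype) decoder.

    The decoder direction is the difference of the *noiseless* class centroids
    in the training context (stimuli x11 vs x21: value varies, the bound
    variable held at its first level), with the boundary halfway between them.
    It is then evaluated on noisy trials from the held-out context (x12, x22).
    Returns ``(error_rate, standard_error)``.
    """
    spec = code.spec
    if spec.K < 2:
        raise ValueError("prototype CCGP needs K >= 2")
    coords = code.stimulus_coords()

    def _idx(v: int, a: int) -> int:
        rest = tuple(0 for _ in range(spec.K - 2))
        target = (v, a) + rest
        return int(np.flatnonzero((coords == target).all(axis=1))[0])

    means = code.noiseless()
    x11, x21 = means[_idx(0, 0)], means[_idx(1, 0)]
    v = x21 - x11
    c = np.linalg.norm(v)
    if c == 0.0:
        # fully degenerate training geometry: the decoder is a coin flip
        return 0.5, 0.5 / np.sqrt(2 * n_trials)
    v = v / c
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    errs = []
    for stim_idx, label in ((_idx(0, 1), -1), (_idx(1, 1), +1)):
        resp = means[stim_idx] + rng.standard_normal((half, code.n_neurons)) * sigma
        proj = (resp - x11) @ v - c / 2.0
        pred = np.where(proj > 0, 1, -1)
        errs.append(pred != label)
    err = np.concatenate(errs).astype(float)
    return float(err.mean()), float(err.std(ddof=1) / np.sqrt(len(err)))


def simulate_error_curves(
    spec: StimulusSpec,
    param_grid: list[CodeParams],
    n_trials: int = 10_000,
    n_neurons: int | None = None,
    seed: int = 0,
    error_types: tuple[str, ...] = ("overall", "misbinding", "generalization"),
) -> pd.DataFrame:
    """Empirical vs analytic error rates over a parameter grid.

    One row per (parameter point, error type) with columns
    ``error_type, dLV, dLA, dN, sigma, empirical, analytic, se, trials, seed``.
    """
    if n_neurons is None:
        n_neurons = max(4 * (spec.K + spec.n_stimuli), 16)
    rows = []
    for i, p in enumerate(param_grid):
        code = build_code(n_neurons, spec, p, seed=seed + 1000 * i)
        for et in error_types:
            if et == "overall":
                emp, se = _measure_overall_rate(code, p.sigma, n_trials, seed + 7 + i)
                ana = theory.overall_error_rate(p, StimulusSpec(spec.K, spec.n, 1))
            elif et == "misbinding":
                mspec = spec if spec.S >= 2 else StimulusSpec(spec.K, spec.n, 2)
                mcode = build_code(n_neurons, mspec, p, seed=seed + 1000 * i)
                emp, se = measure_binding_rate(mcode, p.sigma, n_trials, seed + 13 + i)
                ana = theory.binding_error_rate(p, mspec)
            elif et == "generalization":
                emp, se = prototype_ccgp(code, p.sigma, n_trials, seed + 29 + i)
                ana = theory.generalization_error_rate(p)
            else:
                raise ValueError(f"unknown error type {et!r}")
            rows.append(
                {
                    "error_type": et,
                    "dLV": p.dLV,
                    "dLA": p.dLA,
                    "dN": p.dN,
                    "sigma": p.sigma,
                    "empirical": emp,
                    "analytic": ana,
                    "se": se,
                    "trials": n_trials,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
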