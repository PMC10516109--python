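"""Closed-form theory of linear-nonlinear population codes.

A population code for ``K`` discrete features, each taking ``n`` values, is
modelled as the sum of a *linear* part (a rectangular lattice scaffold spanned
by one axis per feature) and a *nonlinear* part (a condition-specific
conjunctive perturbation, one orthogonal direction per lattice point).  The
geometry is summarised by a handful of distances:

``dLV``
    linear distance between adjacent stimuli differing only in value,
``dLA``
    linear distance for the bound variable (side or presentation time),
``dN``
    distance between the nonlinear parts of any two stimuli,
``sigma``
    isotropic Gaussian noise s.d. per response dimension,
``epsilon``
    standard-error distance from finite-trial centroid estimation.

From these the module derives, in closed form, the maximum-likelihood
decoding error rate of the code (union bound over nearest neighbours), the
rate of *misbinding* errors when multiple stimuli are shown at once (decoding
a chimeric set whose feature values are right but paired wrongly), and the
cross-condition generalization error of a prototype decoder.  Neighbour and
chimera counts are computed by exact lattice enumeration.

Throughout, ``Q(x)`` denotes the standard normal cumulative distribution
function, evaluated at negative arguments exactly as the formulas are
written (so every error term is an upper-tail mass).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import ndtr

__all__ = [
    "StimulusSpec",
    "CodeParams",
    "NeighborCounts",
    "CodeDistances",
    "linear_distance_from_power",
    "linear_power_from_distance",
    "nonlinear_power_from_distance",
    "nonlinear_distance_from_power",
    "neighbor_counts",
    "code_distances",
    "overall_error_rate",
    "chimeric_set_count",
    "binding_error_rate",
    "generalization_error_rate",
    "subspace_correlation_from_distances",
    "continuous_estimator_variance",
]

# enumeration guard for chimeric_set_count (combined size n^K * S)
_ENUMERATION_CAP = 20


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus lattice: ``K`` features, ``n`` values each, ``S`` shown at once."""

    K: int = 2
    n: int = 2
    S: int = 1

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.S < 1:
            raise ValueError(f"S must be >= 1, got {self.S}")

    @property
    def n_stimuli(self) -> int:
        """Number of lattice points, ``n**K``."""
        return self.n**self.K


@dataclass(frozen=True)
class CodeParams:
    """Geometric parameters of a linear-nonlinear code (response units)."""

    dLV: float = 1.0
    dLA: float = 1.0
    dN: float = 1.0
    sigma: float = 0.5
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dLV", "dLA", "dN", "sigma", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def dN_eps(self) -> float:
        """Combined nonlinear + standard-error distance sqrt(dN^2 + eps^2)."""
        return float(np.hypot(self.dN, self.epsilon))

    @property
    def m(self) -> float:
        """Length of each conjunctive column, ``dN / sqrt(2)``."""
        return self.dN / np.sqrt(2.0)


@dataclass(frozen=True)
class NeighborCounts:
    NLA: float  # mean nearest lattice neighbours (one feature off by one step)
    NLD: float  # mean nearest diagonal neighbours (two features off by one step)
    NNL: int  # nonlinear-part neighbours, always n^K - 1
    NC: float = field(init=False)
    NCplus1: float = field(init=False)

    def __post_init__(self) -> None:
        # combined-code counts equal the linear ones (the nonlinear part adds
        # the same offset to every pairwise distance)
        object.__setattr__(self, "NC", self.NLA)
        object.__setattr__(self, "NCplus1", self.NLD)


@dataclass(frozen=True)
class CodeDistances:
    """Pairwise distances of the combined code.

    For non-orthogonal linear/nonlinear parts the squared distances acquire a
    random cross term ``2*dL*dN*eta`` with ``eta ~ N(0, 1/N)``; ``cross_sd_c``
    and ``cross_sd_cplus1`` give the s.d. of that term (zero when orthogonal).
    """

    dC: float
    dCplus1: float
    dS: float
    cross_sd_c: float = 0.0
    cross_sd_cplus1: float = 0.0


def _Q(x: np.ndarray | float) -> np.ndarray | float:
    """Standard normal CDF."""
    return ndtr(x)


def linear_distance_from_power(PL: float, spec: StimulusSpec) -> float:
    """Spacing of a uniformly sampled K-dim lattice with per-axis variance budget.

    The variance (linear power) of a uniform lattice with ``n`` points spaced
    ``dL`` apart along each of ``K`` axes is ``PL = K * dL^2 * (n^2-1) / 12``;
    this inverts it.
    """
    if PL < 0:
        raise ValueError("PL must be >= 0")
    return float(np.sqrt(12.0 * PL / (spec.K * (spec.n**2 - 1))))


def linear_power_from_distance(dL: float, spec: StimulusSpec) -> float:
    """Inverse of :func:`linear_distance_from_power`."""
    return spec.K * dL**2 * (spec.n**2 - 1) / 12.0


def nonlinear_power_from_distance(dN: float, spec: StimulusSpec) -> float:
    """Variance of the nonlinear code part with pairwise distance ``dN``.

    Each stimulus carries an orthogonal conjunctive column of length
    ``m = dN/sqrt(2)``; the variance of that part over the uniformly sampled
    lattice is ``m^2 * (1 - 1/n^K)`` (the mean-offset correction matters for
    small lattices).
    """
    m2 = dN**2 / 2.0
    return m2 * (1.0 - 1.0 / spec.n_stimuli)


def nonlinear_distance_from_power(PNL: float, spec: StimulusSpec) -> float:
    """Inverse of :func:`nonlinear_power_from_distance`."""
    if PNL < 0:
        raise ValueError("PNL must be >= 0")
    m2 = PNL / (1.0 - 1.0 / spec.n_stimuli)
    return float(np.sqrt(2.0 * m2))


def _lattice(K: int, n: int) -> np.ndarray:
    """All ``n**K`` stimuli as integer coordinate rows (values ``0..n-1``)."""
    return np.array(list(itertools.product(range(n), repeat=K)), dtype=int)


@lru_cache(maxsize=None)
def _neighbor_counts_cached(K: int, n: int) -> tuple[float, float, int]:
    pts = _lattice(K, n)
    diff = np.abs(pts[:, None, :] - pts[None, :, :])  # (P, P, K)
    one_step = (diff == 1).sum(axis=2)
    moved = (diff > 0).sum(axis=2)
    # nearest: exactly one feature changed, by one step (distance dL)
    nla = ((moved == 1) & (one_step == 1)).sum(axis=1).mean()
    # nearest diagonal: exactly two features changed, each by one step (sqrt2*dL)
    nld = ((moved == 2) & (one_step == 2)).sum(axis=1).mean()
    return float(nla), float(nld), len(pts) - 1


def neighbor_counts(spec: StimulusSpec) -> NeighborCounts:
    """Mean neighbour counts of the stimulus lattice, by exact enumeration.

    ``NLA`` counts stimuli at the nearest linear distance ``dL`` (one feature
    one step off), ``NLD`` those at the nearest diagonal distance
    ``sqrt(2)*dL``, averaged over the lattice.  ``NNL = n^K - 1`` because every
    conjunctive direction is orthogonal to every other, so all other stimuli
    are equidistant in the nonlinear part.
    """
    nla, nld, nnl = _neighbor_counts_cached(spec.K, spec.n)
    return NeighborCounts(NLA=nla, NLD=nld, NNL=nnl)


def code_distances(
    params: CodeParams,
    orthogonal: bool = True,
    n_neurons: int | None = None,
    dL: float | None = None,
) -> CodeDistances:
    """Nearest and next-nearest distances of the combined code, plus ``dS``.

    ``dL`` defaults to ``params.dLV`` (symmetric lattice spacing).  With
    orthogonal linear and nonlinear parts, ``dC = sqrt(dL^2 + dN^2)`` and
    ``dCplus1 = sqrt(2*dL^2 + dN^2)``.  Without the orthogonality constraint
    the squared distances gain a zero-mean Gaussian cross term whose s.d. is
    reported (requires ``n_neurons``).

    ``dS`` is the distance between the mean response to a stimulus set and to
    a chimeric set.  The linear parts cancel exactly, leaving the four
    conjunctive columns: ``dS = |M1 + M2 - M3 - M4| = 2m = sqrt(2)*dN``.
    """
    if dL is None:
        dL = params.dLV
    dN = params.dN
    dC = float(np.hypot(dL, dN))
    dCplus1 = float(np.sqrt(2.0 * dL**2 + dN**2))
    dS = float(np.sqrt(2.0) * dN)
    if orthogonal:
        return CodeDistances(dC=dC, dCplus1=dCplus1, dS=dS)
    if n_neurons is None or n_neurons < 1:
        raise ValueError("non-orthogonal distances need n_neurons for the cross term")
    scale = 1.0 / np.sqrt(n_neurons)
    return CodeDistances(
        dC=dC,
        dCplus1=dCplus1,
        dS=dS,
        cross_sd_c=2.0 * dL * dN * scale,
        cross_sd_cplus1=np.sqrt(8.0) * dL * dN * scale,
    )


def overall_error_rate(params: CodeParams, spec: StimulusSpec) -> float:
    """Union-bound ML decoding error rate for a single stimulus.

    ``P(error) = NC * Q(-dC/(2 sigma)) + NCplus1 * Q(-dCplus1/(2 sigma))``,
    clipped to ``[0, 1 - 1/n^K]`` (the bound can exceed chance at high noise).
    Assumes a symmetric lattice spacing ``dL = dLV = dLA``.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    nc = neighbor_counts(spec)
    d = code_distances(params)
    rate = nc.NC * _Q(-d.dC / (2 * params.sigma)) + nc.NCplus1 * _Q(
        -d.dCplus1 / (2 * params.sigma)
    )
    chance = 1.0 - 1.0 / spec.n_stimuli
    return float(np.clip(rate, 0.0, chance))


@lru_cache(maxsize=None)
def _chimeric_count_cached(K: int, n: int, S: int) -> float:
    if n**K * S > _ENUMERATION_CAP:
        raise ValueError(
            f"enumeration size n^K*S = {n**K * S} exceeds cap {_ENUMERATION_CAP}"
        )
    pts = _lattice(K, n)
    idx = range(len(pts))
    # candidate sets are multisets; group them by their summed linear encoding
    sums_of: dict[tuple, list[tuple]] = {}
    for comb in itertools.combinations_with_replacement(idx, S):
        key = tuple(pts[list(comb)].sum(axis=0))
        sums_of.setdefault(key, []).append(comb)
    # average over ordered draws with replacement: weight each multiset by its
    # number of ordered arrangements
    total = 0.0
    n_draws = 0
    for draw in itertools.product(idx, repeat=S):
        mset = tuple(sorted(draw))
        key = tuple(pts[list(draw)].sum(axis=0))
        total += len(sums_of[key]) - 1  # exclude the true multiset itself
        n_draws += 1
    return total / n_draws


def chimeric_set_count(spec: StimulusSpec) -> float:
    """Mean number of chimeric stimulus sets, by exhaustive enumeration.

    A chimera of a stimulus set X is a different multiset of stimuli whose
    purely-linear mean response equals that of X (the per-feature sums of the
    set coincide), so a decoder using only the linear part cannot tell them
    apart.  Averaged over ordered stimulus draws with replacement.
    """
    if spec.S < 2:
        raise ValueError("chimeric sets require S >= 2")
    return _chimeric_count_cached(spec.K, spec.n, spec.S)


def binding_error_rate(params: CodeParams, spec: StimulusSpec) -> float:
    """Union-bound misbinding rate ``NS * Q(-dS/(2 sigma))``.

    Depends only on the nonlinear distance (through ``dS = sqrt(2)*dN``) and
    the noise, never on ``dLV`` or ``dLA``; equals the chance level ``NS/2``
    when ``dN = 0`` and decreases strictly with ``dN``.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    ns = chimeric_set_count(spec)
    dS = code_distances(params).dS
    return float(np.clip(ns * _Q(-dS / (2 * params.sigma)), 0.0, 1.0))


def generalization_error_rate(params: CodeParams) -> float:
    """Cross-condition generalization error of a prototype decoder.

    ``P(error) = Q(-(1/sigma) * dLV^2 / (2*sqrt(dLV^2 + dNeps^2)))`` where
    ``dNeps = sqrt(dN^2 + eps^2)``.  Independent of ``dLA`` (the variable
    generalized across); decreasing in ``dLV``, increasing in ``dN`` and
    ``eps``.  Fully degenerate geometry (``dLV = dN = eps = 0``) gives 0.5.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    denom = np.hypot(params.dLV, params.dN_eps)
    if denom == 0.0:
        return 0.5
    margin = 0.5 * params.dLV**2 / denom
    return float(_Q(-margin / params.sigma))


def subspace_correlation_from_distances(dLV: float, dN: float) -> float:
    """Cosine of the two context value vectors: ``rho = dLV^2/(dLV^2+dN^2)``.

    The value vector in each context is the shared linear value axis plus that
    context's pair of conjunctive columns; the conjunctive parts are mutually
    orthogonal, so only the linear part survives the inner product.
    """
    if dLV < 0 or dN < 0:
        raise ValueError("distances must be >= 0")
    denom = dLV**2 + dN**2
    if denom == 0.0:
        raise ValueError("subspace correlation undefined for dLV = dN = 0")
    return dLV**2 / denom


def continuous_estimator_variance(theta: float, sigma: float) -> float:
    """Variance of the linear read-out of two continuously encoded values.

    Two values encoded by columns at angle ``theta`` (subspace correlation
    ``cos(theta)``) are recovered by inverting the 2x2 encoding matrix
    ``A = [[1, cos(theta)], [0, sin(theta)]]``; the total estimator variance
    under isotropic noise is ``2*sigma^2 / sin(theta)^2``, diverging as the
    encodings become (anti-)parallel.
    """
    s = np.sin(theta)
    if abs(s) < 1e-12:
        raise ValueError("singular encoding: sin(theta) = 0 (A is not invertible)")
    return float(2.0 * sigma**2 / s**2)
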