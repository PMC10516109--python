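"""Value-coding subspace vectors and the bootstrap noise-ceiling test.

The value subspace for a context (a side within an offer epoch) is the
per-neuron vector of predicted firing-rate differences between the highest
and lowest normalized value at that side.  Under the interaction regression
model the intercept and pure-side terms cancel, leaving

    w_i = betaValue_i + side * betaInteraction_i      (side: left +1, right -1)

The Pearson correlation between two contexts' vectors is the subspace
correlation.  Because estimation noise deflates any correlation, observed
correlations are compared against a *noise ceiling*: the distribution of
correlations between two independent estimates of the *same* subspace,
obtained from disjoint halves of a trial bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neuron_models import SessionTable, fit_neuron_models

__all__ = [
    "CONTRASTS",
    "SubspaceVector",
    "CeilingDistribution",
    "value_subspace_vector",
    "subspace_correlation",
    "noise_ceiling_test",
    "estimate_subspace_correlation",
]

_SIDE_CODE = {"left": 1.0, "right": -1.0}

# the six task-functional comparisons: (side, epoch) vs (side, epoch)
CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "left-right-offer1": (("left", "offer1"), ("right", "offer1")),
    "left-right-offer2": (("left", "offer2"), ("right", "offer2")),
    "left1-right2": (("left", "offer1"), ("right", "offer2")),
    "right1-left2": (("right", "offer1"), ("left", "offer2")),
    "left-left": (("left", "offer1"), ("left", "offer2")),
    "right-right": (("right", "offer1"), ("right", "offer2")),
}


@dataclass(frozen=True)
class SubspaceVector:
    weights: np.ndarray
    side: str
    epoch: str


@dataclass
class CeilingDistribution:
    """Observed vs noise-ceiling subspace-correlation distributions."""

    observed: np.ndarray  # n_boot cross-context correlations
    ceiling: np.ndarray  # n_boot split-half same-context correlations
    p_vs_ceiling: float  # one-sided: observed below ceiling?
    p_vs_zero: float  # one-sided: observed above zero?
    contrast: str


def value_subspace_vector(fits, side: str, epoch: str = "offer1") -> SubspaceVector:
    """Per-neuron value direction for one side, from the interaction model."""
    fit = fits["interaction"] if isinstance(fits, dict) else fits
    if fit.betaValue is None or fit.betaInteraction is None:
        raise ValueError("value subspace needs an interaction-model fit")
    s = _SIDE_CODE[side]
    return SubspaceVector(
        weights=fit.betaValue + s * fit.betaInteraction, side=side, epoch=epoch
    )


def subspace_correlation(v1, v2) -> float:
    """Pearson correlation between two subspace weight vectors."""
    w1 = np.asarray(v1.weights if isinstance(v1, SubspaceVector) else v1, float)
    w2 = np.asarray(v2.weights if isinstance(v2, SubspaceVector) else v2, float)
    if w1.shape != w2.shape or w1.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if w1.std() == 0 or w2.std() == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float(np.corrcoef(w1, w2)[0, 1])


def _strata(labels: pd.DataFrame) -> np.ndarray:
    """Condition strata for trial resampling: side x binarized-value cells."""
    side = labels["side"].to_numpy()
    value = labels["value"].to_numpy(dtype=float)
    vhigh = value > np.median(value)
    return np.array([f"{s}_{int(v)}" for s, v in zip(side, vhigh)])


def _half_split_vectors(
    tbl_a: SessionTable,
    tbl_b: SessionTable,
    sides: tuple[str, str],
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """One iteration of the half-split scheme.

    Each window's trials are split into disjoint halves within condition
    strata, bootstrap-resampled *within* each half, and fit; returns
    ``vecs[half][side]`` weight vectors.  Estimates from different halves
    carry independent noise, which is what makes the ceiling construction
    below calibrated.
    """
    shared = tbl_a is tbl_b

    def _halves(tbl: SessionTable) -> dict[str, np.ndarray]:
        strata = _strata(tbl.labels)
        parts: dict[str, list[np.ndarray]] = {"A": [], "B": []}
        for s in np.unique(strata):
            g = rng.permutation(np.flatnonzero(strata == s))
            parts["A"].append(g[: len(g) // 2])
            parts["B"].append(g[len(g) // 2 :])
        return {k: np.concatenate(v) for k, v in parts.items()}

    def _fit_half(tbl: SessionTable, rows: np.ndarray):
        take = rng.choice(rows, size=len(rows), replace=True)
        sub = SessionTable(tbl.rates[take], tbl.labels.iloc[take].reset_index(drop=True))
        return fit_neuron_models(sub)

    vecs: dict[str, dict[str, np.ndarray]] = {"A": {}, "B": {}}
    if shared:
        halves = _halves(tbl_a)
        for h in ("A", "B"):
            fits = _fit_half(tbl_a, halves[h])
            for side in set(sides):
                vecs[h][side] = value_subspace_vector(fits, side).weights
    else:
        halves_a, halves_b = _halves(tbl_a), _halves(tbl_b)
        for h in ("A", "B"):
            fits_a = _fit_half(tbl_a, halves_a[h])
            fits_b = _fit_half(tbl_b, halves_b[h])
            vecs[h][f"{sides[0]}@a"] = value_subspace_vector(fits_a, sides[0]).weights
            vecs[h][f"{sides[1]}@b"] = value_subspace_vector(fits_b, sides[1]).weights
    return vecs


def _resolve_tables(session: SessionTable, contrast: str):
    (side_a, epoch_a), (side_b, epoch_b) = CONTRASTS[contrast]
    epochs = set(session.labels.get("epoch", pd.Series(dtype=object)))
    tbl_a = session.window(epoch_a) if epoch_a in epochs else session
    tbl_b = (
        tbl_a
        if epoch_b == epoch_a or epoch_b not in epochs
        else session.window(epoch_b)
    )
    if tbl_a is tbl_b and side_a == side_b:
        raise ValueError(f"contrast {contrast!r} compares a context with itself here")
    return tbl_a, tbl_b, side_a, side_b


def _split_draws(
    session: SessionTable, contrast: str, n_boot: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """(observed_i, ceiling_i) over half-split iterations.

    ``observed_i`` averages the two cross-context, cross-half correlations;
    ``ceiling_i`` is the geometric mean of the two same-context cross-half
    reliabilities.  Under a truly shared subspace both have the same
    attenuation in expectation, so their paired difference is centred on 0.
    """
    tbl_a, tbl_b, side_a, side_b = _resolve_tables(session, contrast)
    shared = tbl_a is tbl_b
    key_a, key_b = (side_a, side_b) if shared else (f"{side_a}@a", f"{side_b}@b")
    rng = np.random.default_rng(seed)
    observed = np.empty(n_boot)
    ceiling = np.empty(n_boot)
    for i in range(n_boot):
        v = _half_split_vectors(tbl_a, tbl_b, (side_a, side_b), rng)
        observed[i] = 0.5 * (
            subspace_correlation(v["A"][key_a], v["B"][key_b])
            + subspace_correlation(v["B"][key_a], v["A"][key_b])
        )
        rel_a = subspace_correlation(v["A"][key_a], v["B"][key_a])
        rel_b = subspace_correlation(v["A"][key_b], v["B"][key_b])
        ceiling[i] = np.sqrt(max(rel_a * rel_b, 0.0)) * np.sign(min(rel_a, rel_b, 1))
    return observed, ceiling


def _paired_p(diffs: np.ndarray, direction: str) -> float:
    """One-sided bootstrap p with the small-sample +1 correction."""
    n = len(diffs)
    k = int(np.sum(diffs >= 0)) if direction == "ge" else int(np.sum(diffs <= 0))
    return (k + 1) / (n + 1)


def noise_ceiling_test(
    session: SessionTable,
    contrast: str = "left-right-offer1",
    n_boot: int = 1000,
    seed: int = 0,
) -> CeilingDistribution:
    """Half-split comparison of a cross-context correlation to its noise ceiling.

    Each iteration splits trials into disjoint halves (within condition
    strata, bootstrap-resampled within each half) and fits the interaction
    model per half.  The observed value is the cross-context correlation
    across halves; the ceiling is the split-half reliability of each
    context's own subspace (geometric mean of the two contexts), i.e. the
    correlation expected if the two contexts shared one subspace and differed
    only by estimation noise.  ``p_vs_ceiling`` is the one-sided paired
    probability (with the +1 small-sample correction) that the observed
    correlation reaches the ceiling; ``p_vs_zero`` that it exceeds zero.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {list(CONTRASTS)}")
    observed, ceiling = _split_draws(session, contrast, n_boot, seed)
    return CeilingDistribution(
        observed=observed,
        ceiling=ceiling,
        p_vs_ceiling=_paired_p(observed - ceiling, "ge"),
        p_vs_zero=_paired_p(observed, "le"),
        contrast=contrast,
    )


def estimate_subspace_correlation(
    session: SessionTable,
    contrast: str = "left-right-offer1",
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Attenuation-corrected subspace correlation with a bootstrap CI.

    The raw correlation between estimated weight vectors is biased toward
    zero by coefficient estimation noise; the half-split reliability measures
    exactly that attenuation, so the classic disattenuation ratio

        rho_hat_i = observed_i / ceiling_i

    converges on the generative correlation.  Returns the observed and
    corrected point estimates and the 2.5/97.5 percentile interval of the
    corrected draws.
    """
    observed, ceiling = _split_draws(session, contrast, n_boot, seed)
    ok = ceiling > 0
    if not ok.any():
        raise ValueError("non-positive split-half reliability; cannot correct")
    draws = observed[ok] / ceiling[ok]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "observed": float(observed.mean()),
        "ceiling": float(ceiling.mean()),
        "corrected": float(draws.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "distribution": draws,
    }
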