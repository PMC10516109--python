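"""Subjective-value choice model for the sequential risky-choice task.

Each trial offers two gambles, defined by a win probability and a stake
(reward volume).  The agent's subjective value of an offer is

    SV(p, s) = w(p) * u(s),    u(s) = s**gamma,
    w(p) = exp(-beta * (-ln p)**alpha)     (two-parameter Prelec warp)

and choices follow a softmax on the subjective-value difference.  Four model
variants nest inside this form: both transforms objective, utility-only,
probability-only, and the full model.  Fitting is multi-start maximum
likelihood with BIC model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "TASK_STAKES",
    "VARIANTS",
    "SubjectiveValueModel",
    "ChoiceModelFit",
    "subjective_value",
    "choice_probability",
    "fit_choice_model",
    "compare_choice_models",
    "binarize_value",
]

# reward volumes (mL) for safe / medium / large offers
TASK_STAKES = (0.125, 0.165, 0.240)

VARIANTS = ("objective", "utility", "probability", "full")

# which parameters are free per variant (temperature is always free); the
# probability warp defaults to the one-parameter Prelec (beta pinned at 1),
# which is identifiable at session-scale trial counts — the two-parameter
# form trades alpha off against beta and temperature and needs far more data
def _free_params(variant: str, prelec: str) -> tuple[str, ...]:
    warp = ("prelec_alpha",) if prelec == "one" else ("prelec_alpha", "prelec_beta")
    return {
        "objective": (),
        "utility": ("utility_exponent",),
        "probability": warp,
        "full": ("utility_exponent",) + warp,
    }[variant]


@dataclass(frozen=True)
class SubjectiveValueModel:
    utility_exponent: float = 1.0
    prelec_alpha: float = 1.0
    prelec_beta: float = 1.0
    temperature: float = 1.0
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class ChoiceModelFit:
    model: SubjectiveValueModel
    log_likelihood: float
    n_params: int
    n_trials: int
    accuracy: float  # cross-validated predicted-choice accuracy
    bic: float = field(init=False)
    warning: str | None = None

    def __post_init__(self) -> None:
        self.bic = self.n_params * np.log(self.n_trials) - 2.0 * self.log_likelihood


def prelec_weight(p, alpha: float, beta: float):
    """Two-parameter Prelec probability warp, with w(0)=0 and w(1)=1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = np.exp(-beta * (-np.log(p[pos])) ** alpha)
    return out if out.ndim else float(out)


def subjective_value(p, s, model: SubjectiveValueModel):
    """SV = w(p) * u(s) for scalar or array inputs."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("stakes must be > 0")
    sv = prelec_weight(p, model.prelec_alpha, model.prelec_beta) * s**model.utility_exponent
    return float(sv) if np.ndim(sv) == 0 else sv


def choice_probability(sv1, sv2, temperature: float):
    """Softmax probability of choosing offer 1 over offer 2."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return expit(temperature * (np.asarray(sv1, float) - np.asarray(sv2, float)))


def _trials_frame(trials) -> pd.DataFrame:
    df = pd.DataFrame(trials) if not isinstance(trials, pd.DataFrame) else trials
    if "choice1" not in df.columns:
        if {"side1", "choice"} <= set(df.columns):
            df = df.assign(choice1=df["choice"] == df["side1"])
        else:
            raise ValueError("need a 'choice1' column or 'side1'+'choice' columns")
    needed = {"probability1", "probability2", "stakes1", "stakes2", "choice1"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def _nll(theta: np.ndarray, free: tuple[str, ...], df: pd.DataFrame, variant: str) -> float:
    params = dict(zip(free, theta))
    m = SubjectiveValueModel(
        utility_exponent=params.get("utility_exponent", 1.0),
        prelec_alpha=params.get("prelec_alpha", 1.0),
        prelec_beta=params.get("prelec_beta", 1.0),
        temperature=params["temperature"],
        variant=variant,
    )
    sv1 = subjective_value(df["probability1"].to_numpy(), df["stakes1"].to_numpy(), m)
    sv2 = subjective_value(df["probability2"].to_numpy(), df["stakes2"].to_numpy(), m)
    p1 = choice_probability(sv1, sv2, m.temperature)
    y = df["choice1"].to_numpy().astype(bool)
    eps = 1e-12
    return -float(
        np.sum(np.log(np.where(y, p1, 1.0 - p1) + eps))
    )


_BOUNDS = {
    "utility_exponent": (0.1, 5.0),
    "prelec_alpha": (0.1, 5.0),
    "prelec_beta": (0.1, 5.0),
    "temperature": (1e-3, 1e4),
}
_STARTS = {
    "utility_exponent": (0.7, 1.0, 1.6),
    "prelec_alpha": (0.5, 1.0, 2.0),
    "prelec_beta": (0.7, 1.0, 1.5),
    "temperature": (1.0, 10.0, 50.0),
}


def fit_choice_model(
    trials,
    variant: str = "full",
    n_starts: int = 6,
    seed: int = 0,
    cv_folds: int = 5,
    prelec: str = "one",
) -> ChoiceModelFit:
    """Multi-start maximum-likelihood fit of one model variant.

    ``prelec`` selects the one- ("one", beta pinned at 1) or two-parameter
    ("two") probability warp.  Reports the best-of-restarts log-likelihood,
    BIC, and a k-fold cross-validated predicted-choice accuracy (the fraction
    of held-out choices on the higher-fitted-SV side).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if prelec not in ("one", "two"):
        raise ValueError("prelec must be 'one' or 'two'")
    df = _trials_frame(trials)
    if len(df) < 100:
        raise ValueError("need at least 100 trials")
    warning = None
    if df["choice1"].nunique() < 2:
        warning = "non-identifiable: all choices on one side"
    free = _free_params(variant, prelec) + ("temperature",)
    rng = np.random.default_rng(seed)

    def _fit_on(data: pd.DataFrame) -> tuple[np.ndarray, float]:
        best, best_nll = None, np.inf
        starts = list(zip(*(_STARTS[name] for name in free)))
        while len(starts) < n_starts:
            starts.append(
                tuple(
                    np.exp(rng.uniform(np.log(lo), np.log(hi)))
                    for lo, hi in (_BOUNDS[name] for name in free)
                )
            )
        for x0 in starts[:n_starts]:
            res = minimize(
                _nll,
                np.array(x0),
                args=(free, data, variant),
                method="L-BFGS-B",
                bounds=[_BOUNDS[name] for name in free],
            )
            if res.fun < best_nll:
                best, best_nll = res.x, float(res.fun)
        return best, best_nll

    theta, nll = _fit_on(df)
    params = dict(zip(free, theta))
    model = SubjectiveValueModel(
        utility_exponent=params.get("utility_exponent", 1.0),
        prelec_alpha=params.get("prelec_alpha", 1.0),
        prelec_beta=params.get("prelec_beta", 1.0),
        temperature=params["temperature"],
        variant=variant,
    )

    if cv_folds < 2:  # in-sample predicted-choice accuracy, no refits
        sv1 = subjective_value(df["probability1"].to_numpy(), df["stakes1"].to_numpy(), model)
        sv2 = subjective_value(df["probability2"].to_numpy(), df["stakes2"].to_numpy(), model)
        acc = float(((sv1 > sv2) == df["choice1"].to_numpy().astype(bool)).mean())
        return ChoiceModelFit(
            model=model,
            log_likelihood=-nll,
            n_params=len(free),
            n_trials=len(df),
            accuracy=acc,
            warning=warning,
        )

    # cross-validated predicted-choice accuracy
    idx = rng.permutation(len(df))
    folds = np.array_split(idx, cv_folds)
    correct = 0
    for k in range(cv_folds):
        test = df.iloc[folds[k]]
        train = df.iloc[np.concatenate([folds[j] for j in range(cv_folds) if j != k])]
        th, _ = _fit_on(train)
        pk = dict(zip(free, th))
        mk = replace(
            model,
            utility_exponent=pk.get("utility_exponent", 1.0),
            prelec_alpha=pk.get("prelec_alpha", 1.0),
            prelec_beta=pk.get("prelec_beta", 1.0),
            temperature=pk["temperature"],
        )
        sv1 = subjective_value(test["probability1"].to_numpy(), test["stakes1"].to_numpy(), mk)
        sv2 = subjective_value(test["probability2"].to_numpy(), test["stakes2"].to_numpy(), mk)
        pred1 = sv1 > sv2
        correct += int((pred1 == test["choice1"].to_numpy().astype(bool)).sum())
    return ChoiceModelFit(
        model=model,
        log_likelihood=-nll,
        n_params=len(free),
        n_trials=len(df),
        accuracy=correct / len(df),
        warning=warning,
    )


def compare_choice_models(
    trials, seed: int = 0, prelec: str = "one"
) -> dict[str, ChoiceModelFit]:
    """Fit all four variants and return them keyed by variant (pick min BIC)."""
    return {v: fit_choice_model(trials, v, seed=seed, prelec=prelec) for v in VARIANTS}


def binarize_value(values, low_pct: float = 35.0, high_pct: float = 65.0) -> np.ndarray:
    """Session-wise value binarization, excluding the middle band.

    Values strictly below the ``low_pct`` percentile are labelled ``"low"``,
    strictly above the ``high_pct`` percentile ``"high"``, and the middle
    band (ties included) ``"excluded"``.  Percentiles use linear
    interpolation; an all-equal input is therefore entirely excluded.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 values to binarize")
    lo = np.percentile(values, low_pct)
    hi = np.percentile(values, high_pct)
    labels = np.full(len(values), "excluded", dtype=object)
    labels[values < lo] = "low"
    labels[values > hi] = "high"
    return labels
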