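"""Synthetic experiments with controlled representational geometry.

Everything the analysis pipeline consumes can be generated here from seeds:

* task trials mirroring the sequential risky-choice design (uniform win
  probabilities, a 43.75/43.75/12.5% medium/large/safe offer mix, randomized
  sides and presentation order),
* a softmax subjective-value agent realizing the behavioral model forward,
* neural sessions built from explicit linear-nonlinear codes — a shared
  linear value axis, linear side and order axes, and conjunctive
  (value x side) and (value x order) perturbations with configurable
  distances — plus isotropic Gaussian rate noise,
* an optional *planted* misbinding shift: on suboptimal-choice trials the
  late-epoch response is pushed toward the encoding of the spatially swapped
  offer set, the ground-truth analog of a spatial binding failure.

Every generator is a pure function of its seed, and the session metadata
records all ground truth needed to score recovery.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import behavior_model as bm
from . import code_simulator as cs
from .behavior_model import SubjectiveValueModel
from .neuron_models import SessionTable
from .theory import CodeParams, StimulusSpec

__all__ = [
    "TaskConfig",
    "GenerativeSession",
    "generate_task_trials",
    "simulate_agent",
    "generate_behavior",
    "generate_discrete_session",
    "generate_population_session",
    "recovery_suite",
]

# offer types: (stakes mL, probability draw); safe offers pay with certainty
OFFER_TYPES = {
    "medium": {"stakes": 0.165, "prob": "uniform"},
    "large": {"stakes": 0.240, "prob": "uniform"},
    "safe": {"stakes": 0.125, "prob": "one"},
}


@dataclass(frozen=True)
class TaskConfig:
    n_trials: int = 1000
    type_probs: tuple[float, float, float] = (0.4375, 0.4375, 0.125)  # medium/large/safe
    randomize_side: bool = True
    randomize_order: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_probs) - 1.0) > 1e-9:
            raise ValueError("offer-type probabilities must sum to 1")


# temperature set so a forward-simulated agent picks its higher-SV offer on
# roughly 82% of risky trials, the realism anchor for this task family
DEFAULT_AGENT = SubjectiveValueModel(
    utility_exponent=1.3, prelec_alpha=0.7, prelec_beta=1.0, temperature=58.0
)


def generate_task_trials(cfg: TaskConfig) -> pd.DataFrame:
    """Draw offer pairs: type -> stakes, probability ~ U(0,1), sides randomized.

    Columns: probability1/2, stakes1/2, type1/2, side1 (side of the first
    offer), safe (either offer is a safe option; such trials are excluded
    from neural analyses).
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(OFFER_TYPES)
    cols: dict[str, np.ndarray | list] = {}
    for k in (1, 2):
        types = rng.choice(names, size=cfg.n_trials, p=cfg.type_probs)
        probs = rng.uniform(0.0, 1.0, size=cfg.n_trials)
        probs[types == "safe"] = 1.0
        stakes = np.array([OFFER_TYPES[t]["stakes"] for t in types])
        cols[f"type{k}"] = types
        cols[f"probability{k}"] = probs
        cols[f"stakes{k}"] = stakes
    if cfg.randomize_side:
        side1 = np.where(rng.random(cfg.n_trials) < 0.5, "left", "right")
    else:
        side1 = np.full(cfg.n_trials, "left")
    cols["side1"] = side1
    df = pd.DataFrame(cols)
    df["safe"] = (df["type1"] == "safe") | (df["type2"] == "safe")
    return df


def simulate_agent(
    trials: pd.DataFrame, model: SubjectiveValueModel = DEFAULT_AGENT, seed: int = 0
) -> pd.DataFrame:
    """Sample softmax choices; returns trials plus sv1, sv2, choice, optimal."""
    rng = np.random.default_rng(seed)
    sv1 = bm.subjective_value(trials["probability1"].to_numpy(), trials["stakes1"].to_numpy(), model)
    sv2 = bm.subjective_value(trials["probability2"].to_numpy(), trials["stakes2"].to_numpy(), model)
    p1 = bm.choice_probability(sv1, sv2, model.temperature)
    choice1 = rng.random(len(trials)) < p1
    out = trials.copy()
    out["sv1"], out["sv2"] = sv1, sv2
    out["choice1"] = choice1
    out["choice"] = np.where(
        choice1, out["side1"], np.where(out["side1"] == "left", "right", "left")
    )
    out["optimal"] = np.where(sv1 >= sv2, choice1, ~choice1)
    return out


def generate_behavior(
    cfg: TaskConfig, model: SubjectiveValueModel = DEFAULT_AGENT, seed: int | None = None
) -> pd.DataFrame:
    """Task trials plus agent choices (seed defaults to ``cfg.seed + 1``)."""
    trials = generate_task_trials(cfg)
    return simulate_agent(trials, model, seed=cfg.seed + 1 if seed is None else seed)


def generate_discrete_session(
    n_neurons: int,
    params: CodeParams,
    n_trials_per_condition: int = 200,
    seed: int = 0,
) -> SessionTable:
    """A 4-condition (binary value x side) session from an explicit code.

    The cleanest recovery target: condition means sit exactly at the code's
    lattice points, so the decomposition ground truth is ``params`` itself.
    """
    spec = StimulusSpec(K=2, n=2, S=1)
    code = cs.build_code(n_neurons, spec, params, seed=seed)
    coords = code.stimulus_coords()
    means = code.noiseless()
    rng = np.random.default_rng(seed + 1)
    rows, labels = [], []
    side_name = {0: "left", 1: "right"}
    for si, (v, a) in enumerate(coords):
        resp = means[si] + rng.standard_normal((n_trials_per_condition, n_neurons)) * params.sigma
        rows.append(resp)
        labels.extend(
            {
                "value": float(v),
                "side": 1.0 if a == 0 else -1.0,
                "value_level": "high" if v else "low",
                "side_name": side_name[a],
                "condition": (("high" if v else "low"), side_name[a]),
                "epoch": "offer1",
            }
            for _ in range(n_trials_per_condition)
        )
    order = rng.permutation(sum(len(r) for r in rows))
    rates = np.vstack(rows)[order]
    lab = pd.DataFrame(labels).iloc[order].reset_index(drop=True)
    meta = {
        "generator": "discrete",
        "params": asdict(params),
        "rho": params.dLV**2 / (params.dLV**2 + params.dN**2)
        if params.dLV + params.dN > 0
        else None,
        "seed": seed,
    }
    return SessionTable(rates, lab, meta)


@dataclass(frozen=True)
class GenerativeSession:
    """Ground truth for one synthetic recording session."""

    task: TaskConfig = TaskConfig()
    agent: SubjectiveValueModel = DEFAULT_AGENT
    n_neurons: int = 100
    dLV: float = 1.0  # shared linear value axis
    dLA_space: float = 0.8  # linear side axis
    dN_space: float = 0.8  # value x side conjunctive distance
    dLA_time: float = 0.8  # linear presentation-order axis
    dN_time: float = 0.8  # value x order conjunctive distance
    sigma: float = 0.5  # per-neuron rate noise s.d.
    heterogeneity_sd: float = 0.0  # per-neuron multiplicative gain spread
    misbinding_shift: float = 0.0  # fraction of the spatial-swap vector planted
    value_drive: str = "continuous"  # or "binary"
    seed: int = 0

    @property
    def space_params(self) -> CodeParams:
        return CodeParams(self.dLV, self.dLA_space, self.dN_space, self.sigma)

    @property
    def time_params(self) -> CodeParams:
        return CodeParams(self.dLV, self.dLA_time, self.dN_time, self.sigma)


def _orthonormal_columns(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


def generate_population_session(gen: GenerativeSession) -> SessionTable:
    """Full synthetic session: behavior plus three-epoch neural responses.

    Rows are trial x epoch combinations (``epoch`` in offer1 / offer2 /
    late).  Each risky offer contributes a shared-axis linear value drive, a
    linear side and order drive, and conjunctive (value-level x side) and
    (value-level x order) components; the late window encodes both offers
    simultaneously.  The continuous value drive is scaled so the median-split
    level centroids sit exactly ``dLV`` apart along the value axis, keeping
    the discrete theory's ground truth well defined.
    """
    beh = generate_behavior(gen.task, gen.agent)
    risky = beh.loc[~beh["safe"]].reset_index(drop=True)
    if len(risky) < 20:
        raise ValueError("too few risky trials; increase n_trials")
    rng = np.random.default_rng(gen.seed + 100)
    N = gen.n_neurons
    if N < 11:
        raise ValueError("need at least 11 neurons for the 11 code columns")
    # orthonormal basis: value, side, order, 4 space-conj, 4 time-conj columns
    basis = _orthonormal_columns(N, 11, rng)
    L_val = basis[:, 0] * gen.dLV
    L_side = basis[:, 1] * gen.dLA_space
    L_time = basis[:, 2] * gen.dLA_time
    m_s = gen.dN_space / np.sqrt(2.0)
    m_t = gen.dN_time / np.sqrt(2.0)
    Ms = {  # (level, side) -> column
        (lev, side): basis[:, 3 + 2 * li + si] * m_s
        for li, lev in enumerate(("low", "high"))
        for si, side in enumerate(("left", "right"))
    }
    Mt = {
        (lev, order): basis[:, 7 + 2 * li + oi] * m_t
        for li, lev in enumerate(("low", "high"))
        for oi, order in enumerate(("first", "second"))
    }
    gain = 1.0 + gen.heterogeneity_sd * rng.standard_normal(N)

    sv = np.concatenate([risky["sv1"], risky["sv2"]])
    med = np.median(sv)
    hi, lo = sv[sv > med], sv[sv <= med]
    gap = hi.mean() - lo.mean()
    centered = (sv - sv.mean()) / gap  # median-split centroid gap = 1

    n_t = len(risky)
    u1, u2 = centered[:n_t], centered[n_t:]
    lev1 = np.where(risky["sv1"] > med, "high", "low")
    lev2 = np.where(risky["sv2"] > med, "high", "low")
    side1 = risky["side1"].to_numpy()
    side2 = np.where(side1 == "left", "right", "left")
    order = np.where(side1 == "left", "LR", "RL")

    def _offer(u, lev, side, when) -> np.ndarray:
        t = 0.5 if when == "first" else -0.5
        s = np.where(side == "left", 0.5, -0.5)
        enc = (
            np.outer(u, L_val)
            + np.outer(s, L_side)
            + t * L_time
            + np.stack([Ms[(l, sd)] for l, sd in zip(lev, side)])
            + np.stack([Mt[(l, when)] for l in lev])
        )
        return enc

    enc1 = _offer(u1, lev1, side1, "first")
    enc2 = _offer(u2, lev2, side2, "second")
    late = enc1 + enc2
    # planted spatial-misbinding shift on suboptimal mixed-value trials
    if gen.misbinding_shift:
        swap = np.stack(
            [
                Ms[(l1, s2)] + Ms[(l2, s1)] - Ms[(l1, s1)] - Ms[(l2, s2)]
                for l1, l2, s1, s2 in zip(lev1, lev2, side1, side2)
            ]
        )
        subopt = ~risky["optimal"].to_numpy().astype(bool)
        late = late + gen.misbinding_shift * swap * subopt[:, None]

    frames, blocks = [], []
    sv_all = np.concatenate([risky["sv1"], risky["sv2"]])
    lo_v, hi_v = sv_all.min(), sv_all.max()

    def _norm(x):
        return (x - lo_v) / (hi_v - lo_v) if hi_v > lo_v else x * 0.0

    higher_side = np.where(lev1 == lev2, None, np.where(risky["sv1"] > risky["sv2"], side1, side2))
    higher_order = np.where(
        lev1 == lev2, None, np.where(risky["sv1"] > risky["sv2"], "first", "second")
    )
    common = pd.DataFrame(
        {
            "sv1": risky["sv1"],
            "sv2": risky["sv2"],
            "side1": side1,
            "order": order,
            "choice": risky["choice"],
            "optimal": risky["optimal"].astype(bool),
            "higher_side": higher_side,
            "higher_order": higher_order,
            "condition8": [
                (str(a), str(b), str(o)) for a, b, o in zip(lev1, lev2, order)
            ],
            "trial": np.arange(n_t),
        }
    )
    for epoch, enc, val, lev, side in (
        ("offer1", enc1, risky["sv1"].to_numpy(), lev1, side1),
        ("offer2", enc2, risky["sv2"].to_numpy(), lev2, side2),
        ("late", late, None, None, None),
    ):
        lab = common.copy()
        lab["epoch"] = epoch
        if val is not None:
            lab["value"] = _norm(val)
            lab["side"] = np.where(side == "left", 1.0, -1.0)
            lab["value_level"] = lev
            lab["condition"] = [(str(l), str(s)) for l, s in zip(lev, side)]
        else:
            lab["value"] = _norm(risky["sv1"].to_numpy())
            lab["side"] = np.where(side1 == "left", 1.0, -1.0)
        frames.append(lab)
        noise = rng.standard_normal((n_t, N)) * gen.sigma
        blocks.append(enc * gain + noise)
    labels = pd.concat(frames, ignore_index=True)
    rates = np.vstack(blocks)
    meta = {
        "generator": "population",
        "session": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(gen).items()
        },
        "value_gap": float(gap),
        "n_risky_trials": int(n_t),
        "rho_space": gen.dLV**2 / (gen.dLV**2 + gen.dN_space**2),
        "rho_time": gen.dLV**2 / (gen.dLV**2 + gen.dN_time**2),
    }
    return SessionTable(rates, labels, meta)


def recovery_suite(
    n_neurons: int = 100,
    n_trials_per_condition: int = 200,
    seed: int = 0,
    params: CodeParams | None = None,
) -> pd.DataFrame:
    """Generate-analyze-compare battery; one row per check.

    Columns: check, value, target, tol, passed.  Covers subspace-correlation
    recovery, crossnobis+NNLS distance recovery, noise recovery, predicted vs
    empirical cross-condition generalization, and behavioral parameter
    recovery.  Planted-effect detection has its own heavier battery in the
    tests and acceptance script.
    """
    from . import decoding as dec
    from . import geometry_decomposition as gd
    from . import neuron_models as nm
    from . import subspace_geometry as sg
    from . import theory

    if params is None:
        params = CodeParams(dLV=1.0, dLA=0.8, dN=0.8, sigma=0.5)
    sess = generate_discrete_session(n_neurons, params, n_trials_per_condition, seed)
    rows = []

    # subspace correlation via regression vectors, attenuation-corrected
    est = sg.estimate_subspace_correlation(sess, n_boot=100, seed=seed + 1)
    rho_true = sess.meta["rho"]
    half_ci = (est["ci_high"] - est["ci_low"]) / 2
    rows.append(("subspace_rho", est["corrected"], rho_true, max(half_ci, 0.05)))

    # crossnobis + NNLS distance recovery
    decomp = gd.decompose_session(
        sess.rates, sess.labels["condition"], n_boot=0, seed=seed
    )
    for name, est, true in (
        ("dLV", decomp.dLV, params.dLV),
        ("dLA", decomp.dLA, params.dLA),
        ("dN", decomp.dN, params.dN),
    ):
        rows.append((f"recover_{name}", est, true, 0.1 * true))
    rows.append(("recover_sigma", decomp.sigma_hat, params.sigma, 0.1 * params.sigma))

    # predicted vs empirical CCGP
    pred = gd.predicted_error_rates(decomp)
    pseudo = dec.Pseudopopulation(
        data={
            c: sess.rates[[x == c for x in sess.labels["condition"]]]
            for c in set(sess.labels["condition"])
        },
        included_neurons=[(0, i) for i in range(n_neurons)],
        min_trials=n_trials_per_condition,
        seed=seed,
    )
    rep = dec.decode_value(pseudo, "left", "right", seed=seed + 3)
    rows.append(
        (
            "ccgp_pred_vs_empirical",
            pred["generalization_error"],
            1.0 - rep.generalization_accuracy,
            0.05,
        )
    )

    # behavioral parameter recovery
    beh = generate_behavior(TaskConfig(n_trials=5000, seed=seed + 11))
    fit = bm.fit_choice_model(beh.loc[~beh["safe"]], "full", seed=seed + 12)
    for name, est, true in (
        ("gamma", fit.model.utility_exponent, DEFAULT_AGENT.utility_exponent),
        ("alpha", fit.model.prelec_alpha, DEFAULT_AGENT.prelec_alpha),
        ("temperature", fit.model.temperature, DEFAULT_AGENT.temperature),
    ):
        rows.append((f"behavior_{name}", est, true, 0.1 * true))

    out = pd.DataFrame(rows, columns=["check", "value", "target", "tol"])
    out["passed"] = (out["value"] - out["target"]).abs() <= out["tol"]
    return out
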