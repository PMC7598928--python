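"""Two-scale statistical model: from per-interface cruciality bar-codes and
capsid connectivity pathways to a fitted per-knockout capsid-cruciality score.

For a knockout r and an interface of type i with cumulative bar-code
(mu_minima, mu_capsid), the probability that the knockout breaks the
interface is a logistic model

    P_i(r) = sigmoid(a_i * mu_minima + b_i * mu_capsid + c_i),

the probability of breaking a connectivity pathway p is

    C_p(r) = 1 - prod_{i in p} (1 - w_i * P_i(r)),        w_i in [0, 1],

and the capsid-scale cruciality score is H(r) = sum_p C_p(r).  The free
parameters (a_i, b_i, c_i, w_i) are fitted to a partial order of knockouts
(r_i more assembly-disruptive than r_j) with the pairwise ranking loss

    L = sum_{(r_i, r_j)} sigmoid(H(r_j) - H(r_i)),

which is minimal when every disruptive member outranks its partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import DegenerateDataError, UnknownTypeError

NEUTRAL = (1.0, 1.0)  # bar-code of a knockout absent from an interface type


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class TypeParams:
    a: float
    b: float
    c: float
    w: float

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")


@dataclass(frozen=True)
class TwoScaleParams:
    """Per-interface-type weights (a, b, c) of the logistic interface-break
    model plus the pathway weight w in [0, 1]."""

    per_type: dict  # type label -> TypeParams

    @property
    def types(self) -> list[str]:
        return sorted(self.per_type)

    def __getitem__(self, t: str) -> TypeParams:
        try:
            return self.per_type[t]
        except KeyError:
            raise UnknownTypeError(f"no parameters for interface type {t!r}") from None

    @staticmethod
    def initial(types, a: float = -1.0, b: float = -1.0, c: float = 0.0,
                w: float = 0.5) -> "TwoScaleParams":
        return TwoScaleParams({t: TypeParams(a, b, c, w) for t in sorted(types)})


@dataclass(frozen=True)
class KnockoutFeatures:
    """Cumulative (mu_minima, mu_capsid) per interface type for one knockout.
    Types the knockout does not touch carry the neutral bar-code (1, 1)."""

    knockout: str
    per_type: dict = field(default_factory=dict)

    def barcode(self, t: str) -> tuple[float, float]:
        return self.per_type.get(t, NEUTRAL)


@dataclass(frozen=True)
class TrainingPair:
    """r_more is more assembly-disruptive than r_less."""

    r_more: str
    r_less: str

    def __post_init__(self):
        if self.r_more == self.r_less:
            raise ValueError("a training pair needs two distinct knockouts")


@dataclass(frozen=True)
class MutagenesisRecord:
    virus: str
    residue: int
    label: str  # disrupt | partial | non-disrupt
    source: str = ""

    VOCAB = ("disrupt", "partial", "non-disrupt")

    def __post_init__(self):
        if self.label not in self.VOCAB:
            raise ValueError(f"label {self.label!r} not in {self.VOCAB}")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def interface_break_probability(features: KnockoutFeatures,
                                params: TwoScaleParams, t: str) -> float:
    """P_t = sigmoid(a * mu_minima + b * mu_capsid + c)."""
    p = params[t]
    mm, mc = features.barcode(t)
    return float(sigmoid(p.a * mm + p.b * mc + p.c))


def pathway_break_probability(P: dict, w: dict, pathway) -> float:
    """1 - prod over the pathway's types of (1 - w_t * P_t)."""
    q = 1.0
    for t in pathway:
        q *= 1.0 - w[t] * P[t]
    return 1.0 - q


def capsid_cruciality(features: KnockoutFeatures, params: TwoScaleParams,
                      pathways) -> float:
    """H = sum over connectivity pathways of the pathway-break probability."""
    types = {t for p in pathways for t in p}
    P = {t: interface_break_probability(features, params, t) for t in types}
    w = {t: params[t].w for t in types}
    return float(sum(pathway_break_probability(P, w, p) for p in pathways))


def ranking_loss(pairs: list[TrainingPair], H: dict) -> float:
    """Sum over ordered pairs of sigmoid(H(r_less) - H(r_more)): near 0 when
    every more-disruptive knockout scores higher with margin."""
    total = 0.0
    for pair in pairs:
        if pair.r_more not in H or pair.r_less not in H:
            raise KeyError(f"missing score for pair {pair}")
        total += float(sigmoid(H[pair.r_less] - H[pair.r_more]))
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _pathway_indices(pathways, types) -> list[np.ndarray]:
    tindex = {t: k for k, t in enumerate(types)}
    return [np.array(sorted(tindex[t] for t in p), dtype=int) for p in pathways]


def _forward(theta: np.ndarray, MU: np.ndarray, paths: list[np.ndarray]):
    """theta = [a_k, b_k, c_k, omega_k] per type; MU shape (R, K, 2).
    Returns H (R,), plus intermediates for the gradient."""
    K = MU.shape[1]
    a, b, c, om = theta[:K], theta[K:2 * K], theta[2 * K:3 * K], theta[3 * K:]
    w = sigmoid(om)
    z = a * MU[:, :, 0] + b * MU[:, :, 1] + c
    P = sigmoid(z)
    q = 1.0 - w * P  # (R, K), strictly positive since w, P < 1
    H = np.zeros(MU.shape[0])
    Qs = []
    for idx in paths:
        Qp = np.prod(q[:, idx], axis=1)
        Qs.append(Qp)
        H += 1.0 - Qp
    return H, (P, q, w, Qs)


def _gradient(gH: np.ndarray, MU: np.ndarray, paths, inter) -> np.ndarray:
    P, q, w, Qs = inter
    R, K = P.shape
    dH_dq = np.zeros((R, K))
    for idx, Qp in zip(paths, Qs):
        for k in idx:
            dH_dq[:, k] -= Qp / q[:, k]
    dq_dP = -w  # (K,)
    dq_dw = -P  # (R, K)
    dH_dP = dH_dq * dq_dP
    dH_dw = dH_dq * dq_dw
    s = P * (1.0 - P)
    ga = (gH[:, None] * dH_dP * s * MU[:, :, 0]).sum(axis=0)
    gb = (gH[:, None] * dH_dP * s * MU[:, :, 1]).sum(axis=0)
    gc = (gH[:, None] * dH_dP * s).sum(axis=0)
    gom = (gH[:, None] * dH_dw).sum(axis=0) * (w * (1.0 - w))
    return np.concatenate([ga, gb, gc, gom])


def fit(features: dict, pairs: list[TrainingPair], pathways,
        init: TwoScaleParams | None = None, n_iter: int = 5000,
        step: float = 0.05, seed: int = 0) -> TwoScaleParams:
    """Full-batch gradient descent on the pairwise ranking loss.

    ``features`` maps knockout label -> KnockoutFeatures.  The pathway weight
    w is kept inside [0, 1] by a logistic reparametrization.  Deterministic
    for a fixed init; ``seed`` is accepted for interface symmetry but the
    default optimizer is deterministic.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    types = sorted({t for p in pathways for t in p})
    if init is None:
        init = TwoScaleParams.initial(types)
    K = len(types)
    residues = sorted(features)
    ridx = {r: k for k, r in enumerate(residues)}
    MU = np.array([[features[r].barcode(t) for t in types] for r in residues])
    paths = _pathway_indices(pathways, types)
    i_more = np.array([ridx[p.r_more] for p in pairs], dtype=int)
    i_less = np.array([ridx[p.r_less] for p in pairs], dtype=int)

    def omega(wv: float) -> float:
        wv = min(max(wv, 1e-6), 1 - 1e-6)
        return float(np.log(wv / (1 - wv)))

    theta = np.concatenate([
        [init[t].a for t in types], [init[t].b for t in types],
        [init[t].c for t in types], [omega(init[t].w) for t in types],
    ])

    for _ in range(n_iter):
        H, inter = _forward(theta, MU, paths)
        s = sigmoid(H[i_less] - H[i_more])
        if not np.all(np.isfinite(s)):
            raise FloatingPointError("non-finite ranking loss during fit")
        gH = np.zeros(len(residues))
        ds = s * (1.0 - s)
        np.add.at(gH, i_less, ds)
        np.add.at(gH, i_more, -ds)
        theta = theta - step * _gradient(gH, MU, paths, inter)

    a, b, c, om = theta[:K], theta[K:2 * K], theta[2 * K:3 * K], theta[3 * K:]
    w = sigmoid(om)
    return TwoScaleParams({
        t: TypeParams(float(a[k]), float(b[k]), float(c[k]), float(w[k]))
        for k, t in enumerate(types)
    })


def scores(features: dict, params: TwoScaleParams, pathways) -> dict:
    """H(r) for every knockout in the feature table."""
    return {r: capsid_cruciality(f, params, pathways)
            for r, f in sorted(features.items())}


def first_prediction_scores(features: dict) -> dict:
    """Equal-importance mode: no fitting; a knockout's score is minus its mean
    cumulative mu_capsid over the types it touches (small bar-code = crucial =
    high score), with mean mu_minima breaking ties."""
    out = {}
    for r, f in sorted(features.items()):
        if f.per_type:
            mc = float(np.mean([v[1] for v in f.per_type.values()]))
            mm = float(np.mean([v[0] for v in f.per_type.values()]))
        else:
            mm, mc = NEUTRAL
        out[r] = (-mc, -mm)
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def ranking_concordance(H: dict, labels: dict) -> float:
    """Fraction of (disrupt, non-disrupt) pairs ranked correctly by H; ties
    count 0.5.  Partial-disrupt records are excluded."""
    dis = sorted(r for r, l in labels.items() if l == "disrupt" and r in H)
    non = sorted(r for r, l in labels.items() if l == "non-disrupt" and r in H)
    if not dis or not non:
        raise DegenerateDataError("concordance needs both classes")
    total, good = 0, 0.0
    for i in dis:
        for j in non:
            total += 1
            hi, hj = H[i], H[j]
            good += 1.0 if hi > hj else (0.5 if hi == hj else 0.0)
    return good / total


def linear_separability(points: dict, labels: dict) -> dict:
    """Feasibility of a line separating disrupt from non-disrupt bar-code
    points (mu_minima, mu_capsid), solved as a unit-margin linear program.

    Returns {"separable": bool, "margin": float | None, "trivial": bool};
    a single represented class is trivially separable and flagged.
    """
    dis = [points[r] for r, l in sorted(labels.items())
           if l == "disrupt" and r in points]
    non = [points[r] for r, l in sorted(labels.items())
           if l == "non-disrupt" and r in points]
    if len(dis) + len(non) < 2:
        raise DegenerateDataError("separability needs at least two points")
    if not dis or not non:
        return {"separable": True, "margin": None, "trivial": True}
    rows, signs = [], []
    for p in dis:
        rows.append(p)
        signs.append(1.0)
    for p in non:
        rows.append(p)
        signs.append(-1.0)
    X = np.asarray(rows, dtype=float)
    sg = np.asarray(signs)
    # variables [u+, u-, v+, v-, b+, b-] >= 0; constraint s*(u x + v y + b) >= 1
    A = np.column_stack([
        -sg * X[:, 0], sg * X[:, 0], -sg * X[:, 1], sg * X[:, 1], -sg, sg
    ])
    c = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
    res = linprog(c, A_ub=A, b_ub=-np.ones(len(sg)), bounds=[(0, None)] * 6,
                  method="highs")
    if not res.success:
        return {"separable": False, "margin": None, "trivial": False}
    u = res.x[0] - res.x[1]
    v = res.x[2] - res.x[3]
    margin = 2.0 / float(np.hypot(u, v)) if (u or v) else None
    return {"separable": True, "margin": margin, "trivial": False}


def evaluate(H: dict | None, points: dict | None, labels: dict) -> dict:
    """Joint evaluation report: ranking concordance (when scores are given)
    and 2-D bar-code linear separability (when points are given)."""
    if len(labels) < 2:
        raise DegenerateDataError("need at least two labelled items")
    report: dict = {}
    if H is not None:
        report["concordance"] = ranking_concordance(H, labels)
    if points is not None:
        report["separability"] = linear_separability(points, labels)
    return report


def make_training_pairs(labels: dict) -> list[TrainingPair]:
    """All ordered pairs implied by the label partial order: disrupt >
    partial > non-disrupt; partial records never pair with each other."""
    dis = sorted(r for r, l in labels.items() if l == "disrupt")
    par = sorted(r for r, l in labels.items() if l == "partial")
    non = sorted(r for r, l in labels.items() if l == "non-disrupt")
    pairs = [TrainingPair(i, j) for i in dis for j in non]
    pairs += [TrainingPair(i, j) for i in dis for j in par]
    pairs += [TrainingPair(i, j) for i in par for j in non]
    return pairs


def train_test_split_records(records, fraction: float = 0.4, seed: int = 0):
    """Stratified-by-virus split of mutagenesis records; the training side
    gets `fraction` (< 0.5 by default) of each virus's records."""
    rng = np.random.default_rng(seed)
    by_virus: dict[str, list] = {}
    for rec in records:
        by_virus.setdefault(rec.virus, []).append(rec)
    train, test = [], []
    for virus in sorted(by_virus):
        recs = sorted(by_virus[virus], key=lambda r: r.residue)
        n_train = int(round(fraction * len(recs)))
        idx = rng.permutation(len(recs))
        chosen = set(idx[:n_train].tolist())
        for k, rec in enumerate(recs):
            (train if k in chosen else test).append(rec)
    return train, test
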