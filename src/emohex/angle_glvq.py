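"""Angle-based Generalized Matrix Learning Vector Quantization.

A prototype classifier whose dissimilarity is the relevance-weighted angle
between a sample and a prototype,

    d(x, w) = (1 - cos_L(x, w)) / 2,
    cos_L(x, w) = x' L w / sqrt((x' L x)(w' L w)),    L = O'O,

so classification is invariant to the magnitude of a sample vector and
sensitive only to its *pattern* across features. The metric L (Lambda) is
adapted during training; its unit-trace diagonal is the per-feature
relevance profile (non-negative, sums to 1), giving the model an in-built
feature ranking.

Training minimizes the Sato-Yamada GLVQ cost

    E = sum_i mu_i,   mu_i = (dJ_i - dK_i) / (dJ_i + dK_i),

where dJ is the dissimilarity to the nearest prototype of the sample's own
class and dK to the nearest prototype of any other class, by full-batch
gradient descent on the prototypes and on O (Omega) with per-epoch
learning-rate decay. Steps are taken on per-sample-mean gradients so rates
do not scale with the sample size, and an epoch whose step would increase
the cost is rejected (rates halved), making the cost trajectory
non-increasing. Because cos_L is invariant to positive rescaling of L,
re-normalizing L to unit trace after each epoch changes nothing but the
scale on which relevances are read out.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    DegenerateVectorError,
    DivergenceError,
    SchemaError,
    ValidationError,
)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings. Defaults: one prototype per class, 300 epochs,
    prototype rate 0.05 and metric rate 0.005 each decayed x0.99/epoch."""

    prototypes_per_class: int = 1
    epochs: int = 300
    lr_prototypes: float = 0.05
    lr_omega: float = 0.005
    lr_decay: float = 0.99
    epsilon: float = 1e-12
    seed: int = 0
    tol: float = 0.0  # absolute cost-change tolerance; 0 = run all epochs

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.lr_prototypes <= 0 or self.lr_omega < 0:
            raise ValidationError("learning rates must be positive")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.prototypes_per_class < 1:
            raise ValidationError("prototypes_per_class must be >= 1")


@dataclass
class RelevanceProfile:
    """Per-feature relevance scores (unit-trace diagonal of Lambda)."""

    scores: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def as_dict(self) -> dict:
        names = self.feature_names or tuple(
            f"f{i}" for i in range(len(self.scores))
        )
        return dict(zip(names, self.scores.tolist()))


@dataclass
class AngleGMLVQModel:
    prototypes: np.ndarray  # (P, d)
    prototype_labels: np.ndarray  # (P,)
    omega: np.ndarray  # (d, d)
    classes_: np.ndarray  # sorted unique labels
    feature_names: tuple[str, ...] | None = None
    config: TrainingConfig = field(default_factory=TrainingConfig)
    cost_history: list[float] = field(default_factory=list)

    @property
    def lambda_(self) -> np.ndarray:
        """The relevance metric O'O normalized to unit trace."""
        lam = self.omega.T @ self.omega
        return lam / np.trace(lam)

    def to_json(self) -> str:
        return json.dumps(
            {
                "prototypes": self.prototypes.tolist(),
                "prototype_labels": self.prototype_labels.tolist(),
                "omega": self.omega.tolist(),
                "classes": self.classes_.tolist(),
                "feature_names": list(self.feature_names)
                if self.feature_names
                else None,
                "config": asdict(self.config),
                "cost_history": self.cost_history,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AngleGMLVQModel":
        doc = json.loads(text)
        return cls(
            prototypes=np.asarray(doc["prototypes"], float),
            prototype_labels=np.asarray(doc["prototype_labels"]),
            omega=np.asarray(doc["omega"], float),
            classes_=np.asarray(doc["classes"]),
            feature_names=tuple(doc["feature_names"])
            if doc["feature_names"]
            else None,
            config=TrainingConfig(**doc["config"]),
            cost_history=list(doc["cost_history"]),
        )


def angle_dissimilarity(
    x: np.ndarray, w: np.ndarray, lam: np.ndarray, epsilon: float = 1e-12
) -> float:
    """d(x, w) = (1 - cos_L(x, w)) / 2 in [0, 1].

    Symmetric in its arguments and invariant to positive rescaling of
    either vector (and of ``lam``).
    """
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    a = float(x @ lam @ x)
    b = float(w @ lam @ w)
    if a < epsilon or b < epsilon:
        raise DegenerateVectorError(
            "vector has (numerically) zero generalized norm under Lambda"
        )
    cos = float(x @ lam @ w) / np.sqrt(a * b)
    return (1.0 - cos) / 2.0


def _pairwise(X, W, lam, epsilon):
    """Dissimilarities of every sample to every prototype, with the
    intermediates needed by the gradients."""
    XL = X @ lam  # (n, d)
    a = np.einsum("ij,ij->i", XL, X)  # x'Lx
    WL = W @ lam
    b = np.einsum("ij,ij->i", WL, W)  # w'Lw
    if (a < epsilon).any() or (b < epsilon).any():
        raise DegenerateVectorError(
            "sample or prototype has zero generalized norm under Lambda"
        )
    S = XL @ W.T  # x'Lw
    denom = np.sqrt(np.outer(a, b))
    G = S / denom
    D = (1.0 - G) / 2.0
    return D, S, a, b, denom, XL


def _winners(D, y, proto_labels):
    """Indices and distances of the nearest correct (J) and nearest
    other-class (K) prototypes for every sample."""
    same = y[:, None] == proto_labels[None, :]
    if not same.any(axis=1).all():
        raise ValidationError("a sample's class has no prototype")
    if same.all(axis=1).any():
        raise ValidationError("a sample has no other-class prototype")
    big = np.inf
    DJ = np.where(same, D, big)
    DK = np.where(~same, D, big)
    J = DJ.argmin(axis=1)
    K = DK.argmin(axis=1)
    n = len(D)
    return J, K, D[np.arange(n), J], D[np.arange(n), K]


def glvq_cost(X, y, model: AngleGMLVQModel) -> float:
    """Sato-Yamada cost: sum over samples of (dJ - dK)/(dJ + dK)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    lam = model.omega.T @ model.omega
    eps = model.config.epsilon
    D, *_ = _pairwise(X, model.prototypes, lam, eps)
    _, _, dJ, dK = _winners(D, y, model.prototype_labels)
    return float(_mu_from_distances(dJ, dK, eps).sum())


def _mu_from_distances(dJ, dK, epsilon=1e-12):
    """mu = (dJ - dK)/(dJ + dK), each term in [-1, 1]."""
    dJ = np.asarray(dJ, float)
    dK = np.asarray(dK, float)
    T = dJ + dK
    if (T < epsilon).any():
        raise DegenerateGeometryError(
            "nearest correct and incorrect prototype distances both vanish"
        )
    return (dJ - dK) / T


def cost_gradients(X, y, prototypes, prototype_labels, omega, epsilon=1e-12):
    """Analytic gradients of the summed GLVQ cost.

    Returns ``(grad_prototypes, grad_omega, cost)``. The cost is evaluated
    with Lambda = Omega'Omega unnormalized; the cosine (hence the cost) is
    invariant to the trace normalization, so these gradients are valid for
    the normalized model too.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    W = np.asarray(prototypes, float)
    lam = omega.T @ omega
    n, d = X.shape
    D, S, a, b, denom, XL = _pairwise(X, W, lam, epsilon)
    J, K, dJ, dK = _winners(D, y, prototype_labels)
    T = dJ + dK
    if (T < epsilon).any():
        raise DegenerateGeometryError(
            "nearest correct and incorrect prototype distances both vanish"
        )
    mu = (dJ - dK) / T
    cost = float(mu.sum())
    # d mu / d dJ = 2 dK / T^2 ; d mu / d dK = -2 dJ / T^2 ; dd/dg = -1/2
    coefs = {
        "J": (J, -(2.0 * dK / T**2) / 2.0),
        "K": (K, (2.0 * dJ / T**2) / 2.0),
    }
    idx = np.arange(n)
    grad_W = np.zeros_like(W)
    u_all = np.zeros(n)  # accumulated xx' weights
    M = np.zeros((d, d))
    for _, (P_idx, c) in coefs.items():
        alpha = 1.0 / denom[idx, P_idx]
        s = S[idx, P_idx]
        e = c * alpha
        u_all += -e * s / a
        for p in range(len(W)):
            sel = P_idx == p
            if not sel.any():
                continue
            e_sel = e[sel]
            s_sel = s[sel]
            # prototype gradient
            grad_W[p] += e_sel @ XL[sel] - (e_sel * s_sel / b[p]).sum() * (
                lam @ W[p]
            )
            # Omega gradient pieces: w w' and the symmetric cross term
            v_p = -(e_sel * s_sel).sum() / b[p]
            z_p = e_sel @ X[sel]
            M += v_p * np.outer(W[p], W[p])
            M += np.outer(z_p, W[p]) + np.outer(W[p], z_p)
    M += X.T @ (u_all[:, None] * X)
    grad_omega = omega @ M
    return grad_W, grad_omega, cost


def _init_prototypes(X, y, classes, per_class, rng):
    protos, labels = [], []
    for c in classes:
        mean = X[y == c].mean(axis=0)
        for _ in range(per_class):
            protos.append(mean + rng.normal(0.0, 0.01, size=X.shape[1]))
            labels.append(c)
    return np.asarray(protos), np.asarray(labels)


def fit(
    X,
    y,
    config: TrainingConfig | None = None,
    feature_names=None,
) -> AngleGMLVQModel:
    """Train an Angle-GMLVQ model by full-batch gradient descent.

    Prototypes start at the class means plus a small seeded jitter; Omega
    starts at I/sqrt(d) (isotropic unit-trace Lambda). Deterministic given
    ``config.seed``; the final training cost never exceeds the initial one.
    """
    config = config or TrainingConfig()
    config.validate()
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-d array")
    classes = np.asarray(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValidationError("training requires at least two classes")
    for c in classes:
        if (y == c).sum() < config.prototypes_per_class:
            raise ValidationError(
                f"class {c!r} has fewer samples than prototypes_per_class"
            )
    if feature_names is not None and len(feature_names) != X.shape[1]:
        raise SchemaError("feature_names length does not match X columns")
    d = X.shape[1]
    rng = np.random.default_rng(config.seed)
    W, proto_labels = _init_prototypes(
        X, y, classes, config.prototypes_per_class, rng
    )
    omega = np.eye(d) / np.sqrt(d)
    n = len(X)
    lr_w, lr_o = config.lr_prototypes, config.lr_omega

    def cost_at(W_, omega_):
        lam = omega_.T @ omega_
        D, *_ = _pairwise(X, W_, lam, config.epsilon)
        _, _, dJ, dK = _winners(D, y, proto_labels)
        return float(_mu_from_distances(dJ, dK, config.epsilon).sum())

    cost_prev = cost_at(W, omega)
    history = [cost_prev]
    for epoch in range(config.epochs):
        gW, gO, _ = cost_gradients(
            X, y, W, proto_labels, omega, config.epsilon
        )
        W_new = W - lr_w * gW / n
        omega_new = omega - lr_o * gO / n
        # unit-trace re-normalization; the cost is invariant to this scale
        omega_new = omega_new / np.sqrt(np.trace(omega_new.T @ omega_new))
        cost_new = cost_at(W_new, omega_new)
        if not np.isfinite(cost_new):
            raise DivergenceError(f"non-finite cost at epoch {epoch}")
        if cost_new <= cost_prev + 1e-12:
            delta = cost_prev - cost_new
            W, omega = W_new, omega_new
            cost_prev = cost_new
            if config.tol > 0 and delta < config.tol:
                history.append(cost_prev)
                break
        else:
            # step overshoots: reject it and cool the rates
            lr_w *= 0.5
            lr_o *= 0.5
        history.append(cost_prev)
        lr_w *= config.lr_decay
        lr_o *= config.lr_decay
    return AngleGMLVQModel(
        prototypes=W,
        prototype_labels=proto_labels,
        omega=omega,
        classes_=classes,
        feature_names=tuple(feature_names) if feature_names is not None else None,
        config=config,
        cost_history=history,
    )


def predict(model: AngleGMLVQModel, X, feature_names=None) -> np.ndarray:
    """Label of the nearest prototype; exact ties go to the first class in
    sorted label order."""
    X = np.asarray(X, float)
    if model.feature_names is not None and feature_names is not None:
        if tuple(feature_names) != tuple(model.feature_names):
            raise SchemaError(
                "feature columns do not match the training column order"
            )
    if X.shape[1] != model.prototypes.shape[1]:
        raise SchemaError(
            f"X has {X.shape[1]} columns, model expects "
            f"{model.prototypes.shape[1]}"
        )
    lam = model.omega.T @ model.omega
    D, *_ = _pairwise(X, model.prototypes, lam, model.config.epsilon)
    out = []
    class_rank = {c: i for i, c in enumerate(model.classes_.tolist())}
    for row in D:
        dmin = row.min()
        tied = np.flatnonzero(row - dmin <= 1e-12)
        labels = {model.prototype_labels[t] for t in tied}
        out.append(min(labels, key=lambda c: class_rank[c]))
    return np.asarray(out)


def feature_relevances(model: AngleGMLVQModel) -> RelevanceProfile:
    """Diagonal of the unit-trace Lambda: non-negative, sums to 1."""
    scores = np.diag(model.lambda_).copy()
    return RelevanceProfile(scores=scores, feature_names=model.feature_names)
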