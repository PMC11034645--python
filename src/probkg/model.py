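"""Relation-specific graph embedding with weighted reconstruction.

One aggregation round per relation type (``Y_a = sum_r Ahat_r X_b W_r``), a
shared projection with ReLU and row normalization producing node embeddings
``Z_a``, and bilinear per-relation reconstruction ``Z_a G_r H_r^T Z_b^T``.
Training minimizes the evidence-weighted squared reconstruction error over
all relations plus an l2 penalty, by full-batch Adam on analytic gradients
(no autodiff framework involved; the gradients are checked against central
differences in the test suite).

Symmetric relations tie ``G_r = H_r`` (one parameter block) so their
reconstruction is symmetric by construction.

Four control variants nullify the literature evidence: ``og`` reconstructs
the binarized adjacency unweighted, ``rp`` randomizes the target
probabilities, ``rw`` randomizes the loss weights, ``rpw`` randomizes both.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .graph import ProbAdjacency, ProbKG, RelationSpec, sigmoid

__all__ = [
    "TrainConfig",
    "ModelParams",
    "TrainResult",
    "RandomizedEvidence",
    "build_aggregation_adjacency",
    "binarized_adjacency",
    "aggregate",
    "embed",
    "reconstruct",
    "loss_weight_matrix",
    "objective",
    "control_objective",
    "train",
    "predict_tda",
    "randomized_edge_probability",
    "randomized_weight_matrix",
    "sample_randomized",
    "init_params",
    "save_params",
    "load_params",
]

VARIANTS = ("full", "og", "rp", "rw", "rpw")


@dataclass
class TrainConfig:
    """Training hyperparameters.  None of these are dictated by the method
    itself; defaults are desk-scale choices tuned on validation folds."""

    d0: int = 128
    d1: int = 64
    k: int = 64
    learning_rate: float = 1e-3
    epochs: int = 1000
    l2: float = 1e-4
    seed: int = 0
    optimizer: str = "adam"
    patience: int = 50
    eval_every: int = 10
    norm_mode: str = "row"  # "row" | "frobenius"

    def __post_init__(self):
        if min(self.d0, self.d1, self.k) <= 0:
            raise ValueError("embedding dimensions must be positive")
        if self.l2 < 0:
            raise ValueError("l2 strength must be non-negative")
        if self.norm_mode not in ("row", "frobenius"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ModelParams:
    """All learnables: per-type initial embeddings ``X``, per-relation
    aggregation weights ``W``, projection pairs ``(G, H)`` (tied — the same
    ndarray object — for symmetric relations), and the shared projection
    ``W1``."""

    X: dict[str, np.ndarray]
    W: dict[str, np.ndarray]
    G: dict[str, np.ndarray]
    H: dict[str, np.ndarray]
    W1: np.ndarray
    d0: int
    d1: int
    k: int
    tied: frozenset = frozenset()

    def named(self) -> Iterator[tuple[str, np.ndarray]]:
        """Unique parameter blocks (a tied pair appears once, as ``G:r``)."""
        for t, x in self.X.items():
            yield f"X:{t}", x
        for r, w in self.W.items():
            yield f"W:{r}", w
        for r, g in self.G.items():
            yield f"G:{r}", g
        for r, h in self.H.items():
            if r not in self.tied:
                yield f"H:{r}", h
        yield "W1", self.W1

    def get(self, name: str) -> np.ndarray:
        kind, _, key = name.partition(":")
        if kind == "W1":
            return self.W1
        return {"X": self.X, "W": self.W, "G": self.G, "H": self.H}[kind][key]

    def copy(self) -> "ModelParams":
        out = copy.copy(self)
        out.X = {k: v.copy() for k, v in self.X.items()}
        out.W = {k: v.copy() for k, v in self.W.items()}
        out.G = {k: v.copy() for k, v in self.G.items()}
        out.H = {r: (out.G[r] if r in self.tied else self.H[r].copy()) for r in self.H}
        out.W1 = self.W1.copy()
        return out


def init_params(kg: ProbKG, config: TrainConfig) -> ModelParams:
    """Seeded Gaussian initialization, scale 1/sqrt(fan-in) per grid."""
    rng = np.random.default_rng(config.seed)
    d0, d1, k = config.d0, config.d1, config.k
    X = {
        t: rng.normal(0.0, 1.0 / np.sqrt(d0), size=(kg.catalog.size(t), d0))
        for t in kg.catalog.types
    }
    W = {s.name: rng.normal(0.0, 1.0 / np.sqrt(d0), size=(d0, d0)) for s in kg.specs}
    G: dict[str, np.ndarray] = {}
    H: dict[str, np.ndarray] = {}
    tied = []
    for s in kg.specs:
        G[s.name] = rng.normal(0.0, 1.0 / np.sqrt(d1), size=(d1, k))
        if s.symmetric:
            H[s.name] = G[s.name]  # same object: one parameter block
            tied.append(s.name)
        else:
            H[s.name] = rng.normal(0.0, 1.0 / np.sqrt(d1), size=(d1, k))
    W1 = rng.normal(0.0, 1.0 / np.sqrt(2 * d0), size=(2 * d0, d1))
    return ModelParams(X=X, W=W, G=G, H=H, W1=W1, d0=d0, d1=d1, k=k, tied=frozenset(tied))


# ---------------------------------------------------------------------------
# forward pieces


def binarized_adjacency(adj: ProbAdjacency) -> np.ndarray:
    """``A_r``: the probability grid itself for similarity relations, the
    indicator of positive entries otherwise."""
    if adj.spec.in_similarity_set:
        return adj.probs.copy()
    return (adj.probs > 0).astype(float)


def _normalize_rows(a: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return a / safe


def build_aggregation_adjacency(
    adj: ProbAdjacency, norm_mode: str = "row"
) -> np.ndarray:
    """``Ahat_r``: the (binarized or similarity) adjacency normalized — each
    row scaled to unit Euclidean norm by default, or the whole grid scaled by
    its Frobenius norm.  Zero rows (grids) stay zero."""
    a = binarized_adjacency(adj)
    if norm_mode == "row":
        return _normalize_rows(a)
    if norm_mode == "frobenius":
        f = np.linalg.norm(a)
        return a / f if f > 0 else a
    raise ValueError(f"unknown norm_mode {norm_mode!r}")


def aggregate(
    kg: ProbKG,
    params: ModelParams,
    ahat: Optional[dict[str, np.ndarray]] = None,
    norm_mode: str = "row",
) -> dict[str, np.ndarray]:
    """Per entity type, the summed relation-specific neighborhood aggregation
    ``Y_a = sum_{r in R^a} Ahat_r X_b W_r``.

    Both orientations of a bipartite relation contribute (``Ahat_r`` for the
    source type, its transpose for the target type); a same-type symmetric
    relation contributes once.
    """
    if ahat is None:
        ahat = {
            s.name: build_aggregation_adjacency(kg.adjacency[s.name], norm_mode)
            for s in kg.specs
        }
    Y = {t: np.zeros((kg.catalog.size(t), params.d0)) for t in kg.catalog.types}
    for s in kg.specs:
        A = ahat[s.name]
        W = params.W[s.name]
        if s.source_type == s.target_type:
            Y[s.source_type] += A @ params.X[s.source_type] @ W
        else:
            Y[s.source_type] += A @ params.X[s.target_type] @ W
            Y[s.target_type] += A.T @ params.X[s.source_type] @ W
    return Y


def embed(
    Y: np.ndarray, X: np.ndarray, W1: np.ndarray, norm_mode: str = "row"
) -> np.ndarray:
    """``Z = normalize(ReLU(concat(Y, X) @ W1))``; all-zero rows stay zero."""
    Zt = np.maximum(0.0, np.hstack([Y, X]) @ W1)
    if norm_mode == "row":
        return _normalize_rows(Zt)
    f = np.linalg.norm(Zt)
    return Zt / f if f > 0 else Zt


def reconstruct(
    Za: np.ndarray, G: np.ndarray, H: np.ndarray, Zb: np.ndarray
) -> np.ndarray:
    """Bilinear edge-score grid ``Za G H^T Zb^T``."""
    return (Za @ G) @ (Zb @ H).T


def embeddings(
    params: ModelParams, kg: ProbKG, norm_mode: str = "row"
) -> dict[str, np.ndarray]:
    """Full forward pass to per-type node embeddings."""
    Y = aggregate(kg, params, norm_mode=norm_mode)
    return {
        t: embed(Y[t], params.X[t], params.W1, norm_mode) for t in kg.catalog.types
    }


def predict_tda(
    params: ModelParams, kg: ProbKG, norm_mode: str = "row"
) -> np.ndarray:
    """Reconstructed protein-disease score grid (unclipped)."""
    Z = embeddings(params, kg, norm_mode)
    spec = kg.spec_by_name(kg.tda_name)
    return reconstruct(
        Z[spec.source_type], params.G[spec.name], params.H[spec.name], Z[spec.target_type]
    )


# ---------------------------------------------------------------------------
# loss weights and randomized controls


def loss_weight_matrix(
    C: Optional[np.ndarray],
    P: np.ndarray,
    spec: RelationSpec,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Reconstruction-error weights.

    ``M[i,j] = ((sigmoid(C+beta) - 1) / sigmoid(C+alpha)) * P[i,j] + 1`` for
    literature-set relations, all-ones otherwise.  For an observed entry whose
    probability came from the evidence rule this simplifies to
    ``sigmoid(C + beta)``.
    """
    if not spec.in_literature_set:
        return np.ones_like(P)
    if C is None:
        raise ValueError(f"relation {spec.name!r} needs co-occurrence counts")
    M = (sigmoid(C + beta) - 1.0) / sigmoid(C + alpha) * P + 1.0
    # observed-entry weights live in [sigmoid(beta), 1): clamp below 1 at float
    # saturation, mirroring the probability rule; unobserved entries stay at 1
    return np.where(P > 0, np.minimum(M, float(np.nextafter(1.0, 0.0))), M)


def randomized_edge_probability(
    spec: RelationSpec, alpha: float, rng: np.random.Generator
) -> float:
    """One cached draw of the control probability for an observed edge:
    uniform on [sigmoid(alpha), 1) for literature-set relations, 1 otherwise.
    (Similarity relations keep their similarity grids under the controls and
    never reach this scalar rule.)"""
    if spec.in_literature_set:
        return float(rng.uniform(sigmoid(alpha), 1.0))
    return 1.0


def randomized_weight_matrix(
    p_prime: np.ndarray,
    spec: RelationSpec,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Control loss weights ``M' = ((u2 - 1) / u1) * P' + 1`` with ``u2``
    drawn uniform on [sigmoid(beta), 1) and ``u1`` the cached draw already
    baked into ``P'`` (observed literature entries carry ``P' = u1``)."""
    if not spec.in_literature_set:
        return np.ones_like(p_prime)
    u2 = rng.uniform(sigmoid(beta), 1.0, size=p_prime.shape)
    u1 = np.where(p_prime > 0, p_prime, 1.0)
    return (u2 - 1.0) / u1 * p_prime + 1.0


@dataclass
class RandomizedEvidence:
    """Offline-cached randomized probability and weight grids per relation."""

    p: dict[str, np.ndarray]
    m: dict[str, np.ndarray]


def sample_randomized(kg: ProbKG, rng: np.random.Generator) -> RandomizedEvidence:
    """Draw the control grids once (cached) for every relation."""
    p: dict[str, np.ndarray] = {}
    m: dict[str, np.ndarray] = {}
    for spec in kg.specs:
        adj = kg.adjacency[spec.name]
        if spec.in_literature_set:
            u1 = rng.uniform(sigmoid(kg.alpha), 1.0, size=adj.probs.shape)
            p[spec.name] = np.where(adj.observed, u1, 0.0)
            m[spec.name] = randomized_weight_matrix(
                p[spec.name], spec, kg.alpha, kg.beta, rng
            )
        else:
            # similarity grids and binary association grids are untouched by
            # the controls (their probabilities carry no literature evidence)
            p[spec.name] = adj.probs.copy()
            m[spec.name] = np.ones_like(adj.probs)
    return RandomizedEvidence(p=p, m=m)


# ---------------------------------------------------------------------------
# objective and gradients


class _Problem:
    """Precomputed static quantities for one training run: normalized
    aggregation grids, per-relation reconstruction targets and weights (with
    masked entries at weight 0)."""

    def __init__(
        self,
        kg: ProbKG,
        config: TrainConfig,
        variant: str = "full",
        rand: Optional[RandomizedEvidence] = None,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        if variant in ("rp", "rw", "rpw") and rand is None:
            raise ValueError(f"variant {variant!r} needs RandomizedEvidence")
        self.kg = kg
        self.config = config
        self.variant = variant
        self.types = list(kg.catalog.types)
        self.specs = list(kg.specs)
        self.ahat = {
            s.name: build_aggregation_adjacency(kg.adjacency[s.name], config.norm_mode)
            for s in self.specs
        }
        self.targets: dict[str, np.ndarray] = {}
        self.weights: dict[str, np.ndarray] = {}
        for s in self.specs:
            adj = kg.adjacency[s.name]
            counts = kg.cooccurrence.get(s.name)
            C = counts.counts if counts is not None else None
            if variant == "og":
                T = binarized_adjacency(adj)
                M = np.ones_like(adj.probs)
            else:
                if variant in ("rp", "rpw"):
                    T = rand.p[s.name]
                else:
                    T = adj.probs
                if variant in ("rw", "rpw"):
                    M = rand.m[s.name]
                else:
                    M = loss_weight_matrix(C, adj.probs, s, kg.alpha, kg.beta)
            keep = ~kg.mask_of(s.name)
            self.targets[s.name] = T * keep  # masked targets are irrelevant anyway
            self.weights[s.name] = M * keep

    def forward(self, params: ModelParams) -> dict:
        kg, cfg = self.kg, self.config
        Y = aggregate(kg, params, ahat=self.ahat, norm_mode=cfg.norm_mode)
        cache: dict = {"Y": Y, "U": {}, "V": {}, "Zt": {}, "Z": {}, "norm": {}}
        for t in self.types:
            U = np.hstack([Y[t], params.X[t]])
            V = U @ params.W1
            Zt = np.maximum(0.0, V)
            cache["U"][t] = U
            cache["V"][t] = V
            cache["Zt"][t] = Zt
            if cfg.norm_mode == "row":
                n = np.linalg.norm(Zt, axis=1, keepdims=True)
                cache["norm"][t] = n
                cache["Z"][t] = Zt / np.where(n > 0, n, 1.0)
            else:
                f = np.linalg.norm(Zt)
                cache["norm"][t] = f
                cache["Z"][t] = Zt / f if f > 0 else Zt
        return cache

    def loss(self, params: ModelParams) -> float:
        return self.loss_and_grads(params, want_grads=False)[0]

    def loss_and_grads(
        self, params: ModelParams, want_grads: bool = True
    ) -> tuple[float, Optional[dict[str, np.ndarray]]]:
        cfg = self.config
        cache = self.forward(params)
        Z = cache["Z"]
        loss = 0.0
        grads: Optional[dict[str, np.ndarray]] = None
        dZ: dict[str, np.ndarray] = {}
        if want_grads:
            grads = {name: np.zeros_like(arr) for name, arr in params.named()}
            dZ = {t: np.zeros_like(Z[t]) for t in self.types}

        for s in self.specs:
            ta, tb = s.source_type, s.target_type
            G, H = params.G[s.name], params.H[s.name]
            Qa = Z[ta] @ G
            Qb = Z[tb] @ H
            R = (Qa @ Qb.T - self.targets[s.name]) * self.weights[s.name]
            loss += float(np.sum(R * R))
            if want_grads:
                E = 2.0 * R * self.weights[s.name]
                dQa = E @ Qb
                dQb = E.T @ Qa
                grads[f"G:{s.name}"] += Z[ta].T @ dQa
                h_key = f"G:{s.name}" if s.name in params.tied else f"H:{s.name}"
                grads[h_key] += Z[tb].T @ dQb
                dZ[ta] += dQa @ G.T
                dZ[tb] += dQb @ H.T

        # l2 penalty; a tied pair is one parameter block, counted once
        if cfg.l2 > 0:
            for name, arr in params.named():
                loss += cfg.l2 * float(np.sum(arr * arr))
                if want_grads:
                    grads[name] += 2.0 * cfg.l2 * arr

        if not want_grads:
            return loss, None
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss ({loss}) for variant {self.variant!r}"
            )

        # backward through projection + normalization, per type
        dY: dict[str, np.ndarray] = {}
        for t in self.types:
            Zt, V, U = cache["Zt"][t], cache["V"][t], cache["U"][t]
            if cfg.norm_mode == "row":
                n = cache["norm"][t]
                zdot = np.sum(Z[t] * dZ[t], axis=1, keepdims=True)
                dZt = (dZ[t] - Z[t] * zdot) / np.where(n > 0, n, 1.0)
                dZt[np.squeeze(n, axis=1) == 0] = 0.0
            else:
                f = cache["norm"][t]
                if f > 0:
                    dZt = dZ[t] / f - Zt * (np.sum(Zt * dZ[t]) / f**3)
                else:
                    dZt = np.zeros_like(dZ[t])
            dV = dZt * (V > 0)
            grads["W1"] += U.T @ dV
            dU = dV @ params.W1.T
            dY[t] = dU[:, : params.d0]
            grads[f"X:{t}"] += dU[:, params.d0 :]

        # backward through aggregation
        for s in self.specs:
            A = self.ahat[s.name]
            W = params.W[s.name]
            ta, tb = s.source_type, s.target_type
            if ta == tb:
                AtdY = A.T @ dY[ta]
                grads[f"W:{s.name}"] += params.X[ta].T @ AtdY
                grads[f"X:{ta}"] += AtdY @ W.T
            else:
                AtdY = A.T @ dY[ta]
                grads[f"W:{s.name}"] += params.X[tb].T @ AtdY
                grads[f"X:{tb}"] += AtdY @ W.T
                AdY = A @ dY[tb]
                grads[f"W:{s.name}"] += params.X[ta].T @ AdY
                grads[f"X:{ta}"] += AdY @ W.T

        return loss, grads


def objective(
    params: ModelParams,
    kg: ProbKG,
    config: TrainConfig,
    variant: str = "full",
    rand: Optional[RandomizedEvidence] = None,
) -> float:
    """Scalar training loss: the evidence-weighted squared reconstruction
    error summed over relations (masked entries excluded) plus the l2
    penalty."""
    loss = _Problem(kg, config, variant, rand).loss(params)
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite objective: {loss}")
    return loss


def control_objective(
    variant: str,
    params: ModelParams,
    kg: ProbKG,
    config: TrainConfig,
    rand: Optional[RandomizedEvidence] = None,
) -> float:
    """Objective of one of the ablation controls (og / rp / rw / rpw)."""
    if variant not in ("og", "rp", "rw", "rpw"):
        raise ValueError(f"unknown control variant {variant!r}")
    return objective(params, kg, config, variant=variant, rand=rand)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    params: ModelParams
    loss_history: list[float] = field(default_factory=list)
    val_history: list[tuple[int, float]] = field(default_factory=list)
    best_epoch: int = -1


class _Adam:
    def __init__(self, names: Sequence[str], params: ModelParams, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {n: np.zeros_like(params.get(n)) for n in names}
        self.v = {n: np.zeros_like(params.get(n)) for n in names}

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for n, g in grads.items():
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            mhat = self.m[n] / (1 - self.b1**self.t)
            vhat = self.v[n] / (1 - self.b2**self.t)
            params.get(n)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, names, params, lr):
        self.lr = lr

    def step(self, params, grads):
        for n, g in grads.items():
            params.get(n)[...] -= self.lr * g


def train(
    kg: ProbKG,
    config: TrainConfig,
    variant: str = "full",
    rand: Optional[RandomizedEvidence] = None,
    val_entries: Optional[np.ndarray] = None,
    val_labels: Optional[np.ndarray] = None,
) -> TrainResult:
    """Full-batch training, deterministic per seed.

    When validation entries (flat indices into the protein-disease grid) and
    their binary labels are given, validation AUPR is evaluated every
    ``config.eval_every`` epochs and the parameters from the best epoch are
    returned, with early stopping after ``config.patience`` epochs without
    improvement.  With ``epochs=0`` the seeded initialization is returned
    unchanged.
    """
    if variant in ("rp", "rw", "rpw") and rand is None:
        rand = sample_randomized(kg, np.random.default_rng(config.seed))
    problem = _Problem(kg, config, variant, rand)
    params = init_params(kg, config)
    names = [n for n, _ in params.named()]
    opt = {"adam": _Adam, "sgd": _SGD}[config.optimizer](
        names, params, config.learning_rate
    )
    result = TrainResult(params=params)
    use_val = val_entries is not None and val_labels is not None
    if use_val:
        from .evaluation import aupr

        val_entries = np.asarray(val_entries)
        val_labels = np.asarray(val_labels)
        best_val, best_params, best_epoch = -np.inf, params.copy(), 0

    for epoch in range(config.epochs):
        loss, grads = problem.loss_and_grads(params)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}: loss={loss}")
        result.loss_history.append(loss)
        opt.step(params, grads)
        if use_val and (epoch % config.eval_every == 0 or epoch == config.epochs - 1):
            Z = problem.forward(params)["Z"]
            tda = kg.spec_by_name(kg.tda_name)
            pred = reconstruct(
                Z[tda.source_type], params.G[tda.name], params.H[tda.name], Z[tda.target_type]
            )
            scores = pred.ravel()[val_entries]
            score = aupr(scores, val_labels)
            result.val_history.append((epoch, score))
            if score > best_val:
                best_val, best_params, best_epoch = score, params.copy(), epoch
            elif epoch - best_epoch >= config.patience:
                break

    if use_val:
        result.params = best_params
        result.best_epoch = best_epoch
    else:
        result.params = params
        result.best_epoch = config.epochs - 1
    return result


# ---------------------------------------------------------------------------
# parameter serialization


def save_params(params: ModelParams, path: str, config: Optional[TrainConfig] = None) -> None:
    """Single-archive serialization plus a JSON manifest next to it."""
    arrays = {name.replace(":", "__"): arr for name, arr in params.named()}
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    manifest = {
        "d0": params.d0,
        "d1": params.d1,
        "k": params.k,
        "tied": sorted(params.tied),
        "types": list(params.X),
        "relations": list(params.W),
    }
    if config is not None:
        manifest["seed"] = config.seed
        manifest["config_hash"] = config.config_hash()
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_params(path: str) -> ModelParams:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".manifest.json") as fh:
        manifest = json.load(fh)
    data = np.load(base + ".npz")
    X = {t: data[f"X__{t}"] for t in manifest["types"]}
    W = {r: data[f"W__{r}"] for r in manifest["relations"]}
    G = {r: data[f"G__{r}"] for r in manifest["relations"]}
    tied = frozenset(manifest["tied"])
    H = {r: (G[r] if r in tied else data[f"H__{r}"]) for r in manifest["relations"]}
    return ModelParams(
        X=X,
        W=W,
        G=G,
        H=H,
        W1=data["W1"],
        d0=manifest["d0"],
        d1=manifest["d1"],
        k=manifest["k"],
        tied=tied,
    )
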