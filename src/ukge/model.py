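"""Uncertain knowledge-graph embedding model and training loop.

Each entity and each theme is embedded as a d-dimensional vector.  A triple
l = (h, r, t) gets a bilinear plausibility

    g(l) = r . (h o t)        (o = element-wise product)

which a learned bounded rectifier maps to a predicted confidence

    f(l) = phi(g(l)),   phi(x) = min(max(w x + b, 0), 1)

regressed onto the observed literature support s_l by a squared-error
objective over observed triples and tail-corrupted negatives with assumed
support 0:

    J = sum_{l in L+} |f(l) - s_l|^2  +  sum_{l in L-} |f(l)|^2

At test time the min-max bounding is removed (w g(l) + b) so that candidate
rankings are tie-free.  Optimisation is minibatch Adam; parameters w and b
are global scalars shared across all relations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kg import DataSplit, EntityType, KnowledgeGraph, WeightedTriple


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Hyperparameters of the embedding training run.

    Defaults match the reference setting for a literature-scale graph:
    d=128, 100 epochs, batch size 1024, Adam with beta1=0.9, beta2=0.99,
    one corrupted negative per positive, and a learning-rate grid
    {0.001, 0.005, 0.01} tuned on validation mean squared error.
    """

    d: int = 128
    epochs: int = 100
    batch_size: int = 1024
    learning_rate: float = 0.001
    lr_grid: tuple[float, ...] = (0.001, 0.005, 0.01)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    negatives_per_positive: int = 1
    early_stop_patience: int = 5
    seed: int = 0
    # variant flags (defaults are the standard reading)
    resample_negatives: bool = True     # fresh negatives every epoch
    type_constrained_corruption: bool = False
    filter_collisions: bool = False     # drop corrupted triples that exist as positives
    validation_with_negatives: bool = False
    # leaky subgradient of the bounded rectifier during optimisation, so
    # positives saturated at the wrong bound remain trainable; the loss
    # itself is always the exact clamped objective
    grad_leak: float = 0.01

    def __post_init__(self) -> None:
        for name in ("d", "epochs", "batch_size", "negatives_per_positive",
                     "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class EmbeddingModel:
    """Entity and relation embeddings plus the global rectifier scalars.

    Parameters are dense numpy arrays: ``E`` of shape (n_entities, d) and
    ``R`` of shape (n_relations, d), with lookup tables from ids/theme codes
    to rows.
    """

    def __init__(
        self,
        entity_ids: list[str],
        relation_codes: list[str],
        E: np.ndarray,
        R: np.ndarray,
        w: float = 1.0,
        b: float = 0.0,
    ) -> None:
        E = np.asarray(E, dtype=float)
        R = np.asarray(R, dtype=float)
        if E.shape[0] != len(entity_ids) or R.shape[0] != len(relation_codes):
            raise ValueError("embedding matrix shape does not match id lists")
        if E.shape[1] != R.shape[1]:
            raise ValueError("entity and relation dimensions differ")
        if not (np.isfinite(w) and np.isfinite(b)):
            raise ValueError("w and b must be finite")
        self.entity_ids = list(entity_ids)
        self.relation_codes = list(relation_codes)
        self.entity_index = {e: i for i, e in enumerate(entity_ids)}
        self.relation_index = {r: i for i, r in enumerate(relation_codes)}
        self.E = E
        self.R = R
        self.w = float(w)
        self.b = float(b)

    @property
    def d(self) -> int:
        return self.E.shape[1]

    @classmethod
    def initialize(
        cls,
        entity_ids: list[str],
        relation_codes: list[str],
        d: int,
        rng: np.random.Generator,
    ) -> "EmbeddingModel":
        """Uniform init in [-0.5/sqrt(d), +0.5/sqrt(d)]; w=1, b=0."""
        scale = 0.5 / np.sqrt(d)
        E = rng.uniform(-scale, scale, size=(len(entity_ids), d))
        R = rng.uniform(-scale, scale, size=(len(relation_codes), d))
        return cls(entity_ids, relation_codes, E, R, w=1.0, b=0.0)

    # -- index helpers ------------------------------------------------------

    def _eidx(self, eid: str) -> int:
        try:
            return self.entity_index[eid]
        except KeyError:
            raise KeyError(f"entity {eid!r} not embedded") from None

    def _ridx(self, code: str) -> int:
        try:
            return self.relation_index[code]
        except KeyError:
            raise KeyError(f"relation {code!r} not embedded") from None

    def triple_indices(
        self, triples: list[WeightedTriple]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        H = np.array([self._eidx(t.head) for t in triples], dtype=np.intp)
        Rr = np.array([self._ridx(t.theme) for t in triples], dtype=np.intp)
        T = np.array([self._eidx(t.tail) for t in triples], dtype=np.intp)
        S = np.array([t.support for t in triples], dtype=float)
        return H, Rr, T, S

    # -- vectorised scoring -------------------------------------------------

    def plausibility_batch(self, H: np.ndarray, Rr: np.ndarray, T: np.ndarray) -> np.ndarray:
        return np.einsum("ij,ij,ij->i", self.R[Rr], self.E[H], self.E[T])

    def confidence_batch(self, H: np.ndarray, Rr: np.ndarray, T: np.ndarray) -> np.ndarray:
        # overflow on a diverging model clips to the bound, which is fine
        with np.errstate(over="ignore"):
            return np.clip(self.w * self.plausibility_batch(H, Rr, T) + self.b, 0.0, 1.0)

    def test_score_batch(self, H: np.ndarray, Rr: np.ndarray, T: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            return self.w * self.plausibility_batch(H, Rr, T) + self.b

    def copy_params(self) -> tuple[np.ndarray, np.ndarray, float, float]:
        return self.E.copy(), self.R.copy(), self.w, self.b

    # -- serialization ------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write <prefix>.meta.json plus entity/relation vector TSV tables."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        meta = {"d": self.d, "w": self.w, "b": self.b}
        with open(f"{prefix}.meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)
        for suffix, ids, mat in (
            ("entities", self.entity_ids, self.E),
            ("relations", self.relation_codes, self.R),
        ):
            df = pd.DataFrame(mat, index=pd.Index(ids, name="id"))
            df.to_csv(f"{prefix}.{suffix}.tsv", sep="\t", float_format="%.17g")

    @classmethod
    def load(cls, prefix: str | Path) -> "EmbeddingModel":
        prefix = Path(prefix)
        with open(f"{prefix}.meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        ent = pd.read_csv(f"{prefix}.entities.tsv", sep="\t", index_col="id")
        rel = pd.read_csv(f"{prefix}.relations.tsv", sep="\t", index_col="id")
        return cls(
            [str(i) for i in ent.index],
            [str(i) for i in rel.index],
            ent.to_numpy(),
            rel.to_numpy(),
            w=meta["w"],
            b=meta["b"],
        )


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------


def plausibility(model: EmbeddingModel, head: str, theme: str, tail: str) -> float:
    """Bilinear score g(l) = r . (h o t); symmetric in head/tail exchange."""
    h = model.E[model._eidx(head)]
    r = model.R[model._ridx(theme)]
    t = model.E[model._eidx(tail)]
    return float(np.dot(r, h * t))


def bounded_confidence(model: EmbeddingModel, x: float) -> float:
    """The bounded rectifier phi(x) = min(max(w x + b, 0), 1)."""
    return float(np.clip(model.w * x + model.b, 0.0, 1.0))


def train_confidence(model: EmbeddingModel, triple: tuple[str, str, str]) -> float:
    """Predicted confidence f(l) = phi(g(l)), guaranteed in [0, 1]."""
    head, theme, tail = triple
    return bounded_confidence(model, plausibility(model, head, theme, tail))


def test_score(model: EmbeddingModel, triple: tuple[str, str, str]) -> float:
    """Unbounded ranking score w g(l) + b (the clamp removed at test time)."""
    head, theme, tail = triple
    return float(model.w * plausibility(model, head, theme, tail) + model.b)


test_score.__test__ = False  # not a pytest case despite the name


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------


def sample_negative(
    triple: WeightedTriple,
    graph: KnowledgeGraph,
    rng: np.random.Generator,
) -> WeightedTriple:
    """Corrupt the tail: uniform draw over all entities other than the
    original tail (and the head, so the corrupted triple is not a
    self-loop); support is assumed 0."""
    pool = sorted(graph.entities)
    if len(pool) < 2:
        raise ValueError("need at least 2 entities to corrupt a tail")
    candidates = [e for e in pool if e not in (triple.tail, triple.head)]
    if not candidates:
        raise ValueError("no corruption candidates available")
    new_tail = candidates[int(rng.integers(len(candidates)))]
    return WeightedTriple(head=triple.head, theme=triple.theme, tail=new_tail, support=0.0)


def _sample_negative_tails(
    tails: np.ndarray,
    n_entities: int,
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
    heads: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised tail corruption: uniform over entities excluding the
    original tail (optionally restricted to a type pool).  Passing ``heads``
    additionally excludes each triple's head from its corruption pool."""

    def _bad(draws):
        if heads is None:
            return draws == tails
        return (draws == tails) | (draws == heads)

    if pool is None:
        draws = rng.integers(n_entities, size=tails.shape[0])
        bad = _bad(draws)
        while bad.any():
            draws[bad] = rng.integers(n_entities, size=int(bad.sum()))
            bad = _bad(draws)
    else:
        draws = pool[rng.integers(len(pool), size=tails.shape[0])]
        bad = _bad(draws)
        while bad.any():
            draws[bad] = pool[rng.integers(len(pool), size=int(bad.sum()))]
            bad = _bad(draws)
    return draws


# ---------------------------------------------------------------------------
# Loss and gradients
# ---------------------------------------------------------------------------


def _forward_backward(
    E: np.ndarray,
    R: np.ndarray,
    w: float,
    b: float,
    H: np.ndarray,
    Rr: np.ndarray,
    T: np.ndarray,
    S: np.ndarray,
    compute_grads: bool = True,
    leak: float = 0.0,
):
    """Squared-error objective and its analytic gradients on one batch.

    Targets S already encode positives (observed supports) and negatives
    (zeros), so a single residual form covers both sums of the objective.
    The clamp contributes zero gradient outside the open interval (0, 1);
    with ``leak`` > 0 the rectifier is given a small slope outside the
    bounds instead (an optimisation device only — the loss value is always
    the exact clamped objective), which keeps saturated examples trainable.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        h = E[H]
        t = E[T]
        r = R[Rr]
        g = np.einsum("ij,ij,ij->i", r, h, t)
        u = w * g + b
        f = np.clip(u, 0.0, 1.0)
        resid = f - S
        loss = float(np.sum(resid * resid))
        if not compute_grads:
            return loss, None
        active = ((u > 0.0) & (u < 1.0)).astype(float)
        if leak:
            active = np.maximum(active, leak)
        coeff = 2.0 * resid * active            # dJ/du per example
        dw = float(np.sum(coeff * g))
        db = float(np.sum(coeff))
        cg = (coeff * w)[:, None]               # dJ/dg, broadcast over dims
        dE = np.zeros_like(E)
        dR = np.zeros_like(R)
        np.add.at(dE, H, cg * (r * t))
        np.add.at(dE, T, cg * (r * h))
        np.add.at(dR, Rr, cg * (h * t))
    return loss, (dE, dR, dw, db)


def loss(
    model: EmbeddingModel,
    positives: list[WeightedTriple],
    negatives: list[WeightedTriple],
) -> float:
    """J = sum_{L+} |f(l) - s_l|^2 + sum_{L-} |f(l)|^2 (negatives' supports
    are treated as 0 regardless of their stored value)."""
    total = 0.0
    if positives:
        H, Rr, T, S = model.triple_indices(positives)
        total += _forward_backward(model.E, model.R, model.w, model.b,
                                   H, Rr, T, S, compute_grads=False)[0]
    if negatives:
        H, Rr, T, _ = model.triple_indices(negatives)
        Z = np.zeros(len(negatives))
        total += _forward_backward(model.E, model.R, model.w, model.b,
                                   H, Rr, T, Z, compute_grads=False)[0]
    return total


def loss_gradients(
    model: EmbeddingModel,
    positives: list[WeightedTriple],
    negatives: list[WeightedTriple],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Analytic gradient of :func:`loss` w.r.t. (E, R, w, b)."""
    pos_H, pos_R, pos_T, pos_S = (
        model.triple_indices(positives) if positives else (np.array([], dtype=np.intp),) * 3 + (np.array([]),)
    )
    neg = model.triple_indices(negatives) if negatives else None
    H = np.concatenate([pos_H, neg[0]]) if neg else pos_H
    Rr = np.concatenate([pos_R, neg[1]]) if neg else pos_R
    T = np.concatenate([pos_T, neg[2]]) if neg else pos_T
    S = np.concatenate([pos_S, np.zeros(len(negatives))]) if neg else pos_S
    _, grads = _forward_backward(model.E, model.R, model.w, model.b, H, Rr, T, S)
    return grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, shapes, lr: float, beta1: float, beta2: float, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        # overflow here only happens on a diverging run, which train()
        # detects and reports; silence the intermediate warnings
        with np.errstate(over="ignore", invalid="ignore"):
            for i, (p, g) in enumerate(zip(params, grads)):
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1 ** self.t)
                vhat = self.v[i] / (1 - self.b2 ** self.t)
                out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _validation_mse(model: EmbeddingModel, H, Rr, T, S) -> float:
    f = model.confidence_batch(H, Rr, T)
    return float(np.mean((f - S) ** 2))


def train(
    split: DataSplit,
    config: TrainConfig,
    graph: KnowledgeGraph | None = None,
) -> tuple[EmbeddingModel, pd.DataFrame]:
    """Fit the embedding model by minibatch Adam on the squared-error
    objective, with one fresh corrupted negative per positive per epoch.

    Validation mean squared error (bounded confidence on held-out positives)
    drives early stopping: training halts when it fails to improve for
    ``early_stop_patience`` consecutive epochs, and the parameters at the
    best validation MSE are returned.  The training log has one row per
    epoch (train loss, validation MSE).

    ``graph`` optionally fixes the entity/relation universe and the
    corruption pool; by default both are derived from the split itself.
    """
    all_triples = split.all_triples()
    if not all_triples:
        raise ValueError("empty split")
    if graph is not None:
        entity_ids = sorted(graph.entities)
        relation_codes = sorted({th.code for th in graph.vocabulary} | {t.theme for t in all_triples})
        entity_types = {e: graph.entities[e] for e in entity_ids}
    else:
        entity_ids = sorted({e for t in all_triples for e in (t.head, t.tail)})
        relation_codes = sorted({t.theme for t in all_triples})
        entity_types = None
    rng = np.random.default_rng(config.seed)
    model = EmbeddingModel.initialize(entity_ids, relation_codes, config.d, rng)

    H, Rr, T, S = model.triple_indices(split.train)
    n = len(split.train)
    n_ent = len(entity_ids)

    type_pools: dict[int, np.ndarray] | None = None
    if config.type_constrained_corruption:
        if entity_types is None:
            raise ValueError("type-constrained corruption requires the graph")
        by_type: dict[EntityType, list[int]] = {ty: [] for ty in EntityType}
        for i, e in enumerate(entity_ids):
            by_type[entity_types[e]].append(i)
        type_pools = {
            i: np.array(by_type[entity_types[entity_ids[i]]], dtype=np.intp)
            for i in range(n_ent)
        }
    positive_set = {(t.head, t.theme, t.tail) for t in split.train} if config.filter_collisions else None

    have_val = len(split.validation) > 0
    if have_val:
        vH, vR, vT, vS = model.triple_indices(split.validation)
        if config.validation_with_negatives:
            val_neg_T = _sample_negative_tails(vT, n_ent, rng)

    def val_mse() -> float:
        base = _validation_mse(model, vH, vR, vT, vS)
        if config.validation_with_negatives:
            f_neg = model.confidence_batch(vH, vR, val_neg_T)
            return float((base * len(vS) + np.sum(f_neg**2)) / (2 * len(vS)))
        return base

    def _draw_negatives(tails: np.ndarray, heads: np.ndarray, themes: np.ndarray) -> np.ndarray:
        reps = config.negatives_per_positive
        tl = np.tile(tails, reps)
        if type_pools is not None:
            out = np.empty(tl.shape[0], dtype=np.intp)
            for j, tail in enumerate(tl):
                pool = type_pools[int(tail)]
                out[j] = _sample_negative_tails(np.array([tail]), n_ent, rng, pool)[0]
            return out
        draws = _sample_negative_tails(tl, n_ent, rng)
        if positive_set is not None:
            hd = np.tile(heads, reps)
            th = np.tile(themes, reps)
            for j in range(len(draws)):
                while (entity_ids[hd[j]], relation_codes[th[j]], entity_ids[draws[j]]) in positive_set:
                    draws[j] = _sample_negative_tails(np.array([tl[j]]), n_ent, rng)[0]
        return draws

    best = model.copy_params()
    best_mse = val_mse() if have_val else np.inf
    log_rows = []
    stall = 0
    neg_T = _draw_negatives(T, H, Rr)

    for epoch in range(config.epochs):
        if config.resample_negatives and epoch > 0:
            neg_T = _draw_negatives(T, H, Rr)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            reps = config.negatives_per_positive
            nidx = np.concatenate([idx + k * n for k in range(reps)])
            bH = np.concatenate([H[idx], np.tile(H, reps)[nidx]])
            bR = np.concatenate([Rr[idx], np.tile(Rr, reps)[nidx]])
            bT = np.concatenate([T[idx], neg_T[nidx]])
            bS = np.concatenate([S[idx], np.zeros(len(nidx))])
            batch_loss, grads = _forward_backward(
                model.E, model.R, model.w, model.b, bH, bR, bT, bS,
                leak=config.grad_leak,
            )
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            epoch_loss += batch_loss
            if epoch == 0 and start == 0:
                opt = _Adam(
                    [model.E.shape, model.R.shape, (), ()],
                    config.learning_rate,
                    config.adam_beta1,
                    config.adam_beta2,
                )
            model.E, model.R, w_arr, b_arr = opt.step(
                [model.E, model.R, np.float64(model.w), np.float64(model.b)], list(grads)
            )
            model.w, model.b = float(w_arr), float(b_arr)
        if not (
            np.isfinite(model.w)
            and np.isfinite(model.b)
            and np.isfinite(model.E).all()
            and np.isfinite(model.R).all()
        ):
            raise TrainingDivergedError(f"non-finite parameters at epoch {epoch}")
        row = {"epoch": epoch, "train_loss": epoch_loss}
        if have_val:
            mse = val_mse()
            row["val_mse"] = mse
            if mse < best_mse:
                best_mse = mse
                best = model.copy_params()
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    log_rows.append(row)
                    break
        log_rows.append(row)

    if have_val:
        model.E, model.R, model.w, model.b = best
    return model, pd.DataFrame(log_rows)


def tune_learning_rate(
    split: DataSplit,
    config: TrainConfig,
    graph: KnowledgeGraph | None = None,
    tune_epochs: int | None = None,
) -> TrainConfig:
    """Grid-search the learning rate on validation MSE (ties and diverging
    runs resolved toward the smaller rate); returns the winning config."""
    if not config.lr_grid:
        raise ValueError("empty learning-rate grid")
    if not split.validation:
        raise ValueError("learning-rate tuning requires a validation set")
    best_lr, best_mse = None, np.inf
    for lr in sorted(config.lr_grid):
        trial = dataclasses.replace(
            config, learning_rate=lr, epochs=tune_epochs or config.epochs
        )
        try:
            model, _ = train(split, trial, graph=graph)
        except TrainingDivergedError:
            continue
        vH, vR, vT, vS = model.triple_indices(split.validation)
        mse = _validation_mse(model, vH, vR, vT, vS)
        if mse < best_mse:
            best_lr, best_mse = lr, mse
    if best_lr is None:
        raise TrainingDivergedError("all learning rates diverged")
    return dataclasses.replace(config, learning_rate=best_lr)
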