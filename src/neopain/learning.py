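"""Training objectives, the supervised pipeline, and per-infant
meta-learning personalization.

The multi-task objective is a weighted sum of six components

``L_total = a*L_concept + b*L_ordinal + g*L_evidential + d*L_sparsity
            + e*L_meta + z*L_contrast``

with default weights (1.0, 2.0, 0.5, 0.1, 0.8, 0.3). The components:

* **concept** — binary cross-entropy of the 3x12 learned concept heads
  against concept labels (clips without labels contribute 0);
* **ordinal** — squared difference of predicted vs true cumulative class
  distributions over the four ordered pain levels (an earth-mover-style
  surrogate that penalizes distant misorderings more);
* **evidential** — the Dirichlet evidential mean-square loss: per-class
  Brier term plus variance term, with an annealed KL-to-uniform regularizer
  on the off-target evidence;
* **sparsity** — mean L1 of the off-diagonal gated masked adjacency;
* **meta** — the query loss of the MAML-style personalization objective;
* **contrast** — the NT-Xent contrastive loss over paired augmented views.

Personalization (``maml_adapt``) takes gradient steps *only* on the
per-infant adjacency score offset and the evidential head; concept heads,
encoders and graph weights are bit-identical before and after adaptation,
preserving concept semantics across infants. ``meta_train`` runs the
first-order outer loop over infant tasks (4-way, matching the four pain
levels) and refuses tasks that leak evaluation infants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, SGD, Tensor
from .errors import InsufficientBatchError, LeakageError, ValidationError
from .fusion_net import N_CLASSES, PainFusionModel

_EPS = 1e-12
_CDF_MAT = np.triu(np.ones((N_CLASSES, N_CLASSES)))


@dataclass
class LossWeights:
    """Weights of the six objective components (all non-negative)."""

    alpha: float = 1.0     # concept supervision
    beta: float = 2.0      # ordinal ranking
    gamma: float = 0.5     # evidential
    delta: float = 0.1     # graph sparsity
    epsilon: float = 0.8   # meta
    zeta: float = 0.3      # contrastive

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "loss weights must be >= 0")


# ---------------------------------------------------------------------------
# individual losses
# ---------------------------------------------------------------------------

def contrastive_loss(projections: Tensor, pair_index: np.ndarray,
                     temperature: float = 0.1) -> Tensor:
    """NT-Xent loss over 2N projections of N samples' two augmented views.

    ``pair_index[i]`` is the row of anchor i's positive partner. The i-th
    term is the negative log of the softmax (over all rows but i, at the
    given temperature) of the cosine similarity with the partner, averaged
    over all 2N anchors.
    """
    if temperature <= 0:
        raise ValidationError("temperature", "must be positive")
    n2 = projections.shape[0]
    if n2 < 4:
        raise InsufficientBatchError(
            "contrastive loss needs N >= 2 samples (4 views)")
    z = projections / ((projections ** 2).sum(axis=1, keepdims=True) ** 0.5 + _EPS)
    sim = (z @ z.transpose()) * (1.0 / temperature)
    sim = sim + Tensor(-1e9 * np.eye(n2))          # exclude self-similarity
    logp = sim.log_softmax(axis=1)
    picked = logp[np.arange(n2), np.asarray(pair_index)]
    return -picked.mean()


def ordinal_loss(p: Tensor, y: np.ndarray) -> Tensor:
    """Squared difference of predicted vs true cumulative label
    distributions over the ordered pain levels (summed over levels,
    averaged over the batch)."""
    y = np.asarray(y, dtype=int)
    cdf = p @ Tensor(_CDF_MAT)
    target = _CDF_MAT[y]                            # one-hot CDF is a step
    return ((cdf - Tensor(target)) ** 2).sum(axis=-1).mean()


def evidential_loss(alpha: Tensor, y: np.ndarray,
                    kl_weight: float = 0.0) -> Tensor:
    """Evidential mean-square loss with annealed KL regularizer.

    Sum over classes of (y_k - p_k)^2 + p_k (1 - p_k) / (S + 1), with
    p = alpha / S, plus ``kl_weight`` times the KL divergence from the
    uniform Dirichlet of the off-target evidence (alpha with the true
    class's evidence removed)."""
    y = np.asarray(y, dtype=int)
    onehot = np.eye(N_CLASSES)[y]
    s = alpha.sum(axis=-1, keepdims=True)
    p = alpha / s
    err = ((Tensor(onehot) - p) ** 2).sum(axis=-1)
    var = (p * (1.0 - p) / (s + 1.0)).sum(axis=-1)
    loss = (err + var).mean()
    if kl_weight > 0:
        at = Tensor(onehot) + Tensor(1.0 - onehot) * alpha
        st = at.sum(axis=-1)
        # KL(Dir(at) || Dir(1)); lnGamma(K=4) = ln 6
        kl = (st.lgamma() - at.lgamma().sum(axis=-1) - np.log(6.0)
              + ((at - 1.0) * (at.digamma() - _expand(st.digamma()))).sum(axis=-1))
        loss = loss + kl_weight * kl.mean()
    return loss


def _expand(t: Tensor) -> Tensor:
    return t.reshape(*t.shape, 1)


def sparsity_loss(edges: Tensor) -> Tensor:
    """Mean absolute off-diagonal weight of the gated masked adjacency."""
    off = 1.0 - np.eye(edges.shape[-1])
    return (edges.abs() * Tensor(off)).mean()


def concept_bce(concept_matrix: Tensor, labels: np.ndarray,
                label_mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy of concept-head activations against
    binary concept labels; masked entries contribute 0."""
    t = np.asarray(labels, dtype=np.float64)
    m = np.ones_like(t) if label_mask is None else np.asarray(
        label_mask, dtype=np.float64)
    if m.sum() == 0:
        return Tensor(0.0)
    p = concept_matrix * (1 - 2e-7) + 1e-7          # clamp away from {0,1}
    bce = -(Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log())
    return (bce * Tensor(m)).sum() / float(m.sum())


# ---------------------------------------------------------------------------
# component aggregation
# ---------------------------------------------------------------------------

def component_losses(model: PainFusionModel, batch: dict,
                     kl_weight: float = 0.0) -> dict:
    """The six named loss components on one batch.

    ``batch`` needs ``activations`` (B, 12), ``available`` (B, 12) and
    ``pain`` (B,); optional keys: ``concept_matrix`` + ``concept_labels``
    (+ ``concept_label_mask``) for the concept term, ``projections`` +
    ``pair_index`` for the contrastive term, and a precomputed ``meta``
    scalar. Missing optional terms are zero."""
    if "pain" not in batch or batch["pain"] is None or not len(batch["pain"]):
        raise ValidationError("pain", "supervised losses need pain labels")
    out = model.forward(batch["activations"], batch["available"])
    alpha = out["alpha"]
    p = alpha / alpha.sum(axis=-1, keepdims=True)
    comp = {
        "concept": Tensor(0.0),
        "ordinal": ordinal_loss(p, batch["pain"]),
        "evidential": evidential_loss(alpha, batch["pain"], kl_weight),
        "sparsity": sparsity_loss(out["edges"]),
        "meta": batch.get("meta", Tensor(0.0)),
        "contrast": Tensor(0.0),
    }
    if "concept_matrix" in batch and batch.get("concept_labels") is not None:
        comp["concept"] = concept_bce(batch["concept_matrix"],
                                      batch["concept_labels"],
                                      batch.get("concept_label_mask"))
    if "projections" in batch:
        comp["contrast"] = contrastive_loss(batch["projections"],
                                            batch["pair_index"],
                                            batch.get("temperature", 0.1))
    return comp


def total_loss(components: dict, weights: LossWeights | None = None) -> Tensor:
    """The weighted multi-task objective."""
    w = weights or LossWeights()
    keys = ("concept", "ordinal", "evidential", "sparsity", "meta", "contrast")
    coefs = (w.alpha, w.beta, w.gamma, w.delta, w.epsilon, w.zeta)
    out = Tensor(0.0)
    for key, c in zip(keys, coefs):
        term = components[key]
        if not isinstance(term, Tensor):
            term = Tensor(float(term))
        out = out + c * term
    return out


# ---------------------------------------------------------------------------
# supervised training
# ---------------------------------------------------------------------------

def _supervised_batch_loss(model: PainFusionModel, acts, avail, pain,
                           weights: LossWeights, kl_weight: float) -> Tensor:
    comp = component_losses(model, {"activations": acts, "available": avail,
                                    "pain": pain}, kl_weight)
    return (weights.beta * comp["ordinal"]
            + weights.gamma * comp["evidential"]
            + weights.delta * comp["sparsity"])


def train_supervised(model: PainFusionModel, activations: np.ndarray,
                     available: np.ndarray, pain: np.ndarray, *,
                     epochs: int = 30, batch_size: int = 32, lr: float = 1e-3,
                     seed: int = 0, weights: LossWeights | None = None,
                     kl_max: float = 0.1, kl_anneal_epochs: int = 10) -> list[dict]:
    """Fit the fusion model on concept activations with Adam (cosine-free
    desk-scale schedule); returns the per-epoch loss history.

    The KL coefficient of the evidential term anneals linearly from 0 to
    ``kl_max`` over ``kl_anneal_epochs`` epochs, the standard schedule for
    evidential training (evidence is shaped only once the fit is underway).
    """
    weights = weights or LossWeights()
    rng = np.random.default_rng(seed)
    params = list(model.parameters().values())
    opt = Adam(params, lr=lr)
    n = len(pain)
    history = []
    for epoch in range(epochs):
        kl_w = kl_max * min(1.0, epoch / max(kl_anneal_epochs, 1))
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            opt.zero_grad()
            loss = _supervised_batch_loss(model, activations[idx],
                                          available[idx], pain[idx],
                                          weights, kl_w)
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        history.append({"epoch": epoch, "loss": total / n, "kl_weight": kl_w})
    return history


def predict_levels(model: PainFusionModel, activations: np.ndarray,
                   available: np.ndarray) -> np.ndarray:
    """Argmax pain level per clip (no abstention)."""
    out = model.forward(activations, available)
    return np.argmax(out["alpha"].numpy(), axis=-1)


# ---------------------------------------------------------------------------
# meta-learning personalization
# ---------------------------------------------------------------------------

@dataclass
class MetaTask:
    """One infant's few-shot episode: disjoint support and query clips."""

    infant_id: str
    support: dict                 # activations, available, pain, clip_ids
    query: dict

    def __post_init__(self) -> None:
        s = set(self.support.get("clip_ids", ()))
        q = set(self.query.get("clip_ids", ()))
        if s & q:
            raise LeakageError(
                f"support/query clips overlap for infant {self.infant_id}")


def maml_adapt(model: PainFusionModel, support: dict, inner_lr: float = 0.01,
               steps: int = 1, weights: LossWeights | None = None,
               prox_weight: float = 0.0) -> PainFusionModel:
    """Few-shot adaptation: gradient steps on the per-infant adjacency
    offset and evidential head only; every other parameter is bit-identical
    before and after.

    ``prox_weight`` adds a proximal penalty ``prox/2 * ||phi - phi_0||^2``
    on the adapted parameters (mean support loss vs a fixed pull toward the
    shared initialization): with few support clips the data term is weak and
    the correction stays small, with more clips it can move further — a
    sample-size-adaptive trust region."""
    if not len(support.get("pain", ())):
        raise ValidationError("support", "support set must be non-empty")
    weights = weights or LossWeights()
    adapted = model.clone()
    meta_params = adapted.meta_parameters()
    anchors = {k: p.data.copy() for k, p in meta_params.items()}
    opt = SGD(list(meta_params.values()), lr=inner_lr)
    for _ in range(steps):
        opt.zero_grad()
        loss = _supervised_batch_loss(adapted, support["activations"],
                                      support["available"], support["pain"],
                                      weights, 0.0)
        if prox_weight > 0:
            for k, p in meta_params.items():
                loss = loss + (prox_weight / 2.0) * ((p - Tensor(anchors[k])) ** 2).sum()
        loss.backward()
        opt.step()
    return adapted


def meta_train(model: PainFusionModel, tasks: list[MetaTask],
               outer_lr: float = 0.001, inner_lr: float = 0.01,
               steps: int = 1, weights: LossWeights | None = None,
               eval_infant_ids: set | None = None,
               epochs: int = 1) -> list[float]:
    """First-order outer loop on the sum of query losses of adapted models.

    Raises :class:`LeakageError` if any task cites an evaluation infant.
    Returns the per-epoch mean query loss (the meta component of the
    multi-task objective)."""
    weights = weights or LossWeights()
    eval_infant_ids = eval_infant_ids or set()
    for task in tasks:
        if task.infant_id in eval_infant_ids:
            raise LeakageError(f"task infant {task.infant_id} is an "
                               "evaluation infant")
    history = []
    meta_names = model.meta_parameter_names
    for _ in range(epochs):
        epoch_loss = 0.0
        for task in tasks:
            adapted = maml_adapt(model, task.support, inner_lr, steps, weights)
            for p in adapted.meta_parameters().values():
                p.grad = None
            q_loss = _supervised_batch_loss(
                adapted, task.query["activations"], task.query["available"],
                task.query["pain"], weights, 0.0)
            q_loss.backward()
            # first-order: apply the adapted meta-gradient to the base model
            base = model.meta_parameters()
            for name, p in adapted.meta_parameters().items():
                if p.grad is not None:
                    base[name].data -= outer_lr * p.grad
            epoch_loss += q_loss.item()
        history.append(epoch_loss / max(len(tasks), 1))
    return history
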