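"""Graph-based multimodal fusion with an evidential Dirichlet output.

The fusion stage arranges the 12 concepts as graph nodes. Node features are
activation-scaled learned embeddings ``h_i = c_i * e_i + b_i`` (128-dim), so
a zero activation leaves only the node's constant bias — unavailable
concepts are zeroed first and are therefore feature-neutral. A two-layer
perceptron scores every ordered node pair on ``[h_i; h_j; |h_i - h_j|]``
and a row-wise softmax over ``j != i`` yields the adjacency A. When a
modality is absent, all edges incident to its concept nodes are zeroed and
surviving rows renormalized; two GraphSAGE-style layers propagate features
over the gated adjacency (per-edge sigmoid gates, deterministic at
inference) and a mean-pool over unmasked nodes gives the fused
representation h_GNN.

The evidential head maps h_GNN to Dirichlet parameters over the four pain
levels: ``alpha = ReLU(W h + b) + 1``; epistemic uncertainty is
``u = K / sum(alpha)`` and class probabilities ``p_k = alpha_k / sum(alpha)``.
The assessment abstains whenever ``u > tau`` (default 0.5), deferring to a
clinician.

Lightweight temporal-convolution encoders (kernel 3, dilations 1/2/4,
hidden 128, global average pooling) embed each modality to 128 dimensions
for the learned concept bottleneck; an absent modality yields an exact zero
vector without evaluating its encoder.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Linear, Parameter, Tensor, concat
from .concepts import CONCEPT_MODALITY
from .episodes_io import Episode, mel_spectrogram
from .errors import EmptyGraphError, FormatError, ShapeError

HIDDEN = 128
N_CONCEPTS = 12
N_CLASSES = 4
DEFAULT_TAU = 0.5

# fixed physiological normalization constants (value / scale)
_PHYSIO_SCALE = {"hr": 200.0, "spo2": 100.0, "rr": 60.0, "map": 100.0}


# ---------------------------------------------------------------------------
# evidential output
# ---------------------------------------------------------------------------

@dataclass
class EvidentialOutput:
    """Dirichlet parameters over the 4 pain levels with uncertainty."""

    alpha: np.ndarray      # (4,) each >= 1
    u: float               # K / sum(alpha), in (0, 1]
    p: np.ndarray          # (4,) class probabilities

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.alpha.shape != (N_CLASSES,):
            raise ShapeError(f"alpha shape {self.alpha.shape} != ({N_CLASSES},)")


def evidential_from_alpha(alpha: np.ndarray) -> EvidentialOutput:
    alpha = np.asarray(alpha, dtype=np.float64)
    s = float(alpha.sum())
    return EvidentialOutput(alpha=alpha, u=N_CLASSES / s, p=alpha / s)


def evidential_forward(h_gnn, head) -> Tensor:
    """alpha = ReLU(W h + b) + 1 on a 128-dim fused representation.

    Returns the alpha Tensor (batched or single); use
    :func:`evidential_from_alpha` on the numpy values for the dataclass.
    """
    if h_gnn.shape[-1] != HIDDEN:
        raise ShapeError(f"h_GNN dim {h_gnn.shape[-1]} != {HIDDEN}")
    return head(h_gnn).relu() + 1.0


def predict_or_abstain(out: EvidentialOutput, tau: float = DEFAULT_TAU):
    """Abstain iff u > tau, else argmax p; exact probability ties break
    toward the higher severity class and set the tie flag.

    Returns (level_or_None, abstained, tie_flag).
    """
    if out.u > tau:
        return None, True, False
    best = float(np.max(out.p))
    ties = np.where(out.p == best)[0]
    return int(ties[-1]), False, len(ties) > 1


# ---------------------------------------------------------------------------
# modality encoders
# ---------------------------------------------------------------------------

class Conv1d:
    """Dilated 1-D convolution (same padding) over (channels, time)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.W = Parameter(rng.uniform(-limit, limit, (c_out, c_in * kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.kernel, self.dilation = kernel, dilation

    def __call__(self, x: Tensor) -> Tensor:
        c_in, t = x.shape
        pad = self.dilation * (self.kernel - 1) // 2
        zeros = Tensor(np.zeros((c_in, pad)))
        xp = concat([zeros, x, zeros], axis=1)
        idx = np.arange(t)[:, None] + self.dilation * np.arange(self.kernel)[None, :]
        win = xp[:, idx]                           # (c_in, t, kernel)
        win = win.transpose(1, 0, 2).reshape(t, c_in * self.kernel)
        return (win @ self.W.transpose() + self.b).transpose()  # (c_out, t)

    def parameters(self):
        return [self.W, self.b]


class TCNEncoder:
    """Stacked dilated temporal convolutions with global average pooling."""

    def __init__(self, c_in: int, rng: np.random.Generator,
                 n_layers: int = 3, hidden: int = HIDDEN,
                 dropout: float = 0.2):
        dims = [c_in] + [hidden] * n_layers
        self.layers = [Conv1d(dims[i], dims[i + 1], 3, 2 ** i, rng)
                       for i in range(n_layers)]
        self.dropout = dropout

    def __call__(self, x: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = Tensor(np.asarray(x, dtype=np.float64))
        for layer in self.layers:
            h = layer(h).relu()
            if train and self.dropout > 0 and rng is not None:
                keep = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * Tensor(keep)
        return h.mean(axis=1)                      # (hidden,)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


@dataclass
class ModalityEmbeddings:
    """128-dim embeddings per modality; exact zeros when absent."""

    h_v: np.ndarray
    h_a: np.ndarray
    h_p: np.ndarray
    modality_mask: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        for name in ("h_v", "h_a", "h_p"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (HIDDEN,):
                raise ShapeError(f"{name} shape {v.shape} != ({HIDDEN},)")
            setattr(self, name, v)


class ModalityEncoders:
    """The three clip encoders: mel-spectrogram TCN (audio), physiology TCN,
    and a 2-layer temporal conv on the facial action channels."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.facial = TCNEncoder(4, rng, n_layers=2)
        self.audio = TCNEncoder(128, rng, n_layers=3)
        self.physio = TCNEncoder(4, rng, n_layers=3)

    def parameters(self):
        return (self.facial.parameters() + self.audio.parameters()
                + self.physio.parameters())

    @staticmethod
    def _physio_features(physio) -> np.ndarray:
        cols = ["hr", "spo2", "rr", "map"]
        n = len(physio)
        out = np.zeros((4, n // 10))
        for k, col in enumerate(cols):
            if col in physio.columns:
                x = physio[col].to_numpy(dtype=np.float64) / _PHYSIO_SCALE[col]
                x = np.nan_to_num(x, nan=0.0)
                out[k] = x[: (n // 10) * 10].reshape(-1, 10).mean(axis=1)
        return out

    def encode(self, clip: Episode, train: bool = False,
               rng: np.random.Generator | None = None) -> ModalityEmbeddings:
        video_ok, audio_ok, physio_ok = clip.modality_mask
        zero = np.zeros(HIDDEN)
        h_v = (self.facial(clip.facial.T, train, rng).numpy()
               if video_ok else zero.copy())
        h_a = (self.audio(mel_spectrogram(clip.audio), train, rng).numpy()
               if audio_ok else zero.copy())
        h_p = (self.physio(self._physio_features(clip.physio), train, rng).numpy()
               if physio_ok else zero.copy())
        return ModalityEmbeddings(h_v, h_a, h_p, clip.modality_mask)


def encode_modalities(clip: Episode, encoders: ModalityEncoders,
                      train: bool = False,
                      rng: np.random.Generator | None = None) -> ModalityEmbeddings:
    """Encode a 10-s clip to three 128-dim vectors (zeros for absent
    modalities, whose encoders are never evaluated)."""
    return encoders.encode(clip, train=train, rng=rng)


# ---------------------------------------------------------------------------
# concept graph
# ---------------------------------------------------------------------------

def node_mask_from_modalities(modality_mask) -> np.ndarray:
    """12-node mask from the (video, audio, physio) modality mask."""
    mm = np.asarray(modality_mask, dtype=bool)
    return mm[CONCEPT_MODALITY]


class AdjacencyMLP:
    """Two-layer perceptron scoring ordered concept pairs (hidden 64)."""

    def __init__(self, rng: np.random.Generator, hidden: int = 64):
        self.l1 = Linear(3 * HIDDEN, hidden, rng)
        self.l2 = Linear(hidden, 1, rng)

    def __call__(self, feats: Tensor) -> Tensor:
        return self.l2(self.l1(feats).relu())

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()


_DIAG_NEG = -1e9 * np.eye(N_CONCEPTS)
_I, _J = np.meshgrid(np.arange(N_CONCEPTS), np.arange(N_CONCEPTS), indexing="ij")


def adjacency_scores(h_nodes: Tensor, mlp: AdjacencyMLP,
                     delta: Tensor | None = None) -> Tensor:
    """Pairwise scores from MLP([h_i; h_j; |h_i - h_j|]); (..., 12, 12)."""
    batched = h_nodes.ndim == 3
    hi = h_nodes[:, _I.ravel(), :] if batched else h_nodes[_I.ravel(), :]
    hj = h_nodes[:, _J.ravel(), :] if batched else h_nodes[_J.ravel(), :]
    feats = concat([hi, hj, (hi - hj).abs()], axis=-1)
    scores = mlp(feats)
    shape = (h_nodes.shape[0], N_CONCEPTS, N_CONCEPTS) if batched \
        else (N_CONCEPTS, N_CONCEPTS)
    scores = scores.reshape(shape)
    if delta is not None:
        scores = scores + delta
    return scores


def build_adjacency(h_nodes: Tensor, mlp: AdjacencyMLP,
                    delta: Tensor | None = None) -> Tensor:
    """Row-stochastic adjacency: softmax over j != i of the pair scores.

    ``delta`` is the optional per-infant additive score offset installed by
    meta-learning personalization.
    """
    scores = adjacency_scores(h_nodes, mlp, delta)
    return (scores + Tensor(_DIAG_NEG)).softmax(axis=-1)


def mask_adjacency(A: Tensor | np.ndarray, node_mask: np.ndarray) -> Tensor:
    """Zero all edges incident to masked nodes and renormalize surviving
    rows over surviving columns; fully masked rows stay zero.

    ``node_mask`` may be a 12-vector or a (batch, 12) array; a 3-element
    (video, audio, physio) modality mask is expanded to concept nodes.
    """
    if not isinstance(A, Tensor):
        A = Tensor(np.asarray(A, dtype=np.float64))
    node_mask = np.asarray(node_mask)
    if node_mask.shape[-1] == 3:
        node_mask = node_mask[..., CONCEPT_MODALITY]
    m = node_mask.astype(np.float64)
    if not np.all(node_mask.reshape(-1, N_CONCEPTS).any(axis=-1)):
        raise EmptyGraphError("all concept nodes masked")
    mi = np.expand_dims(m, -1)
    mj = np.expand_dims(m, -2)
    Am = A * Tensor(mi * mj)
    rowsum = Am.sum(axis=-1, keepdims=True)
    safe = Tensor((rowsum.numpy() == 0).astype(np.float64))
    return Am / (rowsum + safe)


class GraphSAGELayer:
    """h_i' = ReLU(W_self h_i + W_nbr * sum_j (A*M)_ij h_j + b)."""

    def __init__(self, rng: np.random.Generator, dim: int = HIDDEN):
        self.w_self = Linear(dim, dim, rng)
        self.w_nbr = Linear(dim, dim, rng, bias=False)

    def __call__(self, h: Tensor, edges: Tensor) -> Tensor:
        return (self.w_self(h) + self.w_nbr(edges @ h)).relu()

    def parameters(self):
        return self.w_self.parameters() + self.w_nbr.parameters()


def propagate_and_pool(h_nodes: Tensor, A_tilde: Tensor, gates: Tensor,
                       layers, node_mask: np.ndarray) -> Tensor:
    """Two GraphSAGE layers over the gated adjacency, then mean-pool over
    unmasked nodes to the fused 128-dim representation."""
    node_mask = np.asarray(node_mask)
    if not node_mask.reshape(-1, N_CONCEPTS).any(axis=-1).all():
        raise EmptyGraphError("all concept nodes masked")
    edges = A_tilde * gates
    h = h_nodes
    for layer in layers:
        h = layer(h, edges)
    m = node_mask.astype(np.float64)
    weights = m / m.sum(axis=-1, keepdims=True)
    return (h * Tensor(np.expand_dims(weights, -1))).sum(axis=-2)


# ---------------------------------------------------------------------------
# the fused concept-graph pain model
# ---------------------------------------------------------------------------

class PainFusionModel:
    """Concept activations -> graph reasoning -> evidential pain output.

    Parameters are named for serialization; ``meta_parameter_names`` lists
    the subset that per-infant personalization may touch (the adjacency
    score offset and the evidential head) — everything else stays frozen
    under adaptation.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.embed = Parameter(rng.normal(0.0, 0.3, (N_CONCEPTS, HIDDEN)))
        self.bias = Parameter(rng.normal(0.0, 0.05, (N_CONCEPTS, HIDDEN)))
        self.adj_mlp = AdjacencyMLP(rng)
        self.gate_logits = Parameter(np.full((N_CONCEPTS, N_CONCEPTS), 2.0))
        self.sage = [GraphSAGELayer(rng), GraphSAGELayer(rng)]
        self.evid_head = Linear(HIDDEN, N_CLASSES, rng)
        # keep evidence units alive at init: a zero-bias ReLU head can start
        # all-negative, freezing p at uniform with no gradient signal
        self.evid_head.b.data[:] = 1.0
        self.delta_A = Parameter(np.zeros((N_CONCEPTS, N_CONCEPTS)))

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> "OrderedDict[str, Parameter]":
        out: OrderedDict[str, Parameter] = OrderedDict()
        out["embed"] = self.embed
        out["bias"] = self.bias
        for i, p in enumerate(self.adj_mlp.parameters()):
            out[f"adj_mlp.{i}"] = p
        out["gate_logits"] = self.gate_logits
        for li, layer in enumerate(self.sage):
            for i, p in enumerate(layer.parameters()):
                out[f"sage{li}.{i}"] = p
        out["evid.W"] = self.evid_head.W
        out["evid.b"] = self.evid_head.b
        out["delta_A"] = self.delta_A
        return out

    meta_parameter_names = ("delta_A", "evid.W", "evid.b")

    def meta_parameters(self):
        params = self.parameters()
        return OrderedDict((k, params[k]) for k in self.meta_parameter_names)

    def clone(self) -> "PainFusionModel":
        other = PainFusionModel(seed=self.seed)
        for (_, src), (_, dst) in zip(self.parameters().items(),
                                      other.parameters().items()):
            dst.data = src.data.copy()
        return other

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.parameters().items():
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    # -- forward ----------------------------------------------------------
    def forward(self, activations: np.ndarray, node_mask: np.ndarray) -> dict:
        """Batched forward pass.

        ``activations``: (B, 12) concept activations; ``node_mask``: (B, 12)
        availability. Unavailable concepts are zeroed before featureization,
        making the output exactly independent of their activation values.
        """
        acts = np.asarray(activations, dtype=np.float64)
        mask = np.asarray(node_mask, dtype=bool)
        if acts.ndim == 1:
            acts, mask = acts[None, :], mask[None, :]
        acts = acts * mask
        h = Tensor(acts[:, :, None]) * self.embed + self.bias   # (B, 12, 128)
        A = build_adjacency(h, self.adj_mlp, self.delta_A)
        A_tilde = mask_adjacency(A, mask)
        gates = self.gate_logits.sigmoid()
        h_gnn = propagate_and_pool(h, A_tilde, gates, self.sage, mask)
        alpha = evidential_forward(h_gnn, self.evid_head)
        return {"alpha": alpha, "h_gnn": h_gnn, "A": A, "A_tilde": A_tilde,
                "edges": A_tilde * gates}

    def predict(self, activations: np.ndarray,
                node_mask: np.ndarray) -> list[EvidentialOutput]:
        out = self.forward(activations, node_mask)
        return [evidential_from_alpha(a) for a in out["alpha"].numpy()]


# ---------------------------------------------------------------------------
# parameter archive (named arrays + JSON manifest)
# ---------------------------------------------------------------------------

def save_params(model: PainFusionModel, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path / "params.npz", **state)
    manifest = {"seed": model.seed,
                "arrays": {k: {"shape": list(v.shape), "dtype": str(v.dtype)}
                           for k, v in state.items()}}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_params(path: str | Path) -> PainFusionModel:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    model = PainFusionModel(seed=manifest.get("seed", 0))
    with np.load(path / "params.npz") as data:
        state = {k: data[k] for k in data.files}
    expected = {k: tuple(v["shape"]) for k, v in manifest["arrays"].items()}
    for k, shape in expected.items():
        if k not in state or tuple(state[k].shape) != shape:
            raise FormatError(f"archive array {k} missing or wrong shape")
    model.load_state_dict(state)
    return model
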