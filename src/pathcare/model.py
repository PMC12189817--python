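"""The PathCare network.

Two GRU encoders read the same preprocessed visit sequence: a
*future-visit* encoder whose hidden state is trained (self-supervised) to
predict the next visit's feature vector, and a *task* encoder trained for
the outcome.  Their final-visit embeddings are projected into a shared
latent space (``g_future``, ``g_task``), a batch-covariance decorrelation
penalty pushes the neurons of each projection to carry non-redundant
information, and a neuron-level filtering gate — the cumulative softmax
(cumax) of a linear map of the patient's latest record — splits the latent
neurons between the two sources:

    gate_future = cumax(W_gate r_T),   gate_task = 1 - gate_future
    s = gate_future ⊙ g_future + gate_task ⊙ g_task

``cumax`` output is monotone non-decreasing from ~0 to 1, so it acts as
the expectation of a binary split gate (0,…,0,1,…,1): low-index neurons
lean on the task embedding, high-index neurons on the future-predictive
embedding, and the split point adapts per patient.  A logistic head on
``s`` yields the outcome probability.

Ablation variants: ``context_minus`` drops the future branch entirely
(task embedding straight into the head); ``gate_minus`` concatenates the
two projections instead of gating (decorrelation still applies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .autograd import Tensor, as_tensor, concat
from .data import Batch

VARIANTS = ("full", "context_minus", "gate_minus")


@dataclass
class ModelConfig:
    n_features: int
    hidden_dim: int = 64       # N_h
    gate_dim: int = 64         # N_g
    alpha: float = 0.1         # decorrelation weight (not stated upstream;
                               # exposed, sensitivity discussed in docs)
    variant: str = "full"
    init_seed: int = 0
    joint_decorrelation: bool = False  # penalize [g_future; g_task] jointly

    def __post_init__(self):
        if min(self.n_features, self.hidden_dim, self.gate_dim) < 1:
            raise ValueError("dimensions must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")


_GRU_GATES = ("r", "z", "n")


def _init_gru(rng: np.random.Generator, n_in: int, n_h: int,
              prefix: str) -> Dict[str, Tensor]:
    k = 1.0 / np.sqrt(n_h)
    p: Dict[str, Tensor] = {}
    for g in _GRU_GATES:
        p[f"{prefix}.W_i{g}"] = Tensor(rng.uniform(-k, k, (n_in, n_h)), True)
        p[f"{prefix}.W_h{g}"] = Tensor(rng.uniform(-k, k, (n_h, n_h)), True)
        p[f"{prefix}.b_{g}"] = Tensor(np.zeros(n_h), True)
    return p


class ModelParams:
    """All learnable weights, addressable by name.

    Groups: ``future_encoder`` + ``future_head`` (auxiliary branch),
    ``task_encoder``, projections ``W_f``/``W_t``, gate matrix ``W_gate``,
    and the ``target_head``.  Projections and the gate are pure matrix
    products (no bias); heads are affine.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        nr, nh, ng = config.n_features, config.hidden_dim, config.gate_dim
        p: Dict[str, Tensor] = {}
        p.update(_init_gru(rng, nr, nh, "future_encoder"))
        kh = 1.0 / np.sqrt(nh)
        p["future_head.W"] = Tensor(rng.uniform(-kh, kh, (nh, nr)), True)
        p["future_head.b"] = Tensor(np.zeros(nr), True)
        p.update(_init_gru(rng, nr, nh, "task_encoder"))
        p["W_f"] = Tensor(rng.uniform(-kh, kh, (ng, nh)), True)
        p["W_t"] = Tensor(rng.uniform(-kh, kh, (ng, nh)), True)
        kr = 1.0 / np.sqrt(nr)
        p["W_gate"] = Tensor(rng.uniform(-kr, kr, (ng, nr)), True)
        head_in = 2 * ng if config.variant == "gate_minus" else ng
        kg = 1.0 / np.sqrt(head_in)
        p["target_head.W"] = Tensor(rng.uniform(-kg, kg, (head_in, 1)), True)
        p["target_head.b"] = Tensor(np.zeros(1), True)
        self._params = p

    def __getitem__(self, name: str) -> Tensor:
        return self._params[name]

    def names(self) -> List[str]:
        return list(self._params)

    def group(self, *prefixes: str) -> List[Tuple[str, Tensor]]:
        return [(n, t) for n, t in self._params.items()
                if any(n.startswith(pre) for pre in prefixes)]

    FUTURE_GROUP = ("future_encoder", "future_head")
    TARGET_GROUP = ("task_encoder", "W_f", "W_t", "W_gate", "target_head")

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self._params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for n, t in self._params.items():
            arr = np.asarray(state[n], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {n}")
            t.data = arr.copy()

    # -- checkpointing -------------------------------------------------
    def save(self, path: str,
             rng_state: Optional[dict] = None) -> None:
        """Single-file checkpoint: config + named weights + RNG state."""
        meta = {"config": self.config.__dict__,
                "rng_state": rng_state}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta, default=_json_fallback).encode(), dtype=np.uint8),
            **self.state_dict())

    @classmethod
    def load(cls, path: str) -> Tuple["ModelParams", Optional[dict]]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {n: z[n] for n in z.files if n != "__meta__"}
        params = cls(ModelConfig(**meta["config"]))
        params.load_state_dict(state)
        return params, meta.get("rng_state")


def _json_fallback(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o))


@dataclass
class ForwardDiagnostics:
    """Everything a forward pass computes, as autodiff tensors.

    Per-visit lists are indexed by time step; vector fields are batched
    (first axis = patient).  Fields not defined under an ablation variant
    are None.  Use ``.data`` on any field for a plain array.
    """

    h_f: Optional[List[Tensor]]
    h: List[Tensor]
    g_future: Optional[Tensor]
    g_task: Tensor
    gate_logits: Optional[Tensor]
    gate_future: Optional[Tensor]
    gate_task: Optional[Tensor]
    s: Tensor
    y_hat: Tensor
    r_hat_seq: Optional[List[Tensor]]
    patient_ids: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _gru_unroll(params: ModelParams, prefix: str,
                batch: Batch) -> List[Tensor]:
    """Run a GRU over the padded batch; returns h_t for t = 0..T_max-1.

    The hidden state starts at zero and the recurrence is causal, so h_t
    never sees visits after t; padded steps are computed but never
    selected downstream.
    """
    B, T, nr = batch.values.shape
    if nr != params.config.n_features:
        raise ValueError(f"batch has {nr} features, model expects "
                         f"{params.config.n_features}")
    nh = params.config.hidden_dim
    h = Tensor(np.zeros((B, nh)))
    W_ir, W_iz, W_in = (params[f"{prefix}.W_i{g}"] for g in _GRU_GATES)
    W_hr, W_hz, W_hn = (params[f"{prefix}.W_h{g}"] for g in _GRU_GATES)
    b_r, b_z, b_n = (params[f"{prefix}.b_{g}"] for g in _GRU_GATES)
    outputs: List[Tensor] = []
    for t in range(T):
        x = Tensor(batch.values[:, t, :])
        r = (x @ W_ir + h @ W_hr + b_r).sigmoid()
        z = (x @ W_iz + h @ W_hz + b_z).sigmoid()
        n = (x @ W_in + (r * h) @ W_hn + b_n).tanh()
        h = (1.0 - z) * n + z * h
        outputs.append(h)
    return outputs


def _select_last(h_seq: List[Tensor], lengths: np.ndarray) -> Tensor:
    """Pick each patient's embedding at its last non-padding visit."""
    out = None
    for t, h_t in enumerate(h_seq):
        mask = (lengths - 1 == t).astype(np.float64)[:, None]
        if mask.any():
            term = h_t * mask
            out = term if out is None else out + term
    return out


def encode_future(params: ModelParams, batch: Batch) -> List[Tensor]:
    """Future-visit encoder: per-visit embeddings h_t^f."""
    return _gru_unroll(params, "future_encoder", batch)


def encode_task(params: ModelParams, batch: Batch) -> List[Tensor]:
    """Task encoder: per-visit embeddings h_t (parameters disjoint from
    the future encoder's)."""
    return _gru_unroll(params, "task_encoder", batch)


def predict_next_visit(params: ModelParams, h_f: Tensor) -> Tensor:
    """Affine head mapping a future embedding to the next visit's record."""
    return h_f @ params["future_head.W"] + params["future_head.b"]


def project(params: ModelParams, h_f_T: Tensor,
            h_T: Tensor) -> Tuple[Tensor, Tensor]:
    """Project final-visit embeddings into the shared gate space (linear,
    no bias): g_future = W_f h^f_T, g_task = W_t h_T."""
    return h_f_T @ params["W_f"].T, h_T @ params["W_t"].T


def covariance_matrix(G: Union[np.ndarray, Tensor]) -> Union[np.ndarray,
                                                             Tensor]:
    """Batch covariance of activations: C_ij = (1/B) Σ_b (g_ib-μ_i)(g_jb-μ_j).

    The divisor is exactly B (population convention).  Returns the same
    type as the input.
    """
    was_tensor = isinstance(G, Tensor)
    Gt = as_tensor(G)
    B = Gt.shape[0]
    if B < 2:
        raise ValueError("covariance needs a batch of at least 2")
    mu = Gt.mean(axis=0, keepdims=True)
    D = Gt - mu
    C = (D.T @ D) / B
    return C if was_tensor else C.data


def decorrelation_loss(G: Union[np.ndarray, Tensor]) -> Union[float, Tensor]:
    """Half the sum of squared off-diagonal batch covariances:
    L = ½(‖C‖_F² − ‖diag C‖₂²) = ½ Σ_{i≠j} C_ij² ≥ 0."""
    was_tensor = isinstance(G, Tensor)
    C = covariance_matrix(as_tensor(G))
    eye = np.eye(C.shape[0])
    L = 0.5 * ((C ** 2).sum() - ((C * eye) ** 2).sum())
    return L if was_tensor else float(L.data)


def compute_gate_logits(params: ModelParams, r_T: np.ndarray) -> Tensor:
    """Gate logits from the latest (last non-padding) visit record:
    gate = W_gate r_T (linear, no bias)."""
    return as_tensor(r_T) @ params["W_gate"].T


def cumax(v: Union[np.ndarray, Tensor],
          axis: int = -1) -> Union[np.ndarray, Tensor]:
    """Cumulative softmax: cumsum(softmax(v)).

    Strictly positive, non-decreasing along ``axis``, last element 1 —
    the expectation of a binary split gate (0,…,0,1,…,1).
    """
    was_tensor = isinstance(v, Tensor)
    out = as_tensor(v).softmax(axis=axis).cumsum(axis=axis)
    return out if was_tensor else out.data


def gate_masks(logits: Union[np.ndarray, Tensor]
               ) -> Tuple[Union[np.ndarray, Tensor],
                          Union[np.ndarray, Tensor]]:
    """Complementary gates: gate_future = cumax(logits), gate_task = 1 − it."""
    gf = cumax(logits)
    return gf, 1.0 - gf


def fuse(g_future: Tensor, g_task: Tensor, gate_future, gate_task) -> Tensor:
    """s = gate_future ⊙ g_future + gate_task ⊙ g_task."""
    shapes = {np.shape(x.data if isinstance(x, Tensor) else x)[-1]
              for x in (g_future, g_task, gate_future, gate_task)}
    if len(shapes) != 1:
        raise ValueError(f"gate-space length mismatch: {sorted(shapes)}")
    return as_tensor(gate_future) * g_future + as_tensor(gate_task) * g_task


def predict_target(params: ModelParams, s: Tensor) -> Tensor:
    """Affine head + logistic squashing to a probability in (0, 1)."""
    return (s @ params["target_head.W"] + params["target_head.b"]).sigmoid()


def forward(params: ModelParams, batch: Batch,
            variant: Optional[str] = None) -> ForwardDiagnostics:
    """Full forward pass; ``variant`` overrides the config's variant."""
    variant = variant or params.config.variant
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    h_seq = encode_task(params, batch)
    h_T = _select_last(h_seq, batch.lengths)

    if variant == "context_minus":
        g_task = h_T @ params["W_t"].T
        y = predict_target(params, g_task).reshape(-1)
        return ForwardDiagnostics(
            h_f=None, h=h_seq, g_future=None, g_task=g_task,
            gate_logits=None, gate_future=None, gate_task=None,
            s=g_task, y_hat=y, r_hat_seq=None,
            patient_ids=list(batch.patient_ids))

    hf_seq = encode_future(params, batch)
    hf_T = _select_last(hf_seq, batch.lengths)
    g_future, g_task = project(params, hf_T, h_T)
    r_hat_seq = [predict_next_visit(params, hf) for hf in hf_seq]

    if variant == "gate_minus":
        s = concat([g_future, g_task], axis=1)
        y = predict_target(params, s).reshape(-1)
        return ForwardDiagnostics(
            h_f=hf_seq, h=h_seq, g_future=g_future, g_task=g_task,
            gate_logits=None, gate_future=None, gate_task=None,
            s=s, y_hat=y, r_hat_seq=r_hat_seq,
            patient_ids=list(batch.patient_ids))

    logits = compute_gate_logits(params, batch.last_records())
    gate_future, gate_task = gate_masks(logits)
    s = fuse(g_future, g_task, gate_future, gate_task)
    y = predict_target(params, s).reshape(-1)
    return ForwardDiagnostics(
        h_f=hf_seq, h=h_seq, g_future=g_future, g_task=g_task,
        gate_logits=logits, gate_future=gate_future, gate_task=gate_task,
        s=s, y_hat=y, r_hat_seq=r_hat_seq,
        patient_ids=list(batch.patient_ids))
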