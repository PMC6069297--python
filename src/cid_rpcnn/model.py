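"""The recurrent piecewise convolutional network for candidate scoring.

Per instance, the model embeds each token as the concatenation of a word
embedding (d_w) and two position embeddings (d_pc, d_pa) for the signed
distances to the chemical and disease marker blocks, convolves filter banks
of sizes 3 and 4 across the sequence, and pools each feature map.  Pooling is
*piecewise* (separately over windows starting in S-1, S0 and S1, outputs
concatenated) and optionally *attention-weighted*: with feature map F
(q filters x p positions), G = F^T M W_classes scores every position against
each relation class, A is the position-wise softmax of G per class, and the
pooled feature for filter t is max_j (F A)_{t,j}.  An LSTM then consumes the
per-instance vectors of a candidate in descending between-context-length
order; its final hidden state is the document-level candidate representation.
Knowledge-base bits are densified by one tanh layer and concatenated before a
single sigmoid output unit.

Ablation flags reduce the model to the plain-CNN baseline (``use_rnn=False``
scores only the shortest-gap instance through a learned projection) and
toggle piecewise pooling, attention and knowledge fusion independently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .candidates import Candidate, EncodedInstance

__all__ = [
    "ModelConfig",
    "RPCNNParams",
    "Batch",
    "forward",
    "embed",
    "convolve",
    "max_pool",
    "attention_pool",
    "instance_repr",
    "document_repr",
    "score",
]


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the published cross-validated optima."""

    d_w: int = 30
    d_pc: int = 5
    d_pa: int = 5
    filter_sizes: tuple[int, ...] = (3, 4)
    filters_per_size: int = 150
    hidden: int = 150
    dropout: float = 0.25
    knowledge_dense: int = 120
    n_classes: int = 2
    use_piecewise: bool = True
    use_attention: bool = True
    use_knowledge: bool = True
    use_rnn: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("d_w", "d_pc", "d_pa", "filters_per_size", "hidden",
                     "knowledge_dense", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.filter_sizes = tuple(self.filter_sizes)

    @property
    def token_dim(self) -> int:
        return self.d_w + self.d_pc + self.d_pa

    @property
    def n_segments(self) -> int:
        return 3 if self.use_piecewise else 1

    @property
    def z_dim(self) -> int:
        return self.n_segments * self.filters_per_size * len(self.filter_sizes)

    @property
    def fused_dim(self) -> int:
        return self.hidden + (self.knowledge_dense if self.use_knowledge else 0)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class RPCNNParams:
    """All learnable tensors, keyed by name; seed-deterministic init."""

    def __init__(
        self,
        config: ModelConfig,
        vocab_size: int,
        n_pos_buckets: int,
        kb_dim: int = 0,
        word_vectors: np.ndarray | None = None,
        dtype=np.float64,
    ):
        self.config = config
        self.vocab_size = vocab_size
        self.n_pos_buckets = n_pos_buckets
        self.kb_dim = kb_dim
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(config.seed)
        q, d = config.filters_per_size, config.token_dim
        p: dict[str, Tensor] = {}

        if word_vectors is not None:
            if word_vectors.shape != (vocab_size, config.d_w):
                raise ValueError(
                    f"word vectors shape {word_vectors.shape} != "
                    f"({vocab_size}, {config.d_w})"
                )
            ew = np.array(word_vectors, dtype=np.float64)
        else:
            ew = rng.uniform(-0.25, 0.25, size=(vocab_size, config.d_w))
        p["E_w"] = Tensor(ew, requires_grad=True)
        # position embeddings initialised from a uniform distribution
        p["E_c"] = Tensor(rng.uniform(-0.25, 0.25, (n_pos_buckets, config.d_pc)),
                          requires_grad=True)
        p["E_a"] = Tensor(rng.uniform(-0.25, 0.25, (n_pos_buckets, config.d_pa)),
                          requires_grad=True)
        for k in config.filter_sizes:
            p[f"W_conv{k}"] = Tensor(_glorot(rng, (k * d, q)), requires_grad=True)
            p[f"b_conv{k}"] = Tensor(np.zeros(q), requires_grad=True)
        if config.use_attention:
            # M from a uniform distribution, W_classes from the identity
            p["M"] = Tensor(rng.uniform(-0.1, 0.1, (q, q)), requires_grad=True)
            p["W_classes"] = Tensor(np.eye(q)[:, : config.n_classes].copy(),
                                    requires_grad=True)
        h = config.hidden
        if config.use_rnn:
            p["W_x"] = Tensor(_glorot(rng, (config.z_dim, 4 * h)), requires_grad=True)
            p["W_h"] = Tensor(_glorot(rng, (h, 4 * h)), requires_grad=True)
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            p["b_lstm"] = Tensor(b, requires_grad=True)
        else:
            p["W_proj"] = Tensor(_glorot(rng, (config.z_dim, h)), requires_grad=True)
            p["b_proj"] = Tensor(np.zeros(h), requires_grad=True)
        if config.use_knowledge:
            p["W_k"] = Tensor(_glorot(rng, (kb_dim, config.knowledge_dense)),
                              requires_grad=True)
            p["b_k"] = Tensor(np.zeros(config.knowledge_dense), requires_grad=True)
        # zero-initialised output layer: untrained candidates score exactly 0.5
        p["u"] = Tensor(np.zeros((config.fused_dim, 1)), requires_grad=True)
        p["b_u"] = Tensor(np.zeros(1), requires_grad=True)
        for t in p.values():
            t.data = t.data.astype(self.dtype)
        self.tensors = p
        self.vocab_words: list[str] | None = None

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def items(self):
        return self.tensors.items()

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def filter_bank(self, k: int) -> np.ndarray:
        """Filters for scale ``k`` as (q, k, token_dim) — the per-filter view."""
        q = self.config.filters_per_size
        return self.tensors[f"W_conv{k}"].data.T.reshape(q, k, self.config.token_dim)

    # -- persistence -------------------------------------------------------

    def save(self, path, vocab_words: list[str] | None = None) -> None:
        meta = {
            "config": asdict(self.config),
            "vocab_size": self.vocab_size,
            "n_pos_buckets": self.n_pos_buckets,
            "kb_dim": self.kb_dim,
            "vocab_words": vocab_words,
        }
        arrays = {name: t.data for name, t in self.tensors.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "RPCNNParams":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["filter_sizes"] = tuple(cfg_d["filter_sizes"])
            config = ModelConfig(**cfg_d)
            obj = cls(config, meta["vocab_size"], meta["n_pos_buckets"],
                      meta["kb_dim"])
            for name in obj.tensors:
                obj.tensors[name].data = np.array(archive[name])
            obj.dtype = obj.tensors["E_w"].data.dtype
            obj.vocab_words = meta.get("vocab_words")
        return obj


# ---------------------------------------------------------------------------
# batched forward pass
# ---------------------------------------------------------------------------


@dataclass
class Batch:
    """Flat instance arrays plus candidate grouping for one forward pass."""

    word_ids: np.ndarray  # (N, l)
    dc_ids: np.ndarray
    da_ids: np.ndarray
    seg_labels: np.ndarray
    mask: np.ndarray  # (N, l) 1 = real token
    groups: list[list[int]]  # per candidate, instance row indices (ordered)
    kbits: np.ndarray  # (B, kb_dim)
    labels: np.ndarray  # (B,)

    @property
    def n_instances(self) -> int:
        return self.word_ids.shape[0]

    @property
    def n_candidates(self) -> int:
        return len(self.groups)


def make_batch(
    cands: list[Candidate], kbits: np.ndarray | None = None
) -> Batch:
    """Stack the encoded instances of ``cands`` into flat arrays."""
    if not cands:
        raise ValueError("empty candidate batch")
    if any(not c.encoded for c in cands):
        raise ValueError("candidates must be encoded first (encode_instances)")
    insts: list[EncodedInstance] = []
    groups: list[list[int]] = []
    for c in cands:
        groups.append(list(range(len(insts), len(insts) + len(c.encoded))))
        insts.extend(c.encoded)
    if kbits is None:
        kbits = np.zeros((len(cands), 0))
    return Batch(
        word_ids=np.stack([e.word_ids for e in insts]),
        dc_ids=np.stack([e.dc_ids for e in insts]),
        da_ids=np.stack([e.da_ids for e in insts]),
        seg_labels=np.stack([e.seg_labels for e in insts]),
        mask=np.stack([e.mask for e in insts]),
        groups=groups,
        kbits=np.asarray(kbits, dtype=np.float64),
        labels=np.array([c.label for c in cands], dtype=np.float64),
    )


def _instance_vectors(batch: Batch, params: RPCNNParams, cfg: ModelConfig) -> Tensor:
    """CNN stage: embed, convolve, pool — returns z for every instance (N, z_dim)."""
    l = batch.word_ids.shape[1]
    dt = params.dtype
    x = concat(
        [
            params["E_w"].take_rows(batch.word_ids),
            params["E_c"].take_rows(batch.dc_ids),
            params["E_a"].take_rows(batch.da_ids),
        ],
        axis=-1,
    )  # (N, l, token_dim)
    pooled_parts: list[Tensor] = []
    for k in cfg.filter_sizes:
        if l < k:
            raise ValueError(f"sequence length {l} shorter than filter size {k}")
        p = l - k + 1
        windows = concat([x[:, i : p + i, :] for i in range(k)], axis=-1)
        feat = (windows @ params[f"W_conv{k}"] + params[f"b_conv{k}"]).relu()
        # a window is real iff its first token is (padding is trailing)
        valid = (batch.mask[:, :p] == 1)
        feat = feat * Tensor(valid[..., None].astype(dt))  # (N, p, q)
        if cfg.use_piecewise:
            seg_masks = [
                valid & (batch.seg_labels[:, :p] == s) for s in range(3)
            ]
        else:
            seg_masks = [valid]
        if cfg.use_attention:
            # (q, n_classes) first: the position scores are F (M W_classes)
            g_full = feat @ (params["M"] @ params["W_classes"])  # (N, p, n_classes)
        for seg_mask in seg_masks:
            if cfg.use_attention:
                a = g_full.masked_softmax(seg_mask[:, :, None], axis=1)
                fa = feat.transpose(0, 2, 1) @ a  # (N, q, n_classes)
                pooled = fa.masked_max(np.ones((1, 1, 1), dtype=bool), axis=2)
            else:
                pooled = feat.masked_max(seg_mask[:, :, None], axis=1)
            pooled_parts.append(pooled)  # (N, q)
    return concat(pooled_parts, axis=-1)  # (N, z_dim)


def _document_vectors(
    z: Tensor, batch: Batch, params: RPCNNParams, cfg: ModelConfig
) -> Tensor:
    """Recurrence stage: combine each candidate's instance vectors (B, hidden)."""
    n, b = batch.n_instances, batch.n_candidates
    dt = params.dtype
    zero_row = Tensor(np.zeros((1, cfg.z_dim), dtype=dt))
    z_pad = concat([z, zero_row], axis=0)
    if not cfg.use_rnn:
        last = np.array([g[-1] for g in batch.groups])
        z_last = z_pad.take_rows(last)
        return (z_last @ params["W_proj"] + params["b_proj"]).tanh()
    max_m = max(len(g) for g in batch.groups)
    gather = np.full((b, max_m), n, dtype=np.int64)
    step_mask = np.zeros((b, max_m))
    for i, g in enumerate(batch.groups):
        gather[i, : len(g)] = g
        step_mask[i, : len(g)] = 1.0
    hdim = cfg.hidden
    h = Tensor(np.zeros((b, hdim), dtype=dt))
    c = Tensor(np.zeros((b, hdim), dtype=dt))
    for t in range(max_m):
        zt = z_pad.take_rows(gather[:, t])
        gates = zt @ params["W_x"] + h @ params["W_h"] + params["b_lstm"]
        i_g = gates[:, :hdim].sigmoid()
        f_g = gates[:, hdim : 2 * hdim].sigmoid()
        g_g = gates[:, 2 * hdim : 3 * hdim].tanh()
        o_g = gates[:, 3 * hdim :].sigmoid()
        c_new = f_g * c + i_g * g_g
        h_new = o_g * c_new.tanh()
        m = Tensor(step_mask[:, t : t + 1].astype(dt))
        inv = Tensor((1.0 - step_mask[:, t : t + 1]).astype(dt))
        h = m * h_new + inv * h
        c = m * c_new + inv * c
    return h


def forward(
    batch: Batch,
    params: RPCNNParams,
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Full forward pass; returns the output logits (B,)."""
    z = _instance_vectors(batch, params, cfg)
    h = _document_vectors(z, batch, params, cfg)
    if cfg.use_knowledge:
        v = (Tensor(batch.kbits.astype(params.dtype)) @ params["W_k"] + params["b_k"]).tanh()
        fused = concat([h, v], axis=-1)
    else:
        fused = h
    if training and cfg.dropout > 0:
        if rng is None:
            raise ValueError("training forward pass needs an rng for dropout")
        fused = fused.dropout(cfg.dropout, rng, training=True)
    logits = fused @ params["u"] + params["b_u"]
    return logits.reshape(batch.n_candidates)


def predict_scores(
    batch: Batch, params: RPCNNParams, cfg: ModelConfig
) -> np.ndarray:
    """Sigmoid scores in (0, 1), evaluation mode (no dropout)."""
    return forward(batch, params, cfg, training=False).sigmoid().data


# ---------------------------------------------------------------------------
# functional single-instance surface (numpy in / numpy out)
# ---------------------------------------------------------------------------


def embed(inst: EncodedInstance, params: RPCNNParams) -> np.ndarray:
    """Token matrix (l, d_w + d_pc + d_pa): [word emb; chem-pos emb; dis-pos emb]."""
    for ids, bound, track in (
        (inst.word_ids, params.vocab_size, "word"),
        (inst.dc_ids, params.n_pos_buckets, "chemical-distance"),
        (inst.da_ids, params.n_pos_buckets, "disease-distance"),
    ):
        if ids.min() < 0 or ids.max() >= bound:
            raise IndexError(f"{track} index out of range [0, {bound})")
    return np.concatenate(
        [
            params["E_w"].data[inst.word_ids],
            params["E_c"].data[inst.dc_ids],
            params["E_a"].data[inst.da_ids],
        ],
        axis=1,
    )


def convolve(
    x: np.ndarray,
    filter_bank: np.ndarray,
    biases: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """ReLU convolution of a (q, k, d) filter bank over x (l, d) -> (q, l-k+1).

    F[t, i] = ReLU(<filter_t, x[i:i+k]> + b_t); windows consisting only of
    padding (mask 0 at the window start, padding being trailing) are forced
    to zero.
    """
    q, k, d = filter_bank.shape
    l = x.shape[0]
    if l < k:
        raise ValueError(f"sequence length {l} < filter size {k}")
    p = l - k + 1
    windows = np.stack([x[i : i + k].reshape(-1) for i in range(p)])  # (p, k*d)
    feat = np.maximum(windows @ filter_bank.reshape(q, -1).T + biases, 0.0).T
    if mask is not None:
        feat = feat * (np.asarray(mask)[:p] == 1)
    return feat


def max_pool(feature_map: np.ndarray) -> np.ndarray:
    """Max over positions for each filter; empty map -> zeros."""
    if feature_map.shape[1] == 0:
        return np.zeros(feature_map.shape[0])
    return feature_map.max(axis=1)


def attention_pool(
    feature_map: np.ndarray, m_matrix: np.ndarray, w_classes: np.ndarray
) -> np.ndarray:
    """Class-attention pooling of F (q, p) -> (q,).

    G = F^T M W_classes (p, n_classes); A = softmax of G over positions per
    class; pooled_t = max_j (F A)_{t, j}.  An empty map returns zeros.
    """
    q, p = feature_map.shape
    if p == 0:
        return np.zeros(q)
    g = feature_map.T @ m_matrix @ w_classes
    g = g - g.max(axis=0, keepdims=True)
    e = np.exp(g)
    a = e / e.sum(axis=0, keepdims=True)
    return (feature_map @ a).max(axis=1)


def instance_repr(
    inst: EncodedInstance, params: RPCNNParams, cfg: ModelConfig
) -> np.ndarray:
    """Pooled instance vector z (z_dim,), built from the functional pieces."""
    x = embed(inst, params)
    l = x.shape[0]
    parts: list[np.ndarray] = []
    for k in cfg.filter_sizes:
        fb = params.filter_bank(k)
        feat = convolve(x, fb, params[f"b_conv{k}"].data, mask=inst.mask)
        p = l - k + 1
        valid = inst.mask[:p] == 1
        if cfg.use_piecewise:
            col_sets = [valid & (inst.seg_labels[:p] == s) for s in range(3)]
        else:
            col_sets = [valid]
        for cols in col_sets:
            sub = feat[:, cols]
            if cfg.use_attention:
                parts.append(attention_pool(sub, params["M"].data,
                                            params["W_classes"].data))
            else:
                parts.append(max_pool(sub))
    return np.concatenate(parts)


def document_repr(
    z_list: list[np.ndarray], params: RPCNNParams, cfg: ModelConfig
) -> np.ndarray:
    """Candidate representation from ordered instance vectors (hidden,)."""
    if not z_list:
        raise ValueError("candidate with no instances")
    if not cfg.use_rnn:
        z = z_list[-1]
        return np.tanh(z @ params["W_proj"].data + params["b_proj"].data)
    hdim = cfg.hidden
    h = np.zeros(hdim)
    c = np.zeros(hdim)

    def sigm(v):
        return 1.0 / (1.0 + np.exp(-v))

    for z in z_list:
        gates = z @ params["W_x"].data + h @ params["W_h"].data + params["b_lstm"].data
        i_g, f_g = sigm(gates[:hdim]), sigm(gates[hdim : 2 * hdim])
        g_g, o_g = np.tanh(gates[2 * hdim : 3 * hdim]), sigm(gates[3 * hdim :])
        c = f_g * c + i_g * g_g
        h = o_g * np.tanh(c)
    return h


def score(
    h: np.ndarray,
    kfeat,
    params: RPCNNParams,
    cfg: ModelConfig,
) -> float:
    """Sigmoid probability for one candidate representation."""
    if cfg.use_knowledge:
        bits = kfeat.bits if hasattr(kfeat, "bits") else np.asarray(kfeat)
        v = np.tanh(bits @ params["W_k"].data + params["b_k"].data)
        fused = np.concatenate([h, v])
    else:
        fused = h
    logit = float(fused @ params["u"].data[:, 0] + params["b_u"].data[0])
    return float(1.0 / (1.0 + np.exp(-logit)))
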