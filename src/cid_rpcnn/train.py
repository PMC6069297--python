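"""Training loop, prediction, document-level evaluation, ablation harness.

The classifier is trained with mean binary cross-entropy on the sigmoid
output (Adam, default learning rate 1e-3), early-stopped on the F-score of a
development split.  Evaluation follows the document-level protocol of the
BioCreative V task: predicted-positive (pmid, chemical id, disease id)
triples are compared as a set against the gold triples, and precision,
recall and F are reported as percentages.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .candidates import Candidate
from .knowledge import FeatureLayout, KnowledgeTable, build_layout, featurize_pair
from .model import Batch, ModelConfig, RPCNNParams, forward, make_batch
from .pubtator import Document, EmbeddingTable

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    threshold: float = 0.5
    seed: int = 0
    patience: int = 5
    dev_fraction: float = 0.1
    pos_weight: float = 1.0
    precision: str = "single"  # "single" for speed, "double" for checking

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class Prediction:
    pmid: str
    chem_id: str
    dis_id: str
    score: float
    label_hat: int


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f: float = field(init=False)

    def __post_init__(self):
        p = 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        r = 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        f = 2.0 * p * r / (p + r) if p + r else 0.0
        self.precision, self.recall, self.f = p, r, f


def knowledge_bits(
    cands: Sequence[Candidate],
    tables: list[KnowledgeTable],
    layout: FeatureLayout | None = None,
) -> tuple[np.ndarray, FeatureLayout]:
    """Feature matrix (n_candidates, layout.width) for a candidate list."""
    if layout is None:
        layout = build_layout(tables)
    bits = np.zeros((len(cands), layout.width))
    for i, c in enumerate(cands):
        bits[i] = featurize_pair(c.chem_id, c.dis_id, tables, layout).bits
    return bits, layout


class _Adam:
    def __init__(self, params: RPCNNParams, lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self, params: RPCNNParams) -> None:
        self.t += 1
        for name, tensor in params.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _f_from_labels(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return EvalResult(tp, fp, fn).f


def _batched_scores(
    cands: Sequence[Candidate],
    kbits: np.ndarray,
    params: RPCNNParams,
    cfg: ModelConfig,
    batch_size: int,
) -> np.ndarray:
    out = np.empty(len(cands))
    for lo in range(0, len(cands), batch_size):
        hi = min(lo + batch_size, len(cands))
        batch = make_batch(list(cands[lo:hi]), kbits[lo:hi])
        out[lo:hi] = forward(batch, params, cfg).sigmoid().data
    return out


def train(
    cands: list[Candidate],
    vocab: EmbeddingTable,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    kb_tables: list[KnowledgeTable] | None = None,
    dev_cands: list[Candidate] | None = None,
    layout: FeatureLayout | None = None,
) -> tuple[RPCNNParams, list[dict]]:
    """Train on encoded candidates; returns the best-dev-F parameters.

    Word embeddings are initialised from ``vocab.vectors`` and fine-tuned.
    When no development split is supplied, ``dev_fraction`` of the training
    candidates is carved off with the training seed.
    """
    if not cands:
        raise ValueError("empty training set")
    tables = kb_tables or []
    rng = np.random.default_rng(train_cfg.seed)
    if dev_cands is None and train_cfg.dev_fraction > 0 and len(cands) >= 10:
        order = rng.permutation(len(cands))
        n_dev = max(1, int(round(train_cfg.dev_fraction * len(cands))))
        dev_cands = [cands[i] for i in order[:n_dev]]
        cands = [cands[i] for i in order[n_dev:]]

    l = cands[0].encoded[0].length
    params = RPCNNParams(
        model_cfg,
        vocab_size=vocab.vectors.shape[0],
        n_pos_buckets=2 * l,
        kb_dim=(build_layout(tables).width if layout is None else layout.width),
        word_vectors=vocab.vectors if vocab.vectors.shape[1] == model_cfg.d_w else None,
        dtype=np.float32 if train_cfg.precision == "single" else np.float64,
    )
    kbits, layout = knowledge_bits(cands, tables, layout)
    dev_bits = (
        knowledge_bits(dev_cands, tables, layout)[0] if dev_cands else None
    )
    dev_labels = (
        np.array([c.label for c in dev_cands], dtype=float) if dev_cands else None
    )
    opt = _Adam(params, train_cfg.learning_rate)
    weights = None
    if train_cfg.pos_weight != 1.0:
        weights = lambda y: np.where(y == 1, train_cfg.pos_weight, 1.0)  # noqa: E731

    best_f, best_f_loss, best_state = -1.0, np.inf, None
    min_dev_loss, patience_left = np.inf, train_cfg.patience
    log: list[dict] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(cands))
        losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            idx = order[lo : lo + train_cfg.batch_size]
            batch = make_batch([cands[i] for i in idx], kbits[idx])
            params.zero_grad()
            logits = forward(batch, params, model_cfg, training=True, rng=rng)
            w = weights(batch.labels) if weights is not None else None
            loss = logits.bce_with_logits(batch.labels, weights=w)
            loss.backward()
            opt.step(params)
            losses.append(float(loss.data))
        record = {"epoch": epoch, "loss": float(np.mean(losses))}
        if dev_cands:
            scores = _batched_scores(
                dev_cands, dev_bits, params, model_cfg, train_cfg.batch_size
            )
            dev_f = _f_from_labels(scores, dev_labels, train_cfg.threshold)
            eps = 1e-7
            s = np.clip(scores, eps, 1 - eps)
            dev_loss = float(
                -np.mean(dev_labels * np.log(s) + (1 - dev_labels) * np.log(1 - s))
            )
            record["dev_f"] = dev_f
            record["dev_loss"] = dev_loss
            # checkpoint: best dev F, ties broken by dev loss
            if dev_f > best_f or (dev_f == best_f and dev_loss < best_f_loss):
                best_f, best_f_loss = dev_f, dev_loss
                best_state = {k: t.data.copy() for k, t in params.items()}
            # patience: a falling dev loss still counts as progress, so the
            # thresholded F cannot starve training during warm-up
            if dev_f >= best_f or dev_loss < min_dev_loss - 1e-4:
                patience_left = train_cfg.patience
            else:
                patience_left -= 1
            min_dev_loss = min(min_dev_loss, dev_loss)
        log.append(record)
        logger.info("epoch %d: %s", epoch, record)
        if dev_cands and patience_left <= 0:
            break
    if best_state is not None:
        for name, tensor in params.items():
            tensor.data = best_state[name]
    return params, log


def predict(
    cands: Sequence[Candidate],
    params: RPCNNParams,
    model_cfg: ModelConfig,
    threshold: float = 0.5,
    kb_tables: list[KnowledgeTable] | None = None,
    layout: FeatureLayout | None = None,
    batch_size: int = 64,
) -> list[Prediction]:
    """Score every candidate (no dropout); one Prediction per candidate."""
    if not cands:
        return []
    kbits, _ = knowledge_bits(cands, kb_tables or [], layout)
    if params.kb_dim != kbits.shape[1]:
        raise ValueError(
            f"knowledge width {kbits.shape[1]} != model kb_dim {params.kb_dim}"
        )
    scores = _batched_scores(cands, kbits, params, model_cfg, batch_size)
    return [
        Prediction(c.pmid, c.chem_id, c.dis_id, float(s), int(s >= threshold))
        for c, s in zip(cands, scores)
    ]


def evaluate(predictions: Iterable[Prediction], docs: Sequence[Document]) -> EvalResult:
    """Document-level set comparison of predicted vs gold identifier triples."""
    known = {d.pmid for d in docs}
    gold = {(d.pmid, c, a) for d in docs for (c, a) in d.gold_pairs}
    predicted: set[tuple[str, str, str]] = set()
    for p in predictions:
        if p.pmid not in known:
            raise ValueError(f"prediction for unknown pmid {p.pmid}")
        if p.label_hat:
            predicted.add((p.pmid, p.chem_id, p.dis_id))
    tp = len(predicted & gold)
    return EvalResult(tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)


def write_predictions(predictions: Iterable[Prediction], path) -> None:
    """Positive predictions as PubTator relation lines (evaluator input)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in predictions:
            if p.label_hat:
                fh.write(f"{p.pmid}\tCID\t{p.chem_id}\t{p.dis_id}\n")


#: the ablation family: name -> (use_rnn, use_piecewise, use_attention)
DEFAULT_ABLATION_GRID: dict[str, tuple[bool, bool, bool]] = {
    "CNN": (False, False, False),
    "CNN+piecewise": (False, True, False),
    "CNN+attention": (False, False, True),
    "CNN+attention+piecewise": (False, True, True),
    "RPCNN": (True, True, True),
}


def run_ablation(
    train_cands: list[Candidate],
    test_cands: list[Candidate],
    test_docs: Sequence[Document],
    vocab: EmbeddingTable,
    kb_tables: list[KnowledgeTable],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    grid: dict[str, tuple[bool, bool, bool]] | None = None,
) -> pd.DataFrame:
    """Train and evaluate every model variant with and without knowledge.

    Returns a table with one row per variant and (knowledge setting, metric)
    column pairs, the shape of the usual piecewise/attention ablation report.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    grid = grid or DEFAULT_ABLATION_GRID
    columns = pd.MultiIndex.from_product(
        [["without knowledge", "with knowledge"], ["P", "R", "F"]]
    )
    rows = {}
    for name, (use_rnn, use_pw, use_att) in grid.items():
        row = []
        for use_kb in (False, True):
            cfg = replace(
                model_cfg,
                use_rnn=use_rnn,
                use_piecewise=use_pw,
                use_attention=use_att,
                use_knowledge=use_kb,
            )
            tables = kb_tables if use_kb else []
            params, _ = train(
                list(train_cands), vocab, cfg, copy.deepcopy(train_cfg), tables
            )
            preds = predict(
                test_cands, params, cfg, train_cfg.threshold, tables
            )
            res = evaluate(preds, test_docs)
            row.extend([res.precision, res.recall, res.f])
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
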