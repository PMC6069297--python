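"""Candidate generation and instance encoding.

A *candidate* is one (chemical identifier, disease identifier) pair within a
document; its *instances* are all mention-level cross pairs of that chemical
and that disease.  Each instance is rendered as a marked-up token sequence

    [ context before first mention | <ENTC> ... </ENTC> | context between |
      <ENTD> ... </ENTD> | context after second mention ]

where the before/after context is bounded by the enclosing sentence and the
between context spans the full text between the two mentions, even across
sentence boundaries.  Tokens carry a segment label (S-1 / S0 / S1) and two
signed token distances, one to the chemical marker block and one to the
disease block; both are 0 on their own block.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pubtator import (
    CHEMICAL,
    ENTC_CLOSE,
    ENTC_OPEN,
    ENTD_CLOSE,
    ENTD_OPEN,
    PAD,
    Document,
    EmbeddingTable,
    Mention,
)

SEG_BEFORE, SEG_BETWEEN, SEG_AFTER = 0, 1, 2
MARKER_TOKENS = frozenset({ENTC_OPEN, ENTC_CLOSE, ENTD_OPEN, ENTD_CLOSE})

#: words after which a sentence-final period does not end the sentence
DEFAULT_ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "et al", "vs", "fig", "dr", "approx", "ca", "no", "resp"}
)

_PUNCT = set(".,;:!?()[]{}\"'`%/")


def tokenize(text: str) -> list[str]:
    """Whitespace split, then peel leading/trailing punctuation into
    separate tokens.  Internal punctuation (hyphens, decimal points) stays."""
    tokens: list[str] = []
    for chunk in text.split():
        head: list[str] = []
        tail: list[str] = []
        while len(chunk) > 1 and chunk[0] in _PUNCT:
            head.append(chunk[0])
            chunk = chunk[1:]
        while len(chunk) > 1 and chunk[-1] in _PUNCT:
            tail.append(chunk[-1])
            chunk = chunk[:-1]
        tokens.extend(head)
        if chunk:
            tokens.append(chunk)
        tokens.extend(reversed(tail))
    return tokens


_SENT_BREAK = re.compile(r"[.!?]+(?=\s+[\"'(]?[A-Z0-9])")


def sentence_spans(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[int, int]]:
    """Character spans of sentences: break after sentence-final punctuation
    followed by whitespace and an uppercase letter or digit, unless the word
    before the period is a known abbreviation."""
    breaks: list[int] = []
    for m in _SENT_BREAK.finditer(text):
        prefix = text[: m.start()]
        last_word = prefix.rsplit(None, 1)[-1].rstrip(".").lower() if prefix.split() else ""
        if last_word in abbreviations:
            continue
        breaks.append(m.end())
    spans: list[tuple[int, int]] = []
    prev = 0
    for b in breaks:
        spans.append((prev, b))
        prev = b
    if prev < len(text):
        spans.append((prev, len(text)))
    if not spans:
        spans = [(0, len(text))]
    return spans


def _containing_sentence(spans: Sequence[tuple[int, int]], pos: int) -> tuple[int, int]:
    for s, e in spans:
        if s <= pos < e:
            return s, e
    return spans[-1]


@dataclass
class Instance:
    """One (chemical mention, disease mention) pair rendered for the model."""

    chem_mention: Mention
    dis_mention: Mention
    tokens: list[str]
    seg_labels: np.ndarray  # int, values in {0, 1, 2} = {S-1, S0, S1}
    d_c: np.ndarray  # signed token distance to the chemical marker block
    d_a: np.ndarray  # signed token distance to the disease marker block
    block1: tuple[int, int]  # token-index range of the first marker block
    block2: tuple[int, int]
    first_is_chem: bool
    between_len: int  # tokens strictly between the two blocks
    doc_order: int = 0  # tie-break key preserving document order

    @property
    def s_before(self) -> list[str]:
        return self.tokens[: self.block1[0]]

    @property
    def s_between(self) -> list[str]:
        return self.tokens[self.block1[1] : self.block2[0]]

    @property
    def s_after(self) -> list[str]:
        return self.tokens[self.block2[1] :]


@dataclass
class EncodedInstance:
    """Fixed-length index view of an :class:`Instance`."""

    word_ids: np.ndarray
    dc_ids: np.ndarray
    da_ids: np.ndarray
    seg_labels: np.ndarray
    mask: np.ndarray  # 1 = real token, 0 = padding
    between_len: int

    @property
    def length(self) -> int:
        return len(self.word_ids)


@dataclass
class Candidate:
    """A (chemical id, disease id) pair with its bag of instances."""

    pmid: str
    chem_id: str
    dis_id: str
    instances: list[Instance]
    label: int
    encoded: list[EncodedInstance] = field(default_factory=list)


def _block_distances(n: int, block: tuple[int, int]) -> np.ndarray:
    """Signed distances to a token block: 0 on the block, -k / +k outside."""
    idx = np.arange(n)
    d = np.zeros(n, dtype=np.int64)
    s, e = block
    d[idx < s] = idx[idx < s] - s
    d[idx >= e] = idx[idx >= e] - (e - 1)
    return d


def build_instance(
    doc: Document,
    chem: Mention,
    dis: Mention,
    spans: Sequence[tuple[int, int]] | None = None,
) -> Instance | None:
    """Render one mention pair; returns None (with a warning) on overlap."""
    if chem.start < dis.end and dis.start < chem.end:
        warnings.warn(
            f"pmid {doc.pmid}: overlapping mention spans "
            f"({chem.start},{chem.end}) / ({dis.start},{dis.end}); "
            "instance skipped",
            stacklevel=2,
        )
        return None
    text = doc.text
    if spans is None:
        spans = sentence_spans(text)
    first, second = (chem, dis) if chem.start < dis.start else (dis, chem)
    first_is_chem = first is chem
    sent1 = _containing_sentence(spans, first.start)
    sent2 = _containing_sentence(spans, second.start)

    before = tokenize(text[sent1[0] : first.start])
    open1, close1 = (ENTC_OPEN, ENTC_CLOSE) if first_is_chem else (ENTD_OPEN, ENTD_CLOSE)
    open2, close2 = (ENTD_OPEN, ENTD_CLOSE) if first_is_chem else (ENTC_OPEN, ENTC_CLOSE)
    blk1 = [open1, *tokenize(first.text), close1]
    between = tokenize(text[first.end : second.start])
    blk2 = [open2, *tokenize(second.text), close2]
    after = tokenize(text[second.end : sent2[1]])

    tokens = before + blk1 + between + blk2 + after
    b1 = (len(before), len(before) + len(blk1))
    b2 = (b1[1] + len(between), b1[1] + len(between) + len(blk2))
    seg = np.empty(len(tokens), dtype=np.int64)
    seg[: b1[1]] = SEG_BEFORE  # context before + first marker block
    seg[b1[1] : b2[1]] = SEG_BETWEEN  # between context + second marker block
    seg[b2[1] :] = SEG_AFTER
    chem_block, dis_block = (b1, b2) if first_is_chem else (b2, b1)
    return Instance(
        chem_mention=chem,
        dis_mention=dis,
        tokens=tokens,
        seg_labels=seg,
        d_c=_block_distances(len(tokens), chem_block),
        d_a=_block_distances(len(tokens), dis_block),
        block1=b1,
        block2=b2,
        first_is_chem=first_is_chem,
        between_len=len(between),
    )


def order_instances(instances: list[Instance]) -> list[Instance]:
    """Stable sort in descending between-context length (ties keep document
    order), so the recurrence ends on the shortest-gap instance."""
    return sorted(instances, key=lambda inst: -inst.between_len)


def generate_candidates(
    doc: Document, max_instances: int | None = None
) -> list[Candidate]:
    """All (chemical id, disease id) pairs of a document, with their
    mention-level instance bags and gold labels.

    Candidates are returned in lexicographic (chem_id, dis_id) order.  When
    ``max_instances`` is set, only that many shortest-gap instances are kept
    (the tail of the descending ordering).
    """
    spans = sentence_spans(doc.text)
    chem_map: dict[str, list[Mention]] = {}
    dis_map: dict[str, list[Mention]] = {}
    for m in doc.mentions:
        target = chem_map if m.etype == CHEMICAL else dis_map
        for ident in m.ids:
            target.setdefault(ident, []).append(m)
    out: list[Candidate] = []
    for cid in sorted(chem_map):
        for did in sorted(dis_map):
            instances: list[Instance] = []
            for cm in chem_map[cid]:
                for dm in dis_map[did]:
                    inst = build_instance(doc, cm, dm, spans)
                    if inst is not None:
                        inst.doc_order = len(instances)
                        instances.append(inst)
            if not instances:
                warnings.warn(
                    f"pmid {doc.pmid}: candidate ({cid}, {did}) has no "
                    "usable instance; dropped",
                    stacklevel=2,
                )
                continue
            instances = order_instances(instances)
            if max_instances is not None and len(instances) > max_instances:
                instances = instances[-max_instances:]
            out.append(
                Candidate(
                    pmid=doc.pmid,
                    chem_id=cid,
                    dis_id=did,
                    instances=instances,
                    label=int((cid, did) in doc.gold_pairs),
                )
            )
    return out


def corpus_tokens(cands: list[Candidate]) -> list[str]:
    """Sorted lowercased surface tokens over all instances (markers excluded);
    the vocabulary base for randomly initialised embeddings."""
    seen: set[str] = set()
    for cand in cands:
        for inst in cand.instances:
            for tok in inst.tokens:
                if tok not in MARKER_TOKENS:
                    seen.add(tok.lower())
    return sorted(seen)


def _truncate_window(inst: Instance, l: int, pmid: str) -> slice:
    """Center-truncation window of length ``l`` keeping both marker blocks."""
    core_start, core_end = inst.block1[0], inst.block2[1]
    core = core_end - core_start
    if core > l:
        raise ValueError(
            f"pmid {pmid}: marker-to-marker span ({core} tokens) exceeds "
            f"max length l={l}"
        )
    extra = l - core
    left = min(core_start, (extra + 1) // 2)
    right = min(len(inst.tokens) - core_end, extra - left)
    left = min(core_start, extra - right)  # re-balance leftover budget
    return slice(core_start - left, core_end + right)


def encode_instances(
    cands: list[Candidate],
    vocab: EmbeddingTable,
    l: int | str = "auto",
) -> list[list[EncodedInstance]]:
    """Encode every candidate's instances to fixed length ``l``.

    With ``l="auto"`` the corpus maximum instance length is used, so no
    truncation occurs.  Distances are clipped to [-(l-1), l-1] and mapped to
    2l-1 signed buckets; bucket 2l-1 is reserved for padding.  Results are
    also attached to each candidate's ``encoded`` attribute.
    """
    all_insts = [inst for c in cands for inst in c.instances]
    if l == "auto":
        if not all_insts:
            raise ValueError("cannot infer l from an empty candidate list")
        l = max(len(inst.tokens) for inst in all_insts)
    l = int(l)
    pad_word = vocab.vocab[PAD]
    pad_bucket = 2 * l - 1
    out: list[list[EncodedInstance]] = []
    for cand in cands:
        enc_list: list[EncodedInstance] = []
        for inst in cand.instances:
            window = (
                _truncate_window(inst, l, cand.pmid)
                if len(inst.tokens) > l
                else slice(0, len(inst.tokens))
            )
            tokens = inst.tokens[window]
            n = len(tokens)
            word_ids = np.full(l, pad_word, dtype=np.int64)
            for i, tok in enumerate(tokens):
                word_ids[i] = vocab.vocab[tok] if tok in MARKER_TOKENS else vocab.lookup(tok)
            dc = np.clip(inst.d_c[window], -(l - 1), l - 1) + (l - 1)
            da = np.clip(inst.d_a[window], -(l - 1), l - 1) + (l - 1)
            dc_ids = np.full(l, pad_bucket, dtype=np.int64)
            da_ids = np.full(l, pad_bucket, dtype=np.int64)
            dc_ids[:n], da_ids[:n] = dc, da
            seg = np.full(l, SEG_AFTER, dtype=np.int64)
            seg[:n] = inst.seg_labels[window]
            mask = np.zeros(l, dtype=np.int64)
            mask[:n] = 1
            enc_list.append(
                EncodedInstance(word_ids, dc_ids, da_ids, seg, mask, inst.between_len)
            )
        cand.encoded = enc_list
        out.append(enc_list)
    return out
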