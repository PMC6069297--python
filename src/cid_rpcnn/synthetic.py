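"""Synthetic PubTator corpora with planted chemical-induced-disease structure.

The generator emulates the *shape* of an annotated abstract corpus — typed
entity mentions with MeSH-style identifiers, multiple mentions per entity,
document-level relation labels, correlated knowledge tables — while keeping
the relation signal a fully controlled planted rule: a related pair has a
trigger word (e.g. ``induced``) somewhere in the context between one of its
chemical mentions and one of its disease mentions; unrelated pairs never do.

Each document carries one *focal* (chemical, disease) pair, positive with
probability ``prevalence``, plus optionally distractor entities on one side
that create guaranteed-negative candidates.  Mention placement is
constrained so that no negative candidate's between-context ever spans a
planted trigger (distractor diseases precede everything, distractor
chemicals follow everything, and in positive documents every focal chemical
mention precedes the trigger while every focal disease mention follows it).
This makes the labelling exactly recoverable from the between-context alone,
which is what lets a trivial independent classifier certify the corpus and a
trained model demonstrate end-to-end learnability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knowledge import KNOWN_TABLES, PRESENT, KnowledgeTable
from .pubtator import CHEMICAL, DISEASE, Document, Mention

__all__ = ["SynthConfig", "generate_corpus", "generate_worked_example"]


@dataclass
class SynthConfig:
    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (4, 7)
    chem_entities_per_doc: tuple[int, int] = (1, 2)
    dis_entities_per_doc: tuple[int, int] = (1, 2)
    mentions_per_entity: tuple[int, int] = (1, 3)
    words_per_sentence: tuple[int, int] = (5, 10)
    vocab_size: int = 200
    prevalence: float = 0.3  # probability the focal pair is related
    triggers: tuple[str, ...] = ("induced", "caused", "associated with")
    cross_sentence_fraction: float = 0.2
    kb_correlation: float = 0.9  # P(true pair listed in a knowledge table)
    kb_negative_rate: float | None = None  # default: kb_correlation / 10
    seed: int = 0

    def __post_init__(self):
        for name in ("sentences_per_doc", "chem_entities_per_doc",
                     "dis_entities_per_doc", "mentions_per_entity",
                     "words_per_sentence"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        for name in ("prevalence", "cross_sentence_fraction", "kb_correlation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_docs < 0 or self.vocab_size <= 0:
            raise ValueError("n_docs must be >= 0 and vocab_size positive")
        if self.kb_negative_rate is None:
            self.kb_negative_rate = self.kb_correlation / 10.0


@dataclass
class _Entity:
    ident: str
    etype: str
    surface: str


class _DocBuilder:
    """Accumulates sentences and renders text + character-exact mentions."""

    def __init__(self):
        self.sentences: list[list] = []  # elements: str or _Entity

    def add(self, *elements) -> None:
        self.sentences.append(list(elements))

    def render(self) -> tuple[str, list[tuple[_Entity, int, int]]]:
        parts: list[str] = []
        placed: list[tuple[_Entity, int, int]] = []
        pos = 0
        for si, sent in enumerate(self.sentences):
            if si > 0:
                parts.append(" ")
                pos += 1
            for ei, el in enumerate(sent):
                if ei > 0:
                    parts.append(" ")
                    pos += 1
                if isinstance(el, _Entity):
                    text = el.surface
                    placed.append((el, pos, pos + len(text)))
                else:
                    text = el
                    if ei == 0:
                        text = text[0].upper() + text[1:]
                parts.append(text)
                pos += len(text)
            parts.append(".")
            pos += 1
        return "".join(parts), placed


def _int(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def generate_corpus(
    cfg: SynthConfig,
) -> tuple[list[Document], list[KnowledgeTable]]:
    """Generate documents and matching knowledge tables, seed-deterministic."""
    rng = np.random.default_rng(cfg.seed)
    words = [f"w{i:04d}" for i in range(cfg.vocab_size)]

    def filler(n: int) -> list[str]:
        return [words[int(i)] for i in rng.integers(0, cfg.vocab_size, size=n)]

    # capacity: pair needs up to 2 sentences, every extra mention or
    # distractor mention needs room in a zone sentence (2 mentions each)
    max_zone_mentions = (
        (max(cfg.chem_entities_per_doc[1], cfg.dis_entities_per_doc[1]) - 1 + 2)
        * cfg.mentions_per_entity[1]
    )
    needed = 2 + (max_zone_mentions + 1) // 2
    if cfg.sentences_per_doc[1] < min(needed, 3):
        raise ValueError(
            f"sentences_per_doc upper bound {cfg.sentences_per_doc[1]} cannot "
            f"hold the configured entities (need up to {needed})"
        )

    id_counter = {"chem": 0, "dis": 0}

    def new_entity(etype: str) -> _Entity:
        key = "chem" if etype == CHEMICAL else "dis"
        id_counter[key] += 1
        digits = f"{id_counter[key]:05d}"
        ident = ("D0" if key == "chem" else "D5") + digits
        return _Entity(ident, etype, key + digits)

    docs: list[Document] = []
    pair_labels: dict[tuple[str, str], int] = {}
    for doc_i in range(cfg.n_docs):
        chem = new_entity(CHEMICAL)
        dis = new_entity(DISEASE)
        positive = bool(rng.random() < cfg.prevalence)
        cross = bool(rng.random() < cfg.cross_sentence_fraction)

        n_chem = _int(rng, cfg.chem_entities_per_doc)
        n_dis = _int(rng, cfg.dis_entities_per_doc)
        if n_chem > 1 and n_dis > 1:  # distractors on one side only
            if rng.random() < 0.5:
                n_chem = 1
            else:
                n_dis = 1
        dis_distractors = [new_entity(DISEASE) for _ in range(n_dis - 1)]
        chem_distractors = [new_entity(CHEMICAL) for _ in range(n_chem - 1)]

        b = _DocBuilder()

        def zone_sentences(ents_mentions: list[_Entity]) -> None:
            """Sentences holding up to two mentions each."""
            for lo in range(0, len(ents_mentions), 2):
                group = ents_mentions[lo : lo + 2]
                sent: list = filler(2)
                for e in group:
                    sent.append(e)
                    sent.extend(filler(_int(rng, (1, 3))))
                b.add(*sent)

        # zone A: distractor diseases, before everything else
        zone_sentences(
            [e for e in dis_distractors for _ in range(_int(rng, cfg.mentions_per_entity))]
        )
        # zone B: extra focal-chemical mentions (before the trigger)
        zone_sentences([chem] * (_int(rng, cfg.mentions_per_entity) - 1))
        # the pair sentence(s)
        trigger = str(rng.choice(cfg.triggers)) if positive else None
        if cross:
            b.add(*filler(2), chem, *filler(_int(rng, (1, 2))))
            mid: list = [*filler(1)]
            if trigger:
                mid.extend(trigger.split())
            else:
                mid.extend(filler(1))
            b.add(*mid, dis, *filler(_int(rng, (1, 2))))
        else:
            mid = trigger.split() if trigger else filler(_int(rng, (1, 2)))
            b.add(*filler(2), chem, *mid, dis, *filler(_int(rng, (1, 2))))
        # zone C: extra focal-disease mentions (after the trigger)
        zone_sentences([dis] * (_int(rng, cfg.mentions_per_entity) - 1))
        # zone D: distractor chemicals, after everything else
        zone_sentences(
            [e for e in chem_distractors for _ in range(_int(rng, cfg.mentions_per_entity))]
        )
        # pad with plain filler sentences up to the sampled count
        target = _int(rng, cfg.sentences_per_doc)
        while len(b.sentences) < target:
            b.add(*filler(_int(rng, cfg.words_per_sentence)))

        title = " ".join(filler(_int(rng, (3, 6))))
        title = title[0].upper() + title[1:] + "."
        abstract, placed = b.render()
        offset = len(title) + 1
        mentions = [
            Mention(start + offset, end + offset, ent.surface, ent.etype, (ent.ident,))
            for ent, start, end in placed
        ]
        mentions.sort(key=lambda m: (m.start, m.end))
        gold = {(chem.ident, dis.ident)} if positive else set()
        doc = Document(f"{9000000 + doc_i}", title, abstract, mentions, gold)
        doc.validate()
        docs.append(doc)

        # record every candidate pair of this document with its label
        chem_ids = {chem.ident} | {e.ident for e in chem_distractors}
        dis_ids = {dis.ident} | {e.ident for e in dis_distractors}
        for c in chem_ids:
            for d in dis_ids:
                pair_labels[(c, d)] = int((c, d) in gold)

    tables = _knowledge_tables(pair_labels, cfg, rng)
    return docs, tables


def _knowledge_tables(
    pair_labels: dict[tuple[str, str], int],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> list[KnowledgeTable]:
    """Tables listing true pairs with rate kb_correlation, others kb_negative_rate."""
    tables = [KnowledgeTable(name) for name in KNOWN_TABLES]
    for (c, d), label in sorted(pair_labels.items()):
        rate = cfg.kb_correlation if label else cfg.kb_negative_rate
        for table in tables:
            if rng.random() >= rate:
                continue
            if table.name == "CTD":
                tag = "marker/mechanism" if label else str(
                    rng.choice(["therapeutic", "inferred-association"])
                )
            else:
                tag = PRESENT
            table.add(c, d, tag)
    return [t for t in tables if t.entries]


_WORKED_TITLE = (
    "Cardiovascular complications associated with terbutaline treatment "
    "for preterm labor."
)
_WORKED_ABSTRACT = (
    "Severe cardiovascular complications occurred in eight of 160 patients "
    "treated with terbutaline for preterm labor. Associated corticosteroid "
    "therapy and twin gestations appear to be predisposing factors. "
    "Potential mechanisms of the pathophysiology are briefly discussed."
)
_WORKED_MENTIONS = (
    (0, 28, "Cardiovascular complications", DISEASE, "D002318"),
    (45, 56, "terbutaline", CHEMICAL, "D013726"),
    (71, 84, "preterm labor", DISEASE, "D007752"),
    (93, 121, "cardiovascular complications", DISEASE, "D002318"),
    (169, 180, "terbutaline", CHEMICAL, "D013726"),
    (185, 198, "preterm labor", DISEASE, "D007752"),
)


def generate_worked_example() -> Document:
    """The terbutaline / preterm-labor abstract used as the worked example.

    Two chemical mentions sharing one MeSH identifier and four disease
    mentions over two identifiers, so candidate generation yields exactly
    two identifier-level candidates with four instances each.  The gold
    relation is <D013726, D007752> (terbutaline, preterm labor).
    """
    doc = Document(
        pmid="6150641",
        title=_WORKED_TITLE,
        abstract=_WORKED_ABSTRACT,
        mentions=[
            Mention(s, e, t, ty, (i,)) for s, e, t, ty, i in _WORKED_MENTIONS
        ],
        gold_pairs={("D013726", "D007752")},
    )
    doc.validate()
    return doc
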