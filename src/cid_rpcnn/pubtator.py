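"""Reading and writing PubTator-format corpora and word-embedding files.

The PubTator plain-text layout (used by the BioCreative V chemical–disease
relation corpus, among others) stores one abstract per block::

    PMID|t|Title text
    PMID|a|Abstract text
    PMID<TAB>start<TAB>end<TAB>mention text<TAB>Chemical|Disease<TAB>MeSH id
    PMID<TAB>CID<TAB>chemical id<TAB>disease id
    <blank line>

Character offsets index into ``title + " " + abstract`` (the corpus
convention).  Mentions normalised to several MeSH identifiers carry them
joined by ``|``; mentions without an identifier (``-1``) are dropped at parse
time because identifier-level candidate generation cannot use them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

CHEMICAL = "Chemical"
DISEASE = "Disease"

#: tokens every vocabulary must contain, in fixed order
PAD, UNK = "PAD", "UNK"
ENTC_OPEN, ENTC_CLOSE = "<ENTC>", "</ENTC>"
ENTD_OPEN, ENTD_CLOSE = "<ENTD>", "</ENTD>"
RESERVED_TOKENS = (PAD, UNK, ENTC_OPEN, ENTC_CLOSE, ENTD_OPEN, ENTD_CLOSE)


class PubtatorFormatError(ValueError):
    """Raised for malformed corpus lines or span/text mismatches."""


@dataclass(frozen=True)
class Mention:
    """A typed entity mention with character span and MeSH identifiers."""

    start: int
    end: int
    text: str
    etype: str
    ids: tuple[str, ...]

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty span ({self.start}, {self.end})")
        if self.etype not in (CHEMICAL, DISEASE):
            raise ValueError(f"unknown entity type {self.etype!r}")
        if not self.ids:
            raise ValueError("mention without identifiers")


@dataclass
class Document:
    """One abstract: text, typed mentions, and gold CID identifier pairs."""

    pmid: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    gold_pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def text(self) -> str:
        """Concatenated ``title + " " + abstract`` that spans index into."""
        return self.title + " " + self.abstract

    def validate(self) -> None:
        text = self.text
        for m in self.mentions:
            if m.end > len(text) or text[m.start : m.end] != m.text:
                raise PubtatorFormatError(
                    f"pmid {self.pmid}: span ({m.start}, {m.end}) reads "
                    f"{text[m.start:m.end]!r}, annotation says {m.text!r}"
                )
        mention_ids = {i for m in self.mentions for i in m.ids}
        for c, d in self.gold_pairs:
            if c not in mention_ids or d not in mention_ids:
                warnings.warn(
                    f"pmid {self.pmid}: gold pair ({c}, {d}) references an "
                    "identifier with no mention",
                    stacklevel=2,
                )


@dataclass
class EmbeddingTable:
    """Word → row-index map plus the embedding matrix (one row per word)."""

    vocab: dict[str, int]
    vectors: np.ndarray

    @property
    def d_w(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.vocab

    def __len__(self) -> int:
        return len(self.vocab)

    def lookup(self, token: str) -> int:
        """Index for a surface token: reserved tokens as-is, else lowercased
        with UNK fallback."""
        if token in self.vocab:
            return self.vocab[token]
        return self.vocab.get(token.lower(), self.vocab[UNK])


def _blocks(lines: Iterable[str]) -> Iterator[list[tuple[int, str]]]:
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if line.strip() == "":
            if block:
                yield block
                block = []
        else:
            block.append((lineno, line))
    if block:
        yield block


def parse_pubtator(stream: IO[str] | Iterable[str]) -> list[Document]:
    """Parse a PubTator-format stream into :class:`Document` objects.

    Raises :class:`PubtatorFormatError` (naming the offending line number)
    for malformed lines and for mention spans that do not match the text.
    Relation lines with a type other than ``CID`` are ignored with a warning.
    """
    docs: list[Document] = []
    for block in _blocks(stream):
        title = abstract = pmid = None
        mentions: list[Mention] = []
        gold: set[tuple[str, str]] = set()
        for lineno, line in block:
            if "|t|" in line and "\t" not in line.split("|t|", 1)[0]:
                pmid, title = line.split("|t|", 1)
                continue
            if "|a|" in line and "\t" not in line.split("|a|", 1)[0]:
                pmid_a, abstract = line.split("|a|", 1)
                if pmid is not None and pmid_a != pmid:
                    raise PubtatorFormatError(
                        f"line {lineno}: abstract pmid {pmid_a} != title pmid {pmid}"
                    )
                pmid = pmid_a
                continue
            fields = line.split("\t")
            if len(fields) == 4 and not fields[1].isdigit():
                # relation line: PMID <TAB> TYPE <TAB> chem <TAB> dis
                _, rtype, chem, dis = fields
                if rtype != "CID":
                    warnings.warn(
                        f"line {lineno}: ignoring relation of type {rtype!r}",
                        stacklevel=2,
                    )
                    continue
                gold.add((chem, dis))
                continue
            if len(fields) < 6:
                raise PubtatorFormatError(
                    f"line {lineno}: expected a mention line with >=6 "
                    f"tab-separated fields, got {len(fields)}: {line!r}"
                )
            _, start_s, end_s, text, etype, ident = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PubtatorFormatError(
                    f"line {lineno}: non-integer offsets {start_s!r}, {end_s!r}"
                ) from exc
            ids = tuple(i for i in ident.split("|") if i and i != "-1")
            if not ids:
                logger.debug("line %d: dropping mention without identifier", lineno)
                continue
            if etype not in (CHEMICAL, DISEASE):
                raise PubtatorFormatError(
                    f"line {lineno}: unknown entity type {etype!r}"
                )
            mentions.append(Mention(start, end, text, etype, ids))
        if pmid is None or title is None:
            raise PubtatorFormatError(
                f"line {block[0][0]}: block without a PMID|t| title line"
            )
        mentions.sort(key=lambda m: (m.start, m.end))
        doc = Document(pmid, title, abstract or "", mentions, gold)
        doc.validate()
        docs.append(doc)
    return docs


def write_pubtator(docs: Iterable[Document]) -> str:
    """Serialise documents back to PubTator text (inverse of parsing)."""
    out: list[str] = []
    for doc in docs:
        out.append(f"{doc.pmid}|t|{doc.title}")
        out.append(f"{doc.pmid}|a|{doc.abstract}")
        for m in sorted(doc.mentions, key=lambda m: (m.start, m.end)):
            ident = "|".join(m.ids)
            out.append(f"{doc.pmid}\t{m.start}\t{m.end}\t{m.text}\t{m.etype}\t{ident}")
        for chem, dis in sorted(doc.gold_pairs):
            out.append(f"{doc.pmid}\tCID\t{chem}\t{dis}")
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


def read_pubtator_file(path) -> list[Document]:
    with open(path, encoding="utf-8") as fh:
        return parse_pubtator(fh)


def write_pubtator_file(docs: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_pubtator(docs))


def load_embeddings(
    stream: IO[str] | Iterable[str], d_w: int, seed: int = 0
) -> EmbeddingTable:
    """Load a word2vec-text-dialect embedding file.

    Each line is ``word v1 ... v_{d_w}``; an optional ``count dim`` header is
    tolerated and skipped.  Reserved tokens absent from the file receive rows
    drawn from a seeded uniform distribution on [-0.25, 0.25), so two loads
    with the same seed are bit-identical.
    """
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for i, raw in enumerate(stream):
        parts = raw.split()
        if not parts:
            continue
        if i == 0 and len(parts) == 2 and all(p.lstrip("-").isdigit() for p in parts):
            continue  # word2vec count header
        word, values = parts[0], parts[1:]
        if len(values) != d_w:
            raise PubtatorFormatError(
                f"embedding row for {word!r} has width {len(values)}, expected {d_w}"
            )
        if word in vocab:
            continue
        vocab[word] = len(rows)
        rows.append(np.array(values, dtype=np.float64))
    rng = np.random.default_rng(seed)
    for token in RESERVED_TOKENS:
        if token not in vocab:
            vocab[token] = len(rows)
            rows.append(rng.uniform(-0.25, 0.25, size=d_w))
    matrix = np.vstack(rows) if rows else np.zeros((0, d_w))
    return EmbeddingTable(vocab, matrix)


def random_embeddings(
    words: Iterable[str], d_w: int = 30, seed: int = 0
) -> EmbeddingTable:
    """Build a uniformly initialised table over ``words`` + reserved tokens."""
    rng = np.random.default_rng(seed)
    vocab: dict[str, int] = {}
    for token in RESERVED_TOKENS:
        vocab[token] = len(vocab)
    for w in words:
        w = w.lower() if w not in RESERVED_TOKENS else w
        if w not in vocab:
            vocab[w] = len(vocab)
    vectors = rng.uniform(-0.25, 0.25, size=(len(vocab), d_w))
    return EmbeddingTable(vocab, vectors)
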