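"""Term spaces, documents, term matching, and synthetic corpus generation.

A :class:`TermSpace` is a named, colored, ordered vocabulary of lowercase
phrases.  A :class:`Corpus` is a list of plain-text documents standing in
for pages returned by a search backend.  Matching is presence-based: a
phrase matches a document if its token sequence occurs contiguously in the
case-folded, tokenized text, and counts once per document regardless of
repetition.

The synthetic generator plants exact per-pair co-occurrence counts so that
downstream counting can be validated against known truth.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RGB",
    "TermSpace",
    "Document",
    "Corpus",
    "PlantedSpec",
    "normalize_term",
    "tokenize",
    "load_term_space",
    "save_term_space",
    "match_terms",
    "generate_synthetic_corpus",
    "load_corpus",
    "save_corpus",
]

RGB = tuple[int, int, int]

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Case-fold and split on non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


def normalize_term(term: str) -> str:
    """Canonical form of a term: lowercased, whitespace/punctuation collapsed."""
    return " ".join(tokenize(term))


def _check_color(color: Sequence[int]) -> RGB:
    if len(color) != 3 or any(not (0 <= int(c) <= 255) for c in color):
        raise ValueError(f"invalid RGB color {color!r}: need 3 channels in [0, 255]")
    return (int(color[0]), int(color[1]), int(color[2]))


@dataclass(frozen=True)
class TermSpace:
    """A named list of unique normalized terms with a display color."""

    name: str
    category: str
    color: RGB
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "color", _check_color(self.color))
        normalized = tuple(normalize_term(t) for t in self.terms)
        if not normalized:
            raise ValueError(f"empty term space {self.name!r}")
        if any(not t for t in normalized):
            raise ValueError(f"term space {self.name!r} contains a blank term")
        seen: set[str] = set()
        dups = sorted({t for t in normalized if t in seen or seen.add(t)})  # type: ignore[func-returns-value]
        if dups:
            raise ValueError(
                f"duplicate terms after normalization in {self.name!r}: {', '.join(dups)}"
            )
        object.__setattr__(self, "terms", normalized)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in set(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class Document:
    id: str
    text: str
    url: str | None = None


@dataclass
class Corpus:
    """An id-indexed collection of documents."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate document ids: {', '.join(dups)}")

    @property
    def size(self) -> int:
        return len(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


def load_term_space(
    path: str | Path, name: str, category: str, color: RGB
) -> TermSpace:
    """Read a one-term-per-line UTF-8 file into a :class:`TermSpace`.

    Blank lines are ignored; terms are normalized and must be unique after
    normalization.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` for an empty list or duplicates (naming the duplicates).
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    terms = tuple(ln for ln in lines if ln)
    if not terms:
        raise ValueError(f"empty term space in {path}")
    return TermSpace(name=name, category=category, color=color, terms=terms)


def save_term_space(space: TermSpace, path: str | Path) -> None:
    Path(path).write_text("\n".join(space.terms) + "\n", encoding="utf-8")


def _term_token_seqs(space: TermSpace) -> list[tuple[str, tuple[str, ...]]]:
    return [(t, tuple(t.split(" "))) for t in space.terms]


def _contains_seq(tokens: Sequence[str], seq: Sequence[str]) -> bool:
    n, m = len(tokens), len(seq)
    if m == 0 or m > n:
        return False
    first = seq[0]
    for i in range(n - m + 1):
        if tokens[i] == first and tuple(tokens[i : i + m]) == tuple(seq):
            return True
    return False


def match_terms(doc: Document, space: TermSpace) -> set[str]:
    """Set of space terms whose token sequence occurs contiguously in the doc.

    Presence semantics: each term matches at most once.
    """
    tokens = tokenize(doc.text)
    if not tokens:
        return set()
    token_set = set(tokens)
    matched: set[str] = set()
    for term, seq in _term_token_seqs(space):
        if seq[0] not in token_set:
            continue
        if len(seq) == 1 or _contains_seq(tokens, seq):
            matched.add(term)
    return matched


@dataclass(frozen=True)
class PlantedSpec:
    """Target per-pair document counts for synthetic corpus generation."""

    pair_counts: Mapping[tuple[str, str], int]
    noise_docs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_docs < 0:
            raise ValueError("noise_docs must be >= 0")
        for pair, count in self.pair_counts.items():
            if count < 0:
                raise ValueError(f"negative planted count for pair {pair!r}")


# Filler vocabulary uses a reserved prefix so no filler token can ever be a
# term token; documents are readable gibberish, not matches.
_FILLER_WORDS = [f"zz{w}" for w in (
    "lorem", "ipsum", "dolor", "amet", "consectetur", "adipiscing", "elit",
    "tempor", "incididunt", "labore", "magna", "aliqua", "veniam", "nostrud",
)]


def generate_synthetic_corpus(
    spec: PlantedSpec, space_a: TermSpace, space_b: TermSpace
) -> Corpus:
    """Build a corpus with exactly the planted cross-space co-occurrences.

    For each pair ``(a, b)`` in ``spec.pair_counts`` there are exactly that
    many documents matching both ``a`` and ``b`` and no other cross-space
    pair.  ``spec.noise_docs`` extra documents match terms from at most one
    space.  Deterministic for a given ``spec.seed``.
    """
    a_terms = set(space_a.terms)
    b_terms = set(space_b.terms)
    norm_pairs: list[tuple[str, str, int]] = []
    for (x, y), count in spec.pair_counts.items():
        nx_, ny = normalize_term(x), normalize_term(y)
        if nx_ in a_terms and ny in b_terms:
            a, b = nx_, ny
        elif ny in a_terms and nx_ in b_terms:
            a, b = ny, nx_
        else:
            raise ValueError(f"pair ({x!r}, {y!r}) not covered by the two term spaces")
        norm_pairs.append((a, b, count))
    norm_pairs.sort()

    rng = random.Random(spec.seed)
    docs: list[Document] = []

    def filler(k: int) -> list[str]:
        return [rng.choice(_FILLER_WORDS) for _ in range(k)]

    def build_doc(doc_id: str, phrases: list[str]) -> Document:
        words: list[str] = filler(rng.randint(2, 6))
        for p in phrases:
            words.append(p)
            words += filler(rng.randint(2, 6))
        return Document(id=doc_id, text=" ".join(words))

    serial = 0
    for a, b, count in norm_pairs:
        for _ in range(count):
            phrases = [a, b]
            rng.shuffle(phrases)
            doc = build_doc(f"doc{serial:06d}", phrases)
            serial += 1
            _assert_exact(doc, space_a, space_b, {a}, {b})
            docs.append(doc)

    for _ in range(spec.noise_docs):
        choice = rng.random()
        if choice < 1 / 3:
            phrases, want_a, want_b = [], set(), set()
        elif choice < 2 / 3:
            t = rng.choice(space_a.terms)
            phrases, want_a, want_b = [t], {t}, set()
        else:
            t = rng.choice(space_b.terms)
            phrases, want_a, want_b = [t], set(), {t}
        doc = build_doc(f"doc{serial:06d}", phrases)
        serial += 1
        _assert_exact(doc, space_a, space_b, want_a, want_b)
        docs.append(doc)

    return Corpus(documents=docs)


def _assert_exact(
    doc: Document,
    space_a: TermSpace,
    space_b: TermSpace,
    want_a: set[str],
    want_b: set[str],
) -> None:
    got_a = match_terms(doc, space_a)
    got_b = match_terms(doc, space_b)
    if got_a != want_a or got_b != want_b:
        raise ValueError(
            "cannot plant exact counts: planted phrases collide with other "
            f"terms (document would match A={sorted(got_a)}, B={sorted(got_b)}; "
            f"wanted A={sorted(want_a)}, B={sorted(want_b)}). Term spaces with "
            "one term a sub-phrase of another are not supported by the generator."
        )


def load_corpus(path: str | Path) -> Corpus:
    """Load a corpus from a directory of ``.txt`` files or a JSON-lines file.

    Directory mode: each ``*.txt`` file becomes one document whose id is the
    file stem.  JSONL mode: one object per line with fields ``id``,
    optional ``url``, and ``text``.
    """
    path = Path(path)
    if path.is_dir():
        docs = [
            Document(id=p.stem, text=p.read_text(encoding="utf-8"))
            for p in sorted(path.glob("*.txt"))
        ]
        return Corpus(documents=docs)
    if not path.exists():
        raise FileNotFoundError(path)
    docs = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}:{lineno}: invalid JSON line: {exc}") from exc
        if "id" not in obj or "text" not in obj:
            raise ValueError(f"{path}:{lineno}: document needs 'id' and 'text' fields")
        docs.append(Document(id=str(obj["id"]), text=obj["text"], url=obj.get("url")))
    return Corpus(documents=docs)


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON-lines (id, url, text per line)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in corpus:
            rec: dict[str, str] = {"id": doc.id}
            if doc.url is not None:
                rec["url"] = doc.url
            rec["text"] = doc.text
            fh.write(json.dumps(rec, sort_keys=False) + "\n")
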