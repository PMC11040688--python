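"""Readers and writers for every external format the pipeline touches.

On-disk dialects (all UTF-8, LF line endings):

* n-gram corpus — one record per line, ``tok1 .. tokN<TAB>count``,
  mirroring the layout of the public Google n-gram distributions;
* statement table — CSV (or TSV) with header
  ``statement_id,text,theme,accuracy``;
* rating list — TSV ``word<TAB>rating`` with declared scale bounds;
* construct word list — one word per line.

Tokenisation policy lives here as well, because every stage that looks
at raw text (n-gram extraction, statement embedding, keyword tests) must
tokenise identically.  Tokens are compared after Unicode NFC
normalisation and, by default, lower-casing; punctuation is stripped
except intra-word apostrophes/hyphens.  Transcription pauses written as
``...`` or ``…`` are kept as a filler token: downstream keyword analysis
treats fillers as words, so the tokenizer must not discard them.
"""

from __future__ import annotations

import csv
import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

from .errors import InputFormatError

__all__ = [
    "ELLIPSIS",
    "Tokenizer",
    "make_tokenizer",
    "default_tokenizer",
    "NGramRecord",
    "NGramCorpus",
    "StatementRecord",
    "RatingList",
    "ConstructWordList",
    "read_ngram_corpus",
    "write_ngram_corpus",
    "read_statements",
    "write_statements",
    "read_rating_list",
    "write_rating_list",
    "read_word_list",
    "write_word_list",
]

# ---------------------------------------------------------------------------
# Tokenisation
# ---------------------------------------------------------------------------

ELLIPSIS = "…"

Tokenizer = Callable[[str], list[str]]

# runs of three-or-more dots, or a literal ellipsis character
_FILLER_DOTS = re.compile(r"(?:\.{3,}|…)")
# everything that is not a word character, apostrophe or hyphen
_STRIP = re.compile(r"[^\w'\-]+", re.UNICODE)


def make_tokenizer(*, lowercase: bool = True) -> Tokenizer:
    """Build a whitespace tokenizer with the package's normalisation policy.

    Lower-casing is a switch (not hard-wired) so that the corpus-level
    case policy stays auditable; every consumer accepts an injected
    tokenizer for the same reason.
    """

    def tokenize(text: str) -> list[str]:
        text = unicodedata.normalize("NFC", text)
        if lowercase:
            text = text.lower()
        text = _FILLER_DOTS.sub(f" {ELLIPSIS} ", text)
        out: list[str] = []
        for raw in text.split():
            if raw == ELLIPSIS:
                out.append(raw)
                continue
            cleaned = _STRIP.sub("", raw).strip("'-")
            if cleaned:
                out.append(cleaned)
        return out

    return tokenize


#: Module-level default: NFC + lower-case, fillers kept.
default_tokenizer: Tokenizer = make_tokenizer()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NGramRecord:
    """A fixed-length token tuple with its corpus count."""

    tokens: tuple[str, ...]
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"n-gram count must be >= 1, got {self.count}")
        for tok in self.tokens:
            if "\t" in tok or "\n" in tok:
                raise ValueError(f"token contains tab/newline: {tok!r}")


class NGramCorpus:
    """A multiset of fixed-length token tuples with counts.

    Duplicate grams are summed on insertion (sharded distributions may
    repeat lines).  Iteration order is insertion order, which makes
    writes reproducible.
    """

    def __init__(self, n: int, records: Iterable[NGramRecord] = ()) -> None:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        self.n = n
        self._counts: dict[tuple[str, ...], int] = {}
        for rec in records:
            self.add(rec.tokens, rec.count)

    def add(self, tokens: tuple[str, ...] | Iterable[str], count: int = 1) -> None:
        tokens = tuple(tokens)
        if len(tokens) != self.n:
            raise ValueError(
                f"expected {self.n} tokens per gram, got {len(tokens)}: {tokens!r}"
            )
        NGramRecord(tokens, count)  # validation
        self._counts[tokens] = self._counts.get(tokens, 0) + count

    def items(self) -> Iterator[tuple[tuple[str, ...], int]]:
        return iter(self._counts.items())

    @property
    def records(self) -> list[NGramRecord]:
        return [NGramRecord(t, c) for t, c in self._counts.items()]

    def count(self, tokens: Iterable[str]) -> int:
        return self._counts.get(tuple(tokens), 0)

    def total_count(self) -> int:
        """Sum of gram counts (token occurrences = total_count * n)."""
        return sum(self._counts.values())

    def __len__(self) -> int:  # number of distinct grams
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NGramCorpus):
            return NotImplemented
        return self.n == other.n and self._counts == other._counts

    def __repr__(self) -> str:
        return f"NGramCorpus(n={self.n}, distinct={len(self)}, total={self.total_count()})"


@dataclass(frozen=True)
class StatementRecord:
    """One verifiable eyewitness statement with its accuracy code.

    ``accuracy`` is binary: 1 = the statement matches the witnessed
    event, 0 = it does not.  ``theme`` is the topical category used to
    define cross-validation folds (e.g. "clothes", "weapons").
    """

    statement_id: str
    text: str
    theme: str
    accuracy: int

    def __post_init__(self) -> None:
        if self.accuracy not in (0, 1):
            raise ValueError(
                f"accuracy must be 0 or 1, got {self.accuracy!r} "
                f"(statement {self.statement_id})"
            )
        if not self.text:
            raise ValueError(f"statement {self.statement_id} has empty text")


@dataclass(frozen=True)
class RatingList:
    """Words rated on a construct scale (e.g. dominance on 1-9)."""

    name: str
    entries: Mapping[str, float]
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        bad = [
            w
            for w, r in self.entries.items()
            if not (self.scale_min <= r <= self.scale_max)
        ]
        if bad:
            raise InputFormatError(
                f"ratings outside [{self.scale_min}, {self.scale_max}] "
                f"in list {self.name!r}: {', '.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ConstructWordList:
    """A plain word set defining a construct (e.g. communion)."""

    name: str
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"construct list {self.name!r} is empty")
        if len(set(self.words)) != len(self.words):
            dupes = sorted({w for w in self.words if list(self.words).count(w) > 1})
            raise ValueError(f"duplicate words in list {self.name!r}: {dupes}")


# ---------------------------------------------------------------------------
# n-gram corpus I/O
# ---------------------------------------------------------------------------


def read_ngram_corpus(path: str | Path, n: int = 5) -> NGramCorpus:
    """Parse an n-gram TSV (``tok1 .. tokN<TAB>count``) into a corpus.

    Malformed lines (wrong token count, non-integer or non-positive
    count) raise :class:`InputFormatError` naming the line number.
    Duplicate grams are summed.  An empty file yields an empty corpus
    with a warning.
    """
    path = Path(path)
    corpus = NGramCorpus(n)
    n_lines = 0
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 'tokens<TAB>count', got {line!r}"
                )
            tokens = tuple(parts[0].split(" "))
            if len(tokens) != n or any(not t for t in tokens):
                raise InputFormatError(
                    f"{path}:{lineno}: expected {n} space-separated tokens, "
                    f"got {len([t for t in tokens if t])}"
                )
            try:
                count = int(parts[1])
            except ValueError:
                raise InputFormatError(
                    f"{path}:{lineno}: count is not an integer: {parts[1]!r}"
                ) from None
            if count < 1:
                raise InputFormatError(f"{path}:{lineno}: count must be >= 1, got {count}")
            corpus.add(tokens, count)
    if n_lines == 0:
        warnings.warn(f"{path}: empty n-gram file, returning empty corpus", stacklevel=2)
    return corpus


def write_ngram_corpus(corpus: NGramCorpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for tokens, count in corpus.items():
            fh.write(" ".join(tokens) + "\t" + str(count) + "\n")


# ---------------------------------------------------------------------------
# Statement table I/O
# ---------------------------------------------------------------------------

_STATEMENT_COLUMNS = ("statement_id", "text", "theme", "accuracy")


def read_statements(path: str | Path) -> list[StatementRecord]:
    """Read a statement table (CSV, or TSV if the header contains a tab).

    Enforces unique statement ids and binary accuracy codes.
    """
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        head = fh.readline()
        delim = "\t" if "\t" in head else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise InputFormatError(f"{path}: empty statement table")
        missing = [c for c in _STATEMENT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise InputFormatError(f"{path}: missing columns {missing}")
        records: list[StatementRecord] = []
        seen: set[str] = set()
        for row in reader:
            sid = (row["statement_id"] or "").strip()
            if not sid:
                raise InputFormatError(f"{path}: blank statement_id at row {reader.line_num}")
            if sid in seen:
                raise InputFormatError(f"{path}: duplicate statement_id {sid!r}")
            seen.add(sid)
            acc_raw = (row["accuracy"] or "").strip()
            if acc_raw not in ("0", "1"):
                raise InputFormatError(
                    f"{path}: accuracy must be 0 or 1, got {acc_raw!r} (statement {sid})"
                )
            try:
                rec = StatementRecord(
                    statement_id=sid,
                    text=row["text"] or "",
                    theme=(row["theme"] or "").strip(),
                    accuracy=int(acc_raw),
                )
            except ValueError as exc:
                raise InputFormatError(f"{path}: {exc}") from None
            records.append(rec)
    return records


def write_statements(statements: Iterable[StatementRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_STATEMENT_COLUMNS)
        for rec in statements:
            writer.writerow([rec.statement_id, rec.text, rec.theme, rec.accuracy])


# ---------------------------------------------------------------------------
# Rating list / construct list I/O
# ---------------------------------------------------------------------------


def read_rating_list(
    path: str | Path,
    scale_min: float,
    scale_max: float,
    name: str | None = None,
) -> RatingList:
    """Read a two-column TSV ``word<TAB>rating`` with declared bounds.

    Out-of-bounds ratings raise :class:`InputFormatError` listing the
    offending words; duplicate words are rejected.
    """
    path = Path(path)
    entries: dict[str, float] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 'word<TAB>rating', got {line!r}"
                )
            word = parts[0]
            if word in entries:
                raise InputFormatError(f"{path}:{lineno}: duplicate word {word!r}")
            try:
                entries[word] = float(parts[1])
            except ValueError:
                raise InputFormatError(
                    f"{path}:{lineno}: rating is not a number: {parts[1]!r}"
                ) from None
    return RatingList(
        name=name or path.stem,
        entries=entries,
        scale_min=scale_min,
        scale_max=scale_max,
    )


def write_rating_list(ratings: RatingList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for word, rating in ratings.entries.items():
            fh.write(f"{word}\t{rating!r}\n")


def read_word_list(path: str | Path, name: str | None = None) -> ConstructWordList:
    """Read a one-word-per-line construct list (blank lines skipped)."""
    path = Path(path)
    words: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            word = line.strip()
            if word:
                words.append(word)
    try:
        return ConstructWordList(name=name or path.stem, words=tuple(words))
    except ValueError as exc:
        raise InputFormatError(f"{path}: {exc}") from None


def write_word_list(word_list: ConstructWordList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for word in word_list.words:
            fh.write(word + "\n")
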