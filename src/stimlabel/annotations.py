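"""Word-annotation parsing and sentence reconstruction.

Naturalistic movie-watching datasets distribute the stimulus dialogue as a
word-annotation table: one row per spoken word with its onset and offset in
seconds relative to scan start.  Sentiment is a sentence-level property, so
the words must be regrouped into sentences before scoring.  Two boundary
conventions are supported: an explicit sentence-end flag column, or terminal
punctuation (. ? !) on the token itself.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: default column-name mapping for annotation tables; override via config
DEFAULT_COLUMNS = {
    "word": "word",
    "onset": "onset",
    "offset": "offset",
    "sentence_end": "sentence_end",
}

TERMINAL_PUNCTUATION = (".", "?", "!")


class AnnotationFormatError(ValueError):
    """Raised when an annotation file is missing required columns."""


class AnnotationValidationError(ValueError):
    """Raised when a row violates a timing invariant (offset < onset)."""


@dataclass(frozen=True)
class WordAnnotation:
    """A single stimulus word with its presentation timing in seconds."""

    token: str
    onset: float
    offset: float
    is_sentence_end: bool = False

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise AnnotationValidationError(
                f"offset {self.offset} precedes onset {self.onset} "
                f"for token {self.token!r}"
            )


@dataclass(frozen=True)
class Sentence:
    """An ordered run of words forming one dialogue sentence.

    Duration is first-word onset to last-word offset; inter-word silence
    inside the sentence is included.  Sentences may overlap in time.
    """

    words: tuple[WordAnnotation, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("a Sentence needs at least one word")

    @property
    def text(self) -> str:
        return " ".join(w.token for w in self.words)

    @property
    def onset(self) -> float:
        return self.words[0].onset

    @property
    def offset(self) -> float:
        return self.words[-1].offset

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def n_words(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class SubtitleStats:
    """Corpus-level summary: word/second totals plus per-sentence moments."""

    n_sentences: int
    n_words: int
    n_seconds: float
    length_min: int
    length_max: int
    length_mean: float
    length_sd: float
    duration_min: float
    duration_max: float
    duration_mean: float
    duration_sd: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def parse_word_annotations(
    path: str | Path,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> list[WordAnnotation]:
    """Read a word-annotation CSV/TSV into :class:`WordAnnotation` rows.

    Parameters
    ----------
    path:
        Annotation table with a header row.  The separator is sniffed from
        the extension (``.tsv`` → tab, else comma) unless ``sep`` is given.
    columns:
        Mapping from the logical names ``word``/``onset``/``offset`` (and
        optionally ``sentence_end``) to the file's column names.

    Raises
    ------
    AnnotationFormatError
        If a required column is absent.
    AnnotationValidationError
        If any row has ``offset < onset`` (reported with its row index).
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty and df.columns.size == 0:
        return []
    for logical in ("word", "onset", "offset"):
        if cols[logical] not in df.columns:
            raise AnnotationFormatError(
                f"annotation file {path.name} lacks required column "
                f"{cols[logical]!r} (for {logical})"
            )
    has_end = cols["sentence_end"] in df.columns
    out: list[WordAnnotation] = []
    prev_onset = -math.inf
    for idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        onset = float(rec[cols["onset"]])
        offset = float(rec[cols["offset"]])
        if offset < onset:
            raise AnnotationValidationError(
                f"row {idx}: offset {offset} < onset {onset}"
            )
        if onset < prev_onset:
            # real annotation files contain timing jitter; warn, keep order
            warnings.warn(
                f"row {idx}: onset {onset} decreases below previous "
                f"{prev_onset}; keeping file order",
                stacklevel=2,
            )
        prev_onset = max(prev_onset, onset)
        end = False
        if has_end:
            v = rec[cols["sentence_end"]]
            end = bool(v) and str(v).strip().lower() not in {"", "0", "false", "nan"}
        out.append(
            WordAnnotation(
                token=str(rec[cols["word"]]),
                onset=onset,
                offset=offset,
                is_sentence_end=end,
            )
        )
    return out


def build_sentences(
    words: Sequence[WordAnnotation],
    boundary: str = "flag",
) -> list[Sentence]:
    """Partition a word stream into sentences.

    ``boundary='flag'`` splits after words carrying ``is_sentence_end``;
    ``boundary='punctuation'`` splits after tokens ending in ``. ? !``.
    Trailing words with no terminator form a final sentence.
    """
    if not words:
        raise ValueError("cannot build sentences from an empty word list")
    if boundary not in {"flag", "punctuation"}:
        raise ValueError(f"unknown boundary mode {boundary!r}")

    def is_end(w: WordAnnotation) -> bool:
        if boundary == "flag":
            return w.is_sentence_end
        return w.token.rstrip().endswith(TERMINAL_PUNCTUATION)

    sentences: list[Sentence] = []
    current: list[WordAnnotation] = []
    for w in words:
        current.append(w)
        if is_end(w):
            sentences.append(Sentence(tuple(current)))
            current = []
    if current:
        sentences.append(Sentence(tuple(current)))
    return sentences


def subtitle_stats(sentences: Sequence[Sentence], ddof: int = 1) -> SubtitleStats:
    """Summarise sentence lengths (words) and durations (seconds).

    ``ddof=1`` (sample standard deviation) is the default convention; pass
    ``ddof=0`` for the population form.
    """
    if not sentences:
        raise ValueError("subtitle_stats requires at least one sentence")
    import numpy as np

    lengths = np.array([s.n_words for s in sentences], dtype=float)
    durations = np.array([s.duration for s in sentences], dtype=float)
    sd = lambda x: float(np.std(x, ddof=ddof)) if len(x) > ddof else 0.0
    return SubtitleStats(
        n_sentences=len(sentences),
        n_words=int(lengths.sum()),
        n_seconds=float(durations.sum()),
        length_min=int(lengths.min()),
        length_max=int(lengths.max()),
        length_mean=float(lengths.mean()),
        length_sd=sd(lengths),
        duration_min=float(durations.min()),
        duration_max=float(durations.max()),
        duration_mean=float(durations.mean()),
        duration_sd=sd(durations),
    )


def sentences_to_frame(sentences: Iterable[Sentence]) -> pd.DataFrame:
    """Tabular view (text, onset, offset, duration, n_words) for TSV export."""
    return pd.DataFrame(
        {
            "text": [s.text for s in sentences],
            "onset": [s.onset for s in sentences],
            "offset": [s.offset for s in sentences],
            "duration": [s.duration for s in sentences],
            "n_words": [s.n_words for s in sentences],
        }
    )


def words_to_frame(words: Iterable[WordAnnotation]) -> pd.DataFrame:
    """Tabular view of a word stream in the annotation-file schema."""
    return pd.DataFrame(
        {
            "word": [w.token for w in words],
            "onset": [w.onset for w in words],
            "offset": [w.offset for w in words],
            "sentence_end": [int(w.is_sentence_end) for w in words],
        }
    )
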