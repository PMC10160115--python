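"""Lexicon-based sentence sentiment: compound scores, polarity cases, similarity.

The scorer follows the classic lexicon-analyzer recipe: each token is matched
(lower-cased) against a valence dictionary, a lexicon hit preceded by a
negation word within a short window has its valence flipped and damped, and
the signed valence sum S is squashed to a *compound score*

    compound = S / sqrt(S**2 + alpha),    alpha > 0,

which is bounded in (-1, +1) and preserves the sign of S.  The compound
score's sign defines the three-way polarity (positive / neutral / negative),
and three class schemes fold the neutral class differently:

* ``BINARY_1`` — neutral counts as positive,
* ``BINARY_2`` — neutral counts as negative,
* ``THREE_CLASS`` — neutral kept as its own class.

Class labels are encoded neutral=0, negative=1, positive=2 throughout.
Capitalisation and punctuation intensity boosts are deliberately not
modelled (documented limitation: no closed form exists for them here).
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotations import Sentence

# class-label encoding shared by every downstream stage
CLASS_NEUTRAL = 0
CLASS_NEGATIVE = 1
CLASS_POSITIVE = 2

DEFAULT_ALPHA = 15.0
DEFAULT_NEGATION_FACTOR = -0.74
DEFAULT_NEGATION_WINDOW = 3

DEFAULT_NEGATIONS = frozenset(
    {
        "not", "no", "never", "neither", "nor", "nothing", "nobody",
        "nowhere", "hardly", "barely", "scarcely", "without", "cannot",
        "cant", "can't", "dont", "don't", "didnt", "didn't", "wont",
        "won't", "isnt", "isn't", "wasnt", "wasn't", "aint", "ain't",
    }
)

_TOKEN_STRIP = re.compile(r"^[^\w]+|[^\w]+$")

#: small bundled demo lexicon for tests and examples; point real analyses at
#: a full published valence lexicon via :meth:`Lexicon.from_tsv`
DEMO_LEXICON_VALENCES: dict[str, float] = {
    # positive
    "love": 3.2, "loved": 2.9, "great": 3.1, "good": 1.9, "happy": 2.7,
    "joy": 2.8, "wonderful": 2.7, "beautiful": 2.9, "enjoy": 2.2,
    "excellent": 2.7, "amazing": 2.8, "fantastic": 2.6, "nice": 1.8,
    "sweet": 2.0, "smile": 1.5, "laugh": 2.6, "fun": 2.3, "best": 3.2,
    "friend": 2.2, "kiss": 1.8, "perfect": 2.7, "delight": 2.9,
    "charming": 2.4, "hope": 1.9, "win": 2.8,
    # negative
    "hate": -2.7, "hated": -3.2, "bad": -2.5, "terrible": -2.1,
    "awful": -2.0, "sad": -2.1, "cry": -2.0, "angry": -2.3, "fear": -2.2,
    "horrible": -2.5, "worst": -3.1, "pain": -2.5, "ugly": -2.3,
    "stupid": -2.4, "kill": -3.2, "die": -2.9, "dead": -3.3, "lose": -1.7,
    "lonely": -2.2, "miserable": -2.7, "disaster": -3.1, "wrong": -2.1,
    "fail": -2.5, "broken": -1.8, "hurt": -2.4,
}


class AnalyzerUnavailableError(ImportError):
    """A named third-party sentiment analyzer is not installed."""


@dataclass(frozen=True)
class Lexicon:
    """Token → signed valence map plus negation-handling parameters."""

    valences: dict[str, float]
    negations: frozenset[str] = DEFAULT_NEGATIONS
    negation_factor: float = DEFAULT_NEGATION_FACTOR
    negation_window: int = DEFAULT_NEGATION_WINDOW
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("normalization constant alpha must be positive")
        for tok, v in self.valences.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite valence for token {tok!r}")

    @classmethod
    def demo(cls, **overrides) -> "Lexicon":
        """The small bundled English demo lexicon."""
        return cls(valences=dict(DEMO_LEXICON_VALENCES), **overrides)

    @classmethod
    def from_tsv(cls, path: str | Path, **overrides) -> "Lexicon":
        """Load a two-column TSV (token<TAB>valence), no header required."""
        df = pd.read_csv(path, sep="\t", header=None, names=["token", "valence"],
                         comment="#")
        # tolerate an accidental header row
        df = df[pd.to_numeric(df["valence"], errors="coerce").notna()]
        valences = {
            str(t).lower(): float(v) for t, v in zip(df["token"], df["valence"])
        }
        return cls(valences=valences, **overrides)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tok, v in sorted(self.valences.items()):
                fh.write(f"{tok}\t{v}\n")


@dataclass(frozen=True)
class SentimentScore:
    """Compound score in (-1, +1) together with the raw valence sum."""

    compound: float
    raw_sum: float


class PolarityCase(enum.Enum):
    """How the neutral polarity is folded into classification classes."""

    BINARY_1 = "binary1"   # neutral merged into positive
    BINARY_2 = "binary2"   # neutral merged into negative
    THREE_CLASS = "three"  # neutral kept separate

    @property
    def n_classes(self) -> int:
        return 3 if self is PolarityCase.THREE_CLASS else 2

    @classmethod
    def from_name(cls, name: str) -> "PolarityCase":
        for case in cls:
            if case.value == name or case.name.lower() == name.lower():
                return case
        raise ValueError(f"unknown polarity case {name!r}")


def _clean(token: str) -> str:
    return _TOKEN_STRIP.sub("", token).lower()


def score_tokens(tokens: Sequence[str], lexicon: Lexicon) -> SentimentScore:
    """Score an already-tokenised word sequence."""
    cleaned = [_clean(t) for t in tokens]
    raw = 0.0
    for i, tok in enumerate(cleaned):
        valence = lexicon.valences.get(tok)
        if valence is None:
            continue
        lo = max(0, i - lexicon.negation_window)
        if any(prev in lexicon.negations for prev in cleaned[lo:i]):
            valence *= lexicon.negation_factor
        raw += valence
    if raw == 0.0:
        return SentimentScore(compound=0.0, raw_sum=0.0)
    compound = raw / math.sqrt(raw * raw + lexicon.alpha)
    return SentimentScore(compound=compound, raw_sum=raw)


def score_sentence(sentence: Sentence | str, lexicon: Lexicon) -> SentimentScore:
    """Compound-score one sentence (out-of-lexicon tokens contribute zero)."""
    if isinstance(sentence, Sentence):
        tokens = [w.token for w in sentence.words]
    else:
        tokens = str(sentence).split()
    return score_tokens(tokens, lexicon)


def polarity_of(score: SentimentScore | float) -> int:
    """Sign of the compound score: +1 positive, -1 negative, 0 (exactly) neutral."""
    c = score.compound if isinstance(score, SentimentScore) else float(score)
    if c > 0:
        return 1
    if c < 0:
        return -1
    return 0


def map_polarity_case(polarity: int, case: PolarityCase) -> int:
    """Fold a {-1, 0, +1} polarity into the class encoding of ``case``."""
    if polarity not in (-1, 0, 1):
        raise ValueError(f"polarity must be -1, 0 or +1, got {polarity!r}")
    if case is PolarityCase.BINARY_1:
        return CLASS_POSITIVE if polarity >= 0 else CLASS_NEGATIVE
    if case is PolarityCase.BINARY_2:
        return CLASS_POSITIVE if polarity > 0 else CLASS_NEGATIVE
    if polarity == 0:
        return CLASS_NEUTRAL
    return CLASS_POSITIVE if polarity > 0 else CLASS_NEGATIVE


def similarity_score(
    v1: Sequence[int] | np.ndarray, v2: Sequence[int] | np.ndarray
) -> tuple[int, float]:
    """Element-wise agreement between two polarity vectors.

    Returns ``(matches, fraction)`` where ``matches`` counts positions with
    identical labels and ``fraction = matches / n``.
    """
    a = np.asarray(v1)
    b = np.asarray(v2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"polarity vectors must be 1-D and same length, "
                         f"got shapes {a.shape} and {b.shape}")
    if a.size == 0:
        raise ValueError("polarity vectors must be non-empty")
    matches = int(np.sum(a == b))
    return matches, matches / a.size


def label_sentences(
    sentences: Sequence[Sentence],
    lexicon: Lexicon,
) -> pd.DataFrame:
    """Score a corpus and emit the full label table.

    Columns: sentence_index, compound, polarity, class_binary1, class_binary2,
    class_3class.
    """
    rows = []
    for i, s in enumerate(sentences):
        sc = score_sentence(s, lexicon)
        pol = polarity_of(sc)
        rows.append(
            {
                "sentence_index": i,
                "compound": sc.compound,
                "polarity": pol,
                "class_binary1": map_polarity_case(pol, PolarityCase.BINARY_1),
                "class_binary2": map_polarity_case(pol, PolarityCase.BINARY_2),
                "class_3class": map_polarity_case(pol, PolarityCase.THREE_CLASS),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# external analyzer adapters
# --------------------------------------------------------------------------

_ANALYZER_REGISTRY: dict[str, Callable[[Sequence[Sentence]], np.ndarray]] = {}


def register_analyzer(
    analyzer_id: str, fn: Callable[[Sequence[Sentence]], np.ndarray]
) -> None:
    """Register a callable mapping sentences to a {-1, 0, +1} polarity vector."""
    _ANALYZER_REGISTRY[analyzer_id] = fn


def external_analyzer_adapter(
    sentences: Sequence[Sentence], analyzer_id: str, lexicon: Lexicon | None = None
) -> np.ndarray:
    """Run a named analyzer over a corpus, returning {-1, 0, +1} polarities.

    The built-in ``"internal"`` analyzer is the package's own lexicon scorer.
    Third-party analyzers (e.g. ``"vader"``) must be registered first and
    require their optional dependency; no other operation depends on them.
    """
    if analyzer_id == "internal":
        lex = lexicon or Lexicon.demo()
        return np.array(
            [polarity_of(score_sentence(s, lex)) for s in sentences], dtype=int
        )
    if analyzer_id in _ANALYZER_REGISTRY:
        return np.asarray(_ANALYZER_REGISTRY[analyzer_id](sentences), dtype=int)
    if analyzer_id == "vader":
        try:
            from vaderSentiment.vaderSentiment import SentimentIntensityAnalyzer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise AnalyzerUnavailableError(
                "analyzer 'vader' needs the optional dependency "
                "'vaderSentiment' (pip install vaderSentiment)"
            ) from exc
        sia = SentimentIntensityAnalyzer()  # pragma: no cover
        return np.array(  # pragma: no cover
            [polarity_of(sia.polarity_scores(s.text)["compound"]) for s in sentences],
            dtype=int,
        )
    raise AnalyzerUnavailableError(
        f"analyzer {analyzer_id!r} is not registered and no adapter exists; "
        f"available: {['internal', *sorted(_ANALYZER_REGISTRY)]}"
    )


def pairwise_similarity(
    sentences: Sequence[Sentence],
    analyzer_ids: Sequence[str],
    lexicon: Lexicon | None = None,
) -> pd.DataFrame:
    """Pairwise agreement-fraction matrix across several analyzers."""
    vectors = {
        aid: external_analyzer_adapter(sentences, aid, lexicon)
        for aid in analyzer_ids
    }
    mat = pd.DataFrame(index=list(analyzer_ids), columns=list(analyzer_ids),
                       dtype=float)
    for a in analyzer_ids:
        for b in analyzer_ids:
            mat.loc[a, b] = similarity_score(vectors[a], vectors[b])[1]
    return mat
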