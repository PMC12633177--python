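"""Child-language metrics from CHAT-style conversation transcripts.

Four metrics describe the child's productive language in a transcript:

* **MLU** — mean length of utterance in morphemes,
* **TNW** — total number of word tokens,
* **WPS** — words per sentence (utterances ending in ``.``, ``?`` or ``!``),
* **CPS** — clauses per sentence, a clause being 1 plus each subordinating
  marker in the sentence.

Morphemes are counted with a fixed, documented approximation of the
conventional child-language rules: each word is one morpheme plus one for
each detected inflection (plural/possessive/3rd-person ``-s``, past
``-ed``, progressive ``-ing``, contracted auxiliaries and negations), with
an exceptions lexicon so irregular forms and pseudo-inflected words
("ran", "this", "thing") count as a single morpheme.  Exact parity with
any external coding tool is a non-goal; the rules below are deterministic
and testable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Utterance",
    "Transcript",
    "CommMetrics",
    "parse_chat",
    "to_chat",
    "count_morphemes",
    "compute_metrics",
    "SUBORDINATORS",
]

#: speaker-tier codes understood in CHAT files
SPEAKER_TIERS = {"CHI": "child", "MOT": "mother"}

#: sentence-final terminators
TERMINATORS = (".", "?", "!")

#: surface markers opening a subordinate clause
SUBORDINATORS = frozenset(
    {
        "because", "that", "when", "who", "which", "if", "while",
        "after", "before", "since", "until", "unless", "although", "where",
    }
)

#: fillers excluded from word counts
FILLERS = frozenset({"um", "uh", "er", "eh", "hm", "hmm", "mm", "uhhuh"})

#: words that end in an inflection-like string but are monomorphemic,
#: plus irregular past forms
MONOMORPHEMIC = frozenset(
    {
        # -s lookalikes
        "this", "his", "is", "was", "has", "yes", "its", "us", "bus",
        "gas", "plus", "always", "perhaps", "lens", "news", "pants",
        # -ed lookalikes
        "bed", "red", "need", "feed", "seed", "indeed", "hundred",
        # -ing lookalikes
        "thing", "ring", "sing", "king", "bring", "during", "morning",
        "something", "nothing", "anything", "everything", "spring", "wing",
        # irregular pasts
        "ran", "went", "saw", "came", "got", "did", "made", "said",
        "took", "ate", "fell", "found", "gave", "knew", "left", "put",
        "told", "thought", "broke", "held", "sat", "stood", "won",
    }
)

#: contractions mapping to their morpheme count
_CONTRACTION_MORPHEMES = {
    "n't": 1,  # negation
    "'s": 1,  # is / possessive / has
    "'re": 1, "'ve": 1, "'ll": 1, "'d": 1, "'m": 1,
}


@dataclass(frozen=True)
class Utterance:
    speaker: str  # "child" | "mother"
    tokens: tuple
    terminator: str = "."

    def __init__(self, speaker: str, tokens, terminator: str = "."):
        if speaker not in ("child", "mother"):
            raise ValueError(f"unknown speaker {speaker!r}")
        if not tokens:
            raise ValueError("utterance must contain at least one token")
        object.__setattr__(self, "speaker", speaker)
        object.__setattr__(self, "tokens", tuple(tokens))
        object.__setattr__(self, "terminator", terminator)

    @property
    def is_sentence(self) -> bool:
        return self.terminator in TERMINATORS


@dataclass
class Transcript:
    utterances: list = field(default_factory=list)

    def by_speaker(self, speaker: str) -> list:
        return [u for u in self.utterances if u.speaker == speaker]


@dataclass(frozen=True)
class CommMetrics:
    """The four child-language measures of one transcript."""

    mlu: float  # morphemes per utterance
    tnw: int  # total word tokens
    wps: float  # words per sentence
    cps: float  # clauses per sentence
    n_utterances: int = 0
    n_sentences: int = 0


# ---------------------------------------------------------------------------
# CHAT parsing
# ---------------------------------------------------------------------------

# annotation material stripped from utterance lines before tokenization:
# [...] event/error codes, <...> retrace groups, &=action and &-filler codes,
# +... linking markers, parenthesised omitted material markers
_STRIP_PATTERNS = [
    re.compile(r"\[[^\]]*\]"),
    re.compile(r"<[^>]*>"),
    re.compile(r"&[=+-]?\S*"),
    re.compile(r"\+\S*"),
]
_WORD_RE = re.compile(r"[A-Za-z']+")


def _tokenize(text: str) -> tuple[list[str], str]:
    """Strip annotation codes, lowercase, split; return (tokens, terminator)."""
    terminator = ""
    stripped = text.strip()
    for term in TERMINATORS:
        if stripped.endswith(term):
            terminator = term
            stripped = stripped[: -len(term)]
            break
    for pat in _STRIP_PATTERNS:
        stripped = pat.sub(" ", stripped)
    tokens = [
        w.lower().strip("'")
        for w in _WORD_RE.findall(stripped)
    ]
    tokens = [w for w in tokens if w and w != "xxx" and w not in FILLERS]
    return tokens, terminator


def parse_chat(text: str) -> Transcript:
    """Parse a CHAT-dialect transcript into speaker-tagged utterances.

    Header lines (``@...``) and dependent tiers (``%...``) are skipped;
    tab-indented lines continue the previous utterance.  Annotation codes
    (bracketed codes, retrace groups, ``&``-prefixed events/fillers) and
    filler words are excluded from the tokens.  Unknown speaker tiers
    raise, naming the line.
    """
    lines = text.splitlines()
    raw: list[tuple[str, str]] = []  # (speaker, text)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("@") or line.startswith("%"):
            continue
        if line.startswith(("\t", " ")) and raw:
            raw[-1] = (raw[-1][0], raw[-1][1] + " " + line.strip())
            continue
        m = re.match(r"\*([A-Za-z0-9]+):\s*(.*)$", line)
        if not m:
            raise ValueError(f"line {lineno}: not a valid CHAT tier: {line!r}")
        tier, content = m.group(1), m.group(2)
        if tier not in SPEAKER_TIERS:
            raise ValueError(f"line {lineno}: unknown speaker tier *{tier}:")
        raw.append((SPEAKER_TIERS[tier], content))

    utterances = []
    for speaker, content in raw:
        tokens, terminator = _tokenize(content)
        if tokens:
            utterances.append(Utterance(speaker, tokens, terminator))
    return Transcript(utterances=utterances)


def to_chat(transcript: Transcript) -> str:
    """Serialize a transcript to CHAT-dialect text (inverse of parse_chat)."""
    code = {v: k for k, v in SPEAKER_TIERS.items()}
    lines = ["@Begin", "@Languages:\teng", "@Participants:\tCHI Child, MOT Mother"]
    for u in transcript.utterances:
        body = " ".join(u.tokens)
        if u.terminator:
            body += " " + u.terminator
        lines.append(f"*{code[u.speaker]}:\t{body}")
    lines.append("@End")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# morphemes and metrics
# ---------------------------------------------------------------------------

def _word_morphemes(word: str) -> int:
    """Morphemes in one word token under the documented rule table."""
    word = word.lower()
    count = 1
    # contracted auxiliaries / negations, counted separately from the stem
    for suffix, extra in _CONTRACTION_MORPHEMES.items():
        if word.endswith(suffix) and len(word) > len(suffix):
            return _word_morphemes(word[: -len(suffix)]) + extra
    if word in MONOMORPHEMIC:
        return count
    if word.endswith("ing") and len(word) > 4:
        count += 1
    elif word.endswith("ed") and len(word) > 3:
        count += 1
    elif word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        count += 1
    return count


def count_morphemes(tokens) -> int:
    """Total morphemes of a token list (terminators are not tokens)."""
    return sum(_word_morphemes(t) for t in tokens)


def compute_metrics(transcript: Transcript, speaker: str = "child") -> CommMetrics:
    """MLU, TNW, WPS and CPS for one speaker of a transcript.

    * MLU = total morphemes / number of utterances,
    * TNW = total word tokens,
    * WPS = words in sentence-terminated utterances / number of sentences,
    * CPS = clauses in sentences / number of sentences, clauses being
      1 + the count of subordinating markers.

    Raises when the speaker has no utterance.
    """
    utts = transcript.by_speaker(speaker)
    if not utts:
        raise ValueError(f"no utterances for speaker {speaker!r}")
    total_morphemes = sum(count_morphemes(u.tokens) for u in utts)
    tnw = sum(len(u.tokens) for u in utts)
    sentences = [u for u in utts if u.is_sentence]
    n_sent = len(sentences)
    words_in_sent = sum(len(u.tokens) for u in sentences)
    clauses = sum(
        1 + sum(1 for t in u.tokens if t in SUBORDINATORS) for u in sentences
    )
    return CommMetrics(
        mlu=total_morphemes / len(utts),
        tnw=tnw,
        wps=words_in_sent / n_sent if n_sent else float("nan"),
        cps=clauses / n_sent if n_sent else float("nan"),
        n_utterances=len(utts),
        n_sentences=n_sent,
    )
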