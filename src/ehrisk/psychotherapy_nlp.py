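"""Psychotherapy-status extraction from clinical note text.

Two-stage pipeline: (1) keyword filtering pulls candidate sentences that
mention one of the four therapy classes (CPT, PE, EMDR, CBT); (2) a
sentence-embedding nearest-anchor rule decides whether the mention describes
active/ongoing treatment or a declined/historical/planned one. The embedding
backend is a pluggable contract (any deterministic text -> fixed-length
vector callable); the shipped default is a deterministic hashed bag-of-words
embedder so the pipeline is reproducible without trained weights. A
pre-trained sentence-transformer satisfying the same contract can be dropped
in at runtime.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import re
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = ["KeywordDictionary", "SentenceDictionary", "HashedBowEmbedder",
           "split_sentences", "extract_candidate_sentences", "classify_active",
           "patient_therapy_flags", "DEFAULT_KEYWORDS", "DEFAULT_ANCHORS",
           "TRAUMA_FOCUSED_CLASSES"]

TRAUMA_FOCUSED_CLASSES = frozenset({"CPT", "PE", "EMDR"})

DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "CPT": ["cognitive processing therapy"],
    "PE": ["prolonged exposure"],
    "EMDR": ["eye movement desensitization and reprocessing"],
    "CBT": ["cognitive behavioral therapy"],
}

# Exemplar sentences anchoring the active / inactive decision. "therapy"
# stands in for the specific keyword phrase; similarity is lexical, so the
# surrounding treatment-status wording carries the signal.
DEFAULT_ANCHORS: dict[str, list[str]] = {
    "active": [
        "Patient is currently undergoing therapy weekly.",
        "Pt continues therapy sessions and reports good progress.",
        "Therapy ongoing, completed another session this week.",
    ],
    "inactive": [
        "Patient declined therapy at this time.",
        "History of therapy completed years ago, not currently in treatment.",
        "Patient was referred for therapy but has not started.",
    ],
}


@dataclasses.dataclass(frozen=True)
class KeywordDictionary:
    phrases: Mapping[str, Sequence[str]] = dataclasses.field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_KEYWORDS.items()})

    def __post_init__(self):
        for cls, plist in self.phrases.items():
            if not plist or any((not p) or p != p.lower() for p in plist):
                raise ValueError(f"phrases for {cls} must be non-empty lowercase")


@dataclasses.dataclass(frozen=True)
class SentenceDictionary:
    active: Sequence[str] = tuple(DEFAULT_ANCHORS["active"])
    inactive: Sequence[str] = tuple(DEFAULT_ANCHORS["inactive"])

    def __post_init__(self):
        if not self.active or not self.inactive:
            raise ValueError("need at least one exemplar per label")


Embedder = Callable[[str], np.ndarray]


class HashedBowEmbedder:
    """Deterministic hashed bag-of-words sentence embedder.

    Lowercased word tokens are hashed (md5, stable across processes) into a
    fixed-length signed count vector — the feature-hashing trick. Equal
    inputs always produce equal vectors; no trained weights involved.
    """

    def __init__(self, dim: int = 768):
        self.dim = dim

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for word in re.findall(r"[a-z0-9']+", text.lower()):
            h = int.from_bytes(hashlib.md5(word.encode()).digest()[:8], "big")
            vec[h % self.dim] += 1.0 if (h >> 63) & 1 == 0 else -1.0
        return vec


_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")


def split_sentences(note: str) -> list[str]:
    return [s.strip() for s in _SENT_SPLIT.split(note) if s.strip()]


def extract_candidate_sentences(note: str, keywords: KeywordDictionary | None = None,
                                ) -> list[tuple[str, str]]:
    """(sentence, therapy class) pairs for every keyword hit.

    Case-insensitive substring match; a sentence mentioning several classes
    yields one pair per class.
    """
    kd = keywords or KeywordDictionary()
    out = []
    for sent in split_sentences(note):
        low = sent.lower()
        for cls, phrases in kd.phrases.items():
            if any(p in low for p in phrases):
                out.append((sent, cls))
    return out


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm embedding")
    return float(a @ b / (na * nb))


def classify_active(sentence: str, anchors: SentenceDictionary | None = None,
                    embedder: Embedder | None = None, threshold: float = 0.5,
                    margin: float = 0.0) -> str:
    """'active' or 'inactive' by nearest-anchor cosine similarity.

    Active requires the best active-anchor similarity to beat the best
    inactive-anchor similarity by more than `margin` AND to reach
    `threshold`; ties fall to inactive (conservative).
    """
    anchors = anchors or SentenceDictionary()
    embedder = embedder or HashedBowEmbedder()
    v = embedder(sentence)
    sim_active = max(_cosine(v, embedder(a)) for a in anchors.active)
    sim_inactive = max(_cosine(v, embedder(a)) for a in anchors.inactive)
    if sim_active - sim_inactive > margin and sim_active >= threshold:
        return "active"
    return "inactive"


def patient_therapy_flags(notes: Iterable[tuple[dt.date, str]],
                          keywords: KeywordDictionary | None = None,
                          anchors: SentenceDictionary | None = None,
                          embedder: Embedder | None = None,
                          index_date: dt.date | None = None,
                          threshold: float = 0.5) -> tuple[bool, bool]:
    """(cbt_active, trauma_focused_active) over a patient's notes.

    A flag turns on iff at least one sentence of that class is classified
    active in any note dated on or before the index date (notes after the
    index date are ignored as leakage control). Trauma-focused pools CPT,
    PE and EMDR.
    """
    cbt = tf = False
    for date, text in notes:
        if index_date is not None and date > index_date:
            continue
        for sentence, cls in extract_candidate_sentences(text, keywords):
            if classify_active(sentence, anchors, embedder, threshold) != "active":
                continue
            if cls == "CBT":
                cbt = True
            elif cls in TRAUMA_FOCUSED_CLASSES:
                tf = True
    return cbt, tf
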