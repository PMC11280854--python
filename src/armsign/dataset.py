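"""Shared dataset containers: word dictionary, feature table, labelled dataset."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synth import TwoArmRecording

__all__ = ["Dictionary", "FeatureTable", "SignDataset"]


class Dictionary:
    """Ordered collection of unique, nonempty sign words (full Unicode)."""

    def __init__(self, words: Iterable[str]) -> None:
        words = list(words)
        seen: set[str] = set()
        for i, w in enumerate(words):
            if not isinstance(w, str) or not w.strip():
                raise ValueError(f"word {i} is empty or not text")
            if w in seen:
                raise ValueError(f"duplicate word {w!r} at position {i}")
            seen.add(w)
        self._words = words

    @property
    def words(self) -> list[str]:
        return list(self._words)

    def __len__(self) -> int:
        return len(self._words)

    def __iter__(self):
        return iter(self._words)

    def __contains__(self, word: object) -> bool:
        return word in self._words

    def __getitem__(self, i: int) -> str:
        return self._words[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Dictionary) and other._words == self._words

    def __repr__(self) -> str:  # pragma: no cover
        return f"Dictionary({len(self._words)} words)"

    def index(self, word: str) -> int:
        return self._words.index(word)


@dataclass
class FeatureTable:
    """Feature matrix with a stable column-name registry and row labels."""

    names: list[str]
    X: np.ndarray  # (n_rows, n_features)
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("feature matrix width must match name registry")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("one label per feature row required")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class SignDataset:
    """Labelled recordings plus (optionally) their extracted feature table."""

    dictionary: Dictionary
    recordings: list["TwoArmRecording"] = field(default_factory=list)
    features: Optional[FeatureTable] = None

    def __post_init__(self) -> None:
        for rec in self.recordings:
            if rec.label is not None and rec.label not in self.dictionary:
                raise ValueError(f"label {rec.label!r} not in dictionary")

    def __len__(self) -> int:
        return len(self.recordings)

    def labels(self) -> list[str]:
        return [r.label for r in self.recordings]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {w: 0 for w in self.dictionary}
        for r in self.recordings:
            if r.label is not None:
                counts[r.label] += 1
        return counts

    def remove_recording(self, word: str, repetition: int) -> None:
        """Atomically drop one (sign, repetition) recording and its feature row."""
        idx = None
        for i, r in enumerate(self.recordings):
            if r.label == word and r.repetition == repetition:
                idx = i
                break
        if idx is None:
            raise KeyError(f"no recording for ({word!r}, rep {repetition})")
        del self.recordings[idx]
        if self.features is not None and len(self.features) > idx:
            self.features = FeatureTable(
                self.features.names,
                np.delete(self.features.X, idx, axis=0),
                self.features.labels[:idx] + self.features.labels[idx + 1 :],
            )
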