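"""Trained-model archive: translation transform + memory + config.

A trained classifier is the pair (TranslationTransform, DeltaMemory).  The
archive is a single JSON document with a versioned format tag so a model
written by one run can be reloaded and queried by another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import delta_am
from .dataio import ClassLabel, FundamentalSet
from .delta_am import ClassificationResult, DeltaMemory, MemoryConfig
from .errors import ParseError
from .preprocessing import TranslationTransform, apply_to_patterns, apply_translation, fit_translation

FORMAT_TAG = "deltamem-model/1"


@dataclass
class TrainedModel:
    transform: TranslationTransform
    memory: DeltaMemory

    @property
    def class_names(self) -> list[str]:
        return self.memory.class_names

    def classify(self, x) -> ClassificationResult:
        """Translate a raw (untranslated) query and classify it."""
        return delta_am.classify(self.memory, apply_to_patterns(self.transform, np.asarray(x)))

    def classify_many(self, X) -> list[ClassificationResult]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return [self.classify(row) for row in X]

    def save(self, path: str | Path) -> None:
        doc = {
            "format": FORMAT_TAG,
            "transform": self.transform.to_dict(),
            "memory": {
                "stored": self.memory.stored.tolist(),
                "labels": self.memory.labels.tolist(),
                "class_names": self.memory.class_names,
                "source_fingerprint": list(self.memory.source_fingerprint)
                if self.memory.source_fingerprint
                else None,
            },
            "config": {
                "threshold_policy": self.memory.config.threshold_policy,
                "tau": self.memory.config.tau,
                "reject_enabled": self.memory.config.reject_enabled,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("format") != FORMAT_TAG:
            raise ParseError(f"{path}: not a {FORMAT_TAG} archive")
        mem_d = doc["memory"]
        fp = mem_d.get("source_fingerprint")
        memory = DeltaMemory(
            stored=np.asarray(mem_d["stored"], dtype=float),
            labels=np.asarray(mem_d["labels"], dtype=int),
            class_names=list(mem_d["class_names"]),
            config=MemoryConfig(**doc["config"]),
            source_fingerprint=(int(fp[0]), int(fp[1]), str(fp[2])) if fp else None,
        )
        return cls(transform=TranslationTransform.from_dict(doc["transform"]), memory=memory)


def train(
    fs: FundamentalSet,
    translation_mode: str = "mean",
    custom_offsets=None,
    config: MemoryConfig | None = None,
) -> TrainedModel:
    """Fit the translation on ``fs`` and learn the memory on the translated set."""
    transform = fit_translation(fs, mode=translation_mode, custom_offsets=custom_offsets)
    memory = delta_am.learn(apply_translation(transform, fs), config)
    return TrainedModel(transform=transform, memory=memory)
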