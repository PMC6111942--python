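"""Translation preprocessing of the fundamental set.

Cross-talk — interference between stored associations that saturates an
associative memory — stems from an order relation among the stored
patterns.  The remedy implemented here is a pure per-attribute
*translation* of the data before the memory's learning phase: each value
``v_j`` becomes ``v_j - offset_j``.  A translation changes no pairwise
difference and no central moment of any attribute, so the data's shape is
untouched; only its location moves.

Offset choices
--------------
``mean``    subtract each attribute's mean over the fundamental set
            (default: centres the data, removing the shared magnitude
            component that drives the order relation).
``min``     subtract each attribute's minimum (shifts the set to a zero
            floor, keeping values non-negative for integer data).
``custom``  caller-supplied per-attribute offsets, the hook for plugging
            in any exact transcription of an alternative rule.

The transform is fitted on training data only and applied with those same
offsets to held-out patterns, so no test-set statistic leaks into the
model.  Offsets are kept at full floating precision; applying then
inverting is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dataio import FundamentalSet
from .errors import DimensionMismatchError, SchemaError
from . import __version__ as _pkg_version

MODES = ("mean", "min", "custom")


@dataclass(frozen=True)
class TranslationTransform:
    """Per-attribute translation constants fitted on one fundamental set.

    ``fitted_on`` is the (p, n, checksum) fingerprint of the source set, so a
    serialized model records exactly which data produced it.
    """

    offsets: np.ndarray
    mode: str
    fitted_on: tuple[int, int, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if self.offsets.ndim != 1:
            raise SchemaError("offsets must be a 1-D vector")
        if self.mode not in MODES:
            raise SchemaError(f"unknown translation mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.offsets.shape[0]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "deltamem-translation/1",
            "version": _pkg_version,
            "mode": self.mode,
            "offsets": [float(v) for v in self.offsets],
            "fitted_on": {
                "p": self.fitted_on[0],
                "n": self.fitted_on[1],
                "checksum": self.fitted_on[2],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranslationTransform":
        fp = d["fitted_on"]
        return cls(
            offsets=np.asarray(d["offsets"], dtype=float),
            mode=d["mode"],
            fitted_on=(int(fp["p"]), int(fp["n"]), str(fp["checksum"])),
        )

    def save(self, path: str | Path) -> None:
        """Write a YAML (or JSON, by extension) sidecar."""
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TranslationTransform":
        path = Path(path)
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
        return cls.from_dict(data)


def fit_translation(
    fs: FundamentalSet,
    mode: str = "mean",
    custom_offsets: Sequence[float] | None = None,
) -> TranslationTransform:
    """Compute per-attribute translation offsets from the fundamental set.

    Uses pattern values only (labels never enter); deterministic.
    """
    if fs.p < 1:
        raise SchemaError("cannot fit a translation on an empty fundamental set")
    if mode == "mean":
        offsets = fs.X.mean(axis=0)
    elif mode == "min":
        offsets = fs.X.min(axis=0)
    elif mode == "custom":
        if custom_offsets is None:
            raise SchemaError("mode='custom' requires custom_offsets")
        offsets = np.asarray(custom_offsets, dtype=float)
        if offsets.shape != (fs.n,):
            raise DimensionMismatchError(
                f"custom offsets have length {offsets.shape[0]}, patterns have n={fs.n}"
            )
    else:
        raise SchemaError(f"unknown translation mode {mode!r}")
    return TranslationTransform(offsets=offsets, mode=mode, fitted_on=fs.fingerprint())


def _check_dims(t: TranslationTransform, fs: FundamentalSet) -> None:
    if fs.n != t.n:
        raise DimensionMismatchError(
            f"transform has n={t.n} offsets but patterns have n={fs.n}"
        )


def apply_translation(t: TranslationTransform, fs: FundamentalSet) -> FundamentalSet:
    """Translate every pattern: v_j -> v_j - offset_j.

    Labels, p, n and attribute order are unchanged; every pairwise
    difference between patterns is preserved exactly.
    """
    _check_dims(t, fs)
    return fs.with_values(fs.X - t.offsets)


def invert_translation(t: TranslationTransform, fs: FundamentalSet) -> FundamentalSet:
    """Undo :func:`apply_translation`; apply-then-invert is the identity."""
    _check_dims(t, fs)
    return fs.with_values(fs.X + t.offsets)


def apply_to_patterns(t: TranslationTransform, X: np.ndarray) -> np.ndarray:
    """Translate raw pattern rows (used for held-out queries)."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != t.n:
        raise DimensionMismatchError(
            f"transform has n={t.n} offsets but patterns have n={X.shape[-1]}"
        )
    return X - t.offsets
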