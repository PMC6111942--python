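"""Seeded synthetic clinical datasets with controllable class separation.

Three schemas are provided, all binary (``absence`` / ``presence`` of
coronary artery disease):

``ehealth-like``
    Six attributes in the style of a small biometric-platform screening
    table: age (years), sex (0/1), maximum heart rate achieved (bpm),
    resting electrocardiographic result (category 0/1/2), fasting blood
    sugar > 120 mg/dL flag (0/1), resting blood pressure (mmHg).
``heart-like``
    Thirteen numeric/categorical attributes in the same style, matching
    the shape of the classic 13-attribute heart-disease benchmark table.
``toy``
    Two numeric attributes, for hand-checkable examples.

The class-conditional model is deliberately simple — independent
per-attribute sampling, truncated normals for numeric attributes and
categorical draws for discrete ones — so that a brute-force oracle stays
exact and the effect of the ``separation`` knob is transparent.  The
diseased class is mean-shifted by ``separation`` standard deviations on
heart rate (down) and blood pressure (up), with categorical probabilities
tilted proportionally; ``separation = 0`` makes the two class-conditional
distributions identical.

Value ranges (age 25-80, heart rate 70-200, blood pressure 90-190) are
fixtures chosen for clinical plausibility; they are not estimated from
any real cohort and the generator makes no attempt to match real marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .dataio import AttributeSchema, FundamentalSet
from .errors import SchemaError

SCHEMAS = ("ehealth-like", "heart-like", "toy")
CLASS_NAMES = ["absence", "presence"]  # index 0 = healthy, 1 = diseased


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of one synthetic dataset; a dataset is reproducible
    from its spec alone."""

    schema_name: str = "ehealth-like"
    n_samples: int = 135
    class_balance: float = 0.5
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schema_name not in SCHEMAS:
            raise SchemaError(f"unknown schema {self.schema_name!r}; choose from {SCHEMAS}")
        if self.n_samples < 2:
            raise SchemaError("n_samples must be at least 2")
        if not (0.0 < self.class_balance < 1.0):
            raise SchemaError("class_balance must lie strictly between 0 and 1")
        if self.separation < 0:
            raise SchemaError("separation must be non-negative")

    def as_dict(self) -> dict:
        return {
            "schema_name": self.schema_name,
            "n_samples": self.n_samples,
            "class_balance": self.class_balance,
            "separation": self.separation,
            "seed": self.seed,
        }


def _trunc_normal_int(
    rng: np.random.Generator, size: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Integer-rounded truncated-normal draws within [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    vals = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.round(vals), lo, hi)


def _tilted(probs: np.ndarray, tilt: float) -> np.ndarray:
    """Shift categorical mass toward higher categories by `tilt` (capped)."""
    k = len(probs)
    weights = probs * np.exp(np.minimum(tilt, 5.0) * np.linspace(-0.5, 0.5, k))
    return weights / weights.sum()


# Each attribute: (schema, sampler(rng, size, diseased, separation))
_NumSampler = Callable[[np.random.Generator, int, bool, float], np.ndarray]


def _ehealth_attributes() -> list[tuple[AttributeSchema, _NumSampler]]:
    def age(rng, m, dis, sep):
        return _trunc_normal_int(rng, m, 52, 10, 25, 80)

    def sex(rng, m, dis, sep):
        return rng.integers(0, 2, size=m).astype(float)

    def max_hr(rng, m, dis, sep):  # diseased achieve lower maximum heart rate
        mean = 150 - (15 * sep if dis else 0)
        return _trunc_normal_int(rng, m, mean, 15, 70, 200)

    def rest_ecg(rng, m, dis, sep):
        base = np.array([0.55, 0.30, 0.15])
        p = _tilted(base, sep) if dis else base
        return rng.choice(3, size=m, p=p).astype(float)

    def fbs(rng, m, dis, sep):
        p1 = min(0.15 + (0.12 * sep if dis else 0.0), 0.95)
        return (rng.random(m) < p1).astype(float)

    def rest_bp(rng, m, dis, sep):  # diseased have higher resting blood pressure
        mean = 125 + (12 * sep if dis else 0)
        return _trunc_normal_int(rng, m, mean, 12, 90, 190)

    return [
        (AttributeSchema("age", units="years"), age),
        (AttributeSchema("sex", kind="binary", allowed_values=(0.0, 1.0)), sex),
        (AttributeSchema("max_heart_rate", units="bpm"), max_hr),
        (
            AttributeSchema(
                "resting_ecg", kind="categorical-ordinal", allowed_values=(0.0, 1.0, 2.0)
            ),
            rest_ecg,
        ),
        (
            AttributeSchema("fasting_blood_sugar_gt120", kind="binary", allowed_values=(0.0, 1.0)),
            fbs,
        ),
        (AttributeSchema("resting_blood_pressure", units="mmHg"), rest_bp),
    ]


def _heart_attributes() -> list[tuple[AttributeSchema, _NumSampler]]:
    """13 attributes mirroring the shape of the classic heart benchmark."""
    attrs = _ehealth_attributes()

    def chest_pain(rng, m, dis, sep):
        base = np.array([0.25, 0.25, 0.25, 0.25])
        p = _tilted(base, sep) if dis else base
        return rng.choice(4, size=m, p=p).astype(float) + 1  # codes 1..4

    def cholesterol(rng, m, dis, sep):
        mean = 245 + (20 * sep if dis else 0)
        return _trunc_normal_int(rng, m, mean, 40, 120, 500)

    def exercise_angina(rng, m, dis, sep):
        p1 = min(0.30 + (0.15 * sep if dis else 0.0), 0.95)
        return (rng.random(m) < p1).astype(float)

    def oldpeak(rng, m, dis, sep):  # ST depression, one decimal
        mean = 1.0 + (0.6 * sep if dis else 0)
        a, b = (0 - mean) / 1.1, (6.2 - mean) / 1.1
        vals = stats.truncnorm.rvs(a, b, loc=mean, scale=1.1, size=m, random_state=rng)
        return np.round(vals, 1)

    def slope(rng, m, dis, sep):
        base = np.array([0.45, 0.40, 0.15])
        p = _tilted(base, sep) if dis else base
        return rng.choice(3, size=m, p=p).astype(float) + 1  # codes 1..3

    def n_vessels(rng, m, dis, sep):
        base = np.array([0.55, 0.20, 0.15, 0.10])
        p = _tilted(base, sep) if dis else base
        return rng.choice(4, size=m, p=p).astype(float)

    def thal(rng, m, dis, sep):
        base = np.array([0.55, 0.10, 0.35])
        p = _tilted(base, sep) if dis else base
        return rng.choice(np.array([3.0, 6.0, 7.0]), size=m, p=p)

    extra = [
        (
            AttributeSchema(
                "chest_pain_type", kind="categorical-ordinal", allowed_values=(1.0, 2.0, 3.0, 4.0)
            ),
            chest_pain,
        ),
        (AttributeSchema("serum_cholesterol", units="mg/dL"), cholesterol),
        (
            AttributeSchema("exercise_induced_angina", kind="binary", allowed_values=(0.0, 1.0)),
            exercise_angina,
        ),
        (AttributeSchema("st_depression"), oldpeak),
        (
            AttributeSchema("st_slope", kind="categorical-ordinal", allowed_values=(1.0, 2.0, 3.0)),
            slope,
        ),
        (
            AttributeSchema(
                "n_major_vessels", kind="categorical-ordinal", allowed_values=(0.0, 1.0, 2.0, 3.0)
            ),
            n_vessels,
        ),
        (
            AttributeSchema("thalassemia", kind="categorical-ordinal", allowed_values=(3.0, 6.0, 7.0)),
            thal,
        ),
    ]
    return attrs + extra


def _toy_attributes() -> list[tuple[AttributeSchema, _NumSampler]]:
    def x1(rng, m, dis, sep):
        return rng.normal(10 * sep if dis else 0.0, 1.0, size=m)

    def x2(rng, m, dis, sep):
        return rng.normal(-10 * sep if dis else 0.0, 1.0, size=m)

    return [(AttributeSchema("x1"), x1), (AttributeSchema("x2"), x2)]


_BUILDERS = {
    "ehealth-like": _ehealth_attributes,
    "heart-like": _heart_attributes,
    "toy": _toy_attributes,
}


def generate(spec: GeneratorSpec) -> FundamentalSet:
    """Draw one synthetic fundamental set; bitwise-identical for equal specs.

    All draws flow from a single seeded generator stream.  Class labels are
    assigned first (``round(n * (1 - balance))`` healthy, the rest diseased,
    shuffled), then each attribute column is sampled class-conditionally.
    """
    attrs = _BUILDERS[spec.schema_name]()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 1), n - 1)  # both classes always present
    y = np.array([0] * (n - n_pos) + [1] * n_pos)
    rng.shuffle(y)

    X = np.empty((n, len(attrs)), dtype=float)
    for j, (schema, sampler) in enumerate(attrs):
        col = np.empty(n, dtype=float)
        for dis in (False, True):
            mask = y == (1 if dis else 0)
            col[mask] = sampler(rng, int(mask.sum()), dis, spec.separation)
        X[:, j] = col

    return FundamentalSet(X, y, [s for s, _ in attrs], list(CLASS_NAMES))
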