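"""Composite motor-intent-collapse risk scoring.

The WASe-∞ score condenses seven physiological channels into a single
dimensionless risk number::

    score = (a1*E + a2*dI + a3*phi + a4*E_env)
            / ( max(b1*C, floor) * max(b2*S, floor) )
            * (1 + g*T),            capped at ``score_cap``

where all factors are dimensionless after normalization: neuromuscular
effort E (fraction of MVC), temporal intent asymmetry dI (ms / 500 ms full
scale), force dissociation ratio phi (identity, accepted on [0, 2]),
environmental composite E_env, cognitive capacity C, sleep quality
S (hours on the 0-10 h scale, i.e. hours / 10, after clamping to the
physiological 5-9 h range), and the temporal convergence factor T.  The two
denominator *terms* are floored at ``term_floor`` so the protective product
never falls below ``term_floor**2``; risk factors drive the score up,
protective factors (C, S) drive it down.

Risk bands on the capped score: low < 0.5 <= moderate < 0.8 <= high
< 1.2 <= critical.  Band edges are left-closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RISK_CATEGORIES",
    "RISK_BAND_EDGES",
    "CoefficientSet",
    "RawMeasurement",
    "FactorVector",
    "ScoredSample",
    "normalize",
    "normalize_frame",
    "compute_score",
    "classify_risk",
    "classify_risk_array",
    "score_measurement",
    "score_factor_arrays",
]

#: Band labels in ascending-risk order.
RISK_CATEGORIES = ("low", "moderate", "high", "critical")

#: Left-closed band edges on the capped score: [0, .5) [.5, .8) [.8, 1.2) [1.2, cap].
RISK_BAND_EDGES = (0.5, 0.8, 1.2)

# Physical input ranges; values are clipped to these before normalization.
_RAW_RANGES = {
    "E": (0.0, 100.0),
    "dI": (0.0, 500.0),
    "phi": (0.0, 2.0),
    "e_env": (0.0, 1.0),
    "C": (0.0, 100.0),
    "S": (5.0, 9.0),
    "T": (0.0, 1.0),
}


@dataclass(frozen=True)
class CoefficientSet:
    """Equation weights plus the numerical-stability constants.

    Defaults are the framework's published optimum: risk weights
    a1..a4 = (0.4, 0.3, 0.2, 0.1), protective weights b1, b2 = (0.6, 0.4),
    temporal gain g = 0.2, a 0.1 floor on each denominator term and a 2.0
    score cap.
    """

    a1: float = 0.4
    a2: float = 0.3
    a3: float = 0.2
    a4: float = 0.1
    b1: float = 0.6
    b2: float = 0.4
    g: float = 0.2
    term_floor: float = 0.1
    score_cap: float = 2.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4", "b1", "b2", "g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"coefficient {name} must be positive")
        if not self.term_floor > 0:
            raise ValueError("term_floor must be positive")
        if not self.score_cap > 0:
            raise ValueError("score_cap must be positive")

    def alphas(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "CoefficientSet":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown coefficient keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def replace(self, **kwargs) -> "CoefficientSet":
        d = self.to_dict()
        d.update(kwargs)
        return CoefficientSet(**d)


@dataclass(frozen=True)
class RawMeasurement:
    """One time-stamped sample of the seven channels in physical units."""

    t: float  # seconds from session start
    E: float  # % of MVC
    dI: float  # ms
    phi: float  # dimensionless ratio
    e_env: float  # dimensionless composite
    C: float  # % capacity
    S: float  # hours
    T: float  # dimensionless


@dataclass(frozen=True)
class FactorVector:
    """Normalized, dimensionless factors entering the equation."""

    e_n: float
    di_n: float
    phi_n: float
    env_n: float
    c_n: float
    s_n: float
    t_n: float

    def as_tuple(self) -> tuple:
        return (self.e_n, self.di_n, self.phi_n, self.env_n,
                self.c_n, self.s_n, self.t_n)


@dataclass(frozen=True)
class ScoredSample:
    """Score decomposition for one sample.

    ``raw_score`` is the pre-cap value; ``score`` = min(raw_score, cap).
    The numerator / denominator / multiplier are retained so capped values
    remain distinguishable from native ones and audits can re-derive the
    arithmetic.
    """

    raw_score: float
    score: float
    category: str
    numerator: float
    denominator: float
    multiplier: float


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value for field {name!r}: {value}")
    return value


def normalize(raw: RawMeasurement) -> FactorVector:
    """Map a physical-unit measurement to the dimensionless factor space.

    E, dI and C divide by their full scales (100 %, 500 ms, 100 %); phi and
    the environmental composite pass through unchanged; sleep hours divide
    by the 10 h full scale (so 7.0 h -> 0.70); T clamps to [0, 1].  Inputs
    are clipped
    to their physical ranges first, and non-finite fields are rejected with
    the offending field named.
    """
    vals = {}
    for name in ("t", "E", "dI", "phi", "e_env", "C", "S", "T"):
        vals[name] = _check_finite(name, getattr(raw, name))
    if vals["t"] < 0:
        raise ValueError("t must be non-negative")
    clipped = {k: min(max(vals[k], lo), hi) for k, (lo, hi) in _RAW_RANGES.items()}
    return FactorVector(
        e_n=clipped["E"] / 100.0,
        di_n=clipped["dI"] / 500.0,
        phi_n=clipped["phi"],
        env_n=clipped["e_env"],
        c_n=clipped["C"] / 100.0,
        s_n=clipped["S"] / 10.0,
        t_n=clipped["T"],
    )


# Raw-channel CSV columns, in the order the factor arrays expect.
_FRAME_COLS = ("E_pct", "dI_ms", "phi", "e_env", "C_pct", "S_hours", "T")


def normalize_frame(frame: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`normalize` over the raw-channel columns of ``frame``.

    Returns an (n, 7) array with columns (e_n, di_n, phi_n, env_n, c_n,
    s_n, t_n).
    """
    missing = [c for c in _FRAME_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing raw-measurement columns: {missing}")
    arr = frame.loc[:, list(_FRAME_COLS)].to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        bad = [_FRAME_COLS[j] for j in np.where(~np.isfinite(arr).all(axis=0))[0]]
        raise ValueError(f"non-finite values in columns: {bad}")
    out = np.empty_like(arr)
    out[:, 0] = np.clip(arr[:, 0], 0.0, 100.0) / 100.0
    out[:, 1] = np.clip(arr[:, 1], 0.0, 500.0) / 500.0
    out[:, 2] = np.clip(arr[:, 2], 0.0, 2.0)
    out[:, 3] = np.clip(arr[:, 3], 0.0, 1.0)
    out[:, 4] = np.clip(arr[:, 4], 0.0, 100.0) / 100.0
    out[:, 5] = np.clip(arr[:, 5], 5.0, 9.0) / 10.0
    out[:, 6] = np.clip(arr[:, 6], 0.0, 1.0)
    return out


def classify_risk(score: float, score_cap: float = 2.0) -> str:
    """Assign the risk band of a capped score (left-closed band edges)."""
    score = float(score)
    if not math.isfinite(score) or score < 0 or score > score_cap:
        raise ValueError(f"score {score} outside [0, {score_cap}]")
    lo, mid, hi = RISK_BAND_EDGES
    if score < lo:
        return "low"
    if score < mid:
        return "moderate"
    if score < hi:
        return "high"
    return "critical"


def classify_risk_array(scores: np.ndarray, score_cap: float = 2.0) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite score")
    if (scores < 0).any() or (scores > score_cap).any():
        raise ValueError(f"score outside [0, {score_cap}]")
    idx = np.searchsorted(np.asarray(RISK_BAND_EDGES), scores, side="right")
    return np.asarray(RISK_CATEGORIES, dtype=object)[idx]


def compute_score(f: FactorVector, c: CoefficientSet | None = None) -> ScoredSample:
    """Evaluate the convergence equation on a normalized factor vector."""
    c = c or CoefficientSet()
    numerator = c.a1 * f.e_n + c.a2 * f.di_n + c.a3 * f.phi_n + c.a4 * f.env_n
    denominator = max(c.b1 * f.c_n, c.term_floor) * max(c.b2 * f.s_n, c.term_floor)
    multiplier = 1.0 + c.g * f.t_n
    raw_score = numerator / denominator * multiplier
    score = min(raw_score, c.score_cap)
    return ScoredSample(
        raw_score=raw_score,
        score=score,
        category=classify_risk(score, c.score_cap),
        numerator=numerator,
        denominator=denominator,
        multiplier=multiplier,
    )


def score_measurement(raw: RawMeasurement, c: CoefficientSet | None = None) -> ScoredSample:
    """Normalize then score one physical-unit measurement."""
    return compute_score(normalize(raw), c)


def score_factor_arrays(factors: np.ndarray, c: CoefficientSet | None = None):
    """Vectorized scoring of an (n, 7) normalized factor array.

    Returns ``(raw_score, score, category)`` arrays.  This is the hot path
    used by the cohort simulator and the coefficient-perturbation Monte
    Carlo.
    """
    c = c or CoefficientSet()
    f = np.asarray(factors, dtype=float)
    if f.ndim != 2 or f.shape[1] != 7:
        raise ValueError("factors must be an (n, 7) array")
    numerator = f[:, :4] @ c.alphas()
    denominator = (np.maximum(c.b1 * f[:, 4], c.term_floor)
                   * np.maximum(c.b2 * f[:, 5], c.term_floor))
    raw = numerator / denominator * (1.0 + c.g * f[:, 6])
    score = np.minimum(raw, c.score_cap)
    return raw, score, classify_risk_array(score, c.score_cap)
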