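"""Dataset CSV schema, run manifests and provenance.

The long-format dataset schema (fixed column order)::

    timestamp_ms, athlete_id, sport, E_pct, dI_ms, phi, e_env, C_pct,
    S_hours, T, wase_score, risk_category, sensitivity_pct,
    specificity_pct [, label, noise_free_score]

Files are RFC-4180 CSV, UTF-8, '.' decimal separator, floats at six
significant digits.  The per-row sensitivity/specificity columns carry the
run's *global* operating-point values at the default 0.75 cutoff (the
schema places per-run metrics in per-row columns; blank when undefined).
A run manifest (JSON) snapshots the configuration, seeds, package version
and output checksums so any output can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scoring import RISK_CATEGORIES
from .simulate import CohortDataset, SessionConfig, simulate_cohort

__all__ = [
    "SCHEMA_COLUMNS",
    "OPTIONAL_COLUMNS",
    "write_dataset",
    "read_dataset",
    "ReadReport",
    "RunManifest",
    "build_manifest",
    "write_manifest",
    "read_manifest",
    "reproduce_from_manifest",
]

SCHEMA_COLUMNS = (
    "timestamp_ms", "athlete_id", "sport", "E_pct", "dI_ms", "phi", "e_env",
    "C_pct", "S_hours", "T", "wase_score", "risk_category",
    "sensitivity_pct", "specificity_pct",
)
OPTIONAL_COLUMNS = ("label", "noise_free_score")

_FLOAT_COLS = ("E_pct", "dI_ms", "phi", "e_env", "C_pct", "S_hours", "T",
               "wase_score", "sensitivity_pct", "specificity_pct",
               "noise_free_score")
_INT_COLS = ("timestamp_ms", "athlete_id", "label")

# S is stored in hours; the schema admits [0, 10] even though the sleep
# model draws from [5, 9].
_VALID_RANGES = {"S_hours": (0.0, 10.0), "wase_score": (0.0, 2.0)}


def _validate_schema(df: pd.DataFrame) -> None:
    for col in SCHEMA_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"dataset missing mandatory column {col!r}")
    bad_cat = set(df["risk_category"].unique()) - set(RISK_CATEGORIES)
    if bad_cat:
        raise ValueError(f"invalid risk_category values: {sorted(bad_cat)}")
    if (df["timestamp_ms"].to_numpy() < 0).any():
        raise ValueError("column 'timestamp_ms' contains negative values")
    for col, (lo, hi) in _VALID_RANGES.items():
        v = df[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size and ((v < lo) | (v > hi)).any():
            raise ValueError(f"column {col!r} outside [{lo}, {hi}]")


def _as_schema_frame(dataset, cutoff: float = 0.75) -> pd.DataFrame:
    """Arrange a cohort (or frame) into schema column order, filling the
    global operating-point columns."""
    frame = dataset.frame if isinstance(dataset, CohortDataset) else dataset
    fillable = {"sensitivity_pct", "specificity_pct"}
    for col in SCHEMA_COLUMNS:
        if col not in frame.columns and col not in fillable:
            raise ValueError(f"dataset missing mandatory column {col!r}")
    df = frame.copy()
    if "sensitivity_pct" not in df.columns or "specificity_pct" not in df.columns:
        sens = spec = math.nan
        if "label" in df.columns and len(df):
            labels = df["label"].to_numpy()
            if labels.min() != labels.max():
                from .validate import operating_point
                op = operating_point(df["wase_score"].to_numpy(), labels, cutoff)
                sens, spec = op.sensitivity_pct, op.specificity_pct
        df["sensitivity_pct"] = sens
        df["specificity_pct"] = spec
    cols = list(SCHEMA_COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    return df[cols]


def write_dataset(dataset, path, cutoff: float = 0.75) -> Path:
    """Write a scored dataset as schema CSV; returns the path written."""
    path = Path(path)
    df = _as_schema_frame(dataset, cutoff=cutoff)
    _validate_schema(df)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n",
              encoding="utf-8")
    return path


@dataclass
class ReadReport:
    frame: pd.DataFrame
    n_rejected: int
    rejected: pd.DataFrame
    warnings: list


def read_dataset(path) -> ReadReport:
    """Read a schema CSV back into a typed frame.

    The header must contain every mandatory column with exact
    (case-sensitive) names; extra columns are tolerated with a warning.
    Rows that fail numeric coercion are collected into the rejection
    report rather than silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    warnings_list = []
    for col in SCHEMA_COLUMNS:
        if col not in df.columns:
            lower = {c.lower(): c for c in df.columns}
            hint = (f" (found {lower[col.lower()]!r}; header is case-sensitive)"
                    if col.lower() in lower else "")
            raise ValueError(f"missing mandatory column {col!r}{hint}")
    extra = [c for c in df.columns
             if c not in SCHEMA_COLUMNS and c not in OPTIONAL_COLUMNS]
    if extra:
        warnings_list.append(f"ignoring extra columns: {extra}")

    out = df.copy()
    bad = np.zeros(len(df), dtype=bool)
    for col in out.columns:
        if col in ("sport", "risk_category"):
            continue
        if col in _INT_COLS or col in _FLOAT_COLS:
            num = pd.to_numeric(out[col].replace("", np.nan), errors="coerce")
            allow_na = col in ("sensitivity_pct", "specificity_pct")
            bad |= num.isna().to_numpy() & (out[col].to_numpy() != "") \
                if allow_na else (num.isna().to_numpy()
                                  if col in _INT_COLS or col in
                                  ("E_pct", "dI_ms", "phi", "e_env", "C_pct",
                                   "S_hours", "T", "wase_score")
                                  else np.zeros(len(df), bool))
            out[col] = num
    bad |= ~df["risk_category"].isin(RISK_CATEGORIES).to_numpy()

    rejected = df[bad].copy()
    good = out[~bad].copy()
    for col in _INT_COLS:
        if col in good.columns:
            good[col] = good[col].astype(np.int64)
    for col in _FLOAT_COLS:
        if col in good.columns:
            good[col] = good[col].astype(float)
    good = good.reset_index(drop=True)
    _validate_schema(good)
    return ReadReport(frame=good, n_rejected=int(bad.sum()),
                      rejected=rejected, warnings=warnings_list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    athlete_seeds: list
    package_version: str
    created_utc: str
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def to_dict(self) -> dict:
        return {"config": self.config, "master_seed": self.master_seed,
                "athlete_seeds": self.athlete_seeds,
                "package_version": self.package_version,
                "created_utc": self.created_utc, "outputs": self.outputs}


def build_manifest(dataset: CohortDataset, outputs: dict | None = None) -> RunManifest:
    cfg = dataset.config
    return RunManifest(
        config=cfg.to_dict(),
        master_seed=cfg.master_seed,
        athlete_seeds=[p.seed for p in dataset.profiles],
        package_version=__version__,
        created_utc=datetime.now(timezone.utc).isoformat(),
        outputs={str(k): v for k, v in (outputs or {}).items()},
    )


def write_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(path) -> RunManifest:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return RunManifest(**d)


def _config_from_dict(d: dict) -> SessionConfig:
    from .scoring import CoefficientSet
    d = dict(d)
    d["rho_targets"] = {tuple(k.split("|")): v
                        for k, v in d.get("rho_targets", {}).items()}
    d["coefficients"] = CoefficientSet(**d["coefficients"])
    for key in ("e0_range", "k_range", "di0_range", "couple_range",
                "phi_range", "env_range", "c_clip", "s_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SessionConfig(**d)


def reproduce_from_manifest(manifest: RunManifest, out_csv=None,
                            verify: bool = True) -> CohortDataset:
    """Re-run a simulation from its manifest; optionally rewrite the CSV
    and verify output checksums match the recorded ones."""
    cfg = _config_from_dict(manifest.config)
    dataset = simulate_cohort(cfg)
    if out_csv is not None:
        path = write_dataset(dataset, out_csv)
        if verify and manifest.outputs:
            digest = _sha256(path)
            recorded = set(manifest.outputs.values())
            if digest not in recorded:
                raise RuntimeError(
                    f"reproduced output checksum {digest} does not match the "
                    f"manifest ({sorted(recorded)})")
    return dataset
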