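"""CSV and YAML readers/writers, plus run manifests.

User CSV schema (header names fixed; empty cell = unknown value):
``age, sex, smoker, diabetes, height, weight, sbp, on_bp_medication,
total_cholesterol, family_history``.  Booleans serialize as true/false;
files are UTF-8, comma-delimited, RFC-4180 quoted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .engine import HeartAgeResult, ModelConfig
from .errors import SchemaError
from .risk import RiskProfile

USER_CSV_COLUMNS = [
    "age",
    "sex",
    "smoker",
    "diabetes",
    "height",
    "weight",
    "sbp",
    "on_bp_medication",
    "total_cholesterol",
    "family_history",
]

RESULT_CSV_COLUMNS = [
    "age",
    "sex",
    "heart_age_display",
    "heart_age_raw",
    "category",
    "risk",
    "sbp_imputed",
    "cholesterol_imputed",
    "advisories",
]

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}

_PACKAGED_CONFIGS = {
    "lipid": "framingham_lipid.yaml",
    "bmi": "framingham_bmi.yaml",
}


def load_model_config(
    path: Optional[str | Path] = None, name: str = "lipid"
) -> ModelConfig:
    """Load a model configuration from a YAML file or a packaged default."""
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        if name not in _PACKAGED_CONFIGS:
            raise SchemaError(
                f"unknown packaged config {name!r}; choose from "
                f"{sorted(_PACKAGED_CONFIGS)}"
            )
        text = (
            resources.files("heartage.data")
            .joinpath(_PACKAGED_CONFIGS[name])
            .read_text(encoding="utf-8")
        )
    return ModelConfig.from_dict(yaml.safe_load(text))


@dataclass
class RowError:
    line: int  # 1-based physical line in the file (header is line 1)
    message: str


def _parse_bool(raw: str, column: str, line: int) -> bool:
    value = raw.strip().lower()
    if value in _TRUE:
        return True
    if value in _FALSE:
        return False
    raise ValueError(f"line {line}: cannot parse {column}={raw!r} as boolean")


def _parse_float(raw: str, column: str, line: int) -> Optional[float]:
    value = raw.strip()
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"line {line}: cannot parse {column}={raw!r} as number")


def read_user_csv(path: str | Path) -> tuple[list[RiskProfile], list[RowError]]:
    """Read user records; malformed rows are collected, not fatal.

    Raises :class:`SchemaError` if a required column is missing entirely.
    Empty SBP/cholesterol cells become unknown values (flags false).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in USER_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"user CSV is missing required columns: {missing}")
    profiles: list[RiskProfile] = []
    errors: list[RowError] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header occupies line 1
        try:
            age = _parse_float(row["age"], "age", line)
            height = _parse_float(row["height"], "height", line)
            weight = _parse_float(row["weight"], "weight", line)
            if age is None or height is None or weight is None:
                raise ValueError(f"line {line}: age, height and weight are required")
            sbp = _parse_float(row["sbp"], "sbp", line)
            tc = _parse_float(row["total_cholesterol"], "total_cholesterol", line)
            profiles.append(
                RiskProfile(
                    age=age,
                    sex=row["sex"].strip().lower(),
                    smoker=_parse_bool(row["smoker"], "smoker", line),
                    diabetes=_parse_bool(row["diabetes"], "diabetes", line),
                    height=height,
                    weight=weight,
                    sbp=sbp,
                    on_bp_medication=_parse_bool(
                        row["on_bp_medication"], "on_bp_medication", line
                    ),
                    total_cholesterol=tc,
                    family_history=_parse_bool(
                        row["family_history"], "family_history", line
                    ),
                )
            )
        except Exception as exc:  # collect per-row, keep going
            errors.append(RowError(line=line, message=str(exc)))
    return profiles, errors


def results_to_frame(
    profiles: list[RiskProfile], results: list[HeartAgeResult]
) -> pd.DataFrame:
    rows = []
    for profile, result in zip(profiles, results):
        rows.append(
            {
                "age": profile.age,
                "sex": profile.sex,
                "heart_age_display": result.heart_age_display,
                "heart_age_raw": result.heart_age_raw,
                "category": result.category if result.category else "",
                "risk": result.risk.risk if result.risk else float("nan"),
                "sbp_imputed": result.sbp_imputed,
                "cholesterol_imputed": result.cholesterol_imputed,
                "advisories": "; ".join(m.message for m in result.advisories),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_CSV_COLUMNS)


def write_results_csv(
    profiles: list[RiskProfile],
    results: list[HeartAgeResult],
    path: str | Path,
) -> None:
    """Write results in stable column order; censored ages keep their
    display string (e.g. "<35") alongside the raw value."""
    frame = results_to_frame(profiles, results)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_results_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"heart_age_display": str, "category": str, "advisories": str},
        keep_default_na=False,
        encoding="utf-8",
    )
    for column in ("age", "heart_age_raw", "risk"):
        frame[column] = pd.to_numeric(frame[column], errors="coerce")
    for column in ("sbp_imputed", "cholesterol_imputed"):
        frame[column] = frame[column].map(lambda v: str(v).lower() in _TRUE)
    return frame


@dataclass
class RunManifest:
    """Provenance side-file: one per CLI run."""

    command: str
    config_hash: str
    seed: Optional[int]
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "package_version": self.package_version,
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
        }
        Path(path).write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8"
        )


def hash_config(path: Optional[str | Path]) -> str:
    """SHA-256 of the config file contents ('' keys the packaged default)."""
    if path is None:
        return "packaged-default"
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
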