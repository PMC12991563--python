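"""Delimited-text interchange, configuration loading and provenance headers.

All tables move as UTF-8 CSV with a header row.  Files written by the
pipeline start with ``#``-prefixed provenance comment lines (package
version, seed, config hash); readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .pk_models import DrugModelSpec

PARTICIPANT_COLUMNS = [
    "participant_id",
    "set_id",
    "group",
    "sex",
    "weight_kg",
    "height_m",
    "dose_pyrazinamide_mg",
    "dose_rifampicin_mg",
]

CONCENTRATION_COLUMNS = [
    "participant_id",
    "drug",
    "week",
    "visit_day",
    "concentration_mg_L",
    "blq",
]

THRESHOLD_COLUMNS = [
    "participant_id",
    "drug",
    "week",
    "time_h",
    "percentile",
    "threshold_mg_L",
    "informative",
    "n_sim",
    "seed",
]


class SchemaError(ValueError):
    """An input table violates the documented column/value contract."""


def _spec_from_mapping(drug: str, mapping: dict) -> DrugModelSpec:
    mapping = dict(mapping)
    bsv = {k: float(v) for k, v in mapping.pop("bsv").items()}
    return DrugModelSpec(drug=drug, bsv=bsv, **{k: v for k, v in mapping.items()})


def load_drug_models(path: str | Path | None = None) -> dict[str, DrugModelSpec]:
    """Load drug model specs from YAML; ``None`` loads the packaged defaults."""
    if path is None:
        text = resources.files("tpt_adherence.data").joinpath("drug_models.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {drug: _spec_from_mapping(drug, mapping) for drug, mapping in raw.items()}


def default_drug_models() -> dict[str, DrugModelSpec]:
    return load_drug_models(None)


DEFAULT_LLOQ = {"pyrazinamide": 0.203, "rifampicin": 0.075}


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input tables themselves."""

    outdir: Path = Path("tpt_adherence_run")
    drug_config: Path | None = None
    lloq: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LLOQ))
    n_cases: int = 28
    n_sim: int = 500
    percentiles: tuple[float, ...] = (2.5, 5.0)
    times_h: tuple[float, ...] = (24.0, 48.0)
    seed: int = 0
    exclude_late_week8: bool = False
    residual_error_in_thresholds: bool = False

    def config_hash(self) -> str:
        # the output location does not change what is computed
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items()) if k != "outdir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def provenance_header(cfg: RunConfig | None = None, **extra: object) -> list[str]:
    from . import __version__

    lines = [f"# tpt-adherence {__version__}"]
    if cfg is not None:
        lines.append(f"# seed={cfg.seed} config_hash={cfg.config_hash()}")
    for key, value in extra.items():
        lines.append(f"# {key}={value}")
    return lines


def write_csv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if required:
        validate_columns(df, required, path)
    return df


def validate_columns(df: pd.DataFrame, required: list[str], source: object = "input") -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s): {', '.join(missing)}")


def validate_concentrations(df: pd.DataFrame, source: object = "concentrations") -> None:
    """Row-level checks with line numbers (1-based, excluding the header)."""
    validate_columns(df, CONCENTRATION_COLUMNS, source)
    bad_week = ~df["week"].isin([2, 4, 8])
    for idx in df.index[bad_week]:
        raise SchemaError(f"{source}: line {idx + 1}: week must be one of 2, 4, 8")
    not_blq = ~df["blq"].astype(bool)
    neg = not_blq & (df["concentration_mg_L"] < 0)
    for idx in df.index[neg]:
        raise SchemaError(f"{source}: line {idx + 1}: negative concentration")
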