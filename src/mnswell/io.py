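"""CSV/JSON/YAML readers and writers for the pipeline's file dialects.

All CSVs are comma-separated, UTF-8, with a header row and ``.`` decimals;
no locale inference.  Column names per stage:

* profile:  ``x_um,r_um``
* swelling: ``t_min,mass_mg`` (scalars like ``m0_mg`` in a sidecar/metadata mapping)
* release:  ``t_min,C_sample_mg_per_mL``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .exceptions import ValidationError
from .geometry import RadialProfile
from .release import ReleaseSeries
from .swelling import MassSeries

PROFILE_COLUMNS = ["x_um", "r_um"]
SWELLING_COLUMNS = ["t_min", "mass_mg"]
RELEASE_COLUMNS = ["t_min", "C_sample_mg_per_mL"]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message shaping
        raise ValidationError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}; "
                              f"expected header {','.join(columns)}")
    bad = df[columns].isna().any(axis=1)
    if bad.any():
        raise ValidationError(f"{path}: non-numeric or missing value at data line "
                              f"{int(bad.idxmax()) + 2}")
    return df


def read_profile_csv(path: str | Path, label: str = "") -> RadialProfile:
    df = _read_csv(path, PROFILE_COLUMNS)
    return RadialProfile(x=df["x_um"].to_numpy(float), r=df["r_um"].to_numpy(float),
                         label=label or Path(path).stem)


def write_profile_csv(path: str | Path, profile: RadialProfile) -> None:
    pd.DataFrame({"x_um": profile.x, "r_um": profile.r}).to_csv(path, index=False)


def read_swelling_csv(path: str | Path, m0: float) -> MassSeries:
    df = _read_csv(path, SWELLING_COLUMNS)
    return MassSeries(t=df["t_min"].to_numpy(float), m=df["mass_mg"].to_numpy(float), m0=m0)


def write_swelling_csv(path: str | Path, series: MassSeries) -> None:
    pd.DataFrame({"t_min": series.t, "mass_mg": series.m}).to_csv(path, index=False)


def read_release_csv(path: str | Path, V_reservoir: float = 14.0,
                     V_aliquot: float = 1.0) -> ReleaseSeries:
    df = _read_csv(path, RELEASE_COLUMNS)
    return ReleaseSeries(t=df["t_min"].to_numpy(float),
                         C_sample=df["C_sample_mg_per_mL"].to_numpy(float),
                         V_reservoir=V_reservoir, V_aliquot=V_aliquot)


def write_release_csv(path: str | Path, series: ReleaseSeries) -> None:
    pd.DataFrame({"t_min": series.t,
                  "C_sample_mg_per_mL": series.C_sample}).to_csv(path, index=False)


def load_metadata(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON metadata mapping (sidecar scalars, configs)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return data


def write_json(path: str | Path, obj: Any) -> None:
    """Write JSON deterministically (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
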