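"""Tabular IO for fragment-ion reports, result tables and run configuration.

The pipeline's unit of input is a long-format fragment report: one row per
fragment ion x channel x sample, as exported by a DIA extraction tool.  The
column header set differs between vendors, so the reader takes a *dialect*
mapping from the canonical column names used throughout this package to the
names found in the file.  The canonical schema is:

======================  =======================================================
column                  meaning
======================  =======================================================
bait                    affinity handle (bait protein) of the pulldown
condition               ``treated`` / ``control`` / ``none``
replicate               biological replicate number (>= 1)
time_min                minutes post labeling onset (0 = pre-pulse)
protein_id              protein the fragment is assigned to
is_proteotypic          peptide maps to exactly one protein
precursor_id            peptide sequence + charge
fragment_series         ``y`` or ``b``
fragment_index          fragment series index (>= 1)
fragment_charge         fragment charge (>= 1)
channel                 ``light`` or ``heavy``
intensity               extracted ion intensity (a.u.); 0/empty = not detected
excluded                extraction tool's exclude-from-quantification flag
lysine_count            number of lysines in the peptide
missed_cleavages        tryptic missed cleavages
======================  =======================================================

Intensity 0 and an empty cell both mean "not detected"; detection is defined
as intensity > 0 everywhere downstream.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "FRAGMENT_COLUMNS",
    "SAMPLE_KEY",
    "FormatError",
    "read_fragment_report",
    "write_table",
    "read_table",
    "RunConfig",
    "load_config",
    "save_config",
]

#: sample-identifying columns, in canonical order
SAMPLE_KEY = ["bait", "condition", "replicate", "time_min"]

#: full canonical fragment-report schema
FRAGMENT_COLUMNS = SAMPLE_KEY + [
    "protein_id", "is_proteotypic", "precursor_id",
    "fragment_series", "fragment_index", "fragment_charge",
    "channel", "intensity", "excluded", "lysine_count", "missed_cleavages",
]

_BOOL_COLUMNS = ("is_proteotypic", "excluded")
_INT_COLUMNS = ("replicate", "fragment_index", "fragment_charge",
                "lysine_count", "missed_cleavages")
_CHANNELS = frozenset({"light", "heavy"})


class FormatError(ValueError):
    """Input table does not conform to the expected schema."""


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


def _to_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    vals = series.astype(str).str.strip().str.lower()
    bad = ~(vals.isin(_TRUTHY) | vals.isin(_FALSY))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"column {name!r}: unparseable boolean {series.iloc[row]!r} "
            f"at data row {row}")
    return vals.isin(_TRUTHY)


def read_fragment_report(path, dialect: Mapping[str, str] | None = None,
                         sep: str | None = None) -> pd.DataFrame:
    """Read a long-format fragment-ion report into the canonical schema.

    Parameters
    ----------
    path : path-like
        Delimited text file (TSV by default, CSV accepted), UTF-8, one
        fragment x channel x sample per row.
    dialect : mapping, optional
        ``{canonical name: column name in the file}`` for any columns whose
        header differs from the canonical one.
    sep : str, optional
        Field separator; sniffed from the header line when omitted.

    Returns
    -------
    pandas.DataFrame
        One row per input row (order preserved) with the canonical columns,
        empty/zero intensities normalised to 0.0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      encoding="utf-8")
    rename = {v: k for k, v in (dialect or {}).items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in FRAGMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"fragment report {path.name} lacks required column(s): "
            + ", ".join(missing))
    df = raw.loc[:, FRAGMENT_COLUMNS].copy()

    chan = df["channel"].str.strip().str.lower()
    bad = ~chan.isin(_CHANNELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown channel label {df['channel'].iloc[row]!r} at data row "
            f"{row} (expected 'light' or 'heavy')")
    df["channel"] = chan

    inten = df["intensity"].str.strip().replace({"": "0", "NA": "0",
                                                 "NaN": "0", "nan": "0"})
    try:
        df["intensity"] = pd.to_numeric(inten, errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unreadable intensity value: {exc}") from None
    df["intensity"] = df["intensity"].fillna(0.0)
    if (df["intensity"] < 0).any():
        row = int(np.flatnonzero((df["intensity"] < 0).to_numpy())[0])
        raise ValueError(f"negative intensity at data row {row}")

    try:
        df["time_min"] = pd.to_numeric(df["time_min"], errors="raise").astype(float)
        for col in _INT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unreadable number: {exc}") from None
    for col in _BOOL_COLUMNS:
        df[col] = _to_bool(df[col], col)
    if (df["replicate"] < 1).any():
        raise ValueError("replicate numbers must be >= 1")
    if (df["time_min"] < 0).any():
        raise ValueError("time_min must be non-negative")
    return df


def write_table(path, rows: pd.DataFrame, sep: str = "\t") -> None:
    """Write a result table as delimited UTF-8 text with a header line.

    Floats are serialised with ``repr`` round-trip precision, so a
    write/read cycle reproduces integer columns bitwise and real columns to
    better than 1e-12 relative.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    return pd.read_csv(path, sep=sep or _sniff_sep(path), encoding="utf-8")


class RunConfig(BaseModel):
    """Validated run configuration for the pipeline.

    Defaults follow the package's standard analysis: presence in at least
    two of three replicates at every post-labeling time point, discard of
    the 50% highest-RMSE precursors per protein, detection threshold 0
    (intensity > 0), summing of all retained fragments per precursor.
    """

    min_reps_per_timepoint: int = Field(default=2, ge=0)
    discard_fraction: float = Field(default=0.5, ge=0.0, lt=1.0)
    detection_threshold: float = Field(default=0.0, ge=0.0)
    aggregation: str = Field(default="sum_all")
    both_channels_scope: str = Field(default="experiment")
    tier_map: dict[str, str] = Field(default_factory=dict)
    doubling_time_min: float = Field(default=120.0, gt=0.0)
    seed: int = Field(default=0, ge=0)

    @field_validator("aggregation")
    @classmethod
    def _check_aggregation(cls, v: str) -> str:
        if v not in {"sum_all", "top3"}:
            raise ValueError("aggregation must be 'sum_all' or 'top3'")
        return v

    @field_validator("both_channels_scope")
    @classmethod
    def _check_scope(cls, v: str) -> str:
        if v not in {"experiment", "sample"}:
            raise ValueError("both_channels_scope must be 'experiment' or 'sample'")
        return v

    @field_validator("tier_map")
    @classmethod
    def _check_tiers(cls, v: dict[str, str]) -> dict[str, str]:
        allowed = {"early", "intermediate", "late"}
        bad = {t for t in v.values() if t not in allowed}
        if bad:
            raise ValueError(f"unknown assembly tier(s): {sorted(bad)}")
        return v


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
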