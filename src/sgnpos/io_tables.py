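"""Per-neuron feature tables: the merged row schema and CSV/spreadsheet I/O.

Two dialects are supported: ``package_csv`` (this package's canonical,
round-trippable CSV) and ``paper_source_data`` (deposited per-figure
spreadsheets/CSVs with a user-supplied column map, since the deposited
column headers are not standardized)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureRecord",
    "FEATURE_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "read_feature_table",
    "write_feature_table",
]

_FLOAT_FMT = "%.17g"


@dataclass
class FeatureRecord:
    """One neuron's merged current-clamp, voltage-clamp and position row."""

    neuron_id: str
    age: int
    fiber_type: str = "type_I"
    nbp: float | None = None
    face_class: str | None = None
    spiking: bool | None = None
    firing_pattern: str | None = None
    i_threshold: float | None = None
    v_threshold: float | None = None
    first_spike_latency: float | None = None
    response_latency: float | None = None
    ahp_tau: float | None = None
    resting_potential: float | None = None
    ap_height: float | None = None
    g_max: float | None = None
    g_minus30: float | None = None
    v_half: float | None = None
    tau_inact: float | None = None
    vc_excluded: bool = False
    tau_excluded: bool = False

    def __post_init__(self):
        if self.nbp is not None and not np.isnan(self.nbp):
            if not -1.0 <= self.nbp <= 1.0:
                raise ValueError("nbp outside [-1, 1]")
        if self.vc_excluded and self.g_max is not None and not np.isnan(self.g_max):
            raise ValueError("vc_excluded implies g_max missing")
        if self.tau_excluded and self.tau_inact is not None and not np.isnan(self.tau_inact):
            raise ValueError("tau_excluded implies tau_inact missing")


FEATURE_COLUMNS = [f.name for f in dataclasses.fields(FeatureRecord)]
_NUMERIC = ["age", "nbp", "i_threshold", "v_threshold", "first_spike_latency",
            "response_latency", "ahp_tau", "resting_potential", "ap_height",
            "g_max", "g_minus30", "v_half", "tau_inact"]
_MANDATORY = ["neuron_id", "age"]


def records_to_frame(records: list) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records],
                      columns=FEATURE_COLUMNS)
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col])
    return df


def frame_to_records(df: pd.DataFrame) -> list:
    records = []
    for row in df.to_dict("records"):
        kwargs = {}
        for key in FEATURE_COLUMNS:
            val = row.get(key)
            if isinstance(val, float) and np.isnan(val):
                val = None
            kwargs[key] = val
        kwargs["age"] = int(kwargs["age"])
        for flag in ("vc_excluded", "tau_excluded"):
            kwargs[flag] = bool(kwargs[flag]) if kwargs[flag] is not None else False
        if kwargs["spiking"] is not None:
            kwargs["spiking"] = bool(kwargs["spiking"])
        records.append(FeatureRecord(**kwargs))
    return records


def write_feature_table(records, path):
    """Write records (list of FeatureRecord or DataFrame) as canonical CSV."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _clean_numeric(series: pd.Series, col: str) -> pd.Series:
    """Parse a numeric column tolerating unicode minus signs and thousands
    separators; raises with row-level diagnostics on anything else."""
    raw = series.astype("string")
    cleaned = (raw.str.replace("−", "-", regex=False)
                  .str.replace(",", "", regex=False)
                  .str.strip())

    def parse(s):
        # python float() is correctly rounded; pandas' fast parser is not
        if s is pd.NA or s == "":
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    out = cleaned.map(parse).astype(float)
    bad = cleaned.notna() & (cleaned != "") & out.isna()
    if bad.any():
        rows = [int(i) + 2 for i in series.index[bad][:10]]  # 1-based + header
        raise ValueError(
            f"column {col!r}: unparseable numeric values at file rows {rows} "
            f"(e.g. {series[bad].iloc[0]!r})")
    return out


def read_feature_table(path, dialect: str = "package_csv",
                       column_map: dict | None = None) -> list:
    """Load a feature table as a list of :class:`FeatureRecord`.

    ``package_csv`` expects the canonical column set.  ``paper_source_data``
    reads a deposited spreadsheet (.xlsx) or CSV and renames columns through
    ``column_map`` ({source column -> canonical field}); unknown source
    columns are ignored, and fields absent from the map load as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "package_csv":
        df = pd.read_csv(path, dtype="string")
        missing = [c for c in _MANDATORY if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        for col in FEATURE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        for col in _NUMERIC:
            df[col] = _clean_numeric(df[col], col)
        for col in ("spiking", "vc_excluded", "tau_excluded"):
            df[col] = df[col].map(
                {"True": True, "False": False, "true": True, "false": False})
        return frame_to_records(df[FEATURE_COLUMNS])
    if dialect == "paper_source_data":
        if column_map is None:
            raise ValueError("paper_source_data dialect requires a column_map")
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path, dtype="string")
        else:
            df = pd.read_csv(path, dtype="string")
        df = df.rename(columns=column_map)
        keep = [c for c in df.columns if c in FEATURE_COLUMNS]
        df = df[keep]
        if "neuron_id" not in df.columns:
            df["neuron_id"] = [f"row{i:04d}" for i in range(len(df))]
        if "age" not in df.columns:
            raise ValueError("column_map must provide an 'age' column")
        for col in FEATURE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        for col in _NUMERIC:
            df[col] = _clean_numeric(df[col], col)
        for col in ("vc_excluded", "tau_excluded"):
            df[col] = df[col].map(lambda v: str(v).lower() == "true", na_action="ignore")
        if df["spiking"].isna().all() and df["i_threshold"].notna().any():
            df["spiking"] = df["i_threshold"].notna()
        return frame_to_records(df[FEATURE_COLUMNS])
    raise ValueError(f"unknown dialect {dialect!r}")
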