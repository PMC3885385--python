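"""Reading and writing the pipeline's delimited text tables.

All tables are UTF-8, comma-separated with a header row:

* occurrences: square_id, survey_index (1 or 2), year, species_id
* squares: square_id, altitude_m, altitudinal_range_m
* sti: species_id, group, sti
* stations: station_id, altitude_m, year, month (1–12), mean_temp_c
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .indices import StiTable
from .simulate import StationSeries, SurveyDataset

__all__ = [
    "SchemaError",
    "write_survey_dataset",
    "write_station_series",
    "write_sti_table",
    "read_survey_dataset",
    "read_sti_table",
    "read_station_series",
]

logger = logging.getLogger(__name__)

OCCURRENCE_SCHEMA = ("square_id", "survey_index", "year", "species_id")
SQUARE_SCHEMA = ("square_id", "altitude_m", "altitudinal_range_m")
STI_SCHEMA = ("species_id", "group", "sti")
STATION_SCHEMA = ("station_id", "altitude_m", "year", "month", "mean_temp_c")


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, schema: tuple[str, ...], path) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _check_numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[converted.isna() & df[column].notna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise SchemaError(f"{path}: non-numeric {column!r} at file row(s) {rows}")
    return converted


def write_survey_dataset(dataset: SurveyDataset, outdir, prefix: str = "") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / f"{prefix}occurrences.csv",
        "squares": outdir / f"{prefix}squares.csv",
    }
    dataset.occurrences.to_csv(paths["occurrences"], index=False)
    dataset.squares.to_csv(paths["squares"], index=False)
    return paths


def write_sti_table(sti: StiTable, outdir, prefix: str = "") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{prefix}sti.csv"
    sti.entries.to_csv(path, index=False)
    return path


def write_station_series(series: StationSeries, outdir, prefix: str = "") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{prefix}stations.csv"
    series.records.to_csv(path, index=False)
    return path


def read_survey_dataset(occurrences_path, squares_path) -> SurveyDataset:
    """Read and validate occurrence + square tables.

    Duplicate occurrence rows are collapsed to presence/absence with the
    dropped count logged; schema violations raise :class:`SchemaError`.
    """
    occ = pd.read_csv(occurrences_path)
    _check_columns(occ, OCCURRENCE_SCHEMA, occurrences_path)
    occ["survey_index"] = _check_numeric(occ, "survey_index", occurrences_path).astype(int)
    if not occ["survey_index"].isin((1, 2)).all():
        raise SchemaError(f"{occurrences_path}: survey_index must be 1 or 2")
    n_before = len(occ)
    occ = occ.drop_duplicates(["square_id", "survey_index", "species_id"])
    if len(occ) < n_before:
        logger.warning("%s: dropped %d duplicate occurrence rows",
                       occurrences_path, n_before - len(occ))
    squares = pd.read_csv(squares_path)
    _check_columns(squares, SQUARE_SCHEMA, squares_path)
    squares["altitude_m"] = _check_numeric(squares, "altitude_m", squares_path)
    squares["altitudinal_range_m"] = _check_numeric(squares, "altitudinal_range_m", squares_path)
    return SurveyDataset(occ.reset_index(drop=True), squares)


def read_sti_table(path) -> StiTable:
    df = pd.read_csv(path)
    _check_columns(df, STI_SCHEMA, path)
    df["sti"] = _check_numeric(df, "sti", path)
    return StiTable(df[list(STI_SCHEMA)])


def read_station_series(path) -> StationSeries:
    df = pd.read_csv(path)
    _check_columns(df, STATION_SCHEMA, path)
    for col in ("altitude_m", "year", "month", "mean_temp_c"):
        df[col] = _check_numeric(df, col, path)
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    return StationSeries(df[list(STATION_SCHEMA)])
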