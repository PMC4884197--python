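"""Census and body-size table I/O.

The canonical census dialect is a long-format UTF-8 CSV with one row per
tube x week x stage:

    week,tube,environment,harvest,stage,count,harvested

``harvested`` is the weekly adult take and is carried on the ``adults`` rows
(empty elsewhere). A wide layout (one row per tube x week, columns ``eggs,
juveniles,adults,harvested``) is auto-detected on read. Deposited data with
different headers can be ingested by passing a column-name mapping.

Size tables are long CSVs ``tube,week,stage,length_um`` with stages
``female_adult`` / ``juvenile`` and lengths in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .regimes import HARVEST_KINDS, REGIME_LABELS

STAGES = ("eggs", "juveniles", "adults")
SIZE_STAGES = ("female_adult", "juvenile")
LENGTH_RANGE_UM = (50.0, 1500.0)

_WIDE_COLUMNS = ["week", "tube", "environment", "harvest",
                 "eggs", "juveniles", "adults", "harvested"]
_LONG_COLUMNS = ["week", "tube", "environment", "harvest", "stage", "count", "harvested"]


@dataclass(frozen=True)
class CensusRecord:
    """One tube's weekly census: pre-harvest stage counts plus the take."""

    week: int
    tube: str
    environment: str
    harvest: str
    eggs: int
    juveniles: int
    adults: int
    harvested: int = 0


@dataclass(frozen=True)
class SizeRecord:
    tube: str
    week: int
    stage: str
    length_um: float


@dataclass
class CensusSeries:
    """Weekly census time series for one replicate tube.

    ``counts`` has columns week, eggs, juveniles, adults, harvested, sorted
    by week; counts are pre-harvest, ``harvested`` is that week's adult take.
    """

    tube: str
    environment: str
    harvest: str
    counts: pd.DataFrame

    def __post_init__(self):
        self.counts = self.counts.reset_index(drop=True)

    @property
    def weeks(self) -> np.ndarray:
        return self.counts["week"].to_numpy()

    def stage_counts(self, stage: str) -> pd.Series:
        if stage == "total":
            vals = self.counts[list(STAGES)].sum(axis=1)
        else:
            vals = self.counts[stage]
        return pd.Series(vals.to_numpy(float), index=self.counts["week"].to_numpy())

    def window(self, weeks: tuple[int, int]) -> pd.DataFrame:
        """Rows for the inclusive week range."""
        lo, hi = weeks
        m = (self.counts["week"] >= lo) & (self.counts["week"] <= hi)
        return self.counts.loc[m]


def to_long(series_list: list[CensusSeries]) -> pd.DataFrame:
    """Tidy long-format frame for a collection of census series."""
    frames = []
    for s in sorted(series_list, key=lambda s: str(s.tube)):
        for stage in STAGES:
            f = pd.DataFrame({
                "week": s.counts["week"],
                "tube": s.tube,
                "environment": s.environment,
                "harvest": s.harvest,
                "stage": stage,
                "count": s.counts[stage],
                "harvested": s.counts["harvested"] if stage == "adults" else pd.NA,
            })
            frames.append(f)
    if not frames:
        return pd.DataFrame(columns=_LONG_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    stage_order = {s: i for i, s in enumerate(STAGES)}
    out = out.sort_values(
        ["tube", "week", "stage"],
        key=lambda c: c.map(stage_order) if c.name == "stage" else c,
        kind="mergesort",
    ).reset_index(drop=True)
    return out[_LONG_COLUMNS]


def write_census(series_list: list[CensusSeries], path) -> None:
    """Write a collection of series as canonical long-format CSV.

    Output is deterministic (sorted by tube, week, stage) so identical input
    produces byte-identical files.
    """
    to_long(series_list).to_csv(path, index=False, lineterminator="\n")


def _validate_wide(df: pd.DataFrame) -> None:
    problems: list[str] = []
    bad_rows: list[int] = []

    def flag(mask, msg):
        idx = df.index[mask].tolist()
        if idx:
            problems.append(f"{msg}: rows {idx[:10]}")
            bad_rows.extend(idx)

    flag(~df["environment"].isin(REGIME_LABELS), "unknown environment label")
    flag(~df["harvest"].isin(HARVEST_KINDS), "unknown harvest label")
    flag(df["week"] < 1, "week must be >= 1")
    for c in (*STAGES, "harvested"):
        flag(df[c] < 0, f"negative {c}")
    flag(df["harvested"] > df["adults"], "harvested exceeds adult count")
    dup = df.duplicated(subset=["tube", "week"], keep=False)
    flag(dup, "duplicate (tube, week)")
    if problems:
        raise ValidationError("census validation failed: " + "; ".join(problems),
                              rows=sorted(set(bad_rows)))


def read_census(path, column_map: dict[str, str] | None = None) -> list[CensusSeries]:
    """Read a census CSV (long or wide layout, auto-detected) into series.

    ``column_map`` renames foreign headers onto the canonical names, so
    deposited tables with unknown header conventions can be ingested without
    editing the file. Raises :class:`ValidationError` listing offending rows
    on invariant breaches; warns about gaps in the week sequence.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [str(c).strip().lower() for c in df.columns]

    if "stage" in df.columns:  # long layout
        missing = [c for c in _LONG_COLUMNS if c not in df.columns and c != "harvested"]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        bad_stage = ~df["stage"].isin(STAGES)
        if bad_stage.any():
            raise ValidationError(
                f"unknown stage labels {sorted(df.loc[bad_stage, 'stage'].unique())}",
                rows=df.index[bad_stage].tolist())
        dup = df.duplicated(subset=["tube", "week", "stage"], keep=False)
        if dup.any():
            raise ValidationError("duplicate (tube, week, stage) rows",
                                  rows=df.index[dup].tolist())
        wide = df.pivot_table(index=["tube", "week", "environment", "harvest"],
                              columns="stage", values="count",
                              aggfunc="first").reset_index()
        if "harvested" in df.columns:
            takes = (df[df["stage"] == "adults"]
                     [["tube", "week", "harvested"]])
            wide = wide.merge(takes, on=["tube", "week"], how="left")
        else:
            wide["harvested"] = 0
        df = wide
    missing = [c for c in _WIDE_COLUMNS if c not in df.columns and c != "harvested"]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if "harvested" not in df.columns:
        df["harvested"] = 0
    df["harvested"] = df["harvested"].fillna(0)
    for c in ("week", *STAGES, "harvested"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    df = df[_WIDE_COLUMNS].reset_index(drop=True)
    _validate_wide(df)

    out = []
    for tube, g in df.groupby("tube", sort=True):
        g = g.sort_values("week")
        env = g["environment"].iloc[0]
        harv = g["harvest"].iloc[0]
        if g["environment"].nunique() > 1 or g["harvest"].nunique() > 1:
            raise ValidationError(f"tube {tube!r} has inconsistent treatment labels")
        weeks = g["week"].to_numpy()
        expected = np.arange(weeks.min(), weeks.max() + 1)
        if len(weeks) != len(expected):
            gaps = sorted(set(expected) - set(weeks))
            warnings.warn(f"tube {tube!r} is missing weeks {gaps[:10]}", stacklevel=2)
        counts = g[["week", *STAGES, "harvested"]].astype(int)
        out.append(CensusSeries(tube=str(tube), environment=env, harvest=harv,
                                counts=counts.reset_index(drop=True)))
    return out


def write_sizes(records: pd.DataFrame, path) -> None:
    """Write a size table (columns tube, week, stage, length_um)."""
    cols = ["tube", "week", "stage", "length_um"]
    df = records[cols].sort_values(cols, kind="mergesort")
    df.to_csv(path, index=False, lineterminator="\n")


def read_sizes(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a body-length table."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("tube", "week", "stage", "length_um") if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    bad_stage = ~df["stage"].isin(SIZE_STAGES)
    if bad_stage.any():
        raise ValidationError(
            f"unknown size stages {sorted(df.loc[bad_stage, 'stage'].unique())}",
            rows=df.index[bad_stage].tolist())
    lo, hi = LENGTH_RANGE_UM
    bad_len = ~df["length_um"].between(lo, hi) | df["length_um"].isna()
    if bad_len.any():
        raise ValidationError(f"lengths outside plausible range [{lo}, {hi}] um",
                              rows=df.index[bad_len].tolist())
    return df.reset_index(drop=True)


def write_schedule(schedule, path) -> None:
    """Serialize a food schedule as two-column CSV (day, balls)."""
    pd.DataFrame({"day": np.arange(1, len(schedule.days) + 1),
                  "balls": schedule.days}).to_csv(path, index=False, lineterminator="\n")


def cli(argv=None) -> int:
    """Entry point for the command-line interface (see :mod:`harvestvar.cli`)."""
    from .cli import main
    return main(argv, standalone_mode=False) or 0
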