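"""Reading, validation, reshaping and aggregation of crossover time-course tables.

The canonical in-memory representation is a long-format :class:`pandas.DataFrame`
wrapped in :class:`StudyTable`: one row per measured concentration for one
participant x period x intervention x analyte x time. Wide CSV layouts (one
column per analyte) are an I/O dialect only and are melted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical long-format column order
LONG_COLUMNS = ["participant", "period", "intervention", "time", "analyte", "value"]

#: canonical spellings used on output; matching on input is case-insensitive
CANONICAL_SPELLING = {
    "participant": "Participant",
    "period": "Period",
    "intervention": "Intervention",
    "time": "Time",
    "analyte": "Analyte",
    "value": "Value",
}

_META_KEYS = ["participant", "period", "intervention", "time"]
_SERIES_KEYS = ["participant", "intervention", "analyte"]


@dataclass
class StudyTable:
    """A crossover study in canonical long format.

    Parameters
    ----------
    data
        Long-format frame with columns ``participant, period, intervention,
        time, analyte, value``. ``value`` may contain NaN (missing
        measurements are allowed and excluded point-wise at fit time).
    reference_intervention
        Label of the reference (comparator) intervention.
    analyte_roster
        Ordered list of analyte labels; defaults to order of first appearance.
    """

    data: pd.DataFrame
    reference_intervention: str
    analyte_roster: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.loc[:, LONG_COLUMNS].reset_index(drop=True)
        interventions = set(self.data["intervention"].unique())
        if interventions and self.reference_intervention not in interventions:
            raise ConfigurationError(
                f"reference intervention {self.reference_intervention!r} not found "
                f"among interventions {sorted(interventions)}"
            )
        if not self.analyte_roster:
            self.analyte_roster = list(pd.unique(self.data["analyte"]))
        else:
            present = set(self.data["analyte"].unique())
            missing = [a for a in self.analyte_roster if a not in present]
            if missing:
                raise ConfigurationError(f"analytes in roster but not in data: {missing}")

    @property
    def interventions(self) -> list[str]:
        return list(pd.unique(self.data["intervention"]))

    @property
    def participants(self) -> list:
        return list(pd.unique(self.data["participant"]))

    def series(self):
        """Iterate over (keys, sub-frame) per (participant, intervention, analyte)."""
        for keys, grp in self.data.groupby(_SERIES_KEYS, sort=True):
            yield keys, grp.sort_values("time")

    def __len__(self) -> int:
        return len(self.data)


def _normalize_columns(df: pd.DataFrame) -> dict[str, str]:
    """Map canonical lowercase names to the actual column labels, case-insensitively."""
    lookup: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key not in lookup:
            lookup[key] = col
    return lookup


def _check_structure(df: pd.DataFrame) -> None:
    dup_mask = df.duplicated(subset=["participant", "period", "analyte", "time"], keep=False)
    if dup_mask.any():
        offenders = (
            df.loc[dup_mask, ["participant", "period", "analyte", "time"]]
            .drop_duplicates()
            .head(20)
        )
        raise ValidationError(
            "duplicate (participant, period, analyte, time) measurements:\n"
            f"{offenders.to_string(index=False)}"
        )
    per_period = df.groupby(["participant", "period"])["intervention"].nunique()
    bad = per_period[per_period > 1]
    if len(bad):
        raise ValidationError(
            f"participants with more than one intervention in a period: {bad.index.tolist()}"
        )


def read_study(path, format: str = "wide", reference: str | None = None,
               roster: list[str] | None = None) -> StudyTable:
    """Read a crossover time-course CSV into a canonical :class:`StudyTable`.

    Parameters
    ----------
    path
        CSV file with a header row. Column-name matching is case-insensitive.
    format
        ``"wide"``: columns Participant, Period, Intervention, Time plus one
        column per analyte. ``"long"``: the same four plus Analyte and Value.
    reference
        Label of the reference intervention (required).
    roster
        Optional ordered analyte roster; defaults to the analyte columns /
        labels in order of appearance.

    Non-numeric measurement cells become missing with a logged warning.
    """
    if format not in ("wide", "long"):
        raise ConfigurationError(f"format must be 'wide' or 'long', got {format!r}")
    if reference is None:
        raise ConfigurationError("a reference intervention label is required")

    raw = pd.read_csv(path)
    lookup = _normalize_columns(raw)
    required = ["participant", "period", "intervention", "time"]
    if format == "long":
        required += ["analyte", "value"]
    for name in required:
        if name not in lookup:
            raise FormatError(
                f"required column {CANONICAL_SPELLING[name]!r} missing from {path}"
            )

    if format == "long":
        df = raw.rename(columns={lookup[n]: n for n in required})[required].copy()
    else:
        meta_cols = [lookup[n] for n in required]
        analyte_cols = [c for c in raw.columns if c not in meta_cols]
        if not analyte_cols:
            raise FormatError(f"wide file {path} has no analyte columns")
        df = raw.melt(
            id_vars=meta_cols, value_vars=analyte_cols,
            var_name="analyte", value_name="value",
        ).rename(columns={lookup[n]: n for n in required})
        if roster is None:
            roster = [str(c) for c in analyte_cols]

    df["analyte"] = df["analyte"].astype(str)
    df["intervention"] = df["intervention"].astype(str)
    df["period"] = pd.to_numeric(df["period"], errors="raise").astype(int)
    df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
    if (df["time"] < 0).any():
        raise ValidationError("negative time values found")

    values = pd.to_numeric(df["value"], errors="coerce")
    newly_missing = values.isna() & df["value"].notna()
    if newly_missing.any():
        n = int(newly_missing.sum())
        logger.warning("%d non-numeric measurement cells set to missing", n)
        warnings.warn(f"{n} non-numeric measurement cells set to missing", stacklevel=2)
    df["value"] = values.astype(float)

    _check_structure(df)
    df = df.sort_values(_SERIES_KEYS + ["period", "time"], kind="mergesort")
    return StudyTable(df[LONG_COLUMNS], reference_intervention=str(reference),
                      analyte_roster=list(roster) if roster else [])


def write_study(table: StudyTable, path, format: str = "long") -> None:
    """Write a StudyTable to CSV in long or wide layout, canonical spellings."""
    df = table.data
    if format == "long":
        out = df.rename(columns=CANONICAL_SPELLING)
        out.to_csv(path, index=False)
    elif format == "wide":
        wide = df.pivot(index=_META_KEYS, columns="analyte",
                        values="value").reset_index()
        wide = wide[_META_KEYS + [a for a in table.analyte_roster if a in wide.columns]]
        wide = wide.rename(columns=CANONICAL_SPELLING)
        wide.columns.name = None
        wide.to_csv(path, index=False)
    else:
        raise ConfigurationError(f"format must be 'wide' or 'long', got {format!r}")


def validate_study(table: StudyTable, min_timepoints: int = 5,
                   recommended_timepoints: int = 8) -> pd.DataFrame:
    """Report fit-readiness per (participant, intervention, analyte) series.

    With four curve parameters to estimate, a series needs at least five
    non-missing points to be fittable at all, and eight or more for a
    reliable fit. Pure reporting: no exception is ever raised and the input
    is not modified.

    Returns
    -------
    DataFrame with columns participant, intervention, analyte, n_points,
    n_missing, fittable, meets_recommendation.
    """
    rows = []
    for (participant, intervention, analyte), grp in table.data.groupby(_SERIES_KEYS, sort=True):
        n_obs = int(grp["value"].notna().sum())
        rows.append({
            "participant": participant,
            "intervention": intervention,
            "analyte": analyte,
            "n_points": n_obs,
            "n_missing": int(grp["value"].isna().sum()),
            "fittable": n_obs >= min_timepoints,
            "meets_recommendation": n_obs >= recommended_timepoints,
        })
    columns = ["participant", "intervention", "analyte", "n_points", "n_missing",
               "fittable", "meets_recommendation"]
    return pd.DataFrame(rows, columns=columns)


def aggregate_analytes(table: StudyTable, groups: dict[str, list[str]]) -> StudyTable:
    """Append aggregate analytes (e.g. an essential-amino-acid total).

    Each group's value at a time point is the sum over member analytes; a
    sum with any missing member is missing. Existing records are never
    altered, only new rows appended.
    """
    if not groups:
        return table
    known = set(table.data["analyte"].unique())
    df = table.data
    pieces = [df]
    roster = list(table.analyte_roster)
    for label, members in groups.items():
        unknown = [m for m in members if m not in known]
        if unknown:
            raise ConfigurationError(f"group {label!r} refers to unknown analytes: {unknown}")
        sub = df[df["analyte"].isin(members)]
        agg = (
            sub.groupby(_META_KEYS, sort=True)
            .agg(value=("value", lambda v: v.sum() if v.notna().all() else np.nan),
                 n=("analyte", "nunique"))
            .reset_index()
        )
        # a grid point absent for some member would silently under-sum
        incomplete = agg["n"] != len(set(members))
        if incomplete.any():
            raise ValidationError(
                f"group {label!r}: members do not share the sampling grid at "
                f"{int(incomplete.sum())} points"
            )
        agg["analyte"] = label
        pieces.append(agg[LONG_COLUMNS])
        roster.append(label)
    out = pd.concat(pieces, ignore_index=True)
    return replace(table, data=out, analyte_roster=roster)
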