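"""Long-format weekly panel container and CSV I/O.

The whole pipeline exchanges data as a :class:`PanelSeries`: one row per
(person, week) with a real-valued score or an explicit missing entry.  Within
each person the weeks form the complete consecutive grid ``1..T_p`` — gaps in
the raw data are materialised as missing rows at read time, because every
downstream stage (spline imputation, time-delay embedding) assumes an
equally-spaced weekly grid.
"""

from __future__ import annotations

import io
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = ["PanelSeries", "read_panel", "write_panel"]

_COLUMNS = ("person", "week", "value")


class PanelSeries:
    """Person x week panel on a complete weekly grid.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``person`` (label), ``week`` (int, 1-based) and ``value``
        (float, NaN = missing).  Weeks must form the consecutive range
        ``1..T_p`` within each person; person blocks are kept in
        first-appearance order.

    Notes
    -----
    ``T_p`` is the largest observed week per person; trailing unobserved
    weeks are never invented.  Construction validates the grid invariants
    and raises ``ValueError`` on duplicates or gaps.
    """

    def __init__(self, frame: pd.DataFrame, *, validate: bool = True):
        frame = frame.loc[:, list(_COLUMNS)].reset_index(drop=True)
        frame["week"] = frame["week"].astype(np.int64)
        frame["value"] = frame["value"].astype(float)
        if validate:
            _validate_grid(frame)
        self._frame = frame

    # -- construction -------------------------------------------------

    @classmethod
    def from_observations(cls, frame: pd.DataFrame) -> "PanelSeries":
        """Build a PanelSeries from (possibly gappy) observed rows.

        Inserts explicit missing rows so each person's weeks cover
        ``1..T_p``.  Duplicate (person, week) pairs are a hard error;
        observed values are never altered.
        """
        frame = frame.loc[:, list(_COLUMNS)].copy()
        frame["week"] = _parse_weeks(frame["week"])
        dup = frame.duplicated(subset=["person", "week"])
        if dup.any():
            bad = frame.loc[dup, ["person", "week"]].iloc[0]
            raise ValueError(
                f"duplicate (person, week) pair: ({bad['person']}, {bad['week']})"
            )
        blocks = []
        for person, grp in frame.groupby("person", sort=False):
            grp = grp.dropna(subset=["value"])
            if grp.empty:
                warnings.warn(f"person {person!r} has no observed values; dropped")
                continue
            t_max = int(grp["week"].max())
            full = pd.DataFrame(
                {"person": person, "week": np.arange(1, t_max + 1), "value": np.nan}
            )
            full.loc[grp["week"].to_numpy() - 1, "value"] = grp["value"].to_numpy()
            blocks.append(full)
        if not blocks:
            out = pd.DataFrame({c: [] for c in _COLUMNS})
            out["week"] = out["week"].astype(np.int64)
            return cls(out, validate=False)
        return cls(pd.concat(blocks, ignore_index=True), validate=False)

    # -- accessors ----------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format DataFrame (person, week, value)."""
        return self._frame

    @property
    def persons(self) -> list:
        return list(dict.fromkeys(self._frame["person"]))

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def t_max(self) -> pd.Series:
        """Total weeks T_p per person (largest week index)."""
        return self._frame.groupby("person", sort=False)["week"].max()

    @property
    def n_obs(self) -> pd.Series:
        """Number of non-missing occasions per person."""
        return self._frame.groupby("person", sort=False)["value"].count()

    @property
    def is_complete(self) -> bool:
        return not self._frame["value"].isna().any()

    def person_values(self, person) -> np.ndarray:
        """Values on the week grid 1..T_p for one person (NaN = missing)."""
        sub = self._frame.loc[self._frame["person"] == person]
        if sub.empty:
            raise KeyError(f"unknown person {person!r}")
        return sub["value"].to_numpy()

    def subset(self, persons) -> "PanelSeries":
        """Panel restricted to the given persons (input order preserved)."""
        keep = set(persons)
        mask = self._frame["person"].isin(keep)
        return PanelSeries(self._frame.loc[mask], validate=False)

    def with_values(self, values: np.ndarray) -> "PanelSeries":
        """Copy of the panel with the value column replaced."""
        frame = self._frame.copy()
        frame["value"] = np.asarray(values, dtype=float)
        return PanelSeries(frame, validate=False)

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelSeries):
            return NotImplemented
        a, b = self._frame, other._frame
        if len(a) != len(b):
            return False
        return (
            a["person"].astype(str).equals(b["person"].astype(str))
            and a["week"].equals(b["week"])
            and np.allclose(a["value"], b["value"], rtol=0, atol=0, equal_nan=True)
        )

    def __repr__(self) -> str:
        return (
            f"PanelSeries(n_persons={self.n_persons}, rows={len(self)}, "
            f"complete={self.is_complete})"
        )


def _parse_weeks(col: pd.Series) -> np.ndarray:
    weeks = pd.to_numeric(col, errors="raise")
    if (weeks <= 0).any() or (weeks != weeks.round()).any():
        raise ValueError("week must be a positive integer")
    return weeks.astype(np.int64)


def _validate_grid(frame: pd.DataFrame) -> None:
    if frame.duplicated(subset=["person", "week"]).any():
        raise ValueError("duplicate (person, week) pair")
    for person, grp in frame.groupby("person", sort=False):
        weeks = grp["week"].to_numpy()
        t_max = weeks.max() if len(weeks) else 0
        if len(weeks) != t_max or not np.array_equal(weeks, np.arange(1, t_max + 1)):
            raise ValueError(f"person {person!r}: weeks do not form 1..T_p")


def read_panel(path, schema: Mapping[str, str] | None = None) -> PanelSeries:
    """Read a long-format CSV and align it to the complete weekly grid.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.  Default column names are
        ``person,week,value``; empty fields and ``NA`` are missing.
    schema : mapping, optional
        Map from the canonical names (person/week/value) to the file's
        column names.

    Returns
    -------
    PanelSeries
        With explicit missing rows inserted wherever more than one week
        elapsed between observations.
    """
    names = {k: (schema or {}).get(k, k) for k in _COLUMNS}
    raw = pd.read_csv(
        path,
        na_values=["NA"],
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing_cols = [v for v in names.values() if v not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing columns in {path}: {missing_cols}")
    frame = raw.rename(columns={v: k for k, v in names.items()})
    bad = pd.to_numeric(frame["value"], errors="coerce").isna() & frame["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric value in data row {row + 1} of {path}")
    frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
    return PanelSeries.from_observations(frame)


def write_panel(panel: PanelSeries, path) -> None:
    """Write a PanelSeries as CSV (missing encoded as empty field).

    Values use the shortest decimal representation that reproduces the
    double exactly, so the read/write round trip is the identity.
    """
    frame = panel.frame
    buf = io.StringIO()
    frame.to_csv(buf, index=False, na_rep="")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
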