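"""Reading, validating and writing long-format behavioral tables and results.

The canonical interchange format is a UTF-8 CSV with a header row and one row
per animal x day x measure.  Canonical column names are ``animal_id``,
``strain``, ``experiment``, ``day``, ``measure`` and ``value``; deviating
headers can be mapped via a schema dictionary.  Results are serialized as JSON
documents carrying a schema version, seed and configuration digest so that a
rerun with identical inputs is bitwise identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

CANONICAL_COLUMNS = ("animal_id", "strain", "experiment", "day", "measure", "value")

RESULT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# BehaviorTable
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTable:
    """Validated long-format repeated-measures table.

    Parameters
    ----------
    data
        DataFrame with the canonical columns.  One row per
        (animal_id, day, measure); ``day`` is a 1-based integer trial index
        and ``value`` a finite float in the measure's units.
    """

    data: pd.DataFrame
    measures: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)
        self.measures = tuple(sorted(self.data["measure"].unique()))

    # -- accessors ---------------------------------------------------------

    @property
    def animals(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["animal_id"].unique()))

    def days(self, measure: str | None = None) -> tuple[int, ...]:
        df = self.data if measure is None else self.subset(measure).data
        return tuple(sorted(df["day"].unique()))

    @property
    def n_animals(self) -> int:
        return self.data["animal_id"].nunique()

    def subset(self, measure: str, days: Iterable[int] | None = None) -> "BehaviorTable":
        """Rows of a single measure, optionally restricted to a day set."""
        if measure not in self.measures:
            raise KeyError(f"unknown measure {measure!r}; have {self.measures}")
        df = self.data[self.data["measure"] == measure]
        if days is not None:
            df = df[df["day"].isin(set(days))]
        return BehaviorTable(df.reset_index(drop=True))

    def completeness(self) -> dict[str, dict[str, tuple[int, ...]]]:
        """Days present per measure per animal.

        The table may be unbalanced; this map is how missingness is surfaced
        (no imputation is ever performed).
        """
        out: dict[str, dict[str, tuple[int, ...]]] = {}
        for (measure, animal), grp in self.data.groupby(["measure", "animal_id"], sort=True):
            out.setdefault(str(measure), {})[str(animal)] = tuple(sorted(grp["day"]))
        return out

    def is_balanced(self, measure: str) -> bool:
        counts = self.subset(measure).data.groupby("animal_id")["day"].nunique()
        return counts.nunique() == 1

    def __len__(self) -> int:
        return len(self.data)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.loc[:, list(CANONICAL_COLUMNS)].copy()

    # dtype coercion with row-numbered diagnostics (row numbers are the
    # positions in the frame handed in, 0-based).
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[~np.isfinite(values.to_numpy(dtype=float))].tolist()
    if bad:
        raise ParseError(f"non-numeric or non-finite value in rows {bad[:20]}")
    df["value"] = values.astype(float)

    days = pd.to_numeric(df["day"], errors="coerce")
    day_arr = days.to_numpy(dtype=float)
    bad = df.index[~np.isfinite(day_arr) | (day_arr != np.round(day_arr)) | (day_arr < 1)].tolist()
    if bad:
        raise ParseError(f"day must be a positive integer; offending rows {bad[:20]}")
    df["day"] = days.astype(int)

    for col in ("animal_id", "strain", "experiment", "measure"):
        df[col] = df[col].astype(str)

    dup = df.duplicated(subset=["animal_id", "day", "measure"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["animal_id", "day", "measure"]].drop_duplicates()
        raise IntegrityError(
            "duplicate (animal_id, day, measure) entries: "
            + ", ".join(f"({r.animal_id}, {r.day}, {r.measure})" for r in keys.itertuples())
        )

    for col in ("strain", "experiment"):
        per_animal = df.groupby("animal_id")[col].nunique()
        bad_animals = per_animal.index[per_animal > 1].tolist()
        if bad_animals:
            raise IntegrityError(
                f"animal(s) {bad_animals} mapped to more than one {col}"
            )

    return df.reset_index(drop=True)


def read_behavior_table(path: str | Path, schema: Mapping[str, str] | None = None) -> BehaviorTable:
    """Read a long-format behavioral CSV into a validated :class:`BehaviorTable`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping of canonical column name -> column name in the file,
        e.g. ``{"animal_id": "Animal"}``.  Unmapped columns are looked up
        under their canonical names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = schema.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(f"column {src!r} (for {canon!r}) not found in {path.name}; "
                              f"available: {list(raw.columns)}")
        rename[src] = canon
    return BehaviorTable(raw.rename(columns=rename))


def write_behavior_table(table: BehaviorTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy scalars / arrays to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: to_jsonable(getattr(obj, f.name))
             for f in dataclasses.fields(obj) if not f.name.startswith("_")}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, Mapping):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is None or isinstance(obj, (str, bool, numbers.Real)):
        return obj
    raise TypeError(f"cannot serialize {type(obj)!r}")


def config_digest(payload: Any) -> str:
    """Stable sha256 digest of a JSON-serializable configuration."""
    blob = json.dumps(to_jsonable(payload), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_results(result: Any, path: str | Path, *, seed: int | None = None,
                  input_digest: str | None = None, extra: Mapping[str, Any] | None = None) -> None:
    """Serialize an analysis result to JSON at full float precision.

    The document wraps the payload with a schema version and provenance
    fields (seed, input digest) so that results are self-describing and
    reruns with identical configuration are bitwise identical (no
    timestamps are written).
    """
    doc = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "type": type(result).__name__,
        "seed": seed,
        "input_digest": input_digest,
        "payload": to_jsonable(result),
    }
    if extra:
        doc.update(to_jsonable(extra))
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_results(path: str | Path) -> dict[str, Any]:
    """Read back a JSON result document (returns the full document dict)."""
    return json.loads(Path(path).read_text())


def write_window_series_csv(series_list: Iterable[Any], path: str | Path) -> None:
    """Export one or more window series to CSV.

    Columns: measure, factor, start_day, end_day, R, ci_low, ci_high,
    p_lrt, p_permut.
    """
    rows = []
    for series in series_list:
        for window, res in zip(series.windows, series.results):
            rows.append({
                "measure": series.measure,
                "factor": series.factor,
                "start_day": window.start_day,
                "end_day": window.end_day,
                "R": res.R,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "p_lrt": res.p_lrt,
                "p_permut": res.p_permut,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
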