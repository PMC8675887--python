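"""Reading and writing fluorescence transients, sample metadata and result tables.

Transient tables come in two delimited layouts, both produced by
continuous-excitation fluorometer exports:

* ``long``  — columns ``sample_id``, ``time_s``, ``fluorescence``;
* ``wide``  — a ``time_s`` column plus one fluorescence column per sample.

Times are stored internally in seconds; ``time_unit`` converts on ingest
(``"us"``/``"µs"`` and ``"ms"`` are accepted because instrument exports
commonly use microseconds while the JIP literature quotes milliseconds).
The delimiter (tab or comma) is auto-detected.  All outputs are
tab-separated with a header row and full-precision floats, so a written
table round-trips through the corresponding reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: lux -> PAR conversion factor for a ~6000 K daylight spectrum
LUX_TO_PAR_FACTOR = 0.019

SEASONS = ("summer", "winter")
PERIODS = ("day", "night")

_TIME_UNIT_FACTORS = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6}


@dataclass(frozen=True)
class FluorescenceTransient:
    """One sample's dark-adapted fluorescence rise (OJIP curve).

    Parameters
    ----------
    sample_id : str
        Sample label, unique within an experiment.
    times : array-like of float
        Acquisition times in seconds; strictly increasing, > 0, length >= 4.
    fluorescence : array-like of float
        Fluorescence intensities (arbitrary units), finite and >= 0,
        same length as ``times``.
    """

    sample_id: str
    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise ValidationError(
                f"sample {self.sample_id!r}: times and fluorescence must be "
                f"1-d sequences of equal length"
            )
        if t.size < 4:
            raise ValidationError(
                f"sample {self.sample_id!r}: need at least 4 timepoints, got {t.size}"
            )
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: times must be finite and > 0"
            )
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: fluorescence must be finite and >= 0"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SampleMetadata:
    """Experimental-design metadata for one sample."""

    sample_id: str
    population: str
    season: str
    period: str
    replicate: int

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown season {self.season!r} "
                f"(expected one of {SEASONS})"
            )
        if self.period not in PERIODS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown period {self.period!r} "
                f"(expected one of {PERIODS})"
            )
        if int(self.replicate) < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )
        object.__setattr__(self, "replicate", int(self.replicate))

    @property
    def group(self) -> tuple[str, str, str]:
        """The (population, season, period) cell used as grouping factor."""
        return (self.population, self.season, self.period)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None with the python engine sniffs tab vs comma
    return pd.read_csv(path, sep=None, engine="python")


def _build_transient(sample_id: str, times: np.ndarray, fluor: np.ndarray) -> FluorescenceTransient:
    order = np.argsort(times, kind="stable")
    times, fluor = times[order], fluor[order]
    uniq, first = np.unique(times, return_index=True)
    if uniq.size != times.size:
        logger.warning(
            "sample %r: %d duplicate timepoint(s), keeping first occurrence",
            sample_id, times.size - uniq.size,
        )
        first.sort()
        times, fluor = times[first], fluor[first]
    return FluorescenceTransient(sample_id=sample_id, times=times, fluorescence=fluor)


def read_transients(
    path: str | Path,
    layout: str = "long",
    time_unit: str = "s",
) -> list[FluorescenceTransient]:
    """Read fluorescence transients from a delimited table.

    Parameters
    ----------
    path : path-like
        Tab- or comma-separated text file (delimiter auto-detected).
    layout : {"long", "wide"}
        ``long``: columns (sample_id, time_s, fluorescence).
        ``wide``: a time_s column plus one column per sample.
    time_unit : {"s", "ms", "us", "µs"}
        Unit of the time column; converted to seconds on ingest.

    Returns
    -------
    list of FluorescenceTransient
        One per sample, rows sorted by time, duplicate timepoints dropped
        (first kept, with a logged warning).
    """
    if time_unit not in _TIME_UNIT_FACTORS:
        raise ValueError(f"unknown time_unit {time_unit!r}")
    factor = _TIME_UNIT_FACTORS[time_unit]
    df = _read_delimited(path)
    transients: list[FluorescenceTransient] = []
    if layout == "long":
        required = ("sample_id", "time_s", "fluorescence")
        for col in required:
            if col not in df.columns:
                raise FormatError(f"long-layout table is missing column {col!r}")
        for sid, sub in df.groupby("sample_id", sort=True):
            transients.append(
                _build_transient(
                    str(sid),
                    sub["time_s"].to_numpy(dtype=float) * factor,
                    sub["fluorescence"].to_numpy(dtype=float),
                )
            )
    elif layout == "wide":
        if "time_s" not in df.columns:
            raise FormatError("wide-layout table is missing column 'time_s'")
        times = df["time_s"].to_numpy(dtype=float) * factor
        sample_cols = [c for c in df.columns if c != "time_s"]
        if not sample_cols:
            raise FormatError("wide-layout table has no sample columns")
        for col in sample_cols:
            transients.append(
                _build_transient(str(col), times.copy(), df[col].to_numpy(dtype=float))
            )
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'long' or 'wide')")
    return transients


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read and validate a sample-metadata table.

    Expected columns: sample_id, population, season, period, replicate.
    Unknown season/period levels and duplicated sample ids are rejected.
    An empty table yields an empty list with a logged warning.
    """
    import csv

    try:
        df = _read_delimited(path)
    except (pd.errors.EmptyDataError, csv.Error):
        # an empty (or headerless single-column) file defeats the sniffer
        if Path(path).stat().st_size == 0:
            logger.warning("metadata file %s is empty", path)
            return []
        raise
    required = ("sample_id", "population", "season", "period", "replicate")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"metadata table is missing column {col!r}")
    if df.empty:
        logger.warning("metadata file %s has a header but no rows", path)
        return []
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicated sample_id(s): {sorted(set(dup.astype(str)))}")
    return [
        SampleMetadata(
            sample_id=str(r.sample_id),
            population=str(r.population),
            season=str(r.season),
            period=str(r.period),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def metadata_frame(metadata: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Convert SampleMetadata records into a DataFrame indexed by sample_id."""
    rows = [
        {
            "sample_id": m.sample_id,
            "population": m.population,
            "season": m.season,
            "period": m.period,
            "replicate": m.replicate,
        }
        for m in metadata
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("sample_id")
    return df


def transients_frame(transients: Iterable[FluorescenceTransient]) -> pd.DataFrame:
    """Stack transients into a long-format DataFrame (sample_id, time_s, fluorescence)."""
    parts = [
        pd.DataFrame(
            {"sample_id": tr.sample_id, "time_s": tr.times, "fluorescence": tr.fluorescence}
        )
        for tr in transients
    ]
    if not parts:
        return pd.DataFrame(columns=["sample_id", "time_s", "fluorescence"])
    return pd.concat(parts, ignore_index=True)


def lux_to_par(lux):
    """Convert illuminance (lux) to PAR (µmol photons m⁻² s⁻¹).

    Uses the multiplicative factor 0.019, an approximation for the spectral
    power distribution of ~6000 K sunlight.  Accepts scalars or arrays.
    """
    arr = np.asarray(lux, dtype=float)
    if np.any(arr < 0):
        raise ValueError("illuminance must be non-negative")
    out = arr * LUX_TO_PAR_FACTOR
    return float(out) if np.isscalar(lux) or out.ndim == 0 else out


def write_table(records, path: str | Path) -> None:
    """Write a tabular result as TSV with a header row.

    ``records`` may be a DataFrame or a non-empty sequence of dataclass-like
    records with a ``__dict__``.  Floats are written at full (shortest
    round-trip) precision so that reading the file back reproduces them.
    Empty input is an error and no file is created.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        if df.empty:
            raise ValidationError("refusing to write an empty table")
        df = df.reset_index() if df.index.name is not None else df
    else:
        records = list(records)
        if not records:
            raise ValidationError("refusing to write an empty table")
        df = pd.DataFrame([vars(r) if hasattr(r, "__dict__") else r for r in records])
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
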