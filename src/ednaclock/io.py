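"""Tidy-table I/O for concentration time series, plus run configuration.

The interchange format is a long CSV with one row per tank x target x
time measurement.  Columns::

    tank_id, abundance, replicate, gene, genome, rna_class,
    amplicon_length, nucleic_acid, time_h, copies_per_ml, censored
    [, sample]

Censored rows (non-detects) leave ``copies_per_ml`` blank.  Floats are
written with Python's shortest round-trip representation and re-parsed
exactly, so a write/read cycle is bit-faithful.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .core import (
    ConcentrationSeries,
    GeneTarget,
    Measurement,
    SchemaError,
    ValidationError,
)

log = logging.getLogger("ednaclock")

REQUIRED_COLUMNS = (
    "tank_id",
    "abundance",
    "replicate",
    "gene",
    "genome",
    "rna_class",
    "amplicon_length",
    "nucleic_acid",
    "time_h",
    "copies_per_ml",
    "censored",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {raw!r}")


def read_measurements(
    path, schema: Optional[Mapping[str, str]] = None
) -> List[ConcentrationSeries]:
    """Read a tidy long CSV into one :class:`ConcentrationSeries` per
    (tank, target[, sample]) group.

    Parameters
    ----------
    path : path-like
        CSV file with the documented columns.
    schema : mapping, optional
        Maps the canonical column names to the names used in the file,
        e.g. ``{"tank_id": "tank"}``.

    Raises
    ------
    SchemaError
        A required column is missing (the error names it).
    ValidationError
        Malformed rows; the message carries 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_sample = "sample" in df.columns

    groups: Dict[tuple, list] = {}
    meta: Dict[tuple, tuple] = {}
    errors: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            target = GeneTarget(
                name=getattr(row, "gene"),
                genome=getattr(row, "genome"),
                rna_class=getattr(row, "rna_class"),
                amplicon_length=int(getattr(row, "amplicon_length")),
                nucleic_acid=getattr(row, "nucleic_acid"),
            )
            time_h = float(getattr(row, "time_h"))
            censored = _parse_bool(getattr(row, "censored"))
            raw_copies = getattr(row, "copies_per_ml").strip()
            copies = None if (censored or raw_copies == "") else float(raw_copies)
            if not censored and raw_copies == "":
                raise ValueError("detected row with empty copies_per_ml")
            m = Measurement(
                tank_id=getattr(row, "tank_id"),
                target=target,
                time_h=time_h,
                copies_per_ml=copies,
                censored=censored,
            )
            abundance = int(getattr(row, "abundance"))
            if abundance < 0:
                raise ValueError(f"abundance must be >= 0, got {abundance}")
            sample = getattr(row, "sample") if has_sample else "s1"
        except (ValueError, ValidationError) as exc:
            errors.append(f"row {i}: {exc}")
            continue
        key = (m.tank_id, target.key, sample)
        groups.setdefault(key, []).append(m)
        meta[key] = (abundance, getattr(row, "replicate"), sample)
    if errors:
        raise ValidationError(
            f"{len(errors)} malformed row(s):\n" + "\n".join(errors)
        )

    series: List[ConcentrationSeries] = []
    for key, ms in groups.items():
        abundance, replicate, sample = meta[key]
        ms_sorted = sorted(ms, key=lambda m: m.time_h)
        series.append(
            ConcentrationSeries(
                tank_id=key[0],
                target=ms_sorted[0].target,
                measurements=tuple(ms_sorted),
                abundance=abundance,
                replicate=replicate,
                sample=sample,
            )
        )
    n_rows = sum(len(s) for s in series)
    log.info("read %d measurements into %d series from %s", n_rows, len(series), path)
    return series


def series_to_frame(series: Sequence[ConcentrationSeries]) -> pd.DataFrame:
    """Flatten series into the tidy long table (strings, write-ready)."""
    rows = []
    for s in series:
        for m in s.measurements:
            rows.append(
                {
                    "tank_id": s.tank_id,
                    "abundance": "" if s.abundance is None else s.abundance,
                    "replicate": s.replicate,
                    "gene": s.target.name,
                    "genome": s.target.genome.value,
                    "rna_class": s.target.rna_class.value,
                    "amplicon_length": s.target.amplicon_length,
                    "nucleic_acid": s.target.nucleic_acid.value,
                    "time_h": repr(float(m.time_h)),
                    "copies_per_ml": ""
                    if m.copies_per_ml is None
                    else repr(float(m.copies_per_ml)),
                    "censored": str(m.censored),
                    "sample": s.sample,
                }
            )
    return pd.DataFrame(rows)


def write_measurements(series: Sequence[ConcentrationSeries], path) -> None:
    """Write series to a tidy CSV; the inverse of :func:`read_measurements`.

    Floats are serialized with ``repr`` so that a subsequent read
    reproduces every value bit-for-bit.
    """
    if not series:
        raise ValidationError("refusing to write an empty list of series")
    df = series_to_frame(series)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    log.info("wrote %d series (%d rows) to %s", len(series), len(df), path)


def exclude_tanks(
    series: Sequence[ConcentrationSeries], tank_ids: Iterable[str]
) -> List[ConcentrationSeries]:
    """Drop every series from the listed tanks.

    Mirrors the exclusion of compromised replicate tanks (e.g. ones
    with a dead organism) from all downstream analysis.  Idempotent.

    Raises
    ------
    ValidationError
        A listed tank is not present in the data.
    """
    tank_ids = list(tank_ids)
    present = {s.tank_id for s in series}
    unknown = sorted(set(tank_ids) - present)
    if unknown:
        raise ValidationError(f"unknown tank_id(s): {', '.join(unknown)}")
    kept = [s for s in series if s.tank_id not in set(tank_ids)]
    log.info("excluded %d series from tanks %s", len(series) - len(kept), tank_ids)
    if not kept:
        log.warning("exclusion removed every series")
    return kept


def load_config(path) -> dict:
    """Load a YAML run configuration (paths, exclusions, window, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a YAML mapping")
    return cfg


def write_run_summary(path, summary: Mapping) -> None:
    """Write a machine-readable run summary as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
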