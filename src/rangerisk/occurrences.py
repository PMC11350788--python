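"""Occurrence-record ingestion, filtering, and train/validation splitting.

Records are (species id, longitude, latitude) points.  Ingestion normalizes
longitudes to [-180, 180), rejects out-of-bounds or malformed rows, and keeps
an append-only provenance log of every filter applied.

The minimum-record filter follows the study design: species with fewer than
four records are not modelled, but they are not discarded either — they are
routed to the data-poor assessment path, where their threat status is derived
from record geometry rather than a fitted distribution model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import GridSpec


@dataclass(frozen=True)
class OccurrenceRecord:
    species_id: str
    lon: float
    lat: float
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species id must be nonempty")
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180)")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass
class OccurrenceSet:
    records: dict[str, list[OccurrenceRecord]] = field(default_factory=dict)
    filter_log: list[str] = field(default_factory=list)
    #: species excluded from modelling but kept for the data-poor path
    data_poor: dict[str, list[OccurrenceRecord]] = field(default_factory=dict)

    def log(self, message: str) -> None:
        self.filter_log.append(message)

    @property
    def species_ids(self) -> list[str]:
        return list(self.records)

    def n_records(self, species_id: str) -> int:
        return len(self.records.get(species_id, []))

    def merge(self, other: "OccurrenceSet") -> "OccurrenceSet":
        out = OccurrenceSet(
            {**{k: list(v) for k, v in self.records.items()}},
            self.filter_log + other.filter_log,
            {**{k: list(v) for k, v in self.data_poor.items()}},
        )
        for sp, recs in other.records.items():
            out.records.setdefault(sp, []).extend(recs)
        for sp, recs in other.data_poor.items():
            out.data_poor.setdefault(sp, []).extend(recs)
        return out

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["species", "lon", "lat"])
            for sp in self.records:
                for r in self.records[sp]:
                    w.writerow([sp, repr(r.lon), repr(r.lat)])

    def write_log(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.filter_log, indent=2))


_SPECIES_COLS = {"species", "species_id", "taxon", "name"}
_LON_COLS = {"lon", "longitude", "decimallongitude", "x"}
_LAT_COLS = {"lat", "latitude", "decimallatitude", "y"}


def _find_column(header: list[str], candidates: set[str], what: str) -> int:
    for i, h in enumerate(header):
        if h.strip().lower() in candidates:
            return i
    raise ValueError(f"no {what} column found in header {header}")


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read delimited occurrence records; malformed rows are logged, not fatal."""
    occ = OccurrenceSet()
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        if not sample.strip():
            raise ValueError(f"empty occurrence file: {path}")
        dialect = csv.Sniffer().sniff(sample, delimiters=",;\t")
        fh.seek(0)
        reader = csv.reader(fh, dialect)
        header = next(reader)
        i_sp = _find_column(header, _SPECIES_COLS, "species")
        i_lon = _find_column(header, _LON_COLS, "longitude")
        i_lat = _find_column(header, _LAT_COLS, "latitude")
        n_ok = n_bad = 0
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            try:
                sp = row[i_sp].strip()
                lon = ((float(row[i_lon]) + 180.0) % 360.0) - 180.0
                lat = float(row[i_lat])
                rec = OccurrenceRecord(sp, lon, lat)
            except (ValueError, IndexError):
                n_bad += 1
                continue
            occ.records.setdefault(sp, []).append(rec)
            n_ok += 1
    occ.log(f"read {n_ok} records from {Path(path).name}, rejected {n_bad} malformed rows")
    return occ


def filter_min_records(occ: OccurrenceSet, min_records: int = 4) -> OccurrenceSet:
    """Exclude species with fewer than ``min_records`` records from modelling.

    Excluded species move to ``data_poor`` (they are assessed by record
    geometry downstream), so applying the filter twice is a no-op.
    """
    if min_records < 1:
        raise ValueError("min_records must be >= 1")
    out = OccurrenceSet(filter_log=list(occ.filter_log),
                        data_poor={k: list(v) for k, v in occ.data_poor.items()})
    n_moved = 0
    for sp, recs in occ.records.items():
        if len(recs) < min_records:
            out.data_poor.setdefault(sp, []).extend(recs)
            n_moved += 1
        else:
            out.records[sp] = list(recs)
    out.log(f"min-record filter (<{min_records}): {n_moved} species routed data-poor, "
            f"{len(out.records)} retained for modelling")
    return out


def dedupe_to_cells(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Keep at most one record per species per grid cell (first wins).

    Prevents pseudo-replication in model fitting; cell membership uses the
    half-open [west, east) x [south, north) convention.
    """
    out = OccurrenceSet(filter_log=list(occ.filter_log),
                        data_poor={k: list(v) for k, v in occ.data_poor.items()})
    n_dropped = 0
    for sp, recs in occ.records.items():
        seen: set[tuple[int, int]] = set()
        kept = []
        for r in recs:
            try:
                cell = grid.cell_index(r.lon, r.lat)
            except ValueError:
                n_dropped += 1  # off-grid record cannot enter the model
                continue
            if cell in seen:
                n_dropped += 1
            else:
                seen.add(cell)
                kept.append(r)
        out.records[sp] = kept
    out.log(f"cell dedup on {grid.resolution_arcmin}' grid: {n_dropped} records dropped")
    return out


@dataclass(frozen=True)
class TrainTestSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def split_train_test(n_or_records, train_fraction: float = 0.75,
                     seed: int = 0) -> TrainTestSplit:
    """Random 75/25-style split of record indices.

    Training size is ``round(train_fraction * n)`` (round-half-to-even),
    adjusted so that at least one record lands on each side.
    """
    n = n_or_records if isinstance(n_or_records, int) else len(n_or_records)
    if n < 2:
        raise ValueError("need at least two records to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return TrainTestSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)
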