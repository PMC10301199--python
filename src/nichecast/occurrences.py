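"""Presence records: CSV reading with coordinate validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    """No usable records in the input."""


@dataclass(frozen=True)
class OccurrenceSet:
    """Presence records as (species_label, longitude, latitude) tuples."""

    records: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for _, lon, lat in self.records:
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValueError(f"coordinate out of range: ({lon}, {lat})")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return np.array([r[2] for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["species", "longitude", "latitude"])

    @classmethod
    def from_arrays(cls, lon, lat, species: str = "species") -> "OccurrenceSet":
        recs = tuple((species, float(x), float(y)) for x, y in zip(lon, lat))
        return cls(recs)


def read_occurrences(path: str | Path, lon_field: str = "longitude",
                     lat_field: str = "latitude",
                     species_field: str = "species") -> OccurrenceSet:
    """Read presence records from a delimited text file with a header.

    Rows with unparseable or out-of-range coordinates are rejected and
    their count logged.  Missing coordinate columns raise ``KeyError``;
    a file with no usable rows raises :class:`EmptyInputError`.
    """
    df = pd.read_csv(path)
    for fld in (lon_field, lat_field):
        if fld not in df.columns:
            raise KeyError(f"missing column {fld!r} in {path}")
    lon = pd.to_numeric(df[lon_field], errors="coerce")
    lat = pd.to_numeric(df[lat_field], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("read_occurrences: rejected %d row(s) with bad coordinates", n_bad)
    if not ok.any():
        raise EmptyInputError(f"no valid occurrence rows in {path}")
    if species_field in df.columns:
        species = df.loc[ok, species_field].astype(str).tolist()
    else:
        species = ["species"] * int(ok.sum())
    recs = tuple(zip(species, lon[ok].astype(float), lat[ok].astype(float)))
    return OccurrenceSet(recs)


def write_occurrences(occs: OccurrenceSet, path: str | Path) -> None:
    occs.to_frame().to_csv(path, index=False)
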