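"""Nest-box registry, temporal availability, and box-to-box distances.

A breeding population monitored through a fixed network of nest boxes only
ever yields *box-to-box* dispersal distances: the natal box and the box of
the first breeding attempt are both points of a finite planar set.  This
module holds that set (:class:`BoxRegistry`), its temporal structure (boxes
enter the study in a known year, and a single enlargement year splits the
network into an early and a late era), and all Euclidean distance
computations downstream analyses rely on.

Coordinates are planar kilometres.  Registries supplied in geographic
coordinates (latitude/longitude) are projected once at ingest onto a local
azimuthal-equidistant plane centred on the registry centroid; for a study
area of a few hundred km² the planar approximation is accurate to metres,
far below the granularity of nest-box spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "NestBox",
    "BoxRegistry",
    "ValidationError",
    "pairwise_distances",
    "available_boxes",
    "natal_dispersal_distance",
]

#: mean Earth radius, km (spherical model used for the one-off projection)
_EARTH_RADIUS_KM = 6371.0088


class ValidationError(ValueError):
    """Raised when registry or recruit data violate a structural invariant."""


@dataclass(frozen=True)
class NestBox:
    """A breeding site with planar coordinates and a first-availability year.

    Parameters
    ----------
    box_id : str
        Opaque identifier, unique within a registry.
    x_km, y_km : float
        Planar easting/northing in kilometres.
    first_year : int
        Calendar year the box became available.  Boxes are assumed available
        from ``first_year`` onward indefinitely.
    """

    box_id: str
    x_km: float
    y_km: float
    first_year: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_km) and math.isfinite(self.y_km)):
            raise ValidationError(
                f"nest box {self.box_id!r} has non-finite coordinates "
                f"({self.x_km}, {self.y_km})"
            )


class BoxRegistry:
    """An immutable collection of nest boxes with an era cutoff.

    The cutoff year splits the network into the boxes present before a
    study-area enlargement and the full post-enlargement set; recruit-specific
    availability (:meth:`available_boxes`) is derived from it.

    Parameters
    ----------
    boxes : iterable of NestBox
    era_cutoff_year : int
        Calendar year of the enlargement (default 1987).  Recruits hatched in
        or after this year can settle in any box; earlier recruits only in
        boxes with ``first_year`` before the cutoff.
    """

    def __init__(self, boxes: Iterable[NestBox], era_cutoff_year: int = 1987):
        boxes = list(boxes)
        if len(boxes) < 2:
            raise ValidationError("a registry needs at least 2 nest boxes")
        ids = [b.box_id for b in boxes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate box ids in registry: {sorted(dupes)}")
        self._boxes: dict[str, NestBox] = {b.box_id: b for b in boxes}
        self.era_cutoff_year = int(era_cutoff_year)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._boxes)

    def __iter__(self):
        return iter(self._boxes.values())

    def __contains__(self, box_id: str) -> bool:
        return box_id in self._boxes

    def __getitem__(self, box_id: str) -> NestBox:
        try:
            return self._boxes[box_id]
        except KeyError:
            raise KeyError(f"unknown box id {box_id!r}") from None

    @property
    def box_ids(self) -> list[str]:
        return list(self._boxes)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of planar coordinates, ordered as :attr:`box_ids`."""
        return np.array([[b.x_km, b.y_km] for b in self], dtype=float)

    def diameter_km(self) -> float:
        """Largest pairwise distance in the registry."""
        return float(pairwise_distances(self).to_numpy().max())

    # -- availability -------------------------------------------------------
    def available_boxes(self, hatch_year: int) -> list[NestBox]:
        """Boxes detectable for a recruit of the given hatch year.

        Hatch in or after the cutoff year: the whole network.  Hatch before
        it: only the pre-cutoff boxes (``first_year < era_cutoff_year``).
        """
        if hatch_year >= self.era_cutoff_year:
            out = list(self)
        else:
            out = [b for b in self if b.first_year < self.era_cutoff_year]
        if not out:
            raise ValidationError(
                f"no boxes available for hatch year {hatch_year} "
                f"(era cutoff {self.era_cutoff_year}); "
                "no detectable settlement is possible"
            )
        return out

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, era_cutoff_year: int = 1987) -> "BoxRegistry":
        """Build a registry from a table with columns ``box_id``, ``first_year``
        and either ``x_km``/``y_km`` (planar) or ``lat``/``lon`` (geographic).

        Geographic input is projected to a local azimuthal-equidistant frame
        centred on the centroid of the boxes.
        """
        cols = set(df.columns)
        if {"x_km", "y_km"} <= cols:
            x = df["x_km"].to_numpy(float)
            y = df["y_km"].to_numpy(float)
        elif {"lat", "lon"} <= cols:
            x, y = _project_aeqd(df["lat"].to_numpy(float), df["lon"].to_numpy(float))
        else:
            raise ValidationError(
                "registry table needs columns x_km/y_km or lat/lon "
                f"(got {sorted(cols)})"
            )
        boxes = [
            NestBox(str(b), float(xi), float(yi), int(fy))
            for b, xi, yi, fy in zip(df["box_id"], x, y, df["first_year"])
        ]
        return cls(boxes, era_cutoff_year=era_cutoff_year)

    @classmethod
    def from_csv(cls, path: str | Path, era_cutoff_year: int = 1987) -> "BoxRegistry":
        return cls.from_dataframe(pd.read_csv(path), era_cutoff_year=era_cutoff_year)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "box_id": self.box_ids,
                "x_km": [b.x_km for b in self],
                "y_km": [b.y_km for b in self],
                "first_year": [b.first_year for b in self],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _project_aeqd(lat_deg: np.ndarray, lon_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal-equidistant projection centred on the point-set centroid.

    Spherical model; returns (easting, northing) in km.  Distances from the
    centre are exact great-circle distances; between peripheral points the
    error is O((extent/R)^2), negligible at study-area scale.
    """
    lat = np.radians(lat_deg)
    lon = np.radians(lon_deg)
    lat0, lon0 = lat.mean(), lon.mean()
    # great-circle distance and forward azimuth from the centre
    sin_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    c = np.arccos(np.clip(sin_c, -1.0, 1.0))
    az = np.arctan2(
        np.sin(lon - lon0) * np.cos(lat),
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0),
    )
    rho = _EARTH_RADIUS_KM * c
    return rho * np.sin(az), rho * np.cos(az)


def pairwise_distances(registry: BoxRegistry) -> pd.DataFrame:
    """Symmetric matrix of Euclidean box-to-box distances in km.

    Returns a DataFrame indexed by box id on both axes, with a zero diagonal.
    """
    coords = registry.coordinates()
    mat = squareform(pdist(coords))
    return pd.DataFrame(mat, index=registry.box_ids, columns=registry.box_ids)


def available_boxes(registry: BoxRegistry, hatch_year: int) -> list[NestBox]:
    """Functional alias for :meth:`BoxRegistry.available_boxes`."""
    return registry.available_boxes(hatch_year)


def natal_dispersal_distance(natal: NestBox, breeding: NestBox) -> float:
    """Straight-line distance in km from the natal box to the breeding box.

    Zero when the natal box is reused; whether zero distances enter an
    analysis is decided by the caller.
    """
    return float(math.hypot(breeding.x_km - natal.x_km, breeding.y_km - natal.y_km))
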