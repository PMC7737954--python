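"""Slippy-map x/y/z tile math and offline tile manifests.

The OSM tiling scheme projects WGS84 coordinates to Web-Mercator and, at
zoom ``z``, splits the square world into ``2^z x 2^z`` tiles: column ``x``
grows eastward from lon -180, row ``y`` grows southward from lat ~85.05.
An offline map server needs exactly the tiles covering each community
bounding box across the zoom range of interest; this module computes that
set and writes the ``z/x/y.png`` directory skeleton plus a CSV manifest
(no imagery is fetched — tiles are rendered or copied in separately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .model import BBox, MERCATOR_LAT_LIMIT, TileIndex

#: Nominal size of one pre-rendered 256x256 PNG street tile, used for
#: storage estimates in manifests.
DEFAULT_TILE_BYTES = 15_000


def _clamp_lat(lat: float) -> float:
    return max(-MERCATOR_LAT_LIMIT, min(MERCATOR_LAT_LIMIT, lat))


def _xfrac(lon: float, z: int) -> float:
    return (lon + 180.0) / 360.0 * (1 << z)

def _yfrac(lat: float, z: int) -> float:
    phi = math.radians(_clamp_lat(lat))
    return (1.0 - math.asinh(math.tan(phi)) / math.pi) / 2.0 * (1 << z)


def _snap(v: float) -> float:
    # roundoff from the inverse transform must not flip a floor/ceil across
    # a tile boundary; the forward/inverse error stays well below 1e-9 in
    # fraction space up to z=18 even at the clamp latitude, where sec(lat)
    # amplifies it most
    r = round(v)
    return float(r) if abs(v - r) <= 1e-9 else v


def latlon_to_tile(lat: float, lon: float, z: int) -> TileIndex:
    """Tile containing a WGS84 point at zoom ``z``.

    ``x = floor((lon+180)/360 * 2^z)``;
    ``y = floor((1 - ln(tan(phi) + sec(phi))/pi)/2 * 2^z)``.
    Latitudes beyond the Web-Mercator range are clamped, matching common
    tiling tools; points exactly on the east/south world edge map into the
    last tile.
    """
    if z < 0:
        raise ValidationError(f"zoom must be >= 0, got {z}")
    n = 1 << z
    x = min(n - 1, max(0, math.floor(_snap(_xfrac(lon, z)))))
    y = min(n - 1, max(0, math.floor(_snap(_yfrac(lat, z)))))
    return TileIndex(z=z, x=x, y=y)


def tile_to_bbox(tile: TileIndex) -> BBox:
    """Geographic bounds of a tile (inverse of the tiling transform).

    The north-west corner maps back to the same tile under
    :func:`latlon_to_tile`; the south/east edges belong to the neighbors.
    """
    n = 1 << tile.z

    def lon_of(x):
        return x / n * 360.0 - 180.0

    def lat_of(y):
        return math.degrees(math.atan(math.sinh(math.pi * (1 - 2 * y / n))))

    return BBox(
        min_lat=lat_of(tile.y + 1),
        min_lon=lon_of(tile.x),
        max_lat=lat_of(tile.y),
        max_lon=lon_of(tile.x + 1),
    )


@dataclass(frozen=True)
class TileManifest:
    """A tile set plus its summary statistics."""

    tiles: tuple[TileIndex, ...]
    z_min: int
    z_max: int
    per_tile_bytes: int = DEFAULT_TILE_BYTES

    @property
    def count(self) -> int:
        return len(self.tiles)

    @property
    def estimated_bytes(self) -> int:
        return self.count * self.per_tile_bytes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.z, t.x, t.y, t.path) for t in self.tiles],
            columns=["Z", "X", "Y", "RELATIVE_PATH"],
        )


def tiles_for_bbox(
    bbox: BBox,
    z_min: int,
    z_max: int,
    per_tile_bytes: int = DEFAULT_TILE_BYTES,
) -> TileManifest:
    """All tiles whose extent intersects ``bbox`` for each zoom in range.

    Intersection is half-open per the slippy-map convention: a bbox edge
    lying exactly on a tile boundary does not pull in the neighboring tile
    (except for a degenerate point-bbox, which yields the single tile the
    point falls in). Output is sorted by (z, x, y).
    """
    if z_min < 0:
        raise ValidationError(f"zoom must be >= 0, got {z_min}")
    if z_min > z_max:
        raise ValidationError(f"z_min {z_min} > z_max {z_max}")

    tiles: list[TileIndex] = []
    for z in range(z_min, z_max + 1):
        n = 1 << z
        x_lo = math.floor(_snap(_xfrac(bbox.min_lon, z)))
        x_hi = max(x_lo, math.ceil(_snap(_xfrac(bbox.max_lon, z))) - 1)
        # y grows southward: the north edge (max_lat) gives the low row
        y_lo = math.floor(_snap(_yfrac(bbox.max_lat, z)))
        y_hi = max(y_lo, math.ceil(_snap(_yfrac(bbox.min_lat, z))) - 1)
        x_lo, x_hi = max(0, x_lo), min(n - 1, x_hi)
        y_lo, y_hi = max(0, y_lo), min(n - 1, y_hi)
        tiles.extend(
            TileIndex(z=z, x=x, y=y)
            for x in range(x_lo, x_hi + 1)
            for y in range(y_lo, y_hi + 1)
        )
    tiles.sort(key=lambda t: (t.z, t.x, t.y))
    return TileManifest(
        tiles=tuple(tiles), z_min=z_min, z_max=z_max,
        per_tile_bytes=per_tile_bytes,
    )


def bbox_of_structures(structures: Iterable, margin: float = 0.0) -> BBox:
    """Bounding box around structure coordinates, optionally padded by
    ``margin`` degrees on every side."""
    structures = list(structures)
    if not structures:
        raise ValidationError("cannot compute a bbox of zero structures")
    lats = [s.lat for s in structures]
    lons = [s.lon for s in structures]
    return BBox(
        min_lat=min(lats) - margin,
        min_lon=min(lons) - margin,
        max_lat=max(lats) + margin,
        max_lon=max(lons) + margin,
    )


def write_manifest(manifest: TileManifest, out_dir) -> Path:
    """Write ``manifest.csv`` plus the ``tiles/z/x/y.png`` skeleton.

    Placeholders are empty files; a summary line (count and estimated
    bytes) is appended to the manifest as a trailing comment row.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiles_root = out_dir / "tiles"
    for tile in manifest.tiles:
        target = tiles_root / tile.path
        target.parent.mkdir(parents=True, exist_ok=True)
        target.touch()
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", encoding="utf-8", newline="") as fh:
        manifest.to_frame().to_csv(fh, index=False)
        fh.write(
            f"# tiles={manifest.count} "
            f"estimated_bytes={manifest.estimated_bytes}\n"
        )
    return manifest_path
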