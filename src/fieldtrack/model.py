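"""Domain types for the visit-tracking data model.

The persistent state of a campaign is a preload of geocoded structures plus
an append-mostly log of visit records per household. Visit 0 is the preload
row itself and is immutable; real visit attempts are numbered from 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Iterator, Optional

from .errors import IntegrityError, ValidationError


class AreaType(str, enum.Enum):
    """How a community recruits: door-to-door or centralized (apartments)."""

    NEIGHBORHOOD = "NEIGHBORHOOD"
    APARTMENT = "APARTMENT"


class FinalOutcome(str, enum.Enum):
    """Terminal classification of a household; PENDING while still open."""

    RECRUITED = "RECRUITED"
    REFUSED = "REFUSED"
    INELIGIBLE = "INELIGIBLE"
    NOT_A_HOME = "NOT_A_HOME"
    NO_CONTACT = "NO_CONTACT"
    PENDING = "PENDING"


#: Columns of a final-outcome report, in publication order.
TERMINAL_OUTCOMES = (
    FinalOutcome.RECRUITED,
    FinalOutcome.REFUSED,
    FinalOutcome.INELIGIBLE,
    FinalOutcome.NO_CONTACT,
    FinalOutcome.NOT_A_HOME,
)


@dataclass(frozen=True, slots=True)
class Structure:
    """One geocoded residential unit.

    Parameters
    ----------
    hhid : str
        Unique structure identifier within a campaign.
    cluster : str
        Community code the structure belongs to.
    lat, lon : float
        WGS84 centroid coordinates in decimal degrees.
    area_type : AreaType
        Recruitment modality of the community.
    """

    hhid: str
    cluster: str
    lat: float
    lon: float
    area_type: AreaType = AreaType.NEIGHBORHOOD

    def __post_init__(self):
        if not self.hhid:
            raise ValidationError("hhid must be non-empty")
        if not self.cluster:
            raise ValidationError(f"{self.hhid}: cluster must be non-empty")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"{self.hhid}: latitude {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(
                f"{self.hhid}: longitude {self.lon} out of [-180, 180]"
            )


@dataclass(frozen=True, slots=True)
class VisitRecord:
    """One row of the visit-log schema.

    ``visit == 0`` is the preload row; its STRUCTURE/STATUS/DETAILS/INITIALS
    fields are empty. For ``visit >= 1`` those fields are required and
    DETAILS must be in the vocabulary allowed for STATUS (validated by the
    visit engine, which owns the configuration).
    """

    ref: int
    hhid: str
    cluster: str
    lon: float
    lat: float
    visit: int
    structure: str = ""
    status: str = ""
    details: str = ""
    visit_datetime: Optional[datetime] = None
    fu_date: Optional[date] = None
    fu_notes: str = ""
    initials: str = ""

    def __post_init__(self):
        if self.visit < 0:
            raise ValidationError(f"{self.hhid}: visit number must be >= 0")
        if self.visit >= 1:
            for name in ("structure", "status", "details", "initials"):
                if not getattr(self, name):
                    raise ValidationError(
                        f"{self.hhid} visit {self.visit}: required field "
                        f"{name.upper()} is empty"
                    )
            if self.visit_datetime is None:
                raise ValidationError(
                    f"{self.hhid} visit {self.visit}: VISIT_DATETIME required"
                )

    @property
    def visit_date(self) -> Optional[date]:
        return self.visit_datetime.date() if self.visit_datetime else None


@dataclass(frozen=True)
class HouseholdLog:
    """Ordered visit records for one household.

    The record at index 0 always has ``visit == 0`` (the preload row) and is
    never modified or removed. Visit numbers are contiguous ``0..k`` and
    timestamps are non-decreasing.
    """

    hhid: str
    records: tuple[VisitRecord, ...]
    area_type: AreaType = AreaType.NEIGHBORHOOD

    def __post_init__(self):
        if not self.records:
            raise IntegrityError(f"{self.hhid}: log must contain the preload row")
        if self.records[0].visit != 0:
            raise IntegrityError(f"{self.hhid}: first record must be visit 0")
        for i, rec in enumerate(self.records):
            if rec.hhid != self.hhid:
                raise IntegrityError(
                    f"{self.hhid}: record {i} belongs to {rec.hhid}"
                )
            if rec.visit != i:
                raise IntegrityError(
                    f"{self.hhid}: visit numbers not contiguous "
                    f"(expected {i}, found {rec.visit})"
                )
        stamps = [r.visit_datetime for r in self.records if r.visit_datetime]
        if any(a > b for a, b in zip(stamps, stamps[1:])):
            raise IntegrityError(f"{self.hhid}: visit timestamps decrease")

    @classmethod
    def from_structure(cls, structure: Structure, ref: int = 0) -> "HouseholdLog":
        """Fresh log holding only the immutable preload row."""
        preload = VisitRecord(
            ref=ref,
            hhid=structure.hhid,
            cluster=structure.cluster,
            lon=structure.lon,
            lat=structure.lat,
            visit=0,
        )
        return cls(hhid=structure.hhid, records=(preload,),
                   area_type=structure.area_type)

    @property
    def cluster(self) -> str:
        return self.records[0].cluster

    @property
    def visits(self) -> tuple[VisitRecord, ...]:
        """Recorded visit attempts (visit >= 1), excluding the preload row."""
        return self.records[1:]

    @property
    def n_visits(self) -> int:
        return len(self.records) - 1

    @property
    def last(self) -> VisitRecord:
        return self.records[-1]

    def with_record(self, record: VisitRecord) -> "HouseholdLog":
        return replace(self, records=self.records + (record,))

    def __iter__(self) -> Iterator[VisitRecord]:
        return iter(self.records)


class MarkerColor(str, enum.Enum):
    """Base marker color driving field prioritization."""

    BLUE = "BLUE"        # never visited
    ORANGE = "ORANGE"    # visited, unscheduled follow-up pending
    GREY = "GREY"        # follow-up scheduled on a future weekday
    BLACK = "BLACK"      # Saturday visit required or scheduled
    PINK = "PINK"        # follow-up scheduled for today
    GREEN = "GREEN"      # closed, no more visits


class MarkerOutline(str, enum.Enum):
    NONE = "NONE"
    BLACK_OUTLINE = "BLACK_OUTLINE"   # already visited today, still open
    RED_OUTLINE = "RED_OUTLINE"       # scheduled follow-up date is overdue


@dataclass(frozen=True, slots=True)
class MarkerState:
    """Symbolic display state of a household marker."""

    base: MarkerColor
    outline: MarkerOutline = MarkerOutline.NONE
    advisory: str = ""

    def __post_init__(self):
        if self.base is MarkerColor.GREEN and self.outline is not MarkerOutline.NONE:
            raise ValidationError("GREEN markers never carry an outline")
        if (self.outline is MarkerOutline.BLACK_OUTLINE
                and self.base is not MarkerColor.ORANGE):
            raise ValidationError("BLACK_OUTLINE only applies to ORANGE markers")


@dataclass(frozen=True, slots=True)
class TileIndex:
    """Slippy-map tile address: zoom ``z`` splits the Web-Mercator world
    into ``2^z x 2^z`` tiles, column ``x`` west-to-east, row ``y``
    north-to-south."""

    z: int
    x: int
    y: int

    def __post_init__(self):
        if self.z < 0:
            raise ValidationError(f"zoom must be >= 0, got {self.z}")
        n = 1 << self.z
        if not (0 <= self.x < n and 0 <= self.y < n):
            raise ValidationError(
                f"tile ({self.x}, {self.y}) outside [0, {n}) at z={self.z}"
            )

    @property
    def path(self) -> str:
        return f"{self.z}/{self.x}/{self.y}.png"


#: Latitude bound of the square Web-Mercator world.
MERCATOR_LAT_LIMIT = 85.0511287798066


@dataclass(frozen=True, slots=True)
class BBox:
    """Geographic bounding box in decimal degrees; latitudes are clamped to
    the Web-Mercator range on construction."""

    min_lat: float
    min_lon: float
    max_lat: float
    max_lon: float

    def __post_init__(self):
        object.__setattr__(
            self, "min_lat",
            max(-MERCATOR_LAT_LIMIT, min(MERCATOR_LAT_LIMIT, self.min_lat)))
        object.__setattr__(
            self, "max_lat",
            max(-MERCATOR_LAT_LIMIT, min(MERCATOR_LAT_LIMIT, self.max_lat)))
        if self.min_lat > self.max_lat or self.min_lon > self.max_lon:
            raise ValidationError(
                f"inverted bbox: ({self.min_lat}, {self.min_lon}) .. "
                f"({self.max_lat}, {self.max_lon})"
            )
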