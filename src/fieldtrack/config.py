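"""Study configuration: visit vocabularies, protocol caps, targets.

The status/details vocabularies are drop-down fields in the capture UI and
are customizable per project; DETAILS options are conditioned on the STATUS
selected. The defaults below model a door-to-door recruitment protocol:
up to ``max_visits`` attempts per household, at least one on a Saturday
when earlier attempts found nobody home, and a per-community recruitment
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .errors import ValidationError, VocabularyError
from .model import FinalOutcome

# Default status vocabulary
NO_ANSWER = "NO_ANSWER"
CONTACT_MADE = "CONTACT_MADE"
NOT_A_HOME = "NOT_A_HOME"
VACANT = "VACANT"
SCHEDULED_BY_RESIDENT = "SCHEDULED_BY_RESIDENT"

# Default details vocabulary (terminal ones double as outcome labels)
RECRUITED = "RECRUITED"
REFUSED = "REFUSED"
INELIGIBLE = "INELIGIBLE"
UNDECIDED = "UNDECIDED"

DEFAULT_STATUSES = [
    NO_ANSWER, CONTACT_MADE, NOT_A_HOME, VACANT, SCHEDULED_BY_RESIDENT,
]

DEFAULT_DETAILS_BY_STATUS = {
    NO_ANSWER: ["NO_ONE_HOME", "INACCESSIBLE"],
    CONTACT_MADE: [RECRUITED, REFUSED, INELIGIBLE, UNDECIDED],
    NOT_A_HOME: ["BUSINESS", "NON_RESIDENTIAL", "UNDER_CONSTRUCTION"],
    VACANT: ["EMPTY_HOME", "FOR_SALE_OR_RENT"],
    SCHEDULED_BY_RESIDENT: ["APPOINTMENT_SET"],
}

# Statuses meaning nobody answered the door; these feed the Saturday rule.
DEFAULT_NO_CONTACT_STATUSES = [NO_ANSWER]

# Statuses terminal on first occurrence: non-homes and vacant homes both
# count under the NOT_A_HOME outcome column.
DEFAULT_TERMINAL_STATUSES = {
    NOT_A_HOME: FinalOutcome.NOT_A_HOME,
    VACANT: FinalOutcome.NOT_A_HOME,
}

# Details terminal regardless of repeat visits.
DEFAULT_TERMINAL_DETAILS = {
    RECRUITED: FinalOutcome.RECRUITED,
    REFUSED: FinalOutcome.REFUSED,
    INELIGIBLE: FinalOutcome.INELIGIBLE,
}

DEFAULT_STRUCTURE_TYPES = ["HOUSE", "APARTMENT_UNIT", "OTHER"]


@dataclass(frozen=True)
class StudyConfig:
    """Protocol rules and vocabularies for one study.

    Parameters
    ----------
    max_visits : int
        Maximum number of in-person attempts before a household closes as
        NO_CONTACT.
    saturday_required : bool
        Whether two weekday no-contact attempts trigger the
        next-visit-on-a-Saturday advisory.
    statuses : list of str
        Allowed STATUS values.
    details_by_status : mapping status -> list of str
        Allowed DETAILS per status; every status has at least one.
    no_contact_statuses : list of str
        Subset of ``statuses`` meaning nobody answered.
    terminal_statuses : mapping status -> FinalOutcome
        Statuses that close the household on first occurrence.
    terminal_details : mapping detail -> FinalOutcome
        Details that close the household (e.g. RECRUITED).
    target_per_community : int
        Recruitment target used by replenishment planning.
    """

    max_visits: int = 3
    saturday_required: bool = True
    statuses: tuple = tuple(DEFAULT_STATUSES)
    details_by_status: Mapping[str, tuple] = field(
        default_factory=lambda: {
            k: tuple(v) for k, v in DEFAULT_DETAILS_BY_STATUS.items()
        }
    )
    no_contact_statuses: tuple = tuple(DEFAULT_NO_CONTACT_STATUSES)
    terminal_statuses: Mapping[str, FinalOutcome] = field(
        default_factory=lambda: dict(DEFAULT_TERMINAL_STATUSES)
    )
    terminal_details: Mapping[str, FinalOutcome] = field(
        default_factory=lambda: dict(DEFAULT_TERMINAL_DETAILS)
    )
    structure_types: tuple = tuple(DEFAULT_STRUCTURE_TYPES)
    target_per_community: int = 100

    def __post_init__(self):
        if self.max_visits < 1:
            raise ValidationError("max_visits must be >= 1")
        for status in self.statuses:
            allowed = self.details_by_status.get(status, ())
            if not allowed:
                raise ValidationError(
                    f"status {status} has no allowed DETAILS values"
                )
        unknown = set(self.no_contact_statuses) - set(self.statuses)
        if unknown:
            raise ValidationError(
                f"no_contact_statuses not in statuses: {sorted(unknown)}"
            )

    def validate_pair(self, status: str, details: str) -> None:
        """Raise VocabularyError unless (status, details) is allowed."""
        if status not in self.statuses:
            raise VocabularyError(f"unknown STATUS {status!r}")
        allowed = self.details_by_status.get(status, ())
        if details not in allowed:
            raise VocabularyError(
                f"DETAILS {details!r} not allowed for STATUS {status!r} "
                f"(allowed: {', '.join(allowed)})"
            )

    def outcome_of(self, status: str, details: str) -> Optional[FinalOutcome]:
        """Terminal outcome carried by a visit, or None if non-terminal."""
        if status in self.terminal_statuses:
            return self.terminal_statuses[status]
        if details in self.terminal_details:
            return self.terminal_details[details]
        return None

    def is_terminal(self, status: str, details: str) -> bool:
        return self.outcome_of(status, details) is not None

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "max_visits": self.max_visits,
            "saturday_required": self.saturday_required,
            "statuses": list(self.statuses),
            "details_by_status": {
                k: list(v) for k, v in self.details_by_status.items()
            },
            "no_contact_statuses": list(self.no_contact_statuses),
            "terminal_statuses": {
                k: v.value for k, v in self.terminal_statuses.items()
            },
            "terminal_details": {
                k: v.value for k, v in self.terminal_details.items()
            },
            "structure_types": list(self.structure_types),
            "target_per_community": self.target_per_community,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        kwargs = dict(data)
        if "statuses" in kwargs:
            kwargs["statuses"] = tuple(kwargs["statuses"])
        if "details_by_status" in kwargs:
            kwargs["details_by_status"] = {
                k: tuple(v) for k, v in kwargs["details_by_status"].items()
            }
        if "no_contact_statuses" in kwargs:
            kwargs["no_contact_statuses"] = tuple(kwargs["no_contact_statuses"])
        for key in ("terminal_statuses", "terminal_details"):
            if key in kwargs:
                kwargs[key] = {
                    k: FinalOutcome(v) for k, v in kwargs[key].items()
                }
        if "structure_types" in kwargs:
            kwargs["structure_types"] = tuple(kwargs["structure_types"])
        return cls(**kwargs)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


DEFAULT_CONFIG = StudyConfig()
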