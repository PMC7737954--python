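"""Typed error hierarchy.

Every malformed input raises one of these; rows are never silently dropped.
"""


class FieldTrackError(Exception):
    """Base class for all package errors."""


class SchemaError(FieldTrackError):
    """A required column is missing or a file is structurally unreadable."""


class ValidationError(FieldTrackError):
    """A row violates a domain invariant (range, uniqueness, required field)."""


class DuplicateIDError(ValidationError):
    """Duplicate HHIDs in a preload file."""

    def __init__(self, duplicates):
        self.duplicates = sorted(duplicates)
        super().__init__(f"duplicate HHID(s): {', '.join(self.duplicates)}")


class VocabularyError(ValidationError):
    """A STATUS or DETAILS value outside the configured vocabulary."""


class IntegrityError(ValidationError):
    """Visit numbering or ordering within a household log is inconsistent."""


class ClosedHouseholdError(FieldTrackError):
    """Attempt to record a visit against a household that needs no more visits."""


class ImmutableRowError(FieldTrackError):
    """Attempt to edit or delete the preload row (visit 0)."""


class NotFoundError(FieldTrackError):
    """Referenced household or visit does not exist."""


class MergeConflictError(FieldTrackError):
    """A new selection collides with already-visited households."""

    def __init__(self, collisions):
        self.collisions = sorted(collisions)
        super().__init__(
            f"new selection collides with visited household(s): "
            f"{', '.join(self.collisions)}"
        )
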