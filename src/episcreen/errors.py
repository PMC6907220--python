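"""Exception hierarchy shared across the package."""


class EpiscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EpiscreenError, ValueError):
    """An input value violates a documented precondition or invariant."""


class PlateFormatError(ValidationError):
    """A well address falls outside the declared plate format."""


class OrphanWellError(ValidationError):
    """Raw readings reference wells absent from the paired layout."""

    def __init__(self, orphans):
        self.orphans = sorted(orphans)
        super().__init__(f"readings for wells absent from layout: {', '.join(self.orphans)}")


class MissingControlsError(EpiscreenError):
    """A plate lacks the negative or positive control wells needed to anchor normalization."""


class DegenerateWindowError(EpiscreenError):
    """Negative- and positive-control means coincide; percent viability is undefined."""


class EmptyProfileError(EpiscreenError):
    """No QC-eligible wells match the requested (cell line, compound, arm) query."""
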