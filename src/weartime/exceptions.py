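"""Exception hierarchy for the weartime package."""


class WeartimeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WeartimeError):
    """An invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DataIntegrityError(WeartimeError):
    """Input data violates a structural invariant (e.g. duplicate person-hours)."""


class JoinError(WeartimeError):
    """Step records reference persons absent from the participant table."""

    def __init__(self, orphans):
        self.orphans = sorted(orphans)
        shown = ", ".join(map(str, self.orphans[:10]))
        more = "" if len(self.orphans) <= 10 else f" (+{len(self.orphans) - 10} more)"
        super().__init__(f"step records reference unknown person_id(s): {shown}{more}")


class EmptyGroupError(WeartimeError):
    """A filtering or matching step left a comparison group with no data."""

    def __init__(self, groups, context: str):
        self.groups = list(groups)
        super().__init__(f"{context} emptied group(s): {', '.join(map(str, self.groups))}")


class IdentifiabilityError(WeartimeError):
    """The requested model cannot be identified from the data provided."""


class RankDeficiencyError(WeartimeError):
    """The design matrix is rank deficient; the message names dependent columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; linearly dependent column(s): "
            + ", ".join(self.columns)
        )


class ConvergenceError(WeartimeError):
    """A mixed-model fit failed to converge; never silently degraded."""
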