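"""Exception hierarchy.

Everything raised by this package derives from :class:`AdamError`, so
callers can catch one type at an API boundary (the CLI maps them onto
exit code 2).
"""

from __future__ import annotations


class AdamError(Exception):
    """Base class for all errors raised by adamatrix."""


class MalformedRegistry(AdamError):
    """A registry document could not be parsed at all."""


class RegistryInvariantViolation(AdamError):
    """A registry document parsed but violates a structural invariant.

    The message names the violated invariant.
    """


class MalformedDocument(AdamError):
    """A profile or request document is syntactically broken.

    ``location`` is a JSON path or a 1-based line number, depending on
    the dialect.
    """

    def __init__(self, message: str, location: str | int | None = None):
        self.location = location
        if location is not None:
            message = f"{message} (at {location})"
        super().__init__(message)


class DuplicateKey(MalformedDocument):
    """The same dotted key appears twice in a key-value document."""


class UnknownConcept(AdamError):
    """A concept id is not defined in the registry in use."""


class ValueNotInDomain(AdamError):
    """A value token is not in the concept's permitted value domain."""


class IndexOutOfRange(AdamError):
    """A main-body index does not exist in the profile."""


class EmptyList(AdamError):
    """A condition list to render contains no items."""


class UnknownRule(AdamError):
    """A validation rule id outside R1..R7."""


class InvalidProfile(AdamError):
    """A profile failed validation where a valid one is required.

    Carries the offending :class:`~adamatrix.validation.ValidationReport`.
    """

    def __init__(self, report):
        self.report = report
        rules = ", ".join(sorted({f.rule_id for f in report.findings}))
        super().__init__(f"profile fails validation ({rules})")


class IntentUnsatisfiable(AdamError):
    """No access request with the demanded intent exists for this profile."""


class MutationInapplicable(AdamError):
    """The profile offers no cheap way to violate the requested rule."""
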