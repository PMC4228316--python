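"""Exception hierarchy shared across the package."""


class TailorkitError(Exception):
    """Base class for all package-specific errors."""


class CatalogError(TailorkitError):
    """A variable catalog failed validation (duplicate names, undeclared
    references, dependency cycles, malformed domains, empty documents)."""


class RuleTypeError(TailorkitError):
    """A rule clause compared incompatible kinds, e.g. free text against a
    numeric threshold.  Carries the offending variable name in the message."""


class LibraryError(TailorkitError):
    """A message library failed validation (duplicate ids, unknown slots or
    constructs, undeclared merge fields)."""


class MergeFieldError(LibraryError):
    """A message body referenced a merge field that is not declared."""


class AssemblyError(TailorkitError):
    """Newsletter assembly could not find a message for a tailored slot;
    signals an engine/library mismatch that coverage validation should have
    caught."""


class InfeasibleMomentsError(TailorkitError):
    """No 5-point distribution attains the requested mean, SD and tail mass
    simultaneously (strict moment matching only)."""


class FitError(TailorkitError):
    """An ordinal regression could not be fitted (constant outcome, singular
    design, or complete separation)."""
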