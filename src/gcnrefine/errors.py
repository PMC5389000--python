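"""Exception hierarchy.

All user-facing failures derive from :class:`GcnError` so callers (and the
CLI) can catch one type.  Subclasses distinguish malformed input files from
invalid parameter choices and from data that is degenerate for the requested
computation (e.g. a zero-variance gene fed to a correlation).
"""


class GcnError(Exception):
    """Base class for all errors raised by gcnrefine."""


class FormatError(GcnError):
    """A file or serialized artifact violates its format contract."""


class ParameterError(GcnError):
    """An argument is outside its allowed range or inconsistent."""


class ValidationError(GcnError):
    """In-memory data violates an invariant (mismatched ids, NaNs, ...)."""


class DegenerateDataError(GcnError):
    """Data is structurally valid but degenerate for the computation."""
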