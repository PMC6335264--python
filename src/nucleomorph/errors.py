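"""Exception hierarchy for the pipeline.

All errors derive from :class:`NucleomorphError` so callers can catch the
package's failures with one clause while still distinguishing parameter
misuse from geometric impossibilities and missing-signal conditions.
"""


class NucleomorphError(Exception):
    """Base class for all package errors."""


class ParameterError(NucleomorphError, ValueError):
    """A scalar parameter is outside its documented domain."""


class InputError(NucleomorphError, ValueError):
    """An input array or table violates a precondition (non-finite pixels,
    duplicate frames, too-small samples...)."""


class GeometryError(NucleomorphError, ValueError):
    """Masks or shapes are inconsistent (overlapping nuclei, empty mask
    where an object is required)."""


class NoLaminSignalError(NucleomorphError):
    """A nucleus has no lamin-positive pixels; it must be excluded from
    scoring rather than silently scored as zero."""


class NoCytoplasmError(NucleomorphError):
    """A cell has no measurable cytoplasmic signal above background, so a
    nuclear/cytoplasmic ratio is undefined for it."""


class ConstantChannelError(NucleomorphError):
    """A channel has zero variance on the analysis mask; a correlation is
    undefined."""
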