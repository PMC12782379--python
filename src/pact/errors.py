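"""Exception hierarchy.

All errors raised by this package derive from :class:`PactError` so callers
can catch one base class at CLI boundaries.
"""


class PactError(Exception):
    """Base class for all package errors."""


class MeshFormatError(PactError, ValueError):
    """A mesh file could not be read or is empty/degenerate."""


class TopologyError(PactError, ValueError):
    """Mesh topology prevents the requested operation (e.g. not closable)."""


class GeometryError(PactError, ValueError):
    """Geometric degeneracy (collinear landmarks, zero extent, ...)."""


class RegistrationError(PactError, ValueError):
    """Rigid registration could not be established."""


class InputError(PactError, ValueError):
    """Invalid numeric or structural input."""


class LibraryError(PactError, ValueError):
    """Reference-library construction or lookup failure."""
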