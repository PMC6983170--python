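"""Exception hierarchy for xbtraj.

All package errors derive from :class:`XBTrajError` so callers can catch
one base class at pipeline boundaries.
"""


class XBTrajError(Exception):
    """Base class for all xbtraj errors."""


class ParseError(XBTrajError):
    """A structure or table file could not be parsed (names the line)."""


class EmptyInputError(XBTrajError):
    """An operation received an empty structure, series or list."""


class TopologyError(XBTrajError):
    """Coordinate data does not match the supplied topology."""


class SerialLookupError(XBTrajError, KeyError):
    """An atom serial was not found in the topology."""


class PerceptionError(XBTrajError):
    """Donor/acceptor perception failed for a ligand atom or residue."""


class DegenerateGeometryError(XBTrajError):
    """A geometric quantity is undefined (e.g. zero-length bond vector)."""


class SelectionError(XBTrajError):
    """An atom/residue selection matched nothing."""


class ParameterError(XBTrajError, ValueError):
    """An analysis parameter is out of its valid range."""


class PharmacophoreError(XBTrajError):
    """A required pharmacophore feature (basic N, aromatic ring) is absent."""


class ActivityDomainError(XBTrajError, ValueError):
    """A ligand activity value is outside the positive domain."""


class SyntheticSpecError(XBTrajError, ValueError):
    """A synthetic-trajectory specification is invalid."""
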