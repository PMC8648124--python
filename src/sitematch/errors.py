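"""Exception hierarchy for sitematch."""


class SitematchError(Exception):
    """Base class for all sitematch errors."""


class ParseError(SitematchError):
    """A structure file could not be parsed."""


class EmptyStructureError(SitematchError):
    """A structure contains no residues and no ligands."""


class ParameterError(SitematchError, ValueError):
    """An argument violates an operation's preconditions."""


class DegenerateGeometryError(SitematchError):
    """Coordinates are geometrically degenerate (e.g. collinear point sets)."""


class ConfigurationError(SitematchError):
    """A configuration table is missing a required entry."""


class MultiChainSiteError(SitematchError):
    """Sequence distances are undefined for sites spanning multiple chains."""


class PlacementError(SitematchError):
    """A synthetic ligand could not be placed under the geometric constraints."""
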