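"""Exception hierarchy."""


class OildropError(Exception):
    """Base class for all package errors."""


class StructureFormatError(OildropError):
    """Input file could not be parsed under the requested format."""


class MissingModelError(OildropError):
    """Requested coordinate model is absent from the file."""


class EmptyStructureError(OildropError):
    """No standard amino-acid residues survived filtering."""


class SelectionError(OildropError):
    """Selection expression invalid or matched nothing."""


class DegenerateGeometryError(OildropError):
    """Point cloud too degenerate to fit a Gaussian capsule."""


class ProfileError(OildropError):
    """Profile could not be built or normalized."""


class DivergenceUndefinedError(OildropError):
    """Kullback-Leibler divergence undefined (support mismatch)."""


class IndeterminateRDError(OildropError):
    """Both divergences vanish; relative distance is 0/0."""


class InterfaceError(OildropError):
    """Interface analysis failed (overlapping or non-contacting groups)."""
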