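"""Exception hierarchy shared across the pipeline stages."""


class RegVar3DError(Exception):
    """Base class for all package errors."""


class InputFormatError(RegVar3DError):
    """A file could not be parsed at all (zero usable lines, bad layout)."""


class ValidationError(RegVar3DError):
    """A record violates an invariant (bad r2, inverted interval, ...)."""


class CatalogConsistencyError(RegVar3DError):
    """A variant catalogue carries conflicting records for one key."""


class GenomeMismatchError(RegVar3DError):
    """The reference genome base disagrees with a variant's ref allele."""


class NullDistributionError(RegVar3DError):
    """An empirical LOD null could not be built (no eligible scores)."""


class UnknownCellTypeError(RegVar3DError):
    """Requested cell type absent from the loaded track index."""
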