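"""Exception hierarchy.

All data-level failures derive from :class:`PycnvliteError` so the CLI can
map them to a single exit code; usage errors are left to the argument parser.
"""


class PycnvliteError(Exception):
    """Base class for all pycnvlite data/configuration errors."""


class VcfFormatError(PycnvliteError):
    """The VCF is unreadable or structurally invalid (garbled/empty header)."""


class ConfigurationError(PycnvliteError):
    """Invalid user configuration (unknown sample, bad parameter combination)."""


class GridMismatchError(PycnvliteError):
    """Two tracks/tables do not share the same contigs and bin size."""


class StoreError(PycnvliteError):
    """HDF5 store is missing a dataset, write-protected, or version-incompatible."""


class SpecValidationError(PycnvliteError):
    """A simulation sample specification violates its invariants."""
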