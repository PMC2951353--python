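"""Exception hierarchy.

All data-dependent failures raise :class:`DataError` (or a subclass) so the
command-line layer can map them onto a single exit code, distinct from usage
errors.
"""


class IgtlsError(Exception):
    """Base class for all package errors."""


class ParseError(IgtlsError):
    """Malformed input file (FASTA, config, counts table)."""


class DataError(IgtlsError):
    """Input violates a documented contract (alphabet, uniqueness, geometry)."""
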