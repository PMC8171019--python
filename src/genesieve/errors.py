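"""Exception hierarchy mapped to CLI exit codes.

Exit codes: 0 ok, 2 I/O or format, 3 preprocessing, 4 clustering, 5 selection.
"""


class GenesieveError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(GenesieveError):
    """Malformed or inconsistent input data (negative entries, duplicate
    identifiers, dimension mismatches, unreadable files)."""

    exit_code = 2


class PreprocessError(GenesieveError):
    """A preprocessing filter produced an unusable result."""

    exit_code = 3


class ClusteringError(GenesieveError):
    """Invalid clustering configuration or degenerate model state."""

    exit_code = 4


class SelectionError(GenesieveError):
    """Gene-selection stage could not proceed."""

    exit_code = 5
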