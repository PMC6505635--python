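"""Exception hierarchy shared across the package.

All errors raised by the library derive from :class:`SrakitError` so callers
(and the command-line layer) can distinguish usage problems, database
problems and data-integrity problems by type.
"""


class SrakitError(Exception):
    """Base class for all srakit errors."""


class UsageError(SrakitError):
    """The caller supplied invalid arguments (bad accession, empty query...)."""


class AccessionError(UsageError):
    """A string could not be classified as any known accession type."""


class DatabaseNotFoundError(SrakitError):
    """The metadata database file does not exist at the given path."""


class SchemaError(SrakitError):
    """The database file is missing required tables or columns."""


class ProvenanceError(SrakitError):
    """The database carries no schema-version / creation-timestamp metadata."""


class IntegrityError(SrakitError):
    """A record set violates uniqueness or referential-integrity invariants."""


class DownloadError(SrakitError):
    """A transfer could not be performed or its destination is unusable."""
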