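"""Named error types raised while loading panel and read data."""


class ManifestError(ValueError):
    """Base class for panel manifest load failures."""


class MissingColumnError(ManifestError):
    """The manifest header lacks a required column."""


class UnknownChromError(ManifestError):
    """An amplicon names a chromosome absent from the reference store."""


class ReferenceMismatchError(ManifestError):
    """A stored sequence disagrees with the reference substring it maps to."""


class DuplicateAmpliconError(ManifestError):
    """Two amplicons share the same id."""


class FastqParseError(ValueError):
    """A FASTQ record is malformed; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class VcfParseError(ValueError):
    """A VCF record could not be interpreted as a variant call."""
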