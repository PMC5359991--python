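"""Exception hierarchy.

Parse errors cover malformed FASTQ/FASTA input; corruption errors cover
damaged archives or internally inconsistent streams; WrongReferenceError is
raised when the reference supplied at decompression does not match the
checksum recorded at compression time.
"""


class RefqzipError(Exception):
    """Base class for all refqzip errors."""


class FastqParseError(RefqzipError):
    """Malformed FASTQ input; carries the 1-based record index."""

    def __init__(self, message: str, record_index: int | None = None):
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)
        self.record_index = record_index


class FastaFormatError(RefqzipError):
    """Malformed FASTA input."""


class CorruptionError(RefqzipError):
    """Archive or stream is damaged / internally inconsistent."""


class WrongReferenceError(RefqzipError):
    """Reference supplied at decompression does not match the archive."""

    def __init__(self, expected: int, actual: int):
        super().__init__(
            "wrong reference: archive expects checksum "
            f"{expected:016x}, supplied reference has {actual:016x}"
        )
        self.expected = expected
        self.actual = actual


class AssemblyError(RefqzipError):
    """Reference pseudo-assembly could not run (no read contains the prefix)."""
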