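"""Exception types shared across the package."""


class KmerdeconError(Exception):
    """Base class for package errors."""


class FastxFormatError(KmerdeconError):
    """Unparseable FASTA/FASTQ input; message names the offending record."""


class ReferenceBuildError(KmerdeconError):
    """A reference genome could not be turned into a valid column."""


class DatabaseFormatError(KmerdeconError):
    """Serialized reference database is corrupt or of the wrong version."""


class RankError(KmerdeconError):
    """Unknown taxonomic rank or mismatched ranks in a comparison."""
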