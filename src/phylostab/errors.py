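"""Exception hierarchy shared across the package.

``ValidationError`` marks bad user input (CLI exit code 2), ``DataError``
marks inconsistent or unusable data content (CLI exit code 3).
"""


class PhylostabError(Exception):
    """Base class for all package errors."""


class ValidationError(PhylostabError):
    """Invalid configuration, parameters, or argument combinations."""


class DataError(PhylostabError):
    """Input data is malformed or internally inconsistent."""


class NewickError(DataError):
    """A Newick statement could not be parsed or normalized."""
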