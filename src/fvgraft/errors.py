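"""Exception hierarchy.

``InputError`` covers everything a user can fix (bad sequence, bad file,
mismatched chain types); ``GenerationError`` marks over-constrained synthetic
geometry; everything else is an internal bug.
"""


class FvGraftError(Exception):
    """Base class for all package errors."""


class InputError(FvGraftError):
    """Invalid user input (maps to CLI exit code 1)."""


class NotAnFvError(InputError):
    """Sequence cannot be aligned to an antibody variable-domain template."""


class ChainTypeMismatchError(InputError):
    """Operands belong to different chain types (heavy vs light)."""


class MappingError(InputError):
    """Structure chain could not be mapped onto a numbered sequence."""


class GenerationError(FvGraftError):
    """Synthetic-data request is over-constrained or illegal."""
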