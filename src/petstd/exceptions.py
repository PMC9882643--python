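"""Exception hierarchy shared across the package."""


class PetStdError(Exception):
    """Base class for all errors raised by petstd."""


class DataError(PetStdError):
    """Invalid or inconsistent input data (bad file, bad values, misaligned grids)."""


class DegenerateInputError(DataError):
    """Input is formally valid but degenerate for the requested operation
    (constant volume, collapsed landmark ordering, empty mask, ...)."""


class ModalityError(DataError):
    """Operation applied to a volume of the wrong modality."""
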