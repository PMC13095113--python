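"""Exception types shared across taxcap modules."""


class TaxcapError(Exception):
    """Base class for all taxcap errors."""


class InputError(TaxcapError, ValueError):
    """A value or file handed to an operation violates its preconditions."""


class FormatError(TaxcapError, ValueError):
    """A file is readable but does not match the expected schema."""
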