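"""Exception hierarchy shared across the pipeline."""


class CvrMapError(Exception):
    """Base class for all cvrmap errors."""


class ConfigurationError(CvrMapError, ValueError):
    """A configuration field is invalid (names the offending field)."""


class DomainError(CvrMapError, ValueError):
    """An argument lies outside its physical/mathematical domain."""


class FormatError(CvrMapError):
    """A recording or index file does not conform to the documented format."""


class AlignmentError(CvrMapError):
    """Streams cannot be placed on a common timeline (e.g. no overlap)."""


class ContractError(CvrMapError, ValueError):
    """Caller violated an operation precondition (mismatched timelines etc.)."""
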