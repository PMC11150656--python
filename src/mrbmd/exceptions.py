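"""Exception hierarchy shared across the pipeline."""


class MRBMDError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRBMDError):
    """A config file, column map, or parameter set is unusable."""


class TaxonLabelError(MRBMDError, ValueError):
    """A microbiome taxon label could not be parsed."""

    def __init__(self, label: str, reason: str):
        self.label = label
        super().__init__(f"cannot parse taxon label {label!r}: {reason}")


class DomainError(MRBMDError, ValueError):
    """An input violates a mathematical precondition (e.g. se <= 0)."""


class InsufficientInstrumentsError(MRBMDError, ValueError):
    """Too few SNPs for the requested estimator or diagnostic."""

    def __init__(self, needed: int, got: int, what: str = "estimator"):
        self.needed = needed
        self.got = got
        super().__init__(f"{what} requires at least {needed} instruments, got {got}")
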