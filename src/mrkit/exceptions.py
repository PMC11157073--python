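"""Exception hierarchy for mrkit.

All package errors derive from :class:`MRKitError` so callers can catch one
base class; the orchestrator distinguishes configuration problems (fatal
before any computation) from per-pair analysis failures (logged skips).
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A config file, column map, or parameter set is invalid."""


class InputError(MRKitError):
    """Input values violate a contract (bad allele, se <= 0, p outside (0,1])."""


class HarmonizationError(MRKitError):
    """No SNP survived exposure/outcome harmonization for a pair."""


class SelectionError(MRKitError):
    """Instrument selection left zero instruments for an exposure."""


class InsufficientInstrumentsError(MRKitError):
    """An estimator or diagnostic was given fewer SNPs than its minimum."""
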