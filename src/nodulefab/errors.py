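"""Exception hierarchy for nodulefab."""


class NoduleFabError(Exception):
    """Base class for all nodulefab errors."""


class InputError(NoduleFabError):
    """An input file is missing, unreadable, or malformed."""


class DomainError(NoduleFabError):
    """A parameter is outside its mathematical or physical domain."""


class ConfigurationError(NoduleFabError):
    """Inconsistent configuration, e.g. overlapping HU class intervals."""


class ValidationError(NoduleFabError):
    """An object violates its invariants (non-watertight mesh, bad spec...)."""


class EmptySelectionError(NoduleFabError):
    """A filter or label selection matched nothing."""


class NoFeasibleDesignError(NoduleFabError):
    """Every candidate lattice design is excluded by the active rules."""


class FitError(NoduleFabError):
    """A model fit is unidentifiable (e.g. rank-deficient calibration data)."""
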