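"""Exception hierarchy for telogrs."""


class TelogrsError(Exception):
    """Base class for all telogrs errors."""


class FormatError(TelogrsError):
    """A file or table does not match its declared format."""


class HarmonizationError(TelogrsError):
    """Allele harmonization could not be resolved unambiguously."""


class SeparationError(TelogrsError):
    """Logistic regression detected (quasi-)complete separation."""


class MonomorphicError(TelogrsError):
    """A genotype column carries no variation, so no association is estimable."""


class SimulationError(TelogrsError):
    """A simulation request cannot be satisfied (e.g. unattainable case quota)."""


class ConvergenceError(TelogrsError):
    """A model fit did not converge within its iteration budget."""
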