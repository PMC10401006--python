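"""Exception types shared across the package."""


class ClinCrowdError(Exception):
    """Base class for all package-specific errors."""


class InvalidParametersError(ClinCrowdError, ValueError):
    """Arguments are structurally invalid (infeasible graph, bad ratios, ...)."""


class InvalidInputError(ClinCrowdError, ValueError):
    """Data values are out of their documented range."""


class GenerationFailureError(ClinCrowdError, RuntimeError):
    """A randomized constructor exhausted its attempt budget."""


class NoSignalError(ClinCrowdError, ValueError):
    """A node has no neighbors, so no peer signal can be formed."""


class DegenerateInputError(ClinCrowdError, ValueError):
    """Input carries no information for the requested statistic."""


class MissingDataError(ClinCrowdError, ValueError):
    """A required round or clinician record is absent."""


class InvalidBoundsError(ClinCrowdError, ValueError):
    """Normalization bounds are degenerate (max == min)."""
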