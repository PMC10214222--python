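"""Exception hierarchy shared across the toolkit."""


class NichefabError(Exception):
    """Base class for all toolkit errors."""


class FormatError(NichefabError):
    """A file does not conform to the expected tabular/JSON layout."""


class ValidationError(NichefabError):
    """An in-memory object violates its invariants."""


class EnvelopeError(ValidationError):
    """A design target lies outside the characterized fabrication envelope."""


class DomainError(ValidationError):
    """An argument lies outside the mathematical domain of an operation."""


class SolverError(NichefabError):
    """The inverse-design optimizer failed to converge.

    Carries ``best_point`` (peg_pi, focus_z) and ``best_objective`` for diagnosis.
    """

    def __init__(self, message, best_point=None, best_objective=None):
        super().__init__(message)
        self.best_point = best_point
        self.best_objective = best_objective


class CompileError(NichefabError):
    """Print-plan compilation failed for a named region."""


class ConfigurationError(NichefabError):
    """A required configuration value (e.g. sample thickness) is missing."""


class GeometryError(NichefabError):
    """A region of interest falls outside the image it refers to."""


class PackingError(NichefabError):
    """A synthetic scene could not place the requested number of cells."""


class InsufficientDataError(NichefabError):
    """Too few samples for the requested analysis."""


class UndefinedRatioError(NichefabError):
    """A ratio has an empty denominator (e.g. no cytoplasm voxels)."""
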