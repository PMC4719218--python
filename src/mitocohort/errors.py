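"""Exception hierarchy for the mitocohort pipeline.

Every error raised deliberately by this package derives from
:class:`MitocohortError`, so callers (and the CLI) can distinguish
anticipated input/data problems from genuine bugs.
"""


class MitocohortError(Exception):
    """Base class for all anticipated errors."""


class InvalidParameterError(MitocohortError, ValueError):
    """A simulation or analysis parameter is outside its documented range."""


class PileupParseError(MitocohortError, ValueError):
    """A pileup file line could not be interpreted in the supported dialect."""


class InputContractError(MitocohortError, ValueError):
    """Inputs violate a documented precondition (e.g. mismatched references)."""


class ConfigurationError(MitocohortError, ValueError):
    """A configuration names unknown entities or fails validation."""


class DataError(MitocohortError, ValueError):
    """A lookup table is missing a required row."""


class DegenerateFitError(MitocohortError, ValueError):
    """A regression could not be fit (constant response, separation, n too small)."""


class ConsistencyError(MitocohortError, ValueError):
    """Two pipeline artifacts disagree (e.g. a call at a non-usable site)."""
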