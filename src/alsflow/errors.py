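"""Exception types shared across the package."""


class AlsflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AlsflowError):
    """A file does not conform to the expected tabular layout."""


class VocabularyError(AlsflowError):
    """An activity name is not part of the event vocabulary."""


class ConfigError(AlsflowError):
    """A configuration object violates its constraints."""


class IncompleteAssessmentError(AlsflowError):
    """A visit lacks the functional-scale items a mapping rule requires."""


class ConsistencyError(AlsflowError):
    """Input tables contradict each other (e.g. survival before last visit)."""


class InsufficientDataError(AlsflowError):
    """Too few observations to run the requested estimator or test."""
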