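"""Exception hierarchy shared across the package."""


class ChatmineError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ChatmineError):
    """An input file is missing a required column or field."""


class IntegrityError(ChatmineError):
    """An input violates a uniqueness or consistency constraint."""


class ParameterError(ChatmineError, ValueError):
    """A parameter is outside its valid range."""


class EmptyInputError(ChatmineError):
    """An operation that needs data received none."""


class ConfigurationError(ChatmineError):
    """A configuration table (synonym map, lemma table, ...) is inconsistent."""


class TrainingError(ChatmineError):
    """A language model could not be trained from the given texts."""
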