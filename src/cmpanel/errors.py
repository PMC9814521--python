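"""Exception types shared across the pipeline stages."""


class CMPanelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CMPanelError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(CMPanelError, ValueError):
    """A malformed input file; the message names the file and the bad column/cell."""


class AlignmentError(CMPanelError, ValueError):
    """Sample identifiers of two inputs do not overlap or cannot be aligned."""


class DegenerateTableError(CMPanelError, ValueError):
    """A contingency table with a zero row or column margin."""


class UndefinedAUCError(CMPanelError, ValueError):
    """AUC requested for labels containing a single class."""


class WorkflowError(CMPanelError, RuntimeError):
    """The iterative workflow could not produce any usable iteration."""
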