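"""Exception hierarchy shared across the package."""


class TailbindError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TailbindError):
    """A structure or trajectory source could not be parsed."""


class InvalidSelectionError(TailbindError):
    """An atom group / selection is empty, overlapping or otherwise unusable."""


class IncompleteStructureError(TailbindError):
    """A residue lacks the atoms required for the requested operation."""


class InvalidSpecError(TailbindError):
    """A synthetic-data or pipeline specification is internally inconsistent."""


class ConvergenceError(TailbindError):
    """An iterative solver failed to reach its tolerance."""


class DegenerateInputError(TailbindError):
    """Input is degenerate (collinear fit set, all-equal regressors, ...)."""
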