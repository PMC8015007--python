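"""Exception types raised by tmtdiff."""


class TmtdiffError(Exception):
    """Base class for all tmtdiff errors."""


class SchemaError(TmtdiffError, ValueError):
    """An input table is missing required columns or has the wrong shape."""


class EmptyInputError(TmtdiffError, ValueError):
    """An input file contained no data rows."""


class AnnotationError(TmtdiffError, ValueError):
    """The annotation table violates its invariants."""


class JoinError(TmtdiffError, ValueError):
    """PSM records could not be joined to the annotation."""


class NoReferenceChannelsError(TmtdiffError, ValueError):
    """Reference-channel normalization requested but no 'Norm' channels exist."""


class ContrastError(TmtdiffError, ValueError):
    """A contrast specification is invalid (e.g. weights do not sum to zero)."""


class SimulationConfigError(TmtdiffError, ValueError):
    """A simulation configuration violates its invariants."""
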