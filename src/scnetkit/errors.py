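"""Exception hierarchy shared across the package."""


class ScnetkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScnetkitError):
    """Input file or archive does not conform to the expected format."""


class ConsistencyError(ScnetkitError):
    """Components of a multi-file input disagree (e.g. matrix header vs sidecars)."""


class EmptyCategoryError(ScnetkitError):
    """A category file contained a header but no data rows."""


class TransportError(ScnetkitError):
    """An HTTP request or payload parse failed; message names the URL."""


class UnknownAccessionError(ScnetkitError):
    """The requested accession does not exist at the source."""


class InsufficientCellsError(ScnetkitError):
    """A statistical comparison was requested with an empty group."""


class EmptyNetworkError(ScnetkitError):
    """No marker gene could be mapped to a protein node."""


class ParameterError(ScnetkitError):
    """A parameter is incompatible with the data (e.g. perplexity >= n_cells)."""


class MissingPrerequisiteError(ScnetkitError):
    """A workflow step was requested before the step it depends on."""
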