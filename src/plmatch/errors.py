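"""Exception hierarchy for plmatch.

All errors derive from :class:`PlmatchError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the builtin it most resembles (``ValueError``/``RuntimeError``) so that
generic handling keeps working.
"""


class PlmatchError(Exception):
    """Base class for all plmatch errors."""


class FormatError(PlmatchError, ValueError):
    """A file does not have the expected columns or layout."""


class IntegrityError(PlmatchError, ValueError):
    """Input data violates a structural invariant (duplicate ids, a
    precursor mapped to two protein groups, ...)."""


class DesignError(PlmatchError, ValueError):
    """The study design does not support the requested operation
    (missing group, too few replicates, ...)."""


class PipelineOrderError(PlmatchError, RuntimeError):
    """A stage was invoked on a matrix whose provenance flags show the
    required upstream stage has not run (e.g. log2 before imputation)."""


class DegenerateFitError(PlmatchError, RuntimeError):
    """A model fit is impossible, e.g. every protein has zero residual
    variance."""


class ConfigurationError(PlmatchError, ValueError):
    """A pipeline configuration is incomplete or inconsistent."""
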