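"""Exception hierarchy for azfcnv.

Validation failures raise distinct, named exceptions so callers can react to
the specific problem (e.g. fall back to single-sample mode, or route a sample
to CALL_FAILED) instead of parsing messages.
"""


class AzfcError(Exception):
    """Base class for all azfcnv errors."""


class DefinitionError(AzfcError):
    """An amplicon-class definition set is internally inconsistent."""


class MissingControlClassError(DefinitionError):
    """No class is marked as a single-copy normalization control."""


class IntervalOverlapError(DefinitionError):
    """Two intervals of the same amplicon class overlap."""


class DuplicateSignatureError(DefinitionError):
    """Two catalog signatures share a copy vector; matching would be ambiguous."""


class UnknownClassError(DefinitionError):
    """A class label appears in the BED file but not in the config (or vice versa)."""


class SignatureKeyMismatchError(AzfcError):
    """A query copy vector does not cover exactly the catalog's class set."""


class NormalizationError(AzfcError):
    """Control-region depth is zero or negative; the sample cannot be normalized.

    At the cohort level this is encoded as a CALL_FAILED status rather than
    propagated as an exception.
    """


class CohortTooSmallError(AzfcError):
    """Median centering requested on fewer than three samples."""


class ManifestMismatchError(AzfcError):
    """Sample manifest does not cover the call set (or has duplicate/missing ids)."""


class CollinearDesignError(AzfcError):
    """The regression design matrix is rank-deficient."""


class StudyInputError(AzfcError):
    """A meta-analysis study estimate is degenerate or mis-ordered."""


class SimulationError(AzfcError):
    """Simulation spec is infeasible (unknown architecture, impossible frequency)."""


class DepthSourceError(AzfcError):
    """The depth source does not cover a contig required by the bin set."""
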