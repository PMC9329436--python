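"""Exception types shared across the pipeline."""


class CellHealthError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CellHealthError):
    """A table, panel, or feature vector does not match the expected schema."""


class CapacityError(CellHealthError):
    """A plate layout request exceeds the physical format."""


class IncompatibleHistogramError(CellHealthError):
    """Two histograms do not share bin edges (or kernel size mismatches)."""


class IncompleteSeriesError(CellHealthError):
    """A dose series is missing every replicate at some concentration."""


class DegenerateTrainingError(CellHealthError):
    """Classifier training requested on a single-class label set."""


class InsufficientDataError(CellHealthError):
    """Too few distinct concentrations for a dose-response fit."""


class IndeterminateFoldError(CellHealthError):
    """Both numerator and denominator of a fold change are censored."""
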