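"""Exception hierarchy shared across the package."""


class PairgrnError(Exception):
    """Base class for all pairgrn-specific errors."""


class UnderdeterminedFitError(PairgrnError, ValueError):
    """Fewer observations than the polynomial fit needs (m <= order + 1)."""


class DegenerateRegressorError(PairgrnError, ValueError):
    """Design matrix is (near-)rank-deficient, e.g. a constant regressor."""


class UndefinedCorrelationError(PairgrnError, ValueError):
    """Pearson correlation undefined because an input has zero variance."""


class UndefinedMetricError(PairgrnError, ValueError):
    """Ranking metric undefined, e.g. AUROC with a single-class label set."""


class InfeasibleCountsError(PairgrnError, ValueError):
    """In-degree count vector cannot be matched to the gene set."""
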