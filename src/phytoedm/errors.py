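"""Exception hierarchy for the phytoedm pipeline.

Every stage raises a subclass of :class:`PhytoEDMError`, so callers can
distinguish "this series cannot be forecast" (recoverable, e.g. skip the
Monte-Carlo trial) from programming errors.
"""


class PhytoEDMError(Exception):
    """Base class for all phytoedm errors."""


# --- embedding / forecasting ------------------------------------------------

class InsufficientLengthError(PhytoEDMError):
    """Series too short to build a single embedding vector."""


class InvalidDimensionError(PhytoEDMError):
    """Embedding dimension E < 1 (or otherwise nonsensical)."""


class InsufficientPredictionsError(PhytoEDMError):
    """Fewer than 3 valid (observed, predicted) pairs."""


class UndefinedCorrelationError(PhytoEDMError):
    """Pearson correlation undefined (zero variance in one of the pair sets)."""


class SeriesUnusableError(PhytoEDMError):
    """No embedding dimension in the scanned range admits a forecast."""


# --- surrogates -------------------------------------------------------------

class UndefinedClimatologyError(PhytoEDMError):
    """A calendar month has no non-missing observation."""


# --- assemblages ------------------------------------------------------------

class MemberNotFoundError(PhytoEDMError):
    """Requested taxon id absent from the community table."""


class EmptyAssemblageError(PhytoEDMError):
    """An assemblage needs at least one member."""


class PoolExhaustedError(PhytoEDMError):
    """Requested assemblage size exceeds the strategy's taxon pool."""


class InvalidStrategyError(PhytoEDMError):
    """Unknown sampling strategy, functional group, or size class."""


class UndefinedCVError(PhytoEDMError):
    """Coefficient of variation undefined (zero mean or < 2 observations)."""


class FilterTooAggressiveError(PhytoEDMError):
    """Exclusion filter would remove every taxon."""


# --- simulators -------------------------------------------------------------

class IntegrationDivergedError(PhytoEDMError):
    """Community-model state became non-finite during integration."""


# --- io ---------------------------------------------------------------------

class MalformedTableError(PhytoEDMError):
    """Abundance CSV is ragged or otherwise unparseable."""


class InvalidMetadataError(PhytoEDMError):
    """Metadata row missing, group outside vocabulary, or radius <= 0."""


class InvalidValueError(PhytoEDMError):
    """Negative or non-numeric abundance cell."""


class BrokenGridError(PhytoEDMError):
    """Month headers are not strictly consecutive."""
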