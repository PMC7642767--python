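"""Exception hierarchy shared across the toolkit."""


class CvalkitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CvalkitError, ValueError):
    """A configuration or input value violates an invariant."""


class EmptyInputError(CvalkitError, ValueError):
    """An operation received no data to work on."""


class NoPeakError(CvalkitError, RuntimeError):
    """Peak detection found no qualifying fluorescence peak."""


class ClassificationError(CvalkitError, RuntimeError):
    """No consistent sample/standard assignment of fluorescence peaks."""


class AmbiguityError(ClassificationError):
    """More than one consistent peak assignment; a different internal
    standard should be used rather than guessing."""


class DegenerateVarianceError(CvalkitError, ValueError):
    """A variance-based test received data with zero variance."""


class EstimationError(CvalkitError, RuntimeError):
    """A spectrum- or likelihood-based estimate could not be formed."""


class LambdaUnidentifiableError(EstimationError):
    """Pagel's lambda has no effect on a star phylogeny."""


class PipelineError(CvalkitError, RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""
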