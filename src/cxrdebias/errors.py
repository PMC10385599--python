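"""Exception hierarchy for the cxrdebias package."""


class CxrDebiasError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(CxrDebiasError):
    """A phantom or experiment specification violates its invariants."""


class InvalidProfileError(CxrDebiasError):
    """A site-bias profile is invalid (e.g. non-positive gamma)."""


class EmptyDatasetError(CxrDebiasError):
    """A dataset or manifest with zero usable rows was requested."""


class NoContentError(CxrDebiasError):
    """An all-black image was passed to an operation requiring content."""


class ShapeMismatchError(CxrDebiasError):
    """Two grids that must share a shape do not."""


class EmptyTrainingSetError(CxrDebiasError):
    """A model training routine received no training examples."""


class DegenerateFoldError(CxrDebiasError):
    """A cross-validation fold contains a single class only."""


class UndefinedAUCError(CxrDebiasError):
    """AUC requested for a score vector with a single class present."""


class PruningError(CxrDebiasError):
    """The pruning loop preconditions are violated."""


class ManifestError(CxrDebiasError):
    """A manifest file is malformed or inconsistent."""


class UnsupportedFormatError(CxrDebiasError):
    """An input file is in a format the package does not read."""
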