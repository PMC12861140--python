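"""Exception hierarchy shared across the pipeline stages."""


class IridensError(Exception):
    """Base class for all package-specific errors."""


# --- segmentation / masks -------------------------------------------------

class NoEdgesFound(IridensError):
    """Edge detection produced fewer than two candidate corneal contours."""


class DegenerateRegion(IridensError):
    """A required region of interest is empty."""


class MaskMismatch(IridensError):
    """Mask dimensions do not match the frame."""


class MaskOverlap(IridensError):
    """Region masks intersect; they must be pairwise disjoint."""


# --- densitometry / cohorts -----------------------------------------------

class EmptyInput(IridensError):
    """An aggregation received no records."""


# --- iris color -----------------------------------------------------------

class NotColorImage(IridensError):
    """A three-channel RGB image was expected."""


class CohortTooSmall(IridensError):
    """Robust normalization needs at least four eyes."""


class ZeroIQR(IridensError):
    """A component's interquartile range is zero; normalization undefined."""


# --- statistics -----------------------------------------------------------

class DegenerateVariance(IridensError):
    """A correlation input has zero variance."""


class LengthMismatch(IridensError):
    """Paired inputs differ in length."""


class TooFewSubjects(IridensError):
    """Mixed-model fitting needs at least three subjects."""


class EmptyGroup(IridensError):
    """A two-group comparison received an empty group."""


class NonpositiveReference(IridensError):
    """Relative bias needs a strictly positive reference mean."""


# --- synthetic data -------------------------------------------------------

class SpecInvalid(IridensError):
    """A generator specification violates its invariants."""
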