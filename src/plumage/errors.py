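"""Exception and warning types shared across the package."""


class PlumageError(Exception):
    """Base class for all package errors."""


class GridMismatchError(PlumageError):
    """Spectra do not share a wavelength grid (no silent interpolation)."""


class CoverageError(PlumageError):
    """Wavelength coverage does not span the required interval."""


class PatchMismatchError(PlumageError):
    """Paired spectra do not refer to the same plumage patch."""


class DomainSizeError(PlumageError):
    """Scene geometry does not fit inside the simulation domain."""


class ConvergenceError(PlumageError):
    """Iterative computation failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitError(PlumageError):
    """Curve fit failed."""


class MissingWeightError(PlumageError):
    """Pigment specimens lack sample weights."""

    def __init__(self, specimens):
        super().__init__(f"missing sample weight for specimens: {sorted(specimens)}")
        self.specimens = list(specimens)


class AmbiguousFamilyError(PlumageError):
    """An accurate mass matches more than one pigment family."""


class InsufficientDataError(PlumageError):
    """Too few observations for the requested statistic."""


class TreeError(PlumageError):
    """Invalid phylogeny (negative branch lengths, duplicate tips, ...)."""


class RankError(PlumageError):
    """Design matrix is rank deficient or a column is constant."""


class ResolutionWarning(UserWarning):
    """FDTD mesh does not resolve lambda/20 in the densest material."""


class RegionWarning(UserWarning):
    """A power-monitor region lies outside the structure bounding box."""


class HalfMaxWarning(UserWarning):
    """No leftward half-maximum crossing; width falls back to lambda_max - lambda_min."""


class ESSWarning(UserWarning):
    """Effective sample size of an MCMC chain is below the advisory threshold."""
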