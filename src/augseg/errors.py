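"""Exception types shared across the package."""


class AugsegError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(AugsegError, ValueError):
    """Two objects expected on the same voxel grid are not."""


class FormatError(AugsegError, ValueError):
    """A file's on-disk contents violate the expected format."""


class InversionError(AugsegError, RuntimeError):
    """Numerical inversion of a spatial transform failed to converge.

    Carries the final residual (in voxel units) so callers can report
    how far from the tolerance the fixed-point iteration stopped.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class PhantomGenerationError(AugsegError, RuntimeError):
    """A synthetic phantom could not be generated under its constraints."""
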