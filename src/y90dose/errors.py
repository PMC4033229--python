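"""Exception hierarchy.

Every error raised by this package derives from :class:`Y90DoseError`, so
callers (and the CLI) can catch one type.  Subclasses mirror the failure
modes of the pipeline: bad physics parameters, geometry mismatches between
grids and kernels, unit problems, and malformed external files.
"""


class Y90DoseError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(Y90DoseError, ValueError):
    """A physics or configuration parameter is outside its valid domain."""


class InvalidInputError(Y90DoseError, ValueError):
    """An input object violates a precondition (e.g. unnormalized spectrum)."""


class RangeTruncationError(Y90DoseError, ValueError):
    """Kernel support radius is smaller than the endpoint-energy CSDA range."""


class InconsistentKernelError(Y90DoseError, ValueError):
    """Energy-balance closure failed: off-center voxels already carry more
    than the mean energy per decay, so the self-dose would be negative."""


class KernelParseError(Y90DoseError, ValueError):
    """A tabulated radial-kernel file is malformed (non-monotone radii,
    negative dose, wrong column count)."""


class GeometryError(Y90DoseError, ValueError):
    """Grid/kernel/VOI geometries are incompatible (voxel-size mismatch,
    sphere outside the grid, anisotropic voxels without resampling)."""


class UnitsError(Y90DoseError, ValueError):
    """Voxel values carry unknown or non-convertible units."""


class DataQualityError(Y90DoseError, ValueError):
    """Input voxel data fails a sanity bound (large negative activity)."""


class UnknownNuclideError(Y90DoseError, KeyError):
    """Requested radionuclide is not in the registry."""


class InvalidVoiError(Y90DoseError, ValueError):
    """A volume of interest selects no voxels."""


class BinningMismatchError(Y90DoseError, ValueError):
    """Two DVHs cannot be compared because their bin edges differ."""


class MetadataError(Y90DoseError, ValueError):
    """Required acquisition metadata (timing, units) missing and not
    supplied via overrides."""


class ConfigError(Y90DoseError, ValueError):
    """Pipeline configuration is inconsistent or incomplete."""
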