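"""Exception types shared across the holoxylem pipeline stages."""


class HoloxylemError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(HoloxylemError, ValueError):
    """Beamline geometry is unphysical (e.g. sample behind the detector)."""


class InvalidSpecError(HoloxylemError, ValueError):
    """A phantom specification does not fit the requested grid."""


class InvalidFlatError(HoloxylemError, ValueError):
    """Flat-field frame contains non-positive intensities."""


class CannotRefineError(HoloxylemError, RuntimeError):
    """Geometry refinement failed (featureless hologram)."""


class CannotAlignError(HoloxylemError, RuntimeError):
    """Projection alignment / rotation-centre search failed."""


class TopologyError(HoloxylemError, RuntimeError):
    """Segmented void does not have the expected pit-pair topology."""


class MeasurementError(HoloxylemError, RuntimeError):
    """A morphometric measurement could not be taken (e.g. no contrast)."""
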