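"""Typed exceptions and warnings used across the package."""


class ChromosteerError(Exception):
    """Base class for package errors."""


class FormatError(ChromosteerError, ValueError):
    """A file or record violates its format contract."""


class RangeError(ChromosteerError, IndexError):
    """An index or coordinate falls outside its valid range."""


class DegenerateDataError(ChromosteerError, ValueError):
    """Input data cannot support the requested statistical operation."""


class SimulationError(ChromosteerError, RuntimeError):
    """The integrator became unstable (bond over-extension or blow-up)."""


class PlacementError(ChromosteerError, RuntimeError):
    """Chromosome placement failed; typically the nucleus is too crowded."""


class ConvergenceWarning(UserWarning):
    """An iterative procedure stopped before reaching its tolerance."""
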